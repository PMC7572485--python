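import numpy as np
import pytest
from scipy.stats import ortho_group

from _oracles import best_alignment_bruteforce
from mstates import (
    EEGRecording,
    ModifiedKMeans,
    ParameterError,
    SyntheticSpec,
    align_maps,
    backfit,
    fit_cohort,
    generate_subject,
    gfp_curve,
    modified_kmeans,
    select_k_kl,
)
from mstates.cluster import MicrostateModel, _normalize_rows

from conftest import switch_distance_mask


def orthogonal_maps(k, p, seed=0):
    q = ortho_group.rvs(p, random_state=seed)[:k]
    return _normalize_rows(q)


class TestGFP:
    def test_gfp_matches_spatial_standard_deviation(self):
        rec = EEGRecording(np.array([[1.0, 2.0], [-1.0, -2.0]]), 100.0, ["a", "b"])
        gfp, _ = gfp_curve(rec)
        assert gfp == pytest.approx([1.0, 2.0])

    def test_constant_topography_has_zero_gfp(self):
        rec = EEGRecording(np.zeros((4, 10)), 100.0, list("abcd"))
        gfp, peaks = gfp_curve(rec)
        assert np.all(gfp == 0)
        assert len(peaks) == 0

    def test_gfp_is_polarity_invariant(self, synth_subject):
        rec = synth_subject.recording
        flipped = EEGRecording(-rec.data, rec.fs, rec.labels)
        assert np.allclose(gfp_curve(rec)[0], gfp_curve(flipped)[0])


class TestModifiedKMeans:
    def test_exact_recovery_of_orthogonal_maps(self):
        maps = orthogonal_maps(4, 16, seed=1)
        X = np.repeat(maps, 50, axis=0)
        model = modified_kmeans(X, 4, n_init=10, seed=0)
        perm, signs, corr = align_maps(maps, model)
        assert np.abs(corr[np.arange(4), perm]).min() > 1 - 1e-9
        assert model.gev == pytest.approx(1.0, abs=1e-9)

    def test_polarity_invariance_of_recovered_maps(self):
        maps = orthogonal_maps(3, 12, seed=2)
        X = np.repeat(maps, 30, axis=0)
        a = modified_kmeans(X, 3, n_init=5, seed=1)
        b = modified_kmeans(-X, 3, n_init=5, seed=1)
        perm, _, corr = align_maps(a, b)
        assert np.abs(corr[np.arange(3), perm]).min() > 1 - 1e-9

    def test_parameter_recovery_on_noisy_synthetic_eeg(self, synth_subject):
        from mstates import gfp_peak_maps

        obs = gfp_peak_maps(synth_subject.recording)
        model = modified_kmeans(obs, 4, n_init=20, seed=0)
        perm, _, corr = align_maps(synth_subject.maps, model)
        assert np.abs(corr[np.arange(4), perm]).mean() >= 0.95

    def test_fixed_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((200, 16))
        a = ModifiedKMeans(n_clusters=3, n_init=20, random_state=9).fit(X)
        b = ModifiedKMeans(n_clusters=3, n_init=20, random_state=9).fit(X)
        assert np.array_equal(a.maps_, b.maps_)
        assert a.gev_ == b.gev_

    def test_gev_nondecreasing_in_k(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((300, 16))
        gevs = [modified_kmeans(X, k, n_init=10, seed=0).gev for k in (2, 3, 4, 5)]
        assert all(b >= a - 1e-6 for a, b in zip(gevs[:-1], gevs[1:]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ParameterError):
            modified_kmeans(np.eye(3), 4)

    def test_sklearn_param_interface(self):
        est = ModifiedKMeans(n_clusters=5)
        assert est.get_params()["n_clusters"] == 5
        est.set_params(n_clusters=3)
        assert est.n_clusters == 3


class TestSelectK:
    def test_dispersion_decreases_on_separable_data(self):
        maps = orthogonal_maps(4, 16, seed=3)
        rng = np.random.default_rng(3)
        X = np.repeat(maps, 50, axis=0) + 0.05 * rng.standard_normal((200, 16))
        curve = select_k_kl(X, range(2, 7), n_init=5, seed=0)
        assert np.all(np.diff(curve.W) < 1e-9)

    def test_two_map_data_selects_k_two(self):
        truth = generate_subject(
            SyntheticSpec(n_channels=32, k_true=2, duration_s=10.0, seed=11)
        )
        from mstates import gfp_peak_maps

        curve = select_k_kl(gfp_peak_maps(truth.recording), range(2, 7),
                            n_init=10, seed=0)
        assert curve.k_opt == 2

    def test_short_range_rejected(self):
        with pytest.raises(ParameterError):
            select_k_kl(np.random.default_rng(0).standard_normal((50, 8)),
                        range(2, 4))


class TestCohortAndAlignment:
    def test_identical_subjects_give_the_same_cohort_maps(self):
        maps = orthogonal_maps(3, 12, seed=6)
        models = [MicrostateModel(maps.copy(), 1.0) for _ in range(5)]
        cohort = fit_cohort(models, n_init=5, seed=0)
        perm, _, corr = align_maps(maps, cohort)
        assert np.abs(corr[np.arange(3), perm]).min() > 1 - 1e-9
        assert cohort.level == "cohort"

    def test_noisy_subject_maps_average_toward_truth(self):
        truth = orthogonal_maps(4, 24, seed=7)
        rng = np.random.default_rng(7)
        models = []
        for _ in range(12):
            noisy = _normalize_rows(truth + 0.05 * rng.standard_normal(truth.shape))
            models.append(MicrostateModel(noisy, 1.0))
        cohort = fit_cohort(models, n_init=10, seed=1)
        perm, _, corr = align_maps(truth, cohort)
        assert np.abs(corr[np.arange(4), perm]).min() >= 0.99

    def test_alignment_matches_bruteforce_over_all_permutations(self):
        rng = np.random.default_rng(8)
        a = _normalize_rows(rng.standard_normal((4, 10)))
        b = _normalize_rows(rng.standard_normal((4, 10)))
        perm, signs, corr = align_maps(a, b)
        brute_perm, brute_score = best_alignment_bruteforce(corr)
        assert sum(abs(corr[i, perm[i]]) for i in range(4)) == pytest.approx(brute_score)
        assert np.all(signs * corr[np.arange(4), perm] >= 0)

    def test_reversed_and_flipped_model_aligns_back(self):
        maps = orthogonal_maps(4, 10, seed=9)
        other = MicrostateModel(-maps[::-1].copy(), 1.0)
        perm, signs, corr = align_maps(MicrostateModel(maps, 1.0), other)
        assert list(perm) == [3, 2, 1, 0]
        aligned_r = signs * corr[np.arange(4), perm]
        assert np.allclose(aligned_r, 1.0)

    def test_self_alignment_is_identity(self):
        maps = orthogonal_maps(4, 10, seed=10)
        model = MicrostateModel(maps, 1.0)
        perm, signs, _ = align_maps(model, model)
        assert list(perm) == [0, 1, 2, 3]
        assert list(signs) == [1, 1, 1, 1]


class TestBackfit:
    def test_single_map_modulation_labels_constant(self):
        maps = orthogonal_maps(3, 12, seed=12)
        c = np.sin(np.linspace(0.1, 6, 500)) + 1.5  # never zero
        rec = EEGRecording(np.outer(maps[1], c), 250.0,
                           [f"c{i}" for i in range(12)])
        model = MicrostateModel(maps, 1.0)
        seq = backfit(rec, model)
        assert np.all(seq.labels == 1)

    def test_polarity_invariance(self, synth_subject):
        rec = synth_subject.recording
        model = MicrostateModel(synth_subject.maps, 1.0)
        flipped = EEGRecording(-rec.data, rec.fs, rec.labels)
        assert np.array_equal(backfit(rec, model).labels,
                              backfit(flipped, model).labels)

    def test_ground_truth_recovery_away_from_switches(self, synth_subject):
        model = MicrostateModel(synth_subject.maps, 1.0)
        seq = backfit(synth_subject.recording, model)
        mask = switch_distance_mask(synth_subject.state_sequence,
                                    synth_subject.recording.fs, 10.0)
        agree = np.mean(seq.labels[mask] == synth_subject.state_sequence[mask])
        assert agree >= 0.90

    def test_min_duration_smoothing_removes_short_runs(self):
        maps = orthogonal_maps(2, 8, seed=13)
        labels_true = np.array([0] * 50 + [1] * 2 + [0] * 50 + [1] * 40)
        rec = EEGRecording(maps[labels_true].T * 10.0, 250.0,
                           [f"c{i}" for i in range(8)])
        model = MicrostateModel(maps, 1.0)
        smoothed = backfit(rec, model, min_duration_ms=20.0)  # 5 samples
        from mstates.cluster import runs_of

        assert all(l >= 5 for _, l, _ in runs_of(smoothed.labels))
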