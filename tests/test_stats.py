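import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from _oracles import mannwhitney_exact_p
from mstates import (
    DegenerateSequenceError,
    LabelSequence,
    ParameterError,
    mann_whitney_z,
    sequence_stats,
    tanova,
    two_way_anova,
    u_to_z,
)
from mstates.cluster import _normalize_rows


class TestSequenceStats:
    def test_hand_enumerated_example(self):
        # A A A A B B A A C C C C at 250 Hz
        seq = LabelSequence(np.array([0] * 4 + [1] * 2 + [0] * 2 + [2] * 4), 250.0)
        st_ = sequence_stats(seq)
        assert st_.coverage == pytest.approx([0.5, 1 / 6, 1 / 3])
        # interior runs: BB (8 ms) and AA (8 ms); C has none
        assert st_.mean_duration_ms[0] == pytest.approx(8.0)
        assert st_.mean_duration_ms[1] == pytest.approx(8.0)
        assert np.isnan(st_.mean_duration_ms[2])
        assert st_.missing_duration_classes == [2]
        expected = np.zeros((3, 3))
        expected[0, 1] = expected[1, 0] = expected[0, 2] = 1 / 3
        assert st_.transition_matrix == pytest.approx(expected)

    def test_alternating_sequence(self):
        seq = LabelSequence(np.tile([0, 1], 50), 100.0)
        st_ = sequence_stats(seq)
        assert st_.coverage == pytest.approx([0.5, 0.5])
        assert st_.transition_matrix[0, 1] == pytest.approx(0.5, abs=0.01)
        assert st_.transition_matrix[1, 0] == pytest.approx(0.5, abs=0.01)

    def test_single_run_is_degenerate(self):
        with pytest.raises(DegenerateSequenceError):
            sequence_stats(LabelSequence(np.zeros(100, dtype=int), 100.0))

    def test_truncated_runs_can_be_included(self):
        seq = LabelSequence(np.array([0] * 10 + [1] * 10), 1000.0)
        st_ = sequence_stats(seq, exclude_truncated=False)
        assert st_.mean_duration_ms == pytest.approx([10.0, 10.0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=300))
    def test_normalization_invariants_on_random_sequences(self, labels):
        labels = np.array(labels)
        if len(np.unique(labels)) < 2:
            labels = np.r_[labels, (labels[0] + 1) % 4]  # force a transition
        st_ = sequence_stats(LabelSequence(labels, 250.0))
        assert st_.coverage.sum() == pytest.approx(1.0, abs=1e-9)
        assert st_.transition_matrix.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diag(st_.transition_matrix) == 0)
        assert np.all(st_.transition_matrix >= 0)


class TestMannWhitney:
    def test_published_z_from_u_381_at_26_21(self):
        assert round(u_to_z(381, 26, 21), 2) == 2.30

    def test_symmetric_samples_give_zero_z(self):
        res = mann_whitney_z([1, 2], [1, 2])
        assert res.statistic == 2.0  # n1*n2/2
        assert res.z == 0.0
        assert res.p == 1.0

    def test_u_statistic_matches_scipy(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        res = mann_whitney_z(x, y)
        assert res.statistic == mannwhitneyu(x, y).statistic

    @pytest.mark.parametrize("n1,n2", [(5, 5), (6, 5), (7, 6), (8, 8)])
    def test_normal_approximation_close_to_exact_enumeration(self, n1, n2):
        """At >= 5 per group the continuity/tie-corrected normal
        approximation stays within 0.02 of the exact p for every U."""
        from _oracles import exact_two_sided_p
        from scipy.stats import norm

        for observed in range(n1 * n2 + 1):
            approx = min(1.0, 2 * norm.sf(abs(u_to_z(observed, n1, n2))))
            exact = exact_two_sided_p(n1, n2, observed)
            assert abs(approx - exact) < 0.02, (observed, approx, exact)

    def test_exact_p_for_fully_separated_triples(self):
        assert mannwhitney_exact_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        # normal approximation lands within 0.02 even at this tiny size
        assert abs(mann_whitney_z([1, 2, 3], [4, 5, 6]).p - 0.1) < 0.02

    def test_identical_values_are_degenerate(self):
        res = mann_whitney_z([3, 3, 3], [3, 3])
        assert res.p == 1.0


def _rss(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def _design(df, terms):
    cols = [np.ones(len(df))]
    if "a" in terms:
        cols.append((df.fa == df.fa.unique()[1]).to_numpy(float))
    if "b" in terms:
        cols.append((df.fb == df.fb.unique()[1]).to_numpy(float))
    if "ab" in terms:
        cols.append(cols[1] * cols[2])
    return np.column_stack(cols)


class TestTwoWayAnova:
    @staticmethod
    def frame(values, na, nb):
        rows = []
        for i, j in itertools.product(range(na), range(nb)):
            for v in values[(i, j)]:
                rows.append({"fa": f"a{i}", "fb": f"b{j}", "value": v})
        return pd.DataFrame(rows)

    def test_all_equal_values_give_f_zero_p_one(self):
        df = self.frame({(i, j): [5.0, 5.0] for i in range(2) for j in range(2)}, 2, 2)
        res = two_way_anova(df, factors=("fa", "fb"))
        for term in res.values():
            assert term.statistic == 0.0
            assert term.p == 1.0

    def test_balanced_design_matches_hand_computed_sums_of_squares(self):
        # cell means 0/2 along A, 0/4 along B, no interaction, two exact
        # replicates offset by ±1 -> SSE = 8 on 4 d.f.
        cells = {(0, 0): [0 - 1, 0 + 1], (0, 1): [4 - 1, 4 + 1],
                 (1, 0): [2 - 1, 2 + 1], (1, 1): [6 - 1, 6 + 1]}
        df = self.frame(cells, 2, 2)
        res = two_way_anova(df, factors=("fa", "fb"))
        # SS_A = 8*(1)^2 = 8, SS_B = 8*(2)^2 = 32, SS_AB = 0, MSE = 8/4 = 2
        assert res["fa"].statistic == pytest.approx(8 / 2)
        assert res["fb"].statistic == pytest.approx(32 / 2)
        assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_type_ii_matches_projection_oracle(self):
        rng = np.random.default_rng(2)
        cells = {(0, 0): list(rng.normal(0, 1, 7)), (0, 1): list(rng.normal(1, 1, 3)),
                 (1, 0): list(rng.normal(2, 1, 4)), (1, 1): list(rng.normal(1.5, 1, 6))}
        df = self.frame(cells, 2, 2)
        res = two_way_anova(df, factors=("fa", "fb"))
        y = df.value.to_numpy()
        n = len(df)
        rss_full = _rss(_design(df, ("a", "b", "ab")), y)
        ss_a = _rss(_design(df, ("b",)), y) - _rss(_design(df, ("a", "b")), y)
        ss_b = _rss(_design(df, ("a",)), y) - _rss(_design(df, ("a", "b")), y)
        ss_ab = _rss(_design(df, ("a", "b")), y) - rss_full
        mse = rss_full / (n - 4)
        assert res["fa"].statistic == pytest.approx(ss_a / mse)
        assert res["fb"].statistic == pytest.approx(ss_b / mse)
        assert res["interaction"].statistic == pytest.approx(ss_ab / mse)

    def test_empty_cell_is_rejected_with_advice(self):
        df = self.frame({(0, 0): [1.0, 2.0], (0, 1): [1.0],
                         (1, 0): [2.0, 1.0], (1, 1): []}, 2, 2)
        with pytest.raises(ParameterError, match="drop"):
            two_way_anova(df, factors=("fa", "fb"))


class TestTanova:
    def test_exchangeable_groups_are_not_significant(self):
        rng = np.random.default_rng(3)
        base = _normalize_rows(rng.standard_normal((20, 16)))
        res = tanova(base[:10], base[10:], n_perm=199, seed=0)
        assert res.p > 0.05

    def test_strong_separation_reaches_the_p_floor(self):
        rng = np.random.default_rng(4)
        ta = _normalize_rows(rng.standard_normal((1, 16)))[0]
        tb_raw = rng.standard_normal(16)
        tb = tb_raw - (tb_raw @ ta) * ta
        tb /= np.linalg.norm(tb)
        a = _normalize_rows(ta + 0.05 * rng.standard_normal((10, 16)))
        b = _normalize_rows(tb + 0.05 * rng.standard_normal((10, 16)))
        res = tanova(a, b, n_perm=999, seed=1)
        assert res.p == pytest.approx(0.001)

    def test_statistic_invariant_to_subject_order(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((8, 12))
        b = rng.standard_normal((8, 12))
        s1 = tanova(a, b, n_perm=9, seed=0).statistic
        s2 = tanova(a[::-1], b[::-1], n_perm=9, seed=0).statistic
        assert s1 == pytest.approx(s2)

    def test_null_p_values_are_roughly_uniform(self):
        rng = np.random.default_rng(6)
        template = _normalize_rows(rng.standard_normal((1, 12)))[0]
        hits = 0
        reps = 200
        for i in range(reps):
            maps = _normalize_rows(
                template + 0.5 * rng.standard_normal((12, 12))
            )
            p = tanova(maps[:6], maps[6:], n_perm=199, seed=100 + i).p
            hits += p <= 0.05
        assert 0.01 <= hits / reps <= 0.10

    def test_small_groups_rejected(self):
        with pytest.raises(ParameterError):
            tanova(np.ones((1, 8)), np.ones((4, 8)))
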