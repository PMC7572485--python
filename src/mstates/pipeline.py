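"""End-to-end orchestration: manifest in, per-subject and group results out.

The pipeline mirrors the standard microstate study design: preprocess
each subject, cluster topographies at GFP peaks into subject-level maps,
re-cluster pooled subject maps into cohort-level maps per group, align
cohort maps across groups, backfit every recording against its cohort's
maps, and derive sequence statistics, complexity and θRP per subject,
group-level tests, and a cross-validated (θRP, C) classifier.

Subject failures are recorded and skipped; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cl
from .classify import crossval_svm
from .complexity import microstate_lzc, omega_complexity, timeseries_lzc
from .config import PipelineConfig
from .io import preprocess, read_edf, read_matrix_text
from .recording import EEGRecording
from .spectral import theta_relative_power
from .stats import mann_whitney_z, sequence_stats, tanova, two_way_anova

log = logging.getLogger("mstates")


def load_recording(path, fs=None, labels=None) -> EEGRecording:
    """Read a recording by extension: .edf or a delimited text matrix."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if fs is None:
        raise ValueError(f"{path.name}: text input needs an explicit fs")
    if labels is None:
        with open(path) as fh:
            n_rows = sum(1 for line in fh if line.strip())
        labels = [f"CH{i + 1:02d}" for i in range(n_rows)]
    return read_matrix_text(path, fs=fs, labels=labels)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(manifest, config: PipelineConfig | None = None,
                 out_dir=None, text_fs: float | None = None) -> dict:
    """Run the full analysis over a manifest of recordings.

    ``manifest`` is a DataFrame or CSV path with columns
    ``subject_id, path, group``.  Returns a results dict (also written as
    JSON/CSV under ``out_dir`` when given).  ``text_fs`` supplies the
    sampling rate for delimited-text inputs.
    """
    if config is None:
        config = PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    cc, pc = config.clustering, config.preprocessing
    results: dict = {"config": config.to_dict(), "config_hash": config.hash,
                     "failures": [], "subjects": {}}

    # -- per-subject preprocessing and subject-level maps ------------------
    subjects = {}
    for row in manifest.itertuples(index=False):
        sid = str(row.subject_id)
        try:
            rec = load_recording(row.path, fs=text_fs)
            rec.subject_id, rec.group = sid, str(row.group)
            rec = preprocess(rec, band=pc.band, target_fs=pc.target_fs,
                             epoch_length_s=pc.epoch_length_s)
            obs = cl.gfp_peak_maps(rec) if cc.gfp_peaks_only else rec.data.T
            if cc.select_k:
                curve = cl.select_k_kl(obs, range(cc.k_range[0], cc.k_range[1] + 1),
                                       n_init=cc.n_init, seed=cc.seed)
                k = curve.k_opt
            else:
                k = cc.k
            model = cl.modified_kmeans(obs, k, n_init=cc.n_init, seed=cc.seed)
            model.channel_labels = list(rec.labels)
            subjects[sid] = {"rec": rec, "obs": obs, "model": model,
                             "group": str(row.group)}
        except Exception as exc:
            log.warning("subject %s failed: %s", sid, exc)
            results["failures"].append({"subject_id": sid, "error": str(exc)})

    if not subjects:
        raise RuntimeError("no subject could be processed")

    # cohort k must be shared: take the fixed k (or the median selected k)
    k_cohort = int(np.median([s["model"].k for s in subjects.values()]))
    for s in subjects.values():
        if s["model"].k != k_cohort:
            s["model"] = cl.modified_kmeans(s["obs"], k_cohort,
                                            n_init=cc.n_init, seed=cc.seed)
            s["model"].channel_labels = list(s["rec"].labels)

    # -- cohort-level maps per group, aligned to the first cohort ----------
    groups = sorted({s["group"] for s in subjects.values()})
    cohorts = {}
    for g in groups:
        models = [s["model"] for s in subjects.values() if s["group"] == g]
        cohorts[g] = cl.fit_cohort(models, k=k_cohort, n_init=cc.n_init,
                                   seed=cc.seed)
    ref = groups[0]
    alignments = {}
    for g in groups[1:]:
        perm, signs, corr = cl.align_maps(cohorts[ref], cohorts[g])
        cohorts[g].maps = signs[:, None] * cohorts[g].maps[perm]
        alignments[g] = {"permutation": perm.tolist(), "signs": signs.tolist(),
                         "correlation": corr.tolist()}
    if k_cohort == 4:
        try:
            names = cl.assign_canonical_names(cohorts[ref])
            for g in groups[1:]:
                cohorts[g].names = list(names)
        except Exception as exc:  # montage positions unavailable for labels
            log.info("canonical A-D naming skipped: %s", exc)

    # -- per-subject sequence statistics, complexity, spectral features ----
    feature_rows, duration_rows, class_maps = [], [], {g: {} for g in groups}
    for sid, s in subjects.items():
        try:
            rec, g = s["rec"], s["group"]
            seq = cl.backfit(rec, cohorts[g], min_duration_ms=cc.min_duration_ms)
            st = sequence_stats(seq)
            C = microstate_lzc(seq, collapse=config.complexity.collapse_runs,
                               normalize=config.complexity.normalize)
            trp = theta_relative_power(rec, theta=config.spectral.theta,
                                       total=config.spectral.total)
            feature_rows.append({
                "subject_id": sid, "group": g, "theta_rp": trp.theta_rp,
                "C": C, "omega": omega_complexity(rec),
                "ts_lzc": timeseries_lzc(rec),
                "grand_mean_duration_ms": st.grand_mean_duration_ms,
            })
            for c in range(st.n_classes):
                duration_rows.append({
                    "subject_id": sid, "group": g, "ms_class": c,
                    "mean_duration_ms": st.mean_duration_ms[c],
                    "coverage": st.coverage[c],
                })
            # subject map best matched to each cohort class, for TANOVA
            perm, signs, _ = cl.align_maps(cohorts[g], s["model"])
            for c in range(k_cohort):
                class_maps[g].setdefault(c, []).append(
                    signs[c] * s["model"].maps[perm[c]]
                )
            results["subjects"][sid] = {
                "group": g, "gev": s["model"].gev,
                "stats": dataclasses.asdict(st),
            }
        except Exception as exc:
            log.warning("subject %s failed downstream: %s", sid, exc)
            results["failures"].append({"subject_id": sid, "error": str(exc)})

    features = pd.DataFrame(feature_rows)
    durations = pd.DataFrame(duration_rows)
    results["features"] = feature_rows

    # -- group statistics and classification -------------------------------
    group_sizes = features.groupby("group").size() if len(features) else pd.Series(dtype=int)
    two = [g for g in groups if group_sizes.get(g, 0) >= 2]
    if len(two) == 2:
        ga, gb = two
        tests = {}
        try:
            anova = two_way_anova(durations.dropna(), value="mean_duration_ms")
            tests["duration_anova"] = {k: dataclasses.asdict(v)
                                       for k, v in anova.items()}
        except Exception as exc:
            log.warning("duration ANOVA skipped: %s", exc)
        for col in ("grand_mean_duration_ms", "C", "theta_rp"):
            a = features.loc[features.group == ga, col].dropna()
            b = features.loc[features.group == gb, col].dropna()
            tests[f"mwu_{col}"] = dataclasses.asdict(mann_whitney_z(a, b))
        tests["tanova"] = {}
        for c in range(k_cohort):
            if len(class_maps[ga].get(c, [])) >= 2 and len(class_maps[gb].get(c, [])) >= 2:
                res = tanova(np.array(class_maps[ga][c]),
                             np.array(class_maps[gb][c]),
                             seed=config.classifier.seed)
                tests["tanova"][str(c)] = dataclasses.asdict(res)
        results["group_tests"] = tests
        try:
            cm, folds = crossval_svm(
                features, folds=config.classifier.folds,
                kernel=config.classifier.kernel, seed=config.classifier.seed,
                positive=config.classifier.positive, C=config.classifier.C,
            )
            results["classifier_cv"] = {"metrics": cm.as_dict(), "folds": folds}
        except Exception as exc:
            log.warning("classifier CV skipped: %s", exc)

    results["cohort_models"] = {
        g: {"k": m.k, "gev": m.gev, "maps": m.maps.tolist(),
            "names": m.names, "channel_labels": m.channel_labels}
        for g, m in cohorts.items()
    }
    results["alignments"] = alignments

    if out_dir is not None:
        features.to_csv(out_dir / "features.csv", index=False)
        durations.to_csv(out_dir / "sequence_stats.csv", index=False)
        (out_dir / "results.json").write_text(
            json.dumps(results, default=_json_default, indent=1, sort_keys=True)
        )
        config.to_yaml(out_dir / "config.yaml")
    return results
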