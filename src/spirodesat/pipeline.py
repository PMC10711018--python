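"""End-to-end run: simulate -> segment -> extract -> select -> train -> DPI.

Every stage writes a deterministic artifact (segments JSON, feature TSV,
selection/model/DPI reports) stamped with the run seed and a hash of the
configuration, so a rerun with the same config reproduces every file
byte for byte.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import dpi as dpi_mod
from . import io as io_mod
from . import stats as stats_mod
from .errors import SpirodesatError
from .features import extract_feature_vector
from .io import RunConfig
from .registry import FEATURE_NAMES
from .segmentation import SegmentationConfig, segment_record
from .selection import (FeatureMatrix, SelectionResult, fit_evaluate,
                        filter_select, sbfs, sffs)
from .simulate import generate_cohort

logger = logging.getLogger("spirodesat")

__all__ = ["run_pipeline"]


def _segments_entry(segments) -> dict:
    return {"supine": [segments.supine.start, segments.supine.end],
            "trendelenburg": [segments.trendelenburg.start,
                              segments.trendelenburg.end]}


def _select(matrix: FeatureMatrix, cfg: RunConfig) -> SelectionResult:
    if cfg.selection_method == "sffs":
        return sffs(matrix, model_spec=cfg.selection_model,
                    max_k=cfg.k_features)
    if cfg.selection_method == "sbfs":
        return sbfs(matrix, model_spec=cfg.selection_model)
    if cfg.selection_method == "filter":
        return filter_select(matrix, cfg.filter_method, cfg.k_features)
    if cfg.selection_method == "none":
        return SelectionResult(method="none", selected=list(matrix.X.columns))
    raise ValueError(f"unknown selection method {cfg.selection_method!r}")


def _group_tables(matrix: FeatureMatrix, selected: list[str],
                  stats_cfg: stats_mod.StatsConfig) -> dict:
    """Per-feature split check (train vs test) and group check
    (normal vs desaturation on the held-out rows)."""
    out = {"train_vs_test": {}, "normal_vs_desat_test": {}}
    Xtr, ytr, _ = matrix.train_data(selected)
    Xte, yte = matrix.test_data(selected)

    def entry(a, b):
        if len(a) < 3 or len(b) < 3:
            return {"test": None, "p_value": None}
        r = stats_mod.group_compare(a, b, stats_cfg)
        return {"test": r.test, "p_value": r.p_value}

    for j, name in enumerate(selected):
        out["train_vs_test"][name] = entry(Xtr[:, j], Xte[:, j])
        out["normal_vs_desat_test"][name] = entry(Xte[yte == 0, j],
                                                  Xte[yte == 1, j])
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the artifact set under ``cfg.out_dir``."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash}
    stats_cfg = stats_mod.StatsConfig(n_boot=cfg.n_boot)
    seg_cfg = SegmentationConfig()

    logger.info("simulating cohort (%d normal / %d desaturation)",
                cfg.n_normal, cfg.n_desat)
    cohort = generate_cohort(cfg.n_normal, cfg.n_desat, seed=cfg.seed,
                             profile_overrides=dict(cfg.simulate))
    io_mod.write_manifest(cohort, out / "manifest.csv")
    if cfg.write_cases:
        case_dir = out / "cases"
        case_dir.mkdir(exist_ok=True)
        for rec in cohort.records:
            io_mod.write_case_csv(rec, case_dir / f"{rec.case_id}.csv")

    segments_json: dict = {}
    vectors = []
    for rec in cohort.records:
        try:
            segments = segment_record(rec, seg_cfg)
            vectors.append(extract_feature_vector(rec, segments))
        except SpirodesatError as e:
            raise SpirodesatError(
                f"stage failure on {rec.case_id}: {e}") from e
        segments_json[rec.case_id] = _segments_entry(segments)
    io_mod.write_json({"stamp": stamp, "segments": segments_json},
                      out / "segments.json")

    features = pd.DataFrame(vectors)
    features.index.name = "case_id"
    features.to_csv(out / "features.tsv", sep="\t")
    assert list(features.columns) == list(FEATURE_NAMES)

    matrix = FeatureMatrix.from_features(features, cohort.labels,
                                         cohort.split, seed=cfg.seed)

    logger.info("selecting features (%s)", cfg.selection_method)
    selection = _select(matrix, cfg)
    io_mod.write_json({"stamp": stamp, "method": selection.method,
                       "selected": selection.selected,
                       "score_trace": selection.score_trace},
                      out / "selection.json")

    logger.info("evaluating %d classifiers", len(cfg.models))
    evals = {spec: fit_evaluate(spec, matrix, selection)
             for spec in cfg.models}
    best_model = max(cfg.models,
                     key=lambda s: (evals[s].cv_mean_auroc, s))
    io_mod.write_json(
        {"stamp": stamp,
         "models": {s: {"cv_aurocs": e.cv_aurocs,
                        "cv_mean_auroc": e.cv_mean_auroc,
                        "test_auroc": e.test_auroc}
                    for s, e in evals.items()},
         "best_model": best_model},
        out / "models.json")

    group_tables = _group_tables(matrix, selection.selected, stats_cfg)

    logger.info("fitting DPI")
    train_X = features.loc[~matrix.test_mask, selection.selected]
    train_y = matrix.y[~matrix.test_mask]
    survivors = dpi_mod.lasso_select(train_X, train_y, seed=cfg.seed)
    model = dpi_mod.fit_dpi(train_X[survivors], train_y)
    test_X = features.loc[matrix.test_mask]
    test_y = matrix.y[matrix.test_mask]
    scores = dpi_mod.compute_dpi_matrix(model, test_X)
    point, ci = stats_mod.auroc_ci(scores, test_y, stats_cfg, seed=cfg.seed)
    perm_p = stats_mod.permutation_pvalue(scores, test_y,
                                          n_perm=cfg.n_permutations,
                                          seed=cfg.seed)
    thresholds = stats_mod.threshold_metrics(scores, test_y, stats_cfg)
    dpi_report = {
        "stamp": stamp,
        "wrapper_features": selection.selected,
        "lasso_survivors": survivors,
        "model": model.to_dict(),
        "test_auroc": point,
        "test_auroc_ci95": list(ci),
        "permutation_p": perm_p,
        "thresholds": thresholds.where(pd.notna(thresholds), None)
                                .to_dict(orient="records"),
        "group_tests": group_tables,
    }
    io_mod.write_json(dpi_report, out / "dpi_report.json")

    (out / "run_config.yaml").write_text(cfg.to_yaml())
    report = {
        "stamp": stamp,
        "n_cases": len(cohort),
        "n_desaturation": int(cohort.labels.sum()),
        "n_features": int(features.shape[1]),
        "selection": {"method": selection.method,
                      "selected": selection.selected},
        "best_model": best_model,
        "best_model_cv_auroc": evals[best_model].cv_mean_auroc,
        "best_model_test_auroc": evals[best_model].test_auroc,
        "dpi": {"survivors": survivors, "test_auroc": point,
                "ci95": list(ci), "permutation_p": perm_p},
    }
    io_mod.write_json(report, out / "report.json")
    return report
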