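"""End-to-end orchestration: simulate/ingest -> metrics -> fluctuation
profiles -> scale selection -> marker comparison -> cross-validation.

A single root seed fans out into named sub-seeds (cohort generation, fold
shuffling) so each stage is independently reproducible; every artifact
carries the seed and a hash of the resolved configuration, and an identical
configuration yields byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import classify, io, selection
from .dff import profile_matrix
from .exceptions import DffgluError, InputError
from .metrics import METRIC_NAMES, GlycemicMetricsExtractor
from .simulate import CohortConfig, synthesize_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineStageError", "run_full_analysis"]


@dataclass
class RunConfig:
    """Configuration of one full analysis run.

    Exactly one of (``cgm_csv`` + ``cohort_csv``) or ``sim`` must be
    supplied: real tabular inputs, or a synthetic-cohort specification.
    """

    cgm_csv: str | None = None
    cohort_csv: str | None = None
    sim: CohortConfig | None = None
    l_min: int = 2
    l_max: int = 130
    seed: int = 0
    folds: int = 10
    positive_class: str = "LADA"
    insulin_only: bool = False
    outdir: str | None = None

    def __post_init__(self):
        real = self.cgm_csv is not None and self.cohort_csv is not None
        if real == (self.sim is not None):
            raise InputError(
                "supply exactly one of (cgm_csv + cohort_csv) or sim")


class PipelineStageError(DffgluError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.manifest = manifest
        self.__cause__ = cause


def _sub_seeds(root: int, n: int = 2) -> list[int]:
    state = np.random.SeedSequence(root).generate_state(n, dtype=np.uint32)
    return [int(s) % (2 ** 31) for s in state]


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d.pop("outdir", None)  # the output location is not part of the analysis
    return d


def _config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _group_test(a: np.ndarray, b: np.ndarray) -> tuple[str, float]:
    """Shapiro-gated two-sample test: t-test when both groups look normal,
    Mann-Whitney U otherwise."""
    if min(len(a), len(b)) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return "mannwhitney", float(stats.mannwhitneyu(a, b).pvalue)
    normal = (stats.shapiro(a).pvalue > 0.05) and (stats.shapiro(b).pvalue > 0.05)
    if normal:
        return "ttest", float(stats.ttest_ind(a, b).pvalue)
    return "mannwhitney", float(stats.mannwhitneyu(a, b).pvalue)


def _cohort_summary(cohort, M: np.ndarray, fd: np.ndarray, l_star: int) -> pd.DataFrame:
    rows = []
    is_lada = cohort.labels == "LADA"
    variables = {"FCP_ng_ml": cohort.fcp, "2hCP_ng_ml": cohort.c2h}
    display = {"mean_glucose": "mean_glucose_mmol_l", "sd": "SD_mmol_l",
               "cv_percent": "CV_percent", "tir_percent": "TIR_percent",
               "mage": "MAGE_mmol_l"}
    for j, name in enumerate(METRIC_NAMES):
        variables[display[name]] = M[:, j]
    variables[f"Fd_{l_star}"] = fd
    for name, v in variables.items():
        a, b = v[is_lada], v[~is_lada]
        test, p = _group_test(a, b)
        rows.append({
            "variable": name,
            "lada_median": float(np.median(a)),
            "lada_q1": float(np.percentile(a, 25)),
            "lada_q3": float(np.percentile(a, 75)),
            "t2dm_median": float(np.median(b)),
            "t2dm_q1": float(np.percentile(b, 25)),
            "t2dm_q3": float(np.percentile(b, 75)),
            "test": test,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def run_full_analysis(config: RunConfig):
    """Run every stage and (if ``config.outdir`` is set) write all artifacts.

    Returns ``(report, manifest)`` where manifest maps artifact names to
    paths (empty when no outdir). Any stage failure raises
    :class:`PipelineStageError` naming the stage and listing the artifacts
    written so far.
    """
    manifest: dict[str, str] = {}
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = _config_dict(config)
    cfg_hash = _config_hash(cfg_dict)
    gen_seed, cv_seed = _sub_seeds(config.seed)
    stage = "configure"
    try:
        if outdir:
            p = outdir / "config.json"
            p.write_text(json.dumps(
                {"config": cfg_dict, "config_hash": cfg_hash, "seed": config.seed,
                 "sub_seeds": {"generation": gen_seed, "cv": cv_seed}},
                indent=2, sort_keys=True, default=str) + "\n")
            manifest["config"] = str(p)

        stage = "cohort"
        if config.sim is not None:
            sim_cfg = dataclasses.replace(config.sim, seed=gen_seed)
            cohort = synthesize_cohort(sim_cfg)
        else:
            traces = io.read_cgm_csv(config.cgm_csv)
            cohort = io.read_cohort_csv(config.cohort_csv, traces)
        if config.insulin_only:
            cohort = cohort.insulin_treated_only()
        logger.info("stage cohort: %d records (%d LADA, %d T2DM)", len(cohort),
                    int((cohort.labels == "LADA").sum()),
                    int((cohort.labels == "T2DM").sum()))

        stage = "metrics"
        M = GlycemicMetricsExtractor().fit_transform(cohort.traces)

        stage = "fluctuation"
        F = profile_matrix(cohort.traces, config.l_min, config.l_max)
        scales = np.arange(config.l_min, config.l_max + 1)

        stage = "scale_selection"
        curves = selection.select_optimal_scale(
            selection.correlation_curve(F, cohort, scales=scales))
        if outdir:
            p = outdir / "correlation_curve.csv"
            pd.DataFrame({"l": curves.scales, "r_fcp": curves.r_fcp,
                          "r_c2h": curves.r_c2h, "n_used": curves.n_used}
                         ).to_csv(p, index=False)
            manifest["correlation_curve"] = str(p)

        stage = "marker_comparison"
        report = classify.compare_markers(
            cohort, F=F, l_min=config.l_min, l_max=config.l_max,
            l_star=curves.l_star, metrics_matrix=M,
            positive_class=config.positive_class)
        report.r_star = curves.r_star

        stage = "cross_validation"
        counts = pd.Series(cohort.labels).value_counts()
        eff_folds = int(min(config.folds, counts.min()))
        warnings = []
        if eff_folds < config.folds:
            warnings.append(
                f"folds reduced from {config.folds} to {eff_folds} "
                f"(smallest class has {int(counts.min())} patients)")
        if eff_folds >= 2:
            folds, means, ci, cv_warn = classify.ten_fold_cv(
                cohort, F=F, l_min=config.l_min, l_max=config.l_max,
                seed=cv_seed, n_folds=eff_folds,
                positive_class=config.positive_class)
            report.cv_folds, report.cv_means, report.cv_ci = folds, means, ci
            warnings.extend(cv_warn)
        else:
            warnings.append("cross-validation skipped: fewer than 2 possible folds")
        report.warnings = warnings
        report.seed = config.seed
        report.config = {"config_hash": cfg_hash,
                         "n_patients": len(cohort),
                         "l_min": config.l_min, "l_max": config.l_max,
                         "folds": eff_folds,
                         "sub_seeds": {"generation": gen_seed, "cv": cv_seed}}

        stage = "artifacts"
        if outdir:
            fd = F[:, int(np.searchsorted(scales, curves.l_star))]
            p = outdir / "cohort_summary.csv"
            _cohort_summary(cohort, M, fd, curves.l_star).to_csv(p, index=False)
            manifest["cohort_summary"] = str(p)

            p = outdir / "markers.csv"
            pd.DataFrame([dataclasses.asdict(m) for m in report.markers]
                         ).to_csv(p, index=False)
            manifest["markers"] = str(p)

            p = outdir / "report.json"
            io.write_report(report, p)
            manifest["report"] = str(p)
            manifest["cv_folds"] = str(outdir / "report_folds.csv")
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError(stage, manifest, exc) from exc
    return report, manifest
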