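"""End-to-end biomarker discovery pipeline.

Stage order follows the study design of untargeted lipidomics biomarker
screens: preprocessing (impute, QC-RSD filter, TIC normalization), then
per pairwise comparison a Mann-Whitney screen (raw p < alpha), OPLS-DA
on the significant features (log10 intensities), VIP > 1 marker
selection, a logistic diagnostic model on the marker panel (raw-scale
intensities) with LOOCV sensitivity/specificity, and pathway
over-representation of the significant lipids.

All randomness (CV folds) flows from the single run seed; a fixed seed
yields byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .chemometrics import cross_validated_q2, fit_opls, select_markers
from .diagnostics import fit_logistic, loocv_performance
from .enrichment import enrich
from .enrichment import results_frame as _enrich_frame
from .feature_table import (FeatureTable, impute_halfmin, qc_rsd_filter,
                            read_table, tic_normalize)
from .synthetic import GroundTruth, SimulationConfig, preset_paper_design, simulate_cohort
from .univariate import differential_lipids
from .univariate import results_frame as _uni_frame

__all__ = ["PipelineConfig", "run_pipeline"]


class PipelineConfig(BaseModel):
    """One run = one config; the seed is mandatory."""

    table_path: str | None = None
    samples_path: str | None = None
    preset: str | None = None  # 'paper' simulates the default design
    comparisons: list[tuple[str, str]] = [
        ("control", "UF"), ("control", "RUF"), ("UF", "RUF")]
    alpha: float = Field(default=0.05, gt=0, le=1)
    tol_ppm: float = Field(default=10.0, gt=0)
    n_ortho: int = Field(default=1, ge=0)
    cv_folds: int = Field(default=7, ge=2)
    vip_threshold: float = Field(default=1.0, ge=0)
    logistic_threshold: float = Field(default=0.5, gt=0, lt=1)
    max_qc_rsd: float = Field(default=0.30, gt=0)
    seed: int
    outdir: str | None = None


def _load_input(config: PipelineConfig) -> tuple[FeatureTable, GroundTruth | None]:
    if config.preset == "paper":
        sim = preset_paper_design(seed=config.seed)
        return simulate_cohort(sim)
    if config.preset is not None:
        raise ValueError(f"unknown preset {config.preset!r}")
    if not config.table_path or not config.samples_path:
        raise ValueError("either a preset or table/samples paths are required")
    return read_table(config.table_path, config.samples_path), None


def _json_default(o):
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _dump_json(payload: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the machine-readable report.

    When ``config.outdir`` is set, the report (``report.json``) and the
    per-stage tables are also written there.
    """
    table, truth = _load_input(config)

    # preprocessing: impute -> QC filter -> TIC normalize
    n0 = table.n_features
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = impute_halfmin(table)
        table = qc_rsd_filter(table, max_rsd=config.max_qc_rsd)
    table = tic_normalize(table)

    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    background = sorted(
        str(a) for a in table.features["annotation"].dropna() if str(a))

    report: dict = {
        "provenance": {
            "tool": "lipidscreen",
            "version": __version__,
            "seed": config.seed,
            # hash covers the analysis parameters, not the output location
            "config_hash": hashlib.sha256(
                config.model_dump_json(exclude={"outdir"}).encode()
            ).hexdigest()[:16],
        },
        "preprocessing": {
            "features_in": int(n0),
            "features_out": int(table.n_features),
            "n_samples": int(table.n_samples),
        },
        "comparisons": {},
    }

    for group_a, group_b in config.comparisons:
        key = f"{group_a}_vs_{group_b}"
        cols_a = table.group_columns(group_a)
        cols_b = table.group_columns(group_b)

        # 1) univariate screen
        results = differential_lipids(table, group_a, group_b, alpha=config.alpha)
        sig_ids = [r.feature_id for r in results if r.significant]
        block: dict = {"n_features": int(table.n_features),
                       "n_significant": len(sig_ids)}

        if outdir:
            _uni_frame(results).to_csv(
                outdir / f"univariate_{key}.tsv", sep="\t", index=False)

        if len(sig_ids) >= 2:
            # 2) OPLS-DA on significant features, log10 intensities
            cols = cols_a + cols_b
            sub = table.subset_features(sig_ids)
            x = np.log10(sub.intensities[cols].to_numpy(dtype=float).T)
            y = np.array([0] * len(cols_a) + [1] * len(cols_b))
            model = fit_opls(x, y, n_ortho=config.n_ortho)
            model.feature_ids = sig_ids
            folds = min(config.cv_folds, len(cols))
            model.q2y = cross_validated_q2(
                x, y, folds=folds, seed=config.seed, n_ortho=config.n_ortho)
            model.cv_folds = folds
            model.cv_seed = config.seed
            block["opls"] = model.summary()

            # 3) VIP > 1 marker panel
            panel = select_markers(model, threshold=config.vip_threshold)
            vip = dict(zip(model.feature_ids, model.vip))
            block["vip_panel"] = [
                {"feature_id": fid,
                 "annotation": str(table.features.loc[fid, "annotation"]),
                 "vip": round(float(vip[fid]), 4)}
                for fid in panel
            ]

            if outdir:
                scores = np.column_stack([model.t, model.t_ortho])
                header = "sample_id\tgroup\tt_pred" + "".join(
                    f"\tt_ortho{i + 1}" for i in range(model.n_ortho))
                with open(outdir / f"opls_scores_{key}.tsv", "w") as fh:
                    fh.write(header + "\n")
                    for sid, g, row in zip(
                            cols, [group_a] * len(cols_a) + [group_b] * len(cols_b),
                            scores):
                        fh.write(sid + "\t" + g + "\t"
                                 + "\t".join(f"{v:.6f}" for v in row) + "\n")

            # 4) logistic diagnostic model on the panel, raw-scale intensities
            if panel:
                import logging as _logging

                xm = table.intensities.loc[panel, cols].to_numpy(dtype=float).T
                diag_logger = _logging.getLogger("lipidscreen.diagnostics")
                prev_level = diag_logger.level
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    # separation is reported in the JSON block, not the log
                    diag_logger.setLevel(_logging.ERROR)
                    try:
                        logit = fit_logistic(xm, y, feature_ids=[
                            str(table.features.loc[fid, "annotation"])
                            for fid in panel])
                        perf = loocv_performance(
                            xm, y, threshold=config.logistic_threshold)
                    finally:
                        diag_logger.setLevel(prev_level)
                block["logistic"] = {
                    "coefficients": [
                        {k: (round(v, 10) if isinstance(v, float) else v)
                         for k, v in row.items()}
                        for row in logit.table()
                    ],
                    "converged": bool(logit.converged),
                    "separated": bool(logit.separated),
                }
                block["loocv"] = {
                    "sensitivity": round(perf.sensitivity, 4),
                    "specificity": round(perf.specificity, 4),
                    "tp": perf.tp, "fp": perf.fp,
                    "tn": perf.tn, "fn": perf.fn,
                    "threshold": config.logistic_threshold,
                }

        # 5) enrichment of significant lipids against the annotated background
        sig_names = sorted(
            {str(table.features.loc[fid, "annotation"]) for fid in sig_ids}
            & set(background))
        if sig_names:
            enr = enrich(sig_names, background)
            block["enrichment"] = [
                {"pathway": r.pathway, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
                 "p": round(r.p, 8), "p_adj_BH": round(r.p_adj_bh, 8)}
                for r in enr
            ]
            if outdir:
                _enrich_frame(enr).to_csv(
                    outdir / f"enrichment_{key}.tsv", sep="\t", index=False)

        report["comparisons"][key] = block

    if truth is not None:
        report["ground_truth_markers"] = {
            f"{a}_vs_{b}": truth.marker_ids((a, b))
            for a, b in config.comparisons
        }

    if outdir:
        _dump_json(report, outdir / "report.json")
    return report
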