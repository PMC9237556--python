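"""End-to-end analysis: candidate assembly → best-PWM selection → validation.

For every TF with measurements: assemble its candidate PWM set from the
catalog (with family extension), select the best PWM by AUPRC on the
labeled batch-1 data, report stratified cross-validation statistics,
validate on batch 2, stratify batch-1 performance by OBS quantile, and
correlate ΔPWM with PBS scores and with allele-specific binding ratios.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .benchmark import (
    EXCLUDED,
    allelic_ratio_correlation,
    correlation_with_pbs,
    cv_performance,
    evaluate_pwm,
    label_records,
    obs_quantile_strata,
    predictions_to_frame,
    read_asb,
    read_measurements,
    select_best_pwm,
)
from .motifs import FamilyRuleSet, assemble_candidate_set, load_candidate_pwms, parse_catalog
from .pvalues import ScoreDistribution

logger = logging.getLogger(__name__)

AUPRC_SUCCESS_THRESHOLD = 0.75


@dataclass
class RunConfig:
    """Paths and thresholds of one pipeline run."""

    catalog: str
    pfm_dir: str
    measurements: list[str]  # one or more measurement TSVs (both batches)
    out_dir: str
    asb: str | None = None
    family_rules: str | None = None
    neg_p: float = 0.005
    strong_hit_alpha: float = 1e-4
    cv_k: int = 5
    cv_seed: int = 0
    n_quantiles: int = 5
    select_per_fold: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.neg_p <= 1 and 0 < self.strong_hit_alpha <= 1):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.cv_k < 2:
            raise ValueError("cv_k must be >= 2")
        if isinstance(self.measurements, str):
            self.measurements = [self.measurements]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def run_pipeline(cfg: RunConfig) -> Path:
    """Run the full analysis; returns the report directory.

    Per-TF failures are isolated, logged, and reported in the summary; the
    run fails only on global errors (unreadable inputs, no TF succeeding).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    logger.info("deltapwm %s pipeline start; cv_seed=%d", __version__, cfg.cv_seed)

    catalog = parse_catalog(cfg.catalog, cfg.pfm_dir)
    rules = FamilyRuleSet.from_yaml(cfg.family_rules) if cfg.family_rules else None
    records = []
    for path in cfg.measurements:
        records.extend(read_measurements(path))
    by_tf: dict[str, list] = {}
    for r in records:
        by_tf.setdefault(r.tf_name, []).append(r)

    tf_rows, cand_tables, pred_frames, quantile_tables = [], [], [], []
    failures: dict[str, str] = {}
    for tf_name in sorted(by_tf):
        try:
            tf_rows_i, cand_i, preds_i, quant_i = _run_tf(
                tf_name, by_tf[tf_name], catalog, rules, cfg
            )
            tf_rows.append(tf_rows_i)
            cand_tables.append(cand_i)
            pred_frames.extend(preds_i)
            if quant_i is not None:
                quantile_tables.append(quant_i)
        except Exception as exc:  # per-TF isolation
            logger.exception("TF %s failed", tf_name)
            failures[tf_name] = str(exc)
    if not tf_rows:
        raise RuntimeError(f"no TF could be evaluated; failures: {failures}")

    tf_table = pd.DataFrame(tf_rows)
    tf_table.to_csv(out / "tf_summary.tsv", sep="\t", index=False, float_format="%.6g")
    pd.concat(cand_tables, ignore_index=True).to_csv(
        out / "best_pwm_table.tsv", sep="\t", index=False, float_format="%.6g"
    )
    predictions = pd.concat(pred_frames, ignore_index=True)
    predictions.to_csv(out / "predictions.tsv", sep="\t", index=False, float_format="%.6g")
    if quantile_tables:
        pd.concat(quantile_tables, ignore_index=True).to_csv(
            out / "quantile_auprc.tsv", sep="\t", index=False, float_format="%.6g"
        )

    corr_rows = _correlations(predictions, records, cfg)
    pd.DataFrame(corr_rows).to_csv(
        out / "correlations.tsv", sep="\t", index=False, float_format="%.6g"
    )

    summary = {
        "version": __version__,
        "config": asdict(cfg),
        "n_tfs": len(tf_table),
        "n_tfs_failed": len(failures),
        "failures": failures,
        "n_tfs_auprc_above_0.75_batch1": int(
            (tf_table["auprc_batch1"] > AUPRC_SUCCESS_THRESHOLD).sum()
        ),
        "n_tfs_auprc_above_0.75_batch2": int(
            (tf_table["auprc_batch2"] > AUPRC_SUCCESS_THRESHOLD).sum()
        ),
        "mean_auprc_batch1": float(tf_table["auprc_batch1"].mean()),
        "mean_auprc_batch2": float(np.nanmean(tf_table["auprc_batch2"])),
        "correlations": corr_rows,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline done: %d TFs, %d failures", len(tf_table), len(failures))
    return out


def _run_tf(tf_name, tf_records, catalog, rules, cfg: RunConfig):
    entries = assemble_candidate_set(tf_name, catalog, rules)
    if not entries:
        raise ValueError(f"no candidate motifs for TF {tf_name}")
    candidates = load_candidate_pwms(entries)

    batch1 = label_records([r for r in tf_records if r.batch == 1], batch=1)
    batch2 = label_records([r for r in tf_records if r.batch == 2], batch=2)
    result, cand_table = select_best_pwm(tf_name, candidates, batch1, neg_threshold=cfg.neg_p)
    best_pwm = next(p for p, e in candidates if p.motif_id == result.motif_id)
    best_entry = next(e for p, e in candidates if p.motif_id == result.motif_id)
    dist = ScoreDistribution(best_pwm)

    cv_mean = cv_sd = float("nan")
    try:
        cv_mean, cv_sd, folds = cv_performance(
            tf_name, best_pwm, dist, batch1, k=cfg.cv_k, seed=cfg.cv_seed,
            candidates=candidates if cfg.select_per_fold else None,
            neg_threshold=cfg.neg_p,
        )
    except ValueError as exc:
        logger.warning("TF %s: CV skipped (%s)", tf_name, exc)

    auprc2 = float("nan")
    preds2 = []
    used2 = [lr for lr in batch2 if lr.label != EXCLUDED]
    if used2:
        try:
            auprc2, preds2 = evaluate_pwm(best_pwm, dist, used2, neg_threshold=cfg.neg_p)
        except ValueError as exc:
            logger.warning("TF %s: batch-2 evaluation skipped (%s)", tf_name, exc)

    used1 = [lr for lr in batch1 if lr.label != EXCLUDED]
    auprc1_check, preds1 = evaluate_pwm(best_pwm, dist, used1, neg_threshold=cfg.neg_p)
    quant_table = None
    if used1:
        _, quant_table = obs_quantile_strata(used1, preds1, n_quantiles=cfg.n_quantiles)
        quant_table.insert(0, "tf_name", tf_name)

    pred_frames = [predictions_to_frame(tf_name, preds1)]
    if preds2:
        pred_frames.append(predictions_to_frame(tf_name, preds2))

    row = {
        "tf_name": tf_name,
        "best_motif_id": result.motif_id,
        "best_motif_status": best_entry.status if best_entry else "direct",
        "n_candidates": len(candidates),
        "auprc_batch1": result.auprc,
        "cv_mean_auprc": cv_mean,
        "cv_sd_auprc": cv_sd,
        "auprc_batch2": auprc2,
        "n_pos_batch1": result.n_pos,
        "n_neg_batch1": result.n_neg,
        "n_pos_batch2": sum(1 for lr in used2 if lr.label == "positive"),
        "n_neg_batch2": sum(1 for lr in used2 if lr.label == "negative"),
    }
    return row, cand_table, pred_frames, quant_table


def _correlations(predictions: pd.DataFrame, records, cfg: RunConfig) -> list[dict]:
    from .benchmark import measurements_to_frame

    meas = measurements_to_frame(records)[["tf_name", "snv_id", "pbs_score"]]
    preds = predictions.drop_duplicates(["tf_name", "snv_id"])
    rows = []
    for subset in ("all", "strong_hits", "best_tf_per_snp"):
        try:
            r, p, sign, n = correlation_with_pbs(
                preds, meas, subset=subset, strong_hit_alpha=cfg.strong_hit_alpha
            )
            rows.append({"analysis": f"pbs_{subset}", "pearson_r": r, "p_value": p,
                         "fitted_sign": sign, "n": n})
        except ValueError as exc:
            logger.warning("PBS correlation %s skipped: %s", subset, exc)
    if cfg.asb:
        asb = read_asb(cfg.asb)
        for filt in (cfg.neg_p, None):
            try:
                r, p, n = allelic_ratio_correlation(asb, preds, motif_p_filter=filt)
                name = "asb_all" if filt is None else f"asb_motif_p_lt_{filt:g}"
                rows.append({"analysis": name, "pearson_r": r, "p_value": p,
                             "fitted_sign": 1 if r >= 0 else -1, "n": n})
            except ValueError as exc:
                logger.warning("ASB correlation (filter=%s) skipped: %s", filt, exc)
    return rows


def _setup_logging(logfile: Path) -> None:
    root = logging.getLogger("deltapwm")
    root.setLevel(logging.INFO)
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "baseFilename", None) == str(logfile) for h in root.handlers):
        fh = logging.FileHandler(logfile, mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        root.addHandler(fh)
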