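"""SNP-SELEX-style benchmarking of allelic PWM predictions.

Implements the evaluation protocol: labeling measured TF–SNV pairs as true
positives/negatives from PBS (preferential binding score) and OBS (observed
binding) P-values, area under the precision-recall curve, best-PWM
selection per TF, stratified k-fold cross-validation, OBS-quantile
stratification, and correlation of ΔPWM with PBS and with ChIP-seq allelic
binding ratios.

Labeling rules
--------------
batch 1: positive ⇔ PBS p < 0.01 and OBS p < 0.05;
         negative ⇔ PBS p > 0.5 and OBS p < 0.05; otherwise excluded.
batch 2: positive ⇔ PBS p < 0.01; negative ⇔ PBS p > 0.5; otherwise excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .motifs import PWM, MotifCatalogEntry
from .pvalues import ScoreDistribution
from .scoring import AllelicPrediction, SnvContext, predict_batch

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"

PBS_POSITIVE_P = 0.01
PBS_NEGATIVE_P = 0.5
OBS_SIGNIFICANT_P = 0.05


@dataclass(frozen=True)
class SnvMeasurement:
    """One measured TF–SNV pair with PBS/OBS statistics and batch label."""

    tf_name: str
    snv: SnvContext
    pbs_score: float
    pbs_pvalue: float
    obs_score: float
    obs_pvalue: float
    batch: int

    def __post_init__(self) -> None:
        if not (0 <= self.pbs_pvalue <= 1 and 0 <= self.obs_pvalue <= 1):
            raise ValueError(f"{self.snv.snv_id}: p-values must lie in [0, 1]")
        if self.batch not in (1, 2):
            raise ValueError(f"{self.snv.snv_id}: batch must be 1 or 2")


@dataclass(frozen=True)
class LabeledRecord:
    measurement: SnvMeasurement
    label: str  # positive | negative | excluded


@dataclass
class BenchmarkResult:
    tf_name: str
    motif_id: str
    auprc: float
    n_pos: int
    n_neg: int
    cv_mean_auprc: float | None = None
    cv_sd_auprc: float | None = None
    fold_auprcs: list[float] = field(default_factory=list)


def label_records(records: list[SnvMeasurement], batch: int) -> list[LabeledRecord]:
    """Assign positive/negative/excluded labels using the batch's threshold rules."""
    if batch not in (1, 2):
        raise ValueError("batch must be 1 or 2")
    out = []
    for r in records:
        if batch == 1:
            if r.pbs_pvalue < PBS_POSITIVE_P and r.obs_pvalue < OBS_SIGNIFICANT_P:
                label = POSITIVE
            elif r.pbs_pvalue > PBS_NEGATIVE_P and r.obs_pvalue < OBS_SIGNIFICANT_P:
                label = NEGATIVE
            else:
                label = EXCLUDED
        else:
            if r.pbs_pvalue < PBS_POSITIVE_P:
                label = POSITIVE
            elif r.pbs_pvalue > PBS_NEGATIVE_P:
                label = NEGATIVE
            else:
                label = EXCLUDED
        out.append(LabeledRecord(measurement=r, label=label))
    return out


def auprc(scores, labels) -> float:
    """Area under the precision-recall curve.

    The curve is built from thresholds at each distinct score (descending),
    with the point (recall=0, precision=1) prepended, and integrated by the
    trapezoidal rule; duplicate recalls contribute zero width.  Returns NaN
    with a warning when either class is absent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUPRC undefined: need at least one positive and one negative")
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, y.size + 1)
    # keep only the last index of each distinct-score run (threshold points)
    last = np.nonzero(np.diff(s, append=-np.inf))[0]
    precision = tp[last] / pred_pos[last]
    recall = tp[last] / n_pos
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[1.0], precision])
    return float(np.trapezoid(precision, recall))


def ranking_scores(
    predictions: list[AllelicPrediction], tie_break_negatives: bool = True
) -> np.ndarray:
    """Scalar ranking scores for PR evaluation.

    Scored pairs rank by |ΔPWM|; predicted negatives rank after all of them
    (their ranking_score is 0), ordered among themselves by the smaller
    best-hit P-value first when ``tie_break_negatives`` — encoded as
    ``-min(p_ref, p_alt)``, which is negative and hence below every |ΔPWM|.
    """
    out = np.empty(len(predictions))
    for i, p in enumerate(predictions):
        if p.predicted_negative and tie_break_negatives:
            out[i] = -min(p.p_ref, p.p_alt)
        else:
            out[i] = p.ranking_score
    return out


def evaluate_pwm(
    pwm: PWM,
    dist: ScoreDistribution,
    labeled: list[LabeledRecord],
    neg_threshold: float = 0.005,
    exclude_predicted_negatives: bool = False,
) -> tuple[float, list[AllelicPrediction]]:
    """AUPRC of one PWM on a labeled record set (excluded records dropped).

    ``exclude_predicted_negatives`` removes predicted-negative pairs from the
    PR curve instead of ranking them last (an alternative reading of the
    protocol; off by default).
    """
    used = [lr for lr in labeled if lr.label != EXCLUDED]
    contexts = [lr.measurement.snv for lr in used]
    preds = predict_batch(pwm, dist, contexts, neg_threshold=neg_threshold)
    y = np.array([1 if lr.label == POSITIVE else 0 for lr in used])
    scores = ranking_scores(preds)
    if exclude_predicted_negatives:
        keep = np.array([not p.predicted_negative for p in preds])
        y, scores = y[keep], scores[keep]
    return auprc(scores, y), preds


def select_best_pwm(
    tf_name: str,
    candidates: list[tuple[PWM, MotifCatalogEntry | None]],
    labeled: list[LabeledRecord],
    neg_threshold: float = 0.005,
    n_steps: int | None = None,
) -> tuple[BenchmarkResult, pd.DataFrame]:
    """Pick the candidate PWM with the highest AUPRC on the labeled set.

    Thin wrapper over :class:`deltapwm.estimator.DeltaPwmVariantClassifier`.
    Returns the winning result plus the full per-candidate table.
    """
    from .estimator import DeltaPwmVariantClassifier

    used = [lr for lr in labeled if lr.label != EXCLUDED]
    contexts = [lr.measurement.snv for lr in used]
    y = np.array([1 if lr.label == POSITIVE else 0 for lr in used])
    kwargs = {} if n_steps is None else {"n_steps": n_steps}
    clf = DeltaPwmVariantClassifier(
        candidates=candidates, neg_pvalue_threshold=neg_threshold, **kwargs
    )
    clf.fit(contexts, y)
    table = clf.candidate_table_.copy()
    table.insert(0, "tf_name", tf_name)
    result = BenchmarkResult(
        tf_name=tf_name,
        motif_id=clf.best_motif_id_,
        auprc=clf.best_auprc_,
        n_pos=int(y.sum()),
        n_neg=int((1 - y).sum()),
    )
    return result, table


def stratified_kfold(
    labeled: list[LabeledRecord], k: int = 5, seed: int = 0
) -> list[list[LabeledRecord]]:
    """Partition non-excluded records into k folds with balanced class counts.

    Per-fold positive counts differ by at most 1 (likewise negatives);
    shuffling is driven only by ``seed``.
    """
    used = [lr for lr in labeled if lr.label != EXCLUDED]
    y = np.array([1 if lr.label == POSITIVE else 0 for lr in used])
    if int(y.sum()) < k or int((1 - y).sum()) < k:
        raise ValueError(f"need at least {k} records of each class for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [[used[i] for i in test_idx] for _, test_idx in skf.split(np.zeros(len(used)), y)]


def cv_performance(
    tf_name: str,
    pwm: PWM,
    dist: ScoreDistribution,
    labeled: list[LabeledRecord],
    k: int = 5,
    seed: int = 0,
    candidates: list[tuple[PWM, MotifCatalogEntry | None]] | None = None,
    neg_threshold: float = 0.005,
) -> tuple[float, float, list[float]]:
    """Stratified k-fold CV: AUPRC on each held-out fold, mean and sd.

    With ``candidates`` given, the best PWM is re-selected on the training
    folds within each split; otherwise the fixed ``pwm`` is evaluated on
    every held-out fold (the default protocol).
    """
    folds = stratified_kfold(labeled, k=k, seed=seed)
    fold_auprcs = []
    for i, test_fold in enumerate(folds):
        if candidates is not None:
            train = [lr for j, f in enumerate(folds) if j != i for lr in f]
            result, _ = select_best_pwm(tf_name, candidates, train, neg_threshold=neg_threshold)
            sel = next(p for p, e in candidates if p.motif_id == result.motif_id)
            sel_dist = ScoreDistribution(sel)
        else:
            sel, sel_dist = pwm, dist
        a, _ = evaluate_pwm(sel, sel_dist, test_fold, neg_threshold=neg_threshold)
        fold_auprcs.append(a)
    arr = np.asarray(fold_auprcs)
    return float(arr.mean()), float(arr.std(ddof=0)), fold_auprcs


def obs_quantile_strata(
    labeled: list[LabeledRecord],
    predictions: list[AllelicPrediction],
    n_quantiles: int = 5,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Equal-count quantile strata by OBS score, with per-quantile AUPRC.

    Records are assigned to ``n_quantiles`` rank-based strata of (nearly)
    equal size by obs_score (stable ranking resolves ties); AUPRC within a
    stratum that lacks a class is NaN with a warning.  Excluded records must
    already have been dropped; predictions align positionally with
    ``labeled``.
    """
    if len(labeled) != len(predictions):
        raise ValueError("labeled and predictions must align")
    obs = np.array([lr.measurement.obs_score for lr in labeled])
    n = obs.size
    order = np.argsort(obs, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    quantile_idx = (ranks * n_quantiles) // n
    y = np.array([1 if lr.label == POSITIVE else 0 for lr in labeled])
    scores = ranking_scores(predictions)
    rows = []
    for q in range(n_quantiles):
        mask = quantile_idx == q
        yq, sq = y[mask], scores[mask]
        if yq.size == 0 or yq.sum() == 0 or yq.sum() == yq.size:
            warnings.warn(f"quantile {q}: AUPRC undefined (one class absent)")
            a = float("nan")
        else:
            a = auprc(sq, yq)
        rows.append({
            "quantile": q,
            "n": int(mask.sum()),
            "n_pos": int(yq.sum()),
            "n_neg": int(yq.size - yq.sum()),
            "auprc": a,
            "obs_min": float(obs[mask].min()) if mask.any() else float("nan"),
            "obs_max": float(obs[mask].max()) if mask.any() else float("nan"),
        })
    return quantile_idx, pd.DataFrame(rows)


def correlation_with_pbs(
    predictions: pd.DataFrame,
    measurements: pd.DataFrame,
    subset: str = "all",
    strong_hit_alpha: float = 1e-4,
) -> tuple[float, float, int, int]:
    """Pearson correlation of ΔPWM with the PBS score on a chosen subset.

    ``predictions`` needs columns (tf_name, snv_id, p_ref, p_alt, delta);
    ``measurements`` needs (tf_name, snv_id, pbs_score).  Subsets:

    - ``all`` — every joined pair;
    - ``strong_hits`` — pairs whose stronger-bound allele has a best-hit
      motif P-value below ``strong_hit_alpha`` (min(p_ref, p_alt) < α);
    - ``best_tf_per_snp`` — per SNV, only the TF with the highest PBS score.

    Returns (pearson_r, two_sided_p, fitted_sign, n_used); fitted_sign is
    +1 when delta correlates positively with PBS, else −1.
    """
    df = predictions.merge(measurements, on=["tf_name", "snv_id"], how="inner")
    if subset == "strong_hits":
        df = df[np.minimum(df["p_ref"], df["p_alt"]) < strong_hit_alpha]
    elif subset == "best_tf_per_snp":
        df = df.loc[df.groupby("snv_id")["pbs_score"].idxmax()]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    if len(df) < 3:
        raise ValueError(f"subset {subset!r}: fewer than 3 pairs ({len(df)})")
    r, p = stats.pearsonr(df["delta"], df["pbs_score"])
    sign = 1 if r >= 0 else -1
    return float(r), float(p), sign, len(df)


def allelic_ratio_correlation(
    asb: pd.DataFrame,
    predictions: pd.DataFrame,
    motif_p_filter: float | None = 0.005,
) -> tuple[float, float, int]:
    """Correlation of ΔPWM with ChIP-seq allelic binding ratios.

    ``asb`` needs columns (tf_name, snv_id, allelic_ratio); ``predictions``
    as in :func:`correlation_with_pbs`.  With ``motif_p_filter`` set, only
    pairs whose best hit on either allele has P-value below the filter are
    kept.  Returns (pearson_r, two_sided_p, n_used).
    """
    df = predictions.merge(asb, on=["tf_name", "snv_id"], how="inner")
    if motif_p_filter is not None:
        df = df[np.minimum(df["p_ref"], df["p_alt"]) < motif_p_filter]
    if len(df) < 3:
        raise ValueError(f"fewer than 3 pairs after filtering ({len(df)})")
    r, p = stats.pearsonr(df["delta"], df["allelic_ratio"])
    return float(r), float(p), len(df)


# ---------------------------------------------------------------------------
# TSV I/O for measurement and ASB tables

MEASUREMENT_COLUMNS = [
    "tf_name", "snv_id", "oligo", "variant_offset", "ref_allele", "alt_allele",
    "pbs_score", "pbs_pvalue", "obs_score", "obs_pvalue", "batch",
]


def read_measurements(path: str | Path) -> list[SnvMeasurement]:
    """Read an SNP-SELEX-style measurement TSV (one row per TF–SNV pair)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing measurement columns: {missing}")
    return frame_to_measurements(df)


def frame_to_measurements(df: pd.DataFrame) -> list[SnvMeasurement]:
    """Build measurement records from a DataFrame with the measurement columns."""
    out = []
    for row in df.itertuples(index=False):
        ctx = SnvContext(
            snv_id=str(row.snv_id),
            oligo=str(row.oligo),
            variant_offset=int(row.variant_offset),
            ref_allele=str(row.ref_allele),
            alt_allele=str(row.alt_allele),
        )
        out.append(SnvMeasurement(
            tf_name=str(row.tf_name),
            snv=ctx,
            pbs_score=float(row.pbs_score),
            pbs_pvalue=float(row.pbs_pvalue),
            obs_score=float(row.obs_score),
            obs_pvalue=float(row.obs_pvalue),
            batch=int(row.batch),
        ))
    return out


def measurements_to_frame(records: list[SnvMeasurement]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "tf_name": r.tf_name,
            "snv_id": r.snv.snv_id,
            "oligo": r.snv.oligo,
            "variant_offset": r.snv.variant_offset,
            "ref_allele": r.snv.ref_allele,
            "alt_allele": r.snv.alt_allele,
            "pbs_score": r.pbs_score,
            "pbs_pvalue": r.pbs_pvalue,
            "obs_score": r.obs_score,
            "obs_pvalue": r.obs_pvalue,
            "batch": r.batch,
        }
        for r in records
    ], columns=MEASUREMENT_COLUMNS)


def predictions_to_frame(tf_name: str, predictions: list[AllelicPrediction]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "tf_name": tf_name,
            "snv_id": p.snv_id,
            "motif_id": p.motif_id,
            "p_ref": p.p_ref,
            "p_alt": p.p_alt,
            "delta": p.delta,
            "predicted_negative": p.predicted_negative,
            "ranking_score": p.ranking_score,
        }
        for p in predictions
    ])


def read_asb(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("tf_name", "snv_id", "allelic_ratio") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing ASB columns: {missing}")
    return df
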