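"""Scikit-learn-style estimator for best-PWM variant-effect classification.

``DeltaPwmVariantClassifier`` treats best-PWM selection as model fitting:
given a candidate set of PWMs for a transcription factor and a labeled set
of SNVs (positive = preferentially bound allele pair), ``fit`` scores every
candidate with the allelic ΔPWM protocol, computes each candidate's AUPRC,
and selects the argmax.  ``decision_function`` then returns the selected
PWM's ranking scores and ``predict`` the predicted-positive calls, so the
estimator composes with sklearn model selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .benchmark import auprc, ranking_scores
from .motifs import PWM, MotifCatalogEntry
from .pvalues import DEFAULT_GRID_STEPS, ScoreDistribution
from .scoring import SnvContext, predict_batch

_STATUS_RANK = {"direct": 0, "inferred": 1}


class DeltaPwmVariantClassifier(ClassifierMixin, BaseEstimator):
    """Select the best candidate PWM by AUPRC and classify SNVs with it.

    Parameters
    ----------
    candidates : list of (PWM, MotifCatalogEntry or None)
        Candidate motif models for the transcription factor.
    neg_pvalue_threshold : float, default 0.005
        Best-hit P-value above which both alleles must fall for an SNV to be
        a predicted negative (ranking score 0).
    exclude_predicted_negatives : bool, default False
        Drop predicted negatives from the PR curve instead of ranking them
        last during candidate selection.
    n_steps : int
        Grid resolution of the exact score-distribution dynamic program.

    Attributes
    ----------
    best_motif_id_ : str
        Motif id of the selected PWM.
    best_pwm_ : PWM
    best_entry_ : MotifCatalogEntry or None
    best_auprc_ : float
        Training AUPRC of the selected candidate.
    candidate_table_ : pandas.DataFrame
        Per-candidate motif_id, status, AUPRC (sorted best first).
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        candidates: list[tuple[PWM, MotifCatalogEntry | None]] | None = None,
        neg_pvalue_threshold: float = 0.005,
        exclude_predicted_negatives: bool = False,
        n_steps: int = DEFAULT_GRID_STEPS,
    ):
        self.candidates = candidates
        self.neg_pvalue_threshold = neg_pvalue_threshold
        self.exclude_predicted_negatives = exclude_predicted_negatives
        self.n_steps = n_steps

    @staticmethod
    def _as_contexts(X) -> list[SnvContext]:
        if isinstance(X, pd.DataFrame):
            return [
                SnvContext(
                    snv_id=str(r.snv_id),
                    oligo=str(r.oligo),
                    variant_offset=int(r.variant_offset),
                    ref_allele=str(r.ref_allele),
                    alt_allele=str(r.alt_allele),
                )
                for r in X.itertuples(index=False)
            ]
        X = list(X)
        if not all(isinstance(x, SnvContext) for x in X):
            raise TypeError("X must be a list of SnvContext or a DataFrame with SNV columns")
        return X

    def fit(self, X, y):
        """Select the candidate PWM with the highest AUPRC on (X, y).

        X is a list of :class:`SnvContext` (or a DataFrame with columns
        snv_id, oligo, variant_offset, ref_allele, alt_allele); y is a
        binary label vector.  Ties in AUPRC are broken by catalog status
        (direct before inferred), then lexicographic motif_id.
        """
        if not self.candidates:
            raise ValueError("candidates must be a non-empty list of (PWM, entry) pairs")
        contexts = self._as_contexts(X)
        y = np.asarray(y, dtype=int)
        if y.shape != (len(contexts),):
            raise ValueError("y must align with X")
        if y.sum() == 0 or y.sum() == y.size:
            raise ValueError("fit requires at least one positive and one negative")
        self.classes_ = np.array([0, 1])
        rows = []
        scored = []
        for pwm, entry in self.candidates:
            dist = ScoreDistribution(pwm, n_steps=self.n_steps)
            preds = predict_batch(pwm, dist, contexts, neg_threshold=self.neg_pvalue_threshold)
            scores = ranking_scores(preds)
            yy, ss = y, scores
            if self.exclude_predicted_negatives:
                keep = np.array([not p.predicted_negative for p in preds])
                yy, ss = y[keep], scores[keep]
            a = auprc(ss, yy) if 0 < yy.sum() < yy.size else float("nan")
            status = entry.status if entry is not None else "direct"
            rows.append({
                "motif_id": pwm.motif_id,
                "status": status,
                "auprc": a,
                "n_pos": int(y.sum()),
                "n_neg": int(y.size - y.sum()),
            })
            scored.append((pwm, entry, dist, a, status))
        # argmax with deterministic tie-break: AUPRC desc, direct first, motif_id asc
        def key(item):
            a = item[3]
            return (-(a if np.isfinite(a) else -np.inf), _STATUS_RANK.get(item[4], 2), item[0].motif_id)

        best = min(scored, key=key)
        self.best_pwm_, self.best_entry_, self.best_dist_, self.best_auprc_, _ = best
        self.best_motif_id_ = self.best_pwm_.motif_id
        self.candidate_table_ = (
            pd.DataFrame(rows)
            .sort_values(["auprc", "motif_id"], ascending=[False, True], kind="stable")
            .reset_index(drop=True)
        )
        return self

    def predict_allelic(self, X):
        """Full :class:`AllelicPrediction` records for the selected PWM."""
        check_is_fitted(self, "best_pwm_")
        return predict_batch(
            self.best_pwm_, self.best_dist_, self._as_contexts(X),
            neg_threshold=self.neg_pvalue_threshold,
        )

    def decision_function(self, X):
        """Ranking scores of the selected PWM (higher = more likely positive)."""
        return ranking_scores(self.predict_allelic(X))

    def predict(self, X):
        """1 unless the SNV is a predicted negative (weak hits on both alleles)."""
        preds = self.predict_allelic(X)
        return np.array([0 if p.predicted_negative else 1 for p in preds])

    def score(self, X, y):
        """AUPRC of the selected PWM on (X, y)."""
        return auprc(self.decision_function(X), np.asarray(y, dtype=int))
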