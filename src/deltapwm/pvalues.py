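"""Exact motif P-values and best-hit scanning.

The motif P-value of a score s is the probability that a random word of
motif length, drawn from the background nucleotide distribution, scores at
least s under the PWM.  The full score distribution is computed exactly by
dynamic programming: per-position weights are rounded onto a fine integer
grid and the per-position score distributions are convolved, so the tail
function is available for any score in O(1) after an O(L · range) build.

Reported hit P-values are looked up with the window's grid (rounded-weight)
score, which makes them exactly self-consistent with the discretized
distribution; the discrepancy against exhaustive enumeration with exact
weights is bounded by the probability mass within L grid steps of the query
(negligible at the default 2^14-step grid for the decision thresholds used
downstream, 5e-3 and 1e-4).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .motifs import ALPHABET, BASE_INDEX, PWM

logger = logging.getLogger(__name__)

#: Number of grid steps spanning the attainable score range in the DP.
DEFAULT_GRID_STEPS = 2 ** 14

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 indices into ACGT; ambiguity codes map to -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        out[i] = BASE_INDEX.get(c, -1)
    return out


@dataclass(frozen=True)
class Hit:
    """Best PWM match in a sequence: 0-based half-open window, strand, score, P-value."""

    window_start: int
    strand: str  # "+" | "-"
    score: float
    pvalue: float


class ScoreDistribution:
    """Exact distribution of the PWM score of a random background word.

    Parameters
    ----------
    pwm : PWM
        The log-odds matrix.
    background : array-like of 4 floats, optional
        Background nucleotide probabilities (uniform by default).
    n_steps : int
        Grid resolution; the score range is divided into this many steps.
    """

    def __init__(
        self,
        pwm: PWM,
        background: np.ndarray | None = None,
        n_steps: int = DEFAULT_GRID_STEPS,
    ):
        q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if q.shape != (4,) or np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
            raise ValueError("background must be a strictly positive 4-vector summing to 1")
        self.motif_id = pwm.motif_id
        self.background = q
        w = pwm.weights
        self.length = L = w.shape[0]
        lo = float(w.min(axis=1).sum())
        hi = float(w.max(axis=1).sum())
        span = hi - lo
        self.step = span / n_steps if span > 0 else 1.0
        # integer grid weights; DP convolution over positions
        self.int_weights = np.rint(w / self.step).astype(np.int64)
        col_lo = self.int_weights.min(axis=1)
        col_hi = self.int_weights.max(axis=1)
        total_lo = int(col_lo.sum())
        total_hi = int(col_hi.sum())
        size = total_hi - total_lo + 1
        probs = np.zeros(size)
        probs[0] = 1.0
        cur_hi = 0  # current occupied extent relative to running minimum
        run_lo = 0
        for i in range(L):
            new = np.zeros(size)
            width = cur_hi + 1
            for b in range(4):
                off = self.int_weights[i, b] - col_lo[i]
                new[off : off + width] += q[b] * probs[:width]
            probs = new
            run_lo += col_lo[i]
            cur_hi += col_hi[i] - col_lo[i]
        self._origin = total_lo  # integer score of probs[0]
        # tail[k] = P(int score >= origin + k), on the dense grid
        self._tail = np.cumsum(probs[::-1])[::-1]
        grid = (np.arange(total_lo, total_hi + 1) * self.step).astype(float)
        attained = probs > 0  # public support carries only attained scores
        self.probabilities = probs[attained]
        self.support = grid[attained]
        self._support_tail = self._tail[attained]
        # positive-mass floor for scores beyond the attainable maximum
        self._floor = 1.0 / (4.0 ** min(L, 500) + 1.0)

    # -- integer-score interface (used by best_hit for exact self-consistency) --

    def int_score(self, word_idx: np.ndarray) -> int:
        return int(self.int_weights[np.arange(self.length), word_idx].sum())

    def tail_int(self, k: int) -> float:
        i = k - self._origin
        if i < 0:
            return 1.0
        if i >= self._tail.size:
            return self._floor
        return max(float(self._tail[i]), self._floor)

    # -- float-score interface --

    def pvalue(self, score: float) -> float:
        """P(background score >= score); never exactly 0 (floored at 1/(4^L+1))."""
        return self.tail_int(int(np.rint(score / self.step)))

    def threshold(self, alpha: float) -> float:
        """Minimal support score s with P(score >= s) <= alpha (conservative)."""
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        ok = self._support_tail <= alpha
        if not ok.any():
            logger.warning(
                "alpha=%g below the smallest attainable tail for motif %s; nothing passes",
                alpha, self.motif_id,
            )
            return float(self.support[-1] + self.step)
        return float(self.support[int(np.argmax(ok))])


def score_word(pwm: PWM, word: str) -> float:
    """Additive log-odds score of a word whose length equals the PWM length."""
    L = len(pwm)
    if len(word) != L:
        raise ValueError(f"word length {len(word)} != PWM length {L}")
    idx = encode(word)
    if np.any(idx < 0):
        raise ValueError(f"word {word!r} contains non-ACGT characters")
    return float(pwm.weights[np.arange(L), idx].sum())


def score_distribution(
    pwm: PWM,
    background: np.ndarray | None = None,
    n_steps: int = DEFAULT_GRID_STEPS,
) -> ScoreDistribution:
    return ScoreDistribution(pwm, background=background, n_steps=n_steps)


def score_to_pvalue(dist: ScoreDistribution, score: float) -> float:
    return dist.pvalue(score)


def pvalue_to_threshold(dist: ScoreDistribution, alpha: float) -> float:
    return dist.threshold(alpha)


def _window_int_scores(int_weights: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Grid scores of every full window of an encoded sequence; NaN-free.

    Windows containing ambiguity codes (index < 0) get a score of
    ``np.iinfo(int64).min`` so they never win the argmax.
    """
    L = int_weights.shape[0]
    n = idx.size - L + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)  # (n, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n, np.iinfo(np.int64).min, dtype=np.int64)
    if valid.any():
        w = windows[valid]
        scores[valid] = int_weights[np.arange(L), w].sum(axis=1)
    return scores


def best_hit(pwm: PWM, sequence: str, dist: ScoreDistribution | None = None) -> Hit:
    """Best-scoring PWM window over both strands of ``sequence``.

    Ties (equal grid score) prefer the + strand, then the leftmost window.
    Windows containing ambiguity codes are skipped; if every window is
    skipped or the sequence is shorter than the motif, a ValueError is
    raised.
    """
    if dist is None:
        dist = ScoreDistribution(pwm)
    L = dist.length
    if len(sequence) < L:
        raise ValueError(f"sequence length {len(sequence)} < motif length {L}")
    idx = encode(sequence)
    fwd = _window_int_scores(dist.int_weights, idx)
    # reverse strand: score the reverse complement of each window; computing
    # reverse-complemented PWM on the forward sequence keeps window coordinates
    rc_weights = dist.int_weights[::-1, ::-1]
    rev = _window_int_scores(rc_weights, idx)
    nothing = np.iinfo(np.int64).min
    best_f = int(fwd.max()) if fwd.size else nothing
    best_r = int(rev.max()) if rev.size else nothing
    if best_f == nothing and best_r == nothing:
        raise ValueError("no scoreable window (sequence all-ambiguous?)")
    if best_f >= best_r:
        start = int(np.argmax(fwd))
        strand, k = "+", best_f
        word = idx[start : start + L]
        exact = float(pwm.weights[np.arange(L), word].sum())
    else:
        start = int(np.argmax(rev))
        strand, k = "-", best_r
        word = idx[start : start + L]
        exact = float(pwm.weights[::-1, ::-1][np.arange(L), word].sum())
    return Hit(window_start=start, strand=strand, score=exact, pvalue=dist.tail_int(k))
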