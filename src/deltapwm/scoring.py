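"""Allelic ΔPWM scoring of single-nucleotide variants.

For an SNV embedded in an oligo, the ΔPWM score is the log10 fold change of
the best-hit motif P-values between the two alleles, computed over every
motif window that overlaps the variant position, on both strands.  A
positive ΔPWM means the alternative allele is the more strongly bound one
(smaller best-hit P-value).  Pairs whose best hits are weak on both alleles
(P > 0.005 at both) are flagged as predicted negatives and receive a
ranking score of 0, which places them after every scored pair in
precision-recall ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .motifs import PWM
from .pvalues import ScoreDistribution, best_hit

#: Best-hit P-value above which both alleles must fall for a predicted negative.
NEGATIVE_PVALUE_THRESHOLD = 0.005


@dataclass(frozen=True)
class SnvContext:
    """An SNV with its surrounding oligo sequence (reference allele embedded)."""

    snv_id: str
    oligo: str
    variant_offset: int  # 0-based index into oligo
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if not 0 <= self.variant_offset < len(self.oligo):
            raise ValueError(f"{self.snv_id}: variant_offset outside oligo")
        ref = self.ref_allele.upper()
        alt = self.alt_allele.upper()
        if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
            raise ValueError(f"{self.snv_id}: alleles must be distinct ACGT bases")
        if self.oligo[self.variant_offset].upper() != ref:
            raise ValueError(
                f"{self.snv_id}: oligo base {self.oligo[self.variant_offset]!r} at offset "
                f"{self.variant_offset} does not match ref allele {ref!r}"
            )

    def swapped(self) -> "SnvContext":
        """The same SNV with ref and alt exchanged (alt embedded in the oligo)."""
        o = list(self.oligo)
        o[self.variant_offset] = self.alt_allele
        return SnvContext(self.snv_id, "".join(o), self.variant_offset,
                          self.alt_allele, self.ref_allele)


@dataclass(frozen=True)
class AllelicPrediction:
    snv_id: str
    motif_id: str
    p_ref: float
    p_alt: float
    delta: float  # log10(p_ref) - log10(p_alt); > 0 ⇔ alt more strongly bound
    predicted_negative: bool
    ranking_score: float


def allele_sequences(ctx: SnvContext, motif_length: int) -> tuple[str, str]:
    """Subsequences of the oligo in which every motif window overlaps the variant.

    Returns the slice [max(0, offset−L+1), min(len, offset+L)) with the
    reference allele as-is and with the alternative base substituted.
    Raises if no full window fits.
    """
    L = motif_length
    off = ctx.variant_offset
    lo = max(0, off - L + 1)
    hi = min(len(ctx.oligo), off + L)
    if hi - lo < L:
        raise ValueError(
            f"{ctx.snv_id}: no full {L}-window overlapping the variant fits in the oligo"
        )
    ref_seq = ctx.oligo[lo:hi]
    alt = list(ref_seq)
    alt[off - lo] = ctx.alt_allele
    return ref_seq, "".join(alt)


def delta_pwm(
    pwm: PWM,
    dist: ScoreDistribution,
    ctx: SnvContext,
    neg_threshold: float = NEGATIVE_PVALUE_THRESHOLD,
) -> AllelicPrediction:
    """Best-hit P-values per allele and their log10 fold change."""
    ref_seq, alt_seq = allele_sequences(ctx, dist.length)
    p_ref = best_hit(pwm, ref_seq, dist).pvalue
    p_alt = best_hit(pwm, alt_seq, dist).pvalue
    delta = math.log10(p_ref) - math.log10(p_alt)
    negative = p_ref > neg_threshold and p_alt > neg_threshold
    return AllelicPrediction(
        snv_id=ctx.snv_id,
        motif_id=pwm.motif_id,
        p_ref=p_ref,
        p_alt=p_alt,
        delta=delta,
        predicted_negative=negative,
        ranking_score=0.0 if negative else abs(delta),
    )


def predict_batch(
    pwm: PWM,
    dist: ScoreDistribution,
    contexts: list[SnvContext],
    neg_threshold: float = NEGATIVE_PVALUE_THRESHOLD,
) -> list[AllelicPrediction]:
    """One prediction per context, order preserved.

    Per-context failures are collected and re-raised together with their
    snv_ids rather than silently dropped.
    """
    out: list[AllelicPrediction] = []
    errors: list[str] = []
    for ctx in contexts:
        try:
            out.append(delta_pwm(pwm, dist, ctx, neg_threshold=neg_threshold))
        except ValueError as exc:
            errors.append(f"{ctx.snv_id}: {exc}")
    if errors:
        raise ValueError(
            f"{len(errors)} of {len(contexts)} SNV contexts failed:\n" + "\n".join(errors)
        )
    return out
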