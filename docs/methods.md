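# Methods

## PWM scoring and log-odds conversion

A position frequency matrix (PFM) gives per-position nucleotide probabilities
f(b, i) (columns A, C, G, T, each summing to 1).  It is converted to a
log-odds PWM as

    w(b, i) = ln( (f(b,i)·W + p·q_b) / ((W + p)·q_b) )

with word count W = 100, total pseudocount p = 1 distributed according to the
background q (uniform by default).  This is the standard smoothed log-odds
form: a uniform column under a uniform background maps to weight 0, and the
pseudocount keeps every weight finite even for f = 0.  The pseudocount is
distributed by the background (p·q_b) rather than flat (p/4); with a uniform
background the two coincide, and downstream quantities (P-values, ΔPWM) only
depend on the scores through tail probabilities, which are invariant to
monotone reparametrisations such as the log base.

A site score is the sum of weights over the window; both strands are scanned
(the reverse strand via the reverse-complemented matrix, which keeps window
coordinates on the forward sequence).

## Exact motif P-values

The motif P-value of score s is P(score of a random background word ≥ s).
The full score distribution is computed by dynamic programming: per-position
weights are rounded to an integer grid with step

    step = (max attainable score − min attainable score) / 2^14

and the four-outcome per-position distributions are convolved position by
position.  Rounding each weight introduces at most step/2 error per position,
so a length-L word's grid score differs from its exact score by at most
L·step/2; any tail probability queried at a float score is therefore correct
up to the probability mass within L grid steps of the query ("one effective
bin").  At 2^14 steps this mass is far below the decision thresholds used
downstream (0.005 and 10⁻⁴) for realistic motif lengths.  Best-hit P-values
are looked up with the window's own grid score, which makes reported
P-values exactly self-consistent with the discretized distribution.

Numerical conventions:

- Scores beyond the attainable maximum get the floor P-value 1/(4^L + 1)
  instead of 0, keeping log-fold changes finite.
- `pvalue_to_threshold(α)` returns the minimal attained score whose tail is
  ≤ α (conservative inversion: the tail at the returned threshold never
  exceeds α); an α below the smallest attainable tail returns max score +
  step, so nothing passes, with a logged warning.
- Windows containing ambiguity codes (N etc.) are skipped; a sequence with no
  scoreable window is an error.
- Ties in best-hit scanning prefer the + strand, then the leftmost window,
  for determinism.  Coordinates are 0-based, half-open.

## Allelic ΔPWM score

For an SNV at offset v in an oligo, scanning is restricted to the
subsequence [max(0, v−L+1), min(len, v+L)), i.e. exactly the L-windows
overlapping the variant.  With p_ref and p_alt the best-hit P-values for the
two alleles (both strands),

    ΔPWM = log10 p_ref − log10 p_alt,

positive when the alternative allele is more strongly bound.  The sign
convention is internal: classification uses |ΔPWM|, and the correlation
analyses report the fitted sign.  Pairs with p_ref > 0.005 and p_alt > 0.005
are predicted negatives.

In precision-recall ranking, scored pairs rank by |ΔPWM| and predicted
negatives rank after all of them (ranking score 0), ordered among themselves
by their smaller best-hit P-value — encoded as −min(p_ref, p_alt) so the
ordering embeds in a single scalar.  An alternative mode excludes predicted
negatives from the curve entirely; it is exposed as a flag
(`exclude_predicted_negatives`) but off by default, since ranking them last
uses all labeled records without letting unscored pairs outrank scored ones.

## Benchmarking protocol

Labeling of measured TF–SNV pairs: batch 1 — positive iff PBS p < 0.01 and
OBS p < 0.05, negative iff PBS p > 0.5 and OBS p < 0.05; batch 2 — positive
iff PBS p < 0.01, negative iff PBS p > 0.5; everything else is excluded and
never enters AUPRC computation.

AUPRC is the trapezoidal area under the precision–recall curve with
thresholds at each distinct score (descending) and the point
(recall = 0, precision = 1) prepended; duplicate recalls contribute zero
width.  This matches the area produced by scikit-learn's
`precision_recall_curve` + `auc` (cross-checked in the tests) but is
implemented directly so the curve convention is explicit.

Best-PWM selection fits each TF's candidate set (own motifs plus family
members under the configured family rules, ZNF-prefixed TFs excluded from
extension) on the full labeled batch-1 set and picks the AUPRC argmax; ties
break by catalog status (direct before inferred), then lexicographic motif
id.  Stratified 5-fold cross-validation (scikit-learn `StratifiedKFold`,
shuffled with a fixed seed) reports mean and sd of held-out AUPRC; by
default one fixed PWM is evaluated across folds, with per-training-split
re-selection available as an option (`select_per_fold` /
`candidates=` in `cv_performance`), since protocols differ on this point.
OBS-quantile stratification uses equal-count rank-based quantiles (stable
ranking resolves ties).

Correlation analyses report Pearson r with a two-sided t-distribution
P-value: ΔPWM vs PBS on all joined pairs, on the strong-hit subset
(min(p_ref, p_alt) < 10⁻⁴), and on the best-TF-per-SNV subset (highest PBS
per SNV); and ΔPWM vs ChIP-seq allelic binding ratio (an opaque real-valued
column), optionally filtered to pairs with a motif hit at P < 0.005.  Fewer
than 3 pairs after subsetting is an error, reported per analysis.

## Synthetic data generator

The generator emulates the structure of SNP-SELEX-style inputs, not the
biophysics of SELEX enrichment:

- **Motifs.** Each TF's generating PFM has i.i.d. symmetric-Dirichlet columns
  (concentration 0.5, length drawn from 8–12).  Low concentration yields the
  sharp, information-rich columns typical of curated motif collections.
  Decoys (5 per TF) are column permutations (non-identity enforced) or
  Dirichlet-perturbed variants, catalogued as "inferred" motifs of the same
  TF so candidate sets contain the truth plus plausible impostors.
- **SNVs.** Oligos are uniform-random 40-mers with the variant at 0-based
  offset 19, so every motif window fits; boundary placement is exercised
  separately in the scoring tests.  The true effect of an SNV is the ΔPWM of
  the generating PWM.
- **Measurements.** PBS = true ΔPWM + Normal(0, σ) noise with
  σ = 0.25 × sd(true ΔPWM) per TF by default (noise a quarter of the signal
  spread); the PBS P-value is the exact two-sided Gaussian tail under the
  matching null, so P-values of effect-free SNVs are uniform (verified by a
  Kolmogorov–Smirnov check).  OBS = best-hit score of the stronger allele +
  Normal(0, 1) noise, with its P-value defined analogously.  Allelic binding
  ratio = logistic(true ΔPWM) + Normal(0, 0.05), clipped to [0, 1].  Records
  are split between batches at random (fraction 0.5 to batch 1).
- **Determinism.** All randomness derives from one seed; fixture trees are
  byte-identical across reruns with the same configuration.  Ground truth
  (generating motif per TF, true ΔPWM and noiseless label per SNV) is written
  alongside for tests and is never read by the pipeline.

What passing tests on this generator do and do not show: they demonstrate
that the selection protocol identifies the data-generating motif among
decoys, that exact P-values, labeling, AUPRC and correlations are computed
correctly, and that the correlation attenuation behaves analytically
(r = 1/sqrt(1 + σ²/var(ΔPWM))).  They do not show that real SNP-SELEX
measurements follow a Gaussian noise model, that real oligos are
base-uniform (genomic 40-mers around regulatory SNVs are enriched for
binding sites, so real data contain far more strong motif hits), or that
CIS-BP motifs for a TF resemble shuffled decoys.

A structural consequence of the uniform-random oligo design worth noting:
most simulated SNVs lack a motif hit at P < 0.005 on either allele, so a
large share of labeled positives fall into the predicted-negative block of
the ranking.  This caps per-replicate batch-2 AUPRC around 0.88–0.93 (mean
≈ 0.92 at default conditions) even though the generating PWM is recovered
and outranks every decoy essentially always.  On site-centred real data the
predicted-negative fraction among true positives is much lower.

## Problem sizes

The default study conditions are 5 TFs × 1000 SNVs per TF with 6 candidate
motifs per TF; the recovery experiment repeats this across seeded
replicates (20 in the test suite, 10 in the acceptance script).  The test
fixtures use 1–3 TFs × 120–500 SNVs, chosen to exercise every code path at
interactive speeds.

## Known limitations

- Mononucleotide background only (uniform or fixed 4-vector); no
  higher-order background models.
- Oligo-centric scoring of single-nucleotide substitutions only: no indels,
  multi-nucleotide variants, or reference-genome scanning.
- The exact-P-value engine targets motif lengths up to a few tens of
  positions; the discretization guarantee weakens as L grows.
- Family extension is configuration-driven (prefix-keyed family lists with a
  ZNF exclusion list); no automatic DNA-binding-domain similarity inference.
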