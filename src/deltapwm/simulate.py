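"""Synthetic SNP-SELEX-style data generation.

Generates every input the pipeline consumes — a motif catalog with PFM
files, two batches of TF–SNV measurement tables, and an allele-specific
binding (ASB) ratio table — from a documented generative model with a
single seed, so the full analysis is testable without external downloads.

Generative model
----------------
Each simulated TF gets a generating PFM whose columns are independent
symmetric Dirichlet draws (low concentration = sharp, information-rich
columns), plus decoy motifs derived from it by column permutation or
frequency perturbation.  Each SNV sits at the center of a random 40-nt
oligo; its true effect is the ΔPWM of the generating PWM.  The measured
PBS (preferential binding score) is the true ΔPWM plus Gaussian noise and
its P-value is the exact two-sided tail under the matching Gaussian null,
so simulated P-values are uniform for null SNVs; the OBS (observed
binding) score is the stronger allele's best-hit score plus Gaussian
noise, with its P-value defined analogously.  Allelic binding ratios are a
logistic transform of the true ΔPWM plus noise.

Ground truth (generating motif per TF, true ΔPWM and noiseless label per
SNV) is written alongside for tests; the pipeline under test never reads it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .motifs import ALPHABET, PFM, PWM, FamilyRuleSet, pfm_to_pwm, write_pfm
from .pvalues import ScoreDistribution, best_hit
from .scoring import SnvContext, delta_pwm


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic SNP-SELEX emulation.

    ``noise_sd_pbs`` may be a float or "auto", in which case the PBS noise
    sd is 0.25 × sd(true ΔPWM) per TF — noise a quarter of the signal
    spread.  The variant sits at the oligo center so every motif window
    fits; boundary placement is exercised separately in the scoring tests.
    """

    n_tfs: int = 5
    motif_length_range: tuple[int, int] = (8, 12)
    dirichlet_concentration: float = 0.5
    n_snvs_per_tf: int = 1000
    oligo_length: int = 40
    noise_sd_pbs: float | str = "auto"
    noise_sd_obs: float = 1.0
    decoys_per_tf: int = 5
    decoy_corruption: str = "column_shuffle"  # or "weight_noise"
    batch_split_fraction: float = 0.5
    asb_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.motif_length_range
        if min(self.n_tfs, self.n_snvs_per_tf, self.decoys_per_tf, lo) < 1:
            raise ValueError("all counts must be positive")
        if self.oligo_length < hi + 2:
            raise ValueError("oligo_length must be at least max motif length + 2")
        if self.decoy_corruption not in ("column_shuffle", "weight_noise"):
            raise ValueError(f"unknown decoy_corruption {self.decoy_corruption!r}")
        if not 0 < self.batch_split_fraction < 1:
            raise ValueError("batch_split_fraction must lie in (0, 1)")


@dataclass
class TfTruth:
    tf_name: str
    pfm: PFM
    pwm: PWM
    decoys: list[PFM]
    snv_true_delta: dict[str, float] = field(default_factory=dict)
    snv_true_label: dict[str, str] = field(default_factory=dict)


@dataclass
class GroundTruth:
    config: SimulationConfig
    tfs: list[TfTruth]


def generate_pfm(length: int, concentration: float, seed_or_rng) -> PFM:
    """PFM with i.i.d. symmetric-Dirichlet columns; deterministic per seed."""
    if length < 1 or concentration <= 0:
        raise ValueError("length must be >= 1 and concentration > 0")
    rng = _as_rng(seed_or_rng)
    m = rng.dirichlet(np.full(4, concentration), size=length)
    return PFM(motif_id=f"sim_L{length}", matrix=m)


def make_decoys(pfm: PFM, n: int, mode: str, seed_or_rng) -> list[PFM]:
    """Decoy motifs sharing the source's length.

    ``column_shuffle`` permutes positions with a non-identity permutation
    (error for length-1 motifs, where none exists); ``weight_noise`` mixes
    each column with a fresh Dirichlet draw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed_or_rng)
    L = len(pfm)
    out = []
    for k in range(n):
        if mode == "column_shuffle":
            if L < 2:
                raise ValueError("column_shuffle needs motif length >= 2")
            perm = rng.permutation(L)
            while np.array_equal(perm, np.arange(L)):
                perm = rng.permutation(L)
            m = pfm.matrix[perm]
        elif mode == "weight_noise":
            noise = rng.dirichlet(np.full(4, 1.0), size=L)
            m = 0.5 * pfm.matrix + 0.5 * noise
        else:
            raise ValueError(f"unknown decoy mode {mode!r}")
        out.append(PFM(motif_id=f"{pfm.motif_id}_decoy{k + 1}", matrix=m))
    return out


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _random_oligo(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def generate_truth(cfg: SimulationConfig) -> GroundTruth:
    """Draw the generating motif and decoys for every simulated TF."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.motif_length_range
    tfs = []
    for t in range(cfg.n_tfs):
        tf_name = f"TF{t + 1:03d}"
        L = int(rng.integers(lo, hi + 1))
        pfm = generate_pfm(L, cfg.dirichlet_concentration, rng)
        pfm = PFM(motif_id=f"M{t + 1:03d}_true", matrix=pfm.matrix)
        decoys = make_decoys(pfm, cfg.decoys_per_tf, cfg.decoy_corruption, rng)
        decoys = [
            PFM(motif_id=f"M{t + 1:03d}_decoy{k + 1}", matrix=d.matrix)
            for k, d in enumerate(decoys)
        ]
        tfs.append(TfTruth(tf_name=tf_name, pfm=pfm, pwm=pfm_to_pwm(pfm), decoys=decoys))
    return GroundTruth(config=cfg, tfs=tfs)


def simulate_measurements(
    truth: GroundTruth, cfg: SimulationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (batch-1, batch-2, ASB) tables for every TF in ``truth``.

    Fills each TF's ``snv_true_delta`` / ``snv_true_label`` as a side
    effect.  All randomness derives from the config seed (offset so motif
    generation and measurement noise use independent streams).
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(cfg.seed + 1_000_003)
    center = cfg.oligo_length // 2 - 1  # offset 19 of a 40-mer, 0-based
    rows = []
    asb_rows = []
    for tf in truth.tfs:
        dist = ScoreDistribution(tf.pwm)
        contexts = []
        for s in range(cfg.n_snvs_per_tf):
            oligo = _random_oligo(rng, cfg.oligo_length)
            ref = oligo[center]
            others = [b for b in ALPHABET if b != ref]
            alt = others[int(rng.integers(0, 3))]
            contexts.append(SnvContext(
                snv_id=f"{tf.tf_name}_snv{s + 1:05d}",
                oligo=oligo,
                variant_offset=center,
                ref_allele=ref,
                alt_allele=alt,
            ))
        true_deltas = np.empty(len(contexts))
        obs_base = np.empty(len(contexts))
        for i, ctx in enumerate(contexts):
            pred = delta_pwm(tf.pwm, dist, ctx)
            true_deltas[i] = pred.delta
            # stronger allele = smaller best-hit P-value; its best-hit score
            ref_seq, alt_seq = _allele_seqs(ctx, dist.length)
            hit_ref = best_hit(tf.pwm, ref_seq, dist)
            hit_alt = best_hit(tf.pwm, alt_seq, dist)
            obs_base[i] = max(hit_ref.score, hit_alt.score)
        sd_delta = float(true_deltas.std(ddof=0))
        sigma_pbs = (
            0.25 * sd_delta if cfg.noise_sd_pbs == "auto" else float(cfg.noise_sd_pbs)
        )
        sigma_pbs = max(sigma_pbs, 1e-12)
        pbs = true_deltas + rng.normal(0.0, sigma_pbs, size=len(contexts))
        pbs_p = 2.0 * stats.norm.sf(np.abs(pbs) / sigma_pbs)
        obs = obs_base + rng.normal(0.0, cfg.noise_sd_obs, size=len(contexts))
        obs_p = 2.0 * stats.norm.sf(np.abs(obs) / max(cfg.noise_sd_obs, 1e-12))
        # noiseless labels for ground truth
        p0 = 2.0 * stats.norm.sf(np.abs(true_deltas) / sigma_pbs)
        ratio = _logistic(true_deltas) + rng.normal(0.0, cfg.asb_noise_sd, size=len(contexts))
        ratio = np.clip(ratio, 0.0, 1.0)
        n1 = int(round(cfg.batch_split_fraction * len(contexts)))
        batch_of = np.full(len(contexts), 2, dtype=int)
        batch_of[rng.permutation(len(contexts))[:n1]] = 1
        for i, ctx in enumerate(contexts):
            tf.snv_true_delta[ctx.snv_id] = float(true_deltas[i])
            tf.snv_true_label[ctx.snv_id] = (
                "positive" if p0[i] < 0.01 else "negative" if p0[i] > 0.5 else "excluded"
            )
            rows.append({
                "tf_name": tf.tf_name,
                "snv_id": ctx.snv_id,
                "oligo": ctx.oligo,
                "variant_offset": ctx.variant_offset,
                "ref_allele": ctx.ref_allele,
                "alt_allele": ctx.alt_allele,
                "pbs_score": pbs[i],
                "pbs_pvalue": pbs_p[i],
                "obs_score": obs[i],
                "obs_pvalue": obs_p[i],
                "batch": int(batch_of[i]),
            })
            asb_rows.append({
                "tf_name": tf.tf_name,
                "snv_id": ctx.snv_id,
                "allelic_ratio": ratio[i],
            })
    df = pd.DataFrame(rows)
    asb = pd.DataFrame(asb_rows)
    return (
        df[df["batch"] == 1].reset_index(drop=True),
        df[df["batch"] == 2].reset_index(drop=True),
        asb,
    )


def _allele_seqs(ctx: SnvContext, L: int) -> tuple[str, str]:
    from .scoring import allele_sequences

    return allele_sequences(ctx, L)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def write_fixture_tree(
    out_dir: str | Path, cfg: SimulationConfig, overwrite: bool = False
) -> Path:
    """Write a complete fixture: catalog + PFMs, measurements, ASB, rules, truth.

    Re-running with the same config reproduces byte-identical files.
    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (pass overwrite=True)")
    (out / "pfms").mkdir(parents=True, exist_ok=True)
    truth = generate_truth(cfg)
    batch1, batch2, asb = simulate_measurements(truth, cfg)

    catalog_rows = []
    for tf in truth.tfs:
        write_pfm(tf.pfm, out / "pfms" / f"{tf.pfm.motif_id}.txt")
        catalog_rows.append({
            "TF_Name": tf.tf_name, "Motif_ID": tf.pfm.motif_id, "TF_Status": "D",
            "TF_Species": "Homo_sapiens", "MSource_Type": "ChIP-seq",
        })
        for d in tf.decoys:
            write_pfm(d, out / "pfms" / f"{d.motif_id}.txt")
            catalog_rows.append({
                "TF_Name": tf.tf_name, "Motif_ID": d.motif_id, "TF_Status": "I",
                "TF_Species": "Homo_sapiens", "MSource_Type": "PBM",
            })
    pd.DataFrame(catalog_rows).to_csv(out / "catalog.tsv", sep="\t", index=False)
    fmt = "%.10g"
    batch1.to_csv(out / "measurements_batch1.tsv", sep="\t", index=False, float_format=fmt)
    batch2.to_csv(out / "measurements_batch2.tsv", sep="\t", index=False, float_format=fmt)
    asb.to_csv(out / "asb.tsv", sep="\t", index=False, float_format=fmt)
    FamilyRuleSet(families={}, exclude_prefixes=["ZNF"]).to_yaml(out / "family_rules.yaml")

    gt = {
        "config": _config_dict(cfg),
        "tfs": {
            tf.tf_name: {
                "generating_motif": tf.pfm.motif_id,
                "decoys": [d.motif_id for d in tf.decoys],
                "snvs": {
                    sid: {
                        "true_delta": round(tf.snv_true_delta[sid], 10),
                        "true_label": tf.snv_true_label[sid],
                    }
                    for sid in sorted(tf.snv_true_delta)
                },
            }
            for tf in truth.tfs
        },
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["motif_length_range"] = list(d["motif_length_range"])
    return d
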