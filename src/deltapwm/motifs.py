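"""Motif catalog parsing and PFM → log-odds PWM conversion.

Reads CIS-BP-style motif catalogs (a tab-separated metadata table plus one
position-frequency-matrix text file per motif), converts PFMs to log-odds
position weight matrices, and assembles per-TF candidate PWM sets with
family extension (e.g. all FOX* motifs join the FOXA2 candidate set), with
zinc-finger (ZNF*) TFs excluded from extension because their motifs are too
dissimilar for cross-TF transfer to help.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Column-sum slack tolerated in PFM files before a row is rejected.
PFM_COLUMN_SUM_TOL = 0.01


@dataclass(frozen=True)
class PFM:
    """Position frequency matrix: one probability 4-vector (A,C,G,T) per position."""

    motif_id: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PFM {self.motif_id}: matrix must be (L, 4) with L >= 1")
        if np.any(m < 0) or np.any(m > 1 + 1e-9):
            raise ValueError(f"PFM {self.motif_id}: entries must lie in [0, 1]")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"PFM {self.motif_id}: columns must sum to 1 (got {sums})")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass(frozen=True)
class PWM:
    """Log-odds position weight matrix (natural-log units)."""

    motif_id: str
    weights: np.ndarray  # shape (L, 4)
    source_pfm: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValueError(f"PWM {self.motif_id}: weights must be (L, 4) with L >= 1")
        if not np.all(np.isfinite(w)):
            raise ValueError(f"PWM {self.motif_id}: weights must be finite")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.weights[::-1, ::-1], self.source_pfm)


@dataclass(frozen=True)
class MotifCatalogEntry:
    tf_name: str
    motif_id: str
    status: str  # "direct" | "inferred"
    species: str
    experiment_type: str
    pfm_path: Path

    def __post_init__(self) -> None:
        if self.status not in ("direct", "inferred"):
            raise ValueError(f"status must be 'direct' or 'inferred', got {self.status!r}")


@dataclass
class FamilyRuleSet:
    """TF family grouping used to extend candidate PWM sets.

    ``families`` maps a family key (a gene-symbol prefix such as "FOX" or
    "ETV") to its member TF names; TFs whose name starts with an excluded
    prefix (ZNF by default) never receive family extension.
    """

    families: dict[str, list[str]] = field(default_factory=dict)
    exclude_prefixes: list[str] = field(default_factory=lambda: ["ZNF"])

    def family_of(self, tf_name: str) -> str | None:
        for key, members in self.families.items():
            if tf_name in members:
                return key
        return None

    def is_excluded(self, tf_name: str) -> bool:
        return any(tf_name.upper().startswith(p.upper()) for p in self.exclude_prefixes)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FamilyRuleSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            families={str(k): [str(t) for t in v] for k, v in (data.get("families") or {}).items()},
            exclude_prefixes=[str(p) for p in data.get("exclude_prefixes", ["ZNF"])],
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"families": self.families, "exclude_prefixes": self.exclude_prefixes},
                fh,
                sort_keys=True,
            )


# CIS-BP TF_Information_all_motifs.txt column names; remappable for header drift.
DEFAULT_CATALOG_COLUMNS = {
    "tf_name": "TF_Name",
    "motif_id": "Motif_ID",
    "status": "TF_Status",
    "species": "TF_Species",
    "experiment_type": "MSource_Type",
}

_STATUS_ALIASES = {"d": "direct", "direct": "direct", "i": "inferred", "inferred": "inferred"}


def read_pfm(path: str | Path, motif_id: str | None = None) -> PFM:
    """Read a PFM text file (header ``Pos A C G T``, one row per position).

    Columns whose probabilities sum to within 0.01 of 1 are renormalized;
    larger deviations, negative entries, or non-numeric cells raise a
    ``ValueError`` naming the offending line.  Matrices written as counts
    (any entry > 1.5) are detected and normalized per column.
    """
    path = Path(path)
    if motif_id is None:
        motif_id = path.stem
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty PFM file")
    start = 0
    first = lines[0].split()
    if first and not _is_number(first[0]):  # header line
        start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        if not parts:
            continue
        vals = parts[-4:] if len(parts) >= 4 else parts
        if len(vals) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 nucleotide columns, got {len(vals)}")
        try:
            row = [float(v) for v in vals]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
        if any(v < 0 for v in row):
            raise ValueError(f"{path}:{lineno}: negative entry")
        rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no matrix rows")
    m = np.array(rows, dtype=float)
    if np.any(m > 1.5):  # count dialect
        m = m / m.sum(axis=1, keepdims=True)
    else:
        sums = m.sum(axis=1)
        bad = np.abs(sums - 1.0) > PFM_COLUMN_SUM_TOL
        if np.any(bad):
            idx = int(np.nonzero(bad)[0][0])
            raise ValueError(
                f"{path}:{start + idx + 1}: column sum {sums[idx]:.4f} deviates from 1 by more "
                f"than {PFM_COLUMN_SUM_TOL}"
            )
        m = m / sums[:, None]
    return PFM(motif_id=motif_id, matrix=m)


def write_pfm(pfm: PFM, path: str | Path) -> None:
    """Write a PFM in the dialect :func:`read_pfm` reads (header ``Pos A C G T``)."""
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(pfm.matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def parse_catalog(
    catalog_file: str | Path,
    pfm_dir: str | Path,
    columns: dict[str, str] | None = None,
) -> list[MotifCatalogEntry]:
    """Parse a CIS-BP-style catalog TSV into catalog entries.

    Rows whose PFM file is missing or empty are skipped with a logged
    warning; a missing header column is a hard error naming the columns.
    """
    cols = dict(DEFAULT_CATALOG_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(catalog_file, sep="\t", dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"{catalog_file}: missing required catalog columns: {missing}")
    pfm_dir = Path(pfm_dir)
    entries: list[MotifCatalogEntry] = []
    n_skipped = 0
    for _, row in df.iterrows():
        motif_id = str(row[cols["motif_id"]]).strip()
        if not motif_id or motif_id == "." or motif_id.lower() == "nan":
            n_skipped += 1
            continue
        pfm_path = pfm_dir / f"{motif_id}.txt"
        if not pfm_path.exists() or pfm_path.stat().st_size == 0:
            logger.warning("skipping motif %s: PFM file missing or empty (%s)", motif_id, pfm_path)
            n_skipped += 1
            continue
        status = _STATUS_ALIASES.get(str(row[cols["status"]]).strip().lower())
        if status is None:
            raise ValueError(f"{catalog_file}: unknown TF status {row[cols['status']]!r}")
        entries.append(
            MotifCatalogEntry(
                tf_name=str(row[cols["tf_name"]]).strip(),
                motif_id=motif_id,
                status=status,
                species=str(row[cols["species"]]).strip(),
                experiment_type=str(row[cols["experiment_type"]]).strip(),
                pfm_path=pfm_path,
            )
        )
    if n_skipped:
        logger.warning("parse_catalog: skipped %d catalog rows", n_skipped)
    return entries


def pfm_to_pwm(
    pfm: PFM,
    word_count: float = 100.0,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Convert a PFM to a log-odds PWM.

    weight(b, i) = ln( (f(b,i)·W + p·q_b) / ((W + p)·q_b) )

    with word count ``W``, total pseudocount ``p`` distributed according to
    the background ``q`` (uniform by default).  A uniform PFM column under a
    uniform background maps to all-zero weights, and the pseudocount keeps
    every weight finite.
    """
    if word_count <= 0 or pseudocount <= 0:
        raise ValueError("word_count and pseudocount must be positive")
    q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if q.shape != (4,) or np.any(q <= 0) or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a strictly positive 4-vector summing to 1")
    f = pfm.matrix
    weights = np.log((f * word_count + pseudocount * q) / ((word_count + pseudocount) * q))
    return PWM(motif_id=pfm.motif_id, weights=weights, source_pfm=pfm.motif_id)


def pwm_to_smoothed_frequencies(
    pwm: PWM, word_count: float = 100.0, pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Invert :func:`pfm_to_pwm` up to smoothing: exp the weights and rescale.

    Returns the smoothed frequencies (f·W + p·q)/(W + p); useful for
    round-trip checks.
    """
    q = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    return np.exp(pwm.weights) * q  # = (f·W + p·q)/(W + p)


def assemble_candidate_set(
    tf_name: str,
    catalog: list[MotifCatalogEntry],
    rules: FamilyRuleSet | None = None,
) -> list[MotifCatalogEntry]:
    """Assemble the candidate motif set for a TF: own entries plus family members.

    Every entry assigned to ``tf_name`` (direct and inferred) is included;
    if the TF belongs to a family under ``rules`` the entries of all family
    members are added, except for TFs matching an excluded prefix (ZNF*),
    which keep only their own entries.  Duplicates by motif_id are removed
    (first occurrence wins; own entries come first).
    """
    own = [e for e in catalog if e.tf_name == tf_name]
    result = list(own)
    if rules is not None and not rules.is_excluded(tf_name):
        family = rules.family_of(tf_name)
        if family is not None:
            members = set(rules.families[family])
            for e in catalog:
                if e.tf_name in members and e.tf_name != tf_name and not rules.is_excluded(e.tf_name):
                    result.append(e)
    if not result:
        logger.warning("assemble_candidate_set: unknown TF %r, returning empty set", tf_name)
        return []
    seen: set[str] = set()
    unique: list[MotifCatalogEntry] = []
    for e in result:
        if e.motif_id not in seen:
            seen.add(e.motif_id)
            unique.append(e)
    return unique


def load_candidate_pwms(
    entries: list[MotifCatalogEntry],
    word_count: float = 100.0,
    pseudocount: float = 1.0,
) -> list[tuple[PWM, MotifCatalogEntry]]:
    """Read and convert the PFM behind each catalog entry."""
    out = []
    for e in entries:
        pfm = read_pfm(e.pfm_path, motif_id=e.motif_id)
        out.append((pfm_to_pwm(pfm, word_count=word_count, pseudocount=pseudocount), e))
    return out
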