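"""Per-allele 9-mer scoring matrices and their Z-score calibration.

An HLA-DRB1 binding matrix assigns a real-valued score to each of the 20
amino acids at each of the nine positions of the class II binding groove.
The raw score of a 9-mer peptide is the sum of the nine position scores.
Raw scores are standardised into Z-scores against an analytic null: the
score of a random 9-mer whose residues are drawn independently from a
background amino-acid distribution.  A frame with Z >= 1.64 is called a
binding *hit*; 1.28 <= Z < 1.64 is a *likely* hit.

The analytic null uses the fact that position contributions are independent
under the background model, so the null mean and variance are sums of
per-position background moments of the matrix rows.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import norm

#: Canonical one-letter amino-acid order used by every matrix file.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

NINE = 9  # class II binding-groove frame length


class PSSMError(ValueError):
    """Malformed matrix file or invalid matrix contents."""


class DegenerateMatrixError(PSSMError):
    """Matrix whose null standard deviation is zero; Z-scores undefined."""


@dataclass(frozen=True)
class AminoAlphabet:
    """Ordered amino-acid alphabet shared by all matrices in a run."""

    residues: tuple[str, ...] = tuple(CANONICAL_ALPHABET)

    def __post_init__(self) -> None:
        if len(self.residues) != 20 or len(set(self.residues)) != 20:
            raise PSSMError("alphabet must contain exactly 20 unique residues")
        if any(len(r) != 1 or not r.isupper() for r in self.residues):
            raise PSSMError("alphabet residues must be single uppercase letters")

    def index(self, residue: str) -> int:
        try:
            return self.residues.index(residue)
        except ValueError:
            raise PSSMError(f"unknown residue {residue!r}") from None

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to integer indices, naming the offending position."""
        lut = {r: i for i, r in enumerate(self.residues)}
        out = np.empty(len(sequence), dtype=np.int64)
        for i, ch in enumerate(sequence):
            try:
                out[i] = lut[ch]
            except KeyError:
                raise PSSMError(
                    f"unknown residue {ch!r} at position {i + 1}"
                ) from None
        return out


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Background amino-acid distribution used for Z-score calibration."""

    probs: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.probs.values()), dtype=float)
        if (vals <= 0).any():
            raise PSSMError("background probabilities must all be positive")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise PSSMError("background probabilities must sum to 1")

    @classmethod
    def uniform(cls, alphabet: AminoAlphabet | None = None) -> "BackgroundFrequencies":
        alphabet = alphabet or AminoAlphabet()
        p = 1.0 / len(alphabet.residues)
        return cls({r: p for r in alphabet.residues})

    def as_array(self, alphabet: AminoAlphabet) -> np.ndarray:
        missing = [r for r in alphabet.residues if r not in self.probs]
        if missing:
            raise PSSMError(f"background missing residues: {missing}")
        return np.array([self.probs[r] for r in alphabet.residues], dtype=float)


_ALLELE_RE = re.compile(r"DRB1[\s*_\-]*(\d{2}):?(\d{2,3})", re.IGNORECASE)


def normalize_allele(name: str) -> str:
    """Normalise an HLA-DRB1 allele name to two-field colon form.

    Accepts ``DRB1*0101``, ``DRB1*01:01``, ``DRB1_0101`` etc. and returns
    ``DRB1*01:01``.
    """
    m = _ALLELE_RE.search(name)
    if not m:
        raise PSSMError(f"cannot parse HLA-DRB1 allele name from {name!r}")
    return f"DRB1*{m.group(1)}:{m.group(2)}"


@dataclass
class PSSM:
    """One allele's 9-position x 20-residue scoring matrix."""

    allele: str
    matrix: np.ndarray
    source_tag: str = ""
    alphabet: AminoAlphabet = field(default_factory=AminoAlphabet)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (NINE, 20):
            raise PSSMError(
                f"expected 9 positions x 20 residues, got {self.matrix.shape}"
            )
        if not np.isfinite(self.matrix).all():
            raise PSSMError("matrix entries must all be finite")
        self.allele = normalize_allele(self.allele)


@dataclass(frozen=True)
class NullMoments:
    """Mean and standard deviation of the raw 9-mer score under background."""

    allele: str
    mu: float
    sigma: float

    @property
    def degenerate(self) -> bool:
        return self.sigma == 0.0


@dataclass(frozen=True)
class HitThresholds:
    """Z cutoffs for binding hits; comparisons are inclusive."""

    hit: float = 1.64
    likely: float = 1.28

    def __post_init__(self) -> None:
        if not self.likely < self.hit:
            raise PSSMError("likely threshold must be below hit threshold")


def _parse_matrix_csv(path: Path) -> PSSM:
    allele = None
    rows: list[list[float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.search(r"allele\s*=\s*(\S+)", line)
                if m:
                    allele = m.group(1)
                continue
            cells = [c.strip() for c in line.split(",")]
            if header is None:
                header = cells
                if header != list(CANONICAL_ALPHABET):
                    bad = [c for c in header if c not in CANONICAL_ALPHABET]
                    raise PSSMError(
                        f"{path.name}:{lineno}: header must list the 20 residues "
                        f"in canonical order {CANONICAL_ALPHABET}"
                        + (f"; unknown columns {bad}" if bad else "")
                    )
                continue
            if len(cells) != 20:
                raise PSSMError(
                    f"{path.name}:{lineno}: expected 20 values, got {len(cells)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise PSSMError(f"{path.name}:{lineno}: non-numeric entry ({exc})")
    if header is None:
        raise PSSMError(f"{path.name}: empty matrix file")
    if len(rows) != NINE:
        raise PSSMError(
            f"{path.name}: expected 9 positions, got {len(rows)} data rows"
        )
    if allele is None:
        allele = path.stem  # allele encoded in the filename
    return PSSM(allele=allele, matrix=np.array(rows), source_tag=str(path))


def _parse_matrix_json(path: Path) -> PSSM:
    with open(path) as fh:
        obj = json.load(fh)
    try:
        allele = obj["allele"]
        matrix = obj["matrix"]
    except (TypeError, KeyError) as exc:
        raise PSSMError(f"{path.name}: missing key {exc}")
    return PSSM(
        allele=allele,
        matrix=np.array(matrix, dtype=float),
        source_tag=obj.get("source_tag", str(path)),
    )


def load_pssm(path: str | Path) -> PSSM:
    """Load one allele's matrix from a CSV or JSON file.

    CSV dialect: optional ``# allele=...`` comment lines, a header row with
    the 20 residues in canonical order, then nine data rows (binding-groove
    positions 1-9).  JSON dialect: an object with ``allele`` and ``matrix``
    (nine arrays of twenty numbers).  When the CSV carries no allele comment
    the allele is parsed from the filename.
    """
    path = Path(path)
    if not path.exists():
        raise PSSMError(f"matrix file not found: {path}")
    if path.suffix.lower() == ".json":
        return _parse_matrix_json(path)
    return _parse_matrix_csv(path)


def load_pssm_set(directory: str | Path) -> list[PSSM]:
    """Load every ``*.csv`` / ``*.json`` matrix in a directory, sorted by allele."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv")) + sorted(directory.glob("*.json"))
    if not paths:
        raise PSSMError(f"no matrix files found in {directory}")
    pssms = [load_pssm(p) for p in paths]
    return sorted(pssms, key=lambda p: p.allele)


def null_moments(pssm: PSSM, bg: BackgroundFrequencies) -> NullMoments:
    """Analytic null mean/sd of the raw 9-mer score under the background.

    Positions are independent under the null, so the mean is the sum of the
    background-weighted row means and the variance the sum of the
    background-weighted row variances.
    """
    p = bg.as_array(pssm.alphabet)
    row_mean = pssm.matrix @ p
    row_second = (pssm.matrix**2) @ p
    var = float(np.sum(row_second - row_mean**2))
    # guard tiny negative round-off
    var = max(var, 0.0)
    return NullMoments(allele=pssm.allele, mu=float(row_mean.sum()), sigma=float(np.sqrt(var)))


def score_ninemer(pssm: PSSM, peptide: str) -> float:
    """Additive raw score of a single 9-residue frame."""
    if len(peptide) != NINE:
        raise PSSMError(f"peptide must be 9 residues, got {len(peptide)}")
    idx = pssm.alphabet.encode(peptide)
    return float(pssm.matrix[np.arange(NINE), idx].sum())


def zscore(raw: float, nm: NullMoments) -> float:
    if nm.degenerate:
        raise DegenerateMatrixError(
            f"matrix for {nm.allele} has zero null variance; Z undefined"
        )
    return (raw - nm.mu) / nm.sigma


def classify_hit(z: float, thresholds: HitThresholds | None = None) -> str:
    """Classify a Z-value as ``hit``, ``likely`` or ``none`` (inclusive cutoffs)."""
    t = thresholds or HitThresholds()
    if z >= t.hit:
        return "hit"
    if z >= t.likely:
        return "likely"
    return "none"


def expected_hit_excess(theta: float = 1.64) -> float:
    """Null expectation e0 = E[Z * 1{Z >= theta}] for standard-normal Z.

    Closed form: the standard-normal density at theta.  This is the
    per-assessment epitope content a random protein is expected to carry, and
    the quantity protein scores are centred on.
    """
    return float(norm.pdf(theta))


def write_pssm_csv(pssm: PSSM, path: str | Path) -> None:
    """Write a matrix in the documented CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# allele={pssm.allele}\n")
        fh.write(",".join(pssm.alphabet.residues) + "\n")
        for row in pssm.matrix:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
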