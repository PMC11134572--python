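"""Whole-protein epitope scanning and length-normalised protein scores.

A protein of length L is decomposed into its L-8 overlapping 9-mer frames.
Each frame is scored against every allele matrix and standardised to a
Z-score, giving a (frame x allele) assessment grid.  Frames that fall
entirely inside a known regulatory T-cell epitope (Tregitope) are masked so
that their predicted binding content can be excluded from aggregate scores.

The protein-level score is the excess hit-weighted Z content per 1000
(frame x allele) assessments over the random-protein expectation::

    score = (O - A * e0) / A * 1000

where A is the assessment count, O the sum of Z over cells classified as
hits, and e0 = E[Z 1{Z >= theta}] under the standard normal null.  Random
proteins therefore score ~0; epitope-dense proteins score positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .pssm import (
    NINE,
    AminoAlphabet,
    BackgroundFrequencies,
    HitThresholds,
    PSSM,
    PSSMError,
    expected_hit_excess,
    null_moments,
)

#: Reference annotations for the score scale (report metadata only): medians
#: of Tregitope-adjusted scores for the human proteome and for secreted human
#: proteins, computed with the original proprietary matrices and therefore
#: not recomputable by this package.
REFERENCE_SCORE_ANNOTATIONS = {
    "human_proteome_median": -9.05,
    "secreted_human_proteins_median": -23.08,
}

HIT_CLASS_CODES = {0: "none", 1: "likely", 2: "hit"}


class ScanError(ValueError):
    """Invalid protein or grid input."""


@dataclass
class ProteinRecord:
    """A protein sequence to be scanned."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class TregitopeRegistry:
    """Known regulatory T-cell epitope peptides, matched by exact substring."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ScanError("tregitope ids must be unique")
        for tid, pep in self.entries:
            if len(pep) < NINE:
                raise ScanError(f"tregitope {tid} shorter than 9 residues")

    @property
    def peptides(self) -> list[str]:
        return [pep for _, pep in self.entries]


@dataclass
class AssessmentGrid:
    """Per-(frame x allele) Z-scores and hit classes for one protein."""

    protein_id: str
    frames: np.ndarray  # 1-based frame start positions, length L-8
    alleles: list[str]
    z: np.ndarray  # shape (frames, alleles)
    hit_class: np.ndarray  # int8 codes: 0 none, 1 likely, 2 hit
    masked: np.ndarray  # bool per frame: inside a Tregitope span
    thresholds: HitThresholds = field(default_factory=HitThresholds)

    def __post_init__(self) -> None:
        f, k = self.z.shape
        if len(self.frames) != f or len(self.alleles) != k:
            raise ScanError("grid dimensions inconsistent")
        if self.hit_class.shape != (f, k) or self.masked.shape != (f,):
            raise ScanError("grid dimensions inconsistent")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_assessments(self) -> int:
        return self.z.size

    def allele_index(self, allele: str) -> int:
        try:
            return self.alleles.index(allele)
        except ValueError:
            raise ScanError(
                f"allele {allele} not in grid for {self.protein_id}"
            ) from None

    def per_allele_content(self, adjusted: bool = False) -> np.ndarray:
        """Per-allele sum of Z over hit cells (masked frames zeroed if adjusted)."""
        hit = self.hit_class == 2
        contrib = np.where(hit, self.z, 0.0)
        if adjusted:
            contrib = contrib * ~self.masked[:, None]
        return contrib.sum(axis=0)


@dataclass
class ScoreReport:
    """Length-normalised raw and Tregitope-adjusted protein scores."""

    protein_id: str
    alleles: list[str]
    assessments: int
    raw_score: float
    adjusted_score: float
    per_allele_content: dict[str, float]
    per_allele_content_adjusted: dict[str, float]
    reference_annotations: dict[str, float] = field(
        default_factory=lambda: dict(REFERENCE_SCORE_ANNOTATIONS)
    )


def frame_scores(
    encoded: np.ndarray, matrix: np.ndarray
) -> np.ndarray:
    """Raw scores of every overlapping 9-mer of an encoded sequence.

    Vectorised over frames: frame f scores sum_k matrix[k, seq[f+k]].
    """
    n_frames = len(encoded) - NINE + 1
    if n_frames < 1:
        raise ScanError("sequence shorter than 9 residues")
    scores = np.zeros(n_frames)
    for k in range(NINE):
        scores += matrix[k, encoded[k : k + n_frames]]
    return scores


def find_tregitope_spans(
    protein: ProteinRecord, registry: TregitopeRegistry
) -> list[tuple[int, int]]:
    """All maximal matched Tregitope spans, 1-based inclusive, merged.

    Every exact occurrence of every registry peptide is located; overlapping
    or adjacent occurrences are merged into maximal spans.
    """
    raw: list[tuple[int, int]] = []
    seq = protein.sequence
    for _, pep in registry.entries:
        start = seq.find(pep)
        while start != -1:
            raw.append((start + 1, start + len(pep)))
            start = seq.find(pep, start + 1)
    if not raw:
        return []
    raw.sort()
    merged = [raw[0]]
    for s, e in raw[1:]:
        ps, pe = merged[-1]
        if s <= pe + 1:
            merged[-1] = (ps, max(pe, e))
        else:
            merged.append((s, e))
    return merged


def _mask_from_spans(n_frames: int, spans: Sequence[tuple[int, int]]) -> np.ndarray:
    """Frames fully contained in a span are masked; straddling frames kept."""
    masked = np.zeros(n_frames, dtype=bool)
    for s, e in spans:
        lo = max(1, s)
        hi = e - NINE + 1  # last frame start fully inside [s, e]
        if hi >= lo:
            masked[lo - 1 : min(hi, n_frames)] = True
    return masked


def scan_protein(
    protein: ProteinRecord,
    matrices: Sequence[PSSM],
    bg: BackgroundFrequencies | None = None,
    thresholds: HitThresholds | None = None,
    registry: TregitopeRegistry | None = None,
) -> AssessmentGrid:
    """Score every overlapping 9-mer of a protein against every allele.

    Returns the (frame x allele) grid of Z-scores and hit classes, with the
    Tregitope mask applied when a registry is given.
    """
    if not matrices:
        raise ScanError("at least one matrix is required")
    if len(protein.sequence) < NINE:
        raise ScanError(
            f"protein {protein.id} shorter than 9 residues ({len(protein)})"
        )
    bg = bg or BackgroundFrequencies.uniform(matrices[0].alphabet)
    t = thresholds or HitThresholds()
    alphabet = matrices[0].alphabet
    encoded = alphabet.encode(protein.sequence)

    pssms = sorted(matrices, key=lambda p: p.allele)
    alleles = [p.allele for p in pssms]
    if len(set(alleles)) != len(alleles):
        raise ScanError("duplicate allele matrices supplied")

    n_frames = len(encoded) - NINE + 1
    z = np.empty((n_frames, len(pssms)))
    for j, pssm in enumerate(pssms):
        nm = null_moments(pssm, bg)
        if nm.degenerate:
            raise PSSMError(f"degenerate matrix for {pssm.allele}")
        z[:, j] = (frame_scores(encoded, pssm.matrix) - nm.mu) / nm.sigma

    hit_class = np.zeros(z.shape, dtype=np.int8)
    hit_class[z >= t.likely] = 1
    hit_class[z >= t.hit] = 2

    if registry is not None:
        spans = find_tregitope_spans(protein, registry)
        masked = _mask_from_spans(n_frames, spans)
    else:
        masked = np.zeros(n_frames, dtype=bool)

    return AssessmentGrid(
        protein_id=protein.id,
        frames=np.arange(1, n_frames + 1),
        alleles=alleles,
        z=z,
        hit_class=hit_class,
        masked=masked,
        thresholds=t,
    )


def grid_score(grid: AssessmentGrid, adjusted: bool = False) -> float:
    """Scalar protein score over the grid's full allele panel."""
    if grid.n_assessments == 0:
        raise ScanError("empty assessment grid")
    e0 = expected_hit_excess(grid.thresholds.hit)
    content = grid.per_allele_content(adjusted=adjusted)
    a = grid.n_assessments
    return float((content.sum() - a * e0) / a * 1000.0)


def protein_score(
    grid: AssessmentGrid, thresholds: HitThresholds | None = None
) -> ScoreReport:
    """Raw and Tregitope-adjusted length-normalised scores for one protein."""
    if thresholds is not None and thresholds != grid.thresholds:
        raise ScanError("thresholds must match those used to build the grid")
    content_raw = grid.per_allele_content(adjusted=False)
    content_adj = grid.per_allele_content(adjusted=True)
    return ScoreReport(
        protein_id=grid.protein_id,
        alleles=list(grid.alleles),
        assessments=grid.n_assessments,
        raw_score=grid_score(grid, adjusted=False),
        adjusted_score=grid_score(grid, adjusted=True),
        per_allele_content=dict(zip(grid.alleles, content_raw.tolist())),
        per_allele_content_adjusted=dict(zip(grid.alleles, content_adj.tolist())),
    )
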