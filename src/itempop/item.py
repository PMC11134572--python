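"""Individual (allele-pair) T-cell epitope measure (iTEM) scores.

The iTEM score models one patient, who carries two HLA-DRB1 alleles
(heterozygous) or one (homozygous), by restricting the protein-score
aggregation to that pair.  For a pair {a, b} with per-allele hit-Z content
o_a, o_b over F frames::

    heterozygous:  (o_a + o_b - 2 F e0) / (2 F) * 1000
    homozygous:    (o_a - F e0) / F * 1000

i.e. the same per-1000-assessment normalisation as the protein score, with
the allele counted once when a == b (counting it twice cancels in the
normalisation).  Ranking a given pair within the distribution of all
unordered panel pairs places an individual's risk in population context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frequencies import AllelePair
from .pssm import expected_hit_excess
from .scanning import AssessmentGrid, ScanError


@dataclass
class ITEMResult:
    """Raw and Tregitope-adjusted iTEM scores for one allele pair."""

    protein_id: str
    pair: AllelePair
    raw_item: float
    adjusted_item: float


@dataclass
class ITEMDistribution:
    """All-pairs iTEM results for one protein, with adjusted-score quartiles."""

    protein_id: str
    results: list[ITEMResult]
    q1: float
    median: float
    q3: float

    def result_for(self, pair: AllelePair) -> ITEMResult:
        for r in self.results:
            if r.pair == pair:
                return r
        raise ScanError(f"pair {pair} not in iTEM distribution for {self.protein_id}")


def item_score(
    grid: AssessmentGrid, pair: AllelePair, adjusted: bool = False
) -> float:
    """iTEM score of one allele pair (alleles must be in the grid)."""
    alleles = {pair.allele_a} if pair.homozygous else {pair.allele_a, pair.allele_b}
    content = grid.per_allele_content(adjusted=adjusted)
    o = sum(content[grid.allele_index(a)] for a in alleles)
    k = len(alleles)
    f = grid.n_frames
    e0 = expected_hit_excess(grid.thresholds.hit)
    return float((o - k * f * e0) / (k * f) * 1000.0)


def item_distribution(
    grid: AssessmentGrid, panel: Sequence[str]
) -> ITEMDistribution:
    """iTEM scores of every unordered panel pair, homozygous pairs included.

    A panel of k alleles yields k(k+1)/2 pairs.  Quartile boundaries are
    linear-interpolation quantiles of the Tregitope-adjusted scores.
    """
    if not panel:
        raise ScanError("empty allele panel")
    panel_sorted = sorted(set(panel))
    missing = [a for a in panel_sorted if a not in grid.alleles]
    if missing:
        raise ScanError(f"panel alleles missing from grid: {missing}")
    results = []
    for i, a in enumerate(panel_sorted):
        for b in panel_sorted[i:]:
            pair = AllelePair(a, b)
            results.append(
                ITEMResult(
                    protein_id=grid.protein_id,
                    pair=pair,
                    raw_item=item_score(grid, pair, adjusted=False),
                    adjusted_item=item_score(grid, pair, adjusted=True),
                )
            )
    adj = np.array([r.adjusted_item for r in results])
    return ITEMDistribution(
        protein_id=grid.protein_id,
        results=results,
        q1=float(np.quantile(adj, 0.25)),
        median=float(np.quantile(adj, 0.50)),
        q3=float(np.quantile(adj, 0.75)),
    )


def pair_quartile(dist: ITEMDistribution, pair: AllelePair) -> int:
    """Quartile (1 = bottom ... 4 = top) of a pair's adjusted iTEM score.

    Scores on a quartile boundary are assigned to the lower quartile.
    """
    score = dist.result_for(pair).adjusted_item
    if score <= dist.q1:
        return 1
    if score <= dist.median:
        return 2
    if score <= dist.q3:
        return 3
    return 4
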