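"""HLA-frequency-weighted protein scores and resampled score distributions.

The population-specific score of a protein weights each allele's observed
epitope content by that allele's carrier frequency in the population.  With
normalised weights w_a over the panel, F frames and per-allele hit-Z content
o_a, the weighted score is::

    score = (sum_a w_a * o_a / F - e0) * 1000

the frequency-weighted analogue of the unweighted protein score (uniform
weights recover it exactly).  Sampling uncertainty in the carrier
frequencies is propagated by a parametric bootstrap: each of the (default
100) resamples redraws every panel allele's carrier count binomially at the
population's aggregated sample size, and the weighted score is recomputed.
Resample i of every population uses the same per-index RNG substream, so
scores can be paired across populations by index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .frequencies import FrequencyError, FrequencyTable
from .pssm import expected_hit_excess
from .scanning import AssessmentGrid, ScanError


@dataclass
class WeightVector:
    """Nonnegative per-allele weights, normalisable to sum to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise FrequencyError("weight vector is empty")
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise FrequencyError("weights must be nonnegative")
        if not (vals > 0).any():
            raise FrequencyError("at least one weight must be positive")

    def normalized(self) -> "WeightVector":
        total = sum(self.weights.values())
        return WeightVector({a: w / total for a, w in self.weights.items()})

    @classmethod
    def from_table(
        cls, table: FrequencyTable, panel: Sequence[str]
    ) -> "WeightVector":
        """Carrier fractions restricted to the panel, ready for normalisation."""
        w = {a: table.get(a) for a in panel}
        return cls(w)


@dataclass
class ScoreDistribution:
    """Resampled frequency-weighted scores for one protein and population."""

    protein_id: str
    population: str
    scores: np.ndarray
    seed: int

    @property
    def n_resamples(self) -> int:
        return len(self.scores)

    @property
    def median(self) -> float:
        return float(np.median(self.scores))

    @property
    def q1(self) -> float:
        return float(np.quantile(self.scores, 0.25))

    @property
    def q3(self) -> float:
        return float(np.quantile(self.scores, 0.75))


def weighted_protein_score(
    grid: AssessmentGrid,
    weights: WeightVector | Mapping[str, float],
    adjusted: bool = False,
) -> float:
    """Frequency-weighted protein score over the grid.

    Weight alleles must be a subset of the grid's alleles; weights are
    normalised internally, so any positive scaling gives the same score.
    """
    if not isinstance(weights, WeightVector):
        weights = WeightVector(dict(weights))
    overlap = [a for a in weights.weights if a in grid.alleles]
    if not overlap:
        raise ScanError("no overlap between weight alleles and grid alleles")
    missing = [a for a in weights.weights if a not in grid.alleles]
    if missing:
        raise ScanError(f"weight alleles missing from grid: {missing}")
    w = weights.normalized().weights
    content = grid.per_allele_content(adjusted=adjusted)
    o = sum(w[a] * content[grid.allele_index(a)] for a in w)
    f = grid.n_frames
    e0 = expected_hit_excess(grid.thresholds.hit)
    return float((o / f - e0) * 1000.0)


def _substream(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-resample RNG substream, shared across populations."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def resample_frequency_table(
    table: FrequencyTable,
    panel: Sequence[str],
    rng: np.random.Generator,
) -> FrequencyTable:
    """Parametric-bootstrap draw of a carrier-frequency table.

    Each panel allele's carrier count is redrawn Binomial(total_n, carrier)
    and converted back to a fraction.  Alleles carried by nobody stay at 0.
    """
    if table.total_n <= 0:
        raise FrequencyError(f"{table.population}: total_n must be positive")
    n = table.total_n
    carrier = {}
    for allele in panel:
        p = table.get(allele)
        carrier[allele] = float(rng.binomial(n, p)) / n
    return FrequencyTable(population=table.population, carrier=carrier, total_n=n)


def population_score_distribution(
    grid: AssessmentGrid,
    table: FrequencyTable,
    panel: Sequence[str],
    n_resamples: int = 100,
    seed: int = 0,
    adjusted: bool = False,
) -> ScoreDistribution:
    """Distribution of frequency-weighted scores over bootstrap resamples.

    Resample i uses RNG substream (seed, i) regardless of population, so the
    i-th scores of two populations form a matched pair for the signed-rank
    comparison.
    """
    if n_resamples < 1:
        raise FrequencyError("n_resamples must be >= 1")
    scores = np.empty(n_resamples)
    for i in range(n_resamples):
        resampled = resample_frequency_table(table, panel, _substream(seed, i))
        scores[i] = weighted_protein_score(grid, WeightVector.from_table(resampled, panel), adjusted)
    return ScoreDistribution(
        protein_id=grid.protein_id,
        population=table.population,
        scores=scores,
        seed=seed,
    )
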