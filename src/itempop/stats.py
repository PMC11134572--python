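"""Paired nonparametric comparison of population score distributions.

Population score distributions are compared per protein with the Wilcoxon
signed-rank test on index-paired resample scores.  Effect sizes use the
matched-pairs rank-biserial correlation r = (W+ - W-) / (W+ + W-), which is
independent of sample size, with configurable categorical interpretation
schemes.  P-values across proteins are adjusted with the six canonical
multiplicity corrections.  A small utility aggregates reported anti-drug
antibody (ATA) rates across clinical studies by participant-weighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class StatsError(ValueError):
    """Degenerate or invalid statistical input."""


@dataclass
class PairedSamples:
    """Two score vectors paired by resample index."""

    label: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or len(self.x) < 1:
            raise StatsError("x and y must be equal-length 1-d arrays")


@dataclass
class TestResult:
    """Signed-rank test with effect size and multiplicity-adjusted p-values."""

    label: str
    statistic: float  # min(W+, W-)
    w_plus: float
    w_minus: float
    p_value: float
    effect_size: float
    effect_category: dict[str, str] = field(default_factory=dict)
    p_adjusted: dict[str, float] = field(default_factory=dict)


@dataclass
class ATAStudy:
    """One clinical study's reported anti-drug antibody rate."""

    biologic: str
    study_id: str
    participants: int
    ata_rate: float
    monotherapy: bool = True
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.participants <= 0:
            raise StatsError(f"study {self.study_id}: participants must be > 0")
        if not 0.0 <= self.ata_rate <= 1.0:
            raise StatsError(f"study {self.study_id}: ATA rate outside [0, 1]")


def _signed_rank_sums(
    d: np.ndarray, zero_method: str = "wilcox"
) -> tuple[float, float, np.ndarray]:
    """W+ and W- signed-rank sums with the chosen zero-difference handling."""
    if zero_method not in {"wilcox", "pratt"}:
        raise StatsError(f"unknown zero_method {zero_method!r}")
    if zero_method == "wilcox":
        d = d[d != 0]
    if len(d) == 0 or not (d != 0).any():
        raise StatsError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    return w_plus, w_minus, d


def wilcoxon_signed_rank(
    s: PairedSamples, mode: str = "auto", zero_method: str = "wilcox"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on index-paired scores.

    ``mode='exact'`` enumerates the exact null (valid for moderate n without
    ties in |differences|); ``'approx'`` uses the normal approximation with
    tie correction; ``'auto'`` picks exact for n <= 25 without ties.  Zero
    differences are dropped by default (classic Wilcoxon convention); the
    Pratt method keeps them in the ranking.
    """
    d = s.x - s.y
    w_plus, w_minus, d_used = _signed_rank_sums(d, zero_method)
    n = len(d_used)
    has_ties = len(np.unique(np.abs(d_used[d_used != 0]))) < np.count_nonzero(d_used)
    if mode == "auto":
        mode = "exact" if (n <= 25 and not has_ties and zero_method == "wilcox") else "approx"
    if mode not in {"exact", "approx"}:
        raise StatsError(f"unknown mode {mode!r}")
    method = "exact" if mode == "exact" else "approx"
    res = sps.wilcoxon(
        s.x, s.y, zero_method=zero_method, method=method, alternative="two-sided"
    )
    r = (w_plus - w_minus) / (w_plus + w_minus)
    return TestResult(
        label=s.label,
        statistic=float(min(w_plus, w_minus)),
        w_plus=w_plus,
        w_minus=w_minus,
        p_value=float(res.pvalue),
        effect_size=float(r),
    )


def rank_biserial(s: PairedSamples, zero_method: str = "wilcox") -> float:
    """Matched-pairs rank-biserial correlation (W+ - W-) / (W+ + W-)."""
    w_plus, w_minus, _ = _signed_rank_sums(s.x - s.y, zero_method)
    return float((w_plus - w_minus) / (w_plus + w_minus))


#: The six multiplicity corrections, keyed by their conventional names.
ADJUSTMENT_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "BH": "fdr_bh",
    "BY": "fdr_by",
}


def adjust_pvalues(ps: Sequence[float], method: str) -> list[float]:
    """Adjusted p-values for one of the six canonical correction methods."""
    if method not in ADJUSTMENT_METHODS:
        raise StatsError(
            f"unknown adjustment method {method!r}; choose from "
            f"{sorted(ADJUSTMENT_METHODS)}"
        )
    ps = np.asarray(ps, dtype=float)
    if ((ps < 0) | (ps > 1)).any():
        raise StatsError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(ps, method=ADJUSTMENT_METHODS[method])
    return [float(min(p, 1.0)) for p in adjusted]


#: Categorical interpretation schemes for |rank-biserial r|: ascending
#: (threshold, label) bins; |r| below the first threshold takes the first
#: label.  Editable / extensible via config.
EFFECT_SIZE_SCHEMES: dict[str, list[tuple[float, str]]] = {
    # Cohen's classic small/medium/large conventions
    "cohen": [(0.1, "negligible"), (0.3, "small"), (0.5, "medium"), (np.inf, "large")],
    # Funder & Ozer's finer-grained effect-size ladder
    "funder_ozer": [
        (0.05, "tiny"),
        (0.1, "very small"),
        (0.2, "small"),
        (0.3, "medium"),
        (0.4, "large"),
        (np.inf, "very large"),
    ],
    # correlation-strength wording common in applied reporting
    "strength": [
        (0.2, "very weak"),
        (0.4, "weak"),
        (0.6, "moderate"),
        (0.8, "strong"),
        (np.inf, "very strong"),
    ],
}


def interpret_effect(
    r: float,
    scheme: str = "funder_ozer",
    schemes: Mapping[str, list[tuple[float, str]]] | None = None,
) -> str:
    """Categorical label for an effect size |r| under a named scheme."""
    table = (schemes or EFFECT_SIZE_SCHEMES).get(scheme)
    if table is None:
        raise StatsError(f"unknown effect-size scheme {scheme!r}")
    mag = abs(float(r))
    for threshold, label in table:
        if mag < threshold:
            return label
    return table[-1][1]


def compare_populations(
    s: PairedSamples,
    mode: str = "auto",
    zero_method: str = "wilcox",
    schemes: Sequence[str] = ("cohen", "funder_ozer"),
) -> TestResult:
    """Signed-rank test plus rank-biserial effect size and categories."""
    result = wilcoxon_signed_rank(s, mode=mode, zero_method=zero_method)
    result.effect_category = {
        scheme: interpret_effect(result.effect_size, scheme) for scheme in schemes
    }
    return result


def aggregate_ata_rate(studies: Sequence[ATAStudy]) -> float:
    """Participant-weighted mean ATA rate over non-excluded studies."""
    kept = [s for s in studies if not s.excluded]
    if not kept:
        raise StatsError("all ATA studies are excluded")
    total = sum(s.participants for s in kept)
    return float(sum(s.participants * s.ata_rate for s in kept) / total)
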