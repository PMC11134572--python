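"""Population HLA-DRB1 carrier-frequency tables and differential allele pairs.

Carrier frequency is the fraction of individuals in a population carrying at
least one copy of an allele (distinct from the gene-copy allele frequency).
Multi-study records are aggregated into one table per population by
sample-size weighting.  The joint carrier probability of an unordered allele
pair is modelled as the product of the two carrier fractions (the homozygous
pair is the square); pairs whose joint probability and between-population
difference both exceed 5% are the *differential pairs* that drive
population-specific immunogenicity risk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .pssm import normalize_allele


class FrequencyError(ValueError):
    """Invalid frequency inputs."""


@dataclass
class StudySample:
    """One study's typed sample: per-allele carrier fractions and its size."""

    population: str
    study_id: str
    sample_size: int
    carrier: dict[str, float]

    def __post_init__(self) -> None:
        if self.sample_size <= 0:
            raise FrequencyError(f"study {self.study_id}: sample_size must be > 0")
        clean = {}
        for allele, frac in self.carrier.items():
            if not 0.0 <= frac <= 1.0:
                raise FrequencyError(
                    f"study {self.study_id}: carrier fraction {frac} for "
                    f"{allele} outside [0, 1]"
                )
            clean[normalize_allele(allele)] = float(frac)
        self.carrier = clean


@dataclass
class FrequencyTable:
    """Aggregated per-population carrier fractions with provenance size."""

    population: str
    carrier: dict[str, float]
    total_n: int

    def __post_init__(self) -> None:
        clean = {}
        for allele, frac in self.carrier.items():
            if not 0.0 <= frac <= 1.0:
                raise FrequencyError(
                    f"{self.population}: carrier fraction {frac} for {allele} "
                    "outside [0, 1]"
                )
            clean[normalize_allele(allele)] = float(frac)
        self.carrier = clean

    def get(self, allele: str) -> float:
        return self.carrier.get(normalize_allele(allele), 0.0)


@dataclass(frozen=True)
class AllelePair:
    """Unordered pair of alleles; a == b models a homozygous individual."""

    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        a = normalize_allele(self.allele_a)
        b = normalize_allele(self.allele_b)
        if a > b:
            a, b = b, a
        object.__setattr__(self, "allele_a", a)
        object.__setattr__(self, "allele_b", b)

    @property
    def homozygous(self) -> bool:
        return self.allele_a == self.allele_b

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele_a, self.allele_b)

    def __str__(self) -> str:
        return f"{self.allele_a}/{self.allele_b}"


@dataclass
class PairDifferential:
    """Joint carrier probabilities of one pair in two populations."""

    pair: AllelePair
    population_a: str
    population_b: str
    jp_a: float
    jp_b: float

    @property
    def diff(self) -> float:
        return self.jp_a - self.jp_b

    @property
    def dominant(self) -> str:
        return self.population_a if self.jp_a >= self.jp_b else self.population_b


def aggregate_frequencies(
    samples: Sequence[StudySample], population: str
) -> FrequencyTable:
    """Sample-size-weighted mean of per-study carrier fractions.

    An allele unreported by a contributing study counts as 0% in that study,
    so the weighted mean runs over the full summed sample size.
    """
    matching = [s for s in samples if s.population == population]
    if not matching:
        raise FrequencyError(f"no study samples for population {population!r}")
    total_n = sum(s.sample_size for s in matching)
    alleles = sorted({a for s in matching for a in s.carrier})
    carrier = {
        a: sum(s.sample_size * s.carrier.get(a, 0.0) for s in matching) / total_n
        for a in alleles
    }
    return FrequencyTable(population=population, carrier=carrier, total_n=total_n)


def filter_panel(
    tables: Sequence[FrequencyTable], min_freq: float = 0.01
) -> list[str]:
    """Alleles carried at > min_freq in at least one population (strict)."""
    if not 0.0 < min_freq < 1.0:
        raise FrequencyError("min_freq must be in (0, 1)")
    alleles = sorted({a for t in tables for a in t.carrier})
    return [a for a in alleles if any(t.get(a) > min_freq for t in tables)]


def carrier_to_allele_freq(carrier: float) -> float:
    """Gene-copy allele frequency implied by a carrier fraction under HWE.

    Solves P = 1 - (1 - p)^2 for p.  Utility only; joint-probability
    computations work on carrier fractions directly.
    """
    if not 0.0 <= carrier <= 1.0:
        raise FrequencyError(f"carrier fraction {carrier} outside [0, 1]")
    return 1.0 - float(np.sqrt(1.0 - carrier))


def allele_to_carrier_freq(p: float) -> float:
    """Inverse of :func:`carrier_to_allele_freq`."""
    if not 0.0 <= p <= 1.0:
        raise FrequencyError(f"allele frequency {p} outside [0, 1]")
    return 1.0 - (1.0 - p) ** 2


def joint_probability(table: FrequencyTable, pair: AllelePair) -> float:
    """Joint carrier probability: product of the pair's carrier fractions.

    Carriage of the two alleles is treated as independent; the homozygous
    pair is the squared carrier fraction.  Absent alleles contribute 0.
    """
    return table.get(pair.allele_a) * table.get(pair.allele_b)


def joint_genotype_probability(table: FrequencyTable, pair: AllelePair) -> float:
    """HWE genotype-frequency alternative (2 p_a p_b, or p_a^2 if homozygous).

    Provided as a utility; not used by :func:`differential_pairs`.
    """
    pa = carrier_to_allele_freq(table.get(pair.allele_a))
    pb = carrier_to_allele_freq(table.get(pair.allele_b))
    return pa * pa if pair.homozygous else 2.0 * pa * pb


def differential_pairs(
    table_a: FrequencyTable,
    table_b: FrequencyTable,
    panel: Sequence[str],
    jp_min: float = 0.05,
    diff_min: float = 0.05,
) -> list[PairDifferential]:
    """Allele pairs with large, population-differential joint probabilities.

    A pair qualifies when max(jp_a, jp_b) > jp_min and |jp_a - jp_b| >
    diff_min (strict, as for the 1% panel filter).  All unordered pairs over
    the panel, including homozygous pairs, are considered; results are sorted
    by |difference| descending.
    """
    if not panel:
        raise FrequencyError("empty allele panel")
    out: list[PairDifferential] = []
    panel_sorted = sorted({normalize_allele(a) for a in panel})
    for i, a in enumerate(panel_sorted):
        for b in panel_sorted[i:]:
            pair = AllelePair(a, b)
            jp_a = joint_probability(table_a, pair)
            jp_b = joint_probability(table_b, pair)
            if max(jp_a, jp_b) > jp_min and abs(jp_a - jp_b) > diff_min:
                out.append(
                    PairDifferential(
                        pair=pair,
                        population_a=table_a.population,
                        population_b=table_b.population,
                        jp_a=jp_a,
                        jp_b=jp_b,
                    )
                )
    out.sort(key=lambda d: (-abs(d.diff), d.pair.alleles))
    return out


# ---------------------------------------------------------------------------
# CSV dialects (percent 0-100 in files, fractions internally)
# ---------------------------------------------------------------------------

def read_study_csv(path: str | Path) -> list[StudySample]:
    """Read per-study records: population,study_id,sample_size,allele,carrier_percent."""
    rows: dict[tuple[str, str], dict] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            key = (rec["population"], rec["study_id"])
            entry = rows.setdefault(
                key, {"sample_size": int(rec["sample_size"]), "carrier": {}}
            )
            entry["carrier"][rec["allele"]] = float(rec["carrier_percent"]) / 100.0
    return [
        StudySample(
            population=pop,
            study_id=sid,
            sample_size=entry["sample_size"],
            carrier=entry["carrier"],
        )
        for (pop, sid), entry in rows.items()
    ]


def read_frequency_csv(path: str | Path) -> list[FrequencyTable]:
    """Read aggregated tables: population,allele,carrier_percent,total_n."""
    pops: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            entry = pops.setdefault(
                rec["population"], {"carrier": {}, "total_n": int(rec["total_n"])}
            )
            entry["carrier"][rec["allele"]] = float(rec["carrier_percent"]) / 100.0
    return [
        FrequencyTable(population=pop, carrier=e["carrier"], total_n=e["total_n"])
        for pop, e in pops.items()
    ]


def write_frequency_csv(tables: Sequence[FrequencyTable], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["population", "allele", "carrier_percent", "total_n"])
        for t in tables:
            for allele in sorted(t.carrier):
                w.writerow(
                    [t.population, allele, f"{t.carrier[allele] * 100:.2f}", t.total_n]
                )


def write_differential_csv(
    diffs: Sequence[PairDifferential], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["allele_a", "allele_b", "jp_pop1", "jp_pop2", "diff", "dominant"]
        )
        for d in diffs:
            w.writerow(
                [
                    d.pair.allele_a,
                    d.pair.allele_b,
                    f"{d.jp_a * 100:.2f}",
                    f"{d.jp_b * 100:.2f}",
                    f"{d.diff * 100:.2f}",
                    d.dominant,
                ]
            )


def load_reference_frequencies() -> list[FrequencyTable]:
    """Packaged Japanese/Caucasian carrier-frequency tables.

    Aggregated HLA-DRB1 carrier frequencies for the Japanese and Caucasian
    reference populations, shipped as package data.
    """
    ref = resources.files("itempop.data").joinpath("table1_carrier_frequencies.csv")
    with resources.as_file(ref) as path:
        return read_frequency_csv(path)
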