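"""Model/Results interface over the population-weighted risk pipeline.

`PopulationRiskModel` bundles the inputs of an analysis — protein
sequences, per-allele binding matrices, per-population carrier-frequency
tables and an optional Tregitope registry — and `fit()` runs the whole
pipeline: epitope scanning, protein scores, frequency-weighted resampled
score distributions, paired signed-rank comparisons with multiplicity
correction and effect sizes, all-pairs iTEM distributions and differential
allele pairs.  The returned `PopulationRiskResults` carries everything as
pandas DataFrames, prints a summary table, and can export the stage CSVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .frequencies import (
    FrequencyTable,
    differential_pairs,
    filter_panel,
    read_frequency_csv,
    read_study_csv,
    aggregate_frequencies,
    write_differential_csv,
)
from .item import item_distribution, pair_quartile
from .pssm import BackgroundFrequencies, HitThresholds, PSSM, load_pssm_set
from .scanning import (
    AssessmentGrid,
    ProteinRecord,
    TregitopeRegistry,
    protein_score,
    scan_protein,
)
from .stats import PairedSamples, StatsError, adjust_pvalues, compare_populations
from .weighting import population_score_distribution
from . import io as iomod


class ModelError(ValueError):
    pass


class PopulationRiskModel:
    """Population-weighted HLA-DRB1 immunogenicity risk assessment.

    Parameters
    ----------
    proteins
        Protein sequences to assess (each at least nine residues).
    pssms
        One 9x20 scoring matrix per HLA-DRB1 allele.
    frequency_tables
        Aggregated carrier-frequency tables, one per population.  The first
        two populations are compared pairwise; additional populations still
        get score distributions.
    registry
        Optional Tregitope registry for the adjusted scores (no registry
        means adjusted == raw).
    """

    def __init__(
        self,
        proteins: Sequence[ProteinRecord],
        pssms: Sequence[PSSM],
        frequency_tables: Sequence[FrequencyTable],
        registry: TregitopeRegistry | None = None,
        background: BackgroundFrequencies | None = None,
        thresholds: HitThresholds | None = None,
        panel_min_freq: float = 0.01,
        jp_min: float = 0.05,
        diff_min: float = 0.05,
    ) -> None:
        if not proteins:
            raise ModelError("at least one protein is required")
        if not pssms:
            raise ModelError("at least one allele matrix is required")
        if not frequency_tables:
            raise ModelError("at least one population frequency table is required")
        self.proteins = list(proteins)
        self.pssms = sorted(pssms, key=lambda p: p.allele)
        self.tables = list(frequency_tables)
        self.registry = registry
        self.background = background or BackgroundFrequencies.uniform(
            self.pssms[0].alphabet
        )
        self.thresholds = thresholds or HitThresholds()
        self.panel_min_freq = panel_min_freq
        self.jp_min = jp_min
        self.diff_min = diff_min

    @classmethod
    def from_files(
        cls,
        proteins_fasta: str | Path,
        matrix_dir: str | Path,
        frequencies_csv: str | Path | None = None,
        studies_csv: str | Path | None = None,
        registry_path: str | Path | None = None,
        **kwargs,
    ) -> "PopulationRiskModel":
        proteins = iomod.read_proteins_fasta(proteins_fasta)
        pssms = load_pssm_set(matrix_dir)
        if frequencies_csv is not None:
            tables = read_frequency_csv(frequencies_csv)
        elif studies_csv is not None:
            samples = read_study_csv(studies_csv)
            populations = sorted({s.population for s in samples})
            tables = [aggregate_frequencies(samples, p) for p in populations]
        else:
            raise ModelError("provide frequencies_csv or studies_csv")
        registry = iomod.read_registry(registry_path) if registry_path else None
        return cls(proteins, pssms, tables, registry=registry, **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        n_resamples: int = 100,
        seed: int = 0,
        adjust_methods: Sequence[str] = (
            "bonferroni",
            "holm",
            "hochberg",
            "hommel",
            "BH",
            "BY",
        ),
        effect_schemes: Sequence[str] = ("cohen", "funder_ozer"),
    ) -> "PopulationRiskResults":
        """Run the full pipeline and return a results object."""
        panel = filter_panel(self.tables, self.panel_min_freq)
        if not panel:
            raise ModelError("panel filter removed every allele")
        matrix_alleles = [p.allele for p in self.pssms]
        weight_panel = [a for a in panel if a in matrix_alleles]
        if not weight_panel:
            raise ModelError(
                "no overlap between the frequency panel and the matrix alleles"
            )

        grids = {
            p.id: scan_protein(
                p, self.pssms, self.background, self.thresholds, self.registry
            )
            for p in self.proteins
        }
        reports = [protein_score(grids[p.id]) for p in self.proteins]

        # resampled frequency-weighted score distributions, paired by index
        dists: dict[tuple[str, str, str], np.ndarray] = {}
        pop_rows = []
        for p in self.proteins:
            for table in self.tables:
                for score_type, adjusted in (("raw", False), ("adjusted", True)):
                    d = population_score_distribution(
                        grids[p.id],
                        table,
                        weight_panel,
                        n_resamples=n_resamples,
                        seed=seed,
                        adjusted=adjusted,
                    )
                    dists[(p.id, table.population, score_type)] = d.scores
                    for i, s in enumerate(d.scores):
                        pop_rows.append(
                            {
                                "protein": p.id,
                                "population": table.population,
                                "score_type": score_type,
                                "resample_index": i,
                                "score": float(s),
                            }
                        )
        population_scores = pd.DataFrame(
            pop_rows,
            columns=["protein", "population", "score_type", "resample_index", "score"],
        )

        # paired comparison between the first two populations
        comparisons = pd.DataFrame()
        if len(self.tables) >= 2:
            pop_a, pop_b = self.tables[0].population, self.tables[1].population
            rows = []
            for score_type in ("raw", "adjusted"):
                for p in self.proteins:
                    s = PairedSamples(
                        label=f"{p.id}:{score_type}",
                        x=dists[(p.id, pop_a, score_type)],
                        y=dists[(p.id, pop_b, score_type)],
                    )
                    try:
                        res = compare_populations(s, schemes=effect_schemes)
                        stat, p_val, r = res.statistic, res.p_value, res.effect_size
                        cats = res.effect_category
                    except StatsError:
                        # identical scores in every resample (e.g. a protein
                        # with no predicted hits): no evidence of difference
                        stat, p_val, r = np.nan, np.nan, np.nan
                        cats = {k: "degenerate" for k in effect_schemes}
                    rows.append(
                        {
                            "protein": p.id,
                            "score_type": score_type,
                            f"median_{pop_a}": float(
                                np.median(dists[(p.id, pop_a, score_type)])
                            ),
                            f"median_{pop_b}": float(
                                np.median(dists[(p.id, pop_b, score_type)])
                            ),
                            "W": stat,
                            "p_value": p_val,
                            "rank_biserial": r,
                            **{f"effect_{k}": v for k, v in cats.items()},
                        }
                    )
            comparisons = pd.DataFrame(rows)
            # multiplicity correction within each score type, across proteins
            for method in adjust_methods:
                adj = np.full(len(comparisons), np.nan)
                for score_type in ("raw", "adjusted"):
                    mask = (
                        (comparisons["score_type"] == score_type)
                        & comparisons["p_value"].notna()
                    ).to_numpy()
                    if mask.any():
                        adj[mask] = adjust_pvalues(
                            comparisons.loc[mask, "p_value"].tolist(), method
                        )
                comparisons[f"p_{method}"] = adj

        # differential allele pairs over the full frequency panel
        diffs = []
        diff_frame = pd.DataFrame()
        if len(self.tables) >= 2:
            diffs = differential_pairs(
                self.tables[0],
                self.tables[1],
                panel,
                jp_min=self.jp_min,
                diff_min=self.diff_min,
            )
            diff_frame = pd.DataFrame(
                [
                    {
                        "allele_a": d.pair.allele_a,
                        "allele_b": d.pair.allele_b,
                        f"jp_{d.population_a}": d.jp_a,
                        f"jp_{d.population_b}": d.jp_b,
                        "diff": d.diff,
                        "dominant": d.dominant,
                    }
                    for d in diffs
                ]
            )

        # all-pairs iTEM distributions over the matrix-backed panel
        item_rows = []
        item_dists = {}
        for p in self.proteins:
            dist = item_distribution(grids[p.id], weight_panel)
            item_dists[p.id] = dist
            for r in dist.results:
                item_rows.append(
                    {
                        "protein": p.id,
                        "allele_a": r.pair.allele_a,
                        "allele_b": r.pair.allele_b,
                        "raw_item": r.raw_item,
                        "adjusted_item": r.adjusted_item,
                        "quartile": pair_quartile(dist, r.pair),
                    }
                )
        item_frame = pd.DataFrame(
            item_rows,
            columns=[
                "protein",
                "allele_a",
                "allele_b",
                "raw_item",
                "adjusted_item",
                "quartile",
            ],
        )

        return PopulationRiskResults(
            model=self,
            panel=panel,
            weight_panel=weight_panel,
            grids=grids,
            reports=reports,
            population_scores=population_scores,
            comparisons=comparisons,
            differentials=diffs,
            differential_frame=diff_frame,
            item_frame=item_frame,
            item_distributions=item_dists,
            n_resamples=n_resamples,
            seed=seed,
        )


@dataclass
class PopulationRiskResults:
    """Fitted pipeline outputs, ready for inspection and export."""

    model: PopulationRiskModel
    panel: list[str]
    weight_panel: list[str]
    grids: dict[str, AssessmentGrid]
    reports: list
    population_scores: pd.DataFrame
    comparisons: pd.DataFrame
    differentials: list
    differential_frame: pd.DataFrame
    item_frame: pd.DataFrame
    item_distributions: dict
    n_resamples: int
    seed: int

    @property
    def protein_scores(self) -> pd.DataFrame:
        lengths = {p.id: len(p) for p in self.model.proteins}
        return iomod.reports_to_frame(self.reports, lengths)

    def population_summary(self) -> pd.DataFrame:
        """Median and quartiles of the resampled scores per protein/population."""
        g = self.population_scores.groupby(
            ["protein", "population", "score_type"], sort=True
        )["score"]
        out = g.agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
        ).reset_index()
        return out

    def summary(self) -> str:
        """Human-readable overview of the fitted analysis."""
        lines = []
        pops = [t.population for t in self.model.tables]
        lines.append("Population-weighted immunogenicity risk assessment")
        lines.append("=" * 58)
        lines.append(
            f"proteins: {len(self.model.proteins)}   alleles (matrices): "
            f"{len(self.model.pssms)}   populations: {', '.join(pops)}"
        )
        lines.append(
            f"panel (> {self.model.panel_min_freq:.0%} in >= 1 population): "
            f"{len(self.panel)} alleles; {len(self.weight_panel)} matrix-backed"
        )
        lines.append(
            f"resamples per population: {self.n_resamples}   seed: {self.seed}"
        )
        lines.append("")
        lines.append("Protein scores (per 1000 assessments):")
        lines.append(self.protein_scores.to_string(index=False))
        if not self.comparisons.empty:
            lines.append("")
            lines.append("Between-population comparison (paired signed-rank):")
            cols = [
                c
                for c in self.comparisons.columns
                if c.startswith(("protein", "score_type", "median_", "W", "p_value", "rank_"))
            ]
            lines.append(self.comparisons[cols].to_string(index=False))
        if not self.differential_frame.empty:
            lines.append("")
            lines.append(
                f"Differential allele pairs (joint probability > "
                f"{self.model.jp_min:.0%}, |difference| > {self.model.diff_min:.0%}):"
            )
            lines.append(self.differential_frame.to_string(index=False))
        return "\n".join(lines)

    def to_csv(self, out_dir: str | Path) -> None:
        """Export all stage outputs as CSVs with stable column order."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.protein_scores.to_csv(out / "scores.csv", index=False)
        iomod.write_grids_csv(list(self.grids.values()), out / "grids.csv")
        self.population_scores.to_csv(out / "population_scores.csv", index=False)
        self.population_summary().to_csv(out / "population_summary.csv", index=False)
        if not self.comparisons.empty:
            self.comparisons.to_csv(out / "comparison.csv", index=False)
        write_differential_csv(self.differentials, out / "differential_pairs.csv")
        self.item_frame.to_csv(out / "item_scores.csv", index=False)

    def plot_violin(self, **kwargs):
        from .plotting import plot_violin

        return plot_violin(self, **kwargs)

    def plot_item_boxes(self, **kwargs):
        from .plotting import plot_item_boxes

        return plot_item_boxes(self, **kwargs)
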