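"""The synthetic-data generators and their ground-truth guarantees."""

import numpy as np
import pytest

from itempop import (
    differential_pairs,
    filter_panel,
    load_pssm_set,
    protein_score,
    scan_protein,
)
from itempop.io import read_proteins_fasta, read_registry
from itempop.frequencies import read_frequency_csv
from itempop.pssm import BackgroundFrequencies, null_moments
from itempop.simulate import (
    GenerationError,
    PlantedEpitope,
    PlantedTregitope,
    PopulationSpec,
    SimSpec,
    generate_paired_scores,
    generate_population_tables,
    generate_pssm_set,
    generate_random_proteins,
    plant_protein,
    simulate_dataset,
)


class TestMatrixGenerator:
    def test_seeded_determinism(self):
        a = generate_pssm_set(3, seed=5)
        b = generate_pssm_set(3, seed=5)
        for m1, m2 in zip(a, b):
            assert m1.allele == m2.allele
            np.testing.assert_array_equal(m1.matrix, m2.matrix)

    def test_matrices_are_non_degenerate(self, uniform_bg):
        for pssm in generate_pssm_set(6, seed=9):
            assert null_moments(pssm, uniform_bg).sigma > 0.5


class TestPlanting:
    def test_three_plants_recovered(self, pssm_set4):
        alleles = [p.allele for p in pssm_set4]
        spec = SimSpec(
            seed=3,
            n_alleles=4,
            protein_length=150,
            epitopes=[
                PlantedEpitope(alleles[0], 20, 2.0),
                PlantedEpitope(alleles[0], 70, 2.0),
                PlantedEpitope(alleles[3], 110, 2.0),
            ],
        )
        protein, truth, _ = plant_protein(spec, pssm_set4)
        grid = scan_protein(protein, pssm_set4)
        hits = sorted(
            (grid.alleles[j], int(f + 1))
            for f, j in zip(*np.where(grid.hit_class == 2))
        )
        assert hits == truth["hits"]
        assert int((grid.hit_class >= 1).sum()) == 3

    def test_empty_plant_list_has_no_hits(self, pssm_set4):
        spec = SimSpec(seed=6, n_alleles=4, protein_length=120)
        protein, truth, _ = plant_protein(spec, pssm_set4)
        grid = scan_protein(protein, pssm_set4)
        assert truth["hits"] == []
        assert int((grid.hit_class >= 1).sum()) == 0

    def test_tregitope_over_all_hits_floors_adjusted_score(self, pssm_set4):
        alleles = [p.allele for p in pssm_set4]
        spec = SimSpec(
            seed=8,
            n_alleles=4,
            protein_length=120,
            epitopes=[PlantedEpitope(alleles[1], 60, 2.0)],
            tregitopes=[PlantedTregitope("TRG", 55, 20)],
        )
        protein, _, registry = plant_protein(spec, pssm_set4)
        grid = scan_protein(protein, pssm_set4, registry=registry)
        report = protein_score(grid)
        no_hit_spec = SimSpec(seed=8, n_alleles=4, protein_length=120)
        floor_protein, _, _ = plant_protein(no_hit_spec, pssm_set4)
        floor = protein_score(scan_protein(floor_protein, pssm_set4)).raw_score
        assert report.adjusted_score == pytest.approx(floor)
        assert report.raw_score > report.adjusted_score

    def test_out_of_bounds_plant_rejected(self):
        with pytest.raises(GenerationError):
            SimSpec(
                seed=1,
                protein_length=50,
                epitopes=[PlantedEpitope("DRB1*80:01", 49)],
            )

    def test_overlapping_plants_rejected(self, pssm_set4):
        alleles = [p.allele for p in pssm_set4]
        spec = SimSpec(
            seed=1,
            n_alleles=4,
            protein_length=100,
            epitopes=[
                PlantedEpitope(alleles[0], 30),
                PlantedEpitope(alleles[1], 35),
            ],
        )
        with pytest.raises(GenerationError, match="overlap"):
            plant_protein(spec, pssm_set4)


class TestPopulationTables:
    def test_requested_fractions_exact(self):
        spec = SimSpec(
            seed=2,
            populations=[
                PopulationSpec("A", 1000, {"DRB1*80:01": 0.3, "DRB1*80:02": 0.1})
            ],
        )
        (table,) = generate_population_tables(spec)
        assert table.carrier["DRB1*80:01"] == 0.3
        assert table.total_n == 1000

    def test_reference_structure_reproduces_differential_counts(
        self, reference_tables
    ):
        """Copying the packaged two-population structure gives the 3+6 split."""
        caucasian, japanese = reference_tables
        spec = SimSpec(
            seed=0,
            populations=[
                PopulationSpec("Caucasian", 20000, dict(caucasian.carrier)),
                PopulationSpec("Japanese", 5000, dict(japanese.carrier)),
            ],
        )
        t_c, t_j = generate_population_tables(spec)
        panel = filter_panel([t_c, t_j])
        diffs = differential_pairs(t_c, t_j, panel)
        dominants = [d.dominant for d in diffs]
        assert dominants.count("Caucasian") == 3
        assert dominants.count("Japanese") == 6

    def test_identical_populations_have_no_differential_pairs(self):
        carrier = {"DRB1*80:01": 0.25, "DRB1*80:02": 0.25}
        spec = SimSpec(
            seed=0,
            populations=[
                PopulationSpec("A", 1000, dict(carrier)),
                PopulationSpec("B", 1000, dict(carrier)),
            ],
        )
        a, b = generate_population_tables(spec)
        assert differential_pairs(a, b, filter_panel([a, b])) == []

    def test_single_planted_differential_homozygote(self):
        """0.30 vs 0.01 with a small shared remainder flags exactly one pair."""
        base = {f"DRB1*81:{i:02d}": 0.05 for i in range(1, 6)}
        spec = SimSpec(
            seed=0,
            populations=[
                PopulationSpec("A", 1000, {**base, "DRB1*80:01": 0.30}),
                PopulationSpec("B", 1000, {**base, "DRB1*80:01": 0.01}),
            ],
        )
        a, b = generate_population_tables(spec)
        diffs = differential_pairs(a, b, filter_panel([a, b]))
        assert len(diffs) == 1
        assert diffs[0].pair.homozygous
        assert diffs[0].pair.allele_a == "DRB1*80:01"
        assert diffs[0].diff == pytest.approx(0.30**2 - 0.01**2)

    def test_noise_mode_is_seeded(self):
        spec = SimSpec(
            seed=4,
            populations=[PopulationSpec("A", 500, {"DRB1*80:01": 0.3})],
        )
        t1 = generate_population_tables(spec, noise=True)
        t2 = generate_population_tables(spec, noise=True)
        assert t1[0].carrier == t2[0].carrier


class TestPairedScores:
    def test_seeded_determinism(self):
        s1 = generate_paired_scores(30, shift=0.5, seed=9)
        s2 = generate_paired_scores(30, shift=0.5, seed=9)
        np.testing.assert_array_equal(s1.x, s2.x)
        np.testing.assert_array_equal(s1.y, s2.y)

    def test_shift_appears_in_differences(self):
        s = generate_paired_scores(2000, shift=0.7, seed=1)
        assert (s.y - s.x).mean() == pytest.approx(0.7, abs=0.1)


class TestDatasetRoundTrip:
    def test_written_files_read_back_identically(self, tmp_path):
        config = {
            "seed": 13,
            "n_alleles": 3,
            "proteins": [
                {
                    "id": "bio_A",
                    "length": 120,
                    "epitopes": [
                        {"allele": "DRB1*80:01", "position": 40, "target_z": 2.2}
                    ],
                    "tregitopes": [{"id": "TRG1", "position": 80, "length": 15}],
                }
            ],
            "populations": [
                {"label": "A", "total_n": 1000, "default_carrier": 0.12},
                {
                    "label": "B",
                    "total_n": 1000,
                    "default_carrier": 0.12,
                    "carrier": {"DRB1*80:01": 0.3},
                },
            ],
        }
        paths = simulate_dataset(config, tmp_path / "sim")
        pssms = load_pssm_set(paths["matrix_dir"])
        assert [p.allele for p in pssms] == [
            p.allele for p in generate_pssm_set(3, seed=13)
        ]
        for written, regenerated in zip(pssms, generate_pssm_set(3, seed=13)):
            np.testing.assert_array_equal(written.matrix, regenerated.matrix)
        proteins = read_proteins_fasta(paths["proteins"])
        assert proteins[0].id == "bio_A" and len(proteins[0]) == 120
        registry = read_registry(paths["registry"])
        assert registry.entries[0][0] == "TRG1"
        assert registry.entries[0][1] in proteins[0].sequence
        tables = sorted(read_frequency_csv(paths["frequencies"]), key=lambda t: t.population)
        assert tables[1].carrier["DRB1*80:01"] == pytest.approx(0.3)
        # the written dataset scans to exactly the planted ground truth
        grid = scan_protein(proteins[0], pssms, registry=registry)
        hits = [
            (grid.alleles[j], int(f + 1))
            for f, j in zip(*np.where(grid.hit_class == 2))
        ]
        assert hits == [("DRB1*80:01", 40)]
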