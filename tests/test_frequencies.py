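"""Carrier-frequency aggregation, panel filtering and differential pairs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from itempop import (
    AllelePair,
    FrequencyTable,
    StudySample,
    aggregate_frequencies,
    carrier_to_allele_freq,
    differential_pairs,
    filter_panel,
    joint_probability,
)
from itempop.frequencies import (
    FrequencyError,
    allele_to_carrier_freq,
    joint_genotype_probability,
    read_frequency_csv,
    read_study_csv,
    write_frequency_csv,
)


def study(pop, sid, n, **carrier):
    clean = {k.replace("_", "*", 1): v for k, v in carrier.items()}
    return StudySample(population=pop, study_id=sid, sample_size=n, carrier=clean)


class TestAggregation:
    def test_single_study_passthrough(self):
        table = aggregate_frequencies(
            [study("jp", "s1", 100, **{"DRB1*09:01": 0.10})], "jp"
        )
        assert table.carrier["DRB1*09:01"] == pytest.approx(0.10)
        assert table.total_n == 100

    def test_sample_size_weighting(self):
        samples = [
            study("jp", "s1", 100, **{"DRB1*09:01": 0.10}),
            study("jp", "s2", 300, **{"DRB1*09:01": 0.20}),
        ]
        table = aggregate_frequencies(samples, "jp")
        assert table.carrier["DRB1*09:01"] == pytest.approx(0.175)

    def test_unreported_allele_counts_as_zero(self):
        samples = [
            study("jp", "s1", 100, **{"DRB1*09:01": 0.10}),
            study("jp", "s2", 100),
        ]
        table = aggregate_frequencies(samples, "jp")
        assert table.carrier["DRB1*09:01"] == pytest.approx(0.05)

    def test_no_matching_population(self):
        with pytest.raises(FrequencyError):
            aggregate_frequencies([study("jp", "s1", 10)], "caucasian")

    def test_invalid_inputs_rejected(self):
        with pytest.raises(FrequencyError):
            study("jp", "s1", 0, **{"DRB1*09:01": 0.1})
        with pytest.raises(FrequencyError):
            study("jp", "s1", 10, **{"DRB1*09:01": 1.2})

    @given(
        st.floats(0.0, 1.0),
        st.integers(2, 1000),
    )
    @settings(max_examples=50, deadline=None)
    def test_split_study_invariance(self, freq, n):
        whole = aggregate_frequencies(
            [study("p", "s", 2 * n, **{"DRB1*01:01": freq})], "p"
        )
        halves = aggregate_frequencies(
            [
                study("p", "s1", n, **{"DRB1*01:01": freq}),
                study("p", "s2", n, **{"DRB1*01:01": freq}),
            ],
            "p",
        )
        assert halves.carrier["DRB1*01:01"] == pytest.approx(
            whole.carrier["DRB1*01:01"]
        )


class TestPanelFilter:
    def test_rare_everywhere_excluded(self):
        tables = [
            FrequencyTable("a", {"DRB1*01:01": 0.005}, 100),
            FrequencyTable("b", {"DRB1*01:01": 0.005}, 100),
        ]
        assert filter_panel(tables) == []

    def test_common_in_one_population_included(self, reference_tables):
        panel = filter_panel(reference_tables)
        assert "DRB1*04:10" in panel  # 3.80% Japanese, 0.09% Caucasian

    def test_exactly_one_percent_excluded(self):
        tables = [FrequencyTable("a", {"DRB1*01:01": 0.01}, 100)]
        assert filter_panel(tables) == []

    def test_reference_panel_size(self, reference_tables):
        assert len(filter_panel(reference_tables)) == 26


class TestCarrierConversions:
    @pytest.mark.parametrize(
        "carrier,expected",
        [(0.0, 0.0), (0.75, 0.5), (0.2877, 1 - np.sqrt(1 - 0.2877))],
    )
    def test_closed_form(self, carrier, expected):
        assert carrier_to_allele_freq(carrier) == pytest.approx(expected)

    def test_out_of_range(self):
        with pytest.raises(FrequencyError):
            carrier_to_allele_freq(1.2)

    @given(st.floats(0.0, 1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, p):
        assert carrier_to_allele_freq(allele_to_carrier_freq(p)) == pytest.approx(
            p, abs=1e-9
        )


class TestJointProbability:
    def test_homozygous_square(self, reference_tables):
        _, japanese = reference_tables
        pair = AllelePair("DRB1*09:01", "DRB1*09:01")
        assert joint_probability(japanese, pair) == pytest.approx(0.2877**2)

    def test_absent_allele_gives_zero(self):
        table = FrequencyTable("p", {"DRB1*01:01": 0.5}, 10)
        assert joint_probability(table, AllelePair("DRB1*01:01", "DRB1*02:01")) == 0

    def test_heterozygous_product(self, reference_tables):
        caucasian, _ = reference_tables
        pair = AllelePair("DRB1*03:01", "DRB1*07:01")
        assert joint_probability(caucasian, pair) == pytest.approx(0.2904 * 0.2405)

    def test_symmetry_and_monotonicity(self):
        t1 = FrequencyTable("p", {"DRB1*01:01": 0.2, "DRB1*02:01": 0.4}, 10)
        t2 = FrequencyTable("p", {"DRB1*01:01": 0.3, "DRB1*02:01": 0.4}, 10)
        a, b = "DRB1*01:01", "DRB1*02:01"
        assert joint_probability(t1, AllelePair(a, b)) == joint_probability(
            t1, AllelePair(b, a)
        )
        assert joint_probability(t2, AllelePair(a, b)) > joint_probability(
            t1, AllelePair(a, b)
        )

    def test_hwe_genotype_utility(self):
        table = FrequencyTable("p", {"DRB1*01:01": 0.75, "DRB1*02:01": 0.75}, 10)
        pair = AllelePair("DRB1*01:01", "DRB1*02:01")
        assert joint_genotype_probability(table, pair) == pytest.approx(0.5)
        homo = AllelePair("DRB1*01:01", "DRB1*01:01")
        assert joint_genotype_probability(table, homo) == pytest.approx(0.25)


class TestDifferentialPairs:
    def test_reference_tables_reproduce_printed_counts(self, reference_tables):
        """Japanese/Caucasian tables give exactly 3 + 6 differential pairs."""
        caucasian, japanese = reference_tables
        panel = filter_panel(reference_tables)
        diffs = differential_pairs(caucasian, japanese, panel)
        cauc = [d for d in diffs if d.dominant == "Caucasian"]
        jap = [d for d in diffs if d.dominant == "Japanese"]
        assert len(cauc) == 3
        assert len(jap) == 6
        assert {a for d in cauc for a in d.pair.alleles} == {
            "DRB1*03:01",
            "DRB1*07:01",
        }
        assert {a for d in jap for a in d.pair.alleles} == {
            "DRB1*09:01",
            "DRB1*04:05",
            "DRB1*15:02",
        }

    def test_identical_tables_give_nothing(self, reference_tables):
        _, japanese = reference_tables
        panel = filter_panel([japanese])
        assert differential_pairs(japanese, japanese, panel) == []

    def test_sorted_by_absolute_difference(self, reference_tables):
        caucasian, japanese = reference_tables
        diffs = differential_pairs(
            caucasian, japanese, filter_panel(reference_tables)
        )
        magnitudes = [abs(d.diff) for d in diffs]
        assert magnitudes == sorted(magnitudes, reverse=True)

    def test_empty_panel_errors(self, reference_tables):
        caucasian, japanese = reference_tables
        with pytest.raises(FrequencyError):
            differential_pairs(caucasian, japanese, [])


class TestPairIdentity:
    def test_canonical_ordering(self):
        assert AllelePair("DRB1*07:01", "DRB1*03:01") == AllelePair(
            "DRB1*03:01", "DRB1*07:01"
        )
        assert AllelePair("DRB1*0901", "DRB1*09:01").homozygous


class TestCsvDialects:
    def test_frequency_round_trip(self, tmp_path, reference_tables):
        path = tmp_path / "freq.csv"
        write_frequency_csv(reference_tables, path)
        back = sorted(read_frequency_csv(path), key=lambda t: t.population)
        for orig, rt in zip(reference_tables, back):
            assert rt.population == orig.population
            assert rt.total_n == orig.total_n
            for allele, frac in orig.carrier.items():
                assert rt.carrier[allele] == pytest.approx(frac, abs=5e-5)

    def test_study_csv(self, tmp_path):
        path = tmp_path / "studies.csv"
        path.write_text(
            "population,study_id,sample_size,allele,carrier_percent\n"
            "jp,s1,100,DRB1*09:01,10.0\n"
            "jp,s2,300,DRB1*09:01,20.0\n"
        )
        samples = read_study_csv(path)
        table = aggregate_frequencies(samples, "jp")
        assert table.carrier["DRB1*09:01"] == pytest.approx(0.175)
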