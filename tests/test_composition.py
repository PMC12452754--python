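"""Composition: counts, adjacency, k-mers, mean-prediction propositions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aptabench.composition import (
    adjacent_counts,
    base_counts,
    composition_summary,
    kmer_frequencies,
    predicted_base_mean,
    proposition_check,
)
from aptabench.generator import (
    AptamerLibrary,
    AptamerSequence,
    GeneratorConfig,
    LengthSpec,
    generate_library,
)

rna = st.text(alphabet="AUGC", min_size=1, max_size=40)


class TestBaseCounts:
    @pytest.mark.parametrize(
        "residues,expected_counts,expected_pct",
        [
            ("AUGC", {"A": 1, "U": 1, "G": 1, "C": 1}, {"A": 25.0}),
            ("AAAA", {"A": 4, "U": 0, "G": 0, "C": 0}, {"A": 100.0, "U": 0.0}),
            ("GGAU", {"G": 2, "A": 1, "U": 1, "C": 0}, {"G": 50.0}),
        ],
    )
    def test_examples(self, make_seq, residues, expected_counts, expected_pct):
        rec = base_counts(make_seq(residues))
        for b, c in expected_counts.items():
            assert rec.counts[b] == c
        for b, f in expected_pct.items():
            assert rec.frequencies[b] == pytest.approx(f)

    def test_invalid_residue_reports_position(self, make_seq):
        with pytest.raises(ValueError, match="position 3"):
            base_counts(make_seq("AUXC"))

    @settings(max_examples=60, deadline=None)
    @given(residues=rna)
    def test_counts_sum_to_length(self, residues):
        rec = base_counts(AptamerSequence(id="h", residues=residues))
        assert sum(rec.counts.values()) == len(residues)
        assert sum(rec.frequencies.values()) == pytest.approx(100.0)


class TestCompositionSummary:
    def test_permutation_library_zero_variance(self, make_seq):
        lib = AptamerLibrary(
            [make_seq(r, id=f"s{i}") for i, r in enumerate(["AUGC", "UGCA", "GCAU", "CAUG"])]
        )
        table = composition_summary(lib).set_index("Base")
        assert (table["Average"] == 1.0).all()
        assert (table["Variance"] == 0.0).all()

    def test_two_sequence_toy(self, make_seq):
        lib = AptamerLibrary([make_seq("AAUU", id="a"), make_seq("GGCC", id="b")])
        row = composition_summary(lib).set_index("Base").loc["A"]
        assert row["Count"] == 2 and row["Sum"] == 2
        assert row["Average"] == pytest.approx(1.0)
        assert row["Variance"] == pytest.approx(2.0)  # counts 2 and 0, ddof=1

    def test_regenerated_library_near_prediction(self, fixed_library):
        table = composition_summary(fixed_library)
        for _, row in table.iterrows():
            se = np.sqrt(row["Variance"] / row["Count"])
            assert abs(row["Average"] - 5.5) <= 3 * se

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            composition_summary(AptamerLibrary([]))


class TestAdjacency:
    @pytest.mark.parametrize(
        "residues,expected",
        [
            ("AUGC", {"AU": 1, "UG": 1, "GC": 1}),
            ("AAAA", {"AA": 3}),
            ("AUAU", {"AU": 2, "UA": 1}),
        ],
    )
    def test_examples(self, make_seq, residues, expected):
        rec = adjacent_counts(make_seq(residues))
        for d, c in expected.items():
            assert rec.counts[d] == c
        assert rec.total == len(residues) - 1

    def test_length_one_warns_all_zero(self, make_seq, caplog):
        with caplog.at_level("WARNING"):
            rec = adjacent_counts(make_seq("A"))
        assert rec.total == 0
        assert "all-zero" in caplog.text


class TestKmers:
    def test_trimer_example(self, make_seq):
        counts, freqs = kmer_frequencies(make_seq("AUGC"), kmax=3)
        assert counts["AUG"] == 1 and counts["UGC"] == 1
        assert freqs["AUG"] == pytest.approx(0.5)  # 2 windows

    def test_homopolymer_dinucleotide_frequency(self, make_seq):
        _, freqs = kmer_frequencies(make_seq("AAAA"), kmax=2)
        assert freqs["AA"] == pytest.approx(1.0)

    def test_k1_matches_base_counts(self, make_seq):
        seq = make_seq("GGAUCCA")
        counts, _ = kmer_frequencies(seq, kmax=1)
        rec = base_counts(seq)
        assert {b: counts[b] for b in "AUGC"} == rec.counts

    def test_kmax_above_length_rejected(self, make_seq):
        with pytest.raises(ValueError):
            kmer_frequencies(make_seq("AU"), kmax=3)

    @settings(max_examples=60, deadline=None)
    @given(residues=st.text(alphabet="AUGC", min_size=3, max_size=30))
    def test_window_conservation(self, residues):
        counts, _ = kmer_frequencies(AptamerSequence(id="h", residues=residues), kmax=3)
        n = len(residues)
        for k in (1, 2, 3):
            total = sum(c for name, c in counts.items() if len(name) == k)
            assert total == n - k + 1


class TestPrediction:
    @pytest.mark.parametrize(
        "spec,expected",
        [
            (LengthSpec.fixed(22), 5.5),
            (LengthSpec.uniform_range(16, 60), 9.5),
            (LengthSpec.uniform_range(16, 59), 9.375),
        ],
    )
    def test_closed_form(self, spec, expected):
        assert predicted_base_mean(spec).predicted_mean == pytest.approx(expected)

    def test_proposition_fixed_library_passes(self, fixed_library):
        table = proposition_check(fixed_library)
        assert (table["Predicted"] == 5.5).all()
        assert table["Pass"].all()

    def test_single_sequence_exact(self, make_seq):
        lib = AptamerLibrary([make_seq("AUGC")])
        table = proposition_check(lib, spec=LengthSpec.fixed(4))
        assert (table["AbsDeviation"] == 0.0).all()

    def test_imported_library_needs_spec(self, make_seq):
        lib = AptamerLibrary([make_seq("AUGC", id="x"), make_seq("GCUA", id="y")])
        with pytest.raises(ValueError, match="LengthSpec"):
            proposition_check(lib)

    def test_convergence_with_library_size(self):
        """Mean |observed − predicted| per base shrinks as the library grows."""
        devs = []
        for count in (100, 1000, 10_000):
            lib = generate_library(
                GeneratorConfig(seed=5, count=count, length_spec=LengthSpec.fixed(22))
            )
            table = proposition_check(lib)
            devs.append(table["AbsDeviation"].mean())
        assert devs[2] < devs[0]
        assert devs[1] < devs[0] or devs[2] < devs[1]
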