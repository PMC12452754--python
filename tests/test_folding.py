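"""Folding: structural invariants, brute-force oracle equivalence, analysis."""

import numpy as np
import pandas as pd
import pytest

from aptabench.folding import (
    BackendUnavailableError,
    enumerate_structures,
    feature_mfe_correlations,
    fold,
    fold_mfe,
    fold_simple,
    get_backend,
    length_mfe_correlation,
    length_threshold_scan,
    mfe_summary,
    simple_structure_energy,
    structure_energy,
    validate_structure,
)
from aptabench.generator import AptamerLibrary, AptamerSequence

from conftest import random_rna


def _brute_force_min(sequence: str, scorer) -> float:
    return min(scorer(sequence, db) for db in enumerate_structures(sequence))


class TestValidator:
    def test_accepts_legal_hairpin(self):
        validate_structure("GGGAAACCC", "(((...)))")

    def test_rejects_illegal_pair(self):
        with pytest.raises(ValueError, match="illegal pair"):
            validate_structure("GGGAAACCA", "(((...)))")  # G-A terminal pair

    def test_rejects_tight_hairpin(self):
        with pytest.raises(ValueError, match="hairpin"):
            validate_structure("GAAC", "(..)")

    def test_rejects_unbalanced(self):
        with pytest.raises(ValueError, match="unbalanced"):
            validate_structure("GGGAAACCC", "(((....))")

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            validate_structure("GGGAAACCC", "(((...))")


class TestTurnerEngine:
    def test_short_sequences_cannot_fold(self):
        for n in (1, 3, 4):
            s, m = fold_mfe("A" * n)
            assert s == "." * n and m == 0.0

    def test_homopolymer_never_folds(self):
        s, m = fold_mfe("A" * 40)
        assert m == 0.0 and s == "." * 40

    def test_stable_hairpin_folds(self):
        s, m = fold_mfe("GGGGGAAACCCCC")
        assert m < 0
        assert "(" in s
        validate_structure("GGGGGAAACCCCC", s)

    def test_mfe_zero_iff_open_chain(self, rng):
        for _ in range(80):
            seq = random_rna(rng, int(rng.integers(5, 41)))
            s, m = fold_mfe(seq)
            assert m <= 0
            assert (m == 0.0) == (s == "." * len(seq))
            validate_structure(seq, s)

    def test_traceback_energy_matches_dp(self, rng):
        """The traced structure re-scores (by loop decomposition) to the DP value."""
        for _ in range(60):
            seq = random_rna(rng, int(rng.integers(8, 61)))
            s, m = fold_mfe(seq)
            if m < 0:
                assert structure_energy(seq, s) == pytest.approx(m, abs=1e-9)

    def test_dp_equals_exhaustive_enumeration(self, rng):
        """DP minimum equals brute force over all legal structures (n <= 10)."""
        checked = 0
        for _ in range(120):
            seq = random_rna(rng, int(rng.integers(5, 11)))
            best = min(0.0, _brute_force_min(seq, structure_energy))
            _, m = fold_mfe(seq)
            assert m == pytest.approx(best, abs=1e-9)
            checked += 1
        assert checked == 120

    def test_median_mfe_non_increasing_with_length(self, rng):
        medians = []
        for n in (10, 20, 30, 40, 50, 60):
            mfes = [fold_mfe(random_rna(rng, n))[1] for _ in range(120)]
            medians.append(np.median(mfes))
        assert all(b <= a + 1e-9 for a, b in zip(medians, medians[1:]))


class TestSimpleEngine:
    def test_no_complementary_pairs(self):
        s, m = fold_simple("A" * 10)
        assert s == "." * 10 and m == 0.0

    def test_short_sequences(self):
        for n in (1, 4):
            s, m = fold_simple("G" * n + "C" * 0)
            assert m == 0.0

    def test_four_stack_hairpin_breaks_even(self):
        # 4 pairs = 3 stack adjacencies: -3 + 3 = 0, clamped to open chain
        # (confirmed by the exhaustive oracle below)
        s, m = fold_simple("GGGGAAACCCC")
        assert m == 0.0 and s == "." * 11

    def test_strong_hairpin_negative(self):
        # 5 pairs = 4 stack adjacencies beat the +3 hairpin penalty
        s, m = fold_simple("GGGGGAAACCCCC")
        assert m < 0
        validate_structure("GGGGGAAACCCCC", s)

    def test_dp_equals_exhaustive_enumeration(self, rng):
        """Simplified DP equals brute force on a seeded sample (n <= 10)."""
        for _ in range(300):
            seq = random_rna(rng, int(rng.integers(5, 11)))
            best = min(0.0, _brute_force_min(seq, simple_structure_energy))
            _, m = fold_simple(seq)
            assert m == pytest.approx(best)

    def test_traced_structure_rescoring(self, rng):
        for _ in range(100):
            seq = random_rna(rng, int(rng.integers(8, 31)))
            s, m = fold_simple(seq)
            if m < 0:
                assert simple_structure_energy(seq, s) == pytest.approx(m)


class TestBackends:
    def test_registry_and_aliases(self):
        assert get_backend("turner").name == "turner"
        assert get_backend("builtin").name == "nussinov"
        assert get_backend("nussinov").name == "nussinov"

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError, match="unknown backend"):
            get_backend("mfold")

    def test_viennarna_wrapper_or_explicit_error(self):
        """The wrapper either works (bindings present) or names the fallback."""
        try:
            bk = get_backend("vienna")
        except BackendUnavailableError as exc:
            assert "turner" in str(exc)
        else:
            res = bk.fold(AptamerSequence(id="x", residues="GGGGGAAACCCCC"))
            assert res.mfe < 0

    def test_fold_is_deterministic(self):
        seq = AptamerSequence(id="s", residues="GCGCUUAAGCGCAUAGCAU")
        a = fold(seq, "turner")
        b = fold(seq, "turner")
        assert a == b

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            fold(AptamerSequence(id="s", residues="GGGATACCC"), "turner")


class TestAnalysis:
    def test_single_unfoldable_sequence_summary(self):
        lib = AptamerLibrary([AptamerSequence(id="a", residues="AAAAAAA")])
        s = mfe_summary(lib, "turner")
        assert s.zero_fraction == 1.0
        assert s.minimum == s.maximum == 0.0

    def test_summary_counts_are_consistent(self, fixed_library, fixed_folds):
        s = mfe_summary(fixed_library, results=fixed_folds)
        assert s.n == len(fixed_library)
        assert s.zero_count == sum(1 for r in fixed_folds if r.mfe == 0.0)
        assert s.minimum <= s.median <= s.maximum

    def test_length_correlation_examples(self):
        r = length_mfe_correlation([1, 2, 3], [-1.0, -2.0, -3.0])
        assert r == pytest.approx(-1.0)

    def test_fixed_length_correlation_undefined(self):
        with pytest.raises(ValueError, match="fixed-length"):
            length_mfe_correlation([22, 22, 22], [-1.0, -2.0, -3.0])

    def test_feature_correlation_edges(self):
        mfes = np.array([-1.0, -2.0, -3.0, -4.0])
        feats = pd.DataFrame({"same": mfes, "const": np.ones(4)})
        r = feature_mfe_correlations(feats, mfes)
        assert r["same"] == pytest.approx(1.0)
        assert np.isnan(r["const"])

    def test_gg_counts_correlate_negatively_with_mfe(self, random_library, random_folds):
        from aptabench.composition import adjacency_table

        adj = adjacency_table(random_library)
        mfes = np.array([r.mfe for r in random_folds])
        r = feature_mfe_correlations(adj, mfes)
        assert r["GG"] < 0

    def test_scan_small_lengths_exhaustive(self):
        rows = length_threshold_scan(1, 5, "turner")
        assert [r.arrangements for r in rows] == [4, 16, 64, 256, 1024]
        assert all(r.exhaustive and r.sampled_total == r.arrangements for r in rows)
        assert all(r.nonzero_mfe_count == 0 for r in rows)
        assert all(r.zeta == 0 for r in rows)

    def test_scan_sampling_above_cap(self):
        rows = length_threshold_scan(9, 9, "turner", sample_cap=500, seed=3)
        row = rows[0]
        assert not row.exhaustive
        assert row.arrangements == 4**9
        assert 0 < row.sampled_total <= 500
        assert row.zeta == 1
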