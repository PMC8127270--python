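import warnings

import numpy as np
import pandas as pd
import pytest

from ltrdyn.io import SequenceRecord
from ltrdyn.quantify import (average_coverage, call_expressed, condition_sets,
                             differential_expression, expression_matrix,
                             map_reads, rpkm)
from ltrdyn.simulate import (LibraryDesign, mutate_sequence, random_dna,
                             reverse_complement, simulate_rna_counts)


def _design(tp=24, libsize=1_000_000):
    return [LibraryDesign(c, tp, r, libsize)
            for c in ("control", "salt") for r in (1, 2, 3)]


class TestMapReads:
    def test_verbatim_read_is_unique_at_100_identity(self, rng):
        ref = SequenceRecord("e1", random_dna(2000, rng))
        read = SequenceRecord("r1", ref.residues[500:600])
        (a,) = map_reads([read], [ref])
        assert a.primary == "e1" and a.unique and a.identity == 100.0

    def test_reverse_strand_read_maps(self, rng):
        ref = SequenceRecord("e1", random_dna(2000, rng))
        read = SequenceRecord("r1", reverse_complement(ref.residues[300:400]))
        (a,) = map_reads([read], [ref])
        assert a.primary == "e1"

    def test_read_below_identity_threshold_is_unassigned(self, rng):
        ref = SequenceRecord("e1", random_dna(2000, rng))
        frag = list(ref.residues[500:600])
        # 15 substitutions in 100 bp: identity 85% < 90%
        for i in range(0, 90, 6):
            frag[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[frag[i]]
        assert map_reads([SequenceRecord("r1", "".join(frag))], [ref]) == []

    def test_read_matching_two_similar_elements_is_not_unique(self, rng):
        base = random_dna(2000, rng)
        refs = [SequenceRecord("e1", base),
                SequenceRecord("e2", mutate_sequence(base, 0.05, rng))]
        read = SequenceRecord("r1", base[800:900])
        (a,) = map_reads([read], refs)
        assert a.unique is False
        assert sorted(a.elements) == ["e1", "e2"]

    def test_unique_fraction_is_one_for_unrelated_references(self, rng):
        refs = [SequenceRecord(f"e{i}", random_dna(1500, rng))
                for i in range(4)]
        reads = [SequenceRecord(f"r{i}", refs[i % 4].residues[200:320])
                 for i in range(20)]
        assignments = map_reads(reads, refs)
        assert len(assignments) == 20
        assert all(a.unique for a in assignments)


class TestCoverage:
    def test_single_read_coverage(self, rng):
        ref = SequenceRecord("e1", random_dna(1000, rng))
        reads = [SequenceRecord("r1", ref.residues[100:200])]
        cov = average_coverage(map_reads(reads, [ref]), {"e1": 1000})
        assert cov["e1"].coverage == pytest.approx(0.1)

    def test_fifty_reads_coverage(self, rng):
        ref = SequenceRecord("e1", random_dna(1000, rng))
        reads = [SequenceRecord(f"r{i}", ref.residues[i * 18 % 900:
                                                      i * 18 % 900 + 100])
                 for i in range(50)]
        cov = average_coverage(map_reads(reads, [ref]), {"e1": 1000})
        assert cov["e1"].coverage == pytest.approx(5.0)

    def test_zero_reads_is_zero(self):
        cov = average_coverage([], {"e1": 1000})
        assert cov["e1"].coverage == 0.0


class TestRpkm:
    def test_formula_fixtures(self):
        counts = pd.DataFrame({"lib": [10, 0, 100]},
                              index=["a", "b", "c"])
        lengths = {"a": 1000, "b": 500, "c": 5000}
        out = rpkm(counts, lengths, {"lib": 1_000_000})
        assert out.loc["a", "lib"] == pytest.approx(10.0)
        assert out.loc["b", "lib"] == 0.0
        out2 = rpkm(counts, lengths, {"lib": 20_000_000})
        assert out2.loc["c", "lib"] == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(5, 3)),
                              index=list("abcde"), columns=list("xyz"))
        lengths = {k: int(v) for k, v in
                   zip("abcde", rng.integers(500, 5000, 5))}
        totals = {"x": 10_000, "y": 20_000, "z": 15_000}
        doubled = rpkm(counts * 2, lengths,
                       {k: 2 * v for k, v in totals.items()})
        pd.testing.assert_frame_equal(rpkm(counts, lengths, totals), doubled)

    def test_zero_total_is_error(self):
        counts = pd.DataFrame({"lib": [1]}, index=["a"])
        with pytest.raises(ValueError):
            rpkm(counts, {"a": 100}, {"lib": 0})


class TestExpressedCalling:
    def test_all_below_threshold_excluded(self):
        df = pd.DataFrame({"l1": [0.5], "l2": [0.5]}, index=["e"])
        assert call_expressed(df) == set()

    def test_single_library_above_threshold_included(self):
        df = pd.DataFrame({"l1": [1.2], "l2": [0.0]}, index=["e"])
        assert call_expressed(df) == {"e"}

    def test_exactly_threshold_is_excluded(self):
        # strictly greater than 1
        df = pd.DataFrame({"l1": [1.0], "l2": [1.0]}, index=["e"])
        assert call_expressed(df) == set()


class TestConditionSets:
    def _full(self):
        return [LibraryDesign(c, tp, r) for c in ("control", "salt")
                for tp in (24, 48) for r in (1, 2, 3)]

    def test_everywhere_expressed_is_in_four_way_intersection(self):
        design = self._full()
        df = pd.DataFrame({d.name: [5.0] for d in design}, index=["e"])
        sets, member, venn = condition_sets(df, design)
        assert all("e" in s for s in sets.values())
        assert venn[(True, True, True, True)] == 1

    def test_c24_only_element(self):
        design = self._full()
        df = pd.DataFrame({d.name: [2.0 if d.treatment == "C24" else 0.0]
                           for d in design}, index=["e"])
        sets, _member, venn = condition_sets(df, design)
        assert sets["C24"] == {"e"}
        assert sets["S24"] == sets["C48"] == sets["S48"] == set()
        assert venn[(True, False, False, False)] == 1

    def test_empty_matrix_gives_zero_counts(self):
        design = self._full()
        df = pd.DataFrame({d.name: [] for d in design})
        _sets, member, venn = condition_sets(df, design)
        assert member.empty and venn == {}


class TestDifferentialExpression:
    def test_identical_counts_are_ns(self):
        design = _design()
        counts = pd.DataFrame({d.name: [50, 20] for d in design},
                              index=["a", "b"])
        res = differential_expression(counts, design, 24)
        for r in res:
            assert r.status == "ns"
            assert r.fold_change == pytest.approx(1.0)

    def test_planted_fourfold_change_is_called_up(self):
        design = _design()
        totals = pd.Series({d.name: float(d.library_size) for d in design})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts = simulate_rna_counts(
                [(f"e{i}", 1000, {"C24": 60.0,
                                  "S24": 240.0 if i < 5 else 60.0})
                 for i in range(30)], design, 0.05, seed=7)
        res = differential_expression(counts, design, 24,
                                      library_totals=totals)
        called = {r.element_id for r in res if r.status == "up"}
        assert {"e0", "e1", "e2", "e3", "e4"} <= called | set()  # recall
        assert all(r.status == "ns" for r in res[10:])  # no false calls here

    def test_small_fold_change_is_gated_even_with_tiny_p(self):
        design = _design()
        # huge counts make a 1.5-fold difference wildly significant, but
        # the fold-change gate keeps it ns
        counts = pd.DataFrame(
            {d.name: [150_000 if d.condition == "salt" else 100_000]
             for d in design}, index=["e"])
        totals = pd.Series({d.name: 1_000_000.0 for d in design})
        (r,) = differential_expression(counts, design, 24,
                                       library_totals=totals)
        assert r.p_value < 1e-10
        assert r.status == "ns"

    def test_status_invariant(self):
        design = _design()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            counts = simulate_rna_counts(
                [(f"e{i}", 1000, {"C24": 30.0, "S24": 30.0 * (i + 1)})
                 for i in range(10)], design, 0.1, seed=3)
        res = differential_expression(counts, design, 24)
        for r in res:
            if r.status != "ns":
                assert r.fdr < 0.05
                assert r.fold_change > 2 or r.fold_change < 0.5

    def test_single_replicate_is_error(self):
        design = [LibraryDesign("control", 24, 1), LibraryDesign("salt", 24, 1),
                  LibraryDesign("salt", 24, 2)]
        counts = pd.DataFrame({d.name: [5] for d in design}, index=["e"])
        with pytest.raises(ValueError):
            differential_expression(counts, design, 24)


class TestExpressionMatrixFromReads:
    def test_counts_rpkm_and_unique_fraction(self, rng):
        refs = [SequenceRecord("e1", random_dna(2000, rng)),
                SequenceRecord("e2", random_dna(1000, rng))]
        reads = {
            "lib1": [SequenceRecord(f"a{i}", refs[0].residues[i * 10:i * 10 + 100])
                     for i in range(10)],
            "lib2": [SequenceRecord("b0", refs[1].residues[100:200])],
        }
        assignments = {lib: map_reads(rs, refs) for lib, rs in reads.items()}
        m = expression_matrix(assignments, {"e1": 2000, "e2": 1000},
                              library_totals={"lib1": 1000, "lib2": 1000})
        assert m.counts.loc["e1", "lib1"] == 10
        assert m.counts.loc["e2", "lib2"] == 1
        assert m.rpkm.loc["e1", "lib1"] == pytest.approx(
            10 * 1e9 / (1000 * 2000))
        assert (m.unique_fraction == 1.0).all()
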