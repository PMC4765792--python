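"""Mature read counting (the double-count rule), partition statistics vs the
exact permutation oracle, DE and heredity boundaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allomirna.expression import (
    MatureSpan,
    count_mature_reads,
    differential_expression,
    exact_permutation_pvalue,
    expression_matrix,
    heredity_classification,
    mirna_density,
    rank_sum_test,
    subgenome_partition_test,
)
from allomirna.seqio import Alignment, GenomeSet, SmallRNALibrary


def _lib(reads, total=None, lib_id="L1"):
    return SmallRNALibrary(
        lib_id, "T", "leaf", "E1", reads,
        total if total is not None else sum(reads.values()),
    )


MAT_A = "TGACAGAAGAGAGTGAGCACA"
MAT_C = "TGACAGAAGAGAGTGAGCACC"

SPANS = [
    MatureSpan(MAT_A, "locA", "A01", 100, 121, "A"),
    MatureSpan(MAT_C, "locC", "C01", 500, 521, "C"),
]


class TestCounting:
    def test_read_in_one_subgenome_span(self):
        lib = _lib({MAT_A: 7})
        aln = {MAT_A: [Alignment("A01", 100, 121, "+", MAT_A)]}
        col = count_mature_reads(lib, SPANS, aln)
        a = col.set_index("subgenome")["count"]
        assert a["A"] == 7 and a["C"] == 0

    def test_dual_subgenome_read_counted_twice(self):
        lib = _lib({MAT_A: 7})
        aln = {MAT_A: [
            Alignment("A01", 100, 121, "+", MAT_A),
            Alignment("C01", 500, 521, "+", MAT_A),
        ]}
        spans = [
            MatureSpan(MAT_A, "locA", "A01", 100, 121, "A"),
            MatureSpan(MAT_A, "locA2", "C01", 500, 521, "C"),
        ]
        col = count_mature_reads(lib, spans, aln)
        assert col["count"].tolist() == [7, 7]

    def test_read_extending_beyond_span_not_counted(self):
        long_read = "G" + MAT_A + "G" * 4
        lib = _lib({long_read: 5})
        aln = {long_read: [Alignment("A01", 99, 125, "+", long_read)]}
        col = count_mature_reads(lib, SPANS, aln, slack=2)
        assert col["count"].sum() == 0

    def test_slack_admits_small_overhang(self):
        near = MAT_A + "G"
        lib = _lib({near: 5})
        aln = {near: [Alignment("A01", 100, 122, "+", near)]}
        col = count_mature_reads(lib, SPANS, aln, slack=2)
        assert col.set_index("subgenome")["count"]["A"] == 5

    def test_double_count_conservation(self):
        # total A + total C = mapped mature count + one extra per dual read
        lib = _lib({MAT_A: 7, MAT_C: 3})
        spans = [
            MatureSpan(MAT_A, "la", "A01", 100, 121, "A"),
            MatureSpan(MAT_A, "lc", "C01", 500, 521, "C"),
            MatureSpan(MAT_C, "lc2", "C01", 900, 921, "C"),
        ]
        aln = {
            MAT_A: [Alignment("A01", 100, 121, "+", MAT_A),
                    Alignment("C01", 500, 521, "+", MAT_A)],
            MAT_C: [Alignment("C01", 900, 921, "+", MAT_C)],
        }
        col = count_mature_reads(lib, spans, aln)
        assert col["count"].sum() == (7 + 3) + 7  # dual read adds one extra

    def test_rpm_consistent_with_clean_total(self):
        lib = _lib({MAT_A: 50}, total=10_000_000)
        aln = {MAT_A: [Alignment("A01", 100, 121, "+", MAT_A)]}
        col = count_mature_reads(lib, SPANS, aln)
        assert col.set_index("subgenome")["rpm"]["A"] == pytest.approx(5.0)


def _matrix(a_vals, c_vals, lib_id="L1"):
    rows = []
    for i, v in enumerate(a_vals):
        rows.append({"mature": f"a{i}", "subgenome": "A", "locus_id": f"la{i}",
                     "count": v, "rpm": float(v), "library_id": lib_id})
    for i, v in enumerate(c_vals):
        rows.append({"mature": f"c{i}", "subgenome": "C", "locus_id": f"lc{i}",
                     "count": v, "rpm": float(v), "library_id": lib_id})
    return pd.DataFrame(rows)


class TestPartition:
    def test_identical_vectors_ratio_one_p_one(self):
        m = _matrix([1, 2, 3, 4], [1, 2, 3, 4])
        res = subgenome_partition_test(m)
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_tiny_vectors_match_exact_permutation_oracle(self):
        a, c = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        p, name = rank_sum_test(a, c)
        assert "exact" in name
        assert p == pytest.approx(exact_permutation_pvalue(a, c))

    def test_exact_method_matches_oracle_on_random_groups(self, rng):
        for _ in range(20):
            a = rng.lognormal(0, 1, size=int(rng.integers(3, 7)))
            c = rng.lognormal(0, 1, size=int(rng.integers(3, 7)))
            p, _ = rank_sum_test(a, c)
            assert p == pytest.approx(exact_permutation_pvalue(a, c), abs=1e-12)

    def test_per_mb_mode_uses_subgenome_lengths(self):
        genome = GenomeSet(
            {"A01": "A" * 2_000_000, "C01": "C" * 1_000_000},
            {"A01": "A", "C01": "C"},
        )
        m = _matrix([10, 10], [10, 10])
        res = subgenome_partition_test(m, genome, mode="per_mb")
        assert res.ratio == pytest.approx(2.0)  # same totals, half the Mb

    def test_requires_two_loci_per_subgenome(self):
        with pytest.raises(ValueError):
            subgenome_partition_test(_matrix([1], [1, 2]))

    def test_scale_invariance(self):
        lib1 = _lib({MAT_A: 5, MAT_C: 10})
        lib10 = _lib({MAT_A: 50, MAT_C: 100})
        aln = {
            MAT_A: [Alignment("A01", 100, 121, "+", MAT_A)],
            MAT_C: [Alignment("C01", 500, 521, "+", MAT_C)],
        }
        m1 = expression_matrix([lib1], SPANS, aln)
        m10 = expression_matrix([lib10], SPANS, aln)
        assert m1["rpm"].tolist() == m10["rpm"].tolist()


class TestDensity:
    def test_loci_per_mb(self):
        genome = GenomeSet(
            {"A01": "A" * 10_000_000, "C01": "C" * 10_000_000},
            {"A01": "A", "C01": "C"},
        )

        class L:
            def __init__(self, sub):
                self.subgenome = sub

        loci = [L("A")] * 10
        d = mirna_density(loci, genome)
        assert d["A"] == pytest.approx(1.0)
        assert d["C"] == 0.0

    def test_printed_precision_case(self):
        genome = GenomeSet({"A01": "A" * 100_000_000}, {"A01": "A", })
        genome.records["C01"] = "C" * 100_000_000
        genome.subgenome_of["C01"] = "C"

        class L:
            subgenome = "A"

        assert mirna_density([L()] * 103, genome)["A"] == pytest.approx(1.03)


def _two_group_matrix(vals1, vals2, libs=("L1", "L2")):
    frames = [_matrix(vals1, [], lib_id=libs[0]), _matrix(vals2, [], lib_id=libs[1])]
    return pd.concat(frames, ignore_index=True)


class TestDifferentialExpression:
    @pytest.mark.parametrize("m1,m2,expected", [
        (10, 10, False),   # equal means
        (30, 10, True),    # 3-fold
        (20, 10, False),   # exactly 2-fold fails strict >
    ])
    def test_twofold_rule_boundaries(self, m1, m2, expected):
        m = _two_group_matrix([m1], [m2])
        df = differential_expression(m, ["L1"], ["L2"])
        assert bool(df["de"].iloc[0]) is expected

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            differential_expression(_matrix([1], [1]), [], ["L1"])


class TestHeredity:
    def _matrix(self, p1, p2, dh):
        frames = [
            _matrix([p1], [], lib_id="T_E1"),
            _matrix([p2], [], lib_id="N_E1"),
            _matrix([dh], [], lib_id="DH1_E1"),
        ]
        return pd.concat(frames, ignore_index=True)

    def test_derived_equal_mpv_is_additive(self):
        calls, _ = heredity_classification(
            self._matrix(10, 20, 15), ["T_E1"], ["N_E1"], ["DH1_E1"]
        )
        assert calls[0].call == "additive"

    def test_exactly_twofold_is_non_additive_inclusive(self):
        calls, _ = heredity_classification(
            self._matrix(10, 20, 30), ["T_E1"], ["N_E1"], ["DH1_E1"]
        )
        assert calls[0].call == "non-additive"
        assert calls[0].log2_deviation == pytest.approx(1.0)

    def test_half_mpv_is_non_additive(self):
        calls, _ = heredity_classification(
            self._matrix(10, 20, 7.5), ["T_E1"], ["N_E1"], ["DH1_E1"]
        )
        assert calls[0].call == "non-additive"

    def test_summary_counts(self):
        calls, summary = heredity_classification(
            self._matrix(10, 20, 60), ["T_E1"], ["N_E1"], ["DH1_E1"]
        )
        assert summary["n_non_additive"] == 1 and summary["n_total"] == 1
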