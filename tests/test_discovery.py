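"""Duplex evaluation, acceptance gates, and conserved/novel classification."""

import numpy as np
import pytest

from allomirna.discovery import (
    MatureSpansLoop,
    Thresholds,
    assign_subgenome,
    call_mirna,
    classify_mirna,
    cluster_and_excise,
    edit_distance,
    evaluate_duplex,
)
from allomirna.fold import HairpinFold, fold_hairpin
from allomirna.seqio import GenomeSet, revcomp

MATURE = "TGACAGAAGAGAGTGAGCACA"  # 21 nt


def _hairpin_fold(loop="AGCTAGCT", star_mut=()):
    star = list(revcomp(MATURE))
    for pos, base in star_mut:
        star[pos] = base
    seq = MATURE + loop + "".join(star)
    return fold_hairpin(seq)


def _dummy_fold(dg):
    n = 30
    return HairpinFold("A" * n, "." * n, dg, np.full(n, -1, dtype=np.int64))


def _metrics(matched=19, bulges=1, spacing=45):
    from allomirna.discovery import DuplexMetrics

    return DuplexMetrics(matched, bulges, spacing, (40, 63))


class TestEvaluateDuplex:
    def test_perfectly_paired_mature(self):
        f = _hairpin_fold()
        d = evaluate_duplex(f, (0, 21))
        assert d.matched_nt == 21
        assert d.bulge_nt == 0

    def test_star_interval_has_two_nt_overhang(self):
        f = _hairpin_fold()
        d = evaluate_duplex(f, (0, 21))
        lo, hi = d.star_interval
        assert hi - lo >= 21 + 2 or hi == len(f.sequence)

    def test_mature_spanning_loop_rejected(self):
        # the whole hairpin as "mature" pairs with itself
        f = _hairpin_fold()
        with pytest.raises(MatureSpansLoop):
            evaluate_duplex(f, (0, len(f.sequence)))

    def test_unpaired_mature_counts_bulges(self):
        f = fold_hairpin("A" * 60)
        d = evaluate_duplex(f, (0, 21))
        assert d.matched_nt == 0
        assert d.bulge_nt == 21


class TestCallMirna:
    """Exact boundary behaviour of every quoted acceptance criterion."""

    def test_free_energy_strictly_below_minus_18(self):
        ok = call_mirna(_dummy_fold(-18.01), _metrics(), {"L": 10})
        at = call_mirna(_dummy_fold(-18.0), _metrics(), {"L": 10})
        above = call_mirna(_dummy_fold(-17.5), _metrics(), {"L": 10})
        assert ok == []
        assert any("free-energy" in r for r in at)
        assert any("free-energy" in r for r in above)

    def test_matched_nt_more_than_16(self):
        fail = call_mirna(_dummy_fold(-25), _metrics(matched=16), {"L": 10})
        ok = call_mirna(_dummy_fold(-25), _metrics(matched=17), {"L": 10})
        assert any("matched" in r for r in fail) and ok == []

    def test_bulges_fewer_than_four(self):
        fail = call_mirna(_dummy_fold(-25), _metrics(bulges=4), {"L": 10})
        ok = call_mirna(_dummy_fold(-25), _metrics(bulges=3), {"L": 10})
        assert any("bulge" in r for r in fail) and ok == []

    def test_spacing_less_than_300(self):
        fail = call_mirna(_dummy_fold(-25), _metrics(spacing=300), {"L": 10})
        ok = call_mirna(_dummy_fold(-25), _metrics(spacing=299), {"L": 10})
        assert any("spacing" in r for r in fail) and ok == []

    def test_at_least_two_reads_in_a_library(self):
        fail = call_mirna(_dummy_fold(-25), _metrics(), {"L1": 1, "L2": 1})
        ok = call_mirna(_dummy_fold(-25), _metrics(), {"L1": 1, "L2": 2})
        assert any("support" in r for r in fail) and ok == []

    def test_all_passing_example(self):
        assert call_mirna(_dummy_fold(-25.0), _metrics(19, 1, 45), {"L": 10}) == []

    def test_tightening_thresholds_never_accepts_more(self):
        tight = Thresholds(dg_cutoff=-25.0, min_matched=19, max_bulges=1)
        loose = Thresholds()
        for dg in (-20.0, -26.0):
            for matched in (17, 20):
                res_loose = call_mirna(_dummy_fold(dg), _metrics(matched=matched), {"L": 5}, loose)
                res_tight = call_mirna(_dummy_fold(dg), _metrics(matched=matched), {"L": 5}, tight)
                if res_loose:
                    assert res_tight  # anything rejected loose stays rejected tight


class TestClassification:
    REF = {"miR156": ["TGACAGAAGAGAGTGAGCACA"], "miR166": ["TCGGACCAGGCTTCATTCCCC"]}

    def test_identical_is_conserved_distance_zero(self):
        cls, fam, d = classify_mirna("TGACAGAAGAGAGTGAGCACA", self.REF)
        assert (cls, fam, d) == ("conserved", "miR156", 0)

    def test_distance_two_is_conserved(self):
        mat = "TTACAGAAGAGAGTGAGCACC"  # 2 substitutions
        cls, fam, d = classify_mirna(mat, self.REF)
        assert cls == "conserved" and d == 2

    def test_distance_three_is_novel(self):
        mat = "TTACAGAAGAGAGTGAGGACC"  # 3 substitutions from miR156
        cls, fam, d = classify_mirna(mat, self.REF)
        assert cls == "novel" and d == 3 and fam is None

    def test_tie_broken_lexicographically(self):
        ref = {"miRB": ["AAAAAAAAAAAAAAAAAAAAA"], "miRA": ["AAAAAAAAAAAAAAAAAAAAA"]}
        cls, fam, _ = classify_mirna("AAAAAAAAAAAAAAAAAAAAT", ref)
        assert cls == "conserved" and fam == "miRA"

    def test_distance_symmetric(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            a = "".join(rng.choice(bases, int(rng.integers(18, 25))))
            b = "".join(rng.choice(bases, int(rng.integers(18, 25))))
            assert edit_distance(a, b) == edit_distance(b, a)

    def test_matches_needleman_wunsch_oracle(self, rng):
        def nw(a, b):
            dp = list(range(len(b) + 1))
            for i, ca in enumerate(a, 1):
                prev, dp[0] = dp[0], i
                for j, cb in enumerate(b, 1):
                    prev, dp[j] = dp[j], min(
                        dp[j] + 1, dp[j - 1] + 1, prev + (ca != cb)
                    )
            return dp[-1]

        bases = np.array(list("ACGT"))
        for _ in range(20):
            a = "".join(rng.choice(bases, int(rng.integers(10, 24))))
            b = "".join(rng.choice(bases, int(rng.integers(10, 24))))
            assert edit_distance(a, b) == nw(a, b)

    def test_empty_mature_rejected(self):
        with pytest.raises(ValueError):
            classify_mirna("", self.REF)


class TestSubgenomeAssignment:
    GENOME = GenomeSet(
        {"A03": "ACGT" * 10, "C07": "ACGT" * 10, "scaffold_0012": "ACGT" * 10},
        {"A03": "A", "C07": "C", "scaffold_0012": "unplaced"},
    )

    @pytest.mark.parametrize("chrom,label", [
        ("A03", "A"), ("C07", "C"), ("scaffold_0012", "unplaced"),
    ])
    def test_labels(self, chrom, label):
        assert assign_subgenome(chrom, self.GENOME) == label

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(KeyError):
            assign_subgenome("B99", self.GENOME)


class TestClusterAndExcise:
    def _genome(self):
        return GenomeSet({"A01": "ACGT" * 500}, {"A01": "A"})

    def test_single_read_count_one_everywhere_excluded(self):
        genome = self._genome()
        read = genome.records["A01"][100:121]
        from allomirna.seqio import Alignment

        aln = {read: [Alignment("A01", 100, 121, "+", read)]}
        cands = cluster_and_excise(aln, genome, {"L1": {read: 1}, "L2": {read: 1}})
        assert cands == []

    def test_count_two_in_one_library_emitted(self):
        genome = self._genome()
        read = genome.records["A01"][100:121]
        from allomirna.seqio import Alignment

        aln = {read: [Alignment("A01", 100, 121, "+", read)]}
        cands = cluster_and_excise(aln, genome, {"L1": {read: 2}})
        assert len(cands) == 2  # both flanking windows

    def test_window_clipped_at_chromosome_start(self):
        genome = self._genome()
        read = genome.records["A01"][0:21]
        from allomirna.seqio import Alignment

        aln = {read: [Alignment("A01", 0, 21, "+", read)]}
        cands = cluster_and_excise(aln, genome, {"L1": {read: 5}})
        assert min(c.window_start for c in cands) == 0
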