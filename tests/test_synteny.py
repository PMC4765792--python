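"""Flanking-gene contexts, microsynteny classes, homology search, and the
family copy-number table."""

import numpy as np
import pytest

from allomirna.seqio import GenomeIndex, GenomeSet, Gff3Feature, revcomp
from allomirna.synteny import (
    FlankContext,
    GeneTable,
    density_track,
    extract_flanking_genes,
    family_copy_table,
    find_mirna_homologs,
    test_microsynteny as microsynteny_call,
)


def _genes(chrom, n, start=0, spacing=1000, prefix="OG"):
    feats = []
    for i in range(n):
        s = start + i * spacing
        feats.append(Gff3Feature(
            chrom, "sim", "gene", s, s + 400, ".", "+", ".",
            {"ID": f"g{chrom}_{i}", "ortho_family": f"{prefix}{i:03d}"},
        ))
    return feats


class TestFlankContext:
    def test_caps_at_ten_per_side(self):
        feats = _genes("A01", 30)
        # locus between gene 14 and 15
        ctx = extract_flanking_genes("m", "A01", 14_500, 14_600, feats, k=10)
        assert len(ctx.upstream) == 10 and len(ctx.downstream) == 10
        assert ctx.upstream[0] == "OG014"      # nearest first
        assert ctx.downstream[0] == "OG015"

    def test_fewer_near_chromosome_start(self):
        feats = _genes("A01", 30)
        ctx = extract_flanking_genes("m", "A01", 2_500, 2_600, feats, k=10)
        assert len(ctx.upstream) == 3
        assert len(ctx.downstream) == 10

    def test_shared_neighborhood_identical_contexts(self):
        feats = _genes("A01", 30)
        c1 = extract_flanking_genes("m1", "A01", 14_500, 14_600, feats)
        c2 = extract_flanking_genes("m2", "A01", 14_450, 14_550, feats)
        assert c1.upstream == c2.upstream and c1.downstream == c2.downstream

    def test_absent_chromosome_rejected(self):
        with pytest.raises(KeyError):
            extract_flanking_genes("m", "Z01", 100, 200, _genes("A01", 5))

    def test_duplicate_labels_within_side_rejected(self):
        with pytest.raises(ValueError):
            FlankContext("m", ["OG1", "OG1"], [])


class TestMicrosynteny:
    def test_identical_contexts_class_1(self):
        ctx = FlankContext("m", ["a", "b"], ["c", "d"])
        call = microsynteny_call(ctx, FlankContext("n", ["a", "b"], ["c", "d"]))
        assert call.set_class == 1 and call.syntenic

    def test_no_shared_genes_class_4(self):
        call = microsynteny_call(
            FlankContext("m", ["a", "b"], ["c"]),
            FlankContext("n", ["x", "y"], ["z"]),
        )
        assert call.set_class == 4 and not call.syntenic

    def test_one_shared_upstream_only_class_2(self):
        call = microsynteny_call(
            FlankContext("m", ["a", "q"], ["c"]),
            FlankContext("n", ["a", "y"], ["z"]),
        )
        assert call.set_class == 2 and call.syntenic
        assert call.shared_upstream == 1 and call.shared_downstream == 0

    def test_downstream_only_class_3(self):
        call = microsynteny_call(
            FlankContext("m", ["q"], ["c"]),
            FlankContext("n", ["y"], ["c"]),
        )
        assert call.set_class == 3 and call.syntenic

    def test_syntenic_flag_symmetric(self, rng):
        labels = [f"L{i}" for i in range(12)]
        for _ in range(40):
            pick = lambda: list(rng.choice(labels, size=int(rng.integers(1, 5)), replace=False))
            x = FlankContext("x", pick(), pick())
            y = FlankContext("y", pick(), pick())
            assert microsynteny_call(x, y).syntenic == microsynteny_call(y, x).syntenic


class TestHomologySearch:
    def _genome_with_copies(self, rng, query, n_copies, length=60_000):
        bases = np.array(list("ACGT"))
        seq = "".join(rng.choice(bases, length))
        positions = sorted(rng.choice(
            np.arange(1000, length - 1000, 500), size=n_copies, replace=False
        ))
        out = []
        prev = 0
        for p in positions:
            out.append(seq[prev:p])
            out.append(query)
            prev = p
        out.append(seq[prev:])
        genome = GenomeSet({"A01": "".join(out)}, {"A01": "A"})
        return genome

    def test_verbatim_copy_full_coverage(self, rng):
        bases = np.array(list("ACGT"))
        query = "".join(rng.choice(bases, 100))
        genome = self._genome_with_copies(rng, query, 1)
        hits = find_mirna_homologs("q", query, GenomeIndex(genome, k=13))
        assert len(hits) == 1
        assert hits[0].coverage == pytest.approx(1.0)
        assert genome.records["A01"][hits[0].start : hits[0].end] == query

    def test_half_fragment_fails_coverage(self, rng):
        bases = np.array(list("ACGT"))
        query = "".join(rng.choice(bases, 100))
        genome = self._genome_with_copies(rng, query[:50], 1)
        assert find_mirna_homologs("q", query, GenomeIndex(genome, k=13)) == []

    def test_seven_copies_capped_at_top_five(self, rng):
        bases = np.array(list("ACGT"))
        query = "".join(rng.choice(bases, 90))
        genome = self._genome_with_copies(rng, query, 7, length=100_000)
        hits = find_mirna_homologs("q", query, GenomeIndex(genome, k=13))
        assert len(hits) == 5

    def test_reverse_strand_copy_found(self, rng):
        bases = np.array(list("ACGT"))
        query = "".join(rng.choice(bases, 100))
        genome = self._genome_with_copies(rng, revcomp(query), 1)
        hits = find_mirna_homologs("q", query, GenomeIndex(genome, k=13))
        assert len(hits) == 1 and hits[0].strand == "-"

    def test_mutated_copy_found_with_high_coverage(self, rng):
        bases = np.array(list("ACGT"))
        query = list("".join(rng.choice(bases, 120)))
        mutated = query.copy()
        for p in (30, 60, 90):
            mutated[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[p]]
        genome = self._genome_with_copies(rng, "".join(mutated), 1)
        hits = find_mirna_homologs("q", "".join(query), GenomeIndex(genome, k=13))
        assert len(hits) == 1 and hits[0].coverage > 0.9

    def test_short_query_rejected(self, rng):
        genome = self._genome_with_copies(rng, "ACGT" * 10, 1, length=5000)
        with pytest.raises(ValueError):
            find_mirna_homologs("q", "ACGT" * 5, GenomeIndex(genome, k=13))


class TestFamilyCopyTable:
    def test_published_style_delta(self):
        fams = {
            "A_n": ["miR156"] * 17, "C_n": ["miR156"] * 19,
            "A_r": ["miR156"] * 17, "C_o": ["miR156"] * 15,
        }
        df = family_copy_table(fams)
        row = df.loc["miR156"]
        assert (row["A_n"], row["C_n"], row["A_r"], row["C_o"]) == (17, 19, 17, 15)
        assert row["delta"] == 4

    def test_zero_delta_and_sorting(self):
        fams = {
            "A_n": ["f1"] * 3 + ["f2"] * 5, "C_n": ["f1"] * 3 + ["f2"],
            "A_r": ["f1"] * 3, "C_o": ["f1"] * 3 + ["f2"] * 2,
        }
        df = family_copy_table(fams)
        assert df.loc["f1", "delta"] == 0
        assert df.index[0] == "f2"  # |delta| descending

    def test_absent_family_excluded(self):
        df = family_copy_table({"A_n": ["f1"], "C_n": [], "A_r": [], "C_o": []})
        assert list(df.index) == ["f1"]


def test_density_track_counts_loci_per_window():
    genome = GenomeSet({"A01": "ACGT" * 500_000}, {"A01": "A"})

    class L:
        def __init__(self, c, s):
            self.chromosome, self.start = c, s

    loci = [L("A01", 10), L("A01", 999_999), L("A01", 1_500_000)]
    df = density_track(loci, genome, window=1_000_000)
    assert df["n_loci"].tolist() == [2, 1]
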