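"""Generator invariants: determinism, conservation accounting, planted-locus
discoverability, library composition, and the degradome signal."""

import dataclasses

import numpy as np
import pytest

from allomirna.discovery import call_mirna, evaluate_duplex
from allomirna.fold import fold_hairpin
from allomirna.seqio import revcomp
from allomirna.simulate import (
    SimulationConfig,
    simulate_degradome,
    simulate_genomes,
    simulate_srna_libraries,
)
from conftest import TINY


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_losses=-1).validate()

    def test_rho_must_be_positive(self):
        with pytest.raises(ValueError, match="rho"):
            SimulationConfig(subgenome_bias_rho=0.0).validate()

    def test_capacity_violation_names_constraint(self):
        cfg = SimulationConfig(**{**TINY, "chromosome_length": 10_000})
        with pytest.raises(ValueError, match="capacity"):
            cfg.validate()

    def test_too_few_genes_for_flanks_rejected(self):
        cfg = SimulationConfig(**{**TINY, "n_protein_genes_per_chromosome": 12})
        with pytest.raises(ValueError, match="flanking"):
            cfg.validate()


class TestGenomes:
    def test_deterministic_under_fixed_seed(self, tiny_config, tiny_dataset):
        ga2, gc2, gt2, ann2, truth2 = simulate_genomes(tiny_config)
        assert ga2.records == tiny_dataset["A"].records
        assert gt2.records == tiny_dataset["tetraploid"].records
        assert [l.locus_id for l in truth2.tetraploid_loci] == [
            l.locus_id for l in tiny_dataset["truth"].tetraploid_loci
        ]

    def test_conservation_accounting(self, tiny_config, tiny_dataset):
        truth = tiny_dataset["truth"]
        n = tiny_config.n_mirna_loci_per_subgenome
        assert len(truth.tetraploid_loci) == 2 * n - tiny_config.n_losses + tiny_config.n_gains
        assert len(truth.lost_locus_ids) == tiny_config.n_losses
        assert len(truth.gained_locus_ids) == tiny_config.n_gains

    def test_identity_case_syntenic_copies(self):
        cfg = SimulationConfig(**{**TINY, "n_losses": 0, "n_gains": 0})
        ga, gc, gt, ann, truth = simulate_genomes(cfg)
        prog_a = {l.pair_id: l for l in truth.progenitor_loci["A"]}
        for lt in truth.tetraploid_loci:
            if lt.subgenome != "A":
                continue
            lp = prog_a[lt.pair_id]
            assert (lp.chromosome, lp.start, lp.end) == (
                lt.chromosome, lt.start, lt.end
            )
            assert ga.records[lp.chromosome][lp.start:lp.end] == \
                gt.records[lt.chromosome][lt.start:lt.end]

    def test_lost_loci_absent_gained_present_only_in_tetraploid(self, tiny_dataset):
        truth = tiny_dataset["truth"]
        tet_ids = {l.locus_id for l in truth.tetraploid_loci}
        assert not set(truth.lost_locus_ids) & tet_ids
        assert set(truth.gained_locus_ids) <= tet_ids
        prog_ids = {l.locus_id for sub in ("A", "C") for l in truth.progenitor_loci[sub]}
        assert not set(truth.gained_locus_ids) & prog_ids

    def test_mature_is_substring_of_precursor(self, tiny_dataset):
        gt = tiny_dataset["tetraploid"]
        for l in tiny_dataset["truth"].tetraploid_loci:
            seq = gt.records[l.chromosome][l.start:l.end]
            prec = seq if l.strand == "+" else revcomp(seq)
            assert l.mature in prec
            assert l.star in prec

    def test_every_precursor_passes_discovery_gates(self, tiny_dataset):
        gt = tiny_dataset["tetraploid"]
        for l in tiny_dataset["truth"].tetraploid_loci:
            seq = gt.records[l.chromosome][l.start:l.end]
            prec = seq if l.strand == "+" else revcomp(seq)
            fold = fold_hairpin(prec)
            moff = prec.find(l.mature)
            duplex = evaluate_duplex(fold, (moff, moff + len(l.mature)))
            assert call_mirna(fold, duplex, {"lib": 10}) == []

    def test_every_locus_has_ten_flanking_genes_per_side(self, tiny_dataset):
        from allomirna.synteny import GeneTable

        table = GeneTable(tiny_dataset["annotations"]["tetraploid"])
        for l in tiny_dataset["truth"].tetraploid_loci:
            ctx = table.context(l.locus_id, l.chromosome, l.start, l.end, k=10)
            assert len(ctx.upstream) == 10 and len(ctx.downstream) == 10

    def test_expression_strictly_positive(self, tiny_dataset):
        assert all(v > 0 for v in tiny_dataset["truth"].expression.values())


class TestLibraries:
    def test_twelve_libraries_by_default(self, tiny_libraries):
        assert len(tiny_libraries) == (2 + 4) * 2
        ids = {l.library_id for l in tiny_libraries}
        assert "T_E1" in ids and "DH4_E2" in ids

    def test_deterministic_under_fixed_rng_seed(self, tiny_dataset, tiny_libraries):
        libs2 = simulate_srna_libraries(
            tiny_dataset["truth"], tiny_dataset["tetraploid"],
            tiny_dataset["config"], rng=np.random.default_rng(6),
        )
        assert libs2[0].unique_reads == tiny_libraries[0].unique_reads

    def test_depth_zero_rejected(self, tiny_dataset):
        cfg = dataclasses.replace(tiny_dataset["config"], library_depth=0)
        with pytest.raises(ValueError):
            simulate_srna_libraries(
                tiny_dataset["truth"], tiny_dataset["tetraploid"], cfg
            )

    def test_symmetric_totals_at_rho_one(self):
        cfg = SimulationConfig(
            **{**TINY, "subgenome_bias_rho": 1.0, "background_fraction": 0.0,
               "ncrna_fraction": 0.0, "junk_fraction": 0.0,
               "n_losses": 0, "n_gains": 0, "library_depth": 200_000,
               "n_mirna_loci_per_subgenome": 30, "n_protein_genes_per_chromosome": 52}
        )
        ga, gc, gt, ann, truth = simulate_genomes(cfg)
        # symmetry of the generating model: expected totals equal across
        # subgenomes up to lognormal sampling of per-locus expectations
        ratios = []
        rng = np.random.default_rng(0)
        from allomirna.simulate import draw_locus_expression

        by_id = truth.tetraploid_by_id()
        for _ in range(40):
            e = draw_locus_expression(truth, cfg, rng)
            a = sum(v for k, v in e.items() if by_id[k].subgenome == "A")
            c = sum(v for k, v in e.items() if by_id[k].subgenome == "C")
            ratios.append(c / a)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_mid_parent_expectation_when_no_nonadditive(self):
        cfg = SimulationConfig(**{**TINY, "nonadditive_fraction": 0.0})
        ga, gc, gt, ann, truth = simulate_genomes(cfg)
        assert truth.dh_nonadditive_ids == []
        from allomirna.simulate import _line_expectations

        dh = _line_expectations(truth, "DH1", truth.expression)
        for lid, v in dh.items():
            mpv = 0.5 * (
                truth.parent_expression["T"][lid] + truth.parent_expression["N"][lid]
            )
            assert v == pytest.approx(mpv)


class TestDegradome:
    def test_zero_noise_tags_only_at_planted_sites(self, tiny_dataset):
        cfg = dataclasses.replace(tiny_dataset["config"], degradome_noise=0.0)
        truth = tiny_dataset["truth"]
        tags = simulate_degradome(truth, truth.transcripts, cfg,
                                  rng=np.random.default_rng(3))
        starts = {
            (s.transcript_id, s.position) for s in truth.cleavage_sites
        }
        for tag in tags:
            found = False
            for tid, seq in truth.transcripts.items():
                i = seq.find(tag)
                if i != -1 and (tid, i + 1) in starts:
                    found = True
            assert found

    def test_modal_position_is_planted_site(self, tiny_dataset):
        truth = tiny_dataset["truth"]
        cfg = dataclasses.replace(tiny_dataset["config"], degradome_noise=0.2)
        tags = simulate_degradome(truth, truth.transcripts, cfg,
                                  rng=np.random.default_rng(4))
        from allomirna.targets import build_degradome_profile

        profiles = build_degradome_profile(tags, truth.transcripts)
        site = truth.cleavage_sites[0]
        prof = profiles[site.transcript_id]
        planted_here = {
            s.position for s in truth.cleavage_sites
            if s.transcript_id == site.transcript_id
        }
        modal = max(prof.counts, key=prof.counts.get)
        assert modal in planted_here

    def test_empty_cleavage_sites_rejected(self, tiny_dataset):
        truth = tiny_dataset["truth"]
        empty = dataclasses.replace(truth, cleavage_sites=[])
        with pytest.raises(ValueError):
            simulate_degradome(empty, truth.transcripts, tiny_dataset["config"])
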