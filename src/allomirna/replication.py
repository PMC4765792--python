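"""Scaled-down study reproductions on synthetic data with planted truth.

Each function simulates a dataset under the study conditions the generator
emulates, runs the relevant pipeline stage from scratch, and scores the
result against the planted truth.  These are the entry points used by the
acceptance script; problem sizes are desk-scale (megabase chromosomes,
hundreds of loci, 1e6-read libraries) rather than genome-scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import expression
from .discovery import Thresholds, discover_mirnas
from .seqio import GenomeIndex
from .simulate import (
    SimulationConfig,
    draw_locus_expression,
    simulate_degradome,
    simulate_genomes,
    simulate_srna_libraries,
)
from .synteny import call_gain_loss
from .targets import build_degradome_profile, scan_transcriptome, validate_cleavage


def _mature_spans(truth):
    return [
        expression.MatureSpan(l.mature, l.locus_id, l.chromosome,
                              l.mature_start, l.mature_end, l.subgenome)
        for l in truth.tetraploid_loci
    ]


def discovery_recovery_study(seed: int = 0) -> dict:
    """Plant ~200 loci on a 2+2 x 1 Mb genome, sequence twelve 1e6-read
    libraries with 30% repeat background, run discovery, and score recall and
    precision against the planted loci."""
    cfg = SimulationConfig(seed=seed, mutation_rate=0.0)
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    libs = simulate_srna_libraries(
        truth, gt, cfg, rng=np.random.default_rng(seed + 1)
    )
    loci, _rej = discover_mirnas(libs, gt, truth.reference_families,
                                 thresholds=Thresholds())
    truth_keys = {(l.chromosome, l.mature) for l in truth.tetraploid_loci}
    tp = sum(1 for l in loci if (l.chromosome, l.mature) in truth_keys)
    return {
        "n_true": len(truth.tetraploid_loci),
        "n_called": len(loci),
        "recall": tp / len(truth.tetraploid_loci),
        "precision": tp / len(loci) if loci else 0.0,
    }


def partition_ratio_study(
    seed: int,
    rho: float = 0.55,
    n_pairs: int = 300,
    depth: int = 1_000_000,
) -> dict:
    """Estimate the C:A subgenome expression ratio (total RPM per unique
    mature miRNA) from parental libraries with a planted bias of ``rho``."""
    cfg = SimulationConfig(
        seed=seed, subgenome_bias_rho=rho,
        n_mirna_loci_per_subgenome=n_pairs,
        n_protein_genes_per_chromosome=20 + -(-n_pairs // 2) + 20,
        n_losses=0, n_gains=0, library_depth=depth, mutation_rate=0.0,
    )
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    libs = simulate_srna_libraries(
        truth, gt, cfg, rng=np.random.default_rng(seed + 1),
        lines=["T", "N"], environments=("E1",),
    )
    index = GenomeIndex(gt)
    reads = sorted({r for lib in libs for r in lib.unique_reads})
    alignments = {r: index.find(r) for r in reads}
    matrix = expression.expression_matrix(libs, _mature_spans(truth), alignments)
    res = expression.subgenome_partition_test(
        matrix, gt, mode="per_mature", library_set="T/N", environment="E1"
    )
    return {"ratio": res.ratio, "p_value": res.p_value, "n_loci": 2 * n_pairs}


def null_type_i_study(
    seed: int = 0, n_replicates: int = 200, n_pairs: int = 60,
    depth: int = 100_000, alpha: float = 0.05,
) -> dict:
    """Type-I error of the partition test under the null (rho = 1): the
    fraction of replicate datasets with p below alpha.  The genome is fixed;
    per-locus expectations and library draws are resampled each replicate."""
    cfg = SimulationConfig(
        seed=seed, subgenome_bias_rho=1.0,
        n_chromosomes_per_subgenome=1, chromosome_length=400_000,
        n_mirna_loci_per_subgenome=n_pairs,
        n_protein_genes_per_chromosome=20 + n_pairs + 10,
        n_losses=0, n_gains=0, library_depth=depth,
        background_fraction=0.0, ncrna_fraction=0.0, junk_fraction=0.0,
        mutation_rate=0.0,
    )
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    spans = _mature_spans(truth)
    index = GenomeIndex(gt)
    alignments = {l.mature: index.find(l.mature) for l in truth.tetraploid_loci}
    rng = np.random.default_rng(seed + 1)
    hits = 0
    for _ in range(n_replicates):
        expr = draw_locus_expression(truth, cfg, rng)
        libs = simulate_srna_libraries(
            truth, gt, cfg, rng=rng, lines=["T"], environments=("E1",),
            expression=expr,
        )
        matrix = expression.expression_matrix(libs, spans, alignments)
        res = expression.subgenome_partition_test(matrix, gt, mode="per_mature")
        hits += res.p_value < alpha
    return {"type_i_error": hits / n_replicates, "n_replicates": n_replicates}


def gain_loss_study(seed: int = 0, n_losses: int = 10, n_gains: int = 5) -> dict:
    """Plant losses and gains, call them back by homology + microsynteny,
    and score precision/recall of both event lists."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes_per_subgenome=2, chromosome_length=300_000,
        n_mirna_loci_per_subgenome=50, n_protein_genes_per_chromosome=70,
        n_losses=n_losses, n_gains=n_gains, mutation_rate=0.005,
    )
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    result = call_gain_loss(
        truth.tetraploid_loci, truth.progenitor_loci,
        {"A": ga, "C": gc, "tetraploid": gt}, ann,
    )
    expected_lost = {
        i.replace("An_", "Ar_").replace("Cn_", "Co_") for i in truth.lost_locus_ids
    }

    def pr(called, expected):
        called, expected = set(called), set(expected)
        tp = len(called & expected)
        return (
            tp / len(called) if called else 1.0,
            tp / len(expected) if expected else 1.0,
        )

    loss_p, loss_r = pr(result.lost, expected_lost)
    gain_p, gain_r = pr(result.gained, truth.gained_locus_ids)
    return {
        "loss_precision": loss_p, "loss_recall": loss_r,
        "gain_precision": gain_p, "gain_recall": gain_r,
        "n_losses": n_losses, "n_gains": n_gains,
    }


def degradome_study(seed: int = 0, n_sites: int = 50, n_decoys: int = 50,
                    noise: float = 0.2) -> dict:
    """Plant cleavage sites and decoy signals at +8 nt, predict targets,
    validate with the 5-nt window, and score validation sensitivity and
    decoy specificity."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes_per_subgenome=1, chromosome_length=300_000,
        n_mirna_loci_per_subgenome=30, n_protein_genes_per_chromosome=60,
        n_losses=0, n_gains=0, mutation_rate=0.0,
        n_cleavage_sites=n_sites, n_decoy_sites=n_decoys,
        degradome_noise=noise,
    )
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    tags = simulate_degradome(truth, truth.transcripts, cfg,
                              rng=np.random.default_rng(seed + 1))
    mirnas = {l.locus_id: l.mature for l in truth.tetraploid_loci}
    interactions = scan_transcriptome(mirnas, truth.transcripts, cutoff=3.0)
    profiles = build_degradome_profile(tags, truth.transcripts)
    for it in interactions:
        validate_cleavage(it, profiles.get(it.transcript_id), window=5)
    status = {
        (it.mirna_id, it.transcript_id, it.cleavage_pos): it.status
        for it in interactions
    }
    planted = [s for s in truth.cleavage_sites if not s.decoy]
    decoys = [s for s in truth.cleavage_sites if s.decoy]
    validated = sum(
        1 for s in planted
        if status.get((s.mirna_id, s.transcript_id, s.position)) == "validated"
    )
    decoy_validated = sum(
        1 for s in decoys
        if status.get((s.mirna_id, s.transcript_id, s.position)) == "validated"
    )
    return {
        "planted_validated_fraction": validated / len(planted),
        "decoys_validated": decoy_validated,
        "n_sites": len(planted), "n_decoys": len(decoys),
    }


def heredity_study(seed: int = 0, nonadditive_fraction: float = 0.30,
                   factor: float = 4.0) -> dict:
    """Plant a non-additive fraction in the DH lines and recover it from the
    twofold mid-parent rule."""
    cfg = SimulationConfig(
        seed=seed, n_chromosomes_per_subgenome=1, chromosome_length=500_000,
        n_mirna_loci_per_subgenome=100, n_protein_genes_per_chromosome=130,
        n_losses=0, n_gains=0, nonadditive_fraction=nonadditive_fraction,
        nonadditive_factor=factor, background_fraction=0.0,
        ncrna_fraction=0.0, junk_fraction=0.0, mutation_rate=0.0,
    )
    ga, gc, gt, ann, truth = simulate_genomes(cfg)
    libs = simulate_srna_libraries(
        truth, gt, cfg, rng=np.random.default_rng(seed + 1)
    )
    index = GenomeIndex(gt)
    alignments = {l.mature: index.find(l.mature) for l in truth.tetraploid_loci}
    matrix = expression.expression_matrix(libs, _mature_spans(truth), alignments)
    parent1 = [l.library_id for l in libs if l.line == "T"]
    parent2 = [l.library_id for l in libs if l.line == "N"]
    derived = [l.library_id for l in libs if l.line.startswith("DH")]
    _calls, summary = expression.heredity_classification(
        matrix, parent1, parent2, derived
    )
    return {
        "called_fraction": summary["ratio_non_additive"],
        "planted_fraction": nonadditive_fraction,
        "n_loci": summary["n_total"],
    }
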