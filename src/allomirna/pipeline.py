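"""End-to-end pipeline orchestration over a run directory.

Stages run in dependency order -- simulate, preprocess, discover, targets,
synteny, express, report -- each reading the previous stage's files from the
run directory and writing TSV/GFF3 outputs plus a JSON sidecar of parameters
and counts.  Re-running with an identical configuration and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import discovery, expression, preprocess, simulate, synteny, targets
from .seqio import (
    GenomeIndex,
    GenomeSet,
    SmallRNALibrary,
    read_collapsed_fasta,
    read_fasta,
    read_gff3,
    write_gff3,
    Gff3Feature,
)

log = logging.getLogger("allomirna")


@dataclass
class PipelineConfig:
    """All pipeline parameters; thresholds default to their quoted values."""

    workdir: str = "run"
    seed: int = 0
    # discovery thresholds
    dg_cutoff: float = -18.0
    min_matched: int = 17
    max_bulges: int = 3
    max_spacing: int = 299
    min_reads: int = 2
    conserved_max_mismatch: int = 2
    flank: int = 300
    fold_backend: str = "nn"
    # target / degradome thresholds
    expectation_cutoff: float = 3.0
    degradome_window: int = 5
    # synteny thresholds
    flank_genes: int = 10
    top_hits: int = 5
    min_coverage: float = 0.9
    max_evalue: float = 1e-5
    # expression thresholds
    fold: float = 2.0
    epsilon: float = 0.1
    mature_slack: int = 2
    # length filter
    min_read_len: int = 18
    max_read_len: int = 44
    # stage toggles
    stages: dict[str, bool] = field(default_factory=lambda: {
        "simulate": True, "preprocess": True, "discover": True,
        "targets": True, "synteny": True, "express": True, "report": True,
    })
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )

    def validate(self) -> None:
        if self.dg_cutoff >= 0:
            raise ValueError("dg_cutoff must be negative (kcal/mol)")
        if self.min_matched < 1:
            raise ValueError("min_matched must be >= 1")
        if not (0 <= self.max_bulges < 25):
            raise ValueError("max_bulges out of range")
        if self.max_spacing < 0 or self.min_reads < 1:
            raise ValueError("max_spacing/min_reads out of range")
        if self.expectation_cutoff < 0 or self.degradome_window < 0:
            raise ValueError("target thresholds out of range")
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")
        if self.max_evalue <= 0 or self.fold <= 1 or self.epsilon < 0:
            raise ValueError("synteny/expression thresholds out of range")

    def thresholds(self) -> discovery.Thresholds:
        return discovery.Thresholds(
            dg_cutoff=self.dg_cutoff, min_matched=self.min_matched,
            max_bulges=self.max_bulges, max_spacing=self.max_spacing,
            min_reads=self.min_reads,
            conserved_max_mismatch=self.conserved_max_mismatch,
            flank=self.flank, fold_backend=self.fold_backend,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw.pop("workdir", None)   # runtime location, not a parameter
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def _sidecar(outdir: Path, stage: str, payload: dict) -> None:
    with open(outdir / f"{stage}.sidecar.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing input {path}; "
            "enable the producing stage or provide the file"
        )
    return path


_LIB_FILE = re.compile(r"srna_(.+)_(E\d+)\.fasta$")


def _load_libraries(outdir: Path, pattern: str, stage: str) -> list[SmallRNALibrary]:
    libs = []
    files = sorted(outdir.glob(pattern))
    if not files:
        raise FileNotFoundError(
            f"stage '{stage}' found no libraries matching {pattern} in {outdir}"
        )
    totals = {}
    totals_path = outdir / "clean_totals.json"
    if totals_path.exists():
        totals = json.loads(totals_path.read_text())
    for f in files:
        m = _LIB_FILE.search(f.name.replace("filtered_", ""))
        line, env = m.group(1), m.group(2)
        counts = read_collapsed_fasta(f)
        lib_id = f"{line}_{env}"
        total = totals.get(lib_id, sum(counts.values()))
        libs.append(SmallRNALibrary(
            library_id=lib_id, line=line, tissue="leaf", environment=env,
            unique_reads=counts, clean_read_total=total,
        ))
    return libs


def _load_genome(path: Path) -> GenomeSet:
    records = read_fasta(path)
    sub = {
        c: ("A" if c.startswith("A") else "C" if c.startswith("C") else "unplaced")
        for c in records
    }
    return GenomeSet(records, sub)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    ga, gc, gt, ann, truth = simulate.simulate_genomes(sim)
    rng = np.random.default_rng(np.random.PCG64(sim.seed + 1))
    libs = simulate.simulate_srna_libraries(truth, gt, sim, rng=rng)
    degradome = simulate.simulate_degradome(
        truth, truth.transcripts, sim,
        rng=np.random.default_rng(np.random.PCG64(sim.seed + 2)),
    )
    simulate.write_dataset(outdir, sim, ga, gc, gt, ann, truth, libs, degradome)
    _sidecar(outdir, "simulate", {
        "n_true_tetraploid_loci": len(truth.tetraploid_loci),
        "n_losses": len(truth.lost_locus_ids),
        "n_gains": len(truth.gained_locus_ids),
        "n_libraries": len(libs),
    })


def stage_preprocess(cfg: PipelineConfig, outdir: Path) -> None:
    ref_path = _require(outdir / "ncrna_reference.fasta", "preprocess")
    ref_records = read_fasta(ref_path)
    by_class: dict[str, list[str]] = {}
    for rid, seq in ref_records.items():
        by_class.setdefault(rid.rsplit("_", 1)[0], []).append(seq)
    reference = preprocess.NcrnaReference(by_class)
    libs = _load_libraries(outdir, "srna_*.fasta", "preprocess")
    totals = {}
    removal_rows = []
    for lib in libs:
        filtered = preprocess.length_filter(lib, cfg.min_read_len, cfg.max_read_len)
        totals[lib.library_id] = filtered.clean_read_total
        filtered, report = preprocess.filter_ncrna(filtered, reference)
        for cls in preprocess.NCRNA_CLASS_ORDER:
            removal_rows.append((
                lib.library_id, cls,
                report.unique_removed[cls], report.count_removed[cls],
            ))
        from .seqio import write_collapsed_fasta

        write_collapsed_fasta(
            filtered.unique_reads, outdir / f"filtered_srna_{lib.library_id}.fasta"
        )
    with open(outdir / "clean_totals.json", "w") as fh:
        json.dump(totals, fh, indent=1, sort_keys=True)
    pd.DataFrame(
        removal_rows,
        columns=["library_id", "class", "unique_removed", "count_removed"],
    ).to_csv(outdir / "ncrna_removal.tsv", sep="\t", index=False)
    _sidecar(outdir, "preprocess", {"clean_totals": totals})


def _load_reference_families(outdir: Path, stage: str) -> dict[str, list[str]]:
    path = _require(outdir / "known_mature.fasta", stage)
    fams: dict[str, list[str]] = {}
    for rid, seq in read_fasta(path).items():
        fams.setdefault(rid.rsplit("_", 1)[0], []).append(seq)
    return fams


def stage_discover(cfg: PipelineConfig, outdir: Path) -> list[discovery.MirnaLocus]:
    genome = _load_genome(_require(outdir / "tetraploid.fasta", "discover"))
    libs = _load_libraries(outdir, "filtered_srna_*.fasta", "discover")
    reference = _load_reference_families(outdir, "discover")
    index = GenomeIndex(genome)
    loci, rejections = discovery.discover_mirnas(
        libs, genome, reference, thresholds=cfg.thresholds(), index=index
    )
    rows = []
    feats = []
    for l in loci:
        rows.append((
            l.locus_id, l.chromosome, l.start, l.end, l.strand, l.subgenome,
            l.mature, l.mature_start, l.mature_end, l.mature_arm, l.star,
            l.mirna_class, l.family, round(l.delta_g, 2),
            l.duplex.matched_nt, l.duplex.bulge_nt, l.duplex.spacing_nt,
            json.dumps(l.support, sort_keys=True),
        ))
        feats.append(Gff3Feature(
            l.chromosome, "allomirna", "MIRNA", l.start, l.end, ".", l.strand,
            ".", {"ID": l.locus_id, "class": l.mirna_class, "family": l.family},
        ))
    pd.DataFrame(rows, columns=[
        "locus_id", "chromosome", "start", "end", "strand", "subgenome",
        "mature", "mature_start", "mature_end", "mature_arm", "star", "class",
        "family", "delta_g", "matched_nt", "bulge_nt", "spacing_nt", "support",
    ]).to_csv(outdir / "mirna_loci.tsv", sep="\t", index=False)
    write_gff3(feats, outdir / "mirna_loci.gff3")
    pd.DataFrame(
        [(r.chromosome, r.strand, r.mature_start, r.mature_read, ";".join(r.reasons))
         for r in rejections],
        columns=["chromosome", "strand", "mature_start", "mature_read", "reasons"],
    ).to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    counts = {
        "total": len(loci),
        "conserved": sum(1 for l in loci if l.mirna_class == "conserved"),
        "novel": sum(1 for l in loci if l.mirna_class == "novel"),
        "subgenome_A": sum(1 for l in loci if l.subgenome == "A"),
        "subgenome_C": sum(1 for l in loci if l.subgenome == "C"),
        "energy_model": cfg.fold_backend,
    }
    _sidecar(outdir, "discover", counts)
    return loci


def _read_loci_table(outdir: Path, stage: str) -> pd.DataFrame:
    return pd.read_csv(_require(outdir / "mirna_loci.tsv", stage), sep="\t")


def stage_targets(cfg: PipelineConfig, outdir: Path) -> None:
    loci = _read_loci_table(outdir, "targets")
    transcripts = read_fasta(_require(outdir / "transcripts.fasta", "targets"))
    mirnas = dict(zip(loci["locus_id"], loci["mature"]))
    interactions = targets.scan_transcriptome(
        mirnas, transcripts, cutoff=cfg.expectation_cutoff
    )
    tags = read_collapsed_fasta(_require(outdir / "degradome.fasta", "targets"))
    profiles = targets.build_degradome_profile(tags, transcripts)
    for it in interactions:
        targets.validate_cleavage(
            it, profiles.get(it.transcript_id), window=cfg.degradome_window
        )
    pd.DataFrame(
        [(it.mirna_id, it.transcript_id, it.start, it.end,
          round(it.expectation, 2), it.cleavage_pos, it.status, it.tag_support)
         for it in interactions],
        columns=["mirna", "transcript", "start", "end", "expectation",
                 "cleavage_pos", "status", "tag_support"],
    ).to_csv(outdir / "target_interactions.tsv", sep="\t", index=False)
    tplot_rows = [
        (tid, pos, count)
        for tid, prof in sorted(profiles.items())
        for pos, count in sorted(prof.counts.items())
    ]
    pd.DataFrame(tplot_rows, columns=["transcript", "position", "count"]).to_csv(
        outdir / "tplot_data.tsv", sep="\t", index=False
    )
    _sidecar(outdir, "targets", {
        "n_interactions": len(interactions),
        "n_validated": sum(1 for it in interactions if it.status == "validated"),
        "degradome_window": cfg.degradome_window,
        "window_rule": "|offset| <= window (inclusive)",
    })


@dataclass
class _Locus:
    locus_id: str
    chromosome: str
    start: int
    end: int
    subgenome: str
    family: str = ""


def _mirna_features_to_loci(feats: list[Gff3Feature]) -> list[_Locus]:
    return [
        _Locus(
            locus_id=f.attributes.get("ID", f"{f.seqid}:{f.start}"),
            chromosome=f.seqid, start=f.start, end=f.end,
            subgenome="A" if f.seqid.startswith("A") else "C",
            family=f.attributes.get("family", ""),
        )
        for f in feats if f.ftype == "MIRNA"
    ]


def stage_synteny(cfg: PipelineConfig, outdir: Path) -> None:
    genomes = {
        "A": _load_genome(_require(outdir / "progenitor_A.fasta", "synteny")),
        "C": _load_genome(_require(outdir / "progenitor_C.fasta", "synteny")),
        "tetraploid": _load_genome(_require(outdir / "tetraploid.fasta", "synteny")),
    }
    annotations = {
        "A": read_gff3(outdir / "progenitor_A.gff3"),
        "C": read_gff3(outdir / "progenitor_C.gff3"),
        "tetraploid": read_gff3(outdir / "tetraploid.gff3"),
    }
    prog_loci = {
        sub: _mirna_features_to_loci(annotations[sub]) for sub in ("A", "C")
    }
    loci_df = _read_loci_table(outdir, "synteny")
    tet_loci = [
        _Locus(r.locus_id, r.chromosome, int(r.start), int(r.end),
               r.subgenome, r.family)
        for r in loci_df.itertuples()
    ]
    result = synteny.call_gain_loss(
        tet_loci, prog_loci, genomes, annotations,
        k_flank=cfg.flank_genes, max_hits=cfg.top_hits,
    )
    pd.DataFrame(
        [("lost", lid) for lid in result.lost]
        + [("gained", lid) for lid in result.gained]
        + [("opposite_subgenome", lid) for lid in result.opposite_subgenome],
        columns=["event", "locus_id"],
    ).to_csv(outdir / "gain_loss.tsv", sep="\t", index=False)
    fams = {
        "A_n": [l.family for l in tet_loci if l.subgenome == "A" and l.family],
        "C_n": [l.family for l in tet_loci if l.subgenome == "C" and l.family],
        "A_r": [l.family for l in prog_loci["A"] if l.family],
        "C_o": [l.family for l in prog_loci["C"] if l.family],
    }
    synteny.family_copy_table(fams).to_csv(outdir / "family_copy_number.tsv", sep="\t")
    synteny.density_track(tet_loci, genomes["tetraploid"]).to_csv(
        outdir / "mirna_density_track.tsv", sep="\t", index=False
    )
    _sidecar(outdir, "synteny", {
        "n_lost": len(result.lost), "n_gained": len(result.gained),
        "n_opposite_subgenome": len(result.opposite_subgenome),
    })


def stage_express(cfg: PipelineConfig, outdir: Path) -> dict:
    genome = _load_genome(_require(outdir / "tetraploid.fasta", "express"))
    loci = _read_loci_table(outdir, "express")
    libs = _load_libraries(outdir, "filtered_srna_*.fasta", "express")
    spans = [
        expression.MatureSpan(
            mature=r.mature, locus_id=r.locus_id, chromosome=r.chromosome,
            start=int(r.mature_start), end=int(r.mature_end), subgenome=r.subgenome,
        )
        for r in loci.itertuples()
    ]
    index = GenomeIndex(genome)
    all_reads = sorted({read for lib in libs for read in lib.unique_reads})
    alignments = {read: index.find(read) for read in all_reads}
    matrix = expression.expression_matrix(libs, spans, alignments, slack=cfg.mature_slack)
    matrix.to_csv(outdir / "expression_matrix.tsv", sep="\t", index=False)
    parent_lines = {"T", "N"}
    partition_rows = []
    results = {}
    for libset_name, line_filter in (
        ("T/N", lambda l: l in parent_lines),
        ("DH", lambda l: l.startswith("DH")),
    ):
        for env in sorted({lib.environment for lib in libs}):
            lib_ids = [
                lib.library_id for lib in libs
                if lib.environment == env and line_filter(lib.line)
            ]
            if not lib_ids:
                continue
            sub = matrix[matrix["library_id"].isin(lib_ids)]
            for mode in ("per_mature", "per_mb"):
                try:
                    res = expression.subgenome_partition_test(
                        sub, genome, mode=mode, library_set=libset_name,
                        environment=env,
                    )
                except ValueError:
                    continue
                partition_rows.append((
                    f"{mode} ({env})", round(res.mean_a, 2), round(res.mean_c, 2),
                    round(res.ratio, 3), res.p_value, res.test_name, libset_name,
                ))
                results[f"{libset_name}:{env}:{mode}"] = {
                    "ratio": res.ratio, "p": res.p_value,
                }
    pd.DataFrame(partition_rows, columns=[
        "statistic", "A_n", "C_n", "ratio_C_over_A", "p_value", "test", "library_set",
    ]).to_csv(outdir / "partition_report.tsv", sep="\t", index=False)

    parent1 = [l.library_id for l in libs if l.line == "T"]
    parent2 = [l.library_id for l in libs if l.line == "N"]
    derived = [l.library_id for l in libs if l.line.startswith("DH")]
    heredity_summary = {}
    if parent1 and parent2 and derived:
        calls, heredity_summary = expression.heredity_classification(
            matrix, parent1, parent2, derived, fold=cfg.fold, epsilon=cfg.epsilon
        )
        pd.DataFrame(
            [(c.mature, round(c.mid_parent, 3), round(c.derived_mean, 3),
              round(c.log2_deviation, 3), c.call) for c in calls],
            columns=["mature", "mid_parent", "derived_mean", "log2_deviation", "call"],
        ).to_csv(outdir / "heredity.tsv", sep="\t", index=False)
        with open(outdir / "heredity_summary.json", "w") as fh:
            json.dump(heredity_summary, fh, indent=1, sort_keys=True)
    de = None
    if parent1 and parent2:
        de = expression.differential_expression(
            matrix, parent1, parent2, fold=cfg.fold, epsilon=cfg.epsilon
        )
        de.to_csv(outdir / "de_table.tsv", sep="\t", index=False)
    density = expression.mirna_density(
        [expression.MatureSpan(r.mature, r.locus_id, r.chromosome,
                               int(r.start), int(r.end), r.subgenome)
         for r in loci.itertuples()],
        genome,
    )
    payload = {
        "partition": results,
        "heredity": heredity_summary,
        "density_per_mb": density,
        "n_de": int(de["de"].sum()) if de is not None else 0,
    }
    _sidecar(outdir, "express", payload)
    return payload


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    report: dict = {"seed": cfg.seed, "thresholds": {
        "dg_cutoff": cfg.dg_cutoff, "min_matched": cfg.min_matched,
        "max_bulges": cfg.max_bulges, "max_spacing": cfg.max_spacing,
        "min_reads": cfg.min_reads,
        "conserved_max_mismatch": cfg.conserved_max_mismatch,
        "expectation_cutoff": cfg.expectation_cutoff,
        "degradome_window": cfg.degradome_window,
        "flank_genes": cfg.flank_genes, "top_hits": cfg.top_hits,
        "min_coverage": cfg.min_coverage, "max_evalue": cfg.max_evalue,
        "fold": cfg.fold, "epsilon": cfg.epsilon,
    }}
    for stage in ("simulate", "preprocess", "discover", "targets", "synteny", "express"):
        sidecar = outdir / f"{stage}.sidecar.json"
        if sidecar.exists():
            report[stage] = json.loads(sidecar.read_text())
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "discover": stage_discover,
    "targets": stage_targets,
    "synteny": stage_synteny,
    "express": stage_express,
    "report": stage_report,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; returns the final report."""
    cfg.validate()
    outdir = Path(cfg.workdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "pipeline_config.yaml")
    report: dict = {}
    for stage in ("simulate", "preprocess", "discover", "targets",
                  "synteny", "express", "report"):
        if not cfg.stages.get(stage, True):
            log.info("stage %s disabled", stage)
            continue
        t0 = time.monotonic()
        log.info("stage %s starting", stage)
        out = _STAGE_FUNCS[stage](cfg, outdir)
        log.info("stage %s done in %.1fs", stage, time.monotonic() - t0)
        if stage == "report":
            report = out
    return report
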