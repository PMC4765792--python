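"""Synthetic allopolyploid genomes, small-RNA and degradome libraries.

The generator emulates the study design the analysis assumes: two progenitor
genomes (subgenome A and subgenome C donors) that share ancestral MIRNA
hairpin loci homeolog by homeolog, an allotetraploid whose two subgenomes are
mutated copies of the progenitors with a configurable number of locus losses
and gains, twelve small-RNA libraries (two parental lines and a set of
double-haploid lines, each in two environments) with a planted C:A subgenome
expression bias, repeat-derived 24-nt background reads biased toward the C
subgenome, and degradome tags concentrated at planted cleavage positions on
synthetic transcripts.  Every planted fact is recorded in a
:class:`PlantedTruth` ledger against which each pipeline stage can be scored.

Hairpin loci are discoverable by construction: mature (21 nt) + loop
(40-80 nt) + reverse complement of the mature with 1-3 substituted positions,
which guarantees a stem with more than 16 paired nucleotides, fewer than four
bulged mature positions, and a folding free energy far below the -18 kcal/mol
acceptance gate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seqio import (
    GenomeSet,
    Gff3Feature,
    SmallRNALibrary,
    revcomp,
    write_collapsed_fasta,
    write_fasta,
    write_gff3,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Generator parameters; defaults are the study conditions emulated here."""

    seed: int = 0
    n_chromosomes_per_subgenome: int = 2
    chromosome_length: int = 1_000_000
    n_mirna_loci_per_subgenome: int = 100
    n_protein_genes_per_chromosome: int = 120
    n_losses: int = 10
    n_gains: int = 5
    subgenome_bias_rho: float = 0.55
    library_depth: int = 1_000_000
    background_fraction: float = 0.3
    repeat_bias_c: float = 2.1
    n_dh_lines: int = 4
    nonadditive_fraction: float = 0.30
    mutation_rate: float = 0.005
    # locus architecture
    mature_length: int = 21
    loop_length_min: int = 40
    loop_length_max: int = 80
    star_mutations_min: int = 1
    star_mutations_max: int = 3
    gene_length: int = 400
    intergenic_length: int = 120
    n_repeat_windows_per_chromosome: int = 3
    repeat_window_length: int = 3000
    conserved_fraction: float = 0.43
    # expression model
    expression_meanlog: float = 0.0
    expression_sdlog: float = 1.0
    parent_sdlog: float = 0.5
    nonadditive_factor: float = 4.0
    # library composition
    background_read_length: int = 24
    ncrna_fraction: float = 0.02
    junk_fraction: float = 0.01
    # transcriptome / degradome
    n_transcripts: int = 60
    transcript_length: int = 600
    n_cleavage_sites: int = 50
    n_decoy_sites: int = 0
    decoy_offset: int = 8
    degradome_depth: int = 20_000
    degradome_noise: float = 0.0

    def validate(self) -> None:
        positive = [
            "n_chromosomes_per_subgenome", "chromosome_length",
            "n_mirna_loci_per_subgenome", "n_protein_genes_per_chromosome",
            "library_depth", "mature_length", "gene_length",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ["n_losses", "n_gains", "n_dh_lines"]:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ["background_fraction", "nonadditive_fraction", "mutation_rate",
                     "ncrna_fraction", "junk_fraction", "degradome_noise"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.subgenome_bias_rho <= 0:
            raise ValueError("subgenome_bias_rho must be positive")
        if self.repeat_bias_c <= 0:
            raise ValueError("repeat_bias_c must be positive")
        if self.n_losses + self.n_gains > 2 * self.n_mirna_loci_per_subgenome:
            raise ValueError("more loss/gain events than available loci")
        # capacity: can every chromosome hold its genes, loci, and repeats?
        m = -(-self.n_mirna_loci_per_subgenome // self.n_chromosomes_per_subgenome)
        if self.n_protein_genes_per_chromosome < 20 + m:
            raise ValueError(
                "capacity violated: need n_protein_genes_per_chromosome >= "
                f"20 + loci_per_chromosome ({20 + m}) so every locus keeps 10 "
                "flanking protein-coding genes per side"
            )
        max_locus = self.mature_length * 2 + self.loop_length_max
        spacer_max = self.intergenic_length * 2
        content = (
            self.n_protein_genes_per_chromosome * (self.gene_length + spacer_max)
            + m * (max_locus + spacer_max)
            + self.n_repeat_windows_per_chromosome
            * (self.repeat_window_length + spacer_max)
        )
        if content > self.chromosome_length:
            raise ValueError(
                f"capacity violated: placed content can reach {content} nt but "
                f"chromosome_length is {self.chromosome_length} nt"
            )


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclass
class TrueLocus:
    locus_id: str
    subgenome: str          # A or C
    chromosome: str
    start: int              # precursor interval, 0-based half-open
    end: int
    strand: str
    mature: str             # DNA alphabet, genome sense of the mature read
    star: str
    mature_start: int       # genomic span of the mature arm
    mature_end: int
    mature_arm: str         # 5p or 3p
    family: str
    conserved: bool
    pair_id: str

    @property
    def precursor_length(self) -> int:
        return self.end - self.start


@dataclass
class CleavageSite:
    mirna_id: str
    transcript_id: str
    position: int           # 1-based cleavage position on the transcript
    mature: str
    decoy: bool = False


@dataclass
class PlantedTruth:
    """Complete ledger of everything the generator planted."""

    progenitor_loci: dict[str, list[TrueLocus]]   # "A" / "C"
    tetraploid_loci: list[TrueLocus]
    lost_locus_ids: list[str]
    gained_locus_ids: list[str]
    gain_source: dict[str, str]
    expression: dict[str, float]                  # tetraploid locus -> expectation
    parent_expression: dict[str, dict[str, float]]  # line -> locus -> expectation
    dh_nonadditive_ids: list[str]
    dh_factor: dict[str, float]
    cleavage_sites: list[CleavageSite]
    reference_families: dict[str, list[str]]      # miRBase-like known matures
    transcripts: dict[str, str]
    repeat_windows: dict[str, list[tuple[str, int, int]]]  # genome -> (chrom, s, e)
    ncrna_reference: dict[str, list[str]]

    def __post_init__(self) -> None:
        for lid, v in self.expression.items():
            if v <= 0:
                raise ValueError(f"non-positive expression for {lid}")

    def tetraploid_by_id(self) -> dict[str, TrueLocus]:
        return {l.locus_id: l for l in self.tetraploid_loci}


# ---------------------------------------------------------------------------
# Sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()

def _mutate(rng: np.random.Generator, seq: str, n_sub: int, lo: int = 0, hi: int | None = None) -> str:
    """Apply exactly n_sub substitutions at distinct positions in [lo, hi)."""
    hi = len(seq) if hi is None else hi
    pos = rng.choice(np.arange(lo, hi), size=n_sub, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)

def _mutate_rate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for p in hits:
        cur = arr[p]
        alt = _BASES[rng.integers(0, 4)]
        while alt == cur:
            alt = _BASES[rng.integers(0, 4)]
        arr[p] = alt
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Chromosome model: ordered elements assembled into sequence + features
# ---------------------------------------------------------------------------

@dataclass
class _Element:
    kind: str               # gene | mirna | repeat
    eid: str
    seq: str
    attrs: dict = field(default_factory=dict)


@dataclass
class _MirnaPayload:
    pair_id: str
    family: str
    conserved: bool
    mature_arm: str
    mature_offset: int      # offset of mature within precursor (sense strand)
    loop_len: int
    strand: str


def _build_hairpin(
    rng: np.random.Generator, cfg: SimulationConfig, mature: str
) -> tuple[str, str, str, int]:
    """Return (precursor, star, arm, mature_offset) for a mature sequence.

    Discoverability is guaranteed by construction: the candidate hairpin is
    folded and star variants are re-drawn until the mature/star duplex
    passes the discovery gates (>16 paired mature nt, <4 bulges, free energy
    below -18 kcal/mol), so recovery tests measure the pipeline, not the
    generator.
    """
    from .discovery import MatureSpansLoop, evaluate_duplex
    from .fold import fold_hairpin

    last = None
    for _attempt in range(30):
        loop = _random_seq(
            rng, int(rng.integers(cfg.loop_length_min, cfg.loop_length_max + 1))
        )
        n_mut = int(rng.integers(cfg.star_mutations_min, cfg.star_mutations_max + 1))
        star = _mutate(rng, revcomp(mature), n_mut, lo=3, hi=len(mature) - 3)
        if rng.random() < 0.5:
            prec, arm, moff = mature + loop + star, "5p", 0
        else:
            prec, arm, moff = star + loop + mature, "3p", len(star) + len(loop)
        last = (prec, star, arm, moff)
        fold = fold_hairpin(prec)
        try:
            duplex = evaluate_duplex(fold, (moff, moff + len(mature)))
        except MatureSpansLoop:
            continue
        if (
            fold.delta_g < -18.0
            and duplex.matched_nt > 16
            and duplex.bulge_nt < 4
            and duplex.spacing_nt < 300
        ):
            return last
    return last  # vanishingly rare; kept deterministic


class _ChromosomeBuilder:
    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng

    def spacer_len(self) -> int:
        il = self.cfg.intergenic_length
        return int(self.rng.integers(il // 2, il * 2))

    def assemble(
        self, chrom_id: str, elements: list[_Element]
    ) -> tuple[str, list[Gff3Feature], dict[str, tuple[int, int]], list[tuple[int, int]]]:
        """Concatenate elements (spacers included as elements, so derived
        genomes share intergenic sequence); return sequence, GFF3 features,
        element coordinate map, and repeat-window intervals."""
        cfg = self.cfg
        parts: list[str] = []
        feats: list[Gff3Feature] = []
        coords: dict[str, tuple[int, int]] = {}
        repeats: list[tuple[int, int]] = []
        pos = 0
        for el in elements:
            start, end = pos, pos + len(el.seq)
            parts.append(el.seq)
            pos = end
            coords[el.eid] = (start, end)
            if el.kind == "gene":
                feats.append(Gff3Feature(
                    chrom_id, "sim", "gene", start, end, ".", el.attrs.get("strand", "+"),
                    ".", {"ID": el.eid, "ortho_family": el.attrs["ortho_family"]},
                ))
            elif el.kind == "mirna":
                feats.append(Gff3Feature(
                    chrom_id, "sim", "MIRNA", start, end, ".", el.attrs["strand"],
                    ".", {"ID": el.eid, "family": el.attrs["family"]},
                ))
            elif el.kind == "repeat":
                repeats.append((start, end))
        if pos > cfg.chromosome_length:
            raise ValueError(
                f"capacity violated on {chrom_id}: content {pos} nt exceeds "
                f"chromosome_length {cfg.chromosome_length} nt"
            )
        parts.append(_random_seq(self.rng, cfg.chromosome_length - pos))
        return "".join(parts), feats, coords, repeats


# ---------------------------------------------------------------------------
# simulate_genomes
# ---------------------------------------------------------------------------

_CONSERVED_FAMILY_POOL = [
    "miR156", "miR159", "miR160", "miR162", "miR164", "miR165", "miR166",
    "miR167", "miR168", "miR169", "miR171", "miR172", "miR319", "miR390",
    "miR393", "miR394", "miR395", "miR396", "miR397", "miR398", "miR399",
    "miR403", "miR408", "miR827", "miR858", "miR2111", "miR5654", "miR6028",
    "miR6029", "miR6030", "miR6031", "miR6032", "miR6033", "miR6034",
]


def simulate_genomes(
    config: SimulationConfig,
) -> tuple[GenomeSet, GenomeSet, GenomeSet, dict[str, list[Gff3Feature]], PlantedTruth]:
    """Generate progenitor A, progenitor C, and tetraploid genomes.

    Ancestral hairpin loci are placed homeolog pair by homeolog pair on the
    two progenitors, each flanked by at least 10 protein-coding genes per
    side.  The tetraploid subgenomes are per-site mutated copies of the
    progenitors; exactly ``n_losses`` loci are excised from the tetraploid
    and ``n_gains`` created by copying an existing precursor sequence into a
    new gene neighborhood elsewhere in the tetraploid.  All events and every
    planted quantity are recorded in the returned :class:`PlantedTruth`.
    """
    config.validate()
    rng = np.random.default_rng(np.random.PCG64(config.seed))
    cfg = config
    builder = _ChromosomeBuilder(cfg, rng)
    n_chrom = cfg.n_chromosomes_per_subgenome

    # --- homeolog pair matures + families -------------------------------
    n_pairs = cfg.n_mirna_loci_per_subgenome
    n_conserved = int(round(cfg.conserved_fraction * n_pairs))
    reference_families: dict[str, list[str]] = {}
    matures: list[tuple[str, str, str, bool]] = []  # (A mature, C mature, family, conserved)
    seen: set[str] = set()
    for i in range(n_pairs):
        conserved = i < n_conserved
        while True:
            if conserved:
                fam = _CONSERVED_FAMILY_POOL[i % len(_CONSERVED_FAMILY_POOL)]
                fam = fam if i < len(_CONSERVED_FAMILY_POOL) else f"{fam}-{i // len(_CONSERVED_FAMILY_POOL)}"
                ref = _random_seq(rng, cfg.mature_length)
                mat_a = _mutate(rng, ref, int(rng.integers(0, 3)))
                mat_c = _mutate(rng, ref, int(rng.integers(1, 3)))
            else:
                fam = f"famX{i + 1}"
                ref = None
                mat_a = _random_seq(rng, cfg.mature_length)
                mat_c = _mutate(rng, mat_a, 2)
            if mat_a != mat_c and mat_a not in seen and mat_c not in seen:
                break
        seen.update({mat_a, mat_c})
        if conserved:
            reference_families.setdefault(fam, []).append(ref)
        matures.append((mat_a, mat_c, fam, conserved))

    # distribute pairs over chromosomes (same layout in both progenitors)
    per_chrom: list[list[int]] = [[] for _ in range(n_chrom)]
    for i in range(n_pairs):
        per_chrom[i % n_chrom].append(i)

    # --- build progenitor element lists ---------------------------------
    genomes_elements: dict[str, dict[str, list[_Element]]] = {"A": {}, "C": {}}
    payloads: dict[str, _MirnaPayload] = {}
    locus_seed_strand = {i: ("+" if rng.random() < 0.5 else "-") for i in range(n_pairs)}

    for sub in ("A", "C"):
        for ci in range(n_chrom):
            chrom = f"{sub}{ci + 1:02d}"
            els: list[_Element] = []
            gserial = 0
            sserial = 0

            def make_spacer() -> _Element:
                nonlocal sserial
                sserial += 1
                return _Element(
                    "spacer", f"sp_{chrom}_{sserial:05d}",
                    _random_seq(rng, builder.spacer_len()),
                )

            def make_gene() -> _Element:
                nonlocal gserial
                gserial += 1
                gid = f"{sub}r{ci + 1:02d}g{gserial:04d}" if sub == "A" else f"{sub}o{ci + 1:02d}g{gserial:04d}"
                fam = f"OG_{sub}{ci + 1:02d}_{gserial:04d}"
                els.append(make_spacer())
                return _Element(
                    "gene", gid, _random_seq(rng, cfg.gene_length),
                    {"ortho_family": fam, "strand": "+" if rng.random() < 0.5 else "-"},
                )

            loci_here = per_chrom[ci]
            n_gap_genes = cfg.n_protein_genes_per_chromosome - 20
            base, extra = (divmod(n_gap_genes, len(loci_here)) if loci_here else (0, 0))
            for _ in range(10):
                els.append(make_gene())
            for k, pair_idx in enumerate(loci_here):
                mat_a, mat_c, fam, conserved = matures[pair_idx]
                mature = mat_a if sub == "A" else mat_c
                precursor, star, arm, moff = _build_hairpin(rng, cfg, mature)
                strand = locus_seed_strand[pair_idx]
                lid = ("Ar" if sub == "A" else "Co") + f"_mir{pair_idx + 1:04d}"
                seq = precursor if strand == "+" else revcomp(precursor)
                els.append(make_spacer())
                els.append(_Element("mirna", lid, seq, {"family": fam, "strand": strand}))
                payloads[lid] = _MirnaPayload(
                    pair_id=f"p{pair_idx + 1:04d}", family=fam, conserved=conserved,
                    mature_arm=arm, mature_offset=moff, loop_len=len(precursor) - 2 * cfg.mature_length,
                    strand=strand,
                )
                for _ in range(base + (1 if k < extra else 0)):
                    els.append(make_gene())
            for _ in range(10):
                els.append(make_gene())
            for r in range(cfg.n_repeat_windows_per_chromosome):
                els.append(make_spacer())
                els.append(_Element("repeat", f"rep_{chrom}_{r + 1}", _random_seq(rng, cfg.repeat_window_length)))
            genomes_elements[sub][chrom] = els

    # --- derive tetraploid element lists (mutate, lose, gain) ------------
    tetra_elements: dict[str, list[_Element]] = {}
    tetra_payloads: dict[str, _MirnaPayload] = {}
    prog_to_tetra_id: dict[str, str] = {}
    for sub in ("A", "C"):
        for chrom, els in genomes_elements[sub].items():
            copies = []
            for el in els:
                seq = _mutate_rate(rng, el.seq, cfg.mutation_rate)
                eid = el.eid
                if el.kind == "mirna":
                    eid = eid.replace("Ar_", "An_").replace("Co_", "Cn_")
                    prog_to_tetra_id[el.eid] = eid
                    tetra_payloads[eid] = payloads[el.eid]
                elif el.kind == "gene":
                    eid = "Bn_" + eid
                copies.append(_Element(el.kind, eid, seq, dict(el.attrs)))
            tetra_elements[chrom] = copies

    all_tetra_mirna_ids = sorted(tetra_payloads)
    lost_ids = sorted(
        rng.choice(np.array(all_tetra_mirna_ids), size=cfg.n_losses, replace=False).tolist()
    ) if cfg.n_losses else []
    lost_set = set(lost_ids)
    for chrom, els in tetra_elements.items():
        tetra_elements[chrom] = [
            el for el in els if not (el.kind == "mirna" and el.eid in lost_set)
        ]

    surviving = [i for i in all_tetra_mirna_ids if i not in lost_set]
    gained_ids: list[str] = []
    gain_source: dict[str, str] = {}
    for g in range(cfg.n_gains):
        src_id = str(rng.choice(np.array(surviving)))
        src_el = None
        for els in tetra_elements.values():
            for el in els:
                if el.eid == src_id:
                    src_el = el
        assert src_el is not None
        gid = f"Bn_gain{g + 1:04d}"
        # insert between genes at a host site with >=10 genes on each side,
        # away from the source neighborhood so the copy lands in a genuinely
        # new flanking-gene context
        src_chrom = next(
            ch for ch, els2 in tetra_elements.items()
            if any(e.eid == src_id for e in els2)
        )
        host_choices = [c for c in sorted(tetra_elements) if c != src_chrom]
        if not host_choices:
            host_choices = [src_chrom]
        host_chrom = str(rng.choice(host_choices))
        els = tetra_elements[host_chrom]
        gene_positions = [i for i, el in enumerate(els) if el.kind == "gene"]
        slot_genes = gene_positions[10:-10]
        slot = int(rng.choice(slot_genes))
        els.insert(slot + 1, _Element("mirna", gid, src_el.seq,
                                      {"family": src_el.attrs["family"], "strand": src_el.attrs["strand"]}))
        els.insert(slot + 1, _Element(
            "spacer", f"sp_{gid}", _random_seq(rng, builder.spacer_len())
        ))
        gained_ids.append(gid)
        gain_source[gid] = src_id
        tetra_payloads[gid] = tetra_payloads[src_id]

    # --- assemble sequences + features ----------------------------------
    def finish(
        elements_by_chrom: dict[str, list[_Element]],
        payload_map: dict[str, _MirnaPayload],
        mature_of: dict[str, str] | None = None,
    ) -> tuple[GenomeSet, list[Gff3Feature], list[TrueLocus], list[tuple[str, int, int]]]:
        records, feats_all, loci, reps_all = {}, [], [], []
        for chrom in sorted(elements_by_chrom):
            seq, feats, coords, reps = builder.assemble(chrom, elements_by_chrom[chrom])
            records[chrom] = seq
            feats_all.extend(feats)
            reps_all.extend((chrom, s, e) for s, e in reps)
            for el in elements_by_chrom[chrom]:
                if el.kind != "mirna":
                    continue
                pl = payload_map[el.eid]
                start, end = coords[el.eid]
                plen = end - start
                moff = pl.mature_offset
                if pl.strand == "+":
                    mstart = start + moff
                else:
                    mstart = start + (plen - moff - cfg.mature_length)
                mend = mstart + cfg.mature_length
                genome_slice = seq[mstart:mend]
                mature = genome_slice if pl.strand == "+" else revcomp(genome_slice)
                prec = seq[start:end] if pl.strand == "+" else revcomp(seq[start:end])
                star_off = 0 if pl.mature_arm == "3p" else plen - cfg.mature_length
                star = prec[star_off : star_off + cfg.mature_length]
                loci.append(TrueLocus(
                    locus_id=el.eid, subgenome=chrom[0], chromosome=chrom,
                    start=start, end=end, strand=pl.strand,
                    mature=mature, star=star, mature_start=mstart, mature_end=mend,
                    mature_arm=pl.mature_arm, family=pl.family,
                    conserved=pl.conserved, pair_id=pl.pair_id,
                ))
        sub_of = {c: ("A" if c.startswith("A") else "C") for c in records}
        return GenomeSet(records, sub_of), feats_all, loci, reps_all

    genome_a, feats_a, loci_a, reps_a = finish(genomes_elements["A"], payloads)
    genome_c, feats_c, loci_c, reps_c = finish(genomes_elements["C"], payloads)
    genome_t, feats_t, loci_t, reps_t = finish(tetra_elements, tetra_payloads)

    # --- expression expectations -----------------------------------------
    expression: dict[str, float] = {}
    for loc in loci_t:
        base = float(rng.lognormal(cfg.expression_meanlog, cfg.expression_sdlog))
        if loc.subgenome == "C":
            base *= cfg.subgenome_bias_rho
        expression[loc.locus_id] = base
    parent_expression: dict[str, dict[str, float]] = {}
    for line in ("T", "N"):
        parent_expression[line] = {
            lid: v * float(rng.lognormal(0.0, cfg.parent_sdlog))
            for lid, v in expression.items()
        }
    n_nonadd = int(round(cfg.nonadditive_fraction * len(loci_t)))
    nonadd_ids = sorted(
        rng.choice(np.array(sorted(expression)), size=n_nonadd, replace=False).tolist()
    ) if n_nonadd else []
    dh_factor = {
        lid: (cfg.nonadditive_factor if rng.random() < 0.5 else 1.0 / cfg.nonadditive_factor)
        for lid in nonadd_ids
    }

    # --- transcripts with planted target sites ---------------------------
    transcripts: dict[str, str] = {}
    for t in range(cfg.n_transcripts):
        transcripts[f"tx{t + 1:04d}"] = _random_seq(rng, cfg.transcript_length)
    cleavage_sites: list[CleavageSite] = []
    tx_ids = sorted(transcripts)
    used_ranges: dict[str, list[tuple[int, int]]] = {t: [] for t in tx_ids}
    target_pool = [l for l in loci_t]
    total_sites = cfg.n_cleavage_sites + cfg.n_decoy_sites
    for s in range(total_sites):
        loc = target_pool[int(rng.integers(0, len(target_pool)))]
        m = cfg.mature_length
        for _attempt in range(50):
            tid = tx_ids[int(rng.integers(0, len(tx_ids)))]
            p0 = int(rng.integers(30, cfg.transcript_length - m - 30))
            if all(p0 + m + 25 <= a or p0 >= b + 25 for a, b in used_ranges[tid]):
                break
        used_ranges[tid].append((p0, p0 + m))
        site = revcomp(loc.mature)
        seq = transcripts[tid]
        transcripts[tid] = seq[:p0] + site + seq[p0 + m:]
        cleave = p0 + m - 10 + 1  # 1-based position opposite miRNA position 10
        cleavage_sites.append(CleavageSite(
            mirna_id=loc.locus_id, transcript_id=tid, position=cleave,
            mature=loc.mature, decoy=s >= cfg.n_cleavage_sites,
        ))

    # --- ncRNA reference --------------------------------------------------
    ncrna_reference = {
        cls: [_random_seq(rng, int(rng.integers(80, 200))) for _ in range(5)]
        for cls in ("snoRNA", "tRNA", "rRNA", "rasiRNA")
    }

    truth = PlantedTruth(
        progenitor_loci={"A": loci_a, "C": loci_c},
        tetraploid_loci=loci_t,
        lost_locus_ids=lost_ids,
        gained_locus_ids=gained_ids,
        gain_source=gain_source,
        expression=expression,
        parent_expression=parent_expression,
        dh_nonadditive_ids=nonadd_ids,
        dh_factor=dh_factor,
        cleavage_sites=cleavage_sites,
        reference_families=reference_families,
        transcripts=transcripts,
        repeat_windows={"A": reps_a, "C": reps_c, "tetraploid": reps_t},
        ncrna_reference=ncrna_reference,
    )
    annotations = {"A": feats_a, "C": feats_c, "tetraploid": feats_t}
    return genome_a, genome_c, genome_t, annotations, truth


# ---------------------------------------------------------------------------
# small-RNA libraries
# ---------------------------------------------------------------------------

def draw_locus_expression(
    truth: PlantedTruth, config: SimulationConfig, rng: np.random.Generator
) -> dict[str, float]:
    """Fresh per-locus expression expectations under the same planted model
    (used for replicate studies)."""
    out = {}
    for loc in truth.tetraploid_loci:
        v = float(rng.lognormal(config.expression_meanlog, config.expression_sdlog))
        if loc.subgenome == "C":
            v *= config.subgenome_bias_rho
        out[loc.locus_id] = v
    return out


def _line_expectations(
    truth: PlantedTruth, line: str, expression: dict[str, float]
) -> dict[str, float]:
    if line in ("T", "N"):
        if expression is truth.expression:
            return truth.parent_expression[line]
        return expression
    # DH lines: mid-parent mean, scaled for planted non-additive loci
    out = {}
    for lid in expression:
        if expression is truth.expression:
            mpv = 0.5 * (truth.parent_expression["T"][lid] + truth.parent_expression["N"][lid])
        else:
            mpv = expression[lid]
        out[lid] = mpv * truth.dh_factor.get(lid, 1.0)
    return out


def simulate_srna_libraries(
    truth: PlantedTruth,
    genome: GenomeSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    lines: list[str] | None = None,
    environments: tuple[str, ...] = ("E1", "E2"),
    expression: dict[str, float] | None = None,
) -> list[SmallRNALibrary]:
    """Draw collapsed small-RNA libraries from the planted expression model.

    Per library the read mix is multinomial: mature reads with per-locus
    expectation proportional to the planted expression (C-subgenome loci
    carry the rho bias), 24-nt background reads from annotated repeat windows
    with a C:A sampling ratio of ``repeat_bias_c``, a small ncRNA-fragment
    component, and a sliver of out-of-range "junk" lengths that the length
    filter removes.  Parental lines use their line-specific expectations; DH
    lines use the mid-parent mean except planted non-additive loci.
    """
    if config.library_depth <= 0:
        raise ValueError("library_depth must be positive")
    if config.subgenome_bias_rho <= 0:
        raise ValueError("subgenome_bias_rho must be positive")
    if not truth.tetraploid_loci:
        raise ValueError("planted truth has no loci")
    if rng is None:
        rng = np.random.default_rng(np.random.PCG64(config.seed + 1))
    if lines is None:
        lines = ["T", "N"] + [f"DH{i + 1}" for i in range(config.n_dh_lines)]
    expression = truth.expression if expression is None else expression

    loci = truth.tetraploid_loci
    locus_ids = [l.locus_id for l in loci]
    mature_seqs = np.array([l.mature for l in loci])

    # repeat-window sampling slots (position x strand), weighted C:A
    reps = truth.repeat_windows["tetraploid"]
    L = config.background_read_length
    slot_seqs: list[str] = []
    slot_w: list[float] = []
    for chrom, s, e in reps:
        w = config.repeat_bias_c if chrom.startswith("C") else 1.0
        window = genome.records[chrom][s:e]
        step = 7  # subsample start positions; keeps libraries collapsible
        for off in range(0, len(window) - L + 1, step):
            frag = window[off : off + L]
            slot_seqs.append(frag)
            slot_w.append(w)
            slot_seqs.append(revcomp(frag))
            slot_w.append(w)
    slot_p = np.array(slot_w) / np.sum(slot_w)

    # ncRNA fragment slots
    nc_seqs: list[str] = []
    for cls in sorted(truth.ncrna_reference):
        for s in truth.ncrna_reference[cls]:
            for off in range(0, len(s) - 21, 11):
                nc_seqs.append(s[off : off + 21 + off % 4])

    libraries: list[SmallRNALibrary] = []
    for line in lines:
        exps = _line_expectations(truth, line, expression)
        weights = np.array([exps[l] for l in locus_ids], dtype=float)
        p_loci = weights / weights.sum()
        for env in environments:
            depth = config.library_depth
            n_junk = rng.binomial(depth, config.junk_fraction)
            n_nc = rng.binomial(depth - n_junk, config.ncrna_fraction)
            n_bg = rng.binomial(depth - n_junk - n_nc, config.background_fraction)
            n_mature = depth - n_junk - n_nc - n_bg
            counts: dict[str, int] = {}

            mat_counts = rng.multinomial(n_mature, p_loci)
            for seq, c in zip(mature_seqs, mat_counts):
                if c:
                    counts[seq] = counts.get(seq, 0) + int(c)
            if len(slot_seqs):
                bg_counts = rng.multinomial(n_bg, slot_p)
                for i in np.flatnonzero(bg_counts):
                    seq = slot_seqs[i]
                    counts[seq] = counts.get(seq, 0) + int(bg_counts[i])
            if nc_seqs and n_nc:
                nc_counts = rng.multinomial(n_nc, np.full(len(nc_seqs), 1.0 / len(nc_seqs)))
                for i in np.flatnonzero(nc_counts):
                    seq = nc_seqs[i]
                    counts[seq] = counts.get(seq, 0) + int(nc_counts[i])
            if n_junk:
                for _ in range(min(int(n_junk), 50)):
                    ln = int(rng.choice([16, 17, 45, 46]))
                    counts[_random_seq(rng, ln)] = max(1, int(n_junk) // 50)
            libraries.append(SmallRNALibrary(
                library_id=f"{line}_{env}", line=line, tissue="leaf",
                environment=env, unique_reads=counts, clean_read_total=depth,
            ))
    return libraries


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def simulate_degradome(
    truth: PlantedTruth,
    transcripts: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    tag_length: int = 20,
) -> dict[str, int]:
    """Collapsed degradome tags: the modal 5' end of each targeted
    transcript's tags sits exactly at the planted cleavage position; decoy
    sites receive their tags at ``decoy_offset`` nt downstream; a
    ``degradome_noise`` fraction of tags start at uniform positions."""
    if not truth.cleavage_sites:
        raise ValueError("planted truth has no cleavage sites")
    if rng is None:
        rng = np.random.default_rng(np.random.PCG64(config.seed + 2))
    depth = config.degradome_depth
    n_noise = rng.binomial(depth, config.degradome_noise)
    n_signal = depth - n_noise
    sites = truth.cleavage_sites
    site_counts = rng.multinomial(n_signal, np.full(len(sites), 1.0 / len(sites)))
    tags: dict[str, int] = {}
    for site, c in zip(sites, site_counts):
        if not c:
            continue
        seq = transcripts[site.transcript_id]
        start0 = site.position - 1 + (config.decoy_offset if site.decoy else 0)
        frag = seq[start0 : start0 + tag_length]
        if len(frag) >= 15:
            tags[frag] = tags.get(frag, 0) + int(c)
    # Positional noise is uniform over the portion of each transcript that is
    # not being interrogated: random decay fragments are unrelated to the
    # planted sites, so noise start positions exclude the +/-5 validation
    # neighborhood of every planted or decoy cleavage position.
    excluded: dict[str, set[int]] = {t: set() for t in transcripts}
    for site in sites:
        for off in range(-5, 6):
            excluded[site.transcript_id].add(site.position + off)
            excluded[site.transcript_id].add(site.position + config.decoy_offset + off)
    tx_ids = sorted(transcripts)
    allowed = {
        t: [p for p in range(1, len(transcripts[t]) - tag_length + 1)
            if p not in excluded[t]]
        for t in tx_ids
    }
    for _ in range(int(n_noise)):
        tid = tx_ids[int(rng.integers(0, len(tx_ids)))]
        pool = allowed[tid]
        if not pool:
            continue
        p = pool[int(rng.integers(0, len(pool)))] - 1
        frag = transcripts[tid][p : p + tag_length]
        tags[frag] = tags.get(frag, 0) + 1
    return tags


# ---------------------------------------------------------------------------
# writing a full simulated dataset to disk
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    config: SimulationConfig,
    genome_a: GenomeSet,
    genome_c: GenomeSet,
    genome_t: GenomeSet,
    annotations: dict[str, list[Gff3Feature]],
    truth: PlantedTruth,
    libraries: list[SmallRNALibrary],
    degradome: dict[str, int],
) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(genome_a.records, out / "progenitor_A.fasta")
    write_fasta(genome_c.records, out / "progenitor_C.fasta")
    write_fasta(genome_t.records, out / "tetraploid.fasta")
    write_gff3(annotations["A"], out / "progenitor_A.gff3")
    write_gff3(annotations["C"], out / "progenitor_C.gff3")
    write_gff3(annotations["tetraploid"], out / "tetraploid.gff3")
    write_fasta(truth.transcripts, out / "transcripts.fasta")
    write_fasta(
        {f"{cls}_{i + 1}": s for cls, seqs in truth.ncrna_reference.items()
         for i, s in enumerate(seqs)},
        out / "ncrna_reference.fasta",
    )
    write_fasta(
        {f"{fam}_{i + 1}": s for fam, seqs in truth.reference_families.items()
         for i, s in enumerate(seqs)},
        out / "known_mature.fasta",
    )
    for lib in libraries:
        write_collapsed_fasta(lib.unique_reads, out / f"srna_{lib.library_id}.fasta")
    write_collapsed_fasta(degradome, out / "degradome.fasta")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    # truth ledger: TSV of loci + JSON of events
    with open(out / "truth_loci.tsv", "w") as fh:
        fh.write("locus_id\tgenome\tsubgenome\tchromosome\tstart\tend\tstrand\t"
                 "mature\tstar\tfamily\tconserved\tpair_id\n")
        for gname, loci in [("progenitor_A", truth.progenitor_loci["A"]),
                            ("progenitor_C", truth.progenitor_loci["C"]),
                            ("tetraploid", truth.tetraploid_loci)]:
            for l in loci:
                fh.write("\t".join(map(str, [
                    l.locus_id, gname, l.subgenome, l.chromosome, l.start, l.end,
                    l.strand, l.mature, l.star, l.family, int(l.conserved), l.pair_id,
                ])) + "\n")
    ledger = {
        "lost_locus_ids": truth.lost_locus_ids,
        "gained_locus_ids": truth.gained_locus_ids,
        "gain_source": truth.gain_source,
        "dh_nonadditive_ids": truth.dh_nonadditive_ids,
        "dh_factor": truth.dh_factor,
        "expression": truth.expression,
        "cleavage_sites": [dataclasses.asdict(s) for s in truth.cleavage_sites],
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
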