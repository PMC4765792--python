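"""Microsynteny-based MIRNA orthology and gain/loss calling.

Orthology between an allotetraploid locus and its progenitors is decided in
two steps: a seed-and-extend ungapped homology search of the precursor
against the other genome (retained hits must cover more than 90% of the
query and reach a Karlin-Altschul significance below 1e-5; at most the five
best hits are kept), then a microsynteny test comparing the 10 flanking
protein-coding genes on each side of query and subject, keyed by
``ortho_family`` labels.  Syntenic pairs fall in class 1 (shared flanking
genes on both sides), 2 (upstream only) or 3 (downstream only); class 4
(no shared flank) is non-syntenic.

A progenitor locus is called LOST when its precursor has no retained hit in
the tetraploid; a tetraploid locus is called GAINED when no hit in either
progenitor is syntenic.  Best hits landing on the non-corresponding
subgenome (A_r vs C_n, C_o vs A_n) are tallied as opposite-subgenome
matches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .seqio import GenomeIndex, GenomeSet, Gff3Feature, revcomp

# Karlin-Altschul parameters for +1/-2 match/mismatch ungapped scoring
_KA_LAMBDA = 1.33
_KA_K = 0.621
MATCH, MISMATCH = 1, -2
XDROP = 12


@dataclass
class FlankContext:
    locus_id: str
    upstream: list[str]     # ortho-family labels, nearest first, <= k per side
    downstream: list[str]

    def __post_init__(self) -> None:
        if len(set(self.upstream)) != len(self.upstream) or len(
            set(self.downstream)
        ) != len(self.downstream):
            raise ValueError("duplicate flanking gene labels within a side")


@dataclass
class SyntenyCall:
    query_id: str
    subject_id: str
    shared_upstream: int
    shared_downstream: int
    set_class: int          # 1..4

    @property
    def syntenic(self) -> bool:
        return self.set_class in (1, 2, 3)


@dataclass
class HomologyHit:
    query_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    score: int
    coverage: float
    evalue: float


@dataclass
class GainLossResult:
    lost: list[str]
    gained: list[str]
    opposite_subgenome: list[str]
    evidence: dict[str, dict] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# flanking-gene contexts
# ---------------------------------------------------------------------------

class GeneTable:
    """Protein-coding genes per chromosome, sorted by position."""

    def __init__(self, features: Sequence[Gff3Feature]):
        self.by_chrom: dict[str, list[Gff3Feature]] = {}
        for f in features:
            if f.ftype == "gene":
                self.by_chrom.setdefault(f.seqid, []).append(f)
        for genes in self.by_chrom.values():
            genes.sort(key=lambda g: g.start)

    def context(
        self, locus_id: str, chromosome: str, start: int, end: int, k: int = 10
    ) -> FlankContext:
        if chromosome not in self.by_chrom:
            raise KeyError(f"no protein-coding genes annotated on {chromosome!r}")
        genes = self.by_chrom[chromosome]
        upstream = [g for g in genes if g.end <= start]
        downstream = [g for g in genes if g.start >= end]
        upstream.sort(key=lambda g: start - g.end)     # nearest first
        downstream.sort(key=lambda g: g.start - end)
        return FlankContext(
            locus_id=locus_id,
            upstream=[g.attributes["ortho_family"] for g in upstream[:k]],
            downstream=[g.attributes["ortho_family"] for g in downstream[:k]],
        )


def extract_flanking_genes(
    locus_id: str,
    chromosome: str,
    start: int,
    end: int,
    annotation: Sequence[Gff3Feature] | GeneTable,
    k: int = 10,
) -> FlankContext:
    """The k nearest protein-coding genes on each side of a locus (fewer near
    chromosome ends), keyed by ortho-family label."""
    table = annotation if isinstance(annotation, GeneTable) else GeneTable(annotation)
    return table.context(locus_id, chromosome, start, end, k)


def test_microsynteny(query: FlankContext, subject: FlankContext) -> SyntenyCall:
    """Classify a locus pair by shared flanking genes.

    Class 1: >=1 shared gene on both sides; 2: upstream only; 3: downstream
    only; 4: neither.  Classes 1-3 count as syntenic.  Because a hit on the
    opposite strand reverses gene order, each side of the query is compared
    against the union of the subject's two sides.
    """
    sub_all = set(subject.upstream) | set(subject.downstream)
    up = len(set(query.upstream) & sub_all)
    down = len(set(query.downstream) & sub_all)
    if up and down:
        cls = 1
    elif up:
        cls = 2
    elif down:
        cls = 3
    else:
        cls = 4
    return SyntenyCall(query.locus_id, subject.locus_id, up, down, cls)


# ---------------------------------------------------------------------------
# homology search
# ---------------------------------------------------------------------------

def _extend_ungapped(
    qcodes: np.ndarray, gcodes: np.ndarray, qpos: int, gpos: int,
    glo: int, ghi: int, k: int,
) -> tuple[int, int, int, int, int]:
    """Extend an exact k-seed at (qpos, gpos) in both directions with X-drop.
    Returns (qlo, qhi, glo_hit, ghi_hit, score)."""
    score = k * MATCH
    # right
    best, cur = score, score
    qi, gi = qpos + k, gpos + k
    best_q, best_g = qi, gi
    while qi < qcodes.size and gi < ghi:
        cur += MATCH if qcodes[qi] == gcodes[gi] else MISMATCH
        qi += 1
        gi += 1
        if cur > best:
            best, best_q, best_g = cur, qi, gi
        elif best - cur > XDROP:
            break
    score = best
    qhi, ghit_hi = best_q, best_g
    # left
    best, cur = score, score
    qi, gi = qpos, gpos
    best_q, best_g = qi, gi
    while qi > 0 and gi > glo:
        cur += MATCH if qcodes[qi - 1] == gcodes[gi - 1] else MISMATCH
        qi -= 1
        gi -= 1
        if cur > best:
            best, best_q, best_g = cur, qi, gi
        elif best - cur > XDROP:
            break
    return best_q, qhi, best_g, ghit_hi, best


def find_mirna_homologs(
    query_id: str,
    precursor: str,
    index: GenomeIndex,
    max_hits: int = 5,
    min_coverage: float = 0.9,
    max_evalue: float = 1e-5,
    seed_step: int = 4,
) -> list[HomologyHit]:
    """Seed-and-extend ungapped homology search of a precursor against a
    genome; hits failing the coverage or significance gate are discarded and
    at most ``max_hits`` best hits are returned (ties broken by chromosome
    then start)."""
    if len(precursor) < 40:
        raise ValueError("precursor too short for homology search (< 40 nt)")
    genome = index.genome
    k = index.k
    gcodes = index._codes
    db_len = int(gcodes.size)
    best_by_region: dict[tuple[str, str, int], tuple] = {}
    from .seqio import _encode  # shared 2-bit encoding

    for strand in ("+", "-"):
        q = precursor if strand == "+" else revcomp(precursor)
        qcodes = _encode(q)
        for qoff in range(0, len(q) - k + 1, seed_step):
            kint = 0
            window = qcodes[qoff : qoff + k]
            if (window == 255).any():
                continue
            for c in window:
                kint = (kint << 2) | int(c)
            for gpos in index._seed_positions(kint):
                gpos = int(gpos)
                ci = int(np.searchsorted(index._bounds, gpos, side="right")) - 1
                glo, ghi = int(index._bounds[ci]), int(index._bounds[ci + 1])
                diag = gpos - qoff
                key = (index._chrom_ids[ci], strand, diag)
                if key in best_by_region:
                    continue
                qlo, qhi, gl, gh, score = _extend_ungapped(
                    qcodes, gcodes, qoff, gpos, glo, ghi, k
                )
                best_by_region[key] = (score, qlo, qhi, gl, gh, ci)
    hits: list[HomologyHit] = []
    seen_spans: set[tuple[str, int, int, str]] = set()
    for (chrom, strand, _diag), (score, qlo, qhi, gl, gh, ci) in best_by_region.items():
        coverage = (qhi - qlo) / len(precursor)
        evalue = _KA_K * len(precursor) * db_len * math.exp(-_KA_LAMBDA * score)
        if coverage <= min_coverage or evalue >= max_evalue:
            continue
        cstart = gl - int(index._bounds[ci])
        cend = gh - int(index._bounds[ci])
        span = (chrom, cstart, cend, strand)
        if span in seen_spans:
            continue
        seen_spans.add(span)
        hits.append(HomologyHit(
            query_id=query_id, chromosome=chrom, start=cstart, end=cend,
            strand=strand, score=int(score), coverage=coverage, evalue=evalue,
        ))
    hits.sort(key=lambda h: (-h.score, h.chromosome, h.start))
    return hits[:max_hits]


# ---------------------------------------------------------------------------
# gain / loss calling
# ---------------------------------------------------------------------------

def call_gain_loss(
    tetraploid_loci: Sequence,
    progenitor_loci: dict[str, Sequence],
    genomes: dict[str, GenomeSet],
    annotations: dict[str, Sequence[Gff3Feature]],
    k_flank: int = 10,
    max_hits: int = 5,
    indexes: dict[str, GenomeIndex] | None = None,
) -> GainLossResult:
    """Call MIRNA losses (progenitor loci absent from the tetraploid), gains
    (tetraploid loci with no syntenic progenitor partner), and tally best
    hits on the opposite subgenome.

    Loci must expose ``locus_id``, ``chromosome``, ``start``, ``end`` and
    ``subgenome`` attributes; genome/annotation dicts are keyed "A", "C" and
    "tetraploid".
    """
    if indexes is None:
        indexes = {name: GenomeIndex(g, k=13) for name, g in genomes.items()}
    tables = {name: GeneTable(annotations[name]) for name in annotations}
    result = GainLossResult(lost=[], gained=[], opposite_subgenome=[])

    # losses + opposite-subgenome tally
    for sub in ("A", "C"):
        genome = genomes[sub]
        for loc in progenitor_loci[sub]:
            seq = genome.records[loc.chromosome][loc.start : loc.end]
            hits = find_mirna_homologs(
                loc.locus_id, seq, indexes["tetraploid"], max_hits=max_hits
            )
            if not hits:
                result.lost.append(loc.locus_id)
                result.evidence[loc.locus_id] = {"call": "lost", "hits": 0}
                continue
            best = hits[0]
            hit_sub = genomes["tetraploid"].subgenome_of[best.chromosome]
            if hit_sub != loc.subgenome:
                result.opposite_subgenome.append(loc.locus_id)
            result.evidence[loc.locus_id] = {
                "call": "conserved", "hits": len(hits),
                "best_chromosome": best.chromosome, "best_subgenome": hit_sub,
            }

    # gains
    tet_genome = genomes["tetraploid"]
    for loc in tetraploid_loci:
        seq = tet_genome.records[loc.chromosome][loc.start : loc.end]
        qctx = tables["tetraploid"].context(
            loc.locus_id, loc.chromosome, loc.start, loc.end, k_flank
        )
        syntenic = False
        n_hits = 0
        for sub in ("A", "C"):
            hits = find_mirna_homologs(loc.locus_id, seq, indexes[sub], max_hits=max_hits)
            n_hits += len(hits)
            for h in hits:
                sctx = tables[sub].context(
                    f"{h.chromosome}:{h.start}", h.chromosome, h.start, h.end, k_flank
                )
                if test_microsynteny(qctx, sctx).syntenic:
                    syntenic = True
                    break
            if syntenic:
                break
        if not syntenic:
            result.gained.append(loc.locus_id)
            result.evidence[loc.locus_id] = {"call": "gained", "hits": n_hits}
    return result


# ---------------------------------------------------------------------------
# family copy numbers and density tracks
# ---------------------------------------------------------------------------

def family_copy_table(families_by_genome: dict[str, list[str]]) -> pd.DataFrame:
    """Per-family copy-number matrix with the tetraploid-minus-progenitors
    delta: columns A_n, C_n, A_r, C_o and delta = (A_n + C_n) - (A_r + C_o),
    sorted by |delta| descending then family name."""
    cols = ["A_n", "C_n", "A_r", "C_o"]
    fams = sorted({f for v in families_by_genome.values() for f in v})
    data = {
        c: [families_by_genome.get(c, []).count(f) for f in fams] for c in cols
    }
    df = pd.DataFrame(data, index=pd.Index(fams, name="family"))
    df = df[df.sum(axis=1) > 0]
    df["delta"] = (df["A_n"] + df["C_n"]) - (df["A_r"] + df["C_o"])
    df = df.iloc[
        sorted(range(len(df)), key=lambda i: (-abs(df["delta"].iloc[i]), df.index[i]))
    ]
    return df


def density_track(
    loci: Sequence, genome: GenomeSet, window: int = 1_000_000
) -> pd.DataFrame:
    """Per-window locus counts (a plain-TSV substitute for a Circos track)."""
    rows = []
    by_chrom: dict[str, list[int]] = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc.start)
    for chrom in genome.chromosomes:
        length = len(genome.records[chrom])
        starts = np.array(by_chrom.get(chrom, []), dtype=int)
        for ws in range(0, length, window):
            n = int(((starts >= ws) & (starts < ws + window)).sum()) if starts.size else 0
            rows.append((chrom, ws, min(ws + window, length), n))
    return pd.DataFrame(rows, columns=["chromosome", "start", "end", "n_loci"])
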