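"""MIRNA locus prediction from mapped reads and conserved/novel classification.

The discovery chain mirrors the classic hairpin-excision approach used for
plant small-RNA data: read alignments are merged into genomic clusters, the
most abundant read of a cluster is the candidate mature, flanking windows are
excised and folded, the miRNA* arm is delimited from the pair table with the
2-nt 3' overhang convention, and the candidate is accepted only when all of
the duplex criteria hold:

* hairpin free energy below -18 kcal/mol (strict),
* more than 16 mature nucleotides paired in the miRNA/miRNA* duplex,
* fewer than 4 unpaired (bulged) mature nucleotides,
* mature/star spacing below 300 nt,
* at least 2 supporting reads in some library.

Accepted matures are classified conserved (edit distance <= 2 to any known
mature in the reference set) or novel, and novel ones are named
``bna_novel_miRX{n}`` in discovery order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .fold import HairpinFold, fold_hairpin
from .seqio import Alignment, GenomeIndex, GenomeSet, SmallRNALibrary, revcomp


@dataclass
class Thresholds:
    """Every acceptance gate of the discovery stage, at its quoted default."""

    dg_cutoff: float = -18.0       # accept iff delta_g < dg_cutoff
    min_matched: int = 17          # accept iff matched_nt >= min_matched (> 16)
    max_bulges: int = 3            # accept iff bulge_nt <= max_bulges (< 4)
    max_spacing: int = 299         # accept iff spacing_nt <= max_spacing (< 300)
    min_reads: int = 2             # max per-library support must reach this
    conserved_max_mismatch: int = 2
    flank: int = 300
    fold_backend: str = "nn"


@dataclass
class DuplexMetrics:
    matched_nt: int
    bulge_nt: int
    spacing_nt: int
    star_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if min(self.matched_nt, self.bulge_nt, self.spacing_nt) < 0:
            raise ValueError("duplex metrics must be non-negative")


@dataclass
class CandidateWindow:
    chromosome: str
    strand: str
    window_start: int
    window_end: int
    mature_read: str
    mature_start: int      # genomic span of the mature alignment
    mature_end: int
    support: dict[str, int]  # per-library read count of the mature


@dataclass
class RejectionRecord:
    chromosome: str
    strand: str
    mature_read: str
    mature_start: int
    reasons: list[str]


@dataclass
class MirnaLocus:
    locus_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    mature: str
    mature_start: int
    mature_end: int
    mature_arm: str
    star: str
    fold: HairpinFold
    duplex: DuplexMetrics
    support: dict[str, int]
    mirna_class: str = "novel"     # conserved | novel
    family: str = ""
    subgenome: str = "unplaced"

    @property
    def delta_g(self) -> float:
        return self.fold.delta_g


# ---------------------------------------------------------------------------
# clustering and window excision
# ---------------------------------------------------------------------------

def cluster_and_excise(
    alignments: dict[str, list[Alignment]],
    genome: GenomeSet,
    library_counts: dict[str, dict[str, int]],
    flank: int = 300,
    min_reads: int = 2,
) -> list[CandidateWindow]:
    """Merge overlapping alignments into clusters and excise candidate windows.

    Reads whose count is below ``min_reads`` in every library are excluded
    before clustering.  For each cluster the most abundant read (summed over
    libraries; ties broken by lexicographically smallest sequence) becomes
    the candidate mature, and both flanking windows
    ``[mature_start - flank, mature_end]`` and
    ``[mature_start, mature_end + flank]`` are emitted, clipped at
    chromosome ends.
    """
    if not alignments:
        return []
    total: dict[str, int] = {}
    maxlib: dict[str, int] = {}
    for lib_id, counts in library_counts.items():
        for read, c in counts.items():
            total[read] = total.get(read, 0) + c
            maxlib[read] = max(maxlib.get(read, 0), c)
    placed: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    for read, alns in alignments.items():
        if maxlib.get(read, 0) < min_reads:
            continue
        for a in alns:
            placed.setdefault((a.chromosome, a.strand), []).append((a.start, a.end, read))
    windows: list[CandidateWindow] = []
    for (chrom, strand), items in sorted(placed.items()):
        items.sort()
        clusters: list[list[tuple[int, int, str]]] = []
        cur: list[tuple[int, int, str]] = []
        cur_end = -1
        for s, e, read in items:
            if cur and s > cur_end:
                clusters.append(cur)
                cur = []
            cur.append((s, e, read))
            cur_end = max(cur_end, e)
        if cur:
            clusters.append(cur)
        chrom_len = len(genome.records[chrom])
        for cl in clusters:
            best = min(cl, key=lambda t: (-total[t[2]], t[2]))
            ms, me, mread = best
            support = {
                lib_id: counts.get(mread, 0)
                for lib_id, counts in library_counts.items()
            }
            for ws, we in ((max(0, ms - flank), me), (ms, min(chrom_len, me + flank))):
                windows.append(CandidateWindow(
                    chromosome=chrom, strand=strand, window_start=ws, window_end=we,
                    mature_read=mread, mature_start=ms, mature_end=me, support=support,
                ))
    return windows


# ---------------------------------------------------------------------------
# duplex evaluation
# ---------------------------------------------------------------------------

class MatureSpansLoop(ValueError):
    """The candidate mature pairs with itself, i.e. it crosses the loop."""


def evaluate_duplex(fold: HairpinFold, mature_interval: tuple[int, int]) -> DuplexMetrics:
    """Derive miRNA/miRNA* duplex metrics from a fold's pair table.

    The star interval is the span of positions paired with the mature,
    extended by the 2-nt 3' overhang of Dicer processing.  ``matched_nt``
    counts paired mature positions, ``bulge_nt`` unpaired ones, and
    ``spacing_nt`` is the loop span between the inner ends of mature and
    star.  A mature that pairs with itself spans the loop and is rejected.
    """
    ms, me = mature_interval
    if not (0 <= ms < me <= len(fold.sequence)):
        raise ValueError("mature interval outside the folded sequence")
    pt = fold.pair_table
    partners = []
    for i in range(ms, me):
        j = int(pt[i])
        if j >= 0:
            if ms <= j < me:
                raise MatureSpansLoop(
                    f"mature position {i} pairs with mature position {j}: "
                    "candidate spans the hairpin loop"
                )
            partners.append(j)
    matched = len(partners)
    bulges = (me - ms) - matched
    if not partners:
        return DuplexMetrics(0, bulges, 0, (0, 0))
    lo, hi = min(partners), max(partners) + 1
    hi = min(hi + 2, len(fold.sequence))  # 2-nt 3' overhang of the star arm
    if lo >= me:          # star downstream of mature
        spacing = max(0, lo - me)
    else:                 # star upstream
        spacing = max(0, ms - hi)
    return DuplexMetrics(matched, bulges, spacing, (lo, hi))


# ---------------------------------------------------------------------------
# acceptance
# ---------------------------------------------------------------------------

def call_mirna(
    fold: HairpinFold,
    duplex: DuplexMetrics,
    support: dict[str, int],
    thresholds: Thresholds | None = None,
) -> list[str]:
    """Check every acceptance criterion; returns the list of failed criteria
    (empty means accepted)."""
    t = thresholds or Thresholds()
    reasons = []
    if not fold.delta_g < t.dg_cutoff:
        reasons.append(f"free-energy {fold.delta_g:.2f} not below {t.dg_cutoff}")
    if not duplex.matched_nt >= t.min_matched:
        reasons.append(f"matched_nt {duplex.matched_nt} below {t.min_matched}")
    if not duplex.bulge_nt <= t.max_bulges:
        reasons.append(f"bulge_nt {duplex.bulge_nt} above {t.max_bulges}")
    if not duplex.spacing_nt <= t.max_spacing:
        reasons.append(f"spacing_nt {duplex.spacing_nt} above {t.max_spacing}")
    if not support or max(support.values()) < t.min_reads:
        reasons.append(f"read support below {t.min_reads} in every library")
    return reasons


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Global (Needleman-Wunsch, unit cost) edit distance; U and T equal."""
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def classify_mirna(
    mature: str,
    reference: dict[str, list[str]],
    max_mismatch: int = 2,
) -> tuple[str, str | None, int]:
    """Classify a mature as conserved or novel against known miRNAs.

    Distance is the minimum global edit distance to any reference mature;
    the family of the argmin is returned (ties resolved to the
    lexicographically smallest family name).  ``conserved`` iff the distance
    is at most ``max_mismatch``.
    """
    if not mature:
        raise ValueError("empty mature sequence")
    if not reference:
        raise ValueError("empty reference set")
    best_d = None
    best_fam = None
    for fam in sorted(reference):
        for seq in reference[fam]:
            d = edit_distance(mature, seq)
            if best_d is None or d < best_d:
                best_d, best_fam = d, fam
    cls = "conserved" if best_d <= max_mismatch else "novel"
    return cls, (best_fam if cls == "conserved" else None), best_d


def assign_subgenome(chromosome: str, genome: GenomeSet) -> str:
    if chromosome not in genome.subgenome_of:
        raise KeyError(f"unknown chromosome {chromosome!r}")
    return genome.subgenome_of[chromosome]


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _window_candidate_fold(
    genome: GenomeSet, cand: CandidateWindow, backend: str
) -> tuple[HairpinFold, tuple[int, int], tuple[int, int]] | None:
    """Fold a candidate window, excise the precursor around mature + star,
    refold, and return (fold, mature interval in fold, genomic interval)."""
    seq = genome.records[cand.chromosome][cand.window_start : cand.window_end]
    if cand.strand == "-":
        seq = revcomp(seq)
        m_off = cand.window_end - cand.mature_end
    else:
        m_off = cand.mature_start - cand.window_start
    m_len = cand.mature_end - cand.mature_start
    if len(seq) < 40 or "N" in seq:
        return None
    fold0 = fold_hairpin(seq, backend=backend, min_len=10, max_len=1000)
    pt = fold0.pair_table
    partners = [int(pt[i]) for i in range(m_off, m_off + m_len) if pt[i] >= 0]
    partners = [p for p in partners if p < m_off or p >= m_off + m_len]
    if len(partners) < 4:
        return None
    lo = max(0, min(min(partners), m_off) - 10)
    hi = min(len(seq), max(max(partners) + 1, m_off + m_len) + 10)
    sub = seq[lo:hi]
    if len(sub) < 40:
        return None
    fold1 = fold_hairpin(sub, backend=backend, min_len=10, max_len=1000)
    m_in_sub = (m_off - lo, m_off - lo + m_len)
    if cand.strand == "+":
        g = (cand.window_start + lo, cand.window_start + hi)
    else:
        g = (cand.window_end - hi, cand.window_end - lo)
    return fold1, m_in_sub, g


def discover_mirnas(
    libraries: list[SmallRNALibrary],
    genome: GenomeSet,
    reference: dict[str, list[str]],
    thresholds: Thresholds | None = None,
    index: GenomeIndex | None = None,
) -> tuple[list[MirnaLocus], list[RejectionRecord]]:
    """Run the full discovery chain over a set of small-RNA libraries."""
    t = thresholds or Thresholds()
    if index is None:
        index = GenomeIndex(genome)
    pooled: dict[str, list[Alignment]] = {}
    library_counts = {lib.library_id: lib.unique_reads for lib in libraries}
    all_reads: set[str] = set()
    for lib in libraries:
        all_reads.update(lib.unique_reads)
    for read in all_reads:
        try:
            pooled[read] = index.find(read)
        except ValueError:
            pooled[read] = []
    candidates = cluster_and_excise(
        pooled, genome, library_counts, flank=t.flank, min_reads=t.min_reads
    )
    accepted: dict[tuple[str, int, int, str], MirnaLocus] = {}
    rejections: list[RejectionRecord] = []
    by_cluster: dict[tuple[str, str, int], list[CandidateWindow]] = {}
    for cand in candidates:
        by_cluster.setdefault(
            (cand.chromosome, cand.strand, cand.mature_start), []
        ).append(cand)
    for key, cands in sorted(by_cluster.items()):
        best: MirnaLocus | None = None
        fail_reasons: list[str] = ["no hairpin structure around the mature"]
        for cand in cands:
            try:
                res = _window_candidate_fold(genome, cand, t.fold_backend)
            except ValueError:
                continue
            if res is None:
                continue
            fold1, (ms, me), (gs, ge) = res
            try:
                duplex = evaluate_duplex(fold1, (ms, me))
            except MatureSpansLoop as exc:
                fail_reasons = [str(exc)]
                continue
            reasons = call_mirna(fold1, duplex, cand.support, t)
            if reasons:
                fail_reasons = reasons
                continue
            arm = "5p" if duplex.star_interval[0] >= me else "3p"
            star = fold1.sequence[duplex.star_interval[0] : duplex.star_interval[1]]
            locus = MirnaLocus(
                locus_id="", chromosome=cand.chromosome, start=gs, end=ge,
                strand=cand.strand, mature=cand.mature_read,
                mature_start=cand.mature_start, mature_end=cand.mature_end,
                mature_arm=arm,
                star=star.replace("U", "T"), fold=fold1, duplex=duplex,
                support=dict(cand.support),
                subgenome=assign_subgenome(cand.chromosome, genome),
            )
            if best is None or locus.delta_g < best.delta_g:
                best = locus
        if best is not None:
            accepted[(best.chromosome, best.start, best.end, best.strand)] = best
        else:
            cand = cands[0]
            rejections.append(RejectionRecord(
                chromosome=cand.chromosome, strand=cand.strand,
                mature_read=cand.mature_read, mature_start=cand.mature_start,
                reasons=fail_reasons,
            ))
    # classification and naming
    loci = sorted(accepted.values(), key=lambda l: (l.chromosome, l.start, l.strand))
    novel_names: dict[str, str] = {}
    n_novel = 0
    serial = 0
    for locus in loci:
        serial += 1
        locus.locus_id = f"bna_MIR{serial:04d}"
        cls, fam, _d = classify_mirna(locus.mature, reference, t.conserved_max_mismatch)
        locus.mirna_class = cls
        if cls == "conserved":
            locus.family = fam or ""
        else:
            if locus.mature not in novel_names:
                n_novel += 1
                novel_names[locus.mature] = f"bna_novel_miRX{n_novel}"
            locus.family = novel_names[locus.mature]
    return loci, rejections
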