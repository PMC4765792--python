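"""miRNA target prediction and degradome (PARE) cleavage validation.

Target sites are scored with an Allen-style complementarity penalty
("expectation"): on the antiparallel miRNA/target duplex each position
contributes 0 for a Watson-Crick pair, 0.5 for a G:U wobble, 1 for a
mismatch, and 2 per bulged target nucleotide; penalties are doubled at
miRNA positions 2-13 (the seed region).  At most one target-side bulge of
up to 3 nt is considered.  Sites at or below the expectation cutoff
(default 3.0) are retained; the predicted cleavage position is the
transcript nucleotide paired to miRNA position 10, the canonical AGO
slicing site.  A site is degradome-validated when a mapped tag 5' end lies
within 5 nt of the predicted cleavage position (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import revcomp

SEED_START, SEED_END = 2, 13     # 1-based miRNA positions with doubled penalty
GAP_PENALTY = 2.0
WOBBLE_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
MAX_BULGE = 3

_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
# penalty[mirna_base, target_base] on the antiparallel duplex
_PEN = np.full((5, 5), MISMATCH_PENALTY)
for _m, _t in [("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")]:
    _PEN[_IDX[_m], _IDX[_t]] = 0.0
_PEN[_IDX["G"], _IDX["T"]] = WOBBLE_PENALTY   # G:U wobble
_PEN[_IDX["T"], _IDX["G"]] = WOBBLE_PENALTY
_PEN[4, :] = MISMATCH_PENALTY
_PEN[:, 4] = MISMATCH_PENALTY


@dataclass
class TargetInteraction:
    mirna_id: str
    transcript_id: str
    start: int                    # site interval on transcript, 0-based half-open
    end: int
    expectation: float
    alignment: tuple[str, str, str]
    cleavage_pos: int             # 1-based transcript coordinate
    status: str = "unvalidated"   # validated | unvalidated
    tag_support: int = 0
    pathways: list[str] = field(default_factory=list)


@dataclass
class DegradomeProfile:
    transcript_id: str
    counts: dict[int, int]        # 1-based 5'-end position -> summed tag count
    length: int

    def __post_init__(self) -> None:
        for p, c in self.counts.items():
            if not (1 <= p <= self.length) or c < 0:
                raise ValueError(f"invalid profile entry {p}:{c}")


def _codes(seq: str) -> np.ndarray:
    return np.array([_IDX.get(ch, 4) for ch in seq.upper()], dtype=np.intp)


def _weights(m: int) -> np.ndarray:
    w = np.ones(m)
    w[SEED_START - 1 : SEED_END] = 2.0
    return w


def score_target_site(
    mirna: str, window: str
) -> tuple[float, tuple[str, str, str], int]:
    """Score one miRNA against one target window.

    The window is the transcript subsequence (5'->3'); its length must be
    within [len(mirna), len(mirna) + 3].  Returns (expectation, alignment
    strings (miRNA 5'->3', match line, target 3'->5'), and the 0-based index
    *within the window* of the nucleotide paired to miRNA position 10).
    """
    if not mirna or not window:
        raise ValueError("empty miRNA or target window")
    m, wlen = len(mirna), len(window)
    b = wlen - m
    if not (0 <= b <= MAX_BULGE):
        raise ValueError(
            f"window length {wlen} outside [{m}, {m + MAX_BULGE}] for miRNA length {m}"
        )
    mc = _codes(mirna)
    tr = _codes(window)[::-1]     # tr[i] pairs mirna[i] in the ungapped case
    w = _weights(m)
    best = None
    # bulge of b target nt between miRNA positions k and k+1 (k = 0..m)
    ks = [0] if b == 0 else range(0, m + 1)
    for k in ks:
        pen = float(np.sum(_PEN[mc[:k], tr[:k]] * w[:k]))
        pen += float(np.sum(_PEN[mc[k:], tr[k + b :]] * w[k:]))
        if b:
            bulge_w = 2.0 if SEED_START <= min(k + 1, m) <= SEED_END else 1.0
            pen += GAP_PENALTY * b * bulge_w
        if best is None or pen < best[0] - 1e-12:
            best = (pen, k)
    pen, k = best
    # alignment strings (target displayed 3'->5' to lie antiparallel)
    mir_row, match_row, tgt_row = [], [], []
    rev_window = window[::-1]
    ti = 0
    for i in range(m):
        if b and i == k:
            for _ in range(b):
                mir_row.append("-")
                match_row.append(" ")
                tgt_row.append(rev_window[ti])
                ti += 1
        mb, tb = mirna[i].upper(), rev_window[ti]
        p = _PEN[_IDX.get(mb, 4), _IDX.get(tb, 4)]
        mir_row.append(mb)
        tgt_row.append(tb)
        match_row.append("|" if p == 0.0 else ("o" if p == WOBBLE_PENALTY else " "))
        ti += 1
    if b and k == m:
        for _ in range(b):
            mir_row.append("-")
            match_row.append(" ")
            tgt_row.append(rev_window[ti])
            ti += 1
    # window index of the target nt paired to miRNA position 10 (1-based)
    j = 9 + (b if (b and k <= 9) else 0)   # index in reversed window
    cleave_in_window = wlen - 1 - j
    return pen, ("".join(mir_row), "".join(match_row), "".join(tgt_row)), cleave_in_window


def _scan_one(
    mc: np.ndarray, w: np.ndarray, tcodes: np.ndarray, b: int
) -> np.ndarray:
    """Minimum expectation for every start of an (m+b)-window on a transcript,
    minimized over bulge placements; vectorized over starts."""
    m = mc.size
    L = tcodes.size
    n = L - (m + b) + 1
    if n <= 0:
        return np.empty(0)
    # rev[i, s] = target code paired to miRNA position i for window start s,
    # before bulge adjustment: window reversed means mirna[i] pairs
    # tcodes[s + m + b - 1 - i - shift], shift = b for i < bulge point.
    idx = np.arange(n)
    if b == 0:
        pen = np.zeros(n)
        for i in range(m):
            pen += _PEN[mc[i], tcodes[idx + m - 1 - i]] * w[i]
        return pen
    prefix = np.zeros((m + 1, n))
    for i in range(m):
        # miRNA positions before the bulge pair the 3'-most part of the window
        prefix[i + 1] = prefix[i] + _PEN[mc[i], tcodes[idx + m + b - 1 - i]] * w[i]
    suffix = np.zeros((m + 1, n))
    for i in range(m - 1, -1, -1):
        suffix[i] = suffix[i + 1] + _PEN[mc[i], tcodes[idx + m - 1 - i]] * w[i]
    best = np.full(n, np.inf)
    for k in range(0, m + 1):
        bulge_w = 2.0 if SEED_START <= min(k + 1, m) <= SEED_END else 1.0
        cand = prefix[k] + suffix[k] + GAP_PENALTY * b * bulge_w
        np.minimum(best, cand, out=best)
    return best


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 3.0,
) -> list[TargetInteraction]:
    """Score every window of every transcript against every miRNA and keep
    sites with expectation <= cutoff.  Ordering is deterministic:
    (miRNA id, transcript id, position)."""
    if not transcripts:
        raise ValueError("no transcripts supplied")
    interactions: list[TargetInteraction] = []
    tcode_cache = {tid: _codes(seq) for tid, seq in transcripts.items()}
    for mid in sorted(mirnas):
        mature = mirnas[mid].upper().replace("U", "T")
        mc = _codes(mature)
        w = _weights(len(mature))
        m = len(mature)
        for tid in sorted(transcripts):
            tcodes = tcode_cache[tid]
            best_by_start: dict[int, tuple[float, int]] = {}
            for b in range(0, MAX_BULGE + 1):
                pens = _scan_one(mc, w, tcodes, b)
                hits = np.flatnonzero(pens <= cutoff + 1e-9)
                for s in hits:
                    s = int(s)
                    prev = best_by_start.get(s)
                    if prev is None or pens[s] < prev[0] - 1e-12:
                        best_by_start[s] = (float(pens[s]), b)
            for s in sorted(best_by_start):
                pen, b = best_by_start[s]
                window = transcripts[tid][s : s + m + b]
                pen2, aln, cleave_in_win = score_target_site(mature, window)
                cleavage_pos = s + cleave_in_win + 1   # 1-based
                interactions.append(TargetInteraction(
                    mirna_id=mid, transcript_id=tid, start=s, end=s + m + b,
                    expectation=pen2, alignment=aln, cleavage_pos=cleavage_pos,
                ))
    return interactions


# ---------------------------------------------------------------------------
# degradome
# ---------------------------------------------------------------------------

def build_degradome_profile(
    tags: dict[str, int], transcripts: dict[str, str]
) -> dict[str, DegradomeProfile]:
    """Exact-match degradome tags to transcripts (sense strand only) and
    accumulate 5'-end counts; a tag matching several transcripts is counted
    on every one of them."""
    if not tags:
        raise ValueError("no degradome tags supplied")
    profiles = {
        tid: DegradomeProfile(tid, {}, len(seq)) for tid, seq in transcripts.items()
    }
    for tag, count in tags.items():
        tag = tag.upper().replace("U", "T")
        for tid, seq in transcripts.items():
            i = seq.find(tag)
            while i != -1:
                pos = i + 1
                profiles[tid].counts[pos] = profiles[tid].counts.get(pos, 0) + count
                i = seq.find(tag, i + 1)
    return {tid: p for tid, p in profiles.items() if p.counts}


def validate_cleavage(
    interaction: TargetInteraction,
    profile: DegradomeProfile | None,
    window: int = 5,
) -> TargetInteraction:
    """Set degradome status: validated iff some tag 5' end lies within
    ``window`` nt (inclusive) of the predicted cleavage position."""
    if profile is not None and profile.transcript_id != interaction.transcript_id:
        raise ValueError("profile transcript does not match interaction transcript")
    support = 0
    validated = False
    if profile is not None:
        for p, c in profile.counts.items():
            if c > 0 and abs(p - interaction.cleavage_pos) <= window:
                support += c
                validated = True
    interaction.status = "validated" if validated else "unvalidated"
    interaction.tag_support = support
    return interaction


def annotate_pathway_targets(
    interactions: list[TargetInteraction],
    gene_lists: dict[str, list[str]],
) -> dict[str, dict[str, int]]:
    """Flag interactions whose transcript is in a pathway gene list.

    Returns per-pathway summary counts {pathway: {"mirnas": n, "targets": n}}.
    Unknown gene ids in the lists are tolerated.
    """
    sets = {p: set(g) for p, g in gene_lists.items()}
    summary: dict[str, dict[str, set]] = {
        p: {"mirnas": set(), "targets": set()} for p in gene_lists
    }
    for it in interactions:
        it.pathways = []
        for p, genes in sets.items():
            if it.transcript_id in genes:
                it.pathways.append(p)
                summary[p]["mirnas"].add(it.mirna_id)
                summary[p]["targets"].add(it.transcript_id)
    return {
        p: {"mirnas": len(v["mirnas"]), "targets": len(v["targets"])}
        for p, v in summary.items()
    }
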