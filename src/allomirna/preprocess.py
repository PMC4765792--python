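"""Small-RNA library cleaning, ncRNA filtering, and RPM normalization."""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Mapping

from .seqio import SmallRNALibrary, revcomp

#: fixed priority order for ncRNA class tallies when a read matches several
NCRNA_CLASS_ORDER = ("snoRNA", "tRNA", "rRNA", "rasiRNA")


@dataclass
class NcrnaReference:
    """Annotated non-coding RNA sequences used to discard non-miRNA reads."""

    sequences: dict[str, list[str]]

    def __post_init__(self) -> None:
        for cls, seqs in self.sequences.items():
            if any(not s for s in seqs):
                raise ValueError(f"empty reference sequence under class {cls!r}")
        self.sequences = {
            cls: [s.upper().replace("U", "T") for s in seqs]
            for cls, seqs in self.sequences.items()
        }


@dataclass
class FilterReport:
    """Per-class removal tallies from ncRNA filtering."""

    unique_removed: dict[str, int] = field(default_factory=dict)
    count_removed: dict[str, int] = field(default_factory=dict)

    @property
    def total_unique_removed(self) -> int:
        return sum(self.unique_removed.values())


def length_filter(
    library: SmallRNALibrary, min_len: int = 18, max_len: int = 44
) -> SmallRNALibrary:
    """Drop reads outside [min_len, max_len] and refresh the clean-read total.

    The retained count sum becomes the library's clean-read total: that total
    is the RPM denominator for everything downstream.
    """
    if not (0 < min_len <= max_len):
        raise ValueError(f"invalid length bounds [{min_len}, {max_len}]")
    kept = {
        seq: n for seq, n in library.unique_reads.items() if min_len <= len(seq) <= max_len
    }
    return replace(library, unique_reads=kept, clean_read_total=sum(kept.values()))


def filter_ncrna(
    library: SmallRNALibrary, reference: NcrnaReference
) -> tuple[SmallRNALibrary, FilterReport]:
    """Remove reads that match annotated non-coding RNAs.

    A read is removed when it is an exact substring of any reference sequence
    on either strand (U and T equivalent).  A read matching several classes
    is tallied once, under the first matching class in the fixed order
    snoRNA < tRNA < rRNA < rasiRNA.  The clean-read total is left unchanged
    (the RPM denominator is the post-length-filter total).
    """
    haystacks: dict[str, str] = {}
    for cls in NCRNA_CLASS_ORDER:
        seqs = reference.sequences.get(cls, [])
        haystacks[cls] = "#".join(seqs + [revcomp(s) for s in seqs])
    report = FilterReport(
        unique_removed={c: 0 for c in NCRNA_CLASS_ORDER},
        count_removed={c: 0 for c in NCRNA_CLASS_ORDER},
    )
    kept: dict[str, int] = {}
    for seq, n in library.unique_reads.items():
        hit = None
        for cls in NCRNA_CLASS_ORDER:
            if haystacks[cls] and seq in haystacks[cls]:
                hit = cls
                break
        if hit is None:
            kept[seq] = n
        else:
            report.unique_removed[hit] += 1
            report.count_removed[hit] += n
    return replace(library, unique_reads=kept), report


def compute_rpm(count: int, clean_total: int) -> float:
    """Reads-per-million: count / clean_total * 1e6."""
    if clean_total <= 0:
        raise ValueError("clean_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / clean_total * 1e6


def library_rpm(library: SmallRNALibrary) -> Mapping[str, float]:
    """RPM for every unique read of a library."""
    return {
        seq: compute_rpm(n, library.clean_read_total)
        for seq, n in library.unique_reads.items()
    }
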