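"""Sequence and annotation I/O plus exact read-to-genome mapping.

All genomic intervals are 0-based half-open in memory and 1-based inclusive
on disk (GFF3 convention).  Small-RNA libraries use the collapsed-FASTA
dialect ``>id_x{count}`` where ``count`` is the copy number of the read.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")
_VALID_READ = re.compile(r"^[ACGTUN]+$")


def revcomp(seq: str) -> str:
    """Reverse complement (U treated as A-pairing, output in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenomeSet:
    """Labelled chromosome sequences with subgenome assignment.

    ``subgenome_of`` maps every chromosome id to ``"A"``, ``"C"`` or
    ``"unplaced"``; this partition is the coordinate frame for every locus in
    the pipeline.
    """

    records: dict[str, str]
    subgenome_of: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {cid!r}")
        missing = set(self.records) - set(self.subgenome_of)
        if missing:
            raise ValueError(f"chromosomes without subgenome label: {sorted(missing)}")

    def subgenome_length(self, label: str) -> int:
        return sum(
            len(s) for c, s in self.records.items() if self.subgenome_of[c] == label
        )

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.records)


@dataclass
class SmallRNALibrary:
    """Collapsed unique reads with counts and library metadata."""

    library_id: str
    line: str
    tissue: str
    environment: str
    unique_reads: dict[str, int]
    clean_read_total: int

    def __post_init__(self) -> None:
        total = sum(self.unique_reads.values())
        if self.clean_read_total < total:
            raise ValueError(
                f"clean_read_total {self.clean_read_total} < summed counts {total}"
            )

    @property
    def n_reads(self) -> int:
        return sum(self.unique_reads.values())


@dataclass(frozen=True, order=True)
class Alignment:
    """One exact placement of a read on the genome (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    strand: str
    read: str = field(compare=False)
    exact: bool = field(default=True, compare=False)


@dataclass(frozen=True)
class Gff3Feature:
    seqid: str
    source: str
    ftype: str
    start: int  # 0-based
    end: int    # exclusive
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> sequence mapping.

    Raises on duplicate ids or empty sequences.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA id {rec.id!r} in {path}")
        out[rec.id] = seq
    return out


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


_COLLAPSED = re.compile(r"_x(\d+)$")


def read_collapsed_fasta(path: str | Path) -> dict[str, int]:
    """Read collapsed small-RNA reads ``>id_x{count}`` into seq -> count.

    Identical sequences appearing under several ids are summed.
    """
    counts: dict[str, int] = {}
    for lineno_id, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        m = _COLLAPSED.search(rec.id)
        if not m:
            raise ValueError(
                f"malformed collapsed-read header {rec.id!r} (record {lineno_id} in "
                f"{path}): expected suffix _x<count>"
            )
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise ValueError(f"empty read sequence for {rec.id!r} in {path}")
        counts[seq] = counts.get(seq, 0) + int(m.group(1))
    return counts


def write_collapsed_fasta(
    counts: Mapping[str, int], path: str | Path, prefix: str = "srr"
) -> None:
    with open(path, "w") as fh:
        for i, (seq, count) in enumerate(counts.items(), start=1):
            fh.write(f">{prefix}{i}_x{count}\n{seq}\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-", ".", "?"}


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def _format_attributes(attrs: Mapping[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    """Read a 9-column GFF3 file; coordinates converted to 0-based half-open."""
    feats: list[Gff3Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            start1, end1 = int(cols[3]), int(cols[4])
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start {start1} > end {end1}")
            if cols[6] not in _STRANDS:
                raise ValueError(f"{path}:{lineno}: unknown strand {cols[6]!r}")
            feats.append(
                Gff3Feature(
                    seqid=cols[0], source=cols[1], ftype=cols[2],
                    start=start1 - 1, end=end1, score=cols[5], strand=cols[6],
                    phase=cols[7], attributes=_parse_attributes(cols[8]),
                )
            )
    return feats


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.seqid, f.source, f.ftype,
                        str(f.start + 1), str(f.end), f.score, f.strand, f.phase,
                        _format_attributes(f.attributes),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Exact mapping
# ---------------------------------------------------------------------------

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """2-bit-code array; N and any non-ACGT byte become 255 (never matches)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class GenomeIndex:
    """Sorted k-mer index over the forward strands of a genome.

    Positions containing N (or any non-ACGT character) are excluded, so reads
    never match through N.  Queries return all exact occurrences of a read on
    both strands.
    """

    def __init__(self, genome: GenomeSet, k: int = 18):
        self.genome = genome
        self.k = k
        self._chrom_ids: list[str] = genome.chromosomes
        self._offsets: dict[str, int] = {}
        codes_list = []
        off = 0
        for cid in self._chrom_ids:
            self._offsets[cid] = off
            codes_list.append(_encode(genome.records[cid]))
            off += len(genome.records[cid])
        self._codes = np.concatenate(codes_list) if codes_list else np.empty(0, np.uint8)
        self._bounds = np.array(
            [self._offsets[c] for c in self._chrom_ids] + [off], dtype=np.int64
        )
        kmers, pos = self._build(self._codes, k)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._pos = pos[order]

    @staticmethod
    def _build(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
        n = codes.size
        if n < k:
            return np.empty(0, np.uint64), np.empty(0, np.int64)
        valid = codes != 255
        ok = np.ones(n - k + 1, dtype=bool)
        # a window is valid iff all k positions are ACGT
        bad = np.flatnonzero(~valid)
        for b in bad:
            lo = max(0, b - k + 1)
            ok[lo : min(b + 1, n - k + 1)] = False
        vals = codes.astype(np.uint64)
        km = np.zeros(n - k + 1, dtype=np.uint64)
        for i in range(k):
            km = (km << np.uint64(2)) | vals[i : n - k + 1 + i]
        pos = np.flatnonzero(ok).astype(np.int64)
        return km[ok], pos

    def _chrom_of(self, gpos: int) -> tuple[str, int]:
        idx = int(np.searchsorted(self._bounds, gpos, side="right")) - 1
        cid = self._chrom_ids[idx]
        return cid, gpos - self._offsets[cid]

    def _seed_positions(self, kmer_int: int) -> np.ndarray:
        key = np.uint64(kmer_int)
        lo = int(np.searchsorted(self._kmers, key, side="left"))
        hi = int(np.searchsorted(self._kmers, key, side="right"))
        return self._pos[lo:hi]

    def find(self, read: str) -> list[Alignment]:
        """All exact occurrences of ``read`` on both strands."""
        read = read.upper().replace("U", "T")
        if not _VALID_READ.match(read):
            raise ValueError(f"read contains invalid characters: {read!r}")
        if len(read) < self.k or "N" in read:
            return self._find_slow(read)
        hits: set[tuple[str, int, str]] = set()
        for strand, query in (("+", read), ("-", revcomp(read))):
            qcodes = _encode(query)
            kint = 0
            for c in qcodes[: self.k]:
                kint = (kint << 2) | int(c)
            L = len(query)
            for gpos in self._seed_positions(kint):
                gpos = int(gpos)
                if gpos + L > self._codes.size:
                    continue
                if np.array_equal(self._codes[gpos : gpos + L], qcodes):
                    cid, cpos = self._chrom_of(gpos)
                    if cpos + L <= len(self.genome.records[cid]):
                        hits.add((cid, cpos, strand))
        return [
            Alignment(chromosome=c, start=s, end=s + len(read), strand=st, read=read)
            for c, s, st in sorted(hits)
        ]

    def _find_slow(self, read: str) -> list[Alignment]:
        # fallback for reads shorter than k (naive scan)
        out = []
        if "N" in read:
            return out
        for strand, query in (("+", read), ("-", revcomp(read))):
            for cid in self._chrom_ids:
                seq = self.genome.records[cid]
                i = seq.find(query)
                while i != -1:
                    out.append(
                        Alignment(
                            chromosome=cid, start=i, end=i + len(read),
                            strand=strand, read=read,
                        )
                    )
                    i = seq.find(query, i + 1)
        return sorted(out)


def map_reads_exact(
    library: SmallRNALibrary,
    genome: GenomeSet,
    index: GenomeIndex | None = None,
) -> dict[str, list[Alignment]]:
    """Map every unique read of a library to all its exact genomic positions.

    Reads with no hit map to an empty list (flagged unmapped).  Ordering of
    alignments is deterministic: (chromosome, start, strand).
    """
    if not genome.records:
        raise ValueError("genome is empty")
    if index is None:
        index = GenomeIndex(genome)
    return {read: index.find(read) for read in library.unique_reads}


def alignments_to_bed(
    alignments: Mapping[str, list[Alignment]],
    counts: Mapping[str, int],
    path: str | Path,
) -> None:
    """Export alignments as 6-column BED (chrom, start, end, read, count, strand)."""
    rows = []
    for read, alns in alignments.items():
        for a in alns:
            rows.append((a.chromosome, a.start, a.end, read, counts.get(read, 0), a.strand))
    rows.sort()
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")
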