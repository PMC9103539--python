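"""Ungapped short-read alignment to a single locus with at most k mismatches.

The mapping contract is exact: a read is placed at every offset where the
Hamming distance between the (possibly reverse-complemented) read and the
locus substring is at most k. Candidates are found with the pigeonhole
principle — a placement with ≤ k mismatches must contain at least one of
k+1 contiguous read blocks exactly matching the locus — and verified by
full comparison, so the reported set equals the exhaustive scan's.

`N` matches nothing: any position where either the read or the locus shows
`N` counts as a mismatch, which keeps N-rich reads from inflating coverage.

Alignment positions are offsets into the locus sequence (0-based); the
absolute genomic coordinate is ``locus.start + position``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO

from .intervals import GenomicInterval, LocusSpec

logger = logging.getLogger("ernascan")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    origin: GenomicInterval | None = None  # ground truth, synthetic reads only


@dataclass(frozen=True)
class AlignmentRecord:
    read_id: str
    position: int  # 0-based offset on the locus sequence
    strand: str  # "+" or "-"
    mismatches: int
    is_multi: bool = False


@dataclass(frozen=True)
class MapperConfig:
    max_mismatch: int = 1
    report_policy: str = "all_hits"  # or "best_only"
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatch < 0:
            raise ValueError("max_mismatch must be >= 0")
        if self.report_policy not in ("all_hits", "best_only"):
            raise ValueError(f"unknown report_policy {self.report_policy!r}")


def hamming(a: str, b: str) -> int:
    """Mismatch count under the N-matches-nothing metric."""
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


class LocusIndex:
    """Exact-substring index over the locus for pigeonhole seeding.

    For each block length requested, a dictionary from every locus k-mer of
    that length to its start offsets is built once and cached. K-mers
    containing N are excluded: an N position is a mismatch by definition,
    so an exact (0-mismatch) block is necessarily N-free on both sides.
    """

    def __init__(self, sequence: str):
        self.sequence = sequence.upper()
        self._by_length: dict[int, dict[str, list[int]]] = {}

    def _index_for(self, length: int) -> dict[str, list[int]]:
        idx = self._by_length.get(length)
        if idx is None:
            idx = {}
            seq = self.sequence
            for pos in range(len(seq) - length + 1):
                kmer = seq[pos : pos + length]
                if "N" in kmer:
                    continue
                idx.setdefault(kmer, []).append(pos)
            self._by_length[length] = idx
        return idx

    def exact_hits(self, block: str) -> list[int]:
        if "N" in block:
            return []
        return self._index_for(len(block)).get(block, [])


def _split_blocks(length: int, k: int) -> list[tuple[int, int]]:
    """Split [0, length) into k+1 contiguous blocks of near-equal size."""
    n_blocks = k + 1
    base, extra = divmod(length, n_blocks)
    offsets, pos = [], 0
    for i in range(n_blocks):
        size = base + (1 if i < extra else 0)
        offsets.append((pos, pos + size))
        pos += size
    return offsets


def _align_oriented(seq: str, index: LocusIndex, k: int) -> list[tuple[int, int]]:
    """All (position, mismatches) placements of an oriented sequence."""
    locus = index.sequence
    read_len = len(seq)
    if read_len > len(locus):
        return []
    candidates: set[int] = set()
    for b_start, b_end in _split_blocks(read_len, k):
        for pos in index.exact_hits(seq[b_start:b_end]):
            start = pos - b_start
            if 0 <= start <= len(locus) - read_len:
                candidates.add(start)
    hits = []
    for start in candidates:
        mm = hamming(seq, locus[start : start + read_len])
        if mm <= k:
            hits.append((start, mm))
    return hits


def align_read(
    read: ReadRecord,
    locus_sequence: str | LocusIndex,
    config: MapperConfig = MapperConfig(),
) -> list[AlignmentRecord]:
    """All ungapped placements of one read with Hamming distance ≤ k.

    Under ``best_only`` only the minimum-mismatch placements are reported.
    ``is_multi`` flags reads with more than one surviving placement. Ties
    are ordered by position ascending, then '+' before '-'.
    """
    if not read.sequence:
        raise ValueError(f"read {read.read_id} has an empty sequence")
    k = config.max_mismatch
    if len(read.sequence) < 2 * (k + 1):
        logger.warning(
            "read %s shorter than %d bp, too short for k=%d; rejected",
            read.read_id, 2 * (k + 1), k,
        )
        return []
    index = locus_sequence if isinstance(locus_sequence, LocusIndex) else LocusIndex(locus_sequence)
    if len(read.sequence) > len(index.sequence):
        raise ValueError("read longer than locus sequence")

    seq = read.sequence.upper()
    placements = [(pos, "+", mm) for pos, mm in _align_oriented(seq, index, k)]
    if config.search_both_strands:
        placements += [
            (pos, "-", mm) for pos, mm in _align_oriented(reverse_complement(seq), index, k)
        ]
    if config.report_policy == "best_only" and placements:
        best = min(mm for _, _, mm in placements)
        placements = [p for p in placements if p[2] == best]
    placements.sort(key=lambda p: (p[0], p[1]))
    multi = len(placements) > 1
    return [
        AlignmentRecord(read.read_id, pos, strand, mm, is_multi=multi)
        for pos, strand, mm in placements
    ]


def align_all(
    reads: Sequence[ReadRecord],
    locus_sequence: str | LocusIndex,
    config: MapperConfig = MapperConfig(),
) -> list[AlignmentRecord]:
    """Align a batch of reads; order is deterministic (read order, then position).

    A single bad read (short/empty) never aborts the batch.
    """
    index = locus_sequence if isinstance(locus_sequence, LocusIndex) else LocusIndex(locus_sequence)
    out: list[AlignmentRecord] = []
    for read in reads:
        try:
            out.extend(align_read(read, index, config))
        except ValueError as exc:
            logger.warning("read %s skipped: %s", read.read_id, exc)
    return out


# ---------------------------------------------------------------------------
# FASTQ / SAM I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read FASTQ reads (quality values parsed by Biopython but unused)."""
    return [
        ReadRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


def _sam_header(locus: LocusSpec) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": locus.chrom, "LN": locus.length}],
        }
    )


def write_sam(
    alignments: Sequence[AlignmentRecord],
    locus: LocusSpec,
    path: str | Path,
    read_sequences: dict[str, str] | None = None,
    read_lengths: dict[str, int] | int | None = None,
) -> None:
    """Write alignments as SAM (POS 1-based per the standard, NM = mismatches).

    Reference coordinates are offsets into the locus sequence; the @SQ line
    describes the locus contig. Sequences are emitted when provided; with
    only ``read_lengths`` SEQ stays '*' but the (ungapped) CIGAR is still
    written, which keeps the records mapped for downstream SAM consumers.
    """
    header = _sam_header(locus)
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = aln.read_id
            seg.reference_id = 0
            seg.reference_start = aln.position  # pysam is 0-based; POS written 1-based
            seg.flag = 16 if aln.strand == "-" else 0
            seg.mapping_quality = 255
            seq = (read_sequences or {}).get(aln.read_id)
            if seq is not None:
                oriented = reverse_complement(seq) if aln.strand == "-" else seq
                seg.query_sequence = oriented
                seg.cigarstring = f"{len(seq)}M"
            elif read_lengths is not None:
                length = read_lengths if isinstance(read_lengths, int) else read_lengths[aln.read_id]
                seg.cigarstring = f"{length}M"
            else:
                raise ValueError(
                    "write_sam needs read_sequences or read_lengths to emit a CIGAR"
                )
            seg.set_tag("NM", aln.mismatches)
            seg.set_tag("XM", 1 if aln.is_multi else 0)
            sam.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    """Read ungapped alignments from SAM; returns (records, n_skipped).

    Records whose CIGAR contains anything other than match operations
    (insertions, deletions, splices, clips) are skipped with a counted
    warning: the screen's model is strictly ungapped. Externally produced
    SAM can therefore be imported to bypass the internal mapper.
    """
    records: list[AlignmentRecord] = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_unmapped:
                continue
            if seg.cigartuples and any(op not in (0, 7, 8) for op, _ in seg.cigartuples):
                skipped += 1
                continue
            nm = seg.get_tag("NM") if seg.has_tag("NM") else 0
            xm = seg.get_tag("XM") if seg.has_tag("XM") else 0
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    position=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    mismatches=int(nm),
                    is_multi=bool(xm),
                )
            )
    if skipped:
        logger.warning("read_sam: skipped %d gapped/clipped records (ungapped model)", skipped)
    return records, skipped
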