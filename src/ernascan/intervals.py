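"""Genomic interval model, interval algebra, and positional file I/O.

All internal coordinates are 0-based half-open; conversion to and from
1-based closed coordinates happens only at the GTF boundary. The pipeline
universe is a single locus of a couple of megabases, so no interval index
is needed: linear scans and sorts are exact and fast at this scale.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

logger = logging.getLogger("ernascan")

STRANDS = ("+", "-", ".")


class Stage(enum.IntEnum):
    """Funnel stages a candidate region moves through, strictly forward."""

    CONSTRUCTED = 0
    COVERED = 1
    MERGED = 2
    DENSE_SUBREGION = 3
    REPEAT_FREE = 4
    ANNOTATED = 5


class RepeatClass(enum.Enum):
    SINE = "SINE"
    LINE = "LINE"
    LTR = "LTR"
    DNA = "DNA"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "RepeatClass":
        """Parse a repeat-class label; anything unrecognized is ``other``.

        ``other`` never triggers filtering downstream, so an unknown label
        degrades safely rather than silently masking a region.
        """
        norm = label.strip().upper()
        for member in (cls.SINE, cls.LINE, cls.LTR, cls.DNA):
            if norm == member.value:
                return member
        return cls.OTHER


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval must have start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def intersect_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class LocusSpec:
    """The genomic window the whole screen operates in."""

    chrom: str
    start: int
    end: int
    genome_build: str = "hg38"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("locus must have start < end")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_position(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, interval: GenomicInterval) -> bool:
        return (
            interval.chrom == self.chrom
            and interval.start >= self.start
            and interval.end <= self.end
        )


@dataclass(frozen=True)
class PeakRecord:
    """An enhancer ChIP-seq peak; either a full region or a point summit.

    Published enhancer-RNA catalogues distribute regions rather than
    summits, so for an interval-shaped peak the summit is taken as the
    midpoint, rounded down (deterministic).
    """

    interval: GenomicInterval
    source_label: str = ""

    @property
    def summit(self) -> int:
        return (self.interval.start + self.interval.end - 1) // 2


@dataclass(frozen=True)
class CandidateRegion:
    """A candidate eRNA interval carrying its stage history through the funnel."""

    interval: GenomicInterval
    stage: Stage
    region_id: str
    parent_ids: tuple[str, ...] = ()
    read_count: int = 0

    def advance(self, stage: Stage, **changes) -> "CandidateRegion":
        """Return a copy at a later stage; backwards transitions are bugs."""
        if stage < self.stage:
            raise ValueError(
                f"stage may only move forward: {self.stage.name} -> {stage.name}"
            )
        return dataclasses.replace(self, stage=stage, **changes)


@dataclass(frozen=True)
class RepeatRecord:
    interval: GenomicInterval
    repeat_class: RepeatClass


@dataclass(frozen=True)
class TranscriptRecord:
    """An annotated transcript; exons sorted, non-overlapping, non-empty."""

    transcript_id: str
    gene_name: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.transcript_id} exons must be sorted and disjoint"
                )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end
        )


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def build_candidate_regions(
    peaks: Sequence[PeakRecord], flank: int, locus: LocusSpec
) -> list[CandidateRegion]:
    """Expand each peak summit into a [summit - flank, summit + flank) window.

    Windows are clipped to the locus; a summit outside the locus is skipped
    with a warning rather than raised, so a stray record in an external peak
    file does not abort a run.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    regions: list[CandidateRegion] = []
    for i, peak in enumerate(peaks):
        summit = peak.summit
        if not locus.contains_position(summit):
            logger.warning(
                "peak %s summit %d outside locus %s:%d-%d; skipped",
                peak.source_label or i, summit, locus.chrom, locus.start, locus.end,
            )
            continue
        start = max(locus.start, summit - flank)
        end = min(locus.end, summit + flank)
        regions.append(
            CandidateRegion(
                interval=GenomicInterval(locus.chrom, start, end),
                stage=Stage.CONSTRUCTED,
                region_id=f"peak_{i}",
                parent_ids=(peak.source_label or f"peak_{i}",),
            )
        )
    return regions


def merge_regions(
    regions: Sequence[CandidateRegion], merge_touching: bool = True
) -> list[CandidateRegion]:
    """Combine overlapping (and, by default, bookended) regions.

    Output intervals are pairwise disjoint, sorted by start, and their union
    covers exactly the union of the inputs; parent region ids are preserved
    on each merged record and read counts are summed.
    """
    if not regions:
        return []
    chroms = {r.interval.chrom for r in regions}
    if len(chroms) > 1:
        offender = next(r for r in regions if r.interval.chrom != regions[0].interval.chrom)
        raise ValueError(
            f"merge_regions requires a single chromosome; {offender.region_id} "
            f"is on {offender.interval.chrom}"
        )
    ordered = sorted(regions, key=lambda r: (r.interval.start, r.interval.end, r.region_id))
    clusters: list[list[CandidateRegion]] = [[ordered[0]]]
    for reg in ordered[1:]:
        cur_end = max(r.interval.end for r in clusters[-1])
        joined = reg.interval.start <= cur_end if merge_touching else reg.interval.start < cur_end
        if joined:
            clusters[-1].append(reg)
        else:
            clusters.append([reg])
    merged: list[CandidateRegion] = []
    for i, cluster in enumerate(clusters):
        start = min(r.interval.start for r in cluster)
        end = max(r.interval.end for r in cluster)
        parents = tuple(sorted({p for r in cluster for p in (r.region_id,)}))
        merged.append(
            CandidateRegion(
                interval=GenomicInterval(cluster[0].interval.chrom, start, end),
                stage=Stage.MERGED,
                region_id=f"merged_{i}",
                parent_ids=parents,
                read_count=sum(r.read_count for r in cluster),
            )
        )
    return merged


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b``; 0 when disjoint, 1 when a ⊆ b."""
    if a.chrom != b.chrom:
        raise ValueError("overlap_fraction requires intervals on the same chromosome")
    return a.intersect_length(b) / a.length


def union_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total number of bases covered by the union of the intervals."""
    spans = sorted((iv.start, iv.end) for iv in intervals)
    total = 0
    cur_start, cur_end = None, None
    for s, e in spans:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def covered_bases(target: GenomicInterval, intervals: Iterable[GenomicInterval]) -> int:
    """Bases of ``target`` covered by the union of ``intervals``."""
    clipped = []
    for iv in intervals:
        if iv.chrom != target.chrom:
            continue
        s, e = max(iv.start, target.start), min(iv.end, target.end)
        if s < e:
            clipped.append(GenomicInterval(target.chrom, s, e))
    return union_length(clipped)


# ---------------------------------------------------------------------------
# File I/O: BED, GTF, FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BedRecord:
    interval: GenomicInterval
    name: str = ""


def read_bed(path: str | Path) -> list[BedRecord]:
    """Read a minimal BED (3+ columns, 0-based half-open).

    Column 4, when present, is carried as the record name (used for peak
    labels and repeat-class labels). Malformed lines raise with their line
    number; an unknown strand symbol downgrades to unstranded with a warning.
    """
    records: list[BedRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in STRANDS:
                logger.warning("%s:%d: unknown strand %r treated as unstranded", path, lineno, strand)
                strand = "."
            try:
                interval = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            records.append(BedRecord(interval, fields[3] if len(fields) > 3 else ""))
    return records


def write_bed(records: Iterable[BedRecord], path: str | Path) -> None:
    """Write BED records; round-trips bit-exact through :func:`read_bed`."""
    with open(path, "w") as fh:
        for rec in records:
            iv = rec.interval
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if rec.name or iv.strand != ".":
                cols.append(rec.name)
            if iv.strand != ".":
                cols.extend(["0", iv.strand])
            fh.write("\t".join(cols) + "\n")


def peaks_from_bed(records: Iterable[BedRecord]) -> list[PeakRecord]:
    return [PeakRecord(rec.interval, rec.name) for rec in records]


def repeats_from_bed(records: Iterable[BedRecord]) -> list[RepeatRecord]:
    return [RepeatRecord(rec.interval, RepeatClass.parse(rec.name)) for rec in records]


def read_gtf_transcripts(path: str | Path) -> list[TranscriptRecord]:
    """Read transcripts with exon structure from a GTF file.

    GTF is 1-based closed; exons are converted to the internal 0-based
    half-open convention on read.
    """
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes.get("transcript_id", ["?"])[0]
        entry = by_tx.setdefault(
            tx_id,
            {
                "gene": exon.attributes.get("gene_name", exon.attributes.get("gene_id", [""]))[0],
                "biotype": exon.attributes.get("transcript_biotype", [""])[0],
                "exons": [],
            },
        )
        strand = exon.strand if exon.strand in STRANDS else "."
        entry["exons"].append(GenomicInterval(exon.seqid, exon.start - 1, exon.end, strand))
    return [
        TranscriptRecord(
            transcript_id=tx_id,
            gene_name=entry["gene"],
            exons=tuple(sorted(entry["exons"], key=lambda e: e.start)),
            biotype=entry["biotype"],
        )
        for tx_id, entry in sorted(by_tx.items())
    ]


def write_gtf_transcripts(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcript/exon GTF lines (1-based closed on output)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_name}"; transcript_id "{tx.transcript_id}"; '
                f'gene_name "{tx.gene_name}"; transcript_biotype "{tx.biotype}";'
            )
            span = tx.span
            strand = tx.exons[0].strand if tx.exons[0].strand != "." else "+"
            fh.write(
                "\t".join(
                    [span.chrom, "ernascan", "transcript", str(span.start + 1),
                     str(span.end), ".", strand, ".", attrs]
                ) + "\n"
            )
            for exon in tx.exons:
                fh.write(
                    "\t".join(
                        [exon.chrom, "ernascan", "exon", str(exon.start + 1),
                         str(exon.end), ".", strand, ".", attrs]
                    ) + "\n"
                )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into a {name: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
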