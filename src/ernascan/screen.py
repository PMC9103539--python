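"""The candidate eRNA screening funnel.

Stages, in the order the screen runs them:

1. construct   — expand enhancer peak summits into fixed ±flank windows;
2. covered     — drop windows with zero aligned reads;
3. merge       — combine overlapping covered windows;
4. dense       — delineate densely covered sub-regions (the probable
                 transcript) inside each merged region;
5. repeat_free — discard sub-regions overlapping interspersed repeats
                 (SINE/LINE/LTR/DNA), then keep regions with at least one
                 surviving, uniquely-targetable sub-region;
6. annotate    — intersect surviving sub-regions with annotated lncRNA
                 exons; unmatched survivors are reported as novel.

"Densely covered" is formalized as a run-bridging rule with three
parameters: minimum per-base depth c, minimum sub-region length L, and the
maximum below-threshold gap g bridged inside a sub-region. All three are
exposed in :class:`DenseParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import AlignmentRecord, MapperConfig, ReadRecord, align_all
from .intervals import (
    CandidateRegion,
    GenomicInterval,
    LocusSpec,
    PeakRecord,
    RepeatClass,
    RepeatRecord,
    Stage,
    TranscriptRecord,
    build_candidate_regions,
    covered_bases,
    merge_regions,
)

logger = logging.getLogger("ernascan")

FILTERED_CLASSES = frozenset(
    {RepeatClass.SINE, RepeatClass.LINE, RepeatClass.LTR, RepeatClass.DNA}
)


@dataclass(frozen=True)
class DenseParams:
    """Thresholds defining a densely covered sub-region."""

    min_cov: int = 5  # c: minimum per-base read depth
    min_len: int = 100  # L: minimum sub-region length, bp
    max_gap: int = 50  # g: longest below-threshold run bridged, bp

    def __post_init__(self) -> None:
        if self.min_cov < 1 or self.min_len < 1 or self.max_gap < 0:
            raise ValueError("require min_cov >= 1, min_len >= 1, max_gap >= 0")


@dataclass(frozen=True)
class RepeatFilterParams:
    """Repeat-overlap tolerance; the default is strict any-overlap exclusion."""

    max_overlap_frac: float = 0.0
    classes: frozenset[RepeatClass] = FILTERED_CLASSES

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_overlap_frac <= 1.0:
            raise ValueError("max_overlap_frac must be in [0, 1]")


@dataclass
class CoverageTrack:
    """Per-base read depth over the locus (index i = locus.start + i)."""

    locus: LocusSpec
    depth: np.ndarray

    def slice(self, interval: GenomicInterval) -> np.ndarray:
        return self.depth[interval.start - self.locus.start : interval.end - self.locus.start]


@dataclass
class ScreenFunnel:
    """Ordered per-stage survivor counts and identifiers."""

    stage_names: list[str] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)
    survivor_ids: list[tuple[str, ...]] = field(default_factory=list)

    def add(self, name: str, regions: list[CandidateRegion]) -> None:
        self.stage_names.append(name)
        self.counts.append(len(regions))
        self.survivor_ids.append(tuple(r.region_id for r in regions))

    def to_rows(self) -> list[dict]:
        return [
            {"stage": s, "surviving_regions": c, "region_ids": ",".join(ids)}
            for s, c, ids in zip(self.stage_names, self.counts, self.survivor_ids)
        ]


@dataclass
class ScreenResult:
    funnel: ScreenFunnel
    stage_regions: dict[str, list[CandidateRegion]]
    dense_subregions: list[CandidateRegion]
    surviving_subregions: list[CandidateRegion]
    annotation: list[tuple[CandidateRegion, list[TranscriptRecord]]]
    candidates: list[CandidateRegion]
    coverage: CoverageTrack


def _read_length(read_lengths: dict[str, int] | int, read_id: str) -> int:
    if isinstance(read_lengths, int):
        return read_lengths
    return read_lengths[read_id]


def compute_coverage(
    alignments: list[AlignmentRecord],
    read_lengths: dict[str, int] | int,
    locus: LocusSpec,
) -> CoverageTrack:
    """Per-base depth; conserves Σ depth = Σ aligned read lengths.

    Built as a difference array with a prefix sum. An alignment extending
    past the locus end is an error: the internal mapper cannot produce one,
    so it signals a mismatched locus/SAM pair.
    """
    diff = np.zeros(locus.length + 1, dtype=np.int64)
    for aln in alignments:
        length = _read_length(read_lengths, aln.read_id)
        if aln.position < 0 or aln.position + length > locus.length:
            raise ValueError(
                f"alignment of {aln.read_id} at {aln.position} (+{length} bp) "
                f"extends outside the locus"
            )
        diff[aln.position] += 1
        diff[aln.position + length] -= 1
    return CoverageTrack(locus, np.cumsum(diff[:-1]))


def drop_zero_read_regions(
    regions: list[CandidateRegion],
    alignments: list[AlignmentRecord],
    read_lengths: dict[str, int] | int,
    locus: LocusSpec,
) -> list[CandidateRegion]:
    """Keep regions overlapped by at least one alignment by ≥ 1 bp."""
    if alignments:
        starts = np.array([locus.start + a.position for a in alignments])
        ends = np.array(
            [locus.start + a.position + _read_length(read_lengths, a.read_id) for a in alignments]
        )
    else:
        starts = ends = np.empty(0, dtype=int)
    survivors = []
    for region in regions:
        count = int(((ends > region.interval.start) & (starts < region.interval.end)).sum())
        if count > 0:
            survivors.append(region.advance(Stage.COVERED, read_count=count))
    return survivors


def detect_dense_subregions(
    track: CoverageTrack,
    region: CandidateRegion,
    params: DenseParams = DenseParams(),
) -> list[CandidateRegion]:
    """Maximal runs with depth ≥ c, bridging sub-threshold gaps ≤ g.

    Sub-region endpoints always sit on bases with depth ≥ c (bridging never
    extends past the outermost above-threshold base) and runs shorter than
    L after bridging are dropped. Output sub-regions are disjoint, sorted
    and contained in the region.
    """
    depth = track.slice(region.interval)
    above = depth >= params.min_cov
    if not above.any():
        return []
    # Runs of consecutive above-threshold bases as (start, end) offsets.
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = list(zip(edges[0::2], edges[1::2]))
    bridged: list[list[int]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - bridged[-1][1] <= params.max_gap:
            bridged[-1][1] = e
        else:
            bridged.append([s, e])
    out = []
    base = region.interval.start
    for i, (s, e) in enumerate(bridged):
        if e - s >= params.min_len:
            out.append(
                CandidateRegion(
                    interval=GenomicInterval(region.interval.chrom, base + int(s), base + int(e)),
                    stage=Stage.DENSE_SUBREGION,
                    region_id=f"{region.region_id}.sub_{i}",
                    parent_ids=(region.region_id,),
                )
            )
    return out


def filter_repeats(
    subregions: list[CandidateRegion],
    repeats: list[RepeatRecord],
    params: RepeatFilterParams = RepeatFilterParams(),
) -> list[CandidateRegion]:
    """Drop sub-regions whose repeat-overlap fraction exceeds the tolerance.

    The overlap fraction is computed against the union of repeats in the
    filtered classes; class ``other`` never filters.
    """
    filtered_ivs = [r.interval for r in repeats if r.repeat_class in params.classes]
    survivors = []
    for sub in subregions:
        frac = covered_bases(sub.interval, filtered_ivs) / sub.interval.length
        if frac <= params.max_overlap_frac:
            survivors.append(sub.advance(Stage.REPEAT_FREE))
    return survivors


def region_uniqueness_verdict(
    regions: list[CandidateRegion], surviving_subregions: list[CandidateRegion]
) -> list[CandidateRegion]:
    """A merged region survives iff ≥ 1 of its sub-regions passed the repeat filter."""
    alive = {p for sub in surviving_subregions for p in sub.parent_ids}
    return [r.advance(Stage.REPEAT_FREE) for r in regions if r.region_id in alive]


def annotate_candidates(
    subregions: list[CandidateRegion], transcripts: list[TranscriptRecord]
) -> list[tuple[CandidateRegion, list[TranscriptRecord]]]:
    """Match sub-regions to transcripts by ≥ 1 bp exon overlap.

    Intron-only overlap does not count: a spliced, unidirectional eRNA is
    evidenced by exonic reads. Unmatched sub-regions come back with an
    empty transcript list ("novel, unannotated").
    """
    out = []
    for sub in subregions:
        matches = [
            tx
            for tx in transcripts
            if any(sub.interval.overlaps(exon) for exon in tx.exons)
        ]
        region = sub.advance(Stage.ANNOTATED) if matches else sub
        out.append((region, matches))
    return out


def run_screen(
    peaks: list[PeakRecord],
    locus: LocusSpec,
    repeats: list[RepeatRecord],
    transcripts: list[TranscriptRecord],
    locus_sequence: str | None = None,
    reads: list[ReadRecord] | None = None,
    alignments: list[AlignmentRecord] | None = None,
    read_lengths: dict[str, int] | int | None = None,
    flank: int = 3000,
    mapper: MapperConfig = MapperConfig(),
    dense: DenseParams = DenseParams(),
    repeat_filter: RepeatFilterParams = RepeatFilterParams(),
    merge_touching: bool = True,
) -> ScreenResult:
    """Run the full funnel; deterministic given its inputs.

    Either ``reads`` plus ``locus_sequence`` (internal mapping) or
    precomputed ``alignments`` plus ``read_lengths`` must be supplied.
    """
    if alignments is None:
        if reads is None or locus_sequence is None:
            raise ValueError("run_screen needs either alignments or reads + locus_sequence")
        try:
            alignments = align_all(reads, locus_sequence, mapper)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"stage 'align' failed: {exc}") from exc
        read_lengths = {r.read_id: len(r.sequence) for r in reads}
    if read_lengths is None:
        raise ValueError("read_lengths required when passing precomputed alignments")

    funnel = ScreenFunnel()
    stage_regions: dict[str, list[CandidateRegion]] = {}

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    constructed = _stage("construct", lambda: build_candidate_regions(peaks, flank, locus))
    funnel.add("constructed", constructed)
    stage_regions["constructed"] = constructed

    coverage = _stage("coverage", lambda: compute_coverage(alignments, read_lengths, locus))

    covered = _stage(
        "zero_read_drop",
        lambda: drop_zero_read_regions(constructed, alignments, read_lengths, locus),
    )
    funnel.add("covered", covered)
    stage_regions["covered"] = covered

    merged = _stage("merge", lambda: merge_regions(covered, merge_touching))
    funnel.add("merged", merged)
    stage_regions["merged"] = merged

    def _dense():
        subs = []
        for region in merged:
            subs.extend(detect_dense_subregions(coverage, region, dense))
        return subs

    subregions = _stage("dense_subregions", _dense)
    with_dense_ids = {p for s in subregions for p in s.parent_ids}
    with_dense = [r for r in merged if r.region_id in with_dense_ids]
    funnel.add("dense_subregion", with_dense)
    stage_regions["dense_subregion"] = with_dense

    surviving_subs = _stage("repeat_filter", lambda: filter_repeats(subregions, repeats, repeat_filter))
    repeat_free = _stage(
        "uniqueness", lambda: region_uniqueness_verdict(with_dense, surviving_subs)
    )
    funnel.add("repeat_free", repeat_free)
    stage_regions["repeat_free"] = repeat_free

    annotation = _stage("annotate", lambda: annotate_candidates(surviving_subs, transcripts))
    matched_parents = {
        p for sub, txs in annotation if txs for p in sub.parent_ids
    }
    annotated = [r.advance(Stage.ANNOTATED) for r in repeat_free if r.region_id in matched_parents]
    funnel.add("annotated", annotated)
    stage_regions["annotated"] = annotated

    return ScreenResult(
        funnel=funnel,
        stage_regions=stage_regions,
        dense_subregions=subregions,
        surviving_subregions=surviving_subs,
        annotation=annotation,
        candidates=annotated,
        coverage=coverage,
    )
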