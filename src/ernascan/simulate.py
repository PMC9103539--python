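"""Seeded generator for every input the screen consumes, with ground truth.

The generator emulates the statistical structure the screen assumes: a
single locus with planted enhancer peaks, a subset of peak windows
transcribed at a configurable depth with per-base sequencing error,
interspersed repeats of the four filtered classes, one annotated lncRNA,
and an expression matrix in which a target transcript co-varies
monotonically with a planted gene set.

The funnel structure is planted *by construction*, not left to chance:

* two of the transcribed peaks are placed close enough that their ±flank
  windows overlap, so the merge stage combines them (n_transcribed covered
  windows → n_transcribed − 1 merged regions);
* every transcribed singleton except one is fully covered by a planted
  repeat, so the repeat filter removes it (→ 2 repeat-free regions under
  the defaults);
* the one unmasked singleton carries the planted lncRNA annotation
  (→ 1 annotated candidate).

The seed therefore only jitters positions, read placement and noise; the
expected funnel is implied by the recorded ground truth for any seed.
Every output is a pure function of :class:`SimConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import ReadRecord, reverse_complement
from .coexpression import ExpressionMatrix
from .intervals import (
    GenomicInterval,
    LocusSpec,
    PeakRecord,
    RepeatClass,
    RepeatRecord,
    TranscriptRecord,
)

BASES = np.array(list("ACGT"))
SUMMIT_JITTER = 200  # bp of random jitter on planted peak summits
PAIR_OFFSET = 4000  # bp between the two deliberately overlapping summits
DECOY_REPEAT_LEN = 300


@dataclass(frozen=True)
class SimConfig:
    seed: int = 42
    locus_length: int = 100_000
    n_peaks: int = 12
    n_transcribed: int = 5
    transcript_len: int = 1000
    depth: float = 20.0  # mean coverage over transcribed intervals
    read_len: int = 50
    error_rate: float = 0.01  # per-base substitution probability
    n_repeats: int = 8
    repeat_classes: tuple[str, ...] = ("SINE", "LINE", "LTR", "DNA")
    plant_annotated: bool = True
    flank: int = 3000
    chrom: str = "locus_sim"

    def __post_init__(self) -> None:
        if not 0 <= self.n_transcribed <= self.n_peaks:
            raise ValueError("need 0 <= n_transcribed <= n_peaks")
        if self.transcript_len < self.read_len:
            raise ValueError("transcript_len must be >= read_len")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything needed to recompute the expected funnel without the pipeline."""

    summits: list[int]
    transcribed_peak_indices: list[int]
    transcribed: list[GenomicInterval]
    pair_indices: tuple[int, int] | None  # peak indices whose windows overlap
    masked_transcribed: list[GenomicInterval]  # fully inside a planted repeat
    repeats: list[RepeatRecord]
    lncrna: TranscriptRecord | None
    annotated_interval: GenomicInterval | None
    read_origins: dict[str, GenomicInterval] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def iv(i: GenomicInterval) -> list:
            return [i.chrom, i.start, i.end]

        payload = {
            "summits": self.summits,
            "transcribed_peak_indices": self.transcribed_peak_indices,
            "transcribed": [iv(t) for t in self.transcribed],
            "pair_indices": list(self.pair_indices) if self.pair_indices else None,
            "masked_transcribed": [iv(t) for t in self.masked_transcribed],
            "repeats": [[*iv(r.interval), r.repeat_class.value] for r in self.repeats],
            "lncrna": None
            if self.lncrna is None
            else {
                "transcript_id": self.lncrna.transcript_id,
                "gene_name": self.lncrna.gene_name,
                "exons": [iv(e) for e in self.lncrna.exons],
            },
            "annotated_interval": iv(self.annotated_interval)
            if self.annotated_interval
            else None,
            "read_origins": {k: iv(v) for k, v in self.read_origins.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedLocus:
    locus: LocusSpec
    sequence: str
    peaks: list[PeakRecord]
    repeats: list[RepeatRecord]
    transcripts: list[TranscriptRecord]
    truth: GroundTruth


def _pick_singleton_indices(n_peaks: int, n_singles: int, first_free: int) -> list[int]:
    """Evenly spread singleton indices over [first_free, n_peaks)."""
    if n_singles == 0:
        return []
    positions = np.linspace(first_free, n_peaks - 1, n_singles)
    picked: list[int] = []
    for p in positions:
        idx = int(round(p))
        while idx in picked:
            idx += 1
        picked.append(idx)
    return picked


def simulate_locus(config: SimConfig) -> SimulatedLocus:
    """Plant peaks, transcribed intervals, repeats and one lncRNA in a locus."""
    rng = np.random.default_rng(config.seed)
    slot = config.locus_length // max(config.n_peaks, 1)
    needed = 2 * config.flank + 2 * SUMMIT_JITTER
    if config.n_peaks and slot < needed:
        raise ValueError(
            f"cannot pack {config.n_peaks} non-overlapping ±{config.flank} bp windows "
            f"into {config.locus_length} bp; use a locus of at least "
            f"{config.n_peaks * needed} bp"
        )
    sequence = "".join(rng.choice(BASES, size=config.locus_length))
    locus = LocusSpec(config.chrom, 0, config.locus_length, genome_build="synthetic")

    summits = [
        i * slot + slot // 2 + int(rng.integers(-SUMMIT_JITTER, SUMMIT_JITTER + 1))
        for i in range(config.n_peaks)
    ]

    # Transcribed peaks: a deliberately overlapping pair plus spread singles.
    pair: tuple[int, int] | None = None
    if config.n_transcribed >= 2 and config.n_peaks >= 3:
        pair = (1, 2)
        summits[2] = summits[1] + PAIR_OFFSET
        singles = _pick_singleton_indices(config.n_peaks, config.n_transcribed - 2, 4)
        transcribed_idx = [1, 2, *singles]
    else:
        singles = list(range(config.n_transcribed))
        transcribed_idx = singles

    half = config.transcript_len // 2
    transcribed = [
        GenomicInterval(config.chrom, summits[i] - half, summits[i] - half + config.transcript_len)
        for i in transcribed_idx
    ]
    by_peak = dict(zip(transcribed_idx, transcribed))

    peaks = [
        PeakRecord(GenomicInterval(config.chrom, s - 500, s + 501), f"peak_{i}")
        for i, s in enumerate(summits)
    ]

    # Repeats: mask every transcribed singleton but the last, then decoys in
    # the gaps between windows (where they can never touch a dense sub-region).
    class_cycle = [RepeatClass.parse(c) for c in config.repeat_classes] or [RepeatClass.SINE]
    repeats: list[RepeatRecord] = []
    masked: list[GenomicInterval] = []
    keep_single = singles[-1] if singles else None
    for j, idx in enumerate(s for s in singles if s != keep_single):
        t = by_peak[idx]
        mask_iv = GenomicInterval(
            config.chrom,
            max(0, t.start - config.read_len),
            min(config.locus_length, t.end + config.read_len),
        )
        repeats.append(RepeatRecord(mask_iv, class_cycle[j % len(class_cycle)]))
        masked.append(t)

    n_decoys = max(0, config.n_repeats - len(repeats))
    gap_slots = [i for i in range(config.n_peaks) if i not in (2,)]
    for j in range(n_decoys):
        slot_idx = gap_slots[j % len(gap_slots)] if gap_slots else 0
        gap_start = slot_idx * slot + 50  # before the window of this slot
        start = gap_start + int(rng.integers(0, 100))
        end = min(start + DECOY_REPEAT_LEN, config.locus_length)
        repeats.append(
            RepeatRecord(
                GenomicInterval(config.chrom, start, end),
                class_cycle[int(rng.integers(len(class_cycle)))],
            )
        )

    # One planted, annotated lncRNA over the unmasked transcribed interval.
    lncrna = None
    annotated_iv = None
    if config.plant_annotated and transcribed:
        annotated_iv = by_peak[keep_single] if keep_single is not None else transcribed[0]
        if annotated_iv.length >= 600:
            exons = (
                GenomicInterval(config.chrom, annotated_iv.start, annotated_iv.start + 400, "+"),
                GenomicInterval(config.chrom, annotated_iv.start + 500, annotated_iv.end, "+"),
            )
        else:
            exons = (dataclasses.replace(annotated_iv, strand="+"),)
        lncrna = TranscriptRecord("TX_SIM_0001", "LNC_SIM_1", exons, biotype="lncRNA")

    truth = GroundTruth(
        summits=summits,
        transcribed_peak_indices=transcribed_idx,
        transcribed=transcribed,
        pair_indices=pair,
        masked_transcribed=masked,
        repeats=repeats,
        lncrna=lncrna,
        annotated_interval=annotated_iv,
    )
    return SimulatedLocus(
        locus=locus,
        sequence=sequence,
        peaks=peaks,
        repeats=repeats,
        transcripts=[lncrna] if lncrna else [],
        truth=truth,
    )


def simulate_reads(
    sequence: str, truth: GroundTruth, config: SimConfig
) -> list[ReadRecord]:
    """Uniform-start reads from each transcribed interval with substitution errors.

    Read count per interval is depth × interval_length / read_length
    (rounded). Each base is substituted independently with probability
    ``error_rate`` to a uniformly chosen different base; half the reads are
    emitted reverse-complemented. Origins are recorded in the ground truth.
    """
    if not truth.transcribed:
        raise ValueError("no transcribed intervals to generate reads from")
    rng = np.random.default_rng(config.seed + 1)
    reads: list[ReadRecord] = []
    idx = 0
    for interval in truth.transcribed:
        if config.read_len > interval.length:
            raise ValueError(
                f"read_len {config.read_len} exceeds transcribed interval "
                f"length {interval.length}"
            )
        n_reads = round(config.depth * interval.length / config.read_len)
        max_start = min(interval.end, len(sequence) - config.read_len)
        starts = rng.integers(interval.start, max_start, size=n_reads)
        for start in starts:
            start = int(start)
            frag = list(sequence[start : start + config.read_len])
            err_mask = rng.random(config.read_len) < config.error_rate
            for pos in np.flatnonzero(err_mask):
                alternatives = [b for b in "ACGT" if b != frag[pos]]
                frag[pos] = alternatives[int(rng.integers(3))]
            seq = "".join(frag)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            read_id = f"r{idx:06d}"
            origin = GenomicInterval(interval.chrom, start, start + config.read_len)
            reads.append(ReadRecord(read_id, seq, origin=origin))
            truth.read_origins[read_id] = origin
            idx += 1
    return reads


def simulate_expression_matrix(
    n_samples: int = 200,
    n_genes: int = 50,
    n_correlated: int = 10,
    effect: float = 0.8,
    seed: int = 42,
) -> tuple[ExpressionMatrix, list[str]]:
    """Log-normal expression with a planted co-expressed gene set.

    The target gene is log-normal; each correlated gene shares a latent
    Gaussian factor with the target with weight ``effect`` (effect 1 gives
    a noiseless monotone transform, Spearman rho = 1; effect 0 gives
    independence). Returns the matrix and the list of planted gene names.
    """
    if n_correlated >= n_genes:
        raise ValueError("n_correlated must be < n_genes")
    rng = np.random.default_rng(seed)
    z_target = rng.standard_normal(n_samples)
    rows = {"TARGET": np.exp(1.0 + 0.5 * z_target)}
    planted = []
    resid = math.sqrt(max(0.0, 1.0 - effect**2))
    for i in range(n_correlated):
        gene = f"COR_{i:04d}"
        latent = effect * z_target + resid * rng.standard_normal(n_samples)
        rows[gene] = np.exp(1.0 + 0.5 * latent)
        planted.append(gene)
    for i in range(n_genes - n_correlated - 1):
        rows[f"BG_{i:04d}"] = np.exp(1.0 + 0.5 * rng.standard_normal(n_samples))
    df = pd.DataFrame(rows, index=[f"S{j:04d}" for j in range(n_samples)]).T
    return ExpressionMatrix(df), planted


def simulate_knockdown_ct(
    n_experiments: int = 8,
    true_fold: float = 0.5,
    ct_noise_sd: float = 0.3,
    seed: int = 42,
    efficiency: float = 2.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Paired knockdown/control qPCR Ct table with a known true fold change.

    The control ΔCt baseline is fixed; the treated ΔCt is shifted by
    −log_E(true_fold) (one extra cycle at E = 2 for a two-fold knockdown).
    Gaussian noise of ``ct_noise_sd`` applies per technical replicate to
    both genes. Rows follow the :mod:`ernascan.qstats` Ct-table schema.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = np.random.default_rng(seed)
    ref_base, delta_ct_base = 18.0, 6.0
    shift = -math.log(true_fold, efficiency)
    rows = []
    for i in range(n_experiments):
        for condition, extra in (("control", 0.0), ("treated", shift)):
            sample_id = f"exp{i}_{condition}"
            for _ in range(n_replicates):
                rows.append(
                    (sample_id, condition, "REF",
                     ref_base + rng.normal(0.0, ct_noise_sd))
                )
                rows.append(
                    (sample_id, condition, "TARGET",
                     ref_base + delta_ct_base + extra + rng.normal(0.0, ct_noise_sd))
                )
    return pd.DataFrame(rows, columns=["sample_id", "condition", "gene", "ct"])
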