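# Methods

## The screening model

The screen treats eRNA discovery in a single locus (~2 Mb) as an interval
filtering problem. Its assumptions:

* Enhancer positions are given (a peak catalogue is an input, never
  recomputed from ChIP-seq). A peak supplied as a region rather than a
  summit uses the floor midpoint as its summit — deterministic, since
  published eRNA catalogues distribute regions.
* Transcription evidence is unstranded read coverage. Strand is parsed and
  carried but ignored by every filter, because the strandedness of typical
  public RNA-seq libraries for this kind of screen is unknown.
* A targetable eRNA needs a *unique* sequence, so any sub-region lying in
  an interspersed repeat (SINE, LINE, LTR, DNA classes) is disqualified.
  Repeat classes are parsed from the annotation, never guessed; an
  unrecognized label becomes `other`, which never filters.
* Known lncRNA support means ≥ 1 bp overlap between a surviving sub-region
  and an annotated *exon*. Intron-only overlap is not accepted: a spliced,
  unidirectional eRNA is evidenced by exonic reads. The span-based
  alternative can be had by passing single-exon transcripts.

Stage order: construct → zero-read elimination → merge → dense sub-regions
→ repeat filter → region uniqueness verdict → annotation. Zero-read
elimination precedes merging so that only covered windows combine.
Bookended (touching) covered windows merge by default (`merge_touching`),
the more inclusive reading of "combine overlapping covered regions".

All internal coordinates are 0-based half-open; GTF (1-based closed) and
SAM POS (1-based) are converted only at the I/O boundary. A single
convention internally avoids off-by-one drift between stages.

## Read mapping

The mapper is ungapped (substitutions only) with at most `k` mismatches,
default `k = 1`. Ungapped keeps the contract exact and checkable: the
placement set is *defined* as every offset with Hamming distance ≤ k, and
the implementation (pigeonhole split into k+1 blocks, exact block-index
lookup, full verification) is tested for equality against an exhaustive
scan. `N` matches nothing — a position with `N` on either side counts as a
mismatch — so N-rich reads cannot inflate coverage; index k-mers containing
`N` are excluded, which preserves pigeonhole completeness under that
metric. Reads shorter than 2(k+1) bases are rejected with a warning.

Multi-mappers: all placements are reported (`all_hits`) with an `is_multi`
flag, and `best_only` restricts to minimum-mismatch placements; coverage is
built under `all_hits` by default so the screen can be re-run under either
policy. Ties order by position then strand — bit-reproducible output.

## Dense sub-regions

"Densely covered" is formalized as a run-bridging rule with three
parameters, all exposed:

| parameter | meaning | default |
|---|---|---|
| `min_cov` (c) | minimum per-base depth | 5 reads |
| `min_len` (L) | minimum sub-region length | 100 bp |
| `max_gap` (g) | longest below-threshold run bridged | 50 bp |

Sub-regions are maximal above-threshold runs after bridging gaps ≤ g,
trimmed so both endpoints have depth ≥ c, and kept only at length ≥ L.
The rule is deterministic and oracle-checkable (a stateful per-base scan
reproduces it). Defaults were chosen for 20× transcript coverage with
50 bp reads: c = 5 sits far below the ~20 interior depth and above the
noise floor, L = 100 rejects isolated read stacks, g = 50 (one read
length) bridges sampling gaps inside a genuinely transcribed interval.

## Repeat filtering

A sub-region survives when the fraction of its bases covered by the union
of filtered-class repeats is ≤ `max_overlap_frac`, default 0 — strict
any-overlap exclusion, the natural reading of requiring the *absence* of
repeats; the tolerance is a config knob. A merged region survives the
uniqueness verdict when at least one of its sub-regions survived.

## Co-expression screen

Spearman ρ is the Pearson correlation of average (mid-)ranks, so ties are
handled exactly. The p-value switches by sample count: t approximation
with n − 2 df for n ≥ 10; exact enumeration of all n! permutations for
n ≤ 8; seeded Monte-Carlo (10⁴ permutations, add-one estimator) for n = 9.
Zero-variance genes are flagged and skipped, never reported as ρ = 0.
Ranking is by ascending p with |ρ|-then-gene-id tie-breaks, fully
deterministic, and the top-K cut (default 500) uses raw p-values with no
multiple-testing correction — the selection is a ranking, not an inference.
The expression matrix is taken as given (no normalization or covariate
handling); orientation (genes × samples or transposed) is declared at load.

## Expression statistics

ΔΔCt: technical replicates are averaged per (sample, gene); ΔCt =
Ct(target) − Ct(reference); ΔΔCt subtracts the **median** control ΔCt
(robust to one outlier replicate; the mean is available); fold change =
E^(−ΔΔCt) with amplification efficiency E = 2.0 unless configured. Adding
a constant to every Ct of a sample cancels in ΔCt — a tested invariant.
Samples missing the reference gene are excluded with a warning.

Wilcoxon: the default analysis is signed-rank of control-normalized fold
changes against 1.0, matching a paired knockdown/control design; rank-sum
is provided because the pairing is a design choice. Exact p-values come
from full enumeration (2ⁿ sign patterns or all group assignments) for
effective n ≤ 12, two-sided as P(|T − E₀T| ≥ |t − E₀T|), which equals the
classical doubled tail for these symmetric nulls; larger n uses the
tie-corrected normal approximation without continuity correction. Zero
differences are dropped with the count reported; all-zero data yields an
explicitly undefined (NaN) p-value rather than a fabricated one.

The t-test is the pooled-variance two-sided Student's t. Zero pooled
variance with equal means gives t = 0, p = 1; with unequal means the
result is flagged degenerate.

## Synthetic data: what it emulates and what it does not

The generator plants the funnel structure deterministically — two
transcribed peak windows overlap (exercising the merge), every transcribed
singleton but one is fully covered by a planted repeat (exercising the
repeat filter), and the remaining one carries the planted two-exon lncRNA —
while the seed controls sequence content, position jitter (±200 bp),
read placement and noise. Under the defaults (12 peaks, 5 transcribed,
100 kb locus, 20× depth, 50 bp reads, 1% substitution error) the ground
truth implies the funnel 12 → 5 → 4 → 4 → 2 → 1 for any seed, and an
independent recount from the ground truth alone (per-base occupancy
merging, stateful dense scan) must agree with the pipeline.

Reads start uniformly inside each transcribed interval, carry independent
per-base substitutions, and half are reverse-complemented. Deliberately
**not** modeled: splicing in the read signal, strand-specific libraries,
PCR duplicates, indels (the mapper contract is substitution-only, and the
generator matches it), repeat-like sequence content (repeats are planted
as labeled intervals because the filter is annotation-driven), and
non-uniform transcript abundance. Passing tests therefore demonstrate the
correctness of the filtering logic and its calibration on clean planted
signal — not performance on real library artifacts, and not the real-data
survivor counts of any particular locus, which depend on the external peak
catalogue, sequencing runs and annotation versions used.

The expression-matrix generator shares a latent Gaussian factor between
the target and each planted gene (weight = `effect`) on a log-normal
scale; `effect` = 1 gives exact monotone transforms (ρ = 1), 0 gives
independence. The knockdown generator shifts the treated ΔCt by
−log_E(true fold) over a fixed baseline with per-replicate Gaussian noise
(default SD 0.3 cycles, 3 technical replicates) — a standard qPCR design.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale by design: a 100 kb
locus with ~2,000 50-bp reads for funnel runs (10 replicate seeds for the
localization average), a 10 kb locus with 200 36-mers for mapper–oracle
equivalence, 200-sample matrices for the co-expression checks, and 1,000
replicates for type-I calibration. Floating-point comparisons in exact
enumerations use small absolute guards (1e-9 rank sums, 1e-12 on ρ) so
ties in the enumerated statistic are counted as attained. p-values are
clipped into (0, 1]; ρ = ±1 under the t approximation reports the smallest
positive float rather than 0.

## Orchestration and reproducibility

Every CLI run writes a manifest (parameters, input SHA-256 hashes, output
hashes, funnel, version, wall-clock); `ernascan rerun manifest.json`
replays the run and reproduces every data output byte-identically (the
manifest itself differs only in timing fields). One global seed fans out
to per-module streams by fixed offsets. Logs go to stderr; results only to
files.

## Known limitations

* Single-locus universe: no genome-wide indexing, by scope.
* The internal mapper is quadratic-safe only at locus scale; real
  whole-genome alignments should be imported via ungapped SAM
  (gapped records are skipped with a counted warning).
* Exact Wilcoxon enumeration is exponential and capped at effective
  n = 12; beyond that the normal approximation is used.
* The co-expression screen is pairwise-marginal only — no partial
  correlations or covariate adjustment.
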