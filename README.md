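# ernascan

A candidate enhancer-RNA (eRNA) screen for a translocation-partner locus,
built for regulatory-genomics analysts who want the interval-filtering
funnel behind "find the targetable eRNA in this locus" as tested,
re-runnable code rather than a one-off script.

The motivating setting is the immunoglobulin heavy-chain (IGH) locus on
14q32: in B-cell lymphomas carrying an IGH/MYC translocation, enhancer RNAs
transcribed from IGH enhancers can drive MYC expression, and a spliced,
unidirectional (1D) eRNA with a unique — repeat-free — sequence is a
candidate for siRNA targeting. The package answers: given enhancer peaks in
a locus, RNA-seq reads from relevant cell lines, a repeat annotation and an
lncRNA annotation, which peak regions are actually transcribed from unique
sequence, and which carry a known lncRNA?

## What it computes

**Screening funnel** (`ernascan.screen`). Each enhancer peak summit is
expanded to a window of ±3000 bp (6000 bp). Reads are mapped to the locus
ungapped with at most *k* = 1 mismatch by an exact pigeonhole
seed-and-verify mapper (`ernascan.alignment`): the reported placement set
provably equals the exhaustive Hamming scan's. Windows with zero aligned
reads are eliminated; overlapping survivors are merged; within each merged
region, densely covered sub-regions — maximal runs with per-base depth ≥ c
(default 5), bridging sub-threshold gaps ≤ g (50 bp), of final length ≥ L
(100 bp) — mark the probable transcript. Sub-regions overlapping
SINE/LINE/LTR/DNA repeats are discarded (default: any overlap disqualifies),
and the remainder is intersected with annotated lncRNA exons. The funnel
report gives the survivor count at every stage.

**Co-expression ranking** (`ernascan.coexpression`). Tie-aware Spearman
ρ of every gene against a target transcript across samples, with p-values
from the t approximation (n ≥ 10) or exact permutation enumeration (small
n), ranked by ascending p, and a top-K TSV export (default K = 500) for
external enrichment services.

**Expression statistics** (`ernascan.qstats`). ΔΔCt relative
quantification (fold change = E^(−ΔΔCt), E = 2 by default, normalized to
the control-group median), Wilcoxon signed-rank/rank-sum tests (exact by
enumeration for effective n ≤ 12), pooled-variance Student's t-test, and
drug-free-normalized viability tables — the analysis shapes of a
knockdown/chemoresistance experiment, at α = 0.05.

**Synthetic data** (`ernascan.simulate`). A seeded generator for every
input (locus FASTA, peaks/repeats BED, transcripts GTF, reads FASTQ, Ct and
viability tables, expression matrices) with recorded ground truth, so the
whole pipeline is testable end to end without external data.

## Worked example

```bash
ernascan simulate --seed 42 --outdir fixture
ernascan screen --locus-fasta fixture/locus.fasta --peaks fixture/peaks.bed \
    --repeats fixture/repeats.bed --transcripts fixture/transcripts.gtf \
    --reads fixture/reads.fastq --outdir screen_out
```

The screen logs the funnel to stderr:

```
[INFO] ernascan: screen: stage constructed      12 surviving regions
[INFO] ernascan: screen: stage covered          5 surviving regions
[INFO] ernascan: screen: stage merged           4 surviving regions
[INFO] ernascan: screen: stage dense_subregion  4 surviving regions
[INFO] ernascan: screen: stage repeat_free      2 surviving regions
[INFO] ernascan: screen: stage annotated        1 surviving regions
```

Twelve planted peak windows reduce to five with reads, four after merging
(two windows overlap and combine), four with a dense sub-region, two whose
sub-regions avoid repeats, and one overlapping the planted lncRNA — the
final candidate, written to `screen_out/candidates.bed` alongside per-stage
BEDs, `funnel.tsv` and a `manifest.json` that `ernascan rerun` replays
byte-identically. The same API is available in Python
(`ernascan.run_screen`), and `--alignments some.sam` substitutes externally
mapped, ungapped reads for the internal mapper on real data.

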