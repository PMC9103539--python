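"""End-to-end orchestration and the ``ernascan`` command-line interface.

Subcommands: ``simulate`` (fixture generation), ``screen`` (the funnel),
``coexpress`` (Spearman ranking), ``stats ddct`` / ``stats viability``
(qPCR and viability statistics), and ``rerun`` (replay a run manifest).

Every run writes a JSON manifest holding the exact parameters, input file
hashes, output file hashes and per-stage wall-clock; replaying a manifest
with ``rerun`` reproduces every data output byte-identically. Logging goes
to stderr with stage-tagged lines; results go only to files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import click
import pandas as pd

from . import __version__
from .alignment import MapperConfig, read_fastq, read_sam, write_fastq, write_sam
from .coexpression import CoexpressionConfig, ExpressionMatrix, coexpression_screen, export_gene_list
from .intervals import (
    BedRecord,
    LocusSpec,
    peaks_from_bed,
    read_bed,
    read_fasta,
    read_gtf_transcripts,
    repeats_from_bed,
    write_bed,
    write_fasta,
    write_gtf_transcripts,
)
from .qstats import ddct_fold_change, normalize_viability, t_test, wilcoxon_test
from .screen import DenseParams, RepeatFilterParams, run_screen
from .simulate import SimConfig, simulate_locus, simulate_reads

logger = logging.getLogger("ernascan")

# Fixed per-module offsets fanning one global seed into independent streams.
SEED_OFFSET_COEXPRESS = 101


def _setup_logging(level: str) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())


def file_sha256(path: str | Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _write_manifest(
    outdir: Path, command: str, params: dict, inputs: dict[str, str],
    timings: dict[str, float], extra: dict | None = None,
) -> dict:
    outputs = {
        p.name: file_sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "tool": "ernascan",
        "version": __version__,
        "command": command,
        "params": params,
        "input_hashes": inputs,
        "output_hashes": outputs,
        "wall_clock_s": {k: round(v, 4) for k, v in timings.items()},
        **(extra or {}),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# Command implementations (plain functions; click wrappers stay thin)
# ---------------------------------------------------------------------------

def run_simulate(params: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    config = SimConfig(**params)
    sim = simulate_locus(config)
    reads = simulate_reads(sim.sequence, sim.truth, config)
    t_sim = time.perf_counter() - t0

    write_fasta({sim.locus.chrom: sim.sequence}, outdir / "locus.fasta")
    write_bed([BedRecord(p.interval, p.source_label) for p in sim.peaks], outdir / "peaks.bed")
    write_bed(
        [BedRecord(r.interval, r.repeat_class.value) for r in sim.repeats],
        outdir / "repeats.bed",
    )
    write_gtf_transcripts(sim.transcripts, outdir / "transcripts.gtf")
    write_fastq(reads, outdir / "reads.fastq")
    sim.truth.to_json(outdir / "truth.json")
    logger.info("simulate: %d peaks, %d reads, %d repeats -> %s",
                len(sim.peaks), len(reads), len(sim.repeats), outdir)
    return _write_manifest(outdir, "simulate", params, {}, {"simulate": t_sim})


def run_screen_cmd(params: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    inputs = {
        key: file_sha256(params[key])
        for key in ("locus_fasta", "peaks", "repeats", "transcripts", "reads", "alignments")
        if params.get(key)
    }
    sequences = read_fasta(params["locus_fasta"])
    chrom, sequence = next(iter(sequences.items()))
    locus = LocusSpec(chrom, 0, len(sequence), genome_build=params.get("genome_build", "custom"))
    peaks = peaks_from_bed(read_bed(params["peaks"]))
    repeats = repeats_from_bed(read_bed(params["repeats"]))
    transcripts = read_gtf_transcripts(params["transcripts"]) if params.get("transcripts") else []

    kwargs = dict(
        peaks=peaks, locus=locus, repeats=repeats, transcripts=transcripts,
        flank=params.get("flank", 3000),
        mapper=MapperConfig(max_mismatch=params.get("max_mismatch", 1)),
        dense=DenseParams(
            min_cov=params.get("min_cov", 5),
            min_len=params.get("min_len", 100),
            max_gap=params.get("max_gap", 50),
        ),
        repeat_filter=RepeatFilterParams(max_overlap_frac=params.get("max_overlap_frac", 0.0)),
    )
    if params.get("alignments"):
        alignments, _ = read_sam(params["alignments"])
        kwargs.update(alignments=alignments, read_lengths=params.get("read_len", 50))
        logger.info("screen: using %d precomputed alignments, internal mapper bypassed",
                    len(alignments))
    else:
        kwargs.update(reads=read_fastq(params["reads"]), locus_sequence=sequence)
    t_load = time.perf_counter() - t0

    t1 = time.perf_counter()
    result = run_screen(**kwargs)
    t_screen = time.perf_counter() - t1

    for stage, regions in result.stage_regions.items():
        write_bed(
            [BedRecord(r.interval, r.region_id) for r in regions],
            outdir / f"stage_{stage}.bed",
        )
    write_bed(
        [BedRecord(s.interval, s.region_id) for s in result.surviving_subregions],
        outdir / "subregions_repeat_free.bed",
    )
    write_bed(
        [BedRecord(r.interval, r.region_id) for r in result.candidates],
        outdir / "candidates.bed",
    )
    pd.DataFrame(result.funnel.to_rows()).to_csv(outdir / "funnel.tsv", sep="\t", index=False)
    for stage, count in zip(result.funnel.stage_names, result.funnel.counts):
        logger.info("screen: stage %-16s %d surviving regions", stage, count)
    return _write_manifest(
        outdir, "screen", params, inputs,
        {"load": t_load, "screen": t_screen},
        extra={"funnel": dict(zip(result.funnel.stage_names, result.funnel.counts))},
    )


def run_coexpress(params: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    inputs = {"matrix": file_sha256(params["matrix"])}
    matrix = ExpressionMatrix.from_tsv(params["matrix"], params.get("orientation", "genes_by_samples"))
    config = CoexpressionConfig(
        top_k=params.get("top_k", 500),
        min_samples=params.get("min_samples", 10),
        seed=params.get("seed", 42) + SEED_OFFSET_COEXPRESS,
    )
    results, skipped = coexpression_screen(matrix, params["target"], config)
    top_k = min(config.top_k, len(results))
    export_gene_list(results, top_k, outdir / "top_genes.tsv")
    export_gene_list(results, len(results), outdir / "all_genes.tsv")
    logger.info("coexpress: ranked %d genes (%d zero-variance skipped), top %d exported",
                len(results), len(skipped), top_k)
    return _write_manifest(
        outdir, "coexpress", params, inputs, {"coexpress": time.perf_counter() - t0},
        extra={"n_ranked": len(results), "n_skipped": len(skipped)},
    )


def run_stats_ddct(params: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    inputs = {"ct_table": file_sha256(params["ct_table"])}
    ct = pd.read_csv(params["ct_table"], sep="\t")
    folds = ddct_fold_change(
        ct, params["target"], params.get("reference", "REF"),
        efficiency=params.get("efficiency", 2.0),
    )
    folds.to_csv(outdir / "fold_changes.tsv", sep="\t", index=False, float_format="%.6g")
    treated = folds.loc[folds["condition"] == "treated", "fold_change"].to_numpy()
    test = wilcoxon_test(treated, 1.0, mode="signed_rank")
    alpha = params.get("alpha", 0.05)
    report = {
        "test": "wilcoxon_signed_rank_vs_1",
        "statistic": test.statistic,
        "p_value": None if test.undefined else test.p_value,
        "n_effective": test.n_effective,
        "n_dropped": test.n_dropped,
        "alpha": alpha,
        "significant": (not test.undefined) and test.p_value < alpha,
        "median_fold_change_treated": float(pd.Series(treated).median()),
    }
    with open(outdir / "ddct_test.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("stats ddct: median treated fold %.3g, p=%s",
                report["median_fold_change_treated"], report["p_value"])
    return _write_manifest(outdir, "stats_ddct", params, inputs,
                           {"stats": time.perf_counter() - t0}, extra={"report": report})


def run_stats_viability(params: dict, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    inputs = {"viability_table": file_sha256(params["viability_table"])}
    table = pd.read_csv(params["viability_table"], sep="\t")
    normalized = normalize_viability(table)
    normalized.to_csv(outdir / "viability_normalized.tsv", sep="\t", index=False,
                      float_format="%.6g")
    alpha = params.get("alpha", 0.05)
    rows = []
    for (cell_line, conc), group in normalized.groupby(["cell_line", "concentration"]):
        arms = {arm: g["normalized"].to_numpy() for arm, g in group.groupby("arm")}
        if len(arms) != 2 or conc == 0:
            continue
        (arm_a, a), (arm_b, b) = sorted(arms.items())
        test = t_test(a, b)
        rows.append({
            "cell_line": cell_line, "concentration": conc,
            "arm_a": arm_a, "arm_b": arm_b,
            "t": test.statistic, "p_value": test.p_value,
            "significant": (not test.undefined) and test.p_value < alpha,
        })
    pd.DataFrame(rows).to_csv(outdir / "viability_tests.tsv", sep="\t", index=False,
                              float_format="%.6g")
    logger.info("stats viability: %d concentration comparisons", len(rows))
    return _write_manifest(outdir, "stats_viability", params, inputs,
                           {"stats": time.perf_counter() - t0})


_COMMANDS = {
    "simulate": run_simulate,
    "screen": run_screen_cmd,
    "coexpress": run_coexpress,
    "stats_ddct": run_stats_ddct,
    "stats_viability": run_stats_viability,
}


def rerun_manifest(manifest_path: str | Path, outdir: str | Path) -> dict:
    """Re-execute a recorded run with its exact parameters."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    command = manifest["command"]
    if command not in _COMMANDS:
        raise ValueError(f"manifest records unknown command {command!r}")
    return _COMMANDS[command](manifest["params"], outdir)


# ---------------------------------------------------------------------------
# click CLI
# ---------------------------------------------------------------------------

@click.group()
@click.option("--log-level", default="INFO", show_default=True)
@click.version_option(__version__)
def main(log_level: str) -> None:
    """Candidate enhancer-RNA screen and companion analyses."""
    _setup_logging(log_level)


@main.command()
@click.option("--seed", type=int, default=42, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--locus-length", type=int, default=100_000, show_default=True)
@click.option("--n-peaks", type=int, default=12, show_default=True)
@click.option("--n-transcribed", type=int, default=5, show_default=True)
@click.option("--transcript-len", type=int, default=1000, show_default=True)
@click.option("--depth", type=float, default=20.0, show_default=True)
@click.option("--read-len", type=int, default=50, show_default=True)
@click.option("--error-rate", type=float, default=0.01, show_default=True)
@click.option("--n-repeats", type=int, default=8, show_default=True)
@click.option("--plant-annotated/--no-plant-annotated", default=True, show_default=True)
def simulate(outdir, **params) -> None:
    """Generate a seeded synthetic fixture with recorded ground truth."""
    run_simulate(params, outdir)


@main.command()
@click.option("--locus-fasta", type=click.Path(exists=True), required=True)
@click.option("--peaks", type=click.Path(exists=True), required=True)
@click.option("--repeats", type=click.Path(exists=True), required=True)
@click.option("--transcripts", type=click.Path(exists=True))
@click.option("--reads", type=click.Path(exists=True), help="FASTQ for internal mapping")
@click.option("--alignments", type=click.Path(exists=True),
              help="Ungapped SAM; skips the internal mapper")
@click.option("--read-len", type=int, default=50, show_default=True,
              help="Read length assumed for --alignments input")
@click.option("--outdir", type=click.Path(), required=True)
@click.option("--flank", type=int, default=3000, show_default=True)
@click.option("--max-mismatch", type=int, default=1, show_default=True)
@click.option("--min-cov", type=int, default=5, show_default=True)
@click.option("--min-len", type=int, default=100, show_default=True)
@click.option("--max-gap", type=int, default=50, show_default=True)
@click.option("--max-overlap-frac", type=float, default=0.0, show_default=True)
def screen(outdir, **params) -> None:
    """Run the screening funnel on peak/read/repeat/annotation inputs."""
    if not params.get("reads") and not params.get("alignments"):
        raise click.UsageError("provide --reads or --alignments")
    try:
        run_screen_cmd(params, outdir)
    except (RuntimeError, ValueError) as exc:
        raise click.ClickException(str(exc))


@main.command()
@click.option("--matrix", type=click.Path(exists=True), required=True)
@click.option("--target", required=True)
@click.option("--orientation", type=click.Choice(["genes_by_samples", "samples_by_genes"]),
              default="genes_by_samples", show_default=True)
@click.option("--top-k", type=int, default=500, show_default=True)
@click.option("--seed", type=int, default=42, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
def coexpress(outdir, **params) -> None:
    """Spearman co-expression ranking against a target transcript."""
    try:
        run_coexpress(params, outdir)
    except (KeyError, ValueError) as exc:
        raise click.ClickException(str(exc))


@main.group()
def stats() -> None:
    """qPCR relative expression and viability statistics."""


@stats.command("ddct")
@click.option("--ct-table", type=click.Path(exists=True), required=True)
@click.option("--target", required=True)
@click.option("--reference", default="REF", show_default=True)
@click.option("--efficiency", type=float, default=2.0, show_default=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
def stats_ddct(outdir, **params) -> None:
    """ΔΔCt fold changes plus a Wilcoxon signed-rank test against 1.0."""
    run_stats_ddct(params, outdir)


@stats.command("viability")
@click.option("--viability-table", type=click.Path(exists=True), required=True)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--outdir", type=click.Path(), required=True)
def stats_viability(outdir, **params) -> None:
    """Drug-free-normalized viability plus per-concentration t-tests."""
    run_stats_viability(params, outdir)


@main.command()
@click.argument("manifest", type=click.Path(exists=True))
@click.option("--outdir", type=click.Path(), required=True)
def rerun(manifest, outdir) -> None:
    """Replay a recorded manifest; outputs reproduce byte-identically."""
    rerun_manifest(manifest, outdir)


if __name__ == "__main__":  # pragma: no cover
    main()
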