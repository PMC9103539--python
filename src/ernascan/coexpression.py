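"""Spearman co-expression screen of a target transcript against a matrix.

The screen ranks every other gene by the p-value of its tie-aware Spearman
correlation with the target across samples and exports the top-K list for
downstream enrichment tools. No multiple-testing correction is applied
before the top-K cut: the selection criterion is the raw p-value rank.

The p-value switches computation by sample count n:

* n >= 10 — the t approximation with n − 2 degrees of freedom;
* n <= 8  — exact enumeration over all n! permutations of one vector;
* n == 9  — seeded Monte-Carlo with >= 10^4 permutations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ernascan")

EXACT_MAX_N = 8
T_APPROX_MIN_N = 10
MC_PERMUTATIONS = 10_000


@dataclass(frozen=True)
class CoexpressionConfig:
    top_k: int = 500
    min_samples: int = 10
    p_method: str = "auto"  # auto | t_approx | exact_permutation
    seed: int = 42


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    rho: float
    p_value: float
    rank: int = 0


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values (non-negative, normalized units)."""

    data: pd.DataFrame  # index = genes, columns = samples

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate gene or sample identifiers")
        if self.data.isna().any().any():
            raise ValueError("missing expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def zero_variance_genes(self) -> list[str]:
        values = self.data.to_numpy()
        return [g for g, row in zip(self.data.index, values) if np.ptp(row) == 0]

    @classmethod
    def from_tsv(cls, path: str | Path, orientation: str = "genes_by_samples") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "samples_by_genes":
            df = df.T
        elif orientation != "genes_by_samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")


def _rho_from_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of average ranks (the tie-aware Spearman rho)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("zero-variance input: Spearman rho is undefined")
    return float(rx @ ry) / denom


def spearman(
    x,
    y,
    p_method: str = "auto",
    seed: int = 42,
) -> tuple[float, float]:
    """Tie-aware Spearman rho and its p-value.

    Zero-variance input raises (rho is undefined, never reported as 0);
    the screen flags and skips such genes before calling this.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = _rho_from_ranks(rx, ry)

    if p_method == "auto":
        p_method = "t_approx" if n >= T_APPROX_MIN_N else "exact_permutation"

    if p_method == "t_approx":
        if abs(rho) >= 1.0:
            p = np.nextafter(0.0, 1.0)
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    elif p_method == "exact_permutation":
        tol = 1e-12
        if n <= EXACT_MAX_N:
            count = total = 0
            for perm in itertools.permutations(ry):
                total += 1
                if abs(_rho_from_ranks(rx, np.array(perm))) >= abs(rho) - tol:
                    count += 1
            p = count / total
        else:
            rng = np.random.default_rng(seed)
            count = 0
            ry_perm = ry.copy()
            for _ in range(MC_PERMUTATIONS):
                rng.shuffle(ry_perm)
                if abs(_rho_from_ranks(rx, ry_perm)) >= abs(rho) - tol:
                    count += 1
            p = (count + 1) / (MC_PERMUTATIONS + 1)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return rho, float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))


def coexpression_screen(
    matrix: ExpressionMatrix,
    target_gene: str,
    config: CoexpressionConfig = CoexpressionConfig(),
) -> tuple[list[CorrelationResult], list[str]]:
    """Rank all non-target genes by Spearman correlation with the target.

    Returns (ranked results, flagged zero-variance genes). Ranking is by
    ascending p-value, ties broken by |rho| descending then gene id, so the
    order is fully deterministic.
    """
    if target_gene not in matrix.data.index:
        raise KeyError(f"target gene {target_gene!r} not present in the matrix")
    n_samples = matrix.data.shape[1]
    if n_samples < config.min_samples:
        raise ValueError(
            f"need >= {config.min_samples} samples, matrix has {n_samples}"
        )
    target = matrix.data.loc[target_gene].to_numpy(dtype=float)
    if np.ptp(target) == 0:
        raise ValueError(f"target gene {target_gene!r} has zero variance")

    skipped: list[str] = []
    results: list[CorrelationResult] = []
    for gene in matrix.genes:
        if gene == target_gene:
            continue
        values = matrix.data.loc[gene].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            skipped.append(gene)
            continue
        rho, p = spearman(target, values, p_method=config.p_method, seed=config.seed)
        results.append(CorrelationResult(gene, rho, p))
    results.sort(key=lambda r: (r.p_value, -abs(r.rho), r.gene))
    ranked = [
        CorrelationResult(r.gene, r.rho, r.p_value, rank=i + 1)
        for i, r in enumerate(results)
    ]
    if skipped:
        logger.warning("coexpression_screen: %d zero-variance genes skipped", len(skipped))
    return ranked, skipped


def export_gene_list(
    results: list[CorrelationResult], top_k: int, path: str | Path
) -> None:
    """Write the top-K ranked genes as a plain TSV (gene, rho, p, rank).

    Formatting is fixed so re-export is byte-identical; the file is meant
    for pasting into an external enrichment service.
    """
    with open(path, "w") as fh:
        fh.write("gene\trho\tp_value\trank\n")
        for r in results[:top_k]:
            fh.write(f"{r.gene}\t{r.rho:.6g}\t{r.p_value:.6g}\t{r.rank}\n")
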