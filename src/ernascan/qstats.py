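"""Relative-expression quantification and significance tests for qPCR /
viability experiments.

ΔΔCt quantification: per sample, ΔCt = mean Ct(target) − mean Ct(reference);
ΔΔCt = ΔCt − median ΔCt over control samples; fold change = E^(−ΔΔCt) with
amplification efficiency E (default 2.0, i.e. perfect doubling per cycle).
The control group's own median fold change is 1 by construction. The median
(rather than mean) of the control group is used because a single outlier
replicate otherwise shifts every fold change; the summary is configurable.

Wilcoxon tests are exact by enumeration for small samples (all 2^n sign
assignments for the signed-rank test, all group assignments for the
rank-sum test, effective n ≤ 12) and use the tie-corrected normal
approximation otherwise. Two-sided p-values are computed symmetrically:
P(|T − E₀[T]| ≥ |t_obs − E₀[T]|) under the null enumeration, which matches
the classical doubled-tail convention for these symmetric null
distributions.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ernascan")

EXACT_MAX_N = 12

CT_COLUMNS = ["sample_id", "condition", "gene", "ct"]
VIABILITY_COLUMNS = ["cell_line", "arm", "concentration", "value"]


@dataclass(frozen=True)
class TestConfig:
    alpha: float = 0.05
    test: str = "wilcoxon_signed_rank"  # wilcoxon_signed_rank | wilcoxon_rank_sum | t_test

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float  # NaN when the test is undefined (all differences zero)
    n_effective: int
    n_dropped: int = 0
    method: str = ""

    @property
    def undefined(self) -> bool:
        return math.isnan(self.p_value)


# ---------------------------------------------------------------------------
# ΔΔCt relative expression
# ---------------------------------------------------------------------------

def ddct_fold_change(
    ct: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    efficiency: float = 2.0,
    control_summary: str = "median",
) -> pd.DataFrame:
    """Control-normalized relative expression by the ΔΔCt method.

    ``ct`` has one row per technical replicate with columns
    ``sample_id, condition, gene, ct`` and ``condition`` in
    {treated, control}. Samples missing the reference gene are excluded
    with a warning. Returns one row per sample with columns
    ``sample_id, condition, delta_ct, delta_delta_ct, fold_change``.
    """
    if target_gene == reference_gene:
        raise ValueError("target and reference gene must differ")
    if efficiency <= 0:
        raise ValueError("amplification efficiency must be positive")
    missing = set(CT_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(ct["ct"]).all():
        raise ValueError("non-finite Ct values")

    means = (
        ct[ct["gene"].isin([target_gene, reference_gene])]
        .groupby(["sample_id", "condition", "gene"])["ct"]
        .mean()
        .unstack("gene")
    )
    if reference_gene not in means.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from the table")
    bad = means[means[reference_gene].isna() | means.get(target_gene, np.nan).isna()]
    for sample_id, _cond in bad.index:
        logger.warning("sample %s lacks target or reference Ct; excluded", sample_id)
    means = means.dropna()

    out = means.reset_index()
    out["delta_ct"] = out[target_gene] - out[reference_gene]
    controls = out.loc[out["condition"] == "control", "delta_ct"]
    if controls.empty:
        raise ValueError("no control samples in the Ct table")
    baseline = controls.median() if control_summary == "median" else controls.mean()
    out["delta_delta_ct"] = out["delta_ct"] - baseline
    out["fold_change"] = efficiency ** (-out["delta_delta_ct"])
    return out[["sample_id", "condition", "delta_ct", "delta_delta_ct", "fold_change"]]


# ---------------------------------------------------------------------------
# Wilcoxon tests
# ---------------------------------------------------------------------------

def _two_sided_p(null_stats: np.ndarray, observed: float) -> float:
    """Symmetric two-sided p from an enumerated null distribution."""
    center = null_stats.mean()
    tol = 1e-9
    return float((np.abs(null_stats - center) >= abs(observed - center) - tol).mean())


def _signed_rank(d: np.ndarray) -> TestResult:
    nonzero = d[d != 0]
    n_dropped = len(d) - len(nonzero)
    if n_dropped:
        logger.warning("wilcoxon signed-rank: dropped %d zero differences", n_dropped)
    n = len(nonzero)
    if n == 0:
        return TestResult(float("nan"), float("nan"), 0, n_dropped, "undefined")
    ranks = sps.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= EXACT_MAX_N:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        null = signs @ ranks
        return TestResult(w_plus, _two_sided_p(null, w_plus), n, n_dropped, "exact")
    mean = ranks.sum() / 2.0
    var = float((ranks**2).sum()) / 4.0  # midranks make this tie-corrected
    z = (w_plus - mean) / math.sqrt(var)
    return TestResult(w_plus, float(2.0 * sps.norm.sf(abs(z))), n, n_dropped, "normal_approx")


def _rank_sum(a: np.ndarray, b: np.ndarray) -> TestResult:
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    if n <= EXACT_MAX_N:
        null = np.array(
            [ranks[list(idx)].sum() for idx in itertools.combinations(range(n), n1)]
        )
        return TestResult(w, _two_sided_p(null, w), n, 0, "exact")
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = (w - mean) / math.sqrt(var)
    return TestResult(w, float(2.0 * sps.norm.sf(abs(z))), n, 0, "normal_approx")


def wilcoxon_test(a, b=None, mode: str = "signed_rank") -> TestResult:
    """Wilcoxon test, exact for small samples.

    * ``signed_rank`` — paired vectors (``b`` a vector) or one-sample
      against a constant (``b`` a scalar, e.g. 1.0 for control-normalized
      fold changes). Zero differences are dropped with the count reported;
      all-zero data leaves the p-value undefined (NaN), never 1 or 0.
    * ``rank_sum`` — two independent vectors.
    """
    a = np.asarray(a, dtype=float)
    if mode == "signed_rank":
        if b is None:
            raise ValueError("signed_rank needs paired data or a null value")
        b_arr = np.asarray(b, dtype=float)
        d = a - b_arr if b_arr.ndim else a - float(b_arr)
        if d.ndim != 1 or len(d) < 3:
            raise ValueError("need >= 3 paired observations")
        return _signed_rank(d)
    if mode == "rank_sum":
        b_arr = np.asarray(b, dtype=float)
        if len(a) < 3 or len(b_arr) < 3:
            raise ValueError("need >= 3 observations per group")
        return _rank_sum(a, b_arr)
    raise ValueError(f"unknown mode {mode!r}")


def t_test(a, b) -> TestResult:
    """Two-sided Student's t with pooled variance, n1 + n2 − 2 df.

    Zero pooled variance with equal means gives t = 0, p = 1; with unequal
    means the statistic is degenerate and the result is flagged undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TestResult(0.0, 1.0, n1 + n2, 0, "pooled_t")
        logger.warning("t_test: zero pooled variance with unequal means; degenerate")
        return TestResult(math.copysign(math.inf, diff), float("nan"), n1 + n2, 0, "degenerate")
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return TestResult(float(t), float(2.0 * sps.t.sf(abs(t), df=df)), n1 + n2, 0, "pooled_t")


# ---------------------------------------------------------------------------
# Viability normalization
# ---------------------------------------------------------------------------

def normalize_viability(v: pd.DataFrame) -> pd.DataFrame:
    """Normalize each measurement to the mean drug-free value of its own arm.

    ``v`` has columns ``cell_line, arm, concentration, value``; the
    drug-free rows are those with concentration 0. The returned frame adds
    a ``normalized`` column; drug-free rows normalize to mean 1 per
    (cell line, arm) by construction.
    """
    missing = set(VIABILITY_COLUMNS) - set(v.columns)
    if missing:
        raise ValueError(f"viability table missing columns: {sorted(missing)}")
    out = v.copy()
    out["normalized"] = np.nan
    for (cell_line, arm), group in v.groupby(["cell_line", "arm"]):
        baseline_rows = group.loc[group["concentration"] == 0, "value"]
        if baseline_rows.empty:
            raise ValueError(f"no drug-free row for ({cell_line}, {arm})")
        baseline = baseline_rows.mean()
        if baseline == 0:
            raise ValueError(f"zero drug-free baseline for ({cell_line}, {arm})")
        out.loc[group.index, "normalized"] = group["value"] / baseline
    return out
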