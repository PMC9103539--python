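"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately written by the most direct route available
(per-base arrays, exhaustive scans, full enumeration) and shares no code
with the implementation under test.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)


def exhaustive_align(read: str, locus: str, k: int, both_strands: bool = True):
    """Every (position, strand, mismatches) with Hamming distance <= k.

    N on either side counts as a mismatch. Vectorized over all offsets with
    a sliding-window view; independent of the pigeonhole mapper.
    """
    hits = set()
    enc_locus = _encode(locus)
    n_off = len(locus) - len(read) + 1
    if n_off <= 0:
        return hits
    windows = np.lib.stride_tricks.sliding_window_view(enc_locus, len(read))
    orientations = [("+", read)] + ([("-", revcomp(read))] if both_strands else [])
    for strand, seq in orientations:
        enc_read = _encode(seq)
        mm = (windows != enc_read) | (windows == 4) | (enc_read == 4)
        counts = mm.sum(axis=1)
        for pos in np.flatnonzero(counts <= k):
            hits.add((int(pos), strand, int(counts[pos])))
    return hits


def merge_by_occupancy(intervals: list[tuple[int, int]]):
    """Union of intervals (bookended intervals combine) via a boolean
    per-base occupancy array."""
    if not intervals:
        return []
    hi = max(e for _, e in intervals)
    occupied = np.zeros(hi + 1, dtype=bool)
    for s, e in intervals:
        occupied[s:e] = True
    merged, start = [], None
    for pos in range(hi + 1):
        if occupied[pos] and start is None:
            start = pos
        elif not occupied[pos] and start is not None:
            merged.append((start, pos))
            start = None
    if start is not None:
        merged.append((start, hi + 1))
    return merged


def overlap_fraction_by_base(a: tuple[int, int], b: tuple[int, int]) -> float:
    count = sum(1 for pos in range(a[0], a[1]) if b[0] <= pos < b[1])
    return count / (a[1] - a[0])


def dense_runs_by_scan(depth, c: int, L: int, g: int):
    """Dense sub-regions by a direct stateful left-to-right scan."""
    regions = []
    cur_start = None
    last_above = None
    for pos, d in enumerate(depth):
        if d >= c:
            if cur_start is None:
                cur_start = pos
            elif pos - (last_above + 1) > g:
                if last_above + 1 - cur_start >= L:
                    regions.append((cur_start, last_above + 1))
                cur_start = pos
            last_above = pos
    if cur_start is not None and last_above + 1 - cur_start >= L:
        regions.append((cur_start, last_above + 1))
    return regions


def repeat_overlap_frac_by_base(sub: tuple[int, int], repeats: list[tuple[int, int]]) -> float:
    covered = sum(
        1 for pos in range(sub[0], sub[1]) if any(s <= pos < e for s, e in repeats)
    )
    return covered / (sub[1] - sub[0])


def coverage_by_base(alignments: list[tuple[int, int]], length: int) -> np.ndarray:
    depth = np.zeros(length, dtype=int)
    for start, read_len in alignments:
        for pos in range(start, start + read_len):
            depth[pos] += 1
    return depth


# ---------------------------------------------------------------------------
# Funnel recount from generator ground truth alone
# ---------------------------------------------------------------------------

def recount_funnel(
    truth,
    locus_length: int,
    flank: int,
    read_len: int,
    min_cov: int,
    min_len: int,
    max_gap: int,
):
    """Expected per-stage survivor counts computed from GroundTruth only.

    Uses read origins (not alignments), per-base occupancy merging, the
    stateful dense-run scan and per-base repeat overlap — no pipeline code.
    Returns a dict of stage name -> expected survivor count.
    """
    windows = [
        (max(0, s - flank), min(locus_length, s + flank)) for s in truth.summits
    ]
    origins = [(iv.start, iv.end) for iv in truth.read_origins.values()]
    covered_windows = [
        w for w in windows if any(os < w[1] and w[0] < oe for os, oe in origins)
    ]
    merged = merge_by_occupancy(covered_windows)

    depth = coverage_by_base([(s, e - s) for s, e in origins], locus_length)
    repeats = [(r.interval.start, r.interval.end) for r in truth.repeats
               if r.repeat_class.value in ("SINE", "LINE", "LTR", "DNA")]
    exons = [] if truth.lncrna is None else [(e.start, e.end) for e in truth.lncrna.exons]

    n_dense = n_repeat_free = n_annotated = 0
    for ms, me in merged:
        subs = [
            (ms + s, ms + e)
            for s, e in dense_runs_by_scan(depth[ms:me], min_cov, min_len, max_gap)
        ]
        if subs:
            n_dense += 1
        survivors = [sub for sub in subs if repeat_overlap_frac_by_base(sub, repeats) == 0.0]
        if survivors:
            n_repeat_free += 1
            if any(s < ee and es < e for s, e in survivors for es, ee in exons):
                n_annotated += 1
    return {
        "constructed": len(windows),
        "covered": len(covered_windows),
        "merged": len(merged),
        "dense_subregion": n_dense,
        "repeat_free": n_repeat_free,
        "annotated": n_annotated,
    }


# ---------------------------------------------------------------------------
# Statistics oracles
# ---------------------------------------------------------------------------

def average_ranks(values) -> list[float]:
    """Midranks computed by explicit sorting, no scipy."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for idx in order[i : j + 1]:
            ranks[idx] = avg
        i = j + 1
    return ranks


def spearman_rho_by_hand(x, y) -> float:
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    ) ** 0.5
    return num / den


def spearman_exact_p_by_enumeration(x, y) -> float:
    """Two-sided exact p over all n! permutations of y."""
    rho_obs = abs(spearman_rho_by_hand(x, y))
    count = total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho_by_hand(x, perm)) >= rho_obs - 1e-12:
            count += 1
    return count / total


def signed_rank_p_by_enumeration(diffs) -> float:
    """Exact two-sided signed-rank p over all 2^n sign assignments."""
    d = [v for v in diffs if v != 0]
    ranks = average_ranks([abs(v) for v in d])
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    total_rank = sum(ranks)
    center = total_rank / 2
    count = total = 0
    for signs in itertools.product((False, True), repeat=len(d)):
        total += 1
        w = sum(r for r, pos in zip(ranks, signs) if pos)
        if abs(w - center) >= abs(w_obs - center) - 1e-9:
            count += 1
    return count / total


def rank_sum_p_by_enumeration(a, b) -> float:
    """Exact two-sided rank-sum p over all group assignments."""
    pooled = list(a) + list(b)
    ranks = average_ranks(pooled)
    n1, n = len(a), len(pooled)
    w_obs = sum(ranks[:n1])
    stats = [
        sum(ranks[i] for i in combo)
        for combo in itertools.combinations(range(n), n1)
    ]
    center = sum(stats) / len(stats)
    return sum(1 for w in stats if abs(w - center) >= abs(w_obs - center) - 1e-9) / len(stats)


def t_test_by_hand(a, b):
    """Pooled two-sample t statistic by the textbook formula (no scipy here;
    the caller compares the statistic, and the p via scipy in the test)."""
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((v - m1) ** 2 for v in a) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    return (m1 - m2) / (sp2 * (1 / n1 + 1 / n2)) ** 0.5


def ddct_by_spreadsheet(rows, target, reference, efficiency=2.0):
    """Fold changes recomputed spreadsheet-style from raw Ct rows.

    rows: list of (sample_id, condition, gene, ct). Returns
    {sample_id: fold_change}.
    """
    sums: dict[tuple, list] = {}
    for sample, cond, gene, ct in rows:
        sums.setdefault((sample, cond, gene), []).append(ct)
    mean_ct = {k: sum(v) / len(v) for k, v in sums.items()}
    delta = {}
    for (sample, cond, gene) in list(mean_ct):
        if gene != target:
            continue
        ref_key = (sample, cond, reference)
        if ref_key in mean_ct:
            delta[(sample, cond)] = mean_ct[(sample, cond, gene)] - mean_ct[ref_key]
    controls = sorted(v for (s, c), v in delta.items() if c == "control")
    mid = len(controls) // 2
    median = (
        controls[mid] if len(controls) % 2 else (controls[mid - 1] + controls[mid]) / 2
    )
    return {s: efficiency ** -(v - median) for (s, c), v in delta.items()}
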