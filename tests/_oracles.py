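"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over dense arrays, deliberately
avoiding the vectorised code paths of the package.
"""
from __future__ import annotations

import math

import numpy as np


def cell_totals_loop(counts: np.ndarray) -> list[int]:
    """Per-column totals by explicit double loop."""
    n_genes, n_cells = counts.shape
    totals = []
    for j in range(n_cells):
        s = 0
        for i in range(n_genes):
            s += counts[i, j]
        totals.append(int(s))
    return totals


def cell_filter_loop(
    counts: np.ndarray, mito_rows: list[int], min_umi: int, max_mito: float
) -> list[int]:
    """Indices of cells kept by the UMI floor and mito ceiling, via loops."""
    keep = []
    for j in range(counts.shape[1]):
        total = sum(int(counts[i, j]) for i in range(counts.shape[0]))
        mito = sum(int(counts[i, j]) for i in mito_rows)
        frac = mito / total if total > 0 else 0.0
        if total >= min_umi and frac <= max_mito:
            keep.append(j)
    return keep


def gene_filter_loop(
    counts: np.ndarray, min_count: int, min_cells: int
) -> list[int]:
    """Indices of genes with >= min_count counts in >= min_cells cells."""
    keep = []
    for i in range(counts.shape[0]):
        n_expressing = sum(
            1 for j in range(counts.shape[1]) if counts[i, j] >= min_count
        )
        if n_expressing >= min_cells:
            keep.append(i)
    return keep


def hvg_selection_loop(
    linear: np.ndarray, gene_ids: list[str], n_top: int, n_bins: int
) -> set[str]:
    """Independent re-implementation of binned-dispersion HVG ranking."""
    G = linear.shape[0]
    stats = []
    for i in range(G):
        vals = linear[i]
        mean = float(np.mean(vals))
        var = float(np.mean((vals - mean) ** 2))
        disp = var / mean if mean > 0 else 0.0
        stats.append((gene_ids[i], mean, disp))
    # equal-frequency bins on (mean, gene_id)
    by_mean = sorted(range(G), key=lambda i: (stats[i][1], stats[i][0]))
    bin_of = {}
    for rank, i in enumerate(by_mean):
        bin_of[i] = rank * n_bins // G
    scaled = {}
    for b in range(n_bins):
        members = [i for i in range(G) if bin_of[i] == b]
        disps = sorted(stats[i][2] for i in members)
        med = _median(disps)
        mad = _median(sorted(abs(d - med) for d in disps))
        for i in members:
            scaled[i] = 0.0 if mad == 0 else (stats[i][2] - med) / mad
    ranked = sorted(range(G), key=lambda i: (-scaled[i], stats[i][0]))
    return {stats[i][0] for i in ranked[:n_top]}


def _median(sorted_vals: list[float]) -> float:
    n = len(sorted_vals)
    mid = n // 2
    if n % 2:
        return sorted_vals[mid]
    return 0.5 * (sorted_vals[mid - 1] + sorted_vals[mid])


def bh_adjust_loop(pvals: list[float]) -> list[float]:
    """BH step-up from the definition: q_(i) = min_{j>=i} m * p_(j) / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    for pos, i in enumerate(order):
        candidates = [
            m * pvals[order[j]] / (j + 1) for j in range(pos, m)
        ]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def size_factors_loop(counts: np.ndarray) -> list[float]:
    """Median-of-ratios size factors from the definition."""
    G, n = counts.shape
    rows = [i for i in range(G) if all(counts[i, j] > 0 for j in range(n))]
    geomeans = {
        i: math.exp(sum(math.log(counts[i, j]) for j in range(n)) / n)
        for i in rows
    }
    factors = []
    for j in range(n):
        ratios = sorted(counts[i, j] / geomeans[i] for i in rows)
        factors.append(_median(ratios))
    log_gm = sum(math.log(f) for f in factors) / n
    return [f / math.exp(log_gm) for f in factors]


def hypergeom_upper_tail_loop(
    universe: int, set_size: int, query: int, overlap: int
) -> float:
    """P(X >= overlap) by summing hypergeometric point masses exactly."""
    def comb(n, k):
        return math.comb(n, k) if 0 <= k <= n else 0

    total = comb(universe, query)
    p = 0.0
    for k in range(overlap, min(set_size, query) + 1):
        p += comb(set_size, k) * comb(universe - set_size, query - k) / total
    return p


def gmm_two_group_split_loop(scores: list[float]) -> list[bool]:
    """Best two-group split of 1-D scores by Gaussian likelihood.

    Tries every threshold between sorted neighbours; within each side the
    Gaussian MLE (mean, variance with a small floor) scores the split.  The
    group with the larger mean is 'high'.
    """
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    best, best_ll = None, -np.inf
    for cut in range(1, len(scores)):
        low = [scores[i] for i in order[:cut]]
        high = [scores[i] for i in order[cut:]]
        ll = 0.0
        for grp in (low, high):
            mu = sum(grp) / len(grp)
            var = max(sum((x - mu) ** 2 for x in grp) / len(grp), 1e-6)
            ll += sum(
                -0.5 * math.log(2 * math.pi * var) - (x - mu) ** 2 / (2 * var)
                for x in grp
            )
        if ll > best_ll:
            best_ll, best = ll, cut
    high_set = set(order[best:])
    return [i in high_set for i in range(len(scores))]
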