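"""Negative-binomial differential expression with BH correction.

One NB engine serves two unit conventions: bulk samples (median-of-ratios
size factors, five-replicate designs) and single cells within an annotated
class (size factors = per-cell totals / median total).  The model is a
per-gene NB GLM with log link and a two-group indicator, fitted by Newton
iterations vectorized across genes; inference is a Wald test on the group
coefficient (default) or a likelihood-ratio test.  The NB is parameterised
mean/dispersion with variance = mu + phi * mu**2; per-gene dispersions are
method-of-moments estimates shrunk toward a parametric mean-dispersion
trend.  P-values are Benjamini-Hochberg adjusted, and a gene is called
differentially expressed when |log2 fold change| >= log2(1.5) and the
adjusted p-value is <= 0.05 (both thresholds configurable).

The modelling surface follows the Model/Results convention:
``NegativeBinomialDE(counts, groups).fit()`` returns a :class:`DEResults`
carrying the per-gene table and a ``summary()``.
"""
from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.special import gammaln
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix

logger = logging.getLogger("dmhseq")

_DISPERSION_FLOOR = 1e-8


@dataclasses.dataclass
class DGEConfig:
    """Calling rule and test options."""

    fold_threshold: float = 1.5
    alpha: float = 0.05
    test: str = "wald"  # or "lrt"
    min_total_count: int = 10
    shrinkage_weight: float = 0.5  # weight of the trend in dispersion shrinkage

    def __post_init__(self) -> None:
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in ("wald", "lrt"):
            raise ValueError("test must be 'wald' or 'lrt'")


# ----------------------------------------------------------------- size factors
def size_factors_median_of_ratios(m: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample the factor is the median, over genes expressed in every
    sample, of the ratio of the sample's count to the gene's geometric mean.
    """
    counts = m.values.toarray() if isinstance(m, CountMatrix) else np.asarray(m)
    counts = counts.astype(float)
    everywhere = (counts > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no gene expressed in all samples; cannot size-factor")
    sub = counts[everywhere]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    return factors


def total_count_size_factors(m: CountMatrix | np.ndarray) -> np.ndarray:
    """Per-cell totals over the median total (the single-cell convention)."""
    counts = m.values if isinstance(m, CountMatrix) else sp.csr_matrix(m)
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    if (totals <= 0).any():
        raise ValueError("zero-total column; filter cells first")
    return totals / np.median(totals)


# ------------------------------------------------------------------ dispersion
def estimate_dispersion(
    counts: np.ndarray,
    size_factors: np.ndarray,
    groups: np.ndarray,
    shrinkage_weight: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersion: moments estimate shrunk toward the trend.

    The raw estimate solves the moment equation for size-factor-normalized
    counts: for a gene with scaled mean mu, Var(count_j / s_j) =
    mu / s_j + phi * mu**2, so phi = (within-group variance -
    mu * mean(1/s)) / mu**2, clipped at 0.  A parametric trend
    phi(mu) = a/mu + b is fitted by least squares across genes and the
    final value is the weighted average
    ``(1 - w) * raw + w * trend`` with floor 1e-8.  All-zero genes get NaN
    (untestable).
    """
    counts = np.asarray(counts, dtype=float)
    y = counts / size_factors[None, :]
    mean = y.mean(axis=1)
    inv_s = float(np.mean(1.0 / size_factors))

    levels = pd.unique(groups)
    n = y.shape[1]
    resid_ss = np.zeros(counts.shape[0])
    for lev in levels:
        cols = groups == lev
        sub = y[:, cols]
        resid_ss += ((sub - sub.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    var = resid_ss / max(n - len(levels), 1)

    # raw estimates are left unclipped below zero so that, under Poisson-like
    # data, negative excursions cancel in the trend instead of biasing it up
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (var - mean * inv_s) / np.maximum(mean, 1e-300) ** 2
    raw = np.minimum(raw, 50.0)
    testable = mean > 0
    raw[~testable] = np.nan

    # parametric trend a/mu + b, fitted to per-bin winsorized means of the
    # raw dispersions so that genes with real biological structure (markers)
    # cannot drag it up while the bulk estimate stays nearly unbiased
    mu_t = mean[testable]
    raw_t = raw[testable]
    n_bins = min(20, max(1, mu_t.size // 5))
    order = np.argsort(mu_t)
    edges = np.array_split(order, n_bins)

    def _winsor_mean(values: np.ndarray) -> float:
        cap = np.quantile(values, 0.9)
        return float(np.minimum(values, cap).mean())

    bin_mu = np.array([np.median(mu_t[idx]) for idx in edges if idx.size])
    bin_phi = np.array([_winsor_mean(raw_t[idx]) for idx in edges if idx.size])
    design = np.column_stack([1.0 / bin_mu, np.ones_like(bin_mu)])
    coef, *_ = np.linalg.lstsq(design, bin_phi, rcond=None)
    a, b = np.maximum(coef, 0.0)
    trend = np.full_like(mean, np.nan)
    trend[testable] = a / mu_t + b

    w = shrinkage_weight
    phi = (1 - w) * raw + w * trend
    phi = np.clip(phi, _DISPERSION_FLOOR, 50.0)
    phi[~testable] = np.nan
    return phi


# ------------------------------------------------------------------- NB engine
def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Row sums of the NB log-likelihood; safe at mu == 0."""
    r = 1.0 / phi
    mu_safe = np.maximum(mu, 1e-300)
    ll = (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu_safe / (r + mu))
    )
    ll = np.where((mu == 0) & (y == 0), 0.0, ll)
    ll = np.where((mu == 0) & (y > 0), -np.inf, ll)
    return ll.sum(axis=1)


def _fit_log_means(
    y: np.ndarray, s: np.ndarray, phi: np.ndarray, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """MLE of the per-gene group mean q (log link) and its Fisher information.

    Solves sum_j (y_j - s_j q) / (1 + phi s_j q) = 0 by Newton steps on
    theta = log q, vectorized across genes.  Returns (q, info) where info is
    the observed Fisher information of theta at the optimum.
    """
    tot = y.sum(axis=1)
    zero = tot == 0
    q = np.where(zero, 0.0, tot / s.sum())
    theta = np.log(np.maximum(q, 1e-300))
    active = ~zero
    for _ in range(max_iter):
        mu = np.exp(theta)[:, None] * s[None, :]
        denom = 1.0 + phi[:, None] * mu
        score = ((y - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.where(active & (info > 0), score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -5.0, 5.0)
        theta = theta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    mu = np.exp(theta)[:, None] * s[None, :]
    info = (mu / (1.0 + phi[:, None] * mu)).sum(axis=1)
    q = np.where(zero, 0.0, np.exp(theta))
    return q, np.where(zero, 0.0, info)


@dataclasses.dataclass
class DEResults:
    """Fitted differential-expression results.

    ``frame`` columns: gene_id, base_mean, log2_fold_change (B over A),
    dispersion, stat, p_value, p_adjusted, is_deg, untestable.
    """

    frame: pd.DataFrame
    contrast: tuple[str, str]
    config: DGEConfig
    n_units: tuple[int, int]  # samples or cells per group

    @property
    def degs(self) -> pd.DataFrame:
        return self.frame.loc[self.frame["is_deg"]]

    def summary(self) -> str:
        f = self.frame
        up = int((f["is_deg"] & (f["log2_fold_change"] > 0)).sum())
        down = int((f["is_deg"] & (f["log2_fold_change"] < 0)).sum())
        lines = [
            "Negative-binomial differential expression",
            "=" * 46,
            f"contrast:        {self.contrast[1]} vs {self.contrast[0]}"
            f"  (n = {self.n_units[1]} vs {self.n_units[0]})",
            f"test:            {self.config.test}",
            f"genes:           {len(f)} ({int(f['untestable'].sum())} untestable)",
            f"calling rule:    |fold| >= {self.config.fold_threshold}"
            f" and BH-adjusted p <= {self.config.alpha}",
            f"DEGs:            {up + down} ({up} up, {down} down)",
        ]
        return "\n".join(lines)


class NegativeBinomialDE:
    """Two-group NB differential-expression model.

    Parameters
    ----------
    counts
        Integer counts, genes x units (samples or cells).
    groups
        Per-unit group label with exactly two levels.
    gene_ids
        Optional gene identifiers.
    size_factors
        Per-unit scaling; computed by median-of-ratios when omitted.
    dispersions
        Optional per-gene dispersions; estimated when omitted.
    contrast
        ``(reference, treatment)``; fold changes are treatment over
        reference.  Defaults to the two levels in order of appearance.
    """

    def __init__(
        self,
        counts: np.ndarray | sp.spmatrix,
        groups: Sequence[str],
        *,
        gene_ids: Sequence[str] | None = None,
        size_factors: np.ndarray | None = None,
        dispersions: np.ndarray | None = None,
        contrast: tuple[str, str] | None = None,
        config: DGEConfig | None = None,
    ) -> None:
        self.counts = (
            counts.toarray() if sp.issparse(counts) else np.asarray(counts)
        ).astype(float)
        self.groups = np.asarray(groups, dtype=object)
        if self.counts.shape[1] != len(self.groups):
            raise ValueError("groups do not align with count columns")
        levels = list(pd.unique(self.groups))
        if len(levels) != 2:
            raise ValueError(f"need exactly two groups, got {levels}")
        if contrast is None:
            contrast = (levels[0], levels[1])
        if set(contrast) != set(levels):
            raise ValueError(f"contrast {contrast} does not match groups {levels}")
        self.contrast = contrast
        for lev in contrast:
            if not (self.groups == lev).any():
                raise ValueError(f"group {lev!r} is empty")
        self.gene_ids = (
            np.asarray(gene_ids, dtype=object)
            if gene_ids is not None
            else np.array([f"g{i}" for i in range(self.counts.shape[0])], object)
        )
        self.size_factors = size_factors
        self.dispersions = dispersions
        self.config = config or DGEConfig()

    @classmethod
    def from_count_matrix(
        cls,
        m: CountMatrix,
        *,
        contrast: tuple[str, str] | None = None,
        config: DGEConfig | None = None,
        size_factors: np.ndarray | None = None,
    ) -> "NegativeBinomialDE":
        """Build from a CountMatrix using its ``condition`` labels."""
        return cls(
            m.values,
            m.column_labels["condition"].to_numpy(),
            gene_ids=m.gene_ids,
            contrast=contrast,
            config=config,
            size_factors=size_factors,
        )

    def fit(self) -> DEResults:
        cfg = self.config
        counts = self.counts
        sf = (
            self.size_factors
            if self.size_factors is not None
            else size_factors_median_of_ratios(counts)
        )
        sf = np.asarray(sf, dtype=float)
        phi = (
            np.asarray(self.dispersions, dtype=float)
            if self.dispersions is not None
            else estimate_dispersion(counts, sf, self.groups, cfg.shrinkage_weight)
        )
        if np.isscalar(self.dispersions):
            phi = np.full(counts.shape[0], float(self.dispersions))

        a_mask = self.groups == self.contrast[0]
        b_mask = self.groups == self.contrast[1]
        untestable = (counts.sum(axis=1) < cfg.min_total_count) | np.isnan(phi)
        phi_safe = np.where(np.isnan(phi), 1.0, np.maximum(phi, _DISPERSION_FLOOR))

        q_a, info_a = _fit_log_means(counts[:, a_mask], sf[a_mask], phi_safe)
        q_b, info_b = _fit_log_means(counts[:, b_mask], sf[b_mask], phi_safe)
        q_0, _ = _fit_log_means(counts, sf, phi_safe)

        with np.errstate(divide="ignore", invalid="ignore"):
            log2fc = np.log2(q_b) - np.log2(q_a)

        # Wald on the group coefficient where both groups are informative
        both = (q_a > 0) & (q_b > 0)
        stat = np.full(counts.shape[0], np.nan)
        p = np.full(counts.shape[0], np.nan)
        if cfg.test == "wald":
            se = np.sqrt(
                1.0 / np.maximum(info_a, 1e-300) + 1.0 / np.maximum(info_b, 1e-300)
            )
            z = np.where(both, (np.log(np.maximum(q_b, 1e-300))
                                - np.log(np.maximum(q_a, 1e-300))) / se, np.nan)
            stat[both] = z[both]
            p[both] = 2.0 * norm.sf(np.abs(z[both]))
            lrt_needed = ~both & ~untestable
        else:
            lrt_needed = ~untestable

        if lrt_needed.any():
            idx = np.flatnonzero(lrt_needed)
            mu_a = q_a[idx, None] * sf[None, a_mask]
            mu_b = q_b[idx, None] * sf[None, b_mask]
            mu_0 = q_0[idx, None] * sf[None, :]
            ll_alt = (
                _nb_loglik(counts[idx][:, a_mask], mu_a, phi_safe[idx, None])
                + _nb_loglik(counts[idx][:, b_mask], mu_b, phi_safe[idx, None])
            )
            ll_null = _nb_loglik(counts[idx], mu_0, phi_safe[idx, None])
            lr = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
            stat[idx] = lr
            p[idx] = chi2.sf(lr, df=1)

        p[untestable] = np.nan
        stat[untestable] = np.nan
        base_mean = (counts / sf[None, :]).mean(axis=1)

        frame = pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "base_mean": base_mean,
                "log2_fold_change": log2fc,
                "dispersion": phi,
                "stat": stat,
                "p_value": p,
                "p_adjusted": bh_adjust(p),
                "untestable": untestable,
            }
        )
        frame["is_deg"] = _deg_mask(frame, cfg)
        n_a, n_b = int(a_mask.sum()), int(b_mask.sum())
        return DEResults(frame, self.contrast, cfg, (n_a, n_b))


# ------------------------------------------------------------------ adjustment
def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NaN entries pass through unchanged and do not count toward the number of
    tests.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        pv = p[valid]
        if (pv < 0).any() or (pv > 1).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[valid] = multipletests(pv, method="fdr_bh")[1]
    return out


def _deg_mask(frame: pd.DataFrame, cfg: DGEConfig) -> np.ndarray:
    lfc = frame["log2_fold_change"].to_numpy()
    padj = frame["p_adjusted"].to_numpy()
    with np.errstate(invalid="ignore"):
        fold_ok = np.abs(lfc) >= math.log2(cfg.fold_threshold)
    return fold_ok & ~np.isnan(padj) & (padj <= cfg.alpha)


def call_degs(results: DEResults | pd.DataFrame, cfg: DGEConfig | None = None):
    """Apply the calling rule: |fold| >= threshold and adjusted p <= alpha."""
    cfg = cfg or DGEConfig()
    if isinstance(results, DEResults):
        results.frame["is_deg"] = _deg_mask(results.frame, cfg)
        return results
    frame = results.copy()
    frame["is_deg"] = _deg_mask(frame, cfg)
    return frame


# ------------------------------------------------------------------ interfaces
def nb_test(
    m: CountMatrix,
    size_factors: np.ndarray | None = None,
    dispersions: np.ndarray | None = None,
    contrast: tuple[str, str] | None = None,
    config: DGEConfig | None = None,
) -> DEResults:
    """Functional wrapper around :class:`NegativeBinomialDE`."""
    model = NegativeBinomialDE(
        m.values,
        m.column_labels["condition"].to_numpy(),
        gene_ids=m.gene_ids,
        size_factors=size_factors,
        dispersions=dispersions,
        contrast=contrast,
        config=config,
    )
    return model.fit()


def sc_group_test(
    m: CountMatrix,
    cell_classes: Sequence[str],
    class_value: str,
    contrast: tuple[str, str] | None = None,
    config: DGEConfig | None = None,
    min_cells: int = 20,
) -> DEResults:
    """NB test between conditions within one annotated cell class.

    Cells are the units; size factors are per-cell totals over the median
    total of the class's cells.
    """
    cell_classes = np.asarray(cell_classes, dtype=object)
    if len(cell_classes) != m.n_columns:
        raise ValueError("cell class labels do not align with matrix columns")
    mask = cell_classes == class_value
    if not mask.any():
        raise ValueError(f"no cells in class {class_value!r}")
    sub = m.subset_columns(mask)
    conds = sub.column_labels["condition"].to_numpy()
    for lev in pd.unique(conds):
        if (conds == lev).sum() < min_cells:
            raise ValueError(
                f"class {class_value!r}: fewer than {min_cells} cells "
                f"in condition {lev!r}"
            )
    model = NegativeBinomialDE(
        sub.values,
        conds,
        gene_ids=sub.gene_ids,
        size_factors=total_count_size_factors(sub),
        contrast=contrast,
        config=config,
    )
    return model.fit()
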