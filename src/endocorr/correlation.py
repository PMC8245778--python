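"""Correlation kernel: average-tie ranking, Spearman/Pearson with p-values,
and Benjamini-Hochberg FDR adjustment.

Spearman is computed as Pearson on average-tie ranks; the two-sided p-value
comes from the t statistic ``t = rho * sqrt((n - 2) / (1 - rho**2))`` with
``n - 2`` degrees of freedom (``|rho| = 1`` maps to ``p = 0`` by convention).
Missing values are handled by pairwise-complete observations and the
effective ``n`` is reported per correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = [
    "CorrelationResult",
    "rank_average_ties",
    "correlate",
    "bh_adjust",
    "pairwise_marker_correlations",
]

_METHODS = ("spearman", "pearson")


@dataclass(frozen=True)
class CorrelationResult:
    """A single correlation with its two-sided p-value.

    ``rho`` and ``p_raw`` are NaN when the correlation is undefined
    (constant input after pairwise-complete filtering, or n < 3); the
    reason is carried in ``reason`` and the result must be treated as
    missing, never as zero.
    """

    rho: float
    p_raw: float
    n: int
    method: str
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def rank_average_ties(values) -> np.ndarray:
    """Rank a vector 1..n, tied values sharing the mean of their ranks.

    Raises :class:`DataError` naming the offending positions if any value
    is NaN or infinite.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise DataError("rank_average_ties requires a non-empty 1-d vector")
    bad = np.flatnonzero(~np.isfinite(arr))
    if bad.size:
        raise DataError(
            f"non-finite values at positions {bad.tolist()} cannot be ranked"
        )
    return stats.rankdata(arr, method="average")


def _p_from_t(rho: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the t approximation; |rho|=1 -> 0."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, p)


def correlate(x, y, method: str = "spearman") -> CorrelationResult:
    """Correlate two equal-length vectors with pairwise-complete handling.

    Constant vectors (after removing incomplete pairs) yield a flagged
    undefined result rather than an exception or a silent zero.
    """
    if method not in _METHODS:
        raise DataError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(
            f"length mismatch: x has shape {x.shape}, y has shape {y.shape}"
        )
    if x.size < 3:
        raise DataError(f"need at least 3 paired observations, got {x.size}")
    mask = np.isfinite(x) & np.isfinite(y)
    xs, ys = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3:
        return CorrelationResult(np.nan, np.nan, n, method, reason="n_lt_3")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return CorrelationResult(np.nan, np.nan, n, method, reason="constant")
    if method == "spearman":
        xs = rank_average_ties(xs)
        ys = rank_average_ties(ys)
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    rho = float(xs @ ys / math.sqrt((xs @ xs) * (ys @ ys)))
    rho = max(-1.0, min(1.0, rho))
    return CorrelationResult(rho, float(_p_from_t(rho, n)), n, method)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Missing (NaN) entries are preserved in place and excluded from ``m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_adjust requires a 1-d vector")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise DataError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(q, 1.0)
    # guard against 1-ulp rounding in p*m/j so that adjusted >= raw holds
    out[finite] = np.maximum(adj, pv)
    return out


def pairwise_marker_correlations(
    values: np.ndarray, marker_values: np.ndarray, method: str = "spearman"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlate every row of ``values`` (genes x samples) against every row
    of ``marker_values`` (markers x samples).

    Returns ``(rho, p, n)`` each of shape (genes, markers). Rows containing
    missing values fall back to the pairwise-complete scalar kernel; the
    complete-data majority goes through a vectorized rank/centering path.
    Zero-variance rows produce NaN.
    """
    if method not in _METHODS:
        raise DataError(f"unknown correlation method {method!r}")
    values = np.asarray(values, dtype=float)
    marker_values = np.asarray(marker_values, dtype=float)
    n_genes, n_samples = values.shape
    n_markers = marker_values.shape[0]
    rho = np.full((n_genes, n_markers), np.nan)
    nmat = np.full((n_genes, n_markers), n_samples, dtype=int)

    gene_ok = np.isfinite(values).all(axis=1)
    marker_ok = np.isfinite(marker_values).all(axis=1)

    if gene_ok.any() and marker_ok.all():
        sub = values[gene_ok]
        if method == "spearman":
            sub = stats.rankdata(sub, method="average", axis=1)
            mk = stats.rankdata(marker_values, method="average", axis=1)
        else:
            mk = marker_values
        sub = sub - sub.mean(axis=1, keepdims=True)
        mk = mk - mk.mean(axis=1, keepdims=True)
        sn = np.sqrt(np.einsum("ij,ij->i", sub, sub))
        mn = np.sqrt(np.einsum("ij,ij->i", mk, mk))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sub @ mk.T) / np.outer(sn, mn)
        rho[gene_ok] = np.clip(r, -1.0, 1.0)

    # slow path: any gene row or marker row with missing entries
    slow_genes = np.flatnonzero(~gene_ok)
    slow_markers = np.flatnonzero(~marker_ok)
    for g in slow_genes:
        for m in range(n_markers):
            res = correlate(values[g], marker_values[m], method)
            rho[g, m], nmat[g, m] = res.rho, res.n
    if slow_markers.size:
        for m in slow_markers:
            for g in np.flatnonzero(gene_ok):
                res = correlate(values[g], marker_values[m], method)
                rho[g, m], nmat[g, m] = res.rho, res.n

    p = _p_from_t(rho, nmat)
    return rho, p, nmat
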