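"""Marker-panel enrichment screen.

Every gene (markers included, with self-correlation 1) is correlated with
each marker across samples; genes whose mean correlation exceeds a strict
threshold (default 0.3) form the enriched set. Ranks are assigned by
descending mean correlation, rank 1 = highest, ties broken lexicographically
by gene id. Zero-variance genes are reported in a side table with reason
codes, never dropped silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import bh_adjust, pairwise_marker_correlations
from .errors import ConfigError, DataError
from .io import ExpressionMatrix

DEFAULT_MARKERS = ("CDH5", "CLDN5", "VWF")


@dataclass(frozen=True)
class MarkerPanel:
    """The marker gene ids anchoring the screen."""

    marker_ids: tuple[str, ...] = DEFAULT_MARKERS

    def __post_init__(self) -> None:
        if len(self.marker_ids) < 2:
            raise ConfigError("marker panel needs at least 2 markers")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ConfigError("duplicate marker ids in panel")

    def validate_against(self, expr: ExpressionMatrix) -> None:
        for m in self.marker_ids:
            if m not in expr.data.index:
                raise ConfigError(
                    f"marker {m!r} absent from the expression matrix"
                )


@dataclass
class EnrichmentProfile:
    """Per-gene marker correlations and their mean.

    ``table`` is indexed by gene id with columns ``rho_<marker>`` per marker,
    ``mean_corr`` and ``p_raw``; ``excluded`` lists genes that could not be
    scored (reason codes such as ``constant``).
    """

    table: pd.DataFrame
    excluded: pd.DataFrame
    markers: tuple[str, ...]
    method: str
    n_samples: int


@dataclass
class EnrichmentResult:
    """Scored and thresholded screen: fdr, rank, enriched flag."""

    table: pd.DataFrame
    excluded: pd.DataFrame
    threshold: float
    markers: tuple[str, ...]
    method: str

    @property
    def enriched_genes(self) -> list[str]:
        return list(self.table.index[self.table["enriched"]])

    def ranks(self) -> pd.Series:
        return self.table["rank"]


def _combine_p(p: np.ndarray, how: str) -> np.ndarray:
    """Per-gene summary of the per-marker p-values (rows: genes)."""
    if how == "fisher":
        clipped = np.clip(p, 1e-300, 1.0)
        chi2 = -2.0 * np.log(clipped).sum(axis=1)
        return stats.chi2.sf(chi2, df=2 * p.shape[1])
    if how == "minp":
        # Sidak-style correction of the minimum p
        return 1.0 - (1.0 - p.min(axis=1)) ** p.shape[1]
    raise ConfigError(f"unknown p-value summary {how!r}")


def marker_correlation_profile(
    expr: ExpressionMatrix,
    panel: MarkerPanel | None = None,
    method: str = "spearman",
    p_summary: str = "fisher",
) -> EnrichmentProfile:
    """Correlate all genes against the marker panel.

    Markers are scored like any other gene, so their self-correlation of 1
    enters their own mean. Genes constant across samples are excluded from
    scoring and listed with a reason code.
    """
    panel = panel or MarkerPanel()
    panel.validate_against(expr)
    if len(expr.sample_ids) < 3:
        raise DataError(
            f"need at least 3 samples, got {len(expr.sample_ids)}"
        )
    values = expr.values
    marker_values = expr.data.loc[list(panel.marker_ids)].to_numpy()
    rho, p, _n = pairwise_marker_correlations(values, marker_values, method)

    scored = ~np.isnan(rho).any(axis=1)
    genes = np.asarray(expr.gene_ids)
    cols = {f"rho_{m}": rho[scored, i] for i, m in enumerate(panel.marker_ids)}
    table = pd.DataFrame(cols, index=pd.Index(genes[scored], name="gene_id"))
    table["mean_corr"] = rho[scored].mean(axis=1)
    table["p_raw"] = _combine_p(p[scored], p_summary)
    excluded = pd.DataFrame(
        {"reason": "constant"},
        index=pd.Index(genes[~scored], name="gene_id"),
    )
    return EnrichmentProfile(
        table=table,
        excluded=excluded,
        markers=tuple(panel.marker_ids),
        method=method,
        n_samples=len(expr.sample_ids),
    )


def enrichment_screen(
    profile: EnrichmentProfile, threshold: float = 0.3
) -> EnrichmentResult:
    """Apply the strict mean-correlation cutoff, FDR and ranking."""
    if not (-1.0 <= threshold < 1.0):
        raise ConfigError(f"threshold must lie in [-1, 1), got {threshold}")
    if profile.table.empty:
        raise DataError("empty enrichment profile: no scored genes")
    table = profile.table.copy()
    table["fdr"] = bh_adjust(table["p_raw"].to_numpy())
    order = (
        table.reset_index()
        .sort_values(["mean_corr", "gene_id"], ascending=[False, True],
                     kind="stable")["gene_id"]
    )
    rank = pd.Series(np.arange(1, len(order) + 1), index=order.to_numpy())
    table["rank"] = rank.reindex(table.index).astype(int)
    table["enriched"] = table["mean_corr"] > threshold
    return EnrichmentResult(
        table=table,
        excluded=profile.excluded,
        threshold=threshold,
        markers=profile.markers,
        method=profile.method,
    )


def frequency_distribution(
    profile: EnrichmentProfile, bin_width: float = 0.05
) -> pd.DataFrame:
    """Histogram of mean correlations over half-open bins [lo, hi).

    Bin edges are multiples of ``bin_width`` covering [-1, 1]; a value
    landing exactly on the top edge gets its own trailing bin so that
    counts always sum to the number of scored genes.
    """
    if bin_width <= 0:
        raise ConfigError(f"bin_width must be positive, got {bin_width}")
    vals = profile.table["mean_corr"].to_numpy()
    k_lo = int(np.floor(-1.0 / bin_width))
    k_hi = int(np.ceil(1.0 / bin_width))
    if vals.size:
        k_lo = min(k_lo, int(np.floor(vals.min() / bin_width)))
        k_hi = max(k_hi, int(np.floor(vals.max() / bin_width)) + 1)
    idx = np.floor(vals / bin_width).astype(int) - k_lo
    counts = np.bincount(idx, minlength=k_hi - k_lo)
    ks = np.arange(k_lo, k_hi)
    return pd.DataFrame(
        {
            "bin_lo": ks * bin_width,
            "bin_hi": (ks + 1) * bin_width,
            "count": counts,
        }
    )
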