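"""Imaging phenotype and differential correlation scoring.

The phenotype is the enhancing-to-complete tumor volume ratio (EV/CV, with
CV = EV + NV). Samples with the k highest and k lowest ratios form the
CE-high and CE-low extremes; per enriched gene, the mean marker correlation
is recomputed from scratch inside each extreme group and the difference
(CE-high minus CE-low) is the differential correlation score. Scores above
0.1 are CE-high-associated, below -0.4 CE-low-associated (strict, both
CLI-exposed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import MarkerPanel, marker_correlation_profile
from .errors import ConfigError, DataError
from .io import ExpressionMatrix

CE_HIGH = "CE-high"
CE_LOW = "CE-low"
UNASSIGNED = "unassigned"

CE_HIGH_ASSOC = "CE-high-associated"
CE_LOW_ASSOC = "CE-low-associated"
UNCLASSIFIED = "unclassified"


def compute_segmentation_features(volumes: pd.DataFrame) -> pd.DataFrame:
    """Derive CV = EV + NV and the EV/CV ratio from per-sample volumes.

    ``volumes`` is indexed by sample id with columns EV and NV. Negative or
    non-finite volumes, and CV = 0, are data errors naming the sample.
    """
    df = volumes.copy()
    for col in ("EV", "NV"):
        if col not in df.columns:
            raise DataError(f"segmentation table missing column {col!r}")
        vals = df[col].to_numpy(dtype=float)
        bad = df.index[~np.isfinite(vals) | (vals < 0)].tolist()
        if bad:
            raise DataError(f"negative or non-finite {col} for samples {bad}")
    df["CV"] = df["EV"] + df["NV"]
    zero = df.index[df["CV"] == 0].tolist()
    if zero:
        raise DataError(f"zero complete tumor volume for samples {zero}")
    df["ratio"] = df["EV"] / df["CV"]
    return df[["EV", "NV", "CV", "ratio"]]


@dataclass
class GroupAssignment:
    """Per-sample group labels plus the extremes size used (0 = median split)."""

    groups: pd.Series  # index sample_id, values CE_HIGH/CE_LOW/UNASSIGNED
    k: int

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def dichotomize_extremes(features: pd.DataFrame, k: int = 20) -> GroupAssignment:
    """Top-k ratios -> CE-high, bottom-k -> CE-low, rest unassigned.

    Boundary ties are broken deterministically by ascending sample id.
    """
    if k < 1:
        raise ConfigError(f"extremes size k must be positive, got {k}")
    n = len(features)
    if n < 2 * k:
        raise ConfigError(
            f"cannot select top-{k} and bottom-{k} from {n} samples "
            f"(need n >= {2 * k})"
        )
    order = (
        features.reset_index()
        .sort_values(["ratio", "sample_id"], ascending=[True, True],
                     kind="stable")["sample_id"]
        .to_numpy()
    )
    groups = pd.Series(UNASSIGNED, index=features.index, name="group")
    groups.loc[order[:k]] = CE_LOW
    groups.loc[order[-k:]] = CE_HIGH
    return GroupAssignment(groups=groups, k=k)


def differential_correlation_score(
    expr: ExpressionMatrix,
    panel: MarkerPanel,
    ec_genes,
    groups,
    method: str = "spearman",
    ec_ranks: pd.Series | None = None,
) -> pd.DataFrame:
    """Score each enriched gene by its between-group correlation difference.

    ``groups`` is either a :class:`GroupAssignment` or an explicit
    ``(high_sample_ids, low_sample_ids)`` pair. Group-wise mean marker
    correlations use the same convention as the full-cohort screen (marker
    self-correlation included) and are computed on the group samples only.
    Genes constant within either group get a missing group correlation and
    a reason code instead of a score.
    """
    if isinstance(groups, GroupAssignment):
        high = groups.samples(CE_HIGH)
        low = groups.samples(CE_LOW)
    else:
        high, low = (list(g) for g in groups)
    for name, members in ((CE_HIGH, high), (CE_LOW, low)):
        if len(members) < 3:
            raise DataError(
                f"group {name} has {len(members)} samples; need at least 3"
            )
    ec_genes = list(ec_genes)
    unknown = [g for g in ec_genes if g not in expr.data.index]
    if unknown:
        raise DataError(f"ec_genes not in expression matrix: {unknown}")
    gene_universe = list(dict.fromkeys(list(panel.marker_ids) + ec_genes))
    sub = expr.subset_genes(gene_universe)

    def group_means(sample_ids) -> pd.Series:
        prof = marker_correlation_profile(
            sub.subset_samples(sample_ids), panel, method=method
        )
        full = prof.table["mean_corr"].reindex(gene_universe)
        return full  # NaN for genes constant within the group

    corr_high = group_means(high)
    corr_low = group_means(low)
    table = pd.DataFrame(
        {
            "corr_high": corr_high.reindex(ec_genes),
            "corr_low": corr_low.reindex(ec_genes),
        },
        index=pd.Index(ec_genes, name="gene_id"),
    )
    table["delta"] = table["corr_high"] - table["corr_low"]
    table["n_high"] = len(high)
    table["n_low"] = len(low)
    reason = np.where(
        table["corr_high"].isna() | table["corr_low"].isna(),
        "constant_in_group",
        "",
    )
    table["reason"] = reason
    if ec_ranks is not None:
        table["ec_rank"] = ec_ranks.reindex(table.index)
    return table


def classify_ce_association(
    table: pd.DataFrame,
    up_threshold: float = 0.1,
    down_threshold: float = -0.4,
) -> pd.DataFrame:
    """Assign CE-association classes by strict delta thresholds."""
    if not down_threshold < up_threshold:
        raise ConfigError(
            f"down_threshold ({down_threshold}) must be below "
            f"up_threshold ({up_threshold})"
        )
    out = table.copy()
    delta = out["delta"]
    ce_class = np.full(len(out), UNCLASSIFIED, dtype=object)
    ce_class[(delta > up_threshold).to_numpy()] = CE_HIGH_ASSOC
    ce_class[(delta < down_threshold).to_numpy()] = CE_LOW_ASSOC
    ce_class[delta.isna().to_numpy()] = UNCLASSIFIED
    out["ce_class"] = ce_class
    return out
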