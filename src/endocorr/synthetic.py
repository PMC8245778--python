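"""Synthetic bulk-mixture cohort with planted ground truth.

Each sample is a mixture of one endothelial compartment (fraction drawn
independently of a latent contrast-enhancement level z) and several other
cell types. Marker and constitutive endothelial genes are over-expressed in
the EC compartment for every sample; conditional genes only for samples in
the top (or bottom) tertile of z, giving a clean planted signal for the
differential-correlation screen. Segmentation volumes, survival outcomes
and molecular subtype labels are derived from z so that downstream
phenotype, survival and subtype analyses all have recoverable structure.

One global seed spawns independent named sub-streams (latent, expression,
segmentation, clinical), so regenerating one block with changed parameters
leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .enrichment import DEFAULT_MARKERS
from .errors import ConfigError
from .io import ExpressionMatrix

GENE_CLASSES = (
    "marker",
    "ec_constitutive",
    "ce_high_conditional",
    "ce_low_conditional",
    "background",
)

_STREAMS = ("latent", "expression", "segmentation", "clinical")


@dataclass
class MixtureConfig:
    """Parameters of the generative model; validated on construction."""

    n_samples: int = 128
    n_genes: int = 2000
    n_ec_constitutive: int = 150
    n_ce_high_conditional: int = 40
    n_ce_low_conditional: int = 40
    n_cell_types: int = 3
    ec_fraction_range: tuple[float, float] = (0.01, 0.15)
    ec_signal: float = 50.0
    noise_sd: float = 0.3
    hazard_ratio: float = 1.8
    censor_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_cell_types"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "n_ec_constitutive", "n_ce_high_conditional", "n_ce_low_conditional"
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        n_planted = (
            len(DEFAULT_MARKERS)
            + self.n_ec_constitutive
            + self.n_ce_high_conditional
            + self.n_ce_low_conditional
        )
        if n_planted > self.n_genes:
            raise ConfigError(
                f"n_genes={self.n_genes} too small for {n_planted} planted "
                "marker/EC genes"
            )
        lo, hi = self.ec_fraction_range
        if not (0 < lo <= hi < 1):
            raise ConfigError(
                "ec_fraction_range must satisfy 0 < low <= high < 1, got "
                f"{self.ec_fraction_range}"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.ec_signal <= 0:
            raise ConfigError("ec_signal must be positive")
        if not 0 <= self.censor_fraction < 1:
            raise ConfigError("censor_fraction must lie in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be positive")


@dataclass
class SyntheticTruth:
    gene_class: pd.Series  # index gene_id
    ce_latent: pd.Series  # index sample_id, z in [0, 1]
    ec_fraction: pd.Series
    true_group: pd.Series  # CE-high / CE-low / intermediate
    cell_fractions: pd.DataFrame = None  # sample x cell type, rows sum to 1

    def genes_of_class(self, cls: str) -> list[str]:
        return list(self.gene_class.index[self.gene_class == cls])


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    segmentation: pd.DataFrame  # sample_id -> EV, NV, CV, ratio
    clinical: pd.DataFrame  # sample_id -> os_time, os_event, age, subtype
    truth: SyntheticTruth
    config: MixtureConfig = field(repr=False, default=None)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _gene_labels(cfg: MixtureConfig) -> tuple[list[str], np.ndarray]:
    n_named = cfg.n_genes - len(DEFAULT_MARKERS)
    width = len(str(n_named))
    ids = list(DEFAULT_MARKERS) + [f"G{i + 1:0{width}d}" for i in range(n_named)]
    classes = np.full(cfg.n_genes, "background", dtype=object)
    classes[: len(DEFAULT_MARKERS)] = "marker"
    lo = len(DEFAULT_MARKERS)
    for cls, count in (
        ("ec_constitutive", cfg.n_ec_constitutive),
        ("ce_high_conditional", cfg.n_ce_high_conditional),
        ("ce_low_conditional", cfg.n_ce_low_conditional),
    ):
        classes[lo : lo + count] = cls
        lo += count
    return ids, classes


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Upper bound of the Uniform(0, u) censoring time giving the target
    expected censoring fraction under exponential event times."""

    def frac(u: float) -> float:
        return float(np.mean((1.0 - np.exp(-rates * u)) / (rates * u)))

    lo, hi = 1e-9, 1e12
    return float(optimize.brentq(lambda u: frac(u) - target, lo, hi))


def generate_dataset(config: MixtureConfig | None = None) -> SyntheticDataset:
    """Draw a full synthetic cohort: expression, segmentation, clinical, truth.

    Deterministic given ``config.seed``.
    """
    cfg = config or MixtureConfig()
    rng = _streams(cfg.seed)
    n, g = cfg.n_samples, cfg.n_genes
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids, classes = _gene_labels(cfg)

    # latent structure
    z = rng["latent"].uniform(0.0, 1.0, size=n)
    lo, hi = cfg.ec_fraction_range
    f_ec = rng["latent"].uniform(lo, hi, size=n)
    q1, q2 = np.quantile(z, [1 / 3, 2 / 3])
    top = z >= q2
    bottom = z <= q1
    true_group = np.full(n, "intermediate", dtype=object)
    true_group[top] = "CE-high"
    true_group[bottom] = "CE-low"

    # cell-type fractions: EC plus a symmetric Dirichlet over the rest
    other = rng["expression"].dirichlet(np.ones(cfg.n_cell_types), size=n)
    fractions = np.column_stack([f_ec, (1.0 - f_ec)[:, None] * other])

    # bulk signal per gene class (closed forms of sum_c f_c * signature)
    sig = cfg.ec_signal
    bulk = np.ones((g, n))
    ec_like = (classes == "marker") | (classes == "ec_constitutive")
    bulk[ec_like] = f_ec * sig + (1.0 - f_ec)
    ce_hi = classes == "ce_high_conditional"
    ce_lo = classes == "ce_low_conditional"
    bulk[ce_hi] = np.where(top, f_ec * sig + (1.0 - f_ec), 1.0)
    bulk[ce_lo] = np.where(bottom, f_ec * sig + (1.0 - f_ec), 1.0)
    bg = np.flatnonzero(classes == "background")
    hot_type = rng["expression"].integers(1, cfg.n_cell_types + 1, size=bg.size)
    f_hot = fractions[:, hot_type].T  # (n_background, n_samples)
    bulk[bg] = f_hot * sig + (1.0 - f_hot)

    noise = rng["expression"].normal(0.0, cfg.noise_sd, size=(g, n))
    Y = np.log2(1.0 + bulk) + noise
    expr = ExpressionMatrix(
        pd.DataFrame(
            Y, index=pd.Index(gene_ids, name="gene_id"),
            columns=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # segmentation: ratio tracks z with small noise; volumes arbitrary scale
    r = np.clip(
        z + rng["segmentation"].normal(0.0, 0.05, size=n), 0.001, 0.999
    )
    cv_raw = rng["segmentation"].lognormal(mean=np.log(3e4), sigma=0.5, size=n)
    ev = r * cv_raw
    nv = cv_raw - ev
    seg = pd.DataFrame(
        {"EV": ev, "NV": nv, "CV": ev + nv, "ratio": ev / (ev + nv)},
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # clinical: exponential survival with a hazard bump above the median ratio
    h0 = np.log(2.0) / 400.0
    high = (r > np.median(r)).astype(float)
    rates = h0 * cfg.hazard_ratio**high
    t_event = rng["clinical"].exponential(1.0 / rates)
    if cfg.censor_fraction > 0:
        horizon = _censoring_horizon(rates, cfg.censor_fraction)
        c = rng["clinical"].uniform(0.0, horizon, size=n)
        os_time = np.minimum(t_event, c)
        os_event = (t_event <= c).astype(int)
    else:
        os_time = t_event
        os_event = np.ones(n, dtype=int)
    os_time = np.maximum(os_time, 1e-3)
    age = rng["clinical"].normal(60.0, 10.0, size=n)
    for _ in range(100):  # redraw outside [18, 90]
        out = (age < 18) | (age > 90)
        if not out.any():
            break
        age[out] = rng["clinical"].normal(60.0, 10.0, size=int(out.sum()))
    age = np.clip(age, 18.0, 90.0)
    p_mes = 0.25 + 0.35 * z
    is_mes = rng["clinical"].uniform(size=n) < p_mes
    others = rng["clinical"].choice(
        ["proneural", "classical", "neural"], size=n
    )
    subtype = np.where(is_mes, "mesenchymal", others)
    clinical = pd.DataFrame(
        {
            "os_time": os_time,
            "os_event": os_event,
            "age": age,
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    truth = SyntheticTruth(
        gene_class=pd.Series(
            classes, index=pd.Index(gene_ids, name="gene_id"),
            name="gene_class",
        ),
        ce_latent=pd.Series(
            z, index=pd.Index(sample_ids, name="sample_id"), name="ce_latent"
        ),
        ec_fraction=pd.Series(
            f_ec, index=pd.Index(sample_ids, name="sample_id"),
            name="ec_fraction",
        ),
        true_group=pd.Series(
            true_group, index=pd.Index(sample_ids, name="sample_id"),
            name="true_group",
        ),
        cell_fractions=pd.DataFrame(
            fractions,
            index=pd.Index(sample_ids, name="sample_id"),
            columns=["EC"] + [f"CT{i + 1}" for i in range(cfg.n_cell_types)],
        ),
    )
    return SyntheticDataset(
        expression=expr, segmentation=seg, clinical=clinical, truth=truth,
        config=cfg,
    )


def truth_tables(truth: SyntheticTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene-level and sample-level ground-truth tables for writing to TSV."""
    genes = truth.gene_class.to_frame()
    samples = pd.concat(
        [truth.ce_latent, truth.ec_fraction, truth.true_group], axis=1
    )
    return genes, samples


def config_dict(cfg: MixtureConfig) -> dict:
    d = asdict(cfg)
    d["ec_fraction_range"] = list(cfg.ec_fraction_range)
    return d
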