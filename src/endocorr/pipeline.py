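"""End-to-end pipeline: enrichment -> CE association -> survival.

Each stage writes its TSV outputs under the chosen directory; ``run_all``
adds a manifest (config echo, package version, seed, row counts) and is
byte-reproducible for fixed inputs and config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ce_association import (
    classify_ce_association,
    compute_segmentation_features,
    dichotomize_extremes,
    differential_correlation_score,
)
from .config import PipelineConfig
from .enrichment import (
    MarkerPanel,
    enrichment_screen,
    frequency_distribution,
    marker_correlation_profile,
)
from .io import (
    ExpressionMatrix,
    read_clinical,
    read_expression,
    read_segmentation,
    write_table,
)
from .survival import (
    age_subgroup_analysis,
    compare_groups,
    compare_ratio_by_subtype,
    median_split,
)
from .errors import DataError

log = logging.getLogger("endocorr")


def _panel(config: PipelineConfig) -> MarkerPanel:
    return MarkerPanel(tuple(config.marker_ids))


def run_enrich(config: PipelineConfig, out_dir: Path,
               expr: ExpressionMatrix | None = None):
    out_dir.mkdir(parents=True, exist_ok=True)
    if expr is None:
        config.require_inputs("expression")
        expr = read_expression(config.expression)
    log.info(
        "expression: %d genes x %d samples (%d missing values)",
        len(expr.gene_ids), len(expr.sample_ids), expr.n_missing,
    )
    profile = marker_correlation_profile(expr, _panel(config), config.method)
    result = enrichment_screen(profile, config.enrichment_threshold)
    hist = frequency_distribution(profile)
    write_table(result.table, out_dir / "enrichment.tsv")
    write_table(result.excluded, out_dir / "excluded_genes.tsv")
    write_table(hist, out_dir / "histogram.tsv", index=False)
    log.info("enriched genes: %d / %d scored", len(result.enriched_genes),
             len(result.table))
    return expr, result


def run_associate(config: PipelineConfig, out_dir: Path,
                  expr: ExpressionMatrix, result, seg: pd.DataFrame):
    out_dir.mkdir(parents=True, exist_ok=True)
    features = compute_segmentation_features(seg)
    # samples missing from either table are excluded before dichotomization
    shared = [s for s in expr.sample_ids if s in features.index]
    dropped = len(features) - len(shared)
    if dropped:
        log.info("dropping %d samples without expression data", dropped)
    features = features.loc[shared]
    groups = dichotomize_extremes(features, config.extremes_k)
    table = differential_correlation_score(
        expr, _panel(config), result.enriched_genes, groups,
        method=config.method, ec_ranks=result.table["rank"],
    )
    table = classify_ce_association(
        table, config.up_threshold, config.down_threshold
    )
    write_table(table, out_dir / "diff_scores.tsv")
    return features, groups, table


def _km_to_files(comparison, out_dir: Path, prefix: str = "km") -> list[str]:
    written = []
    for name, curve in comparison.km_curves.items():
        fname = f"{prefix}_{name.replace(' ', '_')}.tsv"
        write_table(curve.to_frame(), out_dir / fname, index=False)
        written.append(fname)
    return written


def _comparison_report(comp) -> dict:
    rep = {
        "evaluable": comp.evaluable,
        "n_per_group": comp.n_per_group,
        "logrank_chi2": _num(comp.logrank.chi2),
        "logrank_p": _num(comp.logrank.p),
    }
    if comp.note:
        rep["note"] = comp.note
    if comp.cox is not None:
        rep["cox"] = {
            name: {
                "hr": _num(comp.cox.hr[i]),
                "ci_low": _num(comp.cox.ci_low[i]),
                "ci_high": _num(comp.cox.ci_high[i]),
                "p": _num(comp.cox.p[i]),
            }
            for i, name in enumerate(comp.cox.names)
        }
    return rep


def _num(x) -> float | None:
    x = float(x)
    return None if np.isnan(x) else x


def run_survive(config: PipelineConfig, out_dir: Path,
                features: pd.DataFrame, clinical: pd.DataFrame):
    out_dir.mkdir(parents=True, exist_ok=True)
    shared = features.index.intersection(clinical.index)
    if len(shared) < 4:
        raise DataError(
            f"only {len(shared)} samples shared between segmentation and "
            "clinical tables"
        )
    features = features.loc[shared]
    clinical = clinical.loc[shared]
    split = median_split(features)
    comp = compare_groups(split, clinical, with_cox=True)
    km_files = _km_to_files(comp, out_dir)
    subgroups = age_subgroup_analysis(features, clinical, config.age_cutoff)
    report = {
        "overall": _comparison_report(comp),
        "age_subgroups": {
            name: _comparison_report(c) for name, c in subgroups.items()
        },
    }
    try:
        tt = compare_ratio_by_subtype(features, clinical)
        report["subtype_ttest"] = {
            "t": _num(tt.t), "p": _num(tt.p),
            "mean_mesenchymal": _num(tt.mean_a),
            "mean_other": _num(tt.mean_b),
            "n_mesenchymal": tt.n_a, "n_other": tt.n_b,
            "infinite_separation": tt.infinite_separation,
        }
    except DataError as exc:
        report["subtype_ttest"] = {"evaluable": False, "note": str(exc)}
    with (out_dir / "survival_report.json").open("w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report, km_files


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """All stages in order; returns and writes the run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.require_inputs("expression", "segmentation", "clinical")
    expr = read_expression(config.expression)
    seg = read_segmentation(config.segmentation)
    clinical = read_clinical(config.clinical)

    expr2, result = run_enrich(config, out_dir, expr=expr)
    features, groups, diff = run_associate(config, out_dir, expr, result, seg)
    report, km_files = run_survive(config, out_dir, features, clinical)

    manifest = {
        "package": "endocorr",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "inputs": {
            "n_genes": len(expr.gene_ids),
            "n_samples": len(expr.sample_ids),
            "n_segmentation": len(seg),
            "n_clinical": len(clinical),
        },
        "stages": {
            "enrichment": {
                "n_scored": len(result.table),
                "n_excluded": len(result.excluded),
                "n_enriched": len(result.enriched_genes),
                "outputs": ["enrichment.tsv", "excluded_genes.tsv",
                            "histogram.tsv"],
            },
            "ce_association": {
                "n_scored": len(diff),
                "n_ce_high": int((diff["ce_class"] == "CE-high-associated").sum()),
                "n_ce_low": int((diff["ce_class"] == "CE-low-associated").sum()),
                "outputs": ["diff_scores.tsv"],
            },
            "survival": {
                "outputs": km_files + ["survival_report.json"],
            },
        },
    }
    with (out_dir / "manifest.json").open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
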