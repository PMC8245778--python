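"""Tab-separated file formats shared by every pipeline stage.

All writers emit UTF-8 TSV with a single header line and the missing-value
token ``NA``; readers validate shape and ids and report offending line
numbers. Gene/sample id matching is case-sensitive exact string.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError

NA_TOKEN = "NA"

CLINICAL_COLUMNS = ["os_time", "os_event", "age", "subtype"]
SEGMENTATION_COLUMNS = ["EV", "NV"]


@dataclass
class ExpressionMatrix:
    """Gene x sample numeric matrix on a log-friendly processed scale.

    Missing entries are NaN and tracked; duplicate gene or sample ids are
    rejected at construction.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        idx = self.data.index
        cols = self.data.columns
        if idx.duplicated().any():
            dups = sorted(set(idx[idx.duplicated()]))
            raise DataError(f"duplicate gene ids: {dups}")
        if cols.duplicated().any():
            dups = sorted(set(cols[cols.duplicated()]))
            raise DataError(f"duplicate sample ids: {dups}")
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise DataError(f"unknown sample ids: {missing}")
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)].copy())

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise DataError(f"unknown gene ids: {missing}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)].copy())


def read_expression(path) -> ExpressionMatrix:
    """Read a genes-x-samples TSV: header of sample ids, first column gene ids.

    Numeric cells or ``NA``; ragged rows, non-numeric cells and duplicate
    ids are data errors carrying the 1-based line number.
    """
    path = Path(path)
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header:
            raise DataError(f"{path}: empty file")
        sample_ids = header.rstrip("\n").split("\t")[1:]
        if len(sample_ids) != len(set(sample_ids)):
            dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
            raise DataError(f"{path}:1: duplicate sample ids {dups}")
        width = len(sample_ids)
        seen: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != width + 1:
                raise DataError(
                    f"{path}:{lineno}: expected {width + 1} fields, "
                    f"got {len(fields)}"
                )
            gid = fields[0]
            if gid in seen:
                raise DataError(f"{path}:{lineno}: duplicate gene id {gid!r}")
            seen.add(gid)
            try:
                row = np.array(
                    [np.nan if f == NA_TOKEN else float(f) for f in fields[1:]]
                )
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: non-numeric cell ({exc})")
            gene_ids.append(gid)
            rows.append(row)
    if not rows:
        raise DataError(f"{path}: no gene rows")
    df = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)
    df.index.name = "gene_id"
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN)


def _read_indexed_table(path, required: list[str], kind: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN],
            keep_default_na=False,
        )
    except Exception as exc:  # noqa: BLE001 - wrap parser errors uniformly
        raise DataError(f"{path}: cannot parse {kind} table ({exc})")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise DataError(f"{path}: duplicate sample ids {dups}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    df.index = df.index.astype(str)
    df.index.name = "sample_id"
    return df


def read_segmentation(path) -> pd.DataFrame:
    """Read (sample_id, EV, NV) volumes; values must be numeric."""
    df = _read_indexed_table(path, SEGMENTATION_COLUMNS, "segmentation")
    for col in SEGMENTATION_COLUMNS:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric {col} ({exc})")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read (sample_id, os_time, os_event, age[, subtype])."""
    df = _read_indexed_table(path, ["os_time", "os_event", "age"], "clinical")
    for col in ["os_time", "os_event", "age"]:
        try:
            df[col] = df[col].astype(float)
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric {col} ({exc})")
    if not df["os_event"].isin([0.0, 1.0]).all():
        raise DataError(f"{path}: os_event must be 0 or 1")
    df["os_event"] = df["os_event"].astype(int)
    if (df["os_time"] <= 0).any():
        bad = df.index[df["os_time"] <= 0].tolist()
        raise DataError(f"{path}: non-positive os_time for samples {bad}")
    if "subtype" not in df.columns:
        df["subtype"] = "unknown"
    df["subtype"] = df["subtype"].fillna("unknown").astype(str)
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """Uniform TSV writer used for every stage output."""
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)
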