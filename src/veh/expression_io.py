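"""Reading, preprocessing and writing of delimited expression tables.

Input tables are plain CSV/TSV, either samples-in-rows (one label
column) or genes-in-rows (feature IDs in the first column, one row
holding the class labels).  Preprocessing follows the usual microarray
recipe: per-gene mean substitution of missing values, then per-gene
min-max scaling to [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .datatypes import ExpressionDataset, GeneSubset, VehError

__all__ = [
    "LayoutConfig",
    "read_expression_table",
    "impute_missing_mean",
    "minmax_normalize",
    "write_gene_list",
    "write_run_report",
    "read_run_report",
]

#: column names recognised as the class column when none is given
_LABEL_ALIASES = ("label", "class", "labels", "classes", "target", "y")

DEFAULT_MISSING_TOKENS = ("", "na", "nan", "null", "?")


@dataclass
class LayoutConfig:
    """How a delimited expression file is laid out on disk.

    ``orientation`` is ``"samples"`` when rows are samples (the label is
    a column) or ``"genes"`` when rows are genes (feature IDs in the
    first column, labels in the row whose ID matches ``label_column``).
    """

    delimiter: str = ","
    orientation: str = "samples"
    label_column: str | int | None = None
    missing_tokens: tuple[str, ...] = field(default=DEFAULT_MISSING_TOKENS)

    def __post_init__(self) -> None:
        if not self.delimiter:
            raise VehError("delimiter must be nonempty")
        if self.orientation not in ("samples", "genes"):
            raise VehError("orientation must be 'samples' or 'genes'")


def _resolve_label_column(columns: list[str], layout: LayoutConfig) -> str:
    if layout.label_column is not None:
        if isinstance(layout.label_column, int):
            return columns[layout.label_column]
        if layout.label_column not in columns:
            raise VehError(
                f"label column {layout.label_column!r} not found in header"
            )
        return str(layout.label_column)
    lowered = {c.strip().lower(): c for c in columns}
    for alias in _LABEL_ALIASES:
        if alias in lowered:
            return lowered[alias]
    raise VehError(
        "could not auto-detect the label column; pass layout.label_column"
    )


def read_expression_table(
    path: str | Path, layout: LayoutConfig | None = None, name: str | None = None
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    The returned dataset is always oriented samples x genes; entries
    matching a missing token (case-insensitively) are flagged in
    ``missing_mask`` and stored as NaN.  Values are never otherwise
    altered.
    """
    layout = layout or LayoutConfig()
    path = Path(path)
    if not path.exists():
        raise VehError(f"file not found: {path}")
    tokens = {t.lower() for t in layout.missing_tokens}

    df = pd.read_csv(
        path,
        sep=layout.delimiter,
        dtype=str,
        keep_default_na=False,
        index_col=0 if layout.orientation == "genes" else None,
    )
    if layout.orientation == "genes":
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise VehError(f"duplicate feature ids: {dupes[:5]}")
        df = df.T  # rows become samples; columns are feature IDs
        df.columns = [str(c) for c in df.columns]
        df = df.reset_index(drop=True)
    else:
        # pandas silently renames duplicate header names; check the raw header
        with open(path) as fh:
            header = [h.strip().strip('"') for h in fh.readline().rstrip("\n").split(layout.delimiter)]
        if len(set(header)) != len(header):
            dupes = sorted({h for h in header if header.count(h) > 1})
            raise VehError(f"duplicate feature ids: {dupes[:5]}")

    columns = [str(c) for c in df.columns]
    label_col = _resolve_label_column(columns, layout)
    labels = df[label_col].to_numpy()
    value_df = df.drop(columns=[label_col])
    feature_ids = [str(c) for c in value_df.columns]

    raw = value_df.to_numpy(dtype=object)
    flat = np.char.lower(np.char.strip(raw.astype(str)))
    missing = np.isin(flat, sorted(tokens))
    values = np.full(raw.shape, np.nan)
    try:
        values[~missing] = flat[~missing].astype(float)
    except ValueError as exc:
        raise VehError(f"non-numeric expression value in {path}: {exc}") from exc

    return ExpressionDataset(
        values=values,
        feature_ids=feature_ids,
        labels=labels,
        name=name or path.stem,
        missing_mask=missing,
    )


def impute_missing_mean(ds: ExpressionDataset) -> ExpressionDataset:
    """Replace each absent entry with the mean of its gene's observed values.

    Mean substitution leaves every gene's mean unchanged, which is the
    point of the method.  A gene with zero observed values is an error.
    """
    if not ds.missing_mask.any():
        return replace(
            ds,
            values=ds.values.copy(),
            missing_mask=np.zeros_like(ds.missing_mask),
        )
    observed = ~ds.missing_mask
    n_obs = observed.sum(axis=0)
    if (n_obs == 0).any():
        bad = [ds.feature_ids[i] for i in np.where(n_obs == 0)[0][:5]]
        raise VehError(f"gene(s) with no observed values: {bad}")
    filled = np.where(ds.missing_mask, 0.0, ds.values)
    gene_means = filled.sum(axis=0) / n_obs
    values = np.where(ds.missing_mask, gene_means[np.newaxis, :], ds.values)
    return replace(
        ds, values=values, missing_mask=np.zeros_like(ds.missing_mask)
    )


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Rescale every gene to [0, 1] via (x - min) / (max - min).

    Constant genes map to all-zeros rather than erroring; the variance
    filter removes them immediately afterwards anyway.  Absent entries
    must be imputed first.
    """
    if ds.missing_mask.any():
        raise VehError("impute missing values before normalizing")
    lo = ds.values.min(axis=0)
    hi = ds.values.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    values = (ds.values - lo[np.newaxis, :]) / safe[np.newaxis, :]
    values[:, span == 0] = 0.0
    return replace(ds, values=values)


def write_gene_list(subset: GeneSubset, path: str | Path) -> None:
    """Write one feature ID per line."""
    Path(path).write_text("\n".join(subset.feature_ids) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list, ignoring blank lines."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines()]
    ids = [i for i in ids if i]
    if not ids:
        raise VehError(f"empty gene list: {path}")
    return ids


def write_run_report(result: Any, path: str | Path) -> None:
    """Serialize a run result (dataclass tree or dict) to JSON."""
    payload = _to_jsonable(result)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_run_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _to_jsonable(obj: Any) -> Any:
    import dataclasses

    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
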