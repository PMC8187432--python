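"""Reading and writing omics matrices, labels and result tables.

Matrices are delimited text with a header row of feature names and sample
IDs in the first column; ``.csv``/``.tsv`` pick the delimiter and ``.gz``
is handled transparently.  Labels are two-column ``id,label`` files; labels
may be arbitrary strings and are mapped to contiguous integer classes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LabelVector, MultiOmicsDataset, OmicsView

__all__ = [
    "read_omics_matrix",
    "write_omics_matrix",
    "read_labels",
    "write_labels",
    "align_views",
    "write_table",
    "write_metrics",
]


def _sep_for(path: str | Path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    return "\t" if name.endswith(".tsv") else ","


def read_omics_matrix(
    path: str | Path, name: str | None = None, samples_in_rows: bool = True
) -> OmicsView:
    """Read a samples x features matrix from CSV/TSV.

    With ``samples_in_rows=False`` the file is stored features x samples and
    is transposed on read, so both orientations yield the same view.
    """
    path = Path(path)
    # round_trip parsing makes write -> read reproduce float64 values exactly
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                     float_precision="round_trip")
    if not samples_in_rows:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for col in df.columns:
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                row = df.index[np.where(bad)[0][0]]
                raise ValueError(
                    f"{path}: non-numeric value at row {row!r}, column {col!r}"
                ) from None
        raise
    return OmicsView(
        name=name or path.name.split(".")[0],
        sample_ids=[str(s) for s in df.index],
        feature_names=[str(f) for f in df.columns],
        values=values,
    )


def write_omics_matrix(view: OmicsView, path: str | Path) -> None:
    df = pd.DataFrame(view.values, index=view.sample_ids, columns=view.feature_names)
    df.index.name = "id"
    df.to_csv(path, sep=_sep_for(path))


def read_labels(path: str | Path) -> LabelVector:
    """Read an ``id,label`` file; string labels are mapped to 0..c-1 in sorted order."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns id,label")
    ids = df.iloc[:, 0].tolist()
    raw = df.iloc[:, 1].tolist()
    classes = sorted(set(raw), key=lambda x: (len(x), x) if x.isdigit() else (np.inf, x))
    # numeric labels sort numerically, others lexicographically after them
    mapping = {cls: i for i, cls in enumerate(classes)}
    labels = np.array([mapping[r] for r in raw])
    return LabelVector(ids, labels, n_classes=len(classes), classes_=classes)


def write_labels(labels: LabelVector, path: str | Path) -> None:
    df = pd.DataFrame(
        {"id": labels.sample_ids, "label": [labels.classes_[i] for i in labels.labels]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False)


def align_views(views: list[OmicsView], labels: LabelVector) -> MultiOmicsDataset:
    """Restrict all views and labels to their common samples, in sorted order.

    Only samples with matched measurements in every view (and a label) are
    kept; the canonical order is the sorted intersection so it is identical
    regardless of per-file ordering.  Idempotent.
    """
    if not views:
        raise ValueError("need at least one view")
    common = set(labels.sample_ids)
    for v in views:
        common &= set(v.sample_ids)
    if not common:
        raise ValueError("no samples shared by all views and the label file")
    order = sorted(common)
    return MultiOmicsDataset([v.subset_samples(order) for v in views], labels.subset(order))


def write_table(rows: list[dict] | pd.DataFrame, path: str | Path) -> None:
    """Write a list of records (or a DataFrame) as CSV/TSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_metrics(metrics: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
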