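"""CSV/TSV reading and writing for series and label files."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .series import IndexedSeries
from .pipeline import DetectionTrace, Label, LabelVector

__all__ = ["read_series", "write_series", "read_labels", "write_labels"]


def _has_header(path, delimiter: str) -> bool:
    """True when the first row contains a non-numeric, non-empty field."""
    with open(path, newline="") as fh:
        first = next(csv.reader(fh, delimiter=delimiter), [])
    for tok in first:
        tok = tok.strip()
        if not tok:
            continue
        try:
            float(tok)
        except ValueError:
            return True
    return False


def read_series(path, index_column: str | int = 0, value_column: str | int = 1,
                delimiter: str | None = None) -> IndexedSeries:
    """Read an (index, value) series from a delimited text file.

    ``delimiter=None`` infers CSV vs TSV from the filename suffix.  Columns
    may be named (header row) or positional.  Empty or NA value cells become
    missing positions.  Duplicate indices are rejected.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    named = isinstance(index_column, str) or isinstance(value_column, str)
    header = 0 if named or _has_header(path, delimiter) else None
    frame = pd.read_csv(path, sep=delimiter, header=header, skipinitialspace=True)
    if header == 0 and not named:
        # positional selection still works on a headered file
        frame.columns = range(len(frame.columns))
    try:
        idx_col = frame[index_column] if header == 0 else frame.iloc[:, index_column]
        val_col = frame[value_column] if header == 0 else frame.iloc[:, value_column]
    except (KeyError, IndexError) as exc:
        raise ValueError(f"cannot locate requested columns in {path}") from exc

    idx = pd.to_numeric(idx_col, errors="raise")
    if not np.all(idx == idx.astype(np.int64)):
        raise ValueError("index column must contain integers")
    idx = idx.astype(np.int64).to_numpy()
    if idx.min() < 0:
        raise ValueError("indices must be non-negative")
    if len(np.unique(idx)) != len(idx):
        dupes = pd.Series(idx).value_counts()
        raise ValueError(f"duplicate indices: {sorted(dupes[dupes > 1].index.tolist())}")
    val = pd.to_numeric(val_col, errors="raise").to_numpy(dtype=np.float64)

    order = np.argsort(idx)
    idx, val = idx[order], val[order]
    present = np.isfinite(val)
    if present.sum() < 2:
        raise ValueError("need at least 2 present values")
    return IndexedSeries(idx[present], val[present], missing=idx[~present])


def write_series(path, series: IndexedSeries, delimiter: str = ",") -> None:
    """Write a series (present and missing rows) with an index,value header."""
    rows = {int(i): repr(float(v)) for i, v in zip(series.indices, series.values)}
    rows.update({int(i): "" for i in series.missing})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["index", "value"])
        for i in sorted(rows):
            writer.writerow([i, rows[i]])


def write_labels(path, labels: LabelVector, series: IndexedSeries,
                 trace: DetectionTrace | None = None,
                 trace_path=None, delimiter: str = ",") -> None:
    """Write per-position index, value, label rows (full float precision).

    ``trace_path`` optionally receives a sidecar log, one line per
    iteration.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["index", "value", "label"])
        for pos, label in labels.items():
            value = "" if label is Label.MISSING else repr(series.value_at(pos))
            writer.writerow([pos, value, label.value])
    if trace is not None and trace_path is not None:
        with open(trace_path, "w") as fh:
            for r in trace.records:
                fh.write(
                    f"phase={r.phase} iter={r.iteration} n={r.n} "
                    f"score_max={r.score_max} score_min={r.score_min} r_w={r.r_w} "
                    f"action={r.action} position={r.position} "
                    f"termination={r.termination_reason}\n"
                )


def read_labels(path, delimiter: str | None = None) -> tuple[LabelVector, IndexedSeries]:
    """Read a label file back into (labels, series); inverse of write_labels."""
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=delimiter)
    labels = {}
    idx, val = [], []
    missing = []
    for _, row in frame.iterrows():
        pos = int(row["index"])
        label = Label(row["label"])
        labels[pos] = label
        if label is Label.MISSING:
            missing.append(pos)
        else:
            idx.append(pos)
            val.append(float(row["value"]))
    series = IndexedSeries(np.asarray(idx, dtype=np.int64),
                           np.asarray(val, dtype=np.float64),
                           missing=np.asarray(missing, dtype=np.int64))
    return LabelVector(labels), series
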