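"""Dataset readers and writers.

On-disk cohort layout: a directory with one headerless CSV per subject
(rows = ROIs, columns = time points) plus ``labels.csv`` with columns
``subject_id,label``.  Adjacency and feature matrices are written as CSV
with a header, with a JSON sidecar recording estimator provenance.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bfn import AdjacencyMatrix, TimeSeriesMatrix
from .features import NodeFeatureMatrix

__all__ = [
    "write_cohort",
    "load_cohort",
    "write_adjacency",
    "load_adjacency",
    "write_features",
]


def write_cohort(subjects: list[TimeSeriesMatrix], labels: list[int], out_dir) -> Path:
    """Write per-subject CSVs plus ``labels.csv``; returns the directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "label"])
        for ts, lab in zip(subjects, labels):
            w.writerow([ts.subject_id, lab])
            np.savetxt(out / f"{ts.subject_id}.csv", ts.values, delimiter=",", fmt="%.17g")
    return out


def load_cohort(path, *, transposed: bool = False) -> list[tuple[TimeSeriesMatrix, int]]:
    """Load a cohort directory; validates shapes and labels.

    ``transposed=True`` reads files laid out as time points x ROIs.
    Raises with the offending subject/file named on any problem: missing
    file, ragged rows, non-binary label, or a node count differing across
    subjects.  Constant ROI rows are tolerated here (flagged later by the
    estimators that cannot handle them).
    """
    root = Path(path)
    labels_file = root / "labels.csv"
    if not labels_file.exists():
        raise FileNotFoundError(f"no labels.csv in {root}")
    table = pd.read_csv(labels_file)
    if list(table.columns) != ["subject_id", "label"]:
        raise ValueError(f"{labels_file}: expected columns subject_id,label")
    out: list[tuple[TimeSeriesMatrix, int]] = []
    n_rois = None
    for _, rec in table.iterrows():
        sid = str(rec["subject_id"])
        if rec["label"] not in (0, 1):
            raise ValueError(f"subject {sid}: label {rec['label']!r} not in {{0,1}}")
        f = root / f"{sid}.csv"
        if not f.exists():
            raise FileNotFoundError(f"subject {sid}: missing time-series file {f}")
        rows = []
        with open(f, newline="") as fh:
            for ln, row in enumerate(csv.reader(fh), start=1):
                if not row:
                    continue
                try:
                    rows.append([float(v) for v in row])
                except ValueError as e:
                    raise ValueError(f"{f}: non-numeric value on row {ln}") from e
                if len(rows[-1]) != len(rows[0]):
                    raise ValueError(
                        f"{f}: ragged row {ln} "
                        f"({len(rows[-1])} values, expected {len(rows[0])})"
                    )
        values = np.array(rows)
        if transposed:
            values = values.T
        if n_rois is None:
            n_rois = values.shape[0]
        elif values.shape[0] != n_rois:
            raise ValueError(
                f"subject {sid}: {values.shape[0]} ROIs, cohort has {n_rois}"
            )
        out.append((TimeSeriesMatrix(values=values, subject_id=sid), int(rec["label"])))
    if not out:
        raise ValueError(f"{labels_file}: no subjects listed")
    return out


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    """Adjacency as CSV with ROI-id header, plus a .json provenance sidecar."""
    path = Path(path)
    pd.DataFrame(adj.raw, columns=adj.roi_ids).to_csv(path, index=False)
    sidecar = {"estimator": adj.estimator, "params": adj.params, "n": adj.n}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_adjacency(path) -> AdjacencyMatrix:
    path = Path(path)
    table = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    from .bfn import normalize_adjacency

    adj = AdjacencyMatrix(
        raw=table.to_numpy(),
        estimator=meta.get("estimator", "unknown"),
        params=meta.get("params", {}),
        roi_ids=list(table.columns),
    )
    return normalize_adjacency(adj)


def write_features(x: NodeFeatureMatrix, path) -> None:
    pd.DataFrame(x.values, columns=x.column_names).to_csv(path, index=False)
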