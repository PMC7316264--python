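"""Plain-text readers/writers: TSV time series and matrices, JSON sidecars.

Formats
-------
* time series: TSV, rows = volumes, columns = ROI labels followed by the
  nuisance channels ``nuisance_wm`` and ``nuisance_csf``;
* matrices (functional, mixed, structural, backbone): square TSV with a
  header row and an index column of ROI labels, full symmetric storage;
* network definitions: JSON mapping network name -> ROI label list;
* manifests/reports: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import NetworkDefinition
from .types import FunctionalMatrix, SubjectTimeSeries

NUISANCE_COLUMNS = ("nuisance_wm", "nuisance_csf")


def write_timeseries_tsv(path: str | Path, ts: SubjectTimeSeries) -> None:
    cols = {label: ts.data[i] for i, label in enumerate(ts.roi_labels)}
    if ts.nuisance is not None:
        for k in range(ts.nuisance.shape[0]):
            name = NUISANCE_COLUMNS[k] if k < len(NUISANCE_COLUMNS) else f"nuisance_{k}"
            cols[name] = ts.nuisance[k]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_timeseries_tsv(path: str | Path, tr_seconds: float) -> SubjectTimeSeries:
    df = pd.read_csv(path, sep="\t")
    nuis_cols = [c for c in df.columns if c.startswith("nuisance")]
    roi_cols = [c for c in df.columns if c not in nuis_cols]
    return SubjectTimeSeries(
        data=df[roi_cols].to_numpy().T,
        roi_labels=tuple(roi_cols),
        tr_seconds=tr_seconds,
        nuisance=df[nuis_cols].to_numpy().T if nuis_cols else None,
    )


def write_matrix_tsv(
    path: str | Path, matrix: np.ndarray, roi_labels: Sequence[str]
) -> None:
    pd.DataFrame(matrix, index=list(roi_labels), columns=list(roi_labels)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


def write_functional_tsv(path: str | Path, func: FunctionalMatrix) -> None:
    write_matrix_tsv(path, func.z, func.roi_labels)


def read_functional_tsv(path: str | Path) -> FunctionalMatrix:
    z, labels = read_matrix_tsv(path)
    z = (z + z.T) / 2.0  # absorb round-trip rounding
    np.fill_diagonal(z, 0.0)
    return FunctionalMatrix(z=z, roi_labels=labels)


def realign_matrix(
    matrix: np.ndarray, labels: Sequence[str], ref_labels: Sequence[str]
) -> np.ndarray:
    """Permute a labelled square matrix into the reference label order."""
    if tuple(labels) == tuple(ref_labels):
        return matrix
    if sorted(labels) != sorted(ref_labels):
        raise ValueError("label sets differ; cannot realign")
    pos = {l: i for i, l in enumerate(labels)}
    perm = np.array([pos[l] for l in ref_labels])
    return matrix[np.ix_(perm, perm)]


def write_networks_json(path: str | Path, networks: Mapping[str, Sequence[str]]) -> None:
    Path(path).write_text(
        json.dumps({k: list(v) for k, v in networks.items()}, indent=1) + "\n"
    )


def read_networks_json(path: str | Path) -> list[NetworkDefinition]:
    raw = json.loads(Path(path).read_text())
    return [NetworkDefinition(name=k, members=tuple(v)) for k, v in raw.items()]


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if hasattr(o, "__dict__"):
            return o.__dict__
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=_default) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
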