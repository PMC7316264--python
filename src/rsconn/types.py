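"""Core in-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SubjectTimeSeries:
    """One subject/timepoint of ROI-averaged BOLD signal.

    Parameters
    ----------
    data
        ROI x time matrix (rows follow ``roi_labels``).
    roi_labels
        Ordered ROI label list, one per data row.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    nuisance
        Optional channel x time matrix of nuisance regressors
        (e.g. mean white-matter and CSF signal).
    """

    data: np.ndarray
    roi_labels: tuple[str, ...]
    tr_seconds: float
    nuisance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D ROI x time matrix")
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.roi_labels)} labels for {self.data.shape[0]} data rows"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.nuisance is not None:
            self.nuisance = np.atleast_2d(np.asarray(self.nuisance, dtype=float))
            if self.nuisance.shape[1] != self.data.shape[1]:
                raise ValueError("nuisance channels must match series length")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


@dataclass
class FunctionalMatrix:
    """Symmetric Fisher-z functional connectivity matrix.

    ``z[i, j] = atanh(r[i, j])`` for the Pearson correlation ``r`` of the
    cleaned series of ROIs i and j; the diagonal is fixed at 0 by
    convention (not ``atanh(1)``).
    """

    z: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        n = len(self.roi_labels)
        if self.z.shape != (n, n):
            raise ValueError(f"matrix shape {self.z.shape} does not match {n} labels")
        if not np.isfinite(self.z).all():
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.abs(self.z - self.z.T).max() > 0:
            raise ValueError("connectivity matrix must be exactly symmetric")
        if np.abs(np.diag(self.z)).max() > 0:
            raise ValueError("diagonal must be exactly zero")

    @property
    def r(self) -> np.ndarray:
        """Correlation-scale view (tanh of z), diagonal restored to 1."""
        r = np.tanh(self.z)
        np.fill_diagonal(r, 1.0)
        return r
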