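"""ROI time-series cleaning and Fisher-z connectivity matrices.

Stage order (each stage individually callable and toggleable):

1. discard the initial volumes acquired before scanner stabilization,
2. nuisance regression against mean white-matter/CSF signal,
3. polynomial detrending (thermal drift),
4. zero-phase band-pass filtering (default 0.01-0.1 Hz),
5. Pearson correlation -> Fisher z transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .types import FunctionalMatrix, SubjectTimeSeries

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7  # keeps atanh finite


@dataclass(frozen=True)
class PreprocConfig:
    """Cleaning-stage toggles and parameters.

    Set ``discard_volumes=0``, ``regress_nuisance=False``,
    ``detrend_order=None`` or ``band=None`` to disable a stage; the stage
    order itself is fixed and logged.
    """

    discard_volumes: int = 5
    regress_nuisance: bool = True
    detrend_order: int | None = 2
    band: tuple[float, float] | None = (0.01, 0.1)
    filter_order: int = 4


def discard_initial(ts: SubjectTimeSeries, k: int) -> SubjectTimeSeries:
    """Drop the first ``k`` volumes from the series and nuisance channels."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k >= ts.n_volumes:
        raise ValueError(f"cannot discard {k} of {ts.n_volumes} volumes")
    if k == 0:
        return ts
    return SubjectTimeSeries(
        data=ts.data[:, k:],
        roi_labels=ts.roi_labels,
        tr_seconds=ts.tr_seconds,
        nuisance=None if ts.nuisance is None else ts.nuisance[:, k:],
    )


def regress_nuisance(ts: SubjectTimeSeries) -> SubjectTimeSeries:
    """Replace each ROI series by its OLS residual on [1, nuisance channels]."""
    if ts.nuisance is None:
        raise ValueError("time series carries no nuisance channels to regress")
    n_t = ts.n_volumes
    X = np.column_stack([np.ones(n_t), ts.nuisance.T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        warnings.warn(
            "collinear nuisance channels; using pseudo-inverse least squares",
            RuntimeWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data.T - X @ beta
    return SubjectTimeSeries(
        data=resid.T,
        roi_labels=ts.roi_labels,
        tr_seconds=ts.tr_seconds,
        nuisance=ts.nuisance,
    )


def detrend_poly(ts: SubjectTimeSeries, order: int) -> SubjectTimeSeries:
    """Remove a per-ROI least-squares polynomial of the given degree."""
    if order < 0:
        raise ValueError("polynomial order must be nonnegative")
    if order >= ts.n_volumes - 1:
        raise ValueError(
            f"order {order} too high for {ts.n_volumes} volumes"
        )
    x = np.linspace(-1.0, 1.0, ts.n_volumes)
    X = np.polynomial.legendre.legvander(x, order)  # well-conditioned basis
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    resid = ts.data.T - X @ beta
    return SubjectTimeSeries(
        data=resid.T,
        roi_labels=ts.roi_labels,
        tr_seconds=ts.tr_seconds,
        nuisance=ts.nuisance,
    )


def bandpass(ts: SubjectTimeSeries, f_lo: float, f_hi: float, order: int = 4) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass (forward-backward filtering)."""
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not (0.0 < f_lo < f_hi < nyquist):
        raise ValueError(
            f"band ({f_lo}, {f_hi}) Hz must satisfy 0 < f_lo < f_hi < "
            f"Nyquist ({nyquist} Hz)"
        )
    sos = sps.butter(
        order, [f_lo, f_hi], btype="bandpass", fs=1.0 / ts.tr_seconds, output="sos"
    )
    filtered = sps.sosfiltfilt(sos, ts.data, axis=1)
    return SubjectTimeSeries(
        data=filtered,
        roi_labels=ts.roi_labels,
        tr_seconds=ts.tr_seconds,
        nuisance=ts.nuisance,
    )


def pearson_fisher(ts: SubjectTimeSeries) -> FunctionalMatrix:
    """Pearson correlations of the ROI series, Fisher-z transformed.

    The diagonal is set to 0 by convention; off-diagonal r is clipped to
    +/-(1 - 1e-7) before atanh so z stays finite.
    """
    if ts.n_volumes < 3:
        raise ValueError("need at least 3 volumes for a correlation matrix")
    sd = ts.data.std(axis=1)
    dead = np.where(sd == 0)[0]
    if dead.size:
        raise ValueError(
            f"zero-variance ROI(s): {', '.join(ts.roi_labels[i] for i in dead)}"
        )
    r = np.corrcoef(ts.data)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FunctionalMatrix(z=z, roi_labels=ts.roi_labels)


def run_preproc(ts: SubjectTimeSeries, config: PreprocConfig | None = None) -> FunctionalMatrix:
    """Full cleaning chain ending in a Fisher-z connectivity matrix."""
    if config is None:
        config = PreprocConfig()
    stages = []
    if config.discard_volumes:
        ts = discard_initial(ts, config.discard_volumes)
        stages.append(f"discard_initial(k={config.discard_volumes})")
    if config.regress_nuisance:
        ts = regress_nuisance(ts)
        stages.append("regress_nuisance")
    if config.detrend_order is not None:
        ts = detrend_poly(ts, config.detrend_order)
        stages.append(f"detrend_poly(order={config.detrend_order})")
    if config.band is not None:
        ts = bandpass(ts, *config.band, order=config.filter_order)
        stages.append(f"bandpass({config.band[0]}-{config.band[1]} Hz, order={config.filter_order})")
    stages.append("pearson_fisher")
    logger.info("preprocessing stages: %s", " -> ".join(stages))
    return pearson_fisher(ts)
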