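"""Group consensus structural backbone and mixed structural-functional matrices.

The consensus rule keeps an edge when it is present in at least the
threshold fraction of subjects (inclusive, per "at least 50%"): with 26
subjects and threshold 0.5, 13/26 is kept and 12/26 is dropped.  Pooling
both groups into one consensus gives a single white-matter template, so
group differences in structural connectivity cannot bias the functional
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import FunctionalMatrix


@dataclass
class ConsensusBackbone:
    """Binary group-representative structural connectome."""

    mask: np.ndarray
    roi_labels: tuple[str, ...]
    threshold: float
    n_subjects_used: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        self.roi_labels = tuple(self.roi_labels)
        n = len(self.roi_labels)
        if self.mask.shape != (n, n):
            raise ValueError("mask shape does not match labels")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        if np.abs(self.mask - self.mask.T).max() > 0:
            raise ValueError("mask must be symmetric")
        if np.abs(np.diag(self.mask)).max() > 0:
            raise ValueError("mask diagonal must be zero")


@dataclass
class MixedMatrix:
    """Fisher-z functional matrix gated by the consensus backbone."""

    z_masked: np.ndarray
    roi_labels: tuple[str, ...]
    backbone: ConsensusBackbone

    def __post_init__(self) -> None:
        self.z_masked = np.asarray(self.z_masked, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if np.abs(self.z_masked[self.backbone.mask == 0]).max(initial=0.0) > 0:
            raise ValueError("nonzero value outside the structural mask")


def consensus_binary(
    structural: Sequence[np.ndarray],
    roi_labels: Sequence[str],
    threshold: float = 0.5,
) -> ConsensusBackbone:
    """Vote edges over subjects; keep those present in >= threshold of them.

    Weighted structural inputs (e.g. fiber counts) are binarized at > 0
    before voting.
    """
    if len(structural) < 2:
        raise ValueError("consensus needs at least 2 structural matrices")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    n = len(roi_labels)
    mats = []
    for k, m in enumerate(structural):
        m = np.asarray(m)
        if m.shape != (n, n):
            raise ValueError(f"structural matrix {k} has shape {m.shape}, expected ({n}, {n})")
        mats.append((m > 0).astype(int))
    votes = np.sum(mats, axis=0)
    mask = (votes / len(mats) >= threshold).astype(int)
    mask = mask * mask.T  # symmetry (defensive: inputs may be asymmetric)
    np.fill_diagonal(mask, 0)
    return ConsensusBackbone(
        mask=mask,
        roi_labels=tuple(roi_labels),
        threshold=threshold,
        n_subjects_used=len(mats),
    )


def apply_mask(func: FunctionalMatrix, backbone: ConsensusBackbone) -> MixedMatrix:
    """Element-wise gate: z where a structural connection exists, 0 elsewhere."""
    if func.roi_labels != backbone.roi_labels:
        raise ValueError("functional matrix and backbone have different ROI labels")
    return MixedMatrix(
        z_masked=func.z * backbone.mask,
        roi_labels=func.roi_labels,
        backbone=backbone,
    )
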