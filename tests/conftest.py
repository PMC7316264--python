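import numpy as np
import pytest

from rsconn.backbone import ConsensusBackbone, MixedMatrix
from rsconn.cohort import CohortSpec, EffectSpec
from rsconn.types import FunctionalMatrix


def make_labels(n: int) -> tuple[str, ...]:
    return tuple(f"roi{i:02d}" for i in range(n))


def functional_from(z: np.ndarray) -> FunctionalMatrix:
    z = np.asarray(z, dtype=float)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return FunctionalMatrix(z=z, roi_labels=make_labels(z.shape[0]))


def mixed_from_weights(w: np.ndarray) -> MixedMatrix:
    """Wrap a raw symmetric weight matrix as a MixedMatrix (all-ones mask)."""
    w = np.asarray(w, dtype=float)
    n = w.shape[0]
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 0.0)
    mask = np.ones((n, n), dtype=int)
    np.fill_diagonal(mask, 0)
    bb = ConsensusBackbone(
        mask=mask, roi_labels=make_labels(n), threshold=0.5, n_subjects_used=2
    )
    return MixedMatrix(z_masked=w, roi_labels=make_labels(n), backbone=bb)


@pytest.fixture
def small_spec() -> CohortSpec:
    """A reduced cohort (45 ROIs, short series) for fast end-to-end tests."""
    return CohortSpec(n_group1=5, n_group2=4, n_rois=45, n_volumes=60, seed=7)


@pytest.fixture
def tiny_effect() -> EffectSpec:
    return EffectSpec(
        edges=(("R_IFG_opercularis", "R_STG_posterior"),), delta_z=-0.5
    )
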