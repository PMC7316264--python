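"""Synthetic two-group, two-timepoint resting-state cohort generator.

Emulates the statistical structure the downstream analysis assumes: ROI
time series drawn from a modular base correlation structure with a
planted Group x Timepoint connectivity decrease on a chosen edge set,
contaminated by shared nuisance signals (white-matter/CSF-like) and
low-order polynomial drift; plus per-subject binary structural
connectomes realized as noisy copies of a common backbone template.

Planted effects are expressed on the Fisher-z scale and mapped back to
correlations with tanh, so the z-scale statistics downstream see an
additive shift of exactly ``delta_z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .parcellation import DEFAULT_EFFECT_EDGES, default_parcellation
from .types import SubjectTimeSeries

GROUPS = ("group1", "group2")  # group1 = experimental, group2 = control
TIMEPOINTS = ("tp1", "tp2")

_SPD_FLOOR = 1e-6
_SPD_DRIFT_TOL = 0.01  # max allowed projection perturbation on untouched cells
_DRIFT_COEF_SD = 0.5  # polynomial drift coefficient scale, in signal-s.d. units


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    Defaults follow the study design the pipeline targets: 14
    experimental and 12 control subjects, 129 ROIs, 242 volumes at
    TR = 2 s, scanned at two timepoints.
    """

    n_group1: int = 14
    n_group2: int = 12
    n_rois: int = 129
    n_volumes: int = 242
    tr_seconds: float = 2.0
    module_assignment: Mapping[str, int] | None = None
    base_within_r: float = 0.35
    base_between_r: float = 0.05
    nuisance_amplitude: float = 0.3
    drift_order: int = 2
    structural_flip_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 + self.n_group2 < 4:
            raise ValueError("need at least 4 subjects in total")
        if not (0.0 <= self.base_between_r < self.base_within_r < 1.0):
            raise ValueError("require 0 <= base_between_r < base_within_r < 1")
        if not (0.0 <= self.structural_flip_rate < 0.5):
            raise ValueError("structural_flip_rate must be in [0, 0.5)")
        if self.module_assignment is None:
            _, modules = default_parcellation(self.n_rois)
            object.__setattr__(self, "module_assignment", modules)
        if len(self.module_assignment) != self.n_rois:
            raise ValueError(
                f"module_assignment covers {len(self.module_assignment)} ROIs, "
                f"expected {self.n_rois}"
            )

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return tuple(self.module_assignment)

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2

    @property
    def subject_groups(self) -> tuple[str, ...]:
        return ("group1",) * self.n_group1 + ("group2",) * self.n_group2


@dataclass(frozen=True)
class EffectSpec:
    """Planted Group x Timepoint effect.

    ``delta_z`` is added, on the Fisher-z scale, to the listed edges in
    the (group1, tp2) cell only; all other cells keep the base structure.
    """

    edges: tuple[tuple[str, str], ...] = DEFAULT_EFFECT_EDGES
    delta_z: float = -0.4
    applies_to: str = "interaction"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "edges", tuple((str(a), str(b)) for a, b in self.edges)
        )
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"effect edge ({a}, {b}) joins an ROI to itself")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate effect edge ({a}, {b})")
            seen.add(key)
        if self.applies_to != "interaction":
            raise ValueError("only applies_to='interaction' is supported")


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted effect."""

    planted_edges: tuple[tuple[str, str], ...]
    targets: dict[tuple[str, str], np.ndarray]  # (group, timepoint) -> correlation
    backbone_template: np.ndarray
    roi_labels: tuple[str, ...]

    def edge_indices(self) -> list[tuple[int, int]]:
        idx = {label: i for i, label in enumerate(self.roi_labels)}
        return [tuple(sorted((idx[a], idx[b]))) for a, b in self.planted_edges]


@dataclass
class Cohort:
    """Generated dataset bundle: series, structural matrices, truth, manifest."""

    spec: CohortSpec
    effect: EffectSpec
    subjects: tuple[str, ...]
    groups: dict[str, str]
    series: dict[tuple[str, str], SubjectTimeSeries]  # (subject, timepoint)
    structural: dict[str, np.ndarray]
    truth: GroundTruth
    manifest: dict


def _edge_index_pairs(
    edges: tuple[tuple[str, str], ...], labels: tuple[str, ...]
) -> list[tuple[int, int]]:
    idx = {label: i for i, label in enumerate(labels)}
    out = []
    for a, b in edges:
        if a not in idx or b not in idx:
            missing = a if a not in idx else b
            raise ValueError(f"effect edge ({a}, {b}): ROI '{missing}' not in parcellation")
        out.append(tuple(sorted((idx[a], idx[b]))))
    return out


def _project_spd(r: np.ndarray) -> np.ndarray:
    """Clip eigenvalues at a small floor and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(r)
    if vals.min() >= _SPD_FLOOR:
        return r
    vals = np.clip(vals, _SPD_FLOOR, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    fixed = (fixed + fixed.T) / 2.0
    np.fill_diagonal(fixed, 1.0)
    return fixed


def build_target_covariance(
    spec: CohortSpec,
    effect: EffectSpec,
    group: str,
    timepoint: str,
) -> np.ndarray:
    """Target correlation matrix for one (group, timepoint) cell.

    Off-diagonal (i, j) is ``tanh(atanh(base_r) + delta_z)`` when (i, j)
    carries the planted effect in this cell (group1 at tp2), and the base
    correlation of the community relation of i and j otherwise.  The
    result is projected to the nearest symmetric positive-definite matrix
    (eigenvalues floored at 1e-6, diagonal renormalized) when needed; the
    projection is verified to move untouched cells by < 0.01.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    labels = spec.roi_labels
    modules = np.array([spec.module_assignment[l] for l in labels])
    same = modules[:, None] == modules[None, :]
    r = np.where(same, spec.base_within_r, spec.base_between_r).astype(float)
    np.fill_diagonal(r, 1.0)

    pairs = _edge_index_pairs(effect.edges, labels)
    effect_on = group == "group1" and timepoint == "tp2"
    touched = np.zeros_like(r, dtype=bool)
    if effect_on and effect.delta_z != 0.0:
        for i, j in pairs:
            shifted = np.tanh(np.arctanh(r[i, j]) + effect.delta_z)
            r[i, j] = r[j, i] = shifted
            touched[i, j] = touched[j, i] = True

    fixed = _project_spd(r)
    drift = np.abs(fixed - r)[~touched & ~np.eye(len(r), dtype=bool)]
    if drift.size and drift.max() >= _SPD_DRIFT_TOL:
        raise RuntimeError(
            f"SPD projection perturbed untouched cells by {drift.max():.4f} "
            f"(tolerance {_SPD_DRIFT_TOL})"
        )
    return fixed


def generate_timeseries(
    target: np.ndarray,
    spec: CohortSpec,
    subject_seed: int,
) -> SubjectTimeSeries:
    """Draw one subject/timepoint series from the target correlation.

    ``n_volumes`` samples of a zero-mean multivariate normal with
    covariance ``target``, plus (a) two shared nuisance source signals
    ("white-matter-like" and "CSF-like"), each added to every ROI at
    ``nuisance_amplitude`` and recorded verbatim as nuisance channels,
    and (b) per-ROI polynomial drift of degree ``drift_order``.
    Deterministic given (spec.seed, subject_seed).
    """
    target = np.asarray(target, dtype=float)
    try:
        chol = np.linalg.cholesky(target)
    except np.linalg.LinAlgError as exc:
        raise ValueError("target correlation matrix is not positive definite") from exc
    if target.shape[0] != spec.n_rois:
        raise ValueError("target size does not match spec.n_rois")

    rng = np.random.default_rng((spec.seed, subject_seed))
    n_t, n_r = spec.n_volumes, spec.n_rois
    signal = rng.standard_normal((n_t, n_r)) @ chol.T  # volumes x ROIs
    wm = rng.standard_normal(n_t)
    csf = rng.standard_normal(n_t)
    data = signal.T + spec.nuisance_amplitude * (wm + csf)[None, :]

    if spec.drift_order > 0:
        x = np.linspace(-1.0, 1.0, n_t)
        # Legendre basis keeps drift terms of different degree roughly orthogonal
        basis = np.stack(
            [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(1, spec.drift_order + 1)]
        )
        coefs = rng.normal(0.0, _DRIFT_COEF_SD, size=(n_r, spec.drift_order))
        data = data + coefs @ basis

    return SubjectTimeSeries(
        data=data,
        roi_labels=spec.roi_labels,
        tr_seconds=spec.tr_seconds,
        nuisance=np.stack([wm, csf]),
    )


def default_backbone_template(spec: CohortSpec, effect: EffectSpec) -> np.ndarray:
    """Binary backbone: dense within communities, sparse between, planted edges on."""
    labels = spec.roi_labels
    modules = np.array([spec.module_assignment[l] for l in labels])
    same = modules[:, None] == modules[None, :]
    rng = np.random.default_rng((spec.seed, 99991))
    n = spec.n_rois
    iu = np.triu_indices(n, k=1)
    between_edge = rng.random(iu[0].size) < 0.3
    template = np.zeros((n, n), dtype=int)
    template[iu] = np.where(same[iu], 1, between_edge.astype(int))
    template = template + template.T
    for i, j in _edge_index_pairs(effect.edges, labels):
        template[i, j] = template[j, i] = 1
    np.fill_diagonal(template, 0)
    return template


def generate_structural_cohort(
    spec: CohortSpec, truth: GroundTruth
) -> list[np.ndarray]:
    """Per-subject binary structural connectomes from the backbone template.

    Each off-diagonal cell of the template is flipped independently with
    probability ``structural_flip_rate`` (symmetry preserved); the
    planted edges are never flipped off, so they always survive the
    consensus vote.
    """
    template = np.asarray(truth.backbone_template)
    if np.abs(template - template.T).max() > 0 or np.abs(np.diag(template)).max() > 0:
        raise ValueError("backbone template must be symmetric with zero diagonal")
    n = template.shape[0]
    iu = np.triu_indices(n, k=1)
    planted = truth.edge_indices()
    out = []
    for s in range(spec.n_subjects):
        rng = np.random.default_rng((spec.seed, 10_000 + s))
        flips = rng.random(iu[0].size) < spec.structural_flip_rate
        mat = np.zeros((n, n), dtype=int)
        mat[iu] = np.abs(template[iu] - flips.astype(int))  # XOR
        mat = mat + mat.T
        for i, j in planted:
            mat[i, j] = mat[j, i] = 1
        out.append(mat)
    return out


def generate_cohort(spec: CohortSpec, effect: EffectSpec | None = None) -> Cohort:
    """Generate the full cohort bundle, reproducible from ``spec.seed``.

    Returns one :class:`SubjectTimeSeries` per subject and timepoint
    (2 x (n_group1 + n_group2) series), one structural matrix per
    subject, the ground truth, and a manifest of group membership and
    seeds.
    """
    if effect is None:
        effect = EffectSpec()
    labels = spec.roi_labels
    targets = {
        (g, t): build_target_covariance(spec, effect, g, t)
        for g in GROUPS
        for t in TIMEPOINTS
    }
    truth = GroundTruth(
        planted_edges=effect.edges,
        targets=targets,
        backbone_template=default_backbone_template(spec, effect),
        roi_labels=labels,
    )

    subjects = tuple(f"sub-{i + 1:02d}" for i in range(spec.n_subjects))
    groups = dict(zip(subjects, spec.subject_groups))
    series: dict[tuple[str, str], SubjectTimeSeries] = {}
    for s, sid in enumerate(subjects):
        for t, tp in enumerate(TIMEPOINTS):
            series[(sid, tp)] = generate_timeseries(
                targets[(groups[sid], tp)], spec, subject_seed=2 * s + t
            )
    structural = dict(zip(subjects, generate_structural_cohort(spec, truth)))
    manifest = {
        "seed": spec.seed,
        "groups": groups,
        "roi_labels": list(labels),
        "timepoints": list(TIMEPOINTS),
        "planted_edges": [list(e) for e in effect.edges],
        "delta_z": effect.delta_z,
        "n_rois": spec.n_rois,
        "n_volumes": spec.n_volumes,
        "tr_seconds": spec.tr_seconds,
    }
    return Cohort(
        spec=spec,
        effect=effect,
        subjects=subjects,
        groups=groups,
        series=series,
        structural=structural,
        truth=truth,
        manifest=manifest,
    )
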