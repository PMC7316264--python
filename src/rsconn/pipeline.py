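"""End-to-end orchestration: simulate -> connectivity -> backbone -> metrics -> stats.

Every stage reads and writes plain-text TSV/JSON, so stages can be run
separately (or on user-supplied data laid out the same way) and re-run
reproducibly: the same config and seed give byte-identical numeric
outputs.  A run manifest records the config hash, seeds, per-stage wall
time and the full output inventory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .backbone import ConsensusBackbone, apply_mask, consensus_binary
from .cohort import TIMEPOINTS, CohortSpec, EffectSpec, generate_cohort
from .metrics import NetworkDefinition, compute_metric_table
from .parcellation import default_networks
from .preprocess import PreprocConfig, run_preproc
from .stats import edgewise_scan, network_metric_anova

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One config object for the whole pipeline."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effect: EffectSpec = field(default_factory=EffectSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    consensus_threshold: float = 0.5
    fdr_q: float = 0.05
    networks: dict[str, tuple[str, ...]] = field(default_factory=default_networks)
    restrict_fdr_to_backbone: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must be in (0, 1)")
        if not (0.0 < self.consensus_threshold <= 1.0):
            raise ValueError("consensus_threshold must be in (0, 1]")
        labels = set(self.cohort.roi_labels)
        for name, members in self.networks.items():
            missing = [m for m in members if m not in labels]
            if missing:
                raise ValueError(f"network {name!r}: unknown ROIs {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "cohort" in raw:
            kwargs["cohort"] = CohortSpec(**raw["cohort"])
        if "effect" in raw:
            eff = dict(raw["effect"])
            if "edges" in eff:
                eff["edges"] = tuple(tuple(e) for e in eff["edges"])
            kwargs["effect"] = EffectSpec(**eff)
        if "preproc" in raw:
            pp = dict(raw["preproc"])
            if pp.get("band") is not None:
                pp["band"] = tuple(pp["band"])
            kwargs["preproc"] = PreprocConfig(**pp)
        for key in ("consensus_threshold", "fdr_q", "restrict_fdr_to_backbone"):
            if key in raw:
                kwargs[key] = raw[key]
        if "networks" in raw:
            kwargs["networks"] = {k: tuple(v) for k, v in raw["networks"].items()}
        return cls(**kwargs)

    def hash(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            return obj

        blob = json.dumps(
            _clean(
                {
                    "cohort": asdict(self.cohort) | {"module_assignment": dict(self.cohort.module_assignment)},
                    "effect": asdict(self.effect),
                    "preproc": asdict(self.preproc),
                    "consensus_threshold": self.consensus_threshold,
                    "fdr_q": self.fdr_q,
                    "networks": {k: list(v) for k, v in self.networks.items()},
                    "restrict_fdr_to_backbone": self.restrict_fdr_to_backbone,
                }
            ),
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    seed: int
    stages: list[str]
    wall_time_s: dict[str, float]
    outputs: list[str]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> list[Path]:
    """Generate the synthetic cohort and write it out as TSV/JSON."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "structural").mkdir(exist_ok=True)
    cohort = generate_cohort(config.cohort, config.effect)
    written = []
    for (sid, tp), ts in cohort.series.items():
        p = out / "timeseries" / f"{sid}_{tp}.tsv"
        rio.write_timeseries_tsv(p, ts)
        written.append(p)
    for sid, mat in cohort.structural.items():
        p = out / "structural" / f"{sid}.tsv"
        rio.write_matrix_tsv(p, mat, cohort.truth.roi_labels)
        written.append(p)
    p = out / "manifest.json"
    rio.write_json(p, cohort.manifest)
    written.append(p)
    p = out / "networks.json"
    rio.write_networks_json(p, config.networks)
    written.append(p)
    return written


def _load_cohort_layout(data_dir: Path) -> tuple[dict, list[str]]:
    manifest = rio.read_json(data_dir / "manifest.json")
    return manifest, list(manifest["groups"])


def stage_connectivity(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Clean every series and write Fisher-z functional matrices."""
    data_dir, out = Path(data_dir), Path(out_dir)
    (out / "functional").mkdir(parents=True, exist_ok=True)
    manifest, subjects = _load_cohort_layout(data_dir)
    written = []
    for sid in subjects:
        for tp in TIMEPOINTS:
            ts = rio.read_timeseries_tsv(
                data_dir / "timeseries" / f"{sid}_{tp}.tsv", manifest["tr_seconds"]
            )
            fm = run_preproc(ts, config.preproc)
            p = out / "functional" / f"{sid}_{tp}.tsv"
            rio.write_functional_tsv(p, fm)
            written.append(p)
    return written


def stage_backbone(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Consensus backbone over all subjects, then mixed matrices."""
    data_dir, out = Path(data_dir), Path(out_dir)
    (out / "mixed").mkdir(parents=True, exist_ok=True)
    manifest, subjects = _load_cohort_layout(data_dir)
    mats, labels = [], None
    for sid in subjects:
        m, lab = rio.read_matrix_tsv(data_dir / "structural" / f"{sid}.tsv")
        if labels is None:
            labels = lab
        elif lab != labels:
            logger.warning("structural matrix of %s: realigning ROI label order", sid)
            m = rio.realign_matrix(m, lab, labels)
        mats.append(m)
    bb = consensus_binary(mats, labels, config.consensus_threshold)
    p = out / "backbone.tsv"
    rio.write_matrix_tsv(p, bb.mask, labels)
    written = [p]
    for sid in subjects:
        for tp in TIMEPOINTS:
            fm = rio.read_functional_tsv(out / "functional" / f"{sid}_{tp}.tsv")
            mixed = apply_mask(fm, bb)
            p = out / "mixed" / f"{sid}_{tp}.tsv"
            rio.write_matrix_tsv(p, mixed.z_masked, labels)
            written.append(p)
    return written


def stage_metrics(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Strength/global/local efficiency table per subject, timepoint, network."""
    data_dir, out = Path(data_dir), Path(out_dir)
    manifest, subjects = _load_cohort_layout(data_dir)
    groups = manifest["groups"]
    bb_mask, labels = rio.read_matrix_tsv(out / "backbone.tsv")
    bb = ConsensusBackbone(
        mask=bb_mask.astype(int),
        roi_labels=labels,
        threshold=config.consensus_threshold,
        n_subjects_used=len(subjects),
    )
    functional, mixed = {}, {}
    for sid in subjects:
        for tp in TIMEPOINTS:
            fm = rio.read_functional_tsv(out / "functional" / f"{sid}_{tp}.tsv")
            functional[(sid, tp)] = fm
            mixed[(sid, tp)] = apply_mask(fm, bb)
    networks = [NetworkDefinition(k, v) for k, v in config.networks.items()]
    table = compute_metric_table(functional, mixed, networks, groups)
    p = out / "metrics.tsv"
    table.to_csv(p, sep="\t", index=False, float_format="%.10g")
    return [p]


def stage_stats(
    config: PipelineConfig, data_dir: str | Path, out_dir: str | Path
) -> list[Path]:
    """Edge-wise scan with FDR plus network-level metric ANOVAs."""
    import pandas as pd

    data_dir, out = Path(data_dir), Path(out_dir)
    manifest, subjects = _load_cohort_layout(data_dir)
    groups = manifest["groups"]
    functional = {
        (sid, tp): rio.read_functional_tsv(out / "functional" / f"{sid}_{tp}.tsv")
        for sid in subjects
        for tp in TIMEPOINTS
    }
    edge_mask = None
    if config.restrict_fdr_to_backbone:
        edge_mask, _ = rio.read_matrix_tsv(out / "backbone.tsv")
    scan = edgewise_scan(functional, groups, q=config.fdr_q, edge_mask=edge_mask)
    written = []
    p = out / "edge_stats.tsv"
    scan.table.to_csv(p, sep="\t", index=False, float_format="%.6g")
    written.append(p)
    p = out / "subnetwork_edges.tsv"
    scan.table[scan.table["fdr_flag"]][["node1", "node2"]].to_csv(
        p, sep="\t", index=False
    )
    written.append(p)

    metric_table = pd.read_csv(out / "metrics.tsv", sep="\t")
    network_report = []
    for net in config.networks:
        for metric in ("strength", "e_glob", "e_loc"):
            res = network_metric_anova(metric_table, metric, net)
            network_report.append(
                {
                    "network": net,
                    "metric": metric,
                    "anova": asdict(res["anova"]),
                    "posthoc": res["posthoc"],
                }
            )
    report = {
        "config_hash": config.hash(),
        "edgewise": scan.summary,
        "components": scan.components,
        "network_anovas": network_report,
    }
    p = out / "report.json"
    rio.write_json(p, report)
    written.append(p)
    return written


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages in order; the data dir is ``out_dir`` itself."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_fns = [
        ("simulate", lambda: stage_simulate(config, out)),
        ("connectivity", lambda: stage_connectivity(config, out, out)),
        ("backbone", lambda: stage_backbone(config, out, out)),
        ("metrics", lambda: stage_metrics(config, out, out)),
        ("stats", lambda: stage_stats(config, out, out)),
    ]
    outputs: list[str] = []
    wall: dict[str, float] = {}
    for name, fn in stage_fns:
        t0 = time.perf_counter()
        logger.info("stage %s starting", name)
        try:
            written = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        wall[name] = round(time.perf_counter() - t0, 3)
        outputs.extend(str(p.relative_to(out)) for p in written)
    manifest = RunManifest(
        config_hash=config.hash(),
        seed=config.cohort.seed,
        stages=[n for n, _ in stage_fns],
        wall_time_s=wall,
        outputs=outputs,
    )
    rio.write_json(out / "run_manifest.json", asdict(manifest))
    return manifest


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_inputs(data_dir: str | Path) -> dict:
    """Check a cohort directory for structural problems before running.

    Returns ``{"errors": [...], "warnings": [...]}``; errors cover
    asymmetric matrices, non-binary structural matrices, missing
    timepoints and label mismatches (a pure label *reordering* is a
    warning — readers realign by label).
    """
    data_dir = Path(data_dir)
    errors: list[str] = []
    warnings_: list[str] = []
    try:
        manifest, subjects = _load_cohort_layout(data_dir)
    except FileNotFoundError:
        return {"errors": ["manifest.json not found"], "warnings": []}

    ref_labels: tuple[str, ...] | None = None
    for sid in subjects:
        for tp in TIMEPOINTS:
            p = data_dir / "timeseries" / f"{sid}_{tp}.tsv"
            if not p.exists():
                errors.append(f"subject {sid} is missing timepoint {tp}")
        p = data_dir / "structural" / f"{sid}.tsv"
        if not p.exists():
            errors.append(f"subject {sid} has no structural matrix")
            continue
        mat, labels = rio.read_matrix_tsv(p)
        asym = float(np.abs(mat - mat.T).max())
        if asym > 0:
            errors.append(f"{p.name}: asymmetric (max |A - A.T| = {asym:g})")
        if not np.isin(mat, (0, 1)).all():
            warnings_.append(f"{p.name}: weighted entries; will binarize at > 0")
        if ref_labels is None:
            ref_labels = labels
        elif labels != ref_labels:
            if sorted(labels) == sorted(ref_labels):
                warnings_.append(f"{p.name}: ROI label order differs; will realign")
            else:
                errors.append(f"{p.name}: ROI label set differs")
    return {"errors": errors, "warnings": warnings_}
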