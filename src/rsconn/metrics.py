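"""Weighted network-efficiency measures on attentional subnetworks.

Three measures per network, subject and timepoint:

* **connectivity strength** — mean Fisher-z among the network's member
  ROIs, taken from the full functional matrix (connections to outside
  nodes have no influence);
* **global efficiency** — mean inverse shortest-path length over member
  pairs of the mixed (backbone-gated) matrix; indexes integration;
* **local efficiency** — mean nodal efficiency among each member's
  neighbors, weighted (cube-root) variant; indexes segregation.

Path-based measures run on mixed matrices because functional matrices
alone encode statistical correlation, not routes of information flow.
Negative Fisher-z weights carry no path and are treated as absent edges
for the efficiencies, but keep their sign in connectivity strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .backbone import MixedMatrix
from .types import FunctionalMatrix


@dataclass(frozen=True)
class NetworkDefinition:
    """A named node set (e.g. VAN, DAN) over the parcellation labels."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))
        if not self.members:
            raise ValueError(f"network {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"network {self.name!r} lists duplicate ROIs")

    def indices(self, roi_labels: tuple[str, ...]) -> np.ndarray:
        pos = {label: i for i, label in enumerate(roi_labels)}
        missing = [m for m in self.members if m not in pos]
        if missing:
            raise ValueError(
                f"network {self.name!r} members not in parcellation: {missing}"
            )
        return np.array([pos[m] for m in self.members])


def network_strength(func: FunctionalMatrix, net: NetworkDefinition) -> float:
    """Mean Fisher-z over distinct member pairs of the full functional matrix."""
    idx = net.indices(func.roi_labels)
    if idx.size < 2:
        raise ValueError(f"network {net.name!r} needs at least 2 members")
    sub = func.z[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def to_lengths(weights: np.ndarray) -> np.ndarray:
    """Reciprocal weight-to-length map; nonpositive weights carry no path."""
    w = np.asarray(weights, dtype=float)
    lengths = np.full_like(w, np.inf)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    np.fill_diagonal(lengths, 0.0)
    return lengths


def shortest_path_lengths(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths (Dijkstra); unreachable pairs stay at +inf."""
    lengths = np.asarray(lengths, dtype=float)
    if lengths.size == 0:
        return lengths.copy()
    if np.nanmin(lengths) < 0:
        raise ValueError("edge lengths must be nonnegative")
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def _member_weights(mixed: MixedMatrix, net: NetworkDefinition) -> np.ndarray:
    idx = net.indices(mixed.roi_labels)
    if idx.size < 2:
        raise ValueError(f"network {net.name!r} needs at least 2 members")
    w = mixed.z_masked[np.ix_(idx, idx)].copy()
    w[w < 0] = 0.0  # negative correlations carry no path
    np.fill_diagonal(w, 0.0)
    return w


def _global_efficiency_weights(w: np.ndarray) -> float:
    n = w.shape[0]
    d = shortest_path_lengths(to_lengths(w))
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].sum() / (n * (n - 1)))


def _local_efficiency_weights(w: np.ndarray) -> float:
    """Weighted local efficiency, cube-root variant.

    For node i with neighbors N(i): shortest paths among the neighbors
    are computed on the neighborhood subgraph with cube-rooted edge
    lengths, and each ordered neighbor pair (j, h) contributes
    ``w_ij^(1/3) * w_ih^(1/3) / d_jh`` to the numerator, normalized by
    k_i*(k_i - 1).  Nodes with fewer than two neighbors score 0.
    """
    n = w.shape[0]
    nodal = np.zeros(n)
    for u in range(n):
        nbrs = np.where(w[u] > 0)[0]
        k = nbrs.size
        if k < 2:
            continue
        sw = np.cbrt(w[u, nbrs])
        sub = w[np.ix_(nbrs, nbrs)]
        d = shortest_path_lengths(np.cbrt(to_lengths(sub)))
        inv = np.zeros_like(d)
        off = ~np.eye(k, dtype=bool)
        finite = off & np.isfinite(d) & (d > 0)
        inv[finite] = 1.0 / d[finite]
        numer = float((np.outer(sw, sw) * inv)[off].sum())
        nodal[u] = numer / (k * (k - 1))
    return float(nodal.mean())


def global_efficiency(mixed: MixedMatrix, net: NetworkDefinition) -> float:
    """Weighted global efficiency of the member-induced subgraph."""
    return _global_efficiency_weights(_member_weights(mixed, net))


def local_efficiency(mixed: MixedMatrix, net: NetworkDefinition) -> float:
    """Weighted local efficiency (mean nodal value) of the member subgraph."""
    return _local_efficiency_weights(_member_weights(mixed, net))


def compute_metric_table(
    functional: Mapping[tuple[str, str], FunctionalMatrix],
    mixed: Mapping[tuple[str, str], MixedMatrix],
    networks: Iterable[NetworkDefinition],
    groups: Mapping[str, str],
    timepoints: tuple[str, str] = ("tp1", "tp2"),
) -> pd.DataFrame:
    """One row per subject x timepoint x network.

    Strength comes from the functional matrix, efficiencies from the
    mixed matrix.  A subject missing either matrix at either timepoint is
    an error.
    """
    networks = list(networks)
    rows = []
    for sid in groups:
        for tp in timepoints:
            if (sid, tp) not in functional:
                raise ValueError(f"missing functional matrix for {sid} at {tp}")
            if (sid, tp) not in mixed:
                raise ValueError(f"missing mixed matrix for {sid} at {tp}")
            for net in networks:
                rows.append(
                    {
                        "subject": sid,
                        "group": groups[sid],
                        "timepoint": tp,
                        "network": net.name,
                        "strength": network_strength(functional[(sid, tp)], net),
                        "e_glob": global_efficiency(mixed[(sid, tp)], net),
                        "e_loc": local_efficiency(mixed[(sid, tp)], net),
                    }
                )
    return pd.DataFrame(rows)
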