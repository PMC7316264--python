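"""Mixed 2x2 ANOVA, FDR control, edge-wise scan and post-hoc t-tests.

The design has one between-subject factor (Group: experimental vs
control) and one within-subject factor (Timepoint: tp1 vs tp2).  With
two within levels the classical split-plot decomposition reduces to two
independent strata on subject summaries:

* the **Group** main effect is a pooled-variance two-sample t-test on
  per-subject means across timepoints (F = t^2 on df (1, N-2));
* the **Timepoint** main effect and the **Group x Timepoint**
  interaction are tested on per-subject change scores d = tp2 - tp1:
  the interaction F equals the squared pooled two-sample t comparing
  change scores between groups, and the timepoint F tests whether the
  unweighted mean of the two group change means is zero.

This reproduces the textbook mixed-ANOVA table exactly on balanced
designs and yields df = (1, N-2) for every effect, matching the degrees
of freedom of a 14 + 12 cohort: (1, 24).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .types import FunctionalMatrix

GROUPS = ("group1", "group2")
TIMEPOINTS = ("tp1", "tp2")


# ---------------------------------------------------------------------------
# p-value kernels
# ---------------------------------------------------------------------------

def p_from_t(t: float, df: float) -> float:
    """Two-tailed p for a Student-t statistic."""
    if df < 1:
        raise ValueError(f"t-test degrees of freedom must be >= 1, got {df}")
    return float(2.0 * sps.t.sf(np.abs(t), df))


def p_from_f(F: float, df1: float, df2: float) -> float:
    """Upper-tail p for an F statistic; for df1=1 equals p_from_t(sqrt(F), df2)."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"F-test degrees of freedom must be >= 1, got ({df1}, {df2})")
    return float(sps.f.sf(F, df1, df2))


# ---------------------------------------------------------------------------
# mixed 2x2 ANOVA engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """F, df and p for the three effects of the mixed 2x2 design."""

    F_group: float
    F_time: float
    F_interaction: float
    df: tuple[int, int]
    p_group: float
    p_time: float
    p_interaction: float


def _pooled_stats(values: np.ndarray, g1: np.ndarray):
    """Group means and pooled within-group variance along axis 0.

    ``values``: (N,) or (N, E); ``g1``: boolean mask of group-1 rows.
    """
    n1, n2 = int(g1.sum()), int((~g1).sum())
    m1 = values[g1].mean(axis=0)
    m2 = values[~g1].mean(axis=0)
    ss = ((values[g1] - m1) ** 2).sum(axis=0) + ((values[~g1] - m2) ** 2).sum(axis=0)
    s2 = ss / (n1 + n2 - 2)
    return m1, m2, s2, n1, n2


def _safe_f(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """num/den with the 0/0 (no variance, no effect) case mapped to F=0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.full(np.broadcast_shapes(num.shape, den.shape), np.inf)
    zero = (den == 0) & (num == 0)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    out[zero] = 0.0
    return out


def mixed_anova_arrays(
    y1: np.ndarray, y2: np.ndarray, group1_mask: np.ndarray
) -> dict[str, np.ndarray]:
    """Vectorized mixed 2x2 ANOVA over the trailing axis.

    ``y1``/``y2`` hold the tp1/tp2 values, shape (N,) or (N, E) for E
    simultaneous response variables (e.g. all edges of a connectivity
    matrix).  Returns F and p arrays per effect plus the common df.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    g1 = np.asarray(group1_mask, dtype=bool)
    if y1.shape != y2.shape or y1.shape[0] != g1.size:
        raise ValueError("y1, y2 and group mask sizes are inconsistent")
    n1, n2 = int(g1.sum()), int((~g1).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")
    N = n1 + n2
    df = (1, N - 2)
    inv_n = 1.0 / n1 + 1.0 / n2

    means = (y1 + y2) / 2.0
    change = y2 - y1

    m1, m2, s2m, *_ = _pooled_stats(means, g1)
    F_group = _safe_f((m1 - m2) ** 2, s2m * inv_n)

    d1, d2, s2d, *_ = _pooled_stats(change, g1)
    F_inter = _safe_f((d1 - d2) ** 2, s2d * inv_n)
    # Timepoint effect: unweighted mean of group change means (type-III).
    F_time = _safe_f(((d1 + d2) / 2.0) ** 2, s2d * inv_n / 4.0)

    return {
        "F_group": F_group,
        "F_time": F_time,
        "F_interaction": F_inter,
        "p_group": sps.f.sf(F_group, *df),
        "p_time": sps.f.sf(F_time, *df),
        "p_interaction": sps.f.sf(F_inter, *df),
        "df": df,
    }


def mixed_anova_2x2(obs: pd.DataFrame | Sequence[Mapping]) -> AnovaResult:
    """Mixed 2x2 ANOVA from long-format observations.

    ``obs`` needs columns/keys subject, group, timepoint, value; every
    subject must appear once per timepoint and belong to one group.
    """
    df_obs = pd.DataFrame(obs)
    required = {"subject", "group", "timepoint", "value"}
    if not required.issubset(df_obs.columns):
        raise ValueError(f"observations need columns {sorted(required)}")
    wide = df_obs.pivot_table(
        index="subject", columns="timepoint", values="value", aggfunc="first"
    )
    if list(wide.columns.sort_values()) != list(TIMEPOINTS) or wide.isna().any().any():
        missing = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-subject data (subjects {missing or 'n/a'})")
    grp = df_obs.groupby("subject")["group"].agg(lambda s: s.iloc[0])
    if df_obs.groupby("subject")["group"].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    grp = grp.loc[wide.index]
    res = mixed_anova_arrays(
        wide["tp1"].to_numpy(),
        wide["tp2"].to_numpy(),
        (grp == GROUPS[0]).to_numpy(),
    )
    return AnovaResult(
        F_group=float(res["F_group"]),
        F_time=float(res["F_time"]),
        F_interaction=float(res["F_interaction"]),
        df=res["df"],
        p_group=float(res["p_group"]),
        p_time=float(res["p_time"]),
        p_interaction=float(res["p_interaction"]),
    )


# ---------------------------------------------------------------------------
# FDR
# ---------------------------------------------------------------------------

def bh_fdr(pvals: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < q < 1.0):
        raise ValueError("FDR level q must be in (0, 1)")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# post-hoc t-tests
# ---------------------------------------------------------------------------

def posthoc_edge(
    y1: np.ndarray, y2: np.ndarray, group1_mask: np.ndarray
) -> dict[str, dict[str, float]]:
    """Uncorrected two-tailed post-hoc tests for one edge or metric.

    Paired t (tp2 vs tp1) within each group, and pooled-variance unpaired
    t (group1 vs group2) at each timepoint.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    g1 = np.asarray(group1_mask, dtype=bool)
    out: dict[str, dict[str, float]] = {}
    for gname, mask in (("group1", g1), ("group2", ~g1)):
        n = int(mask.sum())
        if n < 2:
            raise ValueError(f"{gname} has fewer than 2 subjects")
        diff = y2[mask] - y1[mask]
        if diff.std() == 0:  # degenerate: no within-subject variability
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(y2[mask], y1[mask])
        out[f"paired_{gname}"] = {"t": float(t), "df": n - 1, "p": float(p)}
    for tp, y in (("tp1", y1), ("tp2", y2)):
        if y[g1].std() == 0 and y[~g1].std() == 0 and y[g1].mean() == y[~g1].mean():
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_ind(y[g1], y[~g1], equal_var=True)
            if np.isnan(t):
                t, p = 0.0, 1.0
        out[f"unpaired_{tp}"] = {"t": float(t), "df": int(y.size - 2), "p": float(p)}
    return out


# ---------------------------------------------------------------------------
# edge-wise scan
# ---------------------------------------------------------------------------

@dataclass
class EdgeStatsTable:
    """Per-edge ANOVA results, FDR flags and the significant subnetwork."""

    table: pd.DataFrame  # node1, node2, F/p per effect, fdr_flag, post-hocs
    roi_labels: tuple[str, ...]
    q: float
    df: tuple[int, int]
    components: list[dict]
    summary: dict


def edgewise_scan(
    functional: Mapping[tuple[str, str], FunctionalMatrix],
    groups: Mapping[str, str],
    q: float = 0.05,
    edge_mask: np.ndarray | None = None,
    with_posthoc: bool = True,
) -> EdgeStatsTable:
    """Mixed 2x2 ANOVA per upper-triangle edge with BH-FDR on the interaction.

    ``functional`` maps (subject, timepoint) to a Fisher-z matrix; the
    scan runs on these unmasked functional matrices.  ``edge_mask`` can
    restrict the FDR family (e.g. to backbone edges); the default family
    is every upper-triangle edge.  Flagged edges are assembled into
    connected components and summarized.
    """
    subjects = list(groups)
    first = functional[(subjects[0], TIMEPOINTS[0])]
    labels = first.roi_labels
    n = len(labels)
    iu = np.triu_indices(n, k=1)

    def _edges(sid: str, tp: str) -> np.ndarray:
        fm = functional[(sid, tp)]
        if fm.roi_labels != labels:
            raise ValueError(f"ROI labels of {sid}/{tp} differ from the cohort's")
        return fm.z[iu]

    try:
        y1 = np.stack([_edges(s, "tp1") for s in subjects])
        y2 = np.stack([_edges(s, "tp2") for s in subjects])
    except KeyError as exc:
        raise ValueError(f"missing functional matrix for {exc.args[0]}") from exc
    g1 = np.array([groups[s] == GROUPS[0] for s in subjects])

    if edge_mask is not None:
        family = np.asarray(edge_mask)[iu].astype(bool)
    else:
        family = np.ones(iu[0].size, dtype=bool)
    y1, y2 = y1[:, family], y2[:, family]
    e1, e2 = iu[0][family], iu[1][family]

    res = mixed_anova_arrays(y1, y2, g1)
    flags = bh_fdr(res["p_interaction"], q)

    table = pd.DataFrame(
        {
            "node1": [labels[i] for i in e1],
            "node2": [labels[j] for j in e2],
            "F_group": res["F_group"],
            "p_group": res["p_group"],
            "F_time": res["F_time"],
            "p_time": res["p_time"],
            "F_interaction": res["F_interaction"],
            "p_interaction": res["p_interaction"],
            "fdr_flag": flags,
        }
    )

    if with_posthoc and flags.any():
        cols = {
            "t_paired_group1": np.nan, "p_paired_group1": np.nan,
            "t_paired_group2": np.nan, "p_paired_group2": np.nan,
            "t_unpaired_tp1": np.nan, "p_unpaired_tp1": np.nan,
            "t_unpaired_tp2": np.nan, "p_unpaired_tp2": np.nan,
        }
        for c, v in cols.items():
            table[c] = v
        for k in np.where(flags)[0]:
            ph = posthoc_edge(y1[:, k], y2[:, k], g1)
            table.loc[k, "t_paired_group1"] = ph["paired_group1"]["t"]
            table.loc[k, "p_paired_group1"] = ph["paired_group1"]["p"]
            table.loc[k, "t_paired_group2"] = ph["paired_group2"]["t"]
            table.loc[k, "p_paired_group2"] = ph["paired_group2"]["p"]
            table.loc[k, "t_unpaired_tp1"] = ph["unpaired_tp1"]["t"]
            table.loc[k, "p_unpaired_tp1"] = ph["unpaired_tp1"]["p"]
            table.loc[k, "t_unpaired_tp2"] = ph["unpaired_tp2"]["t"]
            table.loc[k, "p_unpaired_tp2"] = ph["unpaired_tp2"]["p"]

    components = _components(labels, e1[flags], e2[flags])
    summary = {
        "n_edges_tested": int(family.sum()),
        "n_edges_flagged": int(flags.sum()),
        "n_nodes_flagged": len({int(i) for i in np.concatenate([e1[flags], e2[flags]])}),
        "n_components": len(components),
        "q": q,
        "df": list(res["df"]),
    }
    return EdgeStatsTable(
        table=table,
        roi_labels=labels,
        q=q,
        df=res["df"],
        components=components,
        summary=summary,
    )


def _components(labels, ei, ej) -> list[dict]:
    """Connected components of the flagged-edge graph."""
    if ei.size == 0:
        return []
    nodes = sorted({int(i) for i in np.concatenate([ei, ej])})
    pos = {v: k for k, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for a, b in zip(ei, ej):
        adj[pos[int(a)], pos[int(b)]] = adj[pos[int(b)], pos[int(a)]] = 1
    n_comp, assign = connected_components(adj, directed=False)
    out = []
    for c in range(n_comp):
        members = [nodes[k] for k in np.where(assign == c)[0]]
        mset = set(members)
        n_edges = sum(1 for a, b in zip(ei, ej) if int(a) in mset)
        out.append(
            {
                "nodes": [labels[m] for m in members],
                "n_nodes": len(members),
                "n_edges": n_edges,
            }
        )
    return out


# ---------------------------------------------------------------------------
# network-level metric ANOVA
# ---------------------------------------------------------------------------

def network_metric_anova(
    metric_table: pd.DataFrame, metric: str, network: str
) -> dict:
    """Mixed 2x2 ANOVA + post-hocs for one efficiency measure of one network."""
    if metric not in metric_table.columns:
        raise ValueError(f"metric {metric!r} not in table")
    sub = metric_table[metric_table["network"] == network]
    if sub.empty:
        raise ValueError(f"network {network!r} not in table")
    obs = sub.rename(columns={metric: "value"})[
        ["subject", "group", "timepoint", "value"]
    ]
    res = mixed_anova_2x2(obs)
    wide = sub.pivot(index="subject", columns="timepoint", values=metric)
    grp = sub.groupby("subject")["group"].first().loc[wide.index]
    ph = posthoc_edge(
        wide["tp1"].to_numpy(), wide["tp2"].to_numpy(), (grp == GROUPS[0]).to_numpy()
    )
    return {"network": network, "metric": metric, "anova": res, "posthoc": ph}
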