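"""ROI-to-ROI connectivity and TFCE permutation inference.

First level: for every participant and session, the pairwise Pearson
correlations of the 18 ROI time series are Fisher z-transformed (atanh),
giving a symmetric connectivity matrix with C(18,2) = 153 unique edges.
The per-edge connectivity change dFC = z(T1) - z(T0) is the unit of
second-level analysis.

Second level: the group x time interaction on each edge reduces, under
complete T0/T1 pairing, to a two-sample equal-variance t-test comparing
dFC between the two groups (df = n1 + n2 - 2). Negative t means the
treated group's connectivity decreased more (or increased less) than the
control group's.

Multiple-comparison control uses threshold-free cluster enhancement over
the edge graph (two edges are adjacent when they share an endpoint ROI):

    TFCE(e) = sum_h extent_e(h)^E * h^H * dh

where extent_e(h) is the size (edge count) of the connected component
containing e among edges with statistic >= h, and h sweeps n_steps equal
increments from 0 to the maximum statistic (defaults H=2, E=0.5,
n_steps=100, per the original TFCE formulation). Family-wise error is
controlled by permuting group labels: the null distribution is the
maximum TFCE over all edges and both tails, and p_FWE uses the +1
smoothed permutation convention. Edges significant at the FWE level are
grouped into connected components (clusters); per-edge Benjamini-Hochberg
FDR p-values over all 153 edges support post-hoc interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synth import RoiTimeSeries

__all__ = [
    "FcMatrix",
    "edge_list",
    "fc_matrix",
    "fc_table",
    "delta_fc",
    "delta_fc_by_group",
    "interaction_t",
    "tfce_scores",
    "edge_fdr",
    "EdgeInteractionTest",
    "cluster_mean_fc",
]

#: Fisher z is clipped at atanh(1 - 1e-7) to keep perfect correlations finite.
Z_CLIP_R = 1.0 - 1e-7


@dataclass(frozen=True)
class FcMatrix:
    """Symmetric Fisher-z connectivity for one participant-session."""

    participant: str
    group: str
    session: str
    z: np.ndarray  # (p, p), diagonal = 0 by convention
    roi_labels: tuple[str, ...]

    @property
    def edge_values(self) -> np.ndarray:
        """Upper-triangle edge vector (canonical edge order)."""
        iu = np.triu_indices(self.z.shape[0], k=1)
        return self.z[iu]


def edge_list(roi_labels: Sequence[str]) -> list[tuple[str, str]]:
    """Canonical (upper-triangle) edge ordering over the ROI labels."""
    return list(combinations(roi_labels, 2))


def fc_matrix(ts: RoiTimeSeries) -> FcMatrix:
    """Fisher z-transformed Pearson correlation matrix of one session."""
    x = ts.data
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = [ts.roi_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance ROI series: {bad}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 0.0)
    if np.any(np.abs(r) >= 1.0 - 1e-12):
        import warnings

        warnings.warn(
            f"perfect correlation in {ts.participant}/{ts.session}; "
            "clipping Fisher z",
            stacklevel=2,
        )
    r = np.clip(r, -Z_CLIP_R, Z_CLIP_R)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return FcMatrix(ts.participant, ts.group, ts.session, z, tuple(ts.roi_labels))


def fc_table(series: Iterable[RoiTimeSeries]) -> dict[tuple[str, str], FcMatrix]:
    """(participant, session) -> FcMatrix for a collection of series."""
    out = {}
    for ts in series:
        out[(ts.participant, ts.session)] = fc_matrix(ts)
    return out


def delta_fc(fc_t1: FcMatrix, fc_t0: FcMatrix) -> np.ndarray:
    """Edge-wise z(T1) - z(T0) for one participant (canonical edge order)."""
    if fc_t1.participant != fc_t0.participant:
        raise ValueError(
            f"session pairing error: {fc_t1.participant} vs {fc_t0.participant}"
        )
    if fc_t1.roi_labels != fc_t0.roi_labels:
        raise ValueError("ROI label mismatch between sessions")
    return fc_t1.edge_values - fc_t0.edge_values


def delta_fc_by_group(
    fcs: Mapping[tuple[str, str], FcMatrix],
    sessions: tuple[str, str] = ("T0", "T1"),
) -> dict[str, pd.DataFrame]:
    """group -> (participants x edges) dFC frame, canonical edge order."""
    t0, t1 = sessions
    per_group: dict[str, dict[str, np.ndarray]] = {}
    participants = sorted({p for p, _ in fcs})
    labels = None
    for pid in participants:
        if (pid, t0) not in fcs or (pid, t1) not in fcs:
            raise ValueError(f"participant {pid} missing session {t0} or {t1}")
        a, b = fcs[(pid, t0)], fcs[(pid, t1)]
        labels = a.roi_labels
        per_group.setdefault(a.group, {})[pid] = delta_fc(b, a)
    cols = [f"{x}--{y}" for x, y in edge_list(labels)]
    return {
        g: pd.DataFrame.from_dict(d, orient="index", columns=cols).sort_index()
        for g, d in per_group.items()
    }


def interaction_t(
    delta_a: np.ndarray, delta_b: np.ndarray
) -> tuple[np.ndarray, int]:
    """Two-sample equal-variance t per edge (group A minus group B).

    Returns (t vector, df). Negative t means the change in group A is
    smaller than in group B.
    """
    a = np.atleast_2d(np.asarray(delta_a, float))
    b = np.atleast_2d(np.asarray(delta_b, float))
    n1, n2 = a.shape[0], b.shape[0]
    if min(n1, n2) < 2:
        raise ValueError(f"need >= 2 participants per group, got {n1} and {n2}")
    df = n1 + n2 - 2
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    ss = ((a - m1) ** 2).sum(axis=0) + ((b - m2) ** 2).sum(axis=0)
    se = np.sqrt(ss / df * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t, df


# -- TFCE ---------------------------------------------------------------------


@njit(cache=True)
def _tfce_one_tail(t, eu, ev, n_nodes, h_pow, e_pow, n_steps):  # pragma: no cover
    m = t.shape[0]
    out = np.zeros(m)
    hmax = 0.0
    for i in range(m):
        if t[i] > hmax:
            hmax = t[i]
    if hmax <= 0.0:
        return out
    dh = hmax / n_steps
    order = np.argsort(-t)
    parent = np.arange(n_nodes)
    csize = np.zeros(n_nodes, dtype=np.int64)  # edges per component root
    added = np.zeros(m, dtype=np.int64)
    n_added = 0
    ptr = 0
    for j in range(n_steps, 0, -1):
        h = dh * j
        while ptr < m and t[order[ptr]] >= h:
            e = order[ptr]
            u, v = eu[e], ev[e]
            ru = u
            while parent[ru] != ru:
                ru = parent[ru]
            rv = v
            while parent[rv] != rv:
                rv = parent[rv]
            if ru == rv:
                csize[ru] += 1
            else:
                if csize[ru] < csize[rv]:
                    ru, rv = rv, ru
                parent[rv] = ru
                csize[ru] += csize[rv] + 1
            added[n_added] = e
            n_added += 1
            ptr += 1
        if n_added == 0:
            continue
        inc = h ** h_pow * dh
        for a in range(n_added):
            e = added[a]
            r = eu[e]
            while parent[r] != r:
                r = parent[r]
            out[e] += csize[r] ** e_pow * inc
    return out


@njit(cache=True)
def _null_max_batch(T, eu, ev, n_nodes, h_pow, e_pow, n_steps):  # pragma: no cover
    B = T.shape[0]
    out = np.empty(B)
    for b in range(B):
        pos = _tfce_one_tail(T[b], eu, ev, n_nodes, h_pow, e_pow, n_steps)
        neg = _tfce_one_tail(-T[b], eu, ev, n_nodes, h_pow, e_pow, n_steps)
        best = 0.0
        for i in range(pos.shape[0]):
            if pos[i] > best:
                best = pos[i]
            if neg[i] > best:
                best = neg[i]
        out[b] = best
    return out


def _edge_endpoints(n_rois: int) -> tuple[np.ndarray, np.ndarray]:
    iu = np.triu_indices(n_rois, k=1)
    return iu[0].astype(np.int64), iu[1].astype(np.int64)


def tfce_scores(
    t_edges: np.ndarray,
    n_rois: int,
    h_pow: float = 2.0,
    e_pow: float = 0.5,
    n_steps: int = 100,
) -> dict[str, np.ndarray]:
    """Per-edge TFCE scores, one array per tail.

    The positive tail enhances t > 0, the negative tail -t > 0. Edge
    adjacency is the shared-endpoint rule on the ROI graph.
    """
    t = np.asarray(t_edges, float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite edge statistics")
    eu, ev = _edge_endpoints(n_rois)
    if t.shape[0] != eu.shape[0]:
        raise ValueError(
            f"expected {eu.shape[0]} edge statistics for {n_rois} ROIs, got {t.shape[0]}"
        )
    return {
        "pos": _tfce_one_tail(t, eu, ev, n_rois, h_pow, e_pow, n_steps),
        "neg": _tfce_one_tail(-t, eu, ev, n_rois, h_pow, e_pow, n_steps),
    }


def edge_fdr(t_edges: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided t p-values and Benjamini-Hochberg FDR across the edges."""
    t = np.asarray(t_edges, float)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return p, multipletests(p, method="fdr_bh")[1]


# -- permutation FWE ----------------------------------------------------------


def _group_label_matrix(
    rng: np.random.Generator, n_total: int, n_a: int, n_perm: int
) -> np.ndarray:
    """(n_perm, n_total) 0/1 indicator of membership in group A.

    Falls back to exhaustive enumeration when n_perm is at least the
    number of distinct relabelings.
    """
    from math import comb

    n_distinct = comb(n_total, n_a)
    if n_perm >= n_distinct:
        out = np.zeros((n_distinct, n_total))
        for i, idx in enumerate(combinations(range(n_total), n_a)):
            out[i, list(idx)] = 1.0
        return out
    out = np.zeros((n_perm, n_total))
    base = np.zeros(n_total)
    base[:n_a] = 1.0
    for b in range(n_perm):
        out[b] = rng.permutation(base)
    return out


class EdgeInteractionTest:
    """Permutation TFCE test of the group x time interaction on edge dFC.

    Parameters
    ----------
    n_perm : int
        Number of random group relabelings (exhaustive enumeration when it
        exceeds the number of distinct relabelings).
    seed : int
        Seed for the permutation stream (required for reproducibility).
    tfce_h, tfce_e : float
        TFCE height and extent exponents (defaults 2 and 0.5).
    n_steps : int
        Number of equal threshold increments from 0 to the max statistic.
    alpha : float
        FWE threshold defining significant edges / clusters.
    fdr_scope : {"all", "cluster"}
        Whether BH-FDR runs over all edges (default) or only cluster
        members.

    After :meth:`fit`: ``t_``, ``df_``, ``tfce_``, ``p_fwe_``, ``p_fdr_``,
    ``edge_stats_`` (per-edge table), ``clusters_`` (list of cluster
    dicts), ``null_max_`` (permutation null distribution).
    """

    def __init__(
        self,
        n_perm: int = 5000,
        seed: int = 0,
        tfce_h: float = 2.0,
        tfce_e: float = 0.5,
        n_steps: int = 100,
        alpha: float = 0.05,
        fdr_scope: str = "all",
    ):
        self.n_perm = n_perm
        self.seed = seed
        self.tfce_h = tfce_h
        self.tfce_e = tfce_e
        self.n_steps = n_steps
        self.alpha = alpha
        self.fdr_scope = fdr_scope

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_perm": self.n_perm,
            "seed": self.seed,
            "tfce_h": self.tfce_h,
            "tfce_e": self.tfce_e,
            "n_steps": self.n_steps,
            "alpha": self.alpha,
            "fdr_scope": self.fdr_scope,
        }

    def set_params(self, **params) -> "EdgeInteractionTest":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(
        self,
        delta_a: np.ndarray | pd.DataFrame,
        delta_b: np.ndarray | pd.DataFrame,
        roi_labels: Sequence[str] | None = None,
    ) -> "EdgeInteractionTest":
        """Fit from per-participant dFC matrices of the two groups.

        ``delta_a`` is the treated group (rows = participants, columns =
        canonical edges); negative t then means a greater connectivity
        decrease in the treated group.
        """
        if isinstance(delta_a, pd.DataFrame):
            if roi_labels is None and delta_a.columns.size:
                roi_labels = self._labels_from_columns(delta_a.columns)
            delta_a = delta_a.to_numpy(float)
        if isinstance(delta_b, pd.DataFrame):
            delta_b = delta_b.to_numpy(float)
        a = np.atleast_2d(np.asarray(delta_a, float))
        b = np.atleast_2d(np.asarray(delta_b, float))
        m = a.shape[1]
        n_rois = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if n_rois * (n_rois - 1) // 2 != m:
            raise ValueError(f"{m} columns is not a C(p,2) edge count")
        if roi_labels is None:
            roi_labels = [f"ROI{i:02d}" for i in range(n_rois)]
        self.roi_labels_ = tuple(roi_labels)
        self.edges_ = edge_list(self.roi_labels_)

        t, df = interaction_t(a, b)
        self.t_, self.df_ = t, df
        tails = tfce_scores(t, n_rois, self.tfce_h, self.tfce_e, self.n_steps)
        self.tfce_pos_, self.tfce_neg_ = tails["pos"], tails["neg"]
        self.tfce_ = np.where(t >= 0, tails["pos"], tails["neg"])

        # Null distribution: max TFCE over edges and both tails under
        # random group relabeling.
        x = np.vstack([a, b])
        n_total, n_a = x.shape[0], a.shape[0]
        rng = np.random.default_rng(self.seed)
        perms = _group_label_matrix(rng, n_total, n_a, self.n_perm)
        t_null = self._batch_t(x, perms, n_a)
        eu, ev = _edge_endpoints(n_rois)
        self.null_max_ = _null_max_batch(
            t_null, eu, ev, n_rois, self.tfce_h, self.tfce_e, self.n_steps
        )
        n_eff = len(self.null_max_)
        self.p_fwe_ = (1.0 + (self.null_max_[None, :] >= self.tfce_[:, None]).sum(axis=1)) / (
            1.0 + n_eff
        )

        p_raw, p_fdr = edge_fdr(t, df)
        self.p_raw_ = p_raw
        sig = self.p_fwe_ < self.alpha
        self.clusters_ = self._extract_clusters(sig)
        cluster_id = np.full(m, -1)
        for c in self.clusters_:
            cluster_id[c["member_idx"]] = c["cluster_id"]
        if self.fdr_scope == "cluster":
            p_fdr = np.full(m, np.nan)
            member = cluster_id >= 0
            if member.any():
                p_fdr[member] = multipletests(p_raw[member], method="fdr_bh")[1]
        self.p_fdr_ = p_fdr

        self.edge_stats_ = pd.DataFrame(
            {
                "roi_a": [e[0] for e in self.edges_],
                "roi_b": [e[1] for e in self.edges_],
                "t": t,
                "tfce": self.tfce_,
                "p_fwe": self.p_fwe_,
                "p_raw": p_raw,
                "p_fdr": p_fdr,
                "cluster_id": [int(c) if c >= 0 else pd.NA for c in cluster_id],
            }
        )
        return self

    @staticmethod
    def _labels_from_columns(columns) -> tuple[str, ...]:
        labels: list[str] = []
        for c in columns:
            for lab in str(c).split("--"):
                if lab not in labels:
                    labels.append(lab)
        return tuple(labels)

    @staticmethod
    def _batch_t(x: np.ndarray, perms: np.ndarray, n_a: int) -> np.ndarray:
        """Equal-variance two-sample t for every relabeling (vectorized)."""
        n, m = x.shape
        n_b = n - n_a
        df = n - 2
        s1 = perms @ x
        q1 = perms @ (x * x)
        st = x.sum(axis=0)
        qt = (x * x).sum(axis=0)
        m1 = s1 / n_a
        m2 = (st - s1) / n_b
        ss = (q1 - n_a * m1 * m1) + ((qt - q1) - n_b * m2 * m2)
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(ss / df * (1.0 / n_a + 1.0 / n_b))
            t = np.where(se > 0, (m1 - m2) / se, 0.0)
        return t

    def _extract_clusters(self, sig: np.ndarray) -> list[dict]:
        g = nx.Graph()
        for idx in np.flatnonzero(sig):
            g.add_edge(*self.edges_[idx], idx=idx)
        clusters = []
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            idx = np.array(sorted(d["idx"] for _, _, d in sub.edges(data=True)))
            clusters.append(
                {
                    "member_idx": idx,
                    "members": [self.edges_[i] for i in idx],
                    "cluster_tfce": float(self.tfce_[idx].max()),
                    "p_fwe": float(self.p_fwe_[idx].min()),
                }
            )
        clusters.sort(key=lambda c: -c["cluster_tfce"])
        for i, c in enumerate(clusters, start=1):
            c["cluster_id"] = i
        return clusters


def cluster_mean_fc(
    fcs: Mapping[tuple[str, str], FcMatrix],
    members: Sequence[tuple[str, str]],
    sessions: tuple[str, str] = ("T0", "T1"),
) -> pd.DataFrame:
    """Per-participant cluster-mean Fisher z at each session and its change.

    The cluster-level connectivity of a participant-session is the mean of
    the member edges' z values; dFC_cluster is the T1 - T0 difference.
    """
    rows = []
    participants = sorted({p for p, _ in fcs})
    for pid in participants:
        rec = {"participant": pid}
        vals = {}
        for s in sessions:
            fc = fcs[(pid, s)]
            rec["group"] = fc.group
            idx = {lab: i for i, lab in enumerate(fc.roi_labels)}
            vals[s] = float(
                np.mean([fc.z[idx[a], idx[b]] for a, b in members])
            )
            rec[f"fc_{s}"] = vals[s]
        rec["delta_fc"] = vals[sessions[1]] - vals[sessions[0]]
        rows.append(rec)
    return pd.DataFrame(rows)
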