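"""Graph-based pseudotime for a linear developmental lineage.

A deliberately simplified, deterministic take on ensemble-graph trajectory
detection (Wanderlust-style): build a k-NN graph on the arcsinh-transformed
trajectory markers, draw an ensemble of random l-of-k subgraphs, compute
shortest-path distances from a chosen start cell, refine each graph's
ordering with randomly placed waypoints by iterated weighted averaging, and
average the ensemble into a single pseudotime normalized to [0, 1]. Single
(non-branching) trajectories only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io_core import EventTable

__all__ = ["TrajectoryParams", "PseudotimeResult", "knn_graph", "pseudotime", "channel_trends"]


@dataclass
class TrajectoryParams:
    """Knobs of the pseudotime stage.

    ``channels`` are the trajectory-construction markers (transformed
    scale); ``k`` the neighborhood size; ``l`` the edges kept per node in
    each ensemble graph; ``n_graphs`` the ensemble size; ``start_rule``
    either an explicit event index or a callable mapping the event table to
    one (e.g. the most CD34-high, CD19-low cell of a B lineage).
    """

    channels: list[str] = field(default_factory=list)
    k: int = 30
    l: int = 25
    n_graphs: int = 20
    n_waypoints: int = 150
    start_rule: int | Callable[[EventTable], int] = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l > self.k:
            raise ValueError("l must be <= k")
        if self.n_waypoints < 2:
            raise ValueError("need at least 2 waypoints")


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray  # per event, in [0, 1]; start cell exactly 0
    start_index: int
    waypoints: np.ndarray
    convergence: list[list[float]]  # per-graph mean-absolute-change traces


def knn_graph(
    values: np.ndarray, k: int
) -> sp.csr_matrix:
    """Symmetric k-NN graph with Euclidean edge weights.

    Disconnected components are joined by their shortest bridging edge,
    with a warning, so shortest-path distances are always finite.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    rows = np.repeat(np.arange(n), k_eff)
    cols = idx[:, 1:].ravel()
    data = dist[:, 1:].ravel()
    g = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    g = g.maximum(g.T)

    n_comp, comp = connected_components(g, directed=False)
    if n_comp > 1:
        warnings.warn(f"k-NN graph has {n_comp} components; adding bridging edges", stacklevel=2)
        g = g.tolil()
        while n_comp > 1:
            a = np.flatnonzero(comp == comp[0])
            b = np.flatnonzero(comp != comp[0])
            d = cdist(x[a], x[b])
            i, j = np.unravel_index(np.argmin(d), d.shape)
            g[a[i], b[j]] = g[b[j], a[i]] = d[i, j]
            n_comp, comp = connected_components(g.tocsr(), directed=False)
        g = g.tocsr()
    return g


def _resolve_start(table: EventTable, params: TrajectoryParams) -> int:
    if callable(params.start_rule):
        start = params.start_rule(table)
        if start is None:
            raise ValueError("start_rule matched no event")
        return int(start)
    return int(params.start_rule)


def _refine(
    d_start: np.ndarray,
    d_way: np.ndarray,
    waypoints: np.ndarray,
    tol: float = 1e-3,
    max_iter: int = 20,
) -> tuple[np.ndarray, list[float]]:
    """Waypoint refinement: iterated weighted averaging of waypoint-relative
    distances. Weights fall off as a Gaussian of the graph distance to the
    waypoint (sigma = 20% of the trajectory span), so each cell's position
    is corrected mainly by nearby waypoints."""
    t = d_start.copy()
    scale = max(t.max(), 1e-12)
    sigma = 0.2 * scale
    weights = np.exp(-0.5 * (d_way / sigma) ** 2) + 1e-12
    weights /= weights.sum(axis=0, keepdims=True)
    trace: list[float] = []
    for _ in range(max_iter):
        t_way = t[waypoints]
        sign = np.where(t[None, :] >= t_way[:, None], 1.0, -1.0)
        proposal = (weights * (t_way[:, None] + sign * d_way)).sum(axis=0)
        change = float(np.abs(proposal - t).mean() / scale)
        t = proposal
        trace.append(change)
        if change < tol:
            break
    return t, trace


def pseudotime(table: EventTable, params: TrajectoryParams) -> PseudotimeResult:
    """Ensemble pseudotime from a start cell; deterministic given the seed.

    For each of ``n_graphs`` random l-of-k subgraphs, shortest-path
    distances from the start cell are refined against ``n_waypoints``
    random waypoints; the ensemble mean is min-max normalized to [0, 1]
    with the start cell pinned at 0.
    """
    channels = params.channels or table.channels_of_kind("phenotype")
    x = table.columns(channels)
    n = len(x)
    start = _resolve_start(table, params)
    if not 0 <= start < n:
        raise ValueError(f"start index {start} out of range")
    rng = np.random.default_rng(params.seed)

    k_eff = min(params.k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]

    n_wp = min(params.n_waypoints, n)
    waypoints = rng.choice(n, size=n_wp, replace=False)
    waypoints[0] = start

    traj = np.zeros(n)
    convergence = []
    l_eff = min(params.l, k_eff)
    for _ in range(params.n_graphs):
        keep = np.argsort(rng.random((n, k_eff)), axis=1)[:, :l_eff]
        rows = np.repeat(np.arange(n), l_eff)
        cols = np.take_along_axis(idx, keep, axis=1).ravel()
        data = np.take_along_axis(dist, keep, axis=1).ravel()
        g = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
        g = g.maximum(g.T)
        n_comp, comp = connected_components(g, directed=False)
        if n_comp > 1:
            g = _bridge(g, x, comp)
        d = dijkstra(g, directed=False, indices=waypoints)
        t, trace = _refine(d[0], d, waypoints)
        traj += t
        convergence.append(trace)

    traj /= params.n_graphs
    traj -= traj[start]
    np.maximum(traj, 0.0, out=traj)
    span = traj.max()
    if span > 0:
        traj /= span
    return PseudotimeResult(
        pseudotime=traj, start_index=start, waypoints=waypoints, convergence=convergence
    )


def _bridge(g: sp.csr_matrix, x: np.ndarray, comp: np.ndarray) -> sp.csr_matrix:
    g = g.tolil()
    n_comp = comp.max() + 1
    while n_comp > 1:
        a = np.flatnonzero(comp == comp[0])
        b = np.flatnonzero(comp != comp[0])
        d = cdist(x[a], x[b])
        i, j = np.unravel_index(np.argmin(d), d.shape)
        g[a[i], b[j]] = g[b[j], a[i]] = d[i, j]
        n_comp, comp = connected_components(g.tocsr(), directed=False)
    return g.tocsr()


def channel_trends(
    table: EventTable,
    result: PseudotimeResult,
    channels: Sequence[str],
    window: float = 0.05,
    n_points: int = 100,
) -> pd.DataFrame:
    """Sliding-window medians of channels along pseudotime.

    At ``n_points`` positions evenly spaced in pseudotime *rank*, the
    median of each channel over the ``window`` fraction of cells nearest in
    rank. The reported pseudotime of each position is the pseudotime value
    at that rank, so curves plot on the [0, 1] axis, while the medians
    depend only on the ordering — they commute with any strictly monotone
    relabeling of pseudotime.
    """
    if not 0 < window <= 1:
        raise ValueError("window must be in (0, 1]")
    t = result.pseudotime
    order = np.argsort(t, kind="stable")
    sorted_t = t[order]
    n = len(t)
    w = max(1, int(round(window * n)))
    centers = np.round(np.linspace(0, n - 1, n_points)).astype(int)
    out = {"pseudotime": sorted_t[centers]}
    values = table.columns(list(channels))[order]
    for pos_j, ch in enumerate(channels):
        col = np.empty(n_points)
        for i, c in enumerate(centers):
            lo = min(max(0, c - w // 2), n - w)
            col[i] = np.median(values[lo : lo + w, pos_j])
        out[str(ch)] = col
    return pd.DataFrame(out)
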