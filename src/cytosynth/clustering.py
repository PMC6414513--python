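"""SPADE-style phenotype clustering.

Density-dependent downsampling (so rare populations survive), average-linkage
agglomeration of the retained events to a target node count, a minimum
spanning tree over the node medians, and upsampling of every event to its
nearest node. Clustering runs on arcsinh-transformed phenotype channels
only; biosynthesis and signaling channels are held out for per-node
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import brentq
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

from .io_core import EventTable

__all__ = [
    "SpadeParams",
    "ClusterGraph",
    "local_density",
    "density_downsample",
    "agglomerate",
    "build_mst",
    "upsample",
    "annotate",
    "spade",
    "AnnotationRule",
]


@dataclass
class SpadeParams:
    """Parameters of the clustering stage.

    ``downsample_target`` is the expected fraction of events retained
    (default 15%); ``n_nodes`` the target cluster count (150 for blood,
    175 for marrow in the study settings); ``density_k`` the neighbor rank
    used for the k-NN density estimate.
    """

    clustering_channels: list[str] = field(default_factory=list)
    downsample_target: float = 0.15
    n_nodes: int = 150
    density_k: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.downsample_target <= 1:
            raise ValueError("downsample_target must be in (0, 1]")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.density_k < 1:
            raise ValueError("density_k must be at least 1")


@dataclass
class ClusterGraph:
    """Cluster medians, MST edges and the full event-to-node assignment."""

    node_medians: pd.DataFrame  # n_nodes x channels, transformed scale
    mst_edges: list[tuple[int, int, float]]
    assignment: np.ndarray  # event index -> node index
    annotations: list[str] | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_medians)

    def nodes_of(self, population: str) -> list[int]:
        if self.annotations is None:
            raise ValueError("graph has no annotations")
        return [i for i, a in enumerate(self.annotations) if a == population]

    def events_of(self, population: str) -> np.ndarray:
        """Boolean mask over events pooled across same-annotation nodes."""
        nodes = set(self.nodes_of(population))
        return np.isin(self.assignment, list(nodes))

    def to_dict(self) -> dict:
        return {
            "channels": list(self.node_medians.columns),
            "node_medians": self.node_medians.to_numpy().tolist(),
            "mst_edges": [[int(a), int(b), float(w)] for a, b, w in self.mst_edges],
            "assignment": self.assignment.astype(int).tolist(),
            "annotations": self.annotations,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ClusterGraph":
        return cls(
            node_medians=pd.DataFrame(doc["node_medians"], columns=doc["channels"]),
            mst_edges=[(int(a), int(b), float(w)) for a, b, w in doc["mst_edges"]],
            assignment=np.asarray(doc["assignment"], dtype=int),
            annotations=doc.get("annotations"),
        )


# ---------------------------------------------------------------------------
# stages


def local_density(
    table_or_values: EventTable | np.ndarray,
    channels: Sequence[str] | None = None,
    k: int = 15,
) -> np.ndarray:
    """k-NN density score per event: 1 / distance to the k-th neighbor.

    Only the ordering of the scores matters downstream; a distance floor
    keeps duplicated points and singleton tables finite.
    """
    x = _as_matrix(table_or_values, channels)
    n = len(x)
    k_eff = min(k, n - 1)
    if k_eff < 1:
        return np.ones(n)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    dk = dist[:, -1]
    floor = max(dk[dk > 0].min() if (dk > 0).any() else 1.0, 1e-12) * 1e-6
    return 1.0 / np.maximum(dk, floor)


def density_downsample(
    density: np.ndarray, target: float, seed: int = 0
) -> np.ndarray:
    """Density-dependent downsample; returns a boolean keep mask.

    Event i is kept with probability min(1, TD / density_i), with TD chosen
    by bisection so that the expected kept fraction equals ``target``. Dense
    regions are thinned while rare, low-density events are retained at a
    rate at least as high.
    """
    density = np.asarray(density, dtype=float)
    if not 0 < target <= 1:
        raise ValueError("target must be in (0, 1]")
    n = len(density)
    if target == 1.0:
        return np.ones(n, dtype=bool)

    def kept_fraction(td: float) -> float:
        return float(np.minimum(1.0, td / density).mean())

    lo, hi = 0.0, float(density.max())
    td = brentq(lambda t: kept_fraction(t) - target, lo, hi, xtol=1e-12 * hi)
    p = np.minimum(1.0, td / density)
    rng = np.random.default_rng(seed)
    return rng.random(n) < p


def agglomerate(
    table_or_values: EventTable | np.ndarray,
    channels: Sequence[str] | None = None,
    n_nodes: int = 150,
) -> np.ndarray:
    """Average-linkage agglomeration cut at ``n_nodes`` clusters.

    Deterministic given the input order. Returns 0-based cluster labels.
    """
    x = _as_matrix(table_or_values, channels)
    n = len(x)
    if n_nodes >= n:
        return np.arange(n)
    z = linkage(x, method="average", metric="euclidean")
    return fcluster(z, t=n_nodes, criterion="maxclust") - 1


def build_mst(node_medians: np.ndarray | pd.DataFrame) -> list[tuple[int, int, float]]:
    """Minimum spanning tree on Euclidean distances among node medians."""
    x = np.asarray(node_medians, dtype=float)
    d = cdist(x, x)
    mst = minimum_spanning_tree(d).tocoo()
    edges = sorted(
        (int(min(i, j)), int(max(i, j)), float(w))
        for i, j, w in zip(mst.row, mst.col, mst.data)
    )
    return edges


def upsample(
    table_or_values: EventTable | np.ndarray,
    node_medians: np.ndarray | pd.DataFrame,
    channels: Sequence[str] | None = None,
) -> np.ndarray:
    """Assign every event to the node with the nearest median.

    Ties go to the lowest node index.
    """
    x = _as_matrix(table_or_values, channels)
    med = np.asarray(node_medians, dtype=float)
    if isinstance(node_medians, pd.DataFrame) and channels is not None:
        med = node_medians[list(channels)].to_numpy()
    out = np.empty(len(x), dtype=int)
    chunk = 200_000
    for lo in range(0, len(x), chunk):
        d = cdist(x[lo : lo + chunk], med)
        out[lo : lo + chunk] = np.argmin(d, axis=1)  # argmin takes lowest index on ties
    return out


@dataclass(frozen=True)
class AnnotationRule:
    """First-match population call on node medians (transformed scale)."""

    name: str
    high: tuple[str, ...] = ()
    low: tuple[str, ...] = ()
    threshold: float = 2.5

    def matches(self, medians: pd.Series) -> bool:
        return all(medians[c] > self.threshold for c in self.high) and all(
            medians[c] <= self.threshold for c in self.low
        )


def annotate(graph: ClusterGraph, rules: Sequence[AnnotationRule]) -> ClusterGraph:
    """Name each node by the first matching rule; unmatched nodes stay
    "unassigned". Rule order is the tie-break: earlier rules win."""
    annotations = []
    for _, med in graph.node_medians.iterrows():
        name = "unassigned"
        for rule in rules:
            if rule.matches(med):
                name = rule.name
                break
        annotations.append(name)
    graph.annotations = annotations
    return graph


def spade(
    table: EventTable,
    params: SpadeParams,
    rules: Sequence[AnnotationRule] | None = None,
) -> ClusterGraph:
    """Full clustering stage on an arcsinh-transformed event table.

    Density estimation and downsampling, agglomeration of the retained
    events, node medians over all channels, MST construction, and
    upsampling of every event; optionally annotates nodes.
    """
    channels = params.clustering_channels or table.channels_of_kind("phenotype")
    missing = set(channels) - set(table.transformed_channels)
    if missing:
        raise ValueError(f"clustering channels must be arcsinh-transformed: {sorted(missing)}")
    density = local_density(table, channels, k=params.density_k)
    keep = density_downsample(density, params.downsample_target, seed=params.seed)
    sub = table.values[keep][:, [table.index_of(c) for c in channels]]
    labels = agglomerate(sub, n_nodes=params.n_nodes)

    n_nodes = labels.max() + 1
    kept_idx = np.flatnonzero(keep)
    med = np.empty((n_nodes, table.n_channels))
    for node in range(n_nodes):
        med[node] = np.median(table.values[kept_idx[labels == node]], axis=0)
    node_medians = pd.DataFrame(med, columns=table.channel_names)

    assignment = upsample(table, node_medians, channels)
    graph = ClusterGraph(
        node_medians=node_medians,
        mst_edges=build_mst(node_medians[channels]),
        assignment=assignment,
    )
    if rules is not None:
        annotate(graph, rules)
    return graph


def _as_matrix(
    table_or_values: EventTable | np.ndarray, channels: Sequence[str] | None
) -> np.ndarray:
    if isinstance(table_or_values, EventTable):
        if channels is None:
            channels = table_or_values.channel_names
        return table_or_values.columns(list(channels))
    return np.asarray(table_or_values, dtype=float)
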