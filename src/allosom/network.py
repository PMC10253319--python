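"""Displacement cross-correlation networks: DCCM, communities, suboptimal paths.

The dynamic cross-correlation matrix (DCCM) between Cα sites i and j over a
fitted trajectory is

    c_ij = <Δr_i · Δr_j> / sqrt(<|Δr_i|²> <|Δr_j|²>)

with Δr the displacement from the site's mean position. Values near +1 mean
concerted motion, near −1 anti-phase motion.

The residue network keeps an edge for every pair with |c_ij| above a cutoff
(default 0.5) and assigns it the path weight w = −log|c_ij|, so that a
shortest path accumulates the strongest chain of couplings; raw |c| weights
are selectable. Communities come from Walktrap random-walk agglomeration
(walk length 4) cut at maximum modularity; suboptimal paths from Yen's
k-shortest-paths pooled over all source×sink residue pairs.
"""

from __future__ import annotations

import dataclasses
import heapq
from itertools import islice
from pathlib import Path
from typing import Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .geometry import iterative_fit
from .structure import AtomSet, Ensemble

DEFAULT_CUTOFF = 0.5  # |c| threshold for network edges
DEFAULT_K_PATHS = 50  # suboptimal paths retained
WALK_LENGTH = 4  # Walktrap random-walk steps


@dataclasses.dataclass
class CorrelationMatrix:
    """Symmetric per-residue displacement correlation matrix."""

    values: np.ndarray  # (N, N) in [-1, 1], unit diagonal
    labels: list[str]  # chain:resid per site

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.labels):
            raise ValueError("matrix/label shape mismatch")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.any(np.abs(self.values) > 1 + 1e-8):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n_sites(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), list(df.columns))


@dataclasses.dataclass
class Partition:
    """Community assignment: node label -> contiguous community id (from 1)."""

    membership: dict[str, int]
    modularity: float

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set[str]]:
        groups: dict[int, set[str]] = {}
        for node, cid in self.membership.items():
            groups.setdefault(cid, set()).add(node)
        return [groups[c] for c in sorted(groups)]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"residue": list(self.membership), "community": list(self.membership.values())}
        ).to_csv(path, index=False)


@dataclasses.dataclass
class PathEnsemble:
    """k shortest simple paths between source and sink residue sets."""

    paths: list[list[str]]
    weights: list[float]
    sources: list[str]
    sinks: list[str]
    node_usage: dict[str, int]
    status: str = "ok"  # "ok" | "disconnected"

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "sources": self.sources,
            "sinks": self.sinks,
            "paths": [
                {"nodes": p, "weight": w} for p, w in zip(self.paths, self.weights)
            ],
            "node_usage": self.node_usage,
        }


# ---------------------------------------------------------------------------
# DCCM


def compute_dccm(ensemble: Ensemble, atom_set: AtomSet, fit: bool = True) -> CorrelationMatrix:
    """Cα displacement cross-correlation matrix over a fitted trajectory.

    The selected coordinates are iteratively superposed on their mean (unless
    ``fit=False``, for pre-fitted input), displacements are taken from the
    mean position, and the normalized 3D-vector covariance is returned. A
    site that never moves has an undefined correlation and is reported as an
    error naming the frozen residue.
    """
    ensemble.require_frames(2)
    coords = ensemble.coords[:, atom_set.indices, :]
    if fit:
        coords = iterative_fit(coords)
    disp = coords - coords.mean(axis=0)
    # <Δr_i · Δr_j> over frames
    inner = np.einsum("fia,fja->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner)
    labels = ensemble.structure.residue_labels(atom_set.indices)
    frozen = np.flatnonzero(var <= 1e-12)  # RMS fluctuation below 1e-6 Å
    if len(frozen):
        raise ValueError(f"zero-variance site(s): {[labels[i] for i in frozen]}")
    denom = np.sqrt(np.outer(var, var))
    values = np.clip(inner / denom, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return CorrelationMatrix(values, labels)


def average_dccm(matrices: Sequence[CorrelationMatrix]) -> CorrelationMatrix:
    """Element-wise mean of per-replica DCCMs (diagonal reset to exactly 1)."""
    if not matrices:
        raise ValueError("nothing to average")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels or m.values.shape != matrices[0].values.shape:
            raise ValueError("matrices have mismatching labels or shape")
    mean = np.mean([m.values for m in matrices], axis=0)
    np.fill_diagonal(mean, 1.0)
    return CorrelationMatrix(mean, list(labels))


# ---------------------------------------------------------------------------
# network construction


def build_network(
    matrix: CorrelationMatrix,
    cutoff: float = DEFAULT_CUTOFF,
    scheme: str = "neglog",
) -> nx.Graph:
    """Correlation-weighted residue graph.

    An edge exists for every pair with |c_ij| > cutoff. Edge attributes:
    ``correlation`` (signed c_ij), ``abs_corr`` (|c_ij|) and ``weight`` (the
    path weight: −log|c| under the default scheme, 1−|c| under ``"linear"``,
    or |c| itself under ``"raw"`` — note raw weights invert shortest-path
    semantics and exist for comparison only).
    """
    if not (0 <= cutoff < 1):
        raise ValueError("cutoff must lie in [0, 1)")
    if scheme not in ("neglog", "linear", "raw"):
        raise ValueError(f"unknown weight scheme {scheme!r}")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.labels)
    n = matrix.n_sites
    for i in range(n):
        for j in range(i + 1, n):
            c = matrix.values[i, j]
            a = abs(c)
            if a > cutoff:
                if scheme == "neglog":
                    w = -np.log(a)
                elif scheme == "linear":
                    w = 1.0 - a
                else:
                    w = a
                graph.add_edge(
                    matrix.labels[i], matrix.labels[j],
                    correlation=float(c), abs_corr=float(a), weight=float(w),
                )
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, **d} for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# communities & modularity


def modularity(graph: nx.Graph, membership: dict[str, int], weight: str = "abs_corr") -> float:
    """Weighted Newman modularity Q = Σ_c (e_cc/m − (d_c/2m)²).

    ``membership`` must cover every node of the graph; |c|-weights by default.
    """
    missing = set(graph.nodes) - set(membership)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    two_m = sum(d.get(weight, 1.0) for _, _, d in graph.edges(data=True)) * 2.0
    if two_m == 0:
        return 0.0
    intra: dict[int, float] = {}
    degree: dict[int, float] = {}
    for u, v, d in graph.edges(data=True):
        w = d.get(weight, 1.0)
        cu, cv = membership[u], membership[v]
        degree[cu] = degree.get(cu, 0.0) + w
        degree[cv] = degree.get(cv, 0.0) + w
        if cu == cv:
            intra[cu] = intra.get(cu, 0.0) + w
    q = 0.0
    for c in set(membership.values()):
        q += intra.get(c, 0.0) / (two_m / 2.0) - (degree.get(c, 0.0) / two_m) ** 2
    return q


def detect_communities(graph: nx.Graph, seed: int = 0) -> Partition:
    """Walktrap community detection (random-walk agglomeration, walk length 4).

    The merge sequence is cut at maximum modularity on the |c|-weighted
    graph. Walktrap itself is deterministic; ``seed`` is accepted for
    interface symmetry with the stochastic stages. Isolated nodes become
    singleton communities.
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        raise ValueError("empty network")
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [graph.edges[u, v].get("abs_corr", 1.0) for u, v in graph.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    if edges:
        dendrogram = g.community_walktrap(weights=weights, steps=WALK_LENGTH)
        clustering = dendrogram.as_clustering()  # cut at max modularity
        raw_membership = clustering.membership
    else:
        raw_membership = list(range(len(nodes)))
    # contiguous ids from 1, ordered by first appearance over sorted nodes
    remap: dict[int, int] = {}
    membership: dict[str, int] = {}
    for node in nodes:
        cid = raw_membership[index[node]]
        if cid not in remap:
            remap[cid] = len(remap) + 1
        membership[node] = remap[cid]
    return Partition(membership, modularity(graph, membership))


# ---------------------------------------------------------------------------
# suboptimal paths


def suboptimal_paths(
    graph: nx.Graph,
    sources: Sequence[str],
    sinks: Sequence[str],
    k: int = DEFAULT_K_PATHS,
) -> PathEnsemble:
    """The k globally shortest simple paths pooled over all source–sink pairs.

    Yen's algorithm (``networkx.shortest_simple_paths``) enumerates paths per
    pair in order of total path weight; a global merge keeps the k shortest
    over all pairs. Per-node usage counts over the retained ensemble indicate
    communication bottlenecks.
    """
    sources = list(dict.fromkeys(sources))
    sinks = list(dict.fromkeys(sinks))
    if not sources or not sinks:
        raise ValueError("sources and sinks must be non-empty")
    if set(sources) & set(sinks):
        raise ValueError("sources and sinks must be disjoint")
    if k < 1:
        raise ValueError("k must be positive")

    def path_weight(p: list[str]) -> float:
        return sum(graph.edges[u, v]["weight"] for u, v in zip(p, p[1:]))

    # lazily merge the per-pair ordered generators with a heap
    heap: list[tuple[float, int, list[str], object]] = []
    counter = 0
    for s in sources:
        for t in sinks:
            if s not in graph or t not in graph:
                continue
            try:
                gen = nx.shortest_simple_paths(graph, s, t, weight="weight")
                first = next(gen)
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                continue
            heapq.heappush(heap, (path_weight(first), counter, first, gen))
            counter += 1
    paths: list[list[str]] = []
    weights: list[float] = []
    seen: set[tuple[str, ...]] = set()
    while heap and len(paths) < k:
        w, _, p, gen = heapq.heappop(heap)
        key = tuple(p)
        if key not in seen:
            seen.add(key)
            paths.append(p)
            weights.append(w)
        try:
            nxt = next(gen)
        except StopIteration:
            continue
        counter += 1
        heapq.heappush(heap, (path_weight(nxt), counter, nxt, gen))
    if not paths:
        return PathEnsemble([], [], sources, sinks, {}, status="disconnected")
    usage: dict[str, int] = {}
    for p in paths:
        for node in p:
            usage[node] = usage.get(node, 0) + 1
    return PathEnsemble(paths, weights, sources, sinks, usage)
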