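"""Toroidal hexagonal self-organizing map for conformational-state analysis.

A SOM tiles the feature space (here: frames × D interface distances, Å) with
a small grid of codebook vectors. On a toroidal hexagonal lattice every
neuron has six equivalent neighbours and no map border, so state clusters
are not distorted by edge effects. Training is the deterministic *batch*
variant: each epoch assigns every input vector to its best-matching unit
(BMU) and moves every codebook to the neighbourhood-weighted mean of the
data, with a Gaussian neighbourhood kernel over toroidal lattice distance
whose width σ decays linearly from half the maximal lattice distance to 0.5.

After training the neurons themselves are grouped by complete-linkage
hierarchical clustering with the cluster count chosen by silhouette scan,
and per-neuron occupancy split by condition exposes map regions visited
(almost) exclusively by one simulation condition.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.metrics import silhouette_samples


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """SOM lattice geometry. Default: 10×10 toroidal hexagonal."""

    rows: int = 10
    cols: int = 10
    toroidal: bool = True

    def __post_init__(self) -> None:
        if self.rows < 2 or self.cols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.toroidal and self.rows % 2:
            raise ValueError("a toroidal hexagonal lattice needs an even row count")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def positions(self) -> np.ndarray:
        """Hex-offset neuron centers, unit spacing: odd rows shifted by 1/2."""
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        x = c + 0.5 * (r % 2)
        y = r * (np.sqrt(3.0) / 2.0)
        return np.column_stack((x, y))

    def rc(self, index: int) -> tuple[int, int]:
        return divmod(int(index), self.cols)

    def index(self, row: int, col: int) -> int:
        return (row % self.rows) * self.cols + (col % self.cols)


def lattice_distance(grid: GridSpec, a: int, b: int) -> float:
    """Euclidean distance between hex neuron centers, wrapped on the torus.

    When toroidal, the minimum over the 9 periodic images is taken (x period
    = cols, y period = rows·√3/2).
    """
    return float(lattice_distance_matrix(grid)[a, b])


def lattice_distance_matrix(grid: GridSpec) -> np.ndarray:
    pos = grid.positions()
    delta = pos[:, None, :] - pos[None, :, :]
    if not grid.toroidal:
        return np.sqrt((delta**2).sum(axis=-1))
    px = float(grid.cols)
    py = grid.rows * np.sqrt(3.0) / 2.0
    best = np.full(delta.shape[:2], np.inf)
    for ix in (-1, 0, 1):
        for iy in (-1, 0, 1):
            shifted = delta + np.array([ix * px, iy * py])
            best = np.minimum(best, (shifted**2).sum(axis=-1))
    return np.sqrt(best)


@dataclasses.dataclass
class SOMModel:
    grid: GridSpec
    codebook: np.ndarray  # (neurons, D), Å
    epochs: int
    seed: int
    sigma_schedule: np.ndarray  # per-epoch neighbourhood width
    quantization_errors: np.ndarray  # per-epoch mean distance to BMU

    def to_json(self, path: str | Path) -> None:
        payload = {
            "grid": dataclasses.asdict(self.grid),
            "codebook": self.codebook.tolist(),
            "epochs": self.epochs,
            "seed": self.seed,
            "sigma_schedule": self.sigma_schedule.tolist(),
            "quantization_errors": self.quantization_errors.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            grid=GridSpec(**payload["grid"]),
            codebook=np.array(payload["codebook"]),
            epochs=payload["epochs"],
            seed=payload["seed"],
            sigma_schedule=np.array(payload["sigma_schedule"]),
            quantization_errors=np.array(payload["quantization_errors"]),
        )


@dataclasses.dataclass
class NeuronClustering:
    assignment: np.ndarray  # neuron -> cluster id, contiguous from 1
    silhouette_by_k: dict[int, float]
    chosen_k: int
    linkage_matrix: np.ndarray


@dataclasses.dataclass
class NeuronMaps:
    """Per-neuron occupancy by condition and per-neuron feature means."""

    counts: pd.DataFrame  # index: neuron, columns: condition labels
    feature_means: pd.DataFrame  # index: neuron, columns: feature names (NaN if empty)
    contrast: pd.Series  # per-feature exclusivity contrast score
    exclusive_neurons: dict[str, np.ndarray]  # condition -> neuron indices

    @property
    def total_counts(self) -> pd.Series:
        return self.counts.sum(axis=1)


def train_som(
    features: np.ndarray,
    grid: GridSpec = GridSpec(),
    epochs: int = 100,
    seed: int = 0,
    sigma: tuple[float, float] | None = None,
) -> SOMModel:
    """Batch-train a SOM on a frames × D feature matrix.

    Codebooks are initialized from seeded random draws of input rows. Each
    epoch: BMU assignment (ties break to the lowest neuron index), then each
    codebook moves to the Gaussian-neighbourhood-weighted mean of all inputs,
    the kernel exp(−d²/2σ²) taken over toroidal lattice distance. σ decays
    linearly from half the maximal lattice distance to 0.5; ``sigma`` can
    override the schedule endpoints (equal values hold σ constant).
    Deterministic for a fixed seed and input order.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("features must be a non-empty frames x D matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain NaN or infinite values")
    n_frames, d = X.shape
    m = grid.n_neurons
    rng = np.random.default_rng(seed)
    if n_frames >= m:
        init_idx = rng.choice(n_frames, size=m, replace=False)
    else:
        init_idx = rng.choice(n_frames, size=m, replace=True)
    codebook = X[init_idx].copy()
    lat = lattice_distance_matrix(grid)
    sigma_start, sigma_end = sigma if sigma is not None else (lat.max() / 2.0, 0.5)
    sigmas = np.linspace(sigma_start, sigma_end, max(2, epochs))[:epochs]
    qe = np.empty(epochs)
    for e in range(epochs):
        d2 = cdist(X, codebook, "sqeuclidean")
        bmu = np.argmin(d2, axis=1)  # argmin takes the lowest index on ties
        qe[e] = float(np.sqrt(d2[np.arange(n_frames), bmu]).mean())
        h = np.exp(-(lat**2) / (2.0 * sigmas[e] ** 2))  # (m, m)
        # accumulate per-BMU sums, then spread through the neighbourhood kernel
        sums = np.zeros((m, d))
        np.add.at(sums, bmu, X)
        counts = np.bincount(bmu, minlength=m).astype(float)
        num = h @ sums
        den = h @ counts
        codebook = num / den[:, None]
    return SOMModel(grid, codebook, epochs, seed, sigmas, qe)


def assign_bmu(model: SOMModel, vectors: np.ndarray) -> np.ndarray:
    """Best-matching-unit index per input vector (ties -> lowest index)."""
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    if V.shape[1] != model.codebook.shape[1]:
        raise ValueError(
            f"vector dimension {V.shape[1]} does not match codebook "
            f"dimension {model.codebook.shape[1]}"
        )
    return np.argmin(cdist(V, model.codebook, "sqeuclidean"), axis=1)


def quantization_error(model: SOMModel, vectors: np.ndarray) -> float:
    V = np.atleast_2d(np.asarray(vectors, dtype=float))
    d = cdist(V, model.codebook)
    return float(d.min(axis=1).mean())


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette with singleton clusters scoring 0 by convention."""
    return float(silhouette_samples(points, labels).mean())


def cluster_neurons(model: SOMModel, k_range: range | tuple[int, int] = (2, 15)) -> NeuronClustering:
    """Complete-linkage clustering of the codebook with silhouette k-scan.

    Silhouettes are computed on the codebook vectors (neurons as points).
    Chosen k maximizes the mean silhouette; ties break to the smallest k.
    """
    if isinstance(k_range, tuple):
        k_range = range(k_range[0], k_range[1] + 1)
    m = model.grid.n_neurons
    if k_range.start < 2 or max(k_range) > m - 1:
        raise ValueError(f"k range must lie within [2, {m - 1}]")
    if np.allclose(np.ptp(model.codebook, axis=0), 0):
        raise ValueError("degenerate codebook: all neurons identical")
    Z = linkage(model.codebook, method="complete", metric="euclidean")
    scores: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in k_range:
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = mean_silhouette(model.codebook, labels)
        assignments[k] = labels
    if not scores:
        raise ValueError("no k in range produced at least 2 clusters")
    best = max(scores.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    labels = assignments[best]
    # contiguous ids from 1 in order of first appearance
    remap: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return NeuronClustering(out, scores, best, Z)


def neuron_statistics(
    model: SOMModel,
    bmu_indices: np.ndarray,
    labels: np.ndarray,
    features: np.ndarray,
    feature_names: list[str] | None = None,
    exclusive_share: float = 0.9,
    min_frames: int = 10,
) -> NeuronMaps:
    """Per-neuron occupancy by condition, feature means, and contrast scores.

    A neuron is *exclusive* to a condition when that condition holds at least
    ``exclusive_share`` of its occupancy and it was visited by at least
    ``min_frames`` frames. The contrast score of a feature is the absolute
    difference of its mean over frames in one condition's exclusive neurons
    versus the other's; ranking by contrast surfaces the features that
    discriminate the two conditions on the map.
    """
    bmu_indices = np.asarray(bmu_indices)
    labels = np.asarray(labels)
    X = np.asarray(features, dtype=float)
    if not (len(bmu_indices) == len(labels) == X.shape[0]):
        raise ValueError("bmu_indices, labels and features must be aligned")
    conditions = sorted(set(labels.tolist()))
    m = model.grid.n_neurons
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    counts = pd.DataFrame(0, index=range(m), columns=conditions, dtype=int)
    for cond in conditions:
        binned = np.bincount(bmu_indices[labels == cond], minlength=m)
        counts[cond] = binned
    sums = np.zeros((m, X.shape[1]))
    np.add.at(sums, bmu_indices, X)
    total = counts.sum(axis=1).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / total[:, None]
    means[total == 0] = np.nan
    feature_means = pd.DataFrame(means, index=range(m), columns=feature_names)

    exclusive: dict[str, np.ndarray] = {}
    share = counts.to_numpy(dtype=float) / np.where(total == 0, 1.0, total)[:, None]
    for ci, cond in enumerate(conditions):
        mask = (share[:, ci] >= exclusive_share) & (total >= min_frames)
        exclusive[cond] = np.flatnonzero(mask)

    if len(conditions) == 2 and all(len(v) for v in exclusive.values()):
        c0, c1 = conditions
        in0 = np.isin(bmu_indices, exclusive[c0])
        in1 = np.isin(bmu_indices, exclusive[c1])
        contrast = pd.Series(
            np.abs(X[in0].mean(axis=0) - X[in1].mean(axis=0)), index=feature_names
        )
    else:
        contrast = pd.Series(np.zeros(X.shape[1]), index=feature_names)
    return NeuronMaps(counts, feature_means, contrast, exclusive)


def unroll_torus(model: SOMModel, maps: NeuronMaps) -> pd.DataFrame:
    """Cyclically re-center the toroidal grid for display.

    The most populated neuron (ties -> lowest index) is shifted to the grid
    center (rows//2, cols//2); rows and columns shift cyclically so lattice
    adjacency is unchanged. Returns a frame: neuron, display_row, display_col.
    """
    grid = model.grid
    totals = maps.total_counts.to_numpy()
    peak = int(np.argmax(totals))  # lowest index on ties
    pr, pc = grid.rc(peak)
    target_r, target_c = grid.rows // 2, grid.cols // 2
    # shifting odd-row-offset hex lattices by an odd row count would change
    # neighbour parity; restrict the row shift to even amounts
    dr = (target_r - pr) % grid.rows
    if dr % 2:
        dr = (dr + 1) % grid.rows
    dc = (target_c - pc) % grid.cols
    rows = []
    for n in range(grid.n_neurons):
        r, c = grid.rc(n)
        rows.append(
            {
                "neuron": n,
                "display_row": (r + dr) % grid.rows,
                "display_col": (c + dc) % grid.cols,
            }
        )
    return pd.DataFrame(rows)
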