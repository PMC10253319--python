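"""Synthetic ensembles with planted, known structure for pipeline validation.

Three generators emulate the statistical features of comparative MD
ensembles without any physics:

* :func:`block_correlated_ensemble` — Cα-like sites whose displacements are
  drawn from a zero-mean Gaussian with block-structured correlation
  (correlated "domains" against an uncorrelated background), the input the
  DCCM and network stages assume.
* :func:`domain_shift_ensemble` — a static scaffold plus a mobile subdomain
  that rotates progressively in the "apo-like" condition only, emulating a
  subdomain reorientation seen in one condition; drives RMSD and PCA checks.
* :func:`two_condition_distances` — D Gaussian distance features in which a
  small planted subset differs in mean between conditions, the ground truth
  for SOM discrimination; emits a paired point-particle ensemble whose
  endpoint distances realize the matrix exactly, so the distance-extraction
  stage can be tested end-to-end.

Every generator is deterministic under a fixed seed and records its ground
truth in the returned object's ``meta`` (or alongside it).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .distances import DistanceDefinition, DistanceSet, EndpointSpec
from .structure import DomainMap, Ensemble, StructureModel
from .radii import radii_for_elements


def _ca_structure(n_sites: int, chain: str = "A", spacing: float = 5.0) -> StructureModel:
    """One Cα pseudo-atom per site on a loose 3D helix (no steric overlap)."""
    t = np.arange(n_sites, dtype=float)
    coords = np.column_stack(
        (8.0 * np.cos(t / 3.0), 8.0 * np.sin(t / 3.0), spacing * t / 3.0)
    )
    elements = np.full(n_sites, "C")
    return StructureModel(
        atom_names=np.full(n_sites, "CA"),
        elements=elements,
        chain_ids=np.full(n_sites, chain),
        res_ids=np.arange(1, n_sites + 1),
        res_names=np.full(n_sites, "ALA"),
        coords=coords,
        radii=radii_for_elements(elements),
    )


# ---------------------------------------------------------------------------
# block-correlated fluctuations


@dataclasses.dataclass
class BlockSpec:
    """Block correlation structure for Gaussian site displacements."""

    blocks: list[int]  # sites per block
    rho: float = 0.8  # intra-block displacement correlation
    inter_rho: float = 0.0  # correlation between different blocks
    sigma: float = 1.0  # per-site fluctuation, Å
    frames: int = 2000
    seed: int = 0
    dt_ps: float = 100.0

    def __post_init__(self) -> None:
        if not self.blocks or any(b < 1 for b in self.blocks):
            raise ValueError("blocks must be non-empty positive site counts")
        if abs(self.rho) > 1 or abs(self.inter_rho) > 1:
            raise ValueError("correlations must lie in [-1, 1]")
        if self.frames < 10:
            raise ValueError("at least 10 frames required")

    @property
    def n_sites(self) -> int:
        return sum(self.blocks)

    def correlation_matrix(self) -> np.ndarray:
        """The ground-truth site correlation matrix implied by the spec."""
        n = self.n_sites
        corr = np.full((n, n), self.inter_rho)
        start = 0
        for b in self.blocks:
            corr[start : start + b, start : start + b] = self.rho
            start += b
        np.fill_diagonal(corr, 1.0)
        return corr


def block_correlated_ensemble(spec: BlockSpec) -> Ensemble:
    """Gaussian site displacements with the requested block correlation.

    Each Cartesian component is drawn independently from N(0, σ²·C) with C
    the block correlation matrix, so the 3D-vector DCCM of the output equals
    C in expectation. A non-positive-semidefinite request is an error.
    """
    corr = spec.correlation_matrix()
    evals = np.linalg.eigvalsh(corr)
    if evals.min() < -1e-10:
        raise ValueError("requested block correlation matrix is not PSD")
    # PSD square root (eigh; tolerant of semi-definite rho=1 blocks)
    w, V = np.linalg.eigh(corr)
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    rng = np.random.default_rng(spec.seed)
    structure = _ca_structure(spec.n_sites)
    disp = np.empty((spec.frames, spec.n_sites, 3))
    for axis in range(3):
        z = rng.standard_normal((spec.frames, spec.n_sites))
        disp[:, :, axis] = spec.sigma * (z @ root.T)
    coords = structure.coords[None, :, :] + disp
    times = spec.dt_ps * np.arange(spec.frames, dtype=float)
    return Ensemble(
        structure,
        coords,
        times,
        condition="synthetic",
        replica=1,
        meta={"ground_truth_correlation": corr, "spec": dataclasses.asdict(spec)},
    )


# ---------------------------------------------------------------------------
# rigid subdomain shift


@dataclasses.dataclass
class ShiftSpec:
    """Progressive rigid rotation of a mobile subdomain in one condition."""

    n_scaffold: int = 30
    n_mobile: int = 12
    rotation_deg: float = 30.0  # reached at the final apo-like frame
    noise_sigma: float = 0.2  # thermal noise, Å
    frames: int = 200
    seed: int = 0
    dt_ps: float = 100.0
    lever_arm: float = 15.0  # distance of the mobile subdomain from the axis, Å

    def __post_init__(self) -> None:
        if self.rotation_deg < 0:
            raise ValueError("rotation magnitude must be non-negative")
        if self.n_scaffold < 3 or self.n_mobile < 1:
            raise ValueError("need at least 3 scaffold and 1 mobile site")


def _shift_structure(spec: ShiftSpec) -> tuple[StructureModel, DomainMap]:
    n = spec.n_scaffold + spec.n_mobile
    base = _ca_structure(n)
    coords = base.coords.copy()
    # place the mobile subdomain as a compact cluster a lever arm away from
    # the scaffold centroid along +x
    scaffold_centroid = coords[: spec.n_scaffold].mean(axis=0)
    t = np.arange(spec.n_mobile, dtype=float)
    cluster = np.column_stack(
        (np.zeros_like(t), 3.0 * np.cos(t), 3.0 * np.sin(t))
    )
    coords[spec.n_scaffold :] = scaffold_centroid + np.array([spec.lever_arm, 0, 0]) + cluster
    structure = StructureModel(
        atom_names=base.atom_names,
        elements=base.elements,
        chain_ids=base.chain_ids,
        res_ids=base.res_ids,
        res_names=base.res_names,
        coords=coords,
        radii=base.radii,
    )
    domain_map = DomainMap(
        {
            "scaffold": [("A", 1, spec.n_scaffold)],
            "mobile": [("A", spec.n_scaffold + 1, n)],
        }
    )
    return structure, domain_map


def _rotation_about_z(angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def domain_shift_ensemble(spec: ShiftSpec) -> tuple[Ensemble, Ensemble, DomainMap]:
    """(apo-like, holo-like) ensembles sharing thermal noise statistics.

    Both conditions add isotropic Gaussian noise σ to every site; the
    apo-like condition additionally rotates the mobile subdomain about the
    z-axis through the scaffold centroid, the angle growing linearly from 0
    to ``rotation_deg`` across frames. The returned DomainMap names the
    ``scaffold`` and ``mobile`` site ranges.
    """
    structure, domain_map = _shift_structure(spec)
    rng = np.random.default_rng(spec.seed)
    times = spec.dt_ps * np.arange(spec.frames, dtype=float)
    center = structure.coords[: spec.n_scaffold].mean(axis=0)
    ensembles = []
    for condition, magnitude in (("apo-like", spec.rotation_deg), ("holo-like", 0.0)):
        coords = np.repeat(structure.coords[None, :, :], spec.frames, axis=0)
        angles = np.deg2rad(magnitude) * np.linspace(0.0, 1.0, spec.frames)
        for f, angle in enumerate(angles):
            if angle != 0.0:
                R = _rotation_about_z(angle)
                mobile = coords[f, spec.n_scaffold :] - center
                coords[f, spec.n_scaffold :] = mobile @ R.T + center
        coords += rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        ensembles.append(
            Ensemble(
                structure,
                coords,
                times,
                condition=condition,
                replica=1,
                meta={"spec": dataclasses.asdict(spec)},
            )
        )
    return ensembles[0], ensembles[1], domain_map


# ---------------------------------------------------------------------------
# two-condition distance features


@dataclasses.dataclass
class TwoConditionSpec:
    """Gaussian distance features with a planted discriminating subset."""

    n_features: int = 25
    planted: tuple[int, ...] = (0, 1, 2, 3)  # feature indices that separate
    base_mean: float = 10.0  # shared mean, Å
    separation: float = 5.0  # mean difference between conditions, in σ units
    noise_sigma: float = 0.4  # feature standard deviation, Å
    frames_per_replica: int = 300
    replicas: int = 3
    seed: int = 0
    dt_ps: float = 100.0
    conditions: tuple[str, str] = ("apo", "holo")

    def __post_init__(self) -> None:
        if any(p >= self.n_features for p in self.planted):
            raise ValueError("planted indices must be < n_features")
        if self.base_mean <= 0:
            raise ValueError("means must be positive")

    def condition_means(self) -> dict[str, np.ndarray]:
        """Ground-truth feature means per condition (Å)."""
        shift = self.separation * self.noise_sigma
        means = {c: np.full(self.n_features, self.base_mean) for c in self.conditions}
        # planted features sit above the shared mean in the first condition
        # and below it in the second — total separation `separation`·σ
        for p in self.planted:
            means[self.conditions[0]][p] = self.base_mean + shift / 2.0
            means[self.conditions[1]][p] = self.base_mean - shift / 2.0
        return means


@dataclasses.dataclass
class TwoConditionResult:
    distance_set: DistanceSet
    ensembles: list[Ensemble]  # one per condition × replica, point particles
    definitions: list[DistanceDefinition]
    ground_truth_means: dict[str, np.ndarray]
    planted: tuple[int, ...]


def _pair_structure(n_features: int) -> StructureModel:
    """Two point particles per feature, pairs 100 Å apart from each other."""
    n_atoms = 2 * n_features
    coords = np.zeros((n_atoms, 3))
    for d in range(n_features):
        coords[2 * d] = (100.0 * d, 0.0, 0.0)
        coords[2 * d + 1] = (100.0 * d + 10.0, 0.0, 0.0)
    elements = np.full(n_atoms, "C")
    return StructureModel(
        atom_names=np.full(n_atoms, "CA"),
        elements=elements,
        chain_ids=np.full(n_atoms, "A"),
        res_ids=np.arange(1, n_atoms + 1),
        res_names=np.full(n_atoms, "ALA"),
        coords=coords,
        radii=radii_for_elements(elements),
    )


def two_condition_distances(spec: TwoConditionSpec) -> TwoConditionResult:
    """Planted two-condition distance features plus a realizing ensemble.

    Features are independent Gaussians N(μ, σ²); the planted subset's μ
    differs between the two conditions by ``separation``·σ. For every
    condition × replica an ensemble of point particles is emitted in which
    atom pair (2d, 2d+1) lies along x at exactly the d-th feature value, so
    running the distance-extraction stage on it reproduces the matrix.
    """
    rng = np.random.default_rng(spec.seed)
    means = spec.condition_means()
    structure = _pair_structure(spec.n_features)
    names = [f"d{idx + 1:02d}" for idx in range(spec.n_features)]
    definitions = [
        DistanceDefinition(
            name=names[idx],
            a=EndpointSpec(chain="A", res_id=2 * idx + 1, mode="atom", atom_name="CA"),
            b=EndpointSpec(chain="A", res_id=2 * idx + 2, mode="atom", atom_name="CA"),
        )
        for idx in range(spec.n_features)
    ]
    blocks = []
    ensembles = []
    times = spec.dt_ps * np.arange(spec.frames_per_replica, dtype=float)
    for condition in spec.conditions:
        for replica in range(1, spec.replicas + 1):
            values = rng.normal(
                means[condition][None, :],
                spec.noise_sigma,
                size=(spec.frames_per_replica, spec.n_features),
            )
            values = np.clip(values, 0.1, None)  # distances stay positive
            blocks.append(
                DistanceSet(
                    times=times,
                    values=values,
                    names=names,
                    conditions=np.full(spec.frames_per_replica, condition),
                    replicas=np.full(spec.frames_per_replica, replica),
                )
            )
            coords = np.repeat(structure.coords[None, :, :], spec.frames_per_replica, axis=0)
            coords[:, 1::2, 0] = coords[:, 0::2, 0] + values  # place B atoms
            ensembles.append(
                Ensemble(
                    structure, coords, times, condition=condition, replica=replica,
                    meta={"planted": list(spec.planted)},
                )
            )
    return TwoConditionResult(
        distance_set=DistanceSet.concatenate(blocks),
        ensembles=ensembles,
        definitions=definitions,
        ground_truth_means=means,
        planted=spec.planted,
    )
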