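"""Superposition, RMSD series, essential-dynamics PCA and Shrake–Rupley SASA.

The RMSD convention follows the usual trajectory reading: every frame is
least-squares fitted (Kabsch) on a *fit set* of atoms, then the deviation is
measured on a *calc set* without refitting. With fit set == calc set this is
the ordinary RMSD from the reference; with a scaffold fit set and a mobile
calc set it isolates the displacement of a subdomain relative to a scaffold
(e.g. PAS-B interface elements after alignment on the PAS-A core).

PCA ("essential dynamics") diagonalizes the 3N×3N covariance of fitted Cα
coordinates pooled over all supplied ensembles, so that projections of two
conditions live in one common mode basis.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structure import AtomSet, Ensemble, StructureModel


class DegenerateFitError(ValueError):
    """Fit set has fewer than 3 non-collinear atoms."""


@dataclasses.dataclass
class Transform:
    """Rigid-body transform: y = R x + t."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclasses.dataclass
class Series:
    """A per-frame scalar trace (RMSD, projection, ...) with labels."""

    times: np.ndarray  # ps
    values: np.ndarray
    condition: str = ""
    replica: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")


@dataclasses.dataclass
class PCAResult:
    """Principal components of Cα motion over pooled ensembles."""

    mean_coords: np.ndarray  # (n_atoms, 3) mean of the fitted analysis set
    eigenvalues: np.ndarray  # (n_modes,), Å², descending
    eigenvectors: np.ndarray  # (n_modes, 3N), orthonormal rows
    projections: list[Series]  # one Series per ensemble per mode
    total_variance: float  # trace of the covariance, Å²

    def variance_fraction(self, mode: int) -> float:
        return float(self.eigenvalues[mode] / self.total_variance)


def _fit_coords(atom_set: AtomSet | None, coords: np.ndarray) -> np.ndarray:
    if atom_set is None:
        return coords
    return coords[..., atom_set.indices, :]


def _check_fit_set(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError("superposition needs at least 3 fit atoms")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateFitError("fit atoms are collinear")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_set: AtomSet | None = None,
) -> tuple[Transform, float]:
    """Least-squares (Kabsch) fit of ``mobile`` onto ``reference``.

    Returns the rigid transform minimizing the RMSD over the fit set and the
    minimized RMSD itself (Å). Coordinates outside the fit set do not
    influence the transform but are moved by it when the caller applies it.
    """
    mob = _fit_coords(fit_set, np.asarray(mobile, dtype=float))
    ref = _fit_coords(fit_set, np.asarray(reference, dtype=float))
    if mob.shape != ref.shape:
        raise ValueError("mobile and reference fit sets differ in shape")
    _check_fit_set(mob)
    mob_center = mob.mean(axis=0)
    ref_center = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_center, mob - mob_center)
    R = rot.as_matrix()
    t = ref_center - R @ mob_center
    transform = Transform(R, t)
    return transform, rmsd(transform.apply(mob), ref)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain no-fit RMSD between two coordinate arrays of equal shape."""
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt((diff**2).sum(axis=-1).mean()))


def rmsd_series(
    ensemble: Ensemble,
    reference: np.ndarray,
    fit_set: AtomSet,
    calc_set: AtomSet | None = None,
) -> Series:
    """Per-frame RMSD: fit on ``fit_set``, measure on ``calc_set`` (no refit).

    ``calc_set=None`` means calc set == fit set (ordinary RMSD). The
    reference is typically the first production frame.
    """
    if calc_set is None:
        calc_set = fit_set
    reference = np.asarray(reference, dtype=float)
    values = np.empty(ensemble.n_frames)
    ref_calc = reference[calc_set.indices]
    for f in range(ensemble.n_frames):
        transform, _ = superpose(ensemble.coords[f], reference, fit_set)
        fitted = transform.apply(ensemble.coords[f][calc_set.indices])
        values[f] = rmsd(fitted, ref_calc)
    return Series(
        ensemble.times, values, condition=ensemble.condition,
        replica=ensemble.replica, name="rmsd",
    )


def iterative_fit(
    frames: np.ndarray, n_passes: int = 2, reference: np.ndarray | None = None
) -> np.ndarray:
    """Superpose frames onto an evolving mean structure.

    Pass 1 fits every frame onto ``reference`` (default: frame 0); each later
    pass refits onto the mean of the previously fitted frames. Removes
    rigid-body motion before covariance analysis.
    """
    frames = np.asarray(frames, dtype=float)
    target = frames[0] if reference is None else np.asarray(reference, dtype=float)
    fitted = np.empty_like(frames)
    for _ in range(max(1, n_passes)):
        for f in range(frames.shape[0]):
            transform, _ = superpose(frames[f], target)
            fitted[f] = transform.apply(frames[f])
        target = fitted.mean(axis=0)
        frames = fitted.copy()
    return fitted


def pca_modes(
    ensembles: Sequence[Ensemble],
    atom_set: AtomSet,
    n_modes: int = 5,
    pooled: bool = True,
    fit: bool = True,
) -> PCAResult:
    """Essential-dynamics PCA of the selected atoms.

    Frames of all ensembles are pooled (default), iteratively fitted to their
    mean, and the 3N×3N coordinate covariance is diagonalized. Per-ensemble
    projections onto each retained mode are returned as labelled Series, so
    two conditions can be compared along a common eigenvector. With
    ``pooled=False`` the covariance uses only the first ensemble but all
    ensembles are still projected. ``fit=False`` skips the superposition for
    input already expressed in one common reference frame.
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    n_coords = 3 * len(atom_set)
    if n_modes > n_coords:
        raise ValueError(f"n_modes {n_modes} exceeds 3N = {n_coords}")
    for e in ensembles:
        e.require_frames(2)
    sub = [e.coords[:, atom_set.indices, :] for e in ensembles]
    pooled_frames = np.concatenate(sub, axis=0)
    fitted_all = iterative_fit(pooled_frames) if fit else pooled_frames
    cov_frames = (
        fitted_all if pooled else fitted_all[: ensembles[0].n_frames]
    )
    flat = cov_frames.reshape(cov_frames.shape[0], -1)
    mean_flat = flat.mean(axis=0)
    centered = flat - mean_flat
    cov = centered.T @ centered / centered.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows are modes
    total_variance = float(np.trace(cov))

    projections: list[Series] = []
    offset = 0
    flat_all = fitted_all.reshape(fitted_all.shape[0], -1) - mean_flat
    for e in ensembles:
        block = flat_all[offset : offset + e.n_frames]
        offset += e.n_frames
        for mode in range(n_modes):
            projections.append(
                Series(
                    e.times,
                    block @ evecs[mode],
                    condition=e.condition,
                    replica=e.replica,
                    name=f"pc{mode + 1}",
                )
            )
    return PCAResult(
        mean_coords=mean_flat.reshape(-1, 3),
        eigenvalues=evals[:n_modes],
        eigenvectors=evecs[:n_modes],
        projections=projections,
        total_variance=total_variance,
    )


# ---------------------------------------------------------------------------
# solvent-accessible surface area


def _fibonacci_sphere(n_points: int) -> np.ndarray:
    """Near-uniform unit-sphere point set (golden-spiral construction)."""
    i = np.arange(n_points, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n_points)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by sphere sampling.

    Each atom is expanded to radius r+probe and sampled with ``n_points``
    near-uniform surface points; a point is accessible when it lies outside
    every neighbouring expanded sphere. Coincident atom positions are an
    error (zero-distance neighbours make the area ill-defined).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be strictly positive")
    if n_points < 92:
        raise ValueError("n_points must be at least 92")
    n = coords.shape[0]
    expanded = radii + probe
    dists = cdist(coords, coords)
    dup = (dists < 1e-9) & ~np.eye(n, dtype=bool)
    if dup.any():
        i, j = np.argwhere(dup)[0]
        raise ValueError(f"atoms {i} and {j} occupy identical positions")
    sphere = _fibonacci_sphere(n_points)
    areas = np.empty(n)
    # neighbours that can possibly occlude atom i
    cut = dists < (expanded[:, None] + expanded[None, :])
    np.fill_diagonal(cut, False)
    for i in range(n):
        points = coords[i] + expanded[i] * sphere
        neighbors = np.flatnonzero(cut[i])
        if len(neighbors) == 0:
            accessible = n_points
        else:
            d2 = cdist(points, coords[neighbors], "sqeuclidean")
            buried = (d2 < (expanded[neighbors] ** 2)[None, :]).any(axis=1)
            accessible = int((~buried).sum())
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible / n_points
    return areas


def delta_sasa(
    structure: StructureModel,
    frame: np.ndarray,
    region: AtomSet,
    partner: AtomSet,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface burial of ``region`` by ``partner`` (Å²).

    SASA of the region atoms computed with the partner atoms deleted, minus
    their SASA in the full complex. Positive values mean the partner buries
    the region.
    """
    if structure.radii is None:
        raise ValueError("structure has no atom radii")
    if np.intersect1d(region.indices, partner.indices).size:
        raise ValueError("region and partner atom sets must be disjoint")
    frame = np.asarray(frame, dtype=float)
    full = shrake_rupley_sasa(frame, structure.radii, probe, n_points)
    keep = np.setdiff1d(np.arange(structure.n_atoms), partner.indices)
    stripped = shrake_rupley_sasa(frame[keep], structure.radii[keep], probe, n_points)
    pos_in_keep = np.searchsorted(keep, region.indices)
    return float(stripped[pos_in_keep].sum() - full[region.indices].sum())
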