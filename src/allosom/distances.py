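"""Monitored salt-bridge and interface distances: the SOM training matrix.

A :class:`DistanceDefinition` names two endpoints; each endpoint is either a
single named atom or the centroid of a charged group. Centroid conventions
(chosen because the side-chain charge is delocalized and centroids are robust
to rotamer flips):

    Arg  ->  NH1 + NH2 + NE        Lys  ->  NZ
    Glu  ->  OE1 + OE2             Asp  ->  OD1 + OD2
    DNA phosphate  ->  atom P

:func:`compute_distances` evaluates every definition on every stride-selected
frame, producing a :class:`DistanceSet`: a frames × D matrix of distances (Å)
with stable column order, so that feature columns align across conditions.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .structure import Ensemble, StructureModel

#: charged-group atoms per residue type for centroid mode
CHARGED_GROUP_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NH1", "NH2", "NE"),
    "LYS": ("NZ",),
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}


class EndpointError(ValueError):
    """An endpoint spec does not resolve to the required atoms."""


@dataclasses.dataclass(frozen=True)
class EndpointSpec:
    """One end of a monitored distance.

    mode: ``"atom"`` (requires ``atom_name``), ``"centroid"`` (charged-group
    centroid of the residue) or ``"phosphate"`` (DNA backbone P atom).
    """

    chain: str
    res_id: int
    mode: str = "centroid"
    atom_name: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("atom", "centroid", "phosphate"):
            raise ValueError(f"unknown endpoint mode {self.mode!r}")
        if self.mode == "atom" and not self.atom_name:
            raise ValueError("atom mode requires atom_name")


@dataclasses.dataclass(frozen=True)
class DistanceDefinition:
    name: str
    a: EndpointSpec
    b: EndpointSpec


@dataclasses.dataclass
class DistanceSet:
    """frames × D named distances (Å) with per-frame condition/replica labels."""

    times: np.ndarray  # ps
    values: np.ndarray  # (frames, D), Å
    names: list[str]
    conditions: np.ndarray  # str per frame
    replicas: np.ndarray  # int per frame

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.names):
            raise ValueError("values must be (frames, len(names))")
        if len(set(self.names)) != len(self.names):
            raise ValueError("distance names must be unique")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be positive and finite")
        self.conditions = np.asarray(self.conditions)
        self.replicas = np.asarray(self.replicas, dtype=int)
        n = self.values.shape[0]
        if not (len(self.times) == len(self.conditions) == len(self.replicas) == n):
            raise ValueError("per-frame labels must match frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.names)
        df.insert(0, "replica", self.replicas)
        df.insert(0, "condition", self.conditions)
        df.insert(0, "time_ps", self.times)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceSet":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("time_ps", "condition", "replica")]
        return cls(
            times=df["time_ps"].to_numpy(),
            values=df[names].to_numpy(),
            names=names,
            conditions=df["condition"].to_numpy(dtype=str),
            replicas=df["replica"].to_numpy(),
        )

    @classmethod
    def concatenate(cls, sets: Sequence["DistanceSet"]) -> "DistanceSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        names = sets[0].names
        for s in sets[1:]:
            if s.names != names:
                raise ValueError("distance sets have mismatching columns")
        return cls(
            times=np.concatenate([s.times for s in sets]),
            values=np.vstack([s.values for s in sets]),
            names=list(names),
            conditions=np.concatenate([s.conditions for s in sets]),
            replicas=np.concatenate([s.replicas for s in sets]),
        )


def _endpoint_atoms(structure: StructureModel, spec: EndpointSpec) -> np.ndarray:
    residue = (structure.chain_ids == spec.chain) & (structure.res_ids == spec.res_id)
    if not residue.any():
        raise EndpointError(f"no residue {spec.chain}:{spec.res_id} in structure")
    if spec.mode == "atom":
        wanted = (spec.atom_name,)
    elif spec.mode == "phosphate":
        wanted = ("P",)
    else:
        res_name = str(structure.res_names[np.flatnonzero(residue)[0]])
        try:
            wanted = CHARGED_GROUP_ATOMS[res_name]
        except KeyError:
            raise EndpointError(
                f"{spec.chain}:{spec.res_id} ({res_name}) has no charged-group "
                f"convention; use atom mode"
            ) from None
    indices = []
    missing = []
    for name in wanted:
        hit = np.flatnonzero(residue & (structure.atom_names == name))
        if len(hit) == 0:
            missing.append(name)
        else:
            indices.append(hit[0])
    if missing:
        raise EndpointError(
            f"endpoint {spec.chain}:{spec.res_id} missing atoms {missing}"
        )
    return np.array(indices, dtype=int)


def endpoint_position(
    structure: StructureModel, frame: np.ndarray, spec: EndpointSpec
) -> np.ndarray:
    """Resolve an endpoint to a 3-vector (Å) in the given frame.

    Single-atom mode returns that atom's position; centroid mode the
    unweighted mean of the charged-group atoms.
    """
    idx = _endpoint_atoms(structure, spec)
    return np.asarray(frame, dtype=float)[idx].mean(axis=0)


def compute_distances(
    ensemble: Ensemble,
    definitions: Sequence[DistanceDefinition],
    stride_ps: float | None = None,
) -> DistanceSet:
    """Evaluate every distance definition on the stride-selected frames.

    ``stride_ps`` keeps frames on a regular time grid (default: every frame);
    it must not be finer than the trajectory spacing.
    """
    if not definitions:
        raise ValueError("no distance definitions supplied")
    seen = set()
    for d in definitions:
        if d.name in seen:
            raise ValueError(f"duplicate distance name {d.name!r}")
        seen.add(d.name)
    times = ensemble.times
    if stride_ps is None:
        frame_idx = np.arange(ensemble.n_frames)
    else:
        spacing = float(np.min(np.diff(times))) if len(times) > 1 else stride_ps
        if stride_ps < spacing - 1e-9:
            raise ValueError(
                f"stride_ps {stride_ps} is finer than frame spacing {spacing}"
            )
        step = max(1, int(round(stride_ps / spacing)))
        frame_idx = np.arange(0, ensemble.n_frames, step)
    # resolve atom indices once; positions vary per frame
    endpoints = [
        (_endpoint_atoms(ensemble.structure, d.a), _endpoint_atoms(ensemble.structure, d.b))
        for d in definitions
    ]
    values = np.empty((len(frame_idx), len(definitions)))
    for row, f in enumerate(frame_idx):
        frame = ensemble.coords[f]
        for col, (ia, ib) in enumerate(endpoints):
            values[row, col] = np.linalg.norm(frame[ia].mean(axis=0) - frame[ib].mean(axis=0))
    return DistanceSet(
        times=times[frame_idx],
        values=values,
        names=[d.name for d in definitions],
        conditions=np.full(len(frame_idx), ensemble.condition),
        replicas=np.full(len(frame_idx), ensemble.replica),
    )


# ---------------------------------------------------------------------------
# config I/O


def _spec_from_dict(raw: dict) -> EndpointSpec:
    return EndpointSpec(
        chain=str(raw["chain"]),
        res_id=int(raw["res_id"]),
        mode=raw.get("mode", "centroid"),
        atom_name=raw.get("atom_name"),
    )


def load_distance_definitions(path: str | Path) -> list[DistanceDefinition]:
    """Read distance definitions from a YAML config (``distances:`` list)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    entries = raw["distances"] if isinstance(raw, dict) else raw
    defs = []
    for item in entries:
        defs.append(
            DistanceDefinition(
                name=str(item["name"]),
                a=_spec_from_dict(item["a"]),
                b=_spec_from_dict(item["b"]),
            )
        )
    return defs


def default_distance_config_path() -> Path:
    """Path of the bundled 25-distance template config."""
    return Path(__file__).parent / "data" / "distances_template.yaml"
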