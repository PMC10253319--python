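"""Structures, trajectories, atom selections and the named domain map.

Everything downstream (RMSD, PCA, SASA, correlation networks, interface
distances) operates on three containers defined here:

``StructureModel``
    The labelled reference topology: one entry per heavy atom with chain id,
    residue number/name, atom name, element and a van der Waals radius.

``Ensemble``
    Frames × atoms × 3 coordinates (Å) tied to a ``StructureModel``, with
    per-frame timestamps (ps), a condition label (e.g. ``"apo"``/``"holo"``)
    and a replica id.

``DomainMap``
    Named residue ranges (chain id + inclusive 1-based intervals) such as
    ``AhR.PASA`` or ``ARNT.bHLH``; the vocabulary used by the selection
    language of :func:`resolve_selection`.

Solvent and monoatomic ions are stripped on load; hydrogens are kept in the
model but every analysis selects heavy atoms (typically Cα) explicitly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

from .radii import radii_for_elements


class FormatError(ValueError):
    """Input file could not be parsed in the expected format."""


class TopologyError(ValueError):
    """Trajectory is inconsistent with the reference structure."""


class SelectionError(ValueError):
    """A selection expression failed to resolve."""


# ---------------------------------------------------------------------------
# containers


@dataclasses.dataclass
class StructureModel:
    """Reference structure: per-atom labels, coordinates and radii."""

    atom_names: np.ndarray  # str, shape (N,)
    elements: np.ndarray  # str, shape (N,)
    chain_ids: np.ndarray  # str, shape (N,)
    res_ids: np.ndarray  # int, shape (N,)
    res_names: np.ndarray  # str, shape (N,)
    coords: np.ndarray  # float, shape (N, 3), Å
    radii: np.ndarray | None = None  # float, shape (N,), Å

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if n == 0:
            raise FormatError("structure contains zero atoms")
        for field in ("elements", "chain_ids", "res_ids", "res_names"):
            if len(getattr(self, field)) != n:
                raise ValueError(f"{field} length does not match atom count")
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if np.any(self.radii <= 0):
                raise ValueError("all atom radii must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_labels(self, indices: np.ndarray | None = None) -> list[str]:
        """``"A:123"`` style labels, one per atom (or per selected atom)."""
        idx = np.arange(self.n_atoms) if indices is None else np.asarray(indices)
        return [f"{self.chain_ids[i]}:{self.res_ids[i]}" for i in idx]

    def to_atom_array(self, coords: np.ndarray | None = None) -> struc.AtomArray:
        arr = struc.AtomArray(self.n_atoms)
        arr.atom_name = self.atom_names
        arr.element = self.elements
        arr.chain_id = self.chain_ids
        arr.res_id = self.res_ids
        arr.res_name = self.res_names
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        arr.coord = np.asarray(self.coords if coords is None else coords, dtype=float)
        return arr


@dataclasses.dataclass
class Ensemble:
    """Coordinate trajectory bound to a :class:`StructureModel`."""

    structure: StructureModel
    coords: np.ndarray  # (frames, atoms, 3), Å
    times: np.ndarray  # (frames,), ps, strictly increasing
    condition: str = ""
    replica: int = 1
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise TopologyError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"structure atom count {self.structure.n_atoms}"
            )
        if len(self.times) != self.n_frames:
            raise ValueError("one timestamp per frame required")
        if self.n_frames > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def require_frames(self, n: int = 2) -> None:
        if self.n_frames < n:
            raise ValueError(f"operation requires at least {n} frames, got {self.n_frames}")


@dataclasses.dataclass(frozen=True)
class AtomSet:
    """Ordered, duplicate-free atom indices with the expression that made them."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise SelectionError("atom set contains duplicate indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


class DomainMap:
    """Named residue ranges: ``name -> [(chain_id, first_res, last_res), ...]``.

    Intervals are inclusive on both ends and use the 1-based residue
    numbering of the source PDB.
    """

    def __init__(self, entries: dict[str, list[tuple[str, int, int]]]):
        self.entries: dict[str, list[tuple[str, int, int]]] = {}
        for name, intervals in entries.items():
            parsed = []
            for chain, lo, hi in intervals:
                lo, hi = int(lo), int(hi)
                if hi < lo:
                    raise ValueError(f"{name}: empty interval {lo}-{hi}")
                parsed.append((str(chain), lo, hi))
            if not parsed:
                raise ValueError(f"{name}: no intervals")
            self.entries[name] = parsed

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return list(self.entries)

    def mask(self, structure: StructureModel, name: str) -> np.ndarray:
        """Boolean per-atom mask of the named entry; errors on unknown names."""
        if name not in self.entries:
            raise SelectionError(f"unknown domain-map entry: {name!r}")
        mask = np.zeros(structure.n_atoms, dtype=bool)
        for chain, lo, hi in self.entries[name]:
            mask |= (
                (structure.chain_ids == chain)
                & (structure.res_ids >= lo)
                & (structure.res_ids <= hi)
            )
        return mask

    def validate(self, structure: StructureModel) -> None:
        """Check every entry resolves to at least one residue."""
        for name in self.entries:
            if not self.mask(structure, name).any():
                raise SelectionError(f"domain-map entry {name!r} matches no atoms")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "DomainMap":
        entries: dict[str, list[tuple[str, int, int]]] = {}
        for name, spec in raw.items():
            intervals = []
            for item in spec:
                intervals.append((item["chain"], item["first"], item["last"]))
            entries[name] = intervals
        return cls(entries)

    def to_dict(self) -> dict:
        return {
            name: [{"chain": c, "first": lo, "last": hi} for c, lo, hi in ivs]
            for name, ivs in self.entries.items()
        }


# ---------------------------------------------------------------------------
# I/O

_SOLVENT_RES = {"HOH", "WAT", "SOL", "TIP3", "TIP4", "SPC"}


def _strip_solvent(array):
    mask = ~np.isin(array.res_name, list(_SOLVENT_RES))
    mask &= ~struc.filter_monoatomic_ions(array)
    return array[..., mask]


def load_structure(path: str | Path) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    The first model is used as the reference; solvent and monoatomic ions are
    removed; per-atom radii are assigned from the bundled element table.
    """
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        array = pdbio.get_structure(pdb_file, model=1)
    except Exception as exc:  # biotite raises several parse error types
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc
    array = _strip_solvent(array)
    if array.array_length() == 0:
        raise FormatError(f"{path}: no atoms after solvent/ion stripping")
    return StructureModel(
        atom_names=np.array(array.atom_name),
        elements=np.array(array.element),
        chain_ids=np.array(array.chain_id),
        res_ids=np.array(array.res_id, dtype=int),
        res_names=np.array(array.res_name),
        coords=np.array(array.coord, dtype=float),
        radii=radii_for_elements(array.element),
    )


def load_ensemble(
    path: str | Path,
    structure: StructureModel,
    stride: int = 1,
    condition: str = "",
    replica: int = 1,
    dt_ps: float = 100.0,
) -> Ensemble:
    """Read one trajectory file (multi-model PDB, XTC or DCD) as an Ensemble.

    Every ``stride``-th frame is kept. Timestamps are carried from the file
    when the format stores them; multi-model PDB has none, so they are
    synthesized on a ``dt_ps`` grid (t = dt_ps · frame index).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        coords, times = _read_multimodel_pdb(path, dt_ps)
    elif suffix in (".xtc", ".dcd"):
        coords, times = _read_mdanalysis(path, structure)
    else:
        raise FormatError(f"unsupported trajectory format: {suffix!r}")
    if coords.shape[1] != structure.n_atoms:
        raise TopologyError(
            f"{path}: trajectory has {coords.shape[1]} atoms, "
            f"structure has {structure.n_atoms}"
        )
    coords = coords[::stride]
    times = times[::stride]
    if len(coords) == 0:
        raise ValueError(f"{path}: stride {stride} leaves no frames")
    return Ensemble(structure, coords, times, condition=condition, replica=replica)


def load_ensembles(
    paths: Sequence[str | Path],
    structure: StructureModel,
    stride: int = 1,
    condition: str = "",
    dt_ps: float = 100.0,
) -> list[Ensemble]:
    """Load several replica files; replica ids run 1..len(paths)."""
    return [
        load_ensemble(p, structure, stride=stride, condition=condition,
                      replica=i + 1, dt_ps=dt_ps)
        for i, p in enumerate(paths)
    ]


def _read_multimodel_pdb(path: Path, dt_ps: float) -> tuple[np.ndarray, np.ndarray]:
    try:
        pdb_file = pdbio.PDBFile.read(str(path))
        stack = pdbio.get_structure(pdb_file)
    except Exception as exc:
        raise FormatError(f"could not parse PDB trajectory {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    stack = _strip_solvent(stack)
    coords = np.array(stack.coord, dtype=float)
    times = dt_ps * np.arange(coords.shape[0], dtype=float)
    return coords, times


def _read_mdanalysis(path: Path, structure: StructureModel) -> tuple[np.ndarray, np.ndarray]:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading XTC/DCD trajectories requires MDAnalysis "
            "(install the 'traj' extra)"
        ) from exc
    # Coordinate-only readers need a topology with the right atom count; the
    # StructureModel provides it.
    universe = mda.Universe.empty(structure.n_atoms, trajectory=True)
    universe.load_new(str(path))
    frames, times = [], []
    for ts in universe.trajectory:
        frames.append(ts.positions.astype(float).copy())
        times.append(float(ts.time))
    coords = np.array(frames)
    times = np.array(times)
    if len(times) > 1 and np.all(np.diff(times) <= 0):
        times = np.arange(len(times), dtype=float)
    return coords, times


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an Ensemble as a multi-model PDB (coordinates to 10⁻³ Å)."""
    s = ensemble.structure
    stack = struc.AtomArrayStack(ensemble.n_frames, s.n_atoms)
    template = s.to_atom_array()
    for category in template.get_annotation_categories():
        stack.set_annotation(category, template.get_annotation(category))
    stack.coord = ensemble.coords.copy()
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, stack)
    pdb_file.write(str(path))


def write_structure(structure: StructureModel, path: str | Path) -> None:
    """Write the reference coordinates as a single-model PDB."""
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, structure.to_atom_array())
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# selection language
#
# Grammar (binding tight -> loose):
#   primary := '(' expr ')' | 'name' ATOMNAME | 'all' | MAP_ENTRY
#   inter   := primary ('&' primary)*
#   expr    := inter (('|' | '-') inter)*
# '&' intersection, '|' union, '-' difference; MAP_ENTRY names come from the
# DomainMap (dots allowed, e.g. AhR.PASB.Falpha).

_OPERATORS = {"&", "|", "-", "−", "(", ")"}


def _tokenize(expr: str) -> list[str]:
    tokens: list[str] = []
    i = 0
    while i < len(expr):
        ch = expr[i]
        if ch.isspace():
            i += 1
        elif ch in _OPERATORS:
            tokens.append("-" if ch == "−" else ch)
            i += 1
        else:
            j = i
            while j < len(expr) and not expr[j].isspace() and expr[j] not in _OPERATORS:
                j += 1
            tokens.append(expr[i:j])
            i = j
    return tokens


class _SelectionParser:
    def __init__(self, tokens: list[str], structure: StructureModel, domain_map: DomainMap | None):
        self.tokens = tokens
        self.pos = 0
        self.structure = structure
        self.map = domain_map

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"trailing tokens at {self.peek()!r}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.inter()
        while self.peek() in ("|", "-"):
            op = self.take()
            rhs = self.inter()
            mask = (mask | rhs) if op == "|" else (mask & ~rhs)
        return mask

    def inter(self) -> np.ndarray:
        mask = self.primary()
        while self.peek() == "&":
            self.take()
            mask = mask & self.primary()
        return mask

    def primary(self) -> np.ndarray:
        tok = self.take()
        if tok == "(":
            mask = self.expr()
            if self.take() != ")":
                raise SelectionError("unbalanced parentheses")
            return mask
        if tok == "name":
            atom = self.take()
            return self.structure.atom_names == atom
        if tok == "all":
            return np.ones(self.structure.n_atoms, dtype=bool)
        if self.map is None:
            raise SelectionError(f"no domain map bound; cannot resolve {tok!r}")
        return self.map.mask(self.structure, tok)


def resolve_selection(
    structure: StructureModel,
    domain_map: DomainMap | None,
    expr: str,
) -> AtomSet:
    """Resolve a selection expression to an ordered :class:`AtomSet`.

    Examples: ``"AhR.PASA & name CA"``, ``"(AhR.all - AhR.PASA.loops) & name CA"``,
    ``"AhR.PASB.Falpha | AhR.PASB.Gbeta"``. The result is sorted by atom index
    and duplicate-free; an empty result is an error.
    """
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    mask = _SelectionParser(tokens, structure, domain_map).parse()
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise SelectionError(f"selection {expr!r} matches no atoms")
    return AtomSet(indices=indices, provenance=expr)
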