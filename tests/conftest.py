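"""Shared fixtures: small labelled structures and synthetic ensembles."""

from __future__ import annotations

import numpy as np
import pytest

from allosom.radii import radii_for_elements
from allosom.structure import DomainMap, Ensemble, StructureModel

# hand-written PDB text: chain A = two-residue peptide fragment (CA atoms),
# chain B = one nucleotide phosphorus
TWO_CHAIN_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CB  ALA A   1       1.500   2.500   3.500  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
ATOM      4  P    DA B   1       9.000   8.000   7.000  1.00  0.00           P
END
"""

MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       1.000   2.000   3.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       4.000   5.000   6.000  1.00  0.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def two_chain_pdb(tmp_path):
    path = tmp_path / "two_chain.pdb"
    path.write_text(TWO_CHAIN_PDB)
    return path


def make_structure(n_residues: int = 12, chain: str = "A") -> StructureModel:
    """Cα-only chain on a loose helix, residues 1..n."""
    t = np.arange(n_residues, dtype=float)
    coords = np.column_stack((6.0 * np.cos(t / 2), 6.0 * np.sin(t / 2), 3.0 * t))
    elements = np.full(n_residues, "C")
    return StructureModel(
        atom_names=np.full(n_residues, "CA"),
        elements=elements,
        chain_ids=np.full(n_residues, chain),
        res_ids=np.arange(1, n_residues + 1),
        res_names=np.full(n_residues, "ALA"),
        coords=coords,
        radii=radii_for_elements(elements),
    )


def make_ensemble(
    structure: StructureModel,
    displacements: np.ndarray,
    condition: str = "test",
    replica: int = 1,
    dt_ps: float = 100.0,
) -> Ensemble:
    """Ensemble whose frame f equals reference + displacements[f]."""
    coords = structure.coords[None, :, :] + displacements
    times = dt_ps * np.arange(coords.shape[0], dtype=float)
    return Ensemble(structure, coords, times, condition=condition, replica=replica)


@pytest.fixture
def toy_structure() -> StructureModel:
    return make_structure(12)


@pytest.fixture
def toy_domain_map() -> DomainMap:
    return DomainMap(
        {
            "head": [("A", 1, 4)],
            "body": [("A", 5, 9)],
            "tail": [("A", 10, 12)],
            "chain": [("A", 1, 12)],
        }
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
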