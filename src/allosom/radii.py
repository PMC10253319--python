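"""Element van der Waals radii used for surface-area calculations.

Bondi-style radii (Å) for the elements that occur in protein/DNA heavy-atom
models. Unknown elements fall back to ``DEFAULT_RADIUS``.
"""

from __future__ import annotations

import numpy as np

#: Bondi-style van der Waals radii, Å.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "MG": 1.73,
    "ZN": 1.39,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "FE": 2.00,
}

DEFAULT_RADIUS: float = 1.70


def radius_for_element(element: str) -> float:
    """Radius (Å) for an element symbol, case-insensitive."""
    return VDW_RADII.get(element.strip().upper(), DEFAULT_RADIUS)


def radii_for_elements(elements) -> np.ndarray:
    """Vector of radii (Å) for an iterable of element symbols."""
    return np.array([radius_for_element(e) for e in elements], dtype=float)
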