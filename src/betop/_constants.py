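"""Shared amino-acid alphabet and atomic radii.

The 20-letter alphabet is kept in one place because the whole feature space
(20 singles, 210 pairs, 1540 triangles) is enumerated from it and every module
must agree on its ordering.
"""

from __future__ import annotations

# One-letter codes, lexicographic. All multiset enumerations derive from this order.
AMINO_ACIDS: tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))

THREE_TO_ONE: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE: dict[str, str] = {v: k for k, v in THREE_TO_ONE.items()}

# NACCESS-like van der Waals radii (Angstrom), keyed by element symbol.
VDW_RADII: dict[str, float] = {"C": 1.87, "N": 1.65, "O": 1.40, "S": 1.85}
DEFAULT_VDW_RADIUS: float = 1.80

# Node / cluster labels.
EPITOPE = "epitope"
NON_EPITOPE = "non-epitope"
BOUNDARY = "boundary"
NOISE = "noise"
UNKNOWN = "unknown"
UNLABELED = "unlabeled"
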