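"""Embedded standard-geometry tables for B-DNA bases.

Coordinates of the base heavy atoms are the published standard reference
frame consensus set (Tsukuba convention): the frame origin sits at the
centre of an idealized Watson-Crick pair, x points toward the major-groove
edge, y along the base long axis toward strand I's sugar, z along the helix
normal.  In this frame an ideal pair has all six intra-base-pair parameters
equal to zero and the complementary base frame is the strand-I frame
rotated 180 degrees about x.

Backbone atoms past C1' are an idealized template (identical for all four
bases, expressed in base-frame coordinates).  They exist so that built
structures look like nucleic acids to downstream tools; their torsions are
NOT realistic and nothing in this package analyses them.
"""

from __future__ import annotations

import numpy as np

# base heavy atoms in the standard reference frame, Angstrom
STANDARD_BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
    },
}

PURINES = ("A", "G")
PYRIMIDINES = ("C", "T")

# ring atoms used for base-frame fitting, fixed order
PURINE_RING = ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")


def ring_atoms(base: str) -> tuple[str, ...]:
    return PURINE_RING if base in PURINES else PYRIMIDINE_RING


# idealized sugar-phosphate template, base-frame coordinates (shared by all
# bases; C1' from the standard set, the rest placed for plausible bonding)
BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "O4'": (-3.515, 4.712, 0.690),
    "C2'": (-2.987, 6.145, -1.230),
    "C3'": (-4.468, 5.878, -1.404),
    "O3'": (-4.783, 5.735, -2.788),
    "C4'": (-4.775, 4.717, -0.467),
    "C5'": (-5.780, 3.738, -1.018),
    "O5'": (-5.253, 2.415, -0.964),
    "P": (-5.944, 1.203, -1.724),
    "OP1": (-7.235, 1.603, -2.327),
    "OP2": (-5.039, 0.603, -2.741),
}

RESIDUE_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
ONE_LETTER = {v: k for k, v in RESIDUE_NAME.items()}
# legacy residue-name dialects seen in deposited nucleic-acid files
ONE_LETTER.update({"ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
                   "A": "A", "C": "C", "G": "G", "T": "T",
                   "DA5": "A", "DC5": "C", "DG5": "G", "DT5": "T",
                   "DA3": "A", "DC3": "C", "DG3": "G", "DT3": "T"})

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

# hydrogen-bond chemistry: donor heavy atom -> names of its hydrogens;
# sp2 ring donors carry one H, exocyclic amines two
BASE_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("H61", "H62")},
    "G": {"N1": ("H1",), "N2": ("H21", "H22")},
    "C": {"N4": ("H41", "H42")},
    "T": {"N3": ("H3",)},
}

BASE_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "A": ("N7", "N1", "N3"),
    "G": ("O6", "N7", "N3"),
    "C": ("O2", "N3"),
    "T": ("O4", "O2"),
}

# heavy-atom neighbours of each polar-H carrier, for idealized H placement
DONOR_NEIGHBOURS: dict[str, dict[str, tuple[str, ...]]] = {
    "A": {"N6": ("C6",)},
    "G": {"N1": ("C2", "C6"), "N2": ("C2",)},
    "C": {"N4": ("C4",)},
    "T": {"N3": ("C2", "C4")},
}

N_H_LENGTH = 1.01  # Angstrom, idealized amine/imino N-H

# Watson-Crick donor/acceptor atom pairs (donor base letter, donor atom,
# acceptor atom on partner); used by the default classification filter
WC_BOND_ATOMS = {
    ("A", "T"): (("A", "N6", "O4"), ("T", "N3", "N1")),
    ("G", "C"): (("G", "N1", "N3"), ("G", "N2", "O2"), ("C", "N4", "O6")),
}


def element_of(atom_name: str) -> str:
    """Element symbol from a PDB v3 nucleic-acid atom name."""
    name = atom_name.strip()
    if name.upper().startswith("PT"):
        return "Pt"
    if name[:2].upper() in ("CL", "BR"):
        return name[:2].capitalize()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


def standard_base_coords(base: str, atoms: tuple[str, ...]) -> np.ndarray:
    table = STANDARD_BASE_ATOMS[base]
    return np.array([table[a] for a in atoms], dtype=float)
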