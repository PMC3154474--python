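"""Geometric hydrogen-bond detection and per-frame species classification.

A hydrogen bond is declared when the donor-acceptor distance is at most
3.5 A and the donor-H-acceptor angle is at least 135 deg; both cutoffs are
inclusive.  Frames of an ensemble are classified by which Pt-amine
contacts they form (by default the O6 of the 3' platinated guanine and the
O4 of the 3'-flanking thymine), giving the class taxonomy
{None, G7-O6, T8-O4, T8-O4+G7-O6} for the 12-mer duplex.  Watson-Crick
bonds are detected like any others but never enter species classification,
which only looks at Pt-amine donors.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np
import pandas as pd

from . import _refgeom
from .errors import PtggError, TopologyError
from .structure_io import DuplexTopology, Ensemble, StructureModel

PT_RESIDUE_NAME = "PTL"  # Pt + carrier-ligand amine HETATM residue


@dataclasses.dataclass
class HBondCriteria:
    """Inclusive geometric cutoffs for hydrogen-bond detection."""

    max_donor_acceptor_distance: float = 3.5  # A
    min_dha_angle: float = 135.0  # deg

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0 < self.min_dha_angle <= 180):
            raise ValueError("angle cutoff must be in (0, 180]")


@dataclasses.dataclass(frozen=True)
class AtomId:
    residue_number: int
    name: str


@dataclasses.dataclass
class HBondRecord:
    donor: AtomId
    hydrogen: AtomId
    acceptor: AtomId
    distance: float
    angle: float
    frame_index: int = 0


@dataclasses.dataclass
class SpeciesDefinition:
    """A named Pt-amine contact: donor pattern plus one acceptor atom.

    ``donor_residue_name`` restricts donors to a residue type (default the
    Pt moiety, so Watson-Crick donors can never satisfy a species).
    """

    name: str
    acceptor_residue_number: int
    acceptor_atom_name: str
    donor_residue_name: str = PT_RESIDUE_NAME


def default_species(topology: DuplexTopology | None = None) -> list[SpeciesDefinition]:
    """The two Pt-amine contacts of the platinated 12-mer: G7-O6 and T8-O4."""
    g3, t3 = 7, 8
    if topology is not None and topology.platinated_pair_indices is not None:
        _, kb = topology.platinated_pair_indices
        g3 = topology.pairs[kb][0]
        t3 = g3 + 1
    return [
        SpeciesDefinition(f"G{g3}-O6", g3, "O6"),
        SpeciesDefinition(f"T{t3}-O4", t3, "O4"),
    ]


def _base_plane_normal(model: StructureModel, residue: int, base: str) -> np.ndarray:
    ring = _refgeom.ring_atoms(base)
    pts = np.asarray([model.atom_position(residue, a) for a in ring])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[2]


def place_polar_hydrogens(model: StructureModel) -> tuple[StructureModel, list[str]]:
    """Add idealized amine/imino hydrogens where they are missing.

    N-H bonds are built at 1.01 A in the base plane with ideal sp2
    geometry: ring N-H along the external bisector of the two ring
    neighbours, exocyclic NH2 at 120 deg from the C-N bond.  Returns the
    augmented model and the names of the hydrogens that were added (so
    callers can flag idealized placement in their output).
    """
    rows = model.atoms.to_dict("records")
    coords = list(model.coords)
    added: list[str] = []
    serial = int(model.atoms["serial"].max()) if len(rows) else 0
    for residue in sorted(set(model.atoms["residue_number"])):
        try:
            base = model.residue_base_letter(residue)
        except KeyError:
            continue
        chain = model.atoms["chain_id"].iloc[model.residue_indices(residue)[0]]
        resname = model.atoms["residue_name"].iloc[model.residue_indices(residue)[0]]
        for donor, hydrogens in _refgeom.BASE_DONORS[base].items():
            missing = [h for h in hydrogens
                       if not _has_atom(model, residue, h)]
            if not missing:
                continue
            n_pos = model.atom_position(residue, donor)
            neighbours = _refgeom.DONOR_NEIGHBOURS[base][donor]
            if len(neighbours) == 2:
                a = model.atom_position(residue, neighbours[0])
                b = model.atom_position(residue, neighbours[1])
                direction = 2 * n_pos - a - b
                direction /= np.linalg.norm(direction)
                h_dirs = {hydrogens[0]: direction}
            else:
                c = model.atom_position(residue, neighbours[0])
                normal = _base_plane_normal(model, residue, base)
                d0 = (c - n_pos) / np.linalg.norm(c - n_pos)
                h_dirs = {}
                for h_name, angle in zip(hydrogens, (120.0, 240.0)):
                    h_dirs[h_name] = _rotate(d0, normal, np.radians(angle))
            for h_name in missing:
                serial += 1
                rows.append({"serial": serial, "name": h_name, "residue_name": resname,
                             "chain_id": chain, "residue_number": residue, "element": "H"})
                coords.append(n_pos + _refgeom.N_H_LENGTH * h_dirs[h_name])
                added.append(f"{residue}:{h_name}")
    if not added:
        return model, []
    return StructureModel(pd.DataFrame(rows), np.asarray(coords), model.model_index), added


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _has_atom(model: StructureModel, residue: int, name: str) -> bool:
    try:
        model.atom_index(residue, name)
        return True
    except KeyError:
        return False


def enumerate_donors_acceptors(
    model: StructureModel,
    topology: DuplexTopology | None = None,
    place_missing_hydrogens: bool = True,
) -> tuple[StructureModel, list[tuple[AtomId, AtomId]], list[AtomId]]:
    """All nucleic-acid donors (as donor-H pairs) and acceptors of a model.

    Donors are base N-H and amine N-H2/N-H3 groups plus Pt carrier-ligand
    amine N-H when a Pt moiety is present; acceptors are the base O and N
    lone-pair sites (G-O6, T-O4, T-O2, G/A-N7, C-O2, ...).  Returns the
    (possibly hydrogen-augmented) model together with the two lists.
    """
    if place_missing_hydrogens:
        model, _ = place_polar_hydrogens(model)
    donors: list[tuple[AtomId, AtomId]] = []
    acceptors: list[AtomId] = []
    for residue in sorted(set(model.atoms["residue_number"])):
        rows = model.residue_indices(residue)
        resname = model.atoms["residue_name"].iloc[rows[0]]
        if resname in _refgeom.ONE_LETTER:
            base = _refgeom.ONE_LETTER[resname]
            for donor, hydrogens in _refgeom.BASE_DONORS[base].items():
                for h in hydrogens:
                    if _has_atom(model, residue, h):
                        donors.append((AtomId(residue, donor), AtomId(residue, h)))
                    else:
                        raise PtggError(
                            f"donor {residue}:{donor} lacks hydrogen {h} and placement is off"
                        )
            for acc in _refgeom.BASE_ACCEPTORS[base]:
                acceptors.append(AtomId(residue, acc))
        else:
            elements = model.atoms["element"].iloc[rows]
            if "Pt" not in set(elements):
                continue
            names = model.atoms["name"].iloc[rows]
            for n_name in [n for n, e in zip(names, elements) if e == "N"]:
                h_names = [h for h, e in zip(names, elements)
                           if e == "H" and h.startswith("H" + n_name[1:])]
                for h in h_names:
                    donors.append((AtomId(residue, n_name), AtomId(residue, h)))
    return model, donors, acceptors


def hbond_geometry(
    d: np.ndarray, h: np.ndarray, a: np.ndarray
) -> tuple[float, float]:
    """Donor-acceptor distance (A) and donor-H-acceptor angle (deg)."""
    dist = float(np.linalg.norm(d - a))
    v1, v2 = d - h, a - h
    cosang = float(np.clip((v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1))
    return dist, float(np.degrees(np.arccos(cosang)))


def detect_hbonds(
    model: StructureModel,
    donors: list[tuple[AtomId, AtomId]],
    acceptors: list[AtomId],
    criteria: HBondCriteria = HBondCriteria(),
    frame_index: int = 0,
) -> list[HBondRecord]:
    """All (donor, H, acceptor) triples inside both inclusive cutoffs.

    Same-residue pairs are skipped; no other filtering happens here (in
    particular Watson-Crick bonds ARE reported).
    """
    records: list[HBondRecord] = []
    for donor, hydrogen in donors:
        d = model.atom_position(donor.residue_number, donor.name)
        h = model.atom_position(hydrogen.residue_number, hydrogen.name)
        for acc in acceptors:
            if acc.residue_number == donor.residue_number:
                continue
            a = model.atom_position(acc.residue_number, acc.name)
            dist, angle = hbond_geometry(d, h, a)
            if dist <= criteria.max_donor_acceptor_distance and \
                    angle >= criteria.min_dha_angle:
                records.append(HBondRecord(donor, hydrogen, acc, dist, angle, frame_index))
    return records


def is_watson_crick(record: HBondRecord, topology: DuplexTopology) -> bool:
    """True when a record joins the two bases of a Watson-Crick pair."""
    pair = {record.donor.residue_number, record.acceptor.residue_number}
    return any({i, j} == pair for i, j in topology.pairs)


@dataclasses.dataclass
class FrameClassTable:
    """Hydrogen-bond species label per frame, plus all species-bond records."""

    labels: list[str]
    species_names: list[str]
    records: list[HBondRecord] = dataclasses.field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.labels)

    def class_names(self) -> list[str]:
        """Canonical label order: singles, combinations, then None."""
        observed = set(self.labels)
        singles = [s for s in self.species_names if s in observed]
        combos = sorted(x for x in observed if "+" in x)
        out = singles + combos
        if "None" in observed or not out:
            out.append("None")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame_index": np.arange(self.n_frames),
                             "class": self.labels})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def combination_label(present: list[str]) -> str:
    """Label for a multi-species frame, e.g. ['G7-O6', 'T8-O4'] -> 'T8-O4+G7-O6'."""
    if not present:
        return "None"
    if len(present) == 1:
        return present[0]
    return "+".join(reversed(present))


def classify_frames(
    ensemble: Ensemble,
    species: list[SpeciesDefinition] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    collect_records: bool = False,
) -> FrameClassTable:
    """Deterministic hydrogen-bond species label for every frame.

    A species is present in a frame when any of its donor hydrogens makes
    the contact within the criteria; frames with two or more species get
    the combination label.  Geometry is evaluated vectorised across the
    whole ensemble.
    """
    if species is None:
        species = default_species(ensemble.topology)
    model0 = ensemble[0]
    atoms = ensemble.atoms
    labels_present = np.zeros((len(ensemble), len(species)), dtype=bool)
    all_records: list[HBondRecord] = []
    for si, sp in enumerate(species):
        donor_rows = atoms[(atoms["residue_name"] == sp.donor_residue_name)
                           & (atoms["element"] == "N")]
        if donor_rows.empty:
            if sp.donor_residue_name == PT_RESIDUE_NAME:
                continue  # Pt-free ensemble: species never present
            raise PtggError(f"species {sp.name}: no donor atoms match "
                            f"{sp.donor_residue_name}")
        try:
            a_idx = model0.atom_index(sp.acceptor_residue_number, sp.acceptor_atom_name)
        except KeyError:
            raise PtggError(f"species {sp.name}: acceptor "
                            f"{sp.acceptor_residue_number}:{sp.acceptor_atom_name} not found")
        pairs = []
        for d_row in donor_rows.itertuples():
            resnum, n_name = d_row.residue_number, d_row.name
            h_rows = atoms[(atoms["residue_number"] == resnum) & (atoms["element"] == "H")
                           & atoms["name"].str.startswith("H" + n_name[1:])]
            for h_row in h_rows.itertuples():
                pairs.append((d_row.Index, h_row.Index, resnum, n_name, h_row.name))
        a_xyz = ensemble.coords[:, a_idx, :]
        for d_i, h_i, resnum, n_name, h_name in pairs:
            d_xyz = ensemble.coords[:, d_i, :]
            h_xyz = ensemble.coords[:, h_i, :]
            dist = np.linalg.norm(d_xyz - a_xyz, axis=1)
            v1 = d_xyz - h_xyz
            v2 = a_xyz - h_xyz
            cosang = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            hit = (dist <= criteria.max_donor_acceptor_distance) & \
                  (angle >= criteria.min_dha_angle)
            labels_present[:, si] |= hit
            if collect_records:
                for fi in np.flatnonzero(hit):
                    all_records.append(HBondRecord(
                        AtomId(resnum, n_name), AtomId(resnum, h_name),
                        AtomId(sp.acceptor_residue_number, sp.acceptor_atom_name),
                        float(dist[fi]), float(angle[fi]), int(fi)))
    labels = [
        combination_label([sp.name for si, sp in enumerate(species) if labels_present[fi, si]])
        for fi in range(len(ensemble))
    ]
    return FrameClassTable(labels, [sp.name for sp in species], all_records)


@dataclasses.dataclass
class FrequencyTable:
    """Percentage of frames per hydrogen-bond class (Table-1-style)."""

    percentages: dict[str, float]
    n_frames: int
    precision: int = 0
    species_names: tuple[str, ...] = ()

    def __post_init__(self):
        total = sum(self.percentages.values())
        # each class can lose/gain half a unit in the last printed digit
        slack = 0.5 * max(1, len(self.percentages)) * 10 ** (-self.precision)
        if abs(total - 100.0) > slack + 1e-9:
            raise ValueError(f"class percentages sum to {total}, not ~100")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"class": list(self.percentages),
                             "frequency_percent": list(self.percentages.values())})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def frequency_table(classes: FrameClassTable, precision: int = 0) -> FrequencyTable:
    """Class occupancy percentages, rounded like a results table (default integers)."""
    if classes.n_frames == 0:
        raise ValueError("need at least one frame")
    counts = Counter(classes.labels)
    out: dict[str, float] = {}
    for name in classes.class_names():
        pct = 100.0 * counts.get(name, 0) / classes.n_frames
        out[name] = round(pct, precision) if precision > 0 else round(pct)
    return FrequencyTable(out, classes.n_frames, precision,
                          tuple(classes.species_names))


def aggregate_bond_occupancy(freq: FrequencyTable, bond_name: str) -> float:
    """Total occupancy of one bond: sum over every class containing it.

    E.g. with classes {G7-O6: 59, T8-O4: 6, T8-O4+G7-O6: 13, None: 20},
    the G7-O6 occupancy is 59 + 13 = 72%.
    """
    known = {part for label in freq.percentages for part in label.split("+")}
    known.update(freq.species_names)
    if bond_name not in known:
        raise KeyError(f"unknown bond {bond_name!r}; classes mention {sorted(known)}")
    return sum(pct for label, pct in freq.percentages.items()
               if bond_name in label.split("+"))
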