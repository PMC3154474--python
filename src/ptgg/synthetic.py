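"""Synthetic duplex-ensemble generator with controlled ground truth.

Stands in for MD trajectories and NMR families of the platinated 12-mer:
frames are built by chaining mid-frame transforms (the exact inverse of
the helical-parameter decomposition in :mod:`ptgg.helix_params`), with
per-frame parameters drawn from configurable Gaussians, an optional Pt
moiety covalently modelled on N7 of the two central guanines, and amine
hydrogens placed to form or break the G7-O6 and T8-O4 contacts at planted
class fractions.  Every generated frame carries its exact parameter draws
and (when planting) its class label, so recovery tests have ground truth.

The backbone is idealized (fixed template per base frame): analyses here
use base atoms, hydrogen-bond geometry and whole-model RMSD, none of
which read backbone torsions.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from . import _refgeom
from .errors import ChemistryError, GenerationError
from .hbonds import (HBondCriteria, PT_RESIDUE_NAME, classify_frames,
                     combination_label, default_species)
from .helix_params import (FLIP_X, PAIR_PARAM_NAMES, STEP_PARAM_NAMES,
                           ParamTable, _rotation_about)
from .structure_io import ATOM_COLUMNS, Ensemble, StructureModel, \
    infer_duplex_topology

FIXTURE_SEQUENCE_I = "CCTCTGGTCTCC"

B_FORM_STEP_MEANS = {"shift": 0.0, "slide": 0.0, "rise": 3.38,
                     "tilt": 0.0, "roll": 0.0, "twist": 36.0}

# free-DNA fluctuation scales (deg / A); the covalent cross-link clamps
# the GG step almost rigid and damps the 3' flank it contacts
DEFAULT_ANGLE_SD = 4.0
DEFAULT_TRANS_SD = 0.25
CORE_ANGLE_SD = 0.75
CORE_TRANS_SD = 0.04
FLANK_ANGLE_SD = 1.5
FLANK_TRANS_SD = 0.08

# the "pt_gg" distortion preset: elevated roll at an unwound, compressed
# platinated step plus the roof-shaped buckling of the two cross-linked
# guanine pairs.  Shipped defaults are config choices giving a plausible
# cross-linked geometry, not literature values.
PT_GG_PRESET = {"roll": 26.0, "twist": 25.0, "slide": -0.9, "shift": -0.3, "rise": 3.2}
PT_GG_BUCKLE = (6.0, -14.0)  # 5' G pair, 3' G pair

PT_N7_DISTANCE = 2.0  # A, Pt-N7 coordination
PT_AMINE_DISTANCE = 2.05  # A, Pt-N(amine)
AMINE_CONE_HALF_ANGLE = np.radians(70.53)  # 180 - 109.47 (sp3 Pt-N-H)

CLASS_NONE = "None"

PT_ATOM_NAMES = ("PT", "N1A", "N2A", "H1A1", "H1A2", "H1A3", "H2A1", "H2A2", "H2A3")
PT_ATOM_ELEMENTS = ("Pt", "N", "N", "H", "H", "H", "H", "H", "H")


def _angle_like(name: str) -> bool:
    return name in ("buckle", "propeller", "opening", "tilt", "roll", "twist")


@dataclasses.dataclass
class GeneratorSpec:
    """Stated world for one synthetic ensemble.

    Parameter means default to ideal B-form (twist 36 deg, rise 3.38 A,
    everything else 0); SDs default to free-DNA fluctuation scales, with
    the platinated core clamped when ``pt`` is on.  ``class_fractions``
    orders classes as (None, G7-O6, T8-O4, both).
    """

    sequence_I: str = FIXTURE_SEQUENCE_I
    n_frames: int = 1
    seed: int = 0
    pt: bool = False
    platinated_residues: tuple[int, int] = (6, 7)
    preset: str | None = None
    pt_aim: str = "none"  # none | g7o6 | t8o4 | both
    class_fractions: tuple[float, float, float, float] | None = None
    ar1: float = 0.0  # optional lag-1 autocorrelation of parameter draws
    pair_means: pd.DataFrame | None = None
    pair_sds: pd.DataFrame | None = None
    step_means: pd.DataFrame | None = None
    step_sds: pd.DataFrame | None = None

    def __post_init__(self):
        n = len(self.sequence_I)
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not (0.0 <= abs(self.ar1) < 1.0):
            raise ValueError("ar1 must lie in (-1, 1)")
        if self.class_fractions is not None:
            f = np.asarray(self.class_fractions, dtype=float)
            if f.shape != (4,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("class_fractions must be 4 non-negative values summing to 1")
        if self.pair_means is None:
            self.pair_means = pd.DataFrame(0.0, index=range(n), columns=PAIR_PARAM_NAMES)
        if self.step_means is None:
            self.step_means = pd.DataFrame(
                {k: [v] * (n - 1) for k, v in B_FORM_STEP_MEANS.items()})[list(STEP_PARAM_NAMES)]
        if self.pair_sds is None:
            self.pair_sds = pd.DataFrame(
                {p: [DEFAULT_ANGLE_SD if _angle_like(p) else DEFAULT_TRANS_SD] * n
                 for p in PAIR_PARAM_NAMES})
        if self.step_sds is None:
            self.step_sds = pd.DataFrame(
                {p: [DEFAULT_ANGLE_SD if _angle_like(p) else DEFAULT_TRANS_SD] * (n - 1)
                 for p in STEP_PARAM_NAMES})
        if np.any(self.pair_sds.to_numpy() < 0) or np.any(self.step_sds.to_numpy() < 0):
            raise ValueError("standard deviations must be non-negative")
        if self.pt:
            self._stiffen_core()
        if self.preset == "pt_gg":
            self._apply_pt_gg()
        elif self.preset is not None:
            raise ValueError(f"unknown preset {self.preset!r}")

    def _central_step(self) -> int:
        # 0-based step index between the two platinated residues
        return self.platinated_residues[0] - 1

    def _stiffen_core(self) -> None:
        ga, gb = self.platinated_residues
        zones = [((ga - 1, gb - 1), (ga - 2, ga - 1), CORE_ANGLE_SD, CORE_TRANS_SD),
                 ((gb,), (gb - 1,), FLANK_ANGLE_SD, FLANK_TRANS_SD)]
        for pairs, steps, ang_sd, trans_sd in zones:
            for p in PAIR_PARAM_NAMES:
                sd = ang_sd if _angle_like(p) else trans_sd
                for k in pairs:
                    if 0 <= k < len(self.pair_sds):
                        self.pair_sds.loc[k, p] = min(self.pair_sds.loc[k, p], sd)
            for p in STEP_PARAM_NAMES:
                sd = ang_sd if _angle_like(p) else trans_sd
                for s in steps:
                    if 0 <= s < len(self.step_sds):
                        self.step_sds.loc[s, p] = min(self.step_sds.loc[s, p], sd)

    def _apply_pt_gg(self) -> None:
        s = self._central_step()
        for p, v in PT_GG_PRESET.items():
            self.step_means.loc[s, p] = v
        ga, gb = self.platinated_residues
        self.pair_means.loc[ga - 1, "buckle"] = PT_GG_BUCKLE[0]
        self.pair_means.loc[gb - 1, "buckle"] = PT_GG_BUCKLE[1]

    @property
    def sequence_II(self) -> str:
        return "".join(_refgeom.COMPLEMENT[b] for b in reversed(self.sequence_I))


@dataclasses.dataclass
class BuiltEnsemble:
    """Generated ensemble plus the exact per-frame ground truth."""

    ensemble: Ensemble
    ground_truth: ParamTable
    class_labels: list[str] | None = None

    def __post_init__(self):
        if self.ground_truth.n_frames != len(self.ensemble):
            raise ValueError("ground-truth rows must match the frame count")
        if self.class_labels is not None and \
                len(self.class_labels) != len(self.ensemble):
            raise ValueError("class labels must match the frame count")


# ---------------------------------------------------------------------------
# fast frame construction: raw (rotation, origin) math plus a precomputed
# per-sequence atom template


def _compose_raw(r1: np.ndarray, o1: np.ndarray, t: np.ndarray, r_deg: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(R2, o2, Rm) from frame 1 and six parameters; no validation."""
    tilt_like, roll_like, omega = np.radians(r_deg)
    gamma = float(np.hypot(tilt_like, roll_like))
    phi = float(np.arctan2(tilt_like, roll_like))
    hinge_local = np.array([np.sin(phi), np.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    a = _rotation_about(hinge_local, -gamma / 2.0) @ _rotation_about(z_hat, -omega / 2.0)
    b = _rotation_about(hinge_local, +gamma / 2.0) @ _rotation_about(z_hat, +omega / 2.0)
    rm = r1 @ a.T
    return rm @ b, o1 + rm @ t, rm


def _split_pair_raw(rm: np.ndarray, om: np.ndarray, t: np.ndarray, r_deg: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(R_flipped_c, o_c, R_w, o_w) from a pair mid-frame and six parameters."""
    tilt_like, roll_like, omega = np.radians(r_deg)
    gamma = float(np.hypot(tilt_like, roll_like))
    phi = float(np.arctan2(tilt_like, roll_like))
    hinge_local = np.array([np.sin(phi), np.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    a = _rotation_about(hinge_local, -gamma / 2.0) @ _rotation_about(z_hat, -omega / 2.0)
    b = _rotation_about(hinge_local, +gamma / 2.0) @ _rotation_about(z_hat, +omega / 2.0)
    half = rm @ t / 2.0
    return rm @ a, om - half, rm @ b, om + half


def _rot_batch(axes: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for (M,3) unit axes and (M,) angles."""
    c = np.cos(angles)[:, None, None]
    s = np.sin(angles)[:, None, None]
    m = axes.shape[0]
    k = np.zeros((m, 3, 3))
    k[:, 0, 1], k[:, 0, 2] = -axes[:, 2], axes[:, 1]
    k[:, 1, 0], k[:, 1, 2] = axes[:, 2], -axes[:, 0]
    k[:, 2, 0], k[:, 2, 1] = -axes[:, 1], axes[:, 0]
    outer = axes[:, :, None] * axes[:, None, :]
    return c * np.eye(3) + s * k + (1 - c) * outer


def _half_transforms_batch(r_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched (A, B) factors of the mid-frame construction for (M,3) angles."""
    tilt, roll, omega = np.radians(r_deg).T
    gamma = np.hypot(tilt, roll)
    phi = np.arctan2(tilt, roll)
    hinge = np.stack([np.sin(phi), np.cos(phi), np.zeros_like(phi)], axis=1)
    z_hat = np.tile(np.array([0.0, 0.0, 1.0]), (len(omega), 1))
    a = _rot_batch(hinge, -gamma / 2.0) @ _rot_batch(z_hat, -omega / 2.0)
    b = _rot_batch(hinge, +gamma / 2.0) @ _rot_batch(z_hat, +omega / 2.0)
    return a, b


def _residue_atoms(base: str) -> list[tuple[str, np.ndarray]]:
    """Atom names and base-frame coordinates of one idealized nucleotide."""
    out = [(name, np.asarray(xyz)) for name, xyz in _refgeom.BACKBONE_TEMPLATE.items()]
    out += [(name, np.asarray(xyz)) for name, xyz in
            _refgeom.STANDARD_BASE_ATOMS[base].items()]
    return out


class _DuplexTemplate:
    """Precomputed atom table and local coordinates for one sequence."""

    def __init__(self, sequence_I: str, pt: bool = False):
        self.sequence_I = sequence_I
        self.pt = pt
        n = len(sequence_I)
        rows = []
        placements: list[tuple[int, str, np.ndarray, slice]] = []  # pair k, strand, locals
        serial = 0
        cursor = 0
        strand_entries = []
        for k in range(n):
            base = sequence_I[k]
            strand_entries.append(("A", k + 1, base, k, "I"))
        for k in reversed(range(n)):
            base = _refgeom.COMPLEMENT[sequence_I[k]]
            strand_entries.append(("B", 2 * n - k, base, k, "II"))
        for chain, resnum, base, k, strand in strand_entries:
            atoms = _residue_atoms(base)
            local = np.array([xyz for _, xyz in atoms])
            sl = slice(cursor, cursor + len(atoms))
            cursor += len(atoms)
            for name, _ in atoms:
                serial += 1
                rows.append((serial, name, _refgeom.RESIDUE_NAME[base], chain,
                             resnum, _refgeom.element_of(name)))
            placements.append((k, strand, local, sl))
        self.n_duplex_atoms = cursor
        if pt:
            resnum = 2 * n + 1
            for name, element in zip(PT_ATOM_NAMES, PT_ATOM_ELEMENTS):
                serial += 1
                rows.append((serial, name, PT_RESIDUE_NAME, "X", resnum, element))
            self.pt_slice = slice(cursor, cursor + len(PT_ATOM_NAMES))
            cursor += len(PT_ATOM_NAMES)
        self.atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
        self.placements = placements
        self.n_atoms = cursor
        self._index = {(r, nm): i for i, (r, nm) in
                       enumerate(zip(self.atoms["residue_number"], self.atoms["name"]))}

    def atom_index(self, residue: int, name: str) -> int:
        return self._index[(residue, name)]

    def duplex_coords(self, pair_params: np.ndarray, step_params: np.ndarray
                      ) -> np.ndarray:
        """Coordinates of the duplex atoms for one frame's parameters."""
        n = len(self.sequence_I)
        mids = [(np.eye(3), np.zeros(3))]
        for s in range(n - 1):
            r2, o2, _ = _compose_raw(mids[-1][0], mids[-1][1],
                                     step_params[s, :3], step_params[s, 3:])
            mids.append((r2, o2))
        frames: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        for k in range(n):
            rm, om = mids[k]
            rc_f, oc, rw, ow = _split_pair_raw(rm, om, pair_params[k, :3],
                                               pair_params[k, 3:])
            frames[(k, "I")] = (rw, ow)
            frames[(k, "II")] = (rc_f @ FLIP_X, oc)
        coords = np.empty((self.n_duplex_atoms, 3))
        for k, strand, local, sl in self.placements:
            rot, origin = frames[(k, strand)]
            coords[sl] = local @ rot.T + origin
        return coords

    def duplex_coords_batch(self, pair_params: np.ndarray, step_params: np.ndarray
                            ) -> np.ndarray:
        """Vectorized ``duplex_coords`` over M frames.

        ``pair_params`` is (M, n, 6) and ``step_params`` (M, n-1, 6);
        returns (M, n_duplex_atoms, 3).
        """
        m = pair_params.shape[0]
        n = len(self.sequence_I)
        rm = np.tile(np.eye(3), (m, 1, 1))
        om = np.zeros((m, 3))
        mids = [(rm, om)]
        for s in range(n - 1):
            a, b = _half_transforms_batch(step_params[:, s, 3:])
            rm_next = mids[-1][0] @ a.transpose(0, 2, 1)
            r2 = rm_next @ b
            o2 = mids[-1][1] + np.einsum("mij,mj->mi", rm_next, step_params[:, s, :3])
            mids.append((r2, o2))
        frames = {}
        for k in range(n):
            a, b = _half_transforms_batch(pair_params[:, k, 3:])
            rmk, omk = mids[k]
            half = np.einsum("mij,mj->mi", rmk, pair_params[:, k, :3]) / 2.0
            frames[(k, "II")] = ((rmk @ a) @ FLIP_X, omk - half)
            frames[(k, "I")] = (rmk @ b, omk + half)
        coords = np.empty((m, self.n_duplex_atoms, 3))
        for k, strand, local, sl in self.placements:
            rot, origin = frames[(k, strand)]
            coords[:, sl] = np.einsum("mij,aj->mai", rot, local) + origin[:, None, :]
        return coords


_TEMPLATE_CACHE: dict[tuple[str, bool], _DuplexTemplate] = {}


def _template(sequence_I: str, pt: bool) -> _DuplexTemplate:
    key = (sequence_I, pt)
    if key not in _TEMPLATE_CACHE:
        _TEMPLATE_CACHE[key] = _DuplexTemplate(sequence_I, pt)
    return _TEMPLATE_CACHE[key]


def _check_range(pair_params: np.ndarray, step_params: np.ndarray) -> None:
    if np.abs(np.concatenate([pair_params[:, :3].ravel(),
                              step_params[:, :3].ravel()])).max() > 6.0 or \
            np.abs(np.concatenate([pair_params[:, 3:].ravel(),
                                   step_params[:, 3:].ravel()])).max() > 85.0:
        raise ValueError("parameters outside the round-trip-validated range "
                         "(|translations| <= 6 A, |angles| <= 85 deg)")


def build_duplex(
    pair_params: pd.DataFrame,
    step_params: pd.DataFrame,
    sequence_I: str = FIXTURE_SEQUENCE_I,
) -> StructureModel:
    """Place standard-geometry bases by chaining mid-frame transforms.

    ``pair_params`` has one row per pair (columns shear..opening),
    ``step_params`` one row per step (columns shift..twist).  Residues are
    numbered 1..n on strand I and n+1..2n on strand II (residue i paired
    with 2n+1-i); the decomposition in :mod:`ptgg.helix_params` recovers
    the inputs exactly.
    """
    n = len(sequence_I)
    if len(pair_params) != n or len(step_params) != n - 1:
        raise ValueError("parameter tables must have n pairs and n-1 steps")
    pair_np = pair_params[list(PAIR_PARAM_NAMES)].to_numpy(dtype=float)
    step_np = step_params[list(STEP_PARAM_NAMES)].to_numpy(dtype=float)
    _check_range(pair_np, step_np)
    tpl = _template(sequence_I, pt=False)
    coords = tpl.duplex_coords(pair_np, step_np)
    return StructureModel(tpl.atoms.copy(), coords)


# ---------------------------------------------------------------------------
# platinum moiety geometry


def _amine_hydrogen_dirs(axis: np.ndarray, ref: np.ndarray, cone_deg: float
                         ) -> list[np.ndarray]:
    e1 = ref - (ref @ axis) * axis
    e1 = e1 / np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    out = []
    for k in range(3):
        theta = np.radians(cone_deg + 120.0 * k)
        out.append(np.cos(AMINE_CONE_HALF_ANGLE) * axis
                   + np.sin(AMINE_CONE_HALF_ANGLE)
                   * (np.cos(theta) * e1 + np.sin(theta) * e2))
    return out


def _pt_coords(
    n7a: np.ndarray, c5a: np.ndarray, c8a: np.ndarray,
    n7b: np.ndarray, c5b: np.ndarray, c8b: np.ndarray,
    o6b: np.ndarray | None, o4t: np.ndarray | None,
    aim: str, cone5_deg: float, cone3_deg: float,
    criteria: HBondCriteria,
) -> np.ndarray:
    """Coordinates of (PT, N1A, N2A, H1A1-3, H2A1-3); see attach_platinum."""
    mid = (n7a + n7b) / 2.0
    sep = n7b - n7a
    half = float(np.linalg.norm(sep)) / 2.0
    if half >= PT_N7_DISTANCE:
        raise GenerationError(
            f"N7-N7 separation {2 * half:.2f} A exceeds twice the Pt-N7 bond "
            "(2.0 A); the duplex lacks the cross-link distortion (use the "
            "'pt_gg' preset or raise central-step roll)")
    lp_a = 2 * n7a - c5a - c8a
    lp_b = 2 * n7b - c5b - c8b
    bisector = lp_a / np.linalg.norm(lp_a) + lp_b / np.linalg.norm(lp_b)
    u = sep / (2.0 * half)
    bisector = bisector - (bisector @ u) * u
    bisector = bisector / np.linalg.norm(bisector)
    pt = mid + float(np.sqrt(PT_N7_DISTANCE ** 2 - half ** 2)) * bisector
    u_a = (n7a - pt) / np.linalg.norm(n7a - pt)
    u_b = (n7b - pt) / np.linalg.norm(n7b - pt)
    plane_normal = np.cross(u_a, u_b)
    plane_normal = plane_normal / np.linalg.norm(plane_normal)
    # square plane: each amine trans to one N7
    n_amine5 = pt - PT_AMINE_DISTANCE * u_b  # trans to the 3' G, sits 5' side
    n_amine3 = pt - PT_AMINE_DISTANCE * u_a  # trans to the 5' G, sits 3' side
    axis5 = (n_amine5 - pt) / np.linalg.norm(n_amine5 - pt)
    axis3 = (n_amine3 - pt) / np.linalg.norm(n_amine3 - pt)
    h5 = [n_amine5 + _refgeom.N_H_LENGTH * d
          for d in _amine_hydrogen_dirs(axis5, plane_normal, cone5_deg)]
    h3 = [n_amine3 + _refgeom.N_H_LENGTH * d
          for d in _amine_hydrogen_dirs(axis3, plane_normal, cone3_deg)]
    if aim not in ("none", "g7o6", "t8o4", "both"):
        raise ValueError(f"unknown aim {aim!r}")
    targets = []
    if aim in ("g7o6", "both"):
        targets.append(("O6", o6b))
    if aim in ("t8o4", "both"):
        if o4t is None:
            raise GenerationError("no 3' flanking thymine O4 to aim at")
        targets.append(("O4", o4t))
    for slot, (name, acc) in enumerate(targets):
        dist = float(np.linalg.norm(n_amine3 - acc))
        if dist > criteria.max_donor_acceptor_distance:
            raise GenerationError(
                f"3'-amine N is {dist:.2f} A from {name}; the {name} contact "
                "cannot be formed under the distance cutoff")
        h3[slot] = n_amine3 + _refgeom.N_H_LENGTH * (acc - n_amine3) / dist
    return np.array([pt, n_amine5, n_amine3, *h5, *h3])


def attach_platinum(
    model: StructureModel,
    aim: str = "none",
    g_residues: tuple[int, int] = (6, 7),
    cone5_deg: float = 0.0,
    cone3_deg: float = 0.0,
    criteria: HBondCriteria = HBondCriteria(),
) -> StructureModel:
    """Model a Pt moiety cross-linking N7 of two adjacent guanines.

    Pt sits on the major-groove bisector of the two N7 lone pairs at
    2.0 A from each N7; two amine nitrogens complete the square plane.
    ``aim`` orients the 3'-amine hydrogens: "g7o6" and/or "t8o4" point a
    hydrogen straight at that acceptor (forming the contact), "both" aims
    two, "none" leaves all hydrogens on their sp3 cones at the knob
    angles.  Raises :class:`GenerationError` when an aimed acceptor is
    beyond the donor-acceptor cutoff so the contact cannot exist.
    """
    ga, gb = g_residues
    for g in (ga, gb):
        if model.residue_base_letter(g) not in _refgeom.PURINES:
            raise ChemistryError(f"residue {g} is not a purine; cannot platinate N7")
    o6b = model.atom_position(gb, "O6") if model.residue_base_letter(gb) == "G" else None
    o4t = None
    try:
        if model.residue_base_letter(gb + 1) == "T":
            o4t = model.atom_position(gb + 1, "O4")
    except KeyError:
        pass
    new_coords = _pt_coords(
        model.atom_position(ga, "N7"), model.atom_position(ga, "C5"),
        model.atom_position(ga, "C8"),
        model.atom_position(gb, "N7"), model.atom_position(gb, "C5"),
        model.atom_position(gb, "C8"),
        o6b, o4t, aim, cone5_deg, cone3_deg, criteria)
    serial = int(model.atoms["serial"].max())
    resnum = int(model.atoms["residue_number"].max()) + 1
    rows = [(serial + 1 + i, name, PT_RESIDUE_NAME, "X", resnum, element)
            for i, (name, element) in enumerate(zip(PT_ATOM_NAMES, PT_ATOM_ELEMENTS))]
    atoms = pd.concat([model.atoms, pd.DataFrame(rows, columns=ATOM_COLUMNS)],
                      ignore_index=True)
    coords = np.vstack([model.coords, new_coords])
    return StructureModel(atoms, coords, model.model_index)


# ---------------------------------------------------------------------------
# sampling and class planting


def _ground_truth_columns(spec: GeneratorSpec) -> list[str]:
    n = len(spec.sequence_I)
    cols = []
    for k in range(n):
        for p in PAIR_PARAM_NAMES:
            cols.append(f"pair_{k + 1}_{2 * n - k}_{p}")
    for s in range(n - 1):
        for p in STEP_PARAM_NAMES:
            cols.append(f"step_{s + 1}_{s + 2}_{p}")
    return cols


def _draw_parameters(spec: GeneratorSpec, rng: np.random.Generator
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Gaussian draws; optional AR(1) correlation across frames."""
    n, m = len(spec.sequence_I), spec.n_frames
    pair_mean = spec.pair_means[list(PAIR_PARAM_NAMES)].to_numpy(dtype=float)
    pair_sd = spec.pair_sds[list(PAIR_PARAM_NAMES)].to_numpy(dtype=float)
    step_mean = spec.step_means[list(STEP_PARAM_NAMES)].to_numpy(dtype=float)
    step_sd = spec.step_sds[list(STEP_PARAM_NAMES)].to_numpy(dtype=float)
    z_pair = rng.standard_normal((m, n, 6))
    z_step = rng.standard_normal((m, n - 1, 6))
    if spec.ar1 != 0.0:
        phi = spec.ar1
        scale = np.sqrt(1.0 - phi * phi)
        for t in range(1, m):
            z_pair[t] = phi * z_pair[t - 1] + scale * z_pair[t]
            z_step[t] = phi * z_step[t - 1] + scale * z_step[t]
    return pair_mean + pair_sd * z_pair, step_mean + step_sd * z_step


def _ground_truth_table(spec: GeneratorSpec, pair_draws: np.ndarray,
                        step_draws: np.ndarray) -> ParamTable:
    n = len(spec.sequence_I)
    m = spec.n_frames
    flat = np.concatenate([pair_draws.reshape(m, -1), step_draws.reshape(m, -1)], axis=1)
    truth = pd.DataFrame(flat, columns=_ground_truth_columns(spec))
    truth.insert(0, "frame_index", np.arange(m))
    return ParamTable(truth, tuple(range(n)), tuple(range(n - 1)))


def sample_ensemble(spec: GeneratorSpec) -> BuiltEnsemble:
    """Draw ``n_frames`` independent duplex conformers from the spec.

    Each parameter is Normal(mean, SD); frames are built by chaining
    mid-frame transforms (plus the Pt moiety when requested) and the
    exact draws are retained as ground truth.  Bit-reproducible by seed.
    """
    rng = np.random.default_rng(spec.seed)
    pair_draws, step_draws = _draw_parameters(spec, rng)
    _check_range(pair_draws.reshape(-1, 6), step_draws.reshape(-1, 6))
    tpl = _template(spec.sequence_I, spec.pt)
    ga, gb = spec.platinated_residues
    criteria = HBondCriteria()
    coords = np.empty((spec.n_frames, tpl.n_atoms, 3))
    coords[:, :tpl.n_duplex_atoms] = tpl.duplex_coords_batch(pair_draws, step_draws)
    if spec.pt:
        has_t3 = spec.sequence_I[gb] == "T"
        for f in range(spec.n_frames):
            duplex = coords[f, :tpl.n_duplex_atoms]
            coords[f, tpl.pt_slice] = _pt_coords(
                *(duplex[tpl.atom_index(r, nm)] for r in (ga, gb)
                  for nm in ("N7", "C5", "C8")),
                duplex[tpl.atom_index(gb, "O6")],
                duplex[tpl.atom_index(gb + 1, "O4")] if has_t3 else None,
                spec.pt_aim, 0.0, 0.0, criteria)
    topo = infer_duplex_topology(
        StructureModel(tpl.atoms, coords[0]),
        spec.platinated_residues if spec.pt else None)
    ensemble = Ensemble(tpl.atoms.copy(), coords, topology=topo, source_tag="synthetic")
    return BuiltEnsemble(ensemble, _ground_truth_table(spec, pair_draws, step_draws))


def class_names_for(spec: GeneratorSpec) -> list[str]:
    """Class labels in fraction order (None, G7-O6, T8-O4, both) for this spec."""
    gb = spec.platinated_residues[1]
    single = [f"G{gb}-O6", f"T{gb + 1}-O4"]
    return [CLASS_NONE, single[0], single[1], combination_label(single)]


def _species_flags(pt_block: np.ndarray, o6: np.ndarray, o4: np.ndarray,
                   criteria: HBondCriteria) -> tuple[bool, bool]:
    """Which of the two Pt-amine contacts the 9-atom Pt block realizes."""
    flags = [False, False]
    for n_idx, h_indices in ((1, (3, 4, 5)), (2, (6, 7, 8))):
        n_pos = pt_block[n_idx]
        for acc_i, acc in enumerate((o6, o4)):
            if np.linalg.norm(n_pos - acc) > criteria.max_donor_acceptor_distance:
                continue
            for h_i in h_indices:
                h = pt_block[h_i]
                v1, v2 = n_pos - h, acc - h
                cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if angle >= criteria.min_dha_angle:
                    flags[acc_i] = True
                    break
    return flags[0], flags[1]


_AIM_FOR_CLASS = ("none", "g7o6", "t8o4", "both")
_WANT_FLAGS = ((False, False), (True, False), (False, True), (True, True))


def _realize_class_coords(duplex: np.ndarray, tpl: _DuplexTemplate,
                          class_idx: int, spec: GeneratorSpec,
                          criteria: HBondCriteria) -> np.ndarray:
    """Pt-block coordinates whose contacts match the planted class exactly.

    Aimed contacts are exact by construction; the free cone angles are
    searched over a deterministic grid until the realized contact flags
    match.  Fails loud when no knob setting realizes the class.
    """
    ga, gb = spec.platinated_residues
    args = [duplex[tpl.atom_index(r, nm)] for r in (ga, gb) for nm in ("N7", "C5", "C8")]
    o6 = duplex[tpl.atom_index(gb, "O6")]
    o4 = duplex[tpl.atom_index(gb + 1, "O4")]
    aim = _AIM_FOR_CLASS[class_idx]
    want = _WANT_FLAGS[class_idx]
    for cone3, cone5 in itertools.product(range(0, 360, 20), (0, 60, 180, 300)):
        block = _pt_coords(*args, o6, o4, aim, float(cone5), float(cone3), criteria)
        if _species_flags(block, o6, o4, criteria) == want:
            return block
    raise GenerationError(
        f"no amine-hydrogen orientation realizes class index {class_idx} "
        "under the current criteria")


def plant_hbond_classes(spec: GeneratorSpec) -> BuiltEnsemble:
    """Generate an ensemble whose frames carry planted hydrogen-bond classes.

    Per frame a class is drawn from ``spec.class_fractions`` (order: None,
    G7-O6, T8-O4, both) and the 3'-amine hydrogens are placed to realize
    exactly that class; the full ensemble is re-classified at the end and
    any mismatch with the plant is a hard error.
    """
    if spec.class_fractions is None:
        raise ValueError("spec.class_fractions is required for planting")
    if not spec.pt:
        raise ValueError("planting requires pt=True")
    gb = spec.platinated_residues[1]
    if spec.sequence_I[gb] != "T":
        raise GenerationError("class planting needs a 3'-flanking thymine (the O4 acceptor)")
    criteria = HBondCriteria()
    rng = np.random.default_rng(spec.seed)
    pair_draws, step_draws = _draw_parameters(spec, rng)
    _check_range(pair_draws.reshape(-1, 6), step_draws.reshape(-1, 6))
    drawn = rng.choice(4, size=spec.n_frames, p=np.asarray(spec.class_fractions))
    names = class_names_for(spec)
    tpl = _template(spec.sequence_I, pt=True)
    coords = np.empty((spec.n_frames, tpl.n_atoms, 3))
    coords[:, :tpl.n_duplex_atoms] = tpl.duplex_coords_batch(pair_draws, step_draws)
    labels = []
    for f in range(spec.n_frames):
        coords[f, tpl.pt_slice] = _realize_class_coords(
            coords[f, :tpl.n_duplex_atoms], tpl, int(drawn[f]), spec, criteria)
        labels.append(names[drawn[f]])
    topo = infer_duplex_topology(StructureModel(tpl.atoms, coords[0]),
                                 spec.platinated_residues)
    ensemble = Ensemble(tpl.atoms.copy(), coords, topology=topo,
                        source_tag="synthetic-planted")
    verify = classify_frames(ensemble, default_species(topo), criteria)
    mismatches = sum(1 for a, b in zip(verify.labels, labels) if a != b)
    if mismatches:
        raise GenerationError(
            f"classifier disagrees with the plant on {mismatches} frames")
    return BuiltEnsemble(ensemble, _ground_truth_table(spec, pair_draws, step_draws),
                         labels)
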