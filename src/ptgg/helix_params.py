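"""Intra-base-pair and base-pair-step helical parameters from coordinates.

The decomposition is the standard-reference-frame mid-frame convention
(CEHS-style): each base gets an orthonormal frame by least-squares
superposition of the standard base onto its ring atoms; the two frames of
a pair (the complementary frame flipped 180 deg about its x axis) are
combined symmetrically about their mid-frame to give shear, stretch,
stagger (A) and buckle, propeller, opening (deg); pair mid-frames of
consecutive pairs combine the same way to give shift, slide, rise and
tilt, roll, twist.  The decomposition is exactly invertible (see
:func:`compose_frames`), which is what the duplex builder in
``ptgg.synthetic`` relies on.

This is deliberately not the curvilinear-axis algorithm of CURVES 5.3:
values are comparable but not bit-identical for B-form DNA; the mid-frame
convention is fully published and invertible.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import _refgeom
from .errors import FrameFitError, OrientationError, TopologyError
from .structure_io import DuplexTopology, Ensemble, StructureModel
from .superpose import kabsch

FLIP_X = np.diag([1.0, -1.0, -1.0])  # 180 deg rotation about the frame x axis

PAIR_PARAM_NAMES = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")
STEP_PARAM_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")


@dataclasses.dataclass
class BaseFrame:
    """Orthonormal reference frame of one base (or one base pair).

    ``axes`` columns are the x (major-groove edge), y (long axis) and z
    (normal) directions in global coordinates; ``origin`` in Angstrom.
    """

    origin: np.ndarray
    axes: np.ndarray
    residual: float = 0.0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be 3x3")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed")

    def flipped(self) -> "BaseFrame":
        """Frame rotated 180 deg about its own x axis."""
        return BaseFrame(self.origin, self.axes @ FLIP_X, self.residual)


@dataclasses.dataclass
class BasePairParams:
    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.shear, self.stretch, self.stagger,
                self.buckle, self.propeller, self.opening)


@dataclasses.dataclass
class StepParams:
    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist)


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit axis (Rodrigues)."""
    x, y, z = axis
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cc = 1.0 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])


def _wrap_angle_deg(a: float) -> float:
    """Map to (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def decompose_frames(
    frame1: BaseFrame, frame2: BaseFrame
) -> tuple[np.ndarray, np.ndarray, BaseFrame]:
    """Mid-frame decomposition of the transform from frame1 to frame2.

    Returns ``(translations, rotations_deg, mid_frame)`` where the
    translations are the origin displacement expressed in mid-frame
    coordinates and the rotations are the (tilt-like, roll-like,
    twist-like) angles in degrees.
    """
    r1, r2 = frame1.axes, frame2.axes
    z1, z2 = r1[:, 2], r2[:, 2]
    if float(z1 @ z2) < 0.0:
        raise OrientationError("frame normals are anti-aligned; check strand sense/flip")
    cross = np.cross(z1, z2)
    sin_g = np.linalg.norm(cross)
    gamma = float(np.arctan2(sin_g, float(z1 @ z2)))
    hinge = cross / sin_g if sin_g > 1e-12 else r1[:, 0]
    r1p = _rotation_about(hinge, +gamma / 2.0) @ r1
    r2p = _rotation_about(hinge, -gamma / 2.0) @ r2
    zm = r1p[:, 2]
    xm = r1p[:, 0] + r2p[:, 0]
    xm = xm - (xm @ zm) * zm
    nx = np.linalg.norm(xm)
    if nx < 1e-12:
        raise OrientationError("mid-frame x axis is degenerate (twist near 180 deg)")
    xm = xm / nx
    ym = np.cross(zm, xm)
    mid_axes = np.column_stack([xm, ym, zm])
    omega = float(np.arctan2(float(np.cross(r1p[:, 0], r2p[:, 0]) @ zm),
                             float(r1p[:, 0] @ r2p[:, 0])))
    phi = float(np.arctan2(float(np.cross(hinge, ym) @ zm), float(hinge @ ym)))
    roll_like = gamma * np.cos(phi)
    tilt_like = gamma * np.sin(phi)
    translations = mid_axes.T @ (frame2.origin - frame1.origin)
    rotations = np.degrees([tilt_like, roll_like, omega])
    mid = BaseFrame((frame1.origin + frame2.origin) / 2.0, mid_axes)
    return translations, rotations, mid


def compose_frames(
    frame1: BaseFrame,
    translations: np.ndarray,
    rotations_deg: np.ndarray,
) -> tuple[BaseFrame, BaseFrame]:
    """Exact inverse of :func:`decompose_frames`.

    Given frame1 and the six parameters, returns ``(frame2, mid_frame)``
    such that decomposing (frame1, frame2) recovers the parameters.
    """
    t = np.asarray(translations, dtype=float)
    tilt_like, roll_like, omega = np.radians(np.asarray(rotations_deg, dtype=float))
    gamma = float(np.hypot(tilt_like, roll_like))
    phi = float(np.arctan2(tilt_like, roll_like))
    hinge_local = np.array([np.sin(phi), np.cos(phi), 0.0])
    z_hat = np.array([0.0, 0.0, 1.0])
    a = _rotation_about(hinge_local, -gamma / 2.0) @ _rotation_about(z_hat, -omega / 2.0)
    b = _rotation_about(hinge_local, +gamma / 2.0) @ _rotation_about(z_hat, +omega / 2.0)
    mid_axes = frame1.axes @ a.T
    r2 = mid_axes @ b
    o2 = frame1.origin + mid_axes @ t
    mid = BaseFrame((frame1.origin + o2) / 2.0, mid_axes)
    return BaseFrame(o2, r2), mid


def fit_base_frame(model: StructureModel, residue: int) -> BaseFrame:
    """Fit the standard reference frame to a residue's base ring atoms.

    The frame is the least-squares rigid superposition of the standard
    base geometry onto the observed ring atoms; the fit residual (RMSD, A)
    is stored on the frame.
    """
    base = model.residue_base_letter(residue)
    ring = _refgeom.ring_atoms(base)
    obs = []
    for name in ring:
        try:
            obs.append(model.atom_position(residue, name))
        except KeyError:
            raise FrameFitError(f"residue {residue} is missing ring atom {name}")
    obs = np.asarray(obs)
    std = _refgeom.standard_base_coords(base, ring)
    sup = kabsch(std, obs)
    return BaseFrame(origin=sup.translation, axes=sup.rotation, residual=sup.rmsd)


def base_pair_params(frame_w: BaseFrame, frame_c: BaseFrame) -> BasePairParams:
    """Six intra-base-pair parameters from the two base frames.

    ``frame_c`` is the complementary (strand II) base frame; it is flipped
    180 deg about its x axis before the symmetric mid-frame combination.
    Parameters describe the strand-I base relative to the flipped
    complementary base.
    """
    t, r, _ = decompose_frames(frame_c.flipped(), frame_w)
    return BasePairParams(shear=t[0], stretch=t[1], stagger=t[2],
                          buckle=_wrap_angle_deg(r[0]),
                          propeller=_wrap_angle_deg(r[1]),
                          opening=_wrap_angle_deg(r[2]))


def pair_frame(frame_w: BaseFrame, frame_c: BaseFrame) -> BaseFrame:
    """Mid-frame of a base pair (used as the reference for step parameters)."""
    _, _, mid = decompose_frames(frame_c.flipped(), frame_w)
    return mid


def step_params(pair_frame_1: BaseFrame, pair_frame_2: BaseFrame) -> StepParams:
    """Six base-pair-step parameters between two consecutive pair frames."""
    t, r, _ = decompose_frames(pair_frame_1, pair_frame_2)
    return StepParams(shift=t[0], slide=t[1], rise=t[2],
                      tilt=_wrap_angle_deg(r[0]),
                      roll=_wrap_angle_deg(r[1]),
                      twist=_wrap_angle_deg(r[2]))


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through ``points`` (SVD fit)."""
    centered = points - points.mean(axis=0)
    _, s, vt = np.linalg.svd(centered)
    if s[1] < 1e-9:
        raise FrameFitError("ring atoms are collinear; plane is degenerate")
    return vt[2]


def gg_plane_dihedral(model: StructureModel, residue_a: int, residue_b: int) -> float:
    """Angle (deg, folded to [0, 90]) between two purine base planes.

    Used for the inter-guanine plane angle of the platinated GG step, the
    hallmark out-of-plane distortion of the cross-link.
    """
    normals = []
    for residue in (residue_a, residue_b):
        base = model.residue_base_letter(residue)
        if base not in _refgeom.PURINES:
            raise FrameFitError(f"residue {residue} ({base}) is not a purine")
        ring = _refgeom.ring_atoms(base)
        try:
            pts = np.asarray([model.atom_position(residue, a) for a in ring])
        except KeyError as exc:
            raise FrameFitError(f"residue {residue}: {exc}")
        normals.append(_plane_normal(pts))
    cosang = abs(float(np.clip(normals[0] @ normals[1], -1.0, 1.0)))
    return float(np.degrees(np.arccos(cosang)))


def _segment_axis(frames: list[BaseFrame]) -> np.ndarray:
    """Best-fit axis of a run of pair frames from their origins and normals.

    Principal eigenvector of the scatter of the pair normals plus the
    normalized origin increments, oriented along the mean normal.
    """
    normals = np.array([f.axes[:, 2] for f in frames])
    vecs = [n for n in normals]
    origins = np.array([f.origin for f in frames])
    for d in np.diff(origins, axis=0):
        norm = np.linalg.norm(d)
        if norm > 1e-9:
            vecs.append(d / norm)
    v = np.asarray(vecs)
    scatter = v.T @ v
    eigval, eigvec = np.linalg.eigh(scatter)
    axis = eigvec[:, -1]
    if axis @ normals.mean(axis=0) < 0:
        axis = -axis
    return axis


def bend_angle(model: StructureModel, topology: DuplexTopology) -> float:
    """Global bend (deg): angle between the entry and exit helix axes.

    The entry axis is fitted to the first four pair frames, the exit axis
    to the last four.
    """
    if topology.n_pairs < 8:
        raise TopologyError("bend angle needs at least 4 pairs in each terminal segment")
    frames = []
    for i, j in topology.pairs:
        fw = fit_base_frame(model, i)
        fc = fit_base_frame(model, j)
        frames.append(pair_frame(fw, fc))
    axis_in = _segment_axis(frames[:4])
    axis_out = _segment_axis(frames[-4:])
    cosang = float(np.clip(axis_in @ axis_out, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


@dataclasses.dataclass
class ParamTable:
    """Per-frame helical parameters for designated pairs and steps.

    ``data`` has one row per frame with a ``frame_index`` column and one
    column per parameter, named like ``pair_7_18_propeller`` or
    ``step_6_7_roll`` (residue numbers in the continuous 1..24 scheme).
    """

    data: pd.DataFrame
    pair_indices: tuple[int, ...]
    step_indices: tuple[int, ...]

    @property
    def n_frames(self) -> int:
        return len(self.data)

    def parameter_names(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("frame_index", "run_id")]

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pair_indices=(), step_indices=()) -> "ParamTable":
        return cls(pd.read_csv(path, sep="\t"),
                   tuple(pair_indices), tuple(step_indices))


def default_designation(topology: DuplexTopology) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Central four base pairs and the steps between them.

    Terminal pairs are computed on request but excluded by default: the
    analyses of interest concern the platinated core of the duplex.
    """
    n = topology.n_pairs
    if n < 4:
        raise TopologyError("need at least 4 pairs for the central designation")
    pairs = tuple(range(n // 2 - 2, n // 2 + 2))
    steps = tuple(range(n // 2 - 2, n // 2 + 1))
    return pairs, steps


def _batched_base_frames(
    ensemble: Ensemble, residue: int
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one residue's base frame across all models at once.

    Returns (rotations (M,3,3), origins (M,3)); vectorized Kabsch via
    batched SVD.
    """
    model0 = ensemble[0]
    base = model0.residue_base_letter(residue)
    ring = _refgeom.ring_atoms(base)
    try:
        idx = np.array([model0.atom_index(residue, a) for a in ring])
    except KeyError as exc:
        raise FrameFitError(f"residue {residue}: {exc}")
    obs = ensemble.coords[:, idx, :]  # (M, k, 3)
    std = _refgeom.standard_base_coords(base, ring)
    std_c = std - std.mean(axis=0)
    mu = obs.mean(axis=1, keepdims=True)
    obs_c = obs - mu
    h = np.einsum("ki,mkj->mij", std_c, obs_c) / len(ring)
    u, _, vt = np.linalg.svd(h)
    det = np.linalg.det(np.transpose(vt, (0, 2, 1)) @ np.transpose(u, (0, 2, 1)))
    flip = np.repeat(np.eye(3)[None], len(det), axis=0)
    flip[:, 2, 2] = np.sign(det)
    rot = np.transpose(vt, (0, 2, 1)) @ flip @ np.transpose(u, (0, 2, 1))
    # the standard-frame origin is the zero vector, so the fitted frame
    # origin is wherever the superposition maps it
    origins = mu[:, 0, :] - np.einsum("mij,j->mi", rot, std.mean(axis=0))
    return rot, origins


def compute_param_table(
    ensemble: Ensemble,
    designation: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
    include_gg_dihedral: bool = False,
    include_bend: bool = False,
) -> ParamTable:
    """One row of helical parameters per model of the ensemble.

    ``designation`` is ``(pair_indices, step_indices)`` into
    ``topology.pairs`` / ``topology.steps``; the default is the central
    four pairs and the central steps.  Optionally adds the platinated-GG
    plane angle (requires ``topology.platinated_pair_indices``) and the
    global bend.
    """
    topo = ensemble.topology
    if topo is None:
        raise TopologyError("ensemble has no topology; run infer_duplex_topology first")
    if designation is None:
        designation = default_designation(topo)
    pair_idx, step_idx = (tuple(designation[0]), tuple(designation[1]))
    for k in pair_idx:
        if not (0 <= k < topo.n_pairs):
            raise TopologyError(f"pair index {k} out of range")
    for s in step_idx:
        if not (0 <= s < len(topo.steps)):
            raise TopologyError(f"step index {s} out of range")

    needed_pairs = sorted(set(pair_idx) | {p for s in step_idx for p in topo.steps[s]})
    # batch-fit frames for every residue involved
    frames: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in needed_pairs:
        for residue in topo.pairs[k]:
            frames[residue] = _batched_base_frames(ensemble, residue)

    m = len(ensemble)
    columns: dict[str, np.ndarray] = {"frame_index": np.arange(m)}
    for name in PAIR_PARAM_NAMES:
        for k in pair_idx:
            columns[f"pair_{topo.pair_label(k)}_{name}"] = np.empty(m)
    for name in STEP_PARAM_NAMES:
        for s in step_idx:
            columns[f"step_{topo.step_label(s)}_{name}"] = np.empty(m)

    pair_mid: dict[int, list[BaseFrame]] = {k: [] for k in needed_pairs}
    for i in range(m):
        for k in needed_pairs:
            ri, rj = topo.pairs[k]
            fw = BaseFrame(frames[ri][1][i], frames[ri][0][i])
            fc = BaseFrame(frames[rj][1][i], frames[rj][0][i])
            t, r, mid = decompose_frames(fc.flipped(), fw)
            pair_mid[k].append(mid)
            if k in pair_idx:
                label = topo.pair_label(k)
                for v, name in zip((*t, *(map(_wrap_angle_deg, r))),
                                   PAIR_PARAM_NAMES):
                    columns[f"pair_{label}_{name}"][i] = v
        for s in step_idx:
            a, b = topo.steps[s]
            try:
                t, r, _ = decompose_frames(pair_mid[a][i], pair_mid[b][i])
            except OrientationError as exc:
                raise OrientationError(f"frame {i}, step {topo.step_label(s)}: {exc}")
            label = topo.step_label(s)
            for v, name in zip((*t, *(map(_wrap_angle_deg, r))), STEP_PARAM_NAMES):
                columns[f"step_{label}_{name}"][i] = v

    if include_gg_dihedral:
        if topo.platinated_pair_indices is None:
            raise TopologyError("gg dihedral requested but no platinated pairs in topology")
        ka, kb = topo.platinated_pair_indices
        ra, rb = topo.pairs[ka][0], topo.pairs[kb][0]
        columns["gg_dihedral"] = np.array([
            gg_plane_dihedral(ensemble[i], ra, rb) for i in range(m)
        ])
    if include_bend:
        columns["bend"] = np.array([bend_angle(ensemble[i], topo) for i in range(m)])

    return ParamTable(pd.DataFrame(columns), pair_idx, step_idx)
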