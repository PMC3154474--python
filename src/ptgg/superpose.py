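"""Rigid-body superposition, ensemble RMSD statistics and centroids.

All superpositions are least-squares proper rotations (Kabsch); reflections
are excluded.  RMSD statistics follow the conventions used when reporting
NMR-family precision: per-model RMSD to an iteratively converged mean
structure, and mean pairwise RMSD for centroid extraction.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .errors import ConvergenceError
from .structure_io import Ensemble, StructureModel, Selector, select_atoms

# atomic masses for mass-weighted RMSD (Da)
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974, "Pt": 195.08}


@dataclasses.dataclass
class Superposition:
    """Optimal rigid transform mapping a mobile point set onto a target."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


def kabsch(
    mobile: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
) -> Superposition:
    """Least-RMSD proper rotation + translation of ``mobile`` onto ``target``.

    With ``weights`` the weighted RMSD is minimized (weights need not be
    normalized).  Degenerate (e.g. collinear) point sets produce a warning
    but still return the optimizer.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    mu_m = w @ mobile
    mu_t = w @ target
    pm = mobile - mu_m
    pt = target - mu_t
    h = (pm * w[:, None]).T @ pt
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        warnings.warn("near-degenerate point set; superposition is ill-conditioned")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = pm @ rot.T
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - pt) ** 2)))
    translation = mu_t - rot @ mu_m
    return Superposition(rotation=rot, translation=translation, rmsd=rmsd)


def _pairwise_rmsd(a: np.ndarray, b: np.ndarray, weights: np.ndarray | None = None) -> float:
    return kabsch(a, b, weights=weights).rmsd


def _apply_selection(ensemble: Ensemble, selection: Selector | None) -> Ensemble:
    if selection is None:
        return ensemble
    return select_atoms(ensemble, selection)


def atom_masses(ensemble: Ensemble) -> np.ndarray:
    return np.array([_MASSES.get(e, 12.0) for e in ensemble.atoms["element"]])


def mean_structure(
    ensemble: Ensemble,
    selection: Selector | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> StructureModel:
    """Iteratively superposed coordinate-average structure.

    Starting from model 1, every model is superposed (on ``selection``)
    onto the current mean and the coordinate average is recomputed, until
    the mean moves less than ``tol`` Angstrom.  Deterministic given model
    order.
    """
    if len(ensemble) < 2:
        raise ValueError("mean structure needs at least 2 models")
    sub = _apply_selection(ensemble, selection)
    full = ensemble.coords
    sel_mean = sub.coords[0].copy()
    full_mean = full[0].copy()
    for _ in range(max_iter):
        moved_full = np.empty_like(full)
        moved_sel = np.empty_like(sub.coords)
        for i in range(len(ensemble)):
            sup = kabsch(sub.coords[i], sel_mean)
            moved_sel[i] = sup.apply(sub.coords[i])
            moved_full[i] = sup.apply(full[i])
        new_sel = moved_sel.mean(axis=0)
        new_full = moved_full.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_sel - sel_mean) ** 2, axis=1))))
        sel_mean, full_mean = new_sel, new_full
        if shift < tol:
            return StructureModel(ensemble.atoms, full_mean, model_index=-1)
    raise ConvergenceError(f"mean structure did not converge in {max_iter} iterations")


@dataclasses.dataclass
class FamilyRmsdReport:
    """Per-model RMSD of an ensemble to its converged mean structure."""

    per_model: np.ndarray
    mean: float
    sd: float
    selection_tag: str

    def __post_init__(self):
        self.per_model = np.asarray(self.per_model, dtype=float)
        assert abs(self.per_model.mean() - self.mean) < 1e-9


def family_rmsd(
    ensemble: Ensemble,
    selection: Selector | None = None,
    selection_tag: str = "all atoms",
) -> FamilyRmsdReport:
    """RMSD of each model to the family mean, as quoted for NMR families."""
    sub = _apply_selection(ensemble, selection)
    mean = mean_structure(sub)
    per_model = np.array([
        kabsch(sub.coords[i], mean.coords).rmsd for i in range(len(sub))
    ])
    return FamilyRmsdReport(
        per_model=per_model,
        mean=float(per_model.mean()),
        sd=float(per_model.std(ddof=1)) if len(per_model) > 1 else 0.0,
        selection_tag=selection_tag,
    )


def centroid_model(ensemble: Ensemble, selection: Selector | None = None) -> int:
    """Index of the model with minimal mean pairwise RMSD to all others.

    Ties resolve to the lowest index.
    """
    sub = _apply_selection(ensemble, selection)
    n = len(sub)
    if n < 2:
        raise ValueError("centroid needs at least 2 models")
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _pairwise_rmsd(sub.coords[i], sub.coords[j])
    mean_to_others = dmat.sum(axis=1) / (n - 1)
    return int(np.argmin(mean_to_others))


def rmsd_series(
    ensemble: Ensemble,
    reference: StructureModel,
    window: int = 1,
    mass_weighted: bool = True,
) -> np.ndarray:
    """Per-frame RMSD to a reference, smoothed by a centered moving average.

    The raw series is the mass-weighted superposed RMSD of each frame to
    ``reference``; the window must be odd and edge windows are truncated
    (not reflected), mirroring a running average over time bins.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd frame count")
    if window > len(ensemble):
        raise ValueError("window exceeds the number of frames")
    if len(reference) != ensemble.n_atoms:
        raise ValueError("reference and ensemble atom counts differ")
    weights = atom_masses(ensemble) if mass_weighted else None
    raw = np.array([
        kabsch(ensemble.coords[i], reference.coords, weights=weights).rmsd
        for i in range(len(ensemble))
    ])
    if window == 1:
        return raw
    half = window // 2
    smoothed = np.empty_like(raw)
    for t in range(len(raw)):
        lo, hi = max(0, t - half), min(len(raw), t + half + 1)
        smoothed[t] = raw[lo:hi].mean()
    return smoothed
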