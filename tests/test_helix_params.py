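"""Helical-parameter engine: frame fitting, mid-frame decomposition,
plane dihedral, bend, and per-ensemble tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from ptgg import _refgeom
from ptgg.errors import FrameFitError, OrientationError
from ptgg.helix_params import (BaseFrame, PAIR_PARAM_NAMES, STEP_PARAM_NAMES,
                               base_pair_params, bend_angle, compose_frames,
                               compute_param_table, decompose_frames,
                               default_designation, fit_base_frame,
                               gg_plane_dihedral, pair_frame, step_params)
from ptgg.structure_io import Ensemble, StructureModel, infer_duplex_topology
from ptgg.synthetic import GeneratorSpec, build_duplex, sample_ensemble
from conftest import random_rotation


def guanine_model(rot=np.eye(3), shift=np.zeros(3), noise=0.0, rng=None):
    rows, coords = [], []
    for i, (name, xyz) in enumerate(_refgeom.STANDARD_BASE_ATOMS["G"].items()):
        rows.append((i + 1, name, "DG", "A", 6, _refgeom.element_of(name)))
        pos = rot @ np.asarray(xyz) + shift
        if noise:
            pos = pos + rng.normal(scale=noise, size=3)
        coords.append(pos)
    atoms = pd.DataFrame(
        rows, columns=["serial", "name", "residue_name", "chain_id",
                       "residue_number", "element"])
    return StructureModel(atoms, np.asarray(coords))


class TestFitBaseFrame:
    def test_exact_recovery(self, rng):
        rot = random_rotation(rng)
        shift = rng.normal(scale=5, size=3)
        frame = fit_base_frame(guanine_model(rot, shift), 6)
        assert np.allclose(frame.axes, rot, atol=1e-9)
        assert np.allclose(frame.origin, shift, atol=1e-9)
        assert frame.residual < 1e-9

    def test_rotation_equivariance(self, rng):
        base = guanine_model()
        frame0 = fit_base_frame(base, 6)
        rot = random_rotation(rng)
        moved = base.copy()
        moved.coords = moved.coords @ rot.T
        frame1 = fit_base_frame(moved, 6)
        assert np.allclose(frame1.axes, rot @ frame0.axes, atol=1e-9)

    def test_noisy_residual_matches_kabsch_oracle(self, rng):
        """Residual equals an independent (scipy) superposition residual."""
        model = guanine_model(noise=0.01, rng=rng)
        frame = fit_base_frame(model, 6)
        ring = _refgeom.ring_atoms("G")
        obs = np.array([model.atom_position(6, a) for a in ring])
        std = _refgeom.standard_base_coords("G", ring)
        _, rssd = Rotation.align_vectors(obs - obs.mean(0), std - std.mean(0))
        assert frame.residual == pytest.approx(rssd / np.sqrt(len(ring)), abs=1e-9)

    def test_missing_ring_atom(self, bform_model):
        drop = bform_model.atom_index(6, "N7")
        broken = StructureModel(
            bform_model.atoms.drop(index=drop).reset_index(drop=True),
            np.delete(bform_model.coords, drop, axis=0))
        with pytest.raises(FrameFitError, match="N7"):
            fit_base_frame(broken, 6)


class TestMidFrameDecomposition:
    def test_identity(self):
        f = BaseFrame(np.zeros(3), np.eye(3))
        p = base_pair_params(f, f.flipped())  # unflips back to f
        assert np.allclose(p.as_tuple(), 0.0, atol=1e-12)

    def test_pure_stretch(self):
        f_c = BaseFrame(np.zeros(3), np.diag([1.0, -1.0, -1.0]))
        f_w = BaseFrame(np.array([0.0, 2.0, 0.0]), np.eye(3))
        p = base_pair_params(f_w, f_c)
        assert p.stretch == pytest.approx(2.0, abs=1e-12)
        others = (p.shear, p.stagger, p.buckle, p.propeller, p.opening)
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_builder_inverse_step(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2, _ = compose_frames(f1, [0.0, 0.0, 3.38], [0.0, 0.0, 36.0])
        s = step_params(f1, f2)
        assert s.twist == pytest.approx(36.0, abs=1e-9)
        assert s.rise == pytest.approx(3.38, abs=1e-12)
        assert np.allclose((s.shift, s.slide, s.tilt, s.roll), 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rebuild_oracle(self, seed):
        """decompose->compose reproduces the second frame to 1e-8."""
        rng = np.random.default_rng(seed)
        f1 = BaseFrame(rng.normal(scale=5, size=3), random_rotation(rng))
        f2 = BaseFrame(f1.origin + rng.normal(scale=3, size=3),
                       random_rotation(rng))
        if f1.axes[:, 2] @ f2.axes[:, 2] < 0:
            f2 = BaseFrame(f2.origin, f2.axes @ np.diag([1.0, -1.0, -1.0]))
        t, r, mid = decompose_frames(f1, f2)
        rebuilt, mid2 = compose_frames(f1, t, r)
        assert np.allclose(rebuilt.axes, f2.axes, atol=1e-8)
        assert np.allclose(rebuilt.origin, f2.origin, atol=1e-8)
        assert np.allclose(mid.axes, mid2.axes, atol=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_swap_consistency_via_rebuild(self, seed):
        """Swapping the frames stays exactly invertible, and the swapped
        translations are the negated originals in the (shared) mid frame."""
        rng = np.random.default_rng(100 + seed)
        f1 = BaseFrame(rng.normal(size=3), random_rotation(rng))
        t = rng.uniform(-3, 3, 3)
        r = rng.uniform(-50, 50, 3)
        f2, mid = compose_frames(f1, t, r)
        t_sw, r_sw, mid_sw = decompose_frames(f2, f1)
        assert np.allclose(mid_sw.origin, mid.origin, atol=1e-9)
        assert np.allclose(t_sw, -t, atol=1e-8)
        rebuilt, _ = compose_frames(f2, t_sw, r_sw)
        assert np.allclose(rebuilt.axes, f1.axes, atol=1e-8)

    def test_antialigned_normals_rejected(self):
        f1 = BaseFrame(np.zeros(3), np.eye(3))
        f2 = BaseFrame(np.zeros(3),
                       np.diag([1.0, -1.0, -1.0]))  # z flipped
        with pytest.raises(OrientationError):
            decompose_frames(f1, f2)

    def test_global_rotation_invariance(self, rng):
        f1 = BaseFrame(rng.normal(size=3), random_rotation(rng))
        f2, _ = compose_frames(f1, [0.3, -1.2, 3.1], [4.0, 20.0, 31.0])
        rot = random_rotation(rng)
        shift = rng.normal(scale=10, size=3)
        g1 = BaseFrame(rot @ f1.origin + shift, rot @ f1.axes)
        g2 = BaseFrame(rot @ f2.origin + shift, rot @ f2.axes)
        t0, r0, _ = decompose_frames(f1, f2)
        t1, r1, _ = decompose_frames(g1, g2)
        assert np.allclose(t0, t1, atol=1e-9)
        assert np.allclose(r0, r1, atol=1e-9)


class TestGgPlaneDihedral:
    def test_coplanar(self, bform_model):
        spec = GeneratorSpec()
        flat = build_duplex(spec.pair_means * 0.0,
                            spec.step_means.assign(twist=0.0, roll=0.0, tilt=0.0))
        # the standard bases are planar only to ~1e-3 A, so "coplanar"
        # holds to the corresponding angular precision
        assert gg_plane_dihedral(flat, 6, 7) == pytest.approx(0.0, abs=1e-4)

    def test_constructed_30_degrees(self, rng):
        m1 = guanine_model()
        rot = Rotation.from_euler("y", 30, degrees=True).as_matrix()
        rows = m1.atoms.copy()
        rows["residue_number"] = 7
        m2_coords = m1.coords @ rot.T + np.array([0.0, 0.0, 3.4])
        atoms = pd.concat([m1.atoms, rows], ignore_index=True)
        model = StructureModel(atoms, np.vstack([m1.coords, m2_coords]))
        assert gg_plane_dihedral(model, 6, 7) == pytest.approx(30.0, abs=1e-6)

    def test_noisy_vs_svd_oracle(self, rng):
        """Matches an independent eigen-decomposition plane fit."""
        model = sample_ensemble(GeneratorSpec(n_frames=1, seed=5)).ensemble[0]
        got = gg_plane_dihedral(model, 6, 7)
        normals = []
        for res in (6, 7):
            pts = np.array([model.atom_position(res, a)
                            for a in _refgeom.PURINE_RING])
            c = pts - pts.mean(0)
            w, v = np.linalg.eigh(c.T @ c)
            normals.append(v[:, 0])
        expect = np.degrees(np.arccos(abs(normals[0] @ normals[1])))
        assert got == pytest.approx(expect, abs=1e-9)

    def test_pyrimidine_rejected(self, bform_model):
        with pytest.raises(FrameFitError, match="purine"):
            gg_plane_dihedral(bform_model, 5, 6)


class TestBendAngle:
    def test_straight_duplex(self, bform_model, bform_topology):
        assert bend_angle(bform_model, bform_topology) == pytest.approx(0.0, abs=0.5)

    def test_central_roll_bend(self, bform_topology):
        spec = GeneratorSpec()
        step = spec.step_means.copy()
        step.loc[5, "roll"] = 40.0
        bent = build_duplex(spec.pair_means, step)
        assert bend_angle(bent, bform_topology) == pytest.approx(40.0, abs=5.0)

    def test_rigid_invariance(self, bform_topology, rng):
        spec = GeneratorSpec()
        step = spec.step_means.copy()
        step.loc[5, "roll"] = 25.0
        bent = build_duplex(spec.pair_means, step)
        a0 = bend_angle(bent, bform_topology)
        bent.coords = bent.coords @ random_rotation(rng).T + rng.normal(size=3)
        assert bend_angle(bent, bform_topology) == pytest.approx(a0, abs=1e-9)


class TestParamTable:
    def test_ideal_fixture_values(self, bform_ensemble):
        table = compute_param_table(bform_ensemble)
        row = table.data.iloc[0]
        for col in table.parameter_names():
            if col.endswith("twist"):
                assert row[col] == pytest.approx(36.0, abs=1e-9)
            elif col.endswith("rise"):
                assert row[col] == pytest.approx(3.38, abs=1e-9)
            else:
                assert row[col] == pytest.approx(0.0, abs=1e-9)

    def test_default_designation_is_central(self, bform_ensemble, bform_topology):
        pairs, steps = default_designation(bform_topology)
        assert pairs == (4, 5, 6, 7)
        assert steps == (4, 5, 6)
        table = compute_param_table(bform_ensemble)
        assert "pair_5_20_buckle" in table.data.columns
        assert "step_6_7_roll" in table.data.columns
        assert "pair_1_24_shear" not in table.data.columns

    def test_identical_models_identical_rows(self, bform_model, bform_topology):
        ens = Ensemble.from_models([bform_model.copy() for _ in range(4)],
                                   topology=bform_topology)
        table = compute_param_table(ens)
        assert (table.data.drop(columns="frame_index").nunique() == 1).all()

    def test_planted_roll_recovery(self):
        """100 frames with central-step roll ~ N(25, 5): sample mean within
        3 s.e.m. of the plant."""
        spec = GeneratorSpec(n_frames=100, seed=77)
        spec.step_means.loc[5, "roll"] = 25.0
        spec.step_sds.loc[5, "roll"] = 5.0
        built = sample_ensemble(spec)
        table = compute_param_table(built.ensemble)
        got = table.column("step_6_7_roll")
        sem = 5.0 / np.sqrt(100)
        assert abs(got.mean() - 25.0) < 3 * sem
        # and the recovered values equal the stored ground truth exactly
        assert np.allclose(got, built.ground_truth.column("step_6_7_roll"), atol=1e-6)

    def test_global_rotation_invariance(self, rng):
        built = sample_ensemble(GeneratorSpec(n_frames=3, seed=8))
        t0 = compute_param_table(built.ensemble).data
        rot = random_rotation(rng)
        moved = Ensemble(built.ensemble.atoms,
                         built.ensemble.coords @ rot.T + rng.normal(size=3),
                         built.ensemble.topology)
        t1 = compute_param_table(moved).data
        assert np.allclose(t0.to_numpy(), t1.to_numpy(), atol=1e-9)

    def test_tsv_round_trip(self, tmp_path, bform_ensemble):
        table = compute_param_table(bform_ensemble)
        path = tmp_path / "params.tsv"
        table.to_tsv(path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("frame_index\t")
        from ptgg.helix_params import ParamTable
        back = ParamTable.from_tsv(path, table.pair_indices, table.step_indices)
        assert np.allclose(back.data.to_numpy(), table.data.to_numpy())


def test_round_trip_property():
    """build -> analyze recovers arbitrary in-range parameters to 1e-6."""
    rng = np.random.default_rng(2024)
    spec = GeneratorSpec()
    for _ in range(25):
        pair = pd.DataFrame(rng.uniform(-3, 3, (12, 6)), columns=PAIR_PARAM_NAMES)
        pair[list(PAIR_PARAM_NAMES[3:])] = rng.uniform(-60, 60, (12, 3))
        step = pd.DataFrame(rng.uniform(-3, 3, (11, 6)), columns=STEP_PARAM_NAMES)
        step[list(STEP_PARAM_NAMES[3:])] = rng.uniform(-60, 60, (11, 3))
        model = build_duplex(pair, step)
        ens = Ensemble.from_models([model],
                                   topology=infer_duplex_topology(model))
        table = compute_param_table(ens, (tuple(range(12)), tuple(range(11))))
        row = table.data.iloc[0]
        for k in range(12):
            for p in PAIR_PARAM_NAMES:
                assert row[f"pair_{k + 1}_{24 - k}_{p}"] == \
                    pytest.approx(pair.loc[k, p], abs=1e-6)
        for s in range(11):
            for p in STEP_PARAM_NAMES:
                assert row[f"step_{s + 1}_{s + 2}_{p}"] == \
                    pytest.approx(step.loc[s, p], abs=1e-6)
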