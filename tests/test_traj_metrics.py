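"""Order parameters, classifiers, Kabsch superposition, dimer projection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from azogate.errors import (ConfigurationError, DegenerateGeometryError,
                            EmptySelectionError, MissingResidueError,
                            ValidationError)
from azogate.structure_io import Atom, Selection, Structure
from azogate.switch_dynamics import Trajectory
from azogate.synthetic_data import (DOMAIN1_RANGE, HELIX_B_RANGE,
                                    HELIX_H_RANGE, ScaffoldSpec, make_toy_lbd)
from azogate.traj_metrics import (MetricConfig, OrderParameterSeries,
                                  azobenzene_pocket_distance, center_of_mass,
                                  clamshell_distance, detect_transitions,
                                  gate_distance, gate_state, helix_distance,
                                  kabsch_superpose, order_parameter_series,
                                  pearson_r2, pose_state, project_dimer)
from conftest import random_rotation


def mono_traj(structure, frames):
    n = len(frames)
    z = np.zeros(n)
    return Trajectory(np.arange(n, dtype=float), np.array(frames), z, z.copy())


def single_atom_structure(coords_masses):
    atoms = [Atom(i + 1, "CA", "GLY", "A", i + 1, "C", m, tuple(c))
             for i, (c, m) in enumerate(coords_masses)]
    return Structure(atoms)


class TestCenterOfMass:
    def test_single_atom(self):
        s = single_atom_structure([((1.0, 2.0, 3.0), 12.0)])
        sel = Selection(s, (0,))
        np.testing.assert_allclose(center_of_mass(sel), [1, 2, 3])

    def test_equal_masses_midpoint(self):
        s = single_atom_structure([((0, 0, 0), 5.0), ((1, 0, 0), 5.0)])
        assert center_of_mass(Selection(s, (0, 1)))[0] == pytest.approx(0.5)

    def test_weighted_mean(self):
        s = single_atom_structure([((0, 0, 0), 1.0), ((4, 0, 0), 3.0)])
        assert center_of_mass(Selection(s, (0, 1)))[0] == pytest.approx(3.0)

    def test_empty_selection_rejected(self, scaffold):
        with pytest.raises(EmptySelectionError):
            center_of_mass(Selection(scaffold, ()))


class TestPlantedDistances:
    @pytest.mark.parametrize("field,value,metric", [
        ("clamshell_nm", 0.70, clamshell_distance),   # bound/closed reading
        ("clamshell_nm", 1.10, clamshell_distance),   # opened reading
        ("gate_nm", 0.55, gate_distance),             # gate closed
        ("gate_nm", 0.80, gate_distance),             # gate open
        ("pocket_nm", 0.75, azobenzene_pocket_distance),  # intermediate pose
        ("pocket_nm", 1.05, azobenzene_pocket_distance),  # position 2
    ])
    def test_planted_value_recovered(self, field, value, metric):
        s = make_toy_lbd(ScaffoldSpec(**{field: value}))
        assert metric(s) == pytest.approx(value, abs=1e-9)

    def test_rigid_motion_invariance(self, scaffold, rng):
        R = random_rotation(rng)
        t = rng.uniform(-3, 3, 3)
        moved = scaffold.with_coordinates(scaffold.coordinates @ R.T + t)
        cfg = MetricConfig(helixH_range=HELIX_H_RANGE, helixB_range=HELIX_B_RANGE)
        for metric in (clamshell_distance, gate_distance,
                       azobenzene_pocket_distance):
            assert metric(moved) == pytest.approx(metric(scaffold), abs=1e-9)
        assert helix_distance(moved, cfg=cfg) == pytest.approx(
            helix_distance(scaffold, cfg=cfg), abs=1e-9)

    def test_missing_gate_sidechain_errors(self, scaffold):
        pruned = Structure([a for a in scaffold.atoms
                            if not (a.res_number == 402
                                    and a.name in ("CD", "OE1", "OE2"))])
        with pytest.raises(MissingResidueError, match="402"):
            gate_distance(pruned)

    def test_missing_pocket_residue_named(self, scaffold):
        pruned = Structure([a for a in scaffold.atoms if a.res_number != 711])
        with pytest.raises(MissingResidueError, match="711"):
            azobenzene_pocket_distance(pruned)

    def test_helix_ranges_required(self, scaffold):
        with pytest.raises(ConfigurationError):
            helix_distance(scaffold, cfg=MetricConfig())


class TestClassifiers:
    @pytest.mark.parametrize("d,state", [
        (0.55, "closed"),  # closed-population reading
        (0.80, "open"),    # open-population reading
        (0.65, "open"),    # boundary assigned open by convention
    ])
    def test_gate_state(self, d, state):
        assert gate_state(d) == state

    @pytest.mark.parametrize("d,state", [
        (1.05, "position2"), (0.75, "intermediate"), (0.40, "position1"),
        (0.60, "intermediate"), (0.90, "position2"),
    ])
    def test_pose_state(self, d, state):
        assert pose_state(d) == state

    def test_negative_distance_rejected(self):
        with pytest.raises(ValidationError):
            gate_state(-0.1)
        with pytest.raises(ValidationError):
            pose_state(-0.1)

    @given(d=st.floats(0, 3))
    def test_classifiers_agree_with_direct_threshold(self, d):
        cfg = MetricConfig()
        assert gate_state(d, cfg) == ("closed" if d < cfg.gate_threshold else "open")
        lo, hi = cfg.pose_bounds
        expected = ("position1" if d < lo
                    else "intermediate" if d < hi else "position2")
        assert pose_state(d, cfg) == expected


class TestKabsch:
    def test_identity(self, rng):
        pts = rng.standard_normal((10, 3))
        tr = kabsch_superpose(pts, pts)
        np.testing.assert_allclose(tr.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-12)
        assert tr.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_apply_and_recover(self, rng):
        ref = rng.standard_normal((20, 3))
        R0 = random_rotation(rng)
        t0 = rng.uniform(-2, 2, 3)
        mobile = ref @ R0.T + t0
        tr = kabsch_superpose(mobile, ref)
        assert tr.rmsd < 1e-9
        np.testing.assert_allclose(tr.apply(mobile), ref, atol=1e-9)
        np.testing.assert_allclose(tr.rotation @ R0, np.eye(3), atol=1e-9)

    def test_noisy_rmsd_vs_brute_force_minimizer(self, rng):
        """rmsd ~ sigma*sqrt(3) and matches a direct quaternion-free minimizer."""
        sigma = 0.01
        ref = rng.standard_normal((200, 3))
        mobile = (ref + sigma * rng.standard_normal(ref.shape))
        R0 = random_rotation(rng)
        mobile = mobile @ R0.T + np.array([0.3, -0.2, 0.1])
        tr = kabsch_superpose(mobile, ref)
        expected = sigma * np.sqrt(3.0)
        assert 0.8 * expected < tr.rmsd < 1.2 * expected

        def objective(x):
            ax, ay, az, tx, ty, tz = x
            Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                           [0, np.sin(ax), np.cos(ax)]])
            Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                           [-np.sin(ay), 0, np.cos(ay)]])
            Rz = np.array([[np.cos(az), -np.sin(az), 0],
                           [np.sin(az), np.cos(az), 0], [0, 0, 1]])
            moved = mobile @ (Rz @ Ry @ Rx).T + [tx, ty, tz]
            return np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))

        res = optimize.minimize(objective, np.zeros(6), method="Nelder-Mead",
                                options={"maxiter": 5000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        assert tr.rmsd == pytest.approx(res.fun, rel=1e-3)

    def test_matches_biopython_superimposer(self, rng):
        SVDSuperimposer = pytest.importorskip(
            "Bio.SVDSuperimposer").SVDSuperimposer
        ref = rng.standard_normal((15, 3))
        mobile = ref + 0.05 * rng.standard_normal(ref.shape)
        tr = kabsch_superpose(mobile, ref)
        sup = SVDSuperimposer()
        sup.set(ref, mobile)  # Bio maps the second onto the first
        sup.run()
        assert tr.rmsd == pytest.approx(sup.get_rms(), rel=1e-9)
        R_bio, t_bio = sup.get_rotran()
        np.testing.assert_allclose(tr.rotation, R_bio.T, atol=1e-9)

    def test_no_reflection(self, rng):
        ref = rng.standard_normal((12, 3))
        mirrored = ref * np.array([-1.0, 1.0, 1.0])
        tr = kabsch_superpose(mirrored, ref)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_errors(self, rng):
        with pytest.raises(ValidationError):
            kabsch_superpose(rng.standard_normal((4, 3)),
                             rng.standard_normal((5, 3)))
        with pytest.raises(ValidationError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(6.0), [1.0, 0.0, 0.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_superpose(line, line)


class TestProjectDimer:
    def test_identity_projection_reproduces_reference_distance(
            self, scaffold, dimer):
        traj = mono_traj(scaffold, [scaffold.coordinates])
        series = project_dimer(traj, dimer, DOMAIN1_RANGE, scaffold)
        assert series.values[0] == pytest.approx(2.50, abs=1e-9)

    def test_every_frame_exact_under_rigid_motion(self, scaffold, dimer, rng):
        frames = []
        for _ in range(5):
            R = random_rotation(rng)
            t = rng.uniform(-2, 2, 3)
            frames.append(scaffold.coordinates @ R.T + t)
        series = project_dimer(mono_traj(scaffold, frames), dimer,
                               DOMAIN1_RANGE, scaffold)
        np.testing.assert_allclose(series.values, 2.50, atol=1e-9)

    def test_displaced_linker_matches_analytic_geometry(self, scaffold, dimer):
        """Domain 1 fixed, monomer linker displaced by d: the projection
        transform is the identity, so the new distance follows vector algebra."""
        coords = scaffold.coordinates.copy()
        idx = [i for i, a in enumerate(scaffold.atoms) if a.res_number == 632]
        d = np.array([0.1, -0.2, 0.3])
        coords[idx] += d
        base = project_dimer(mono_traj(scaffold, [scaffold.coordinates]),
                             dimer, DOMAIN1_RANGE, scaffold)
        m = scaffold.masses[idx]
        com_mono = m @ scaffold.coordinates[idx] / m.sum()
        # chain-B linker COM sits at com_mono + 2.5*y by construction
        com_b = com_mono + np.array([0.0, 2.5, 0.0])
        expected = np.linalg.norm(com_mono + d - com_b)
        series = project_dimer(mono_traj(scaffold, [coords]), dimer,
                               DOMAIN1_RANGE, scaffold)
        assert series.values[0] == pytest.approx(expected, abs=1e-9)

    def test_single_chain_reference_rejected(self, scaffold):
        traj = mono_traj(scaffold, [scaffold.coordinates])
        with pytest.raises(ValidationError, match="two chains"):
            project_dimer(traj, scaffold, DOMAIN1_RANGE, scaffold)


class TestPearsonR2:
    def test_affine_series_is_one(self):
        t = np.arange(10.0)
        a = OrderParameterSeries("a", t, np.linspace(0.5, 1.5, 10))
        b = OrderParameterSeries("b", t, 2 * a.values + 1)
        assert pearson_r2(a, b) == pytest.approx(1.0)

    def test_independent_normals_near_zero(self):
        rng = np.random.default_rng(99)
        n = 100_000
        t = np.arange(float(n))
        a = OrderParameterSeries("a", t, rng.standard_normal(n))
        b = OrderParameterSeries("b", t, rng.standard_normal(n))
        assert pearson_r2(a, b) < 0.01

    def test_too_short_rejected(self):
        t = np.arange(2.0)
        a = OrderParameterSeries("a", t, np.array([1.0, 2.0]))
        with pytest.raises(ValidationError):
            pearson_r2(a, a)

    def test_constant_series_rejected(self):
        t = np.arange(5.0)
        a = OrderParameterSeries("a", t, np.ones(5))
        b = OrderParameterSeries("b", t, np.arange(5.0))
        with pytest.raises(ValidationError, match="constant"):
            pearson_r2(a, b)

    def test_length_mismatch_rejected(self):
        a = OrderParameterSeries("a", np.arange(5.0), np.arange(5.0))
        b = OrderParameterSeries("b", np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValidationError):
            pearson_r2(a, b)


class TestDetectTransitions:
    def test_planted_step_found_exactly(self):
        values = np.concatenate([np.full(500, 0.5), np.full(500, 1.05)])
        ser = OrderParameterSeries("pocket", np.arange(1000.0), values)
        out = detect_transitions(ser, pose_state, 10)
        assert out == [(500, "position1", "position2")]

    def test_single_frame_spike_debounced(self):
        values = np.full(100, 0.4)
        values[50] = 1.2
        ser = OrderParameterSeries("pocket", np.arange(100.0), values)
        assert detect_transitions(ser, pose_state, 10) == []

    def test_noise_only_series_quiet(self):
        quiet = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = np.abs(0.4 + 0.02 * rng.standard_normal(1000))
            ser = OrderParameterSeries("pocket", np.arange(1000.0), values)
            if not detect_transitions(ser, pose_state, 10):
                quiet += 1
        assert quiet >= 95

    def test_empty_series_rejected(self):
        ser = OrderParameterSeries("x", np.zeros(0), np.zeros(0))
        with pytest.raises(ValidationError):
            detect_transitions(ser, pose_state, 10)

    def test_min_dwell_validation(self):
        ser = OrderParameterSeries("x", np.arange(3.0), np.arange(3.0))
        with pytest.raises(ValidationError):
            detect_transitions(ser, pose_state, 0)


class TestVectorizedSeries:
    def test_agrees_with_scalar_metrics(self, scaffold, rng):
        frames = scaffold.coordinates[None] + 0.01 * rng.standard_normal(
            (8, len(scaffold), 3))
        traj = mono_traj(scaffold, frames)
        cfg = MetricConfig(helixH_range=HELIX_H_RANGE, helixB_range=HELIX_B_RANGE)
        scalar = {
            "clamshell": lambda f: clamshell_distance(scaffold, f),
            "gate": lambda f: gate_distance(scaffold, f),
            "pocket": lambda f: azobenzene_pocket_distance(scaffold, f),
            "helix": lambda f: helix_distance(scaffold, f, cfg),
        }
        for name, fn in scalar.items():
            ser = order_parameter_series(scaffold, traj, name, cfg)
            np.testing.assert_allclose(
                ser.values, [fn(f) for f in frames], atol=1e-12)
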