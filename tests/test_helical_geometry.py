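"""Frame fitting, the 12 helical parameters, grooves and torsions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dnamech import (SyntheticSpec, build_coordinates, cehs_compose,
                     cehs_decompose, compute_grooves, compute_parameters,
                     compute_torsions, dihedral, fit_base_pair_frames,
                     generate_helical_ensemble)
from dnamech.core_io import FormatError
from dnamech.helical_geometry import _FLIP, _wrap_deg, classify_bi_bii
from dnamech.synthetic_data import IonModel

from conftest import straight_spec


class TestParameterAlgebra:
    def test_pure_twist_rise_step(self):
        # stacking with a 36 deg z-rotation and 3.4 A z-translation is
        # exactly (twist 36, rise 3.4), all else zero
        params = np.array([0.0, 0.0, 3.4, 0.0, 0.0, 36.0])
        R2, o2, _ = cehs_compose(np.eye(3), np.zeros(3), params)
        measured, _, _ = cehs_decompose(np.eye(3), np.zeros(3), R2, o2)
        np.testing.assert_allclose(measured, params, atol=1e-9)

    def test_compose_decompose_identity_on_random_draws(self):
        rng = np.random.default_rng(1)
        n = 1000
        params = np.zeros((n, 6))
        params[:, :3] = rng.normal([0, 0, 3.4], [0.8, 0.8, 0.4], size=(n, 3))
        params[:, 3:] = rng.normal([0, 3, 34], [8, 8, 8], size=(n, 3))
        R1 = Rotation.random(n, random_state=2).as_matrix()
        o1 = rng.normal(size=(n, 3)) * 5
        R2, o2, _ = cehs_compose(R1, o1, params)
        measured, _, _ = cehs_decompose(R1, o1, R2, o2)
        assert np.abs(measured - params).max() < 1e-6

    def test_strand_reversal_sign_rules(self):
        rng = np.random.default_rng(3)
        n = 200
        params = np.zeros((n, 6))
        params[:, :3] = rng.normal([0, 0, 3.4], [0.8, 0.8, 0.4], size=(n, 3))
        params[:, 3:] = rng.normal([0, 3, 34], [8, 8, 8], size=(n, 3))
        R1 = Rotation.random(n, random_state=4).as_matrix()
        o1 = rng.normal(size=(n, 3)) * 5
        R2, o2, _ = cehs_compose(R1, o1, params)
        fwd, _, _ = cehs_decompose(R1, o1, R2, o2)
        rev, _, _ = cehs_decompose(R2 @ _FLIP, o2, R1 @ _FLIP, o1)
        signs = np.array([-1, 1, 1, -1, 1, 1])  # shift, tilt flip
        np.testing.assert_allclose(rev, fwd * signs, atol=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-500, 500))
    def test_angle_wrapping_range(self, angle):
        w = _wrap_deg(angle)
        assert -180.0 < w <= 180.0
        assert abs((w - angle) % 360.0) < 1e-9 or \
            abs((w - angle) % 360.0 - 360.0) < 1e-9


class TestFrameFitting:
    def test_round_trip_recovers_origins_and_parameters(self):
        spec = SyntheticSpec(n_frames=20, seed=9, ions=IonModel(molarity=0))
        ens = generate_helical_ensemble(spec)
        traj = build_coordinates(ens, spec)
        frames = fit_base_pair_frames(traj)
        measured = compute_parameters(frames)
        assert np.abs(measured.step_params - ens.step_params).max() < 1e-6
        assert np.abs(measured.bp_params[:, :, :6]
                      - ens.bp_params[:, :, :6]).max() < 1e-6

    def test_frame_triads_orthonormal(self, fiber_traj):
        frames = fit_base_pair_frames(fiber_traj)
        gram = np.einsum("fbij,fbkj->fbik", frames.bp_R, frames.bp_R)
        assert np.abs(gram - np.eye(3)).max() < 1e-8
        assert np.allclose(np.linalg.det(frames.bp_R), 1.0)

    def test_mirrored_duplex_rejected(self, fiber_traj):
        coords = fiber_traj.coordinate_array().copy()
        coords[:, :, 0] *= -1.0   # reflect: left-handed helix
        from dnamech import TrajectoryHandle
        u = fiber_traj.universe
        mirrored = TrajectoryHandle.from_arrays(
            coords, list(u.atoms.names), list(u.atoms.resnames),
            list(u.atoms.resids), list(u.atoms.chainIDs),
            fiber_traj.roles, timestep=1.0)
        with pytest.raises(FormatError, match="handed"):
            fit_base_pair_frames(mirrored)

    def test_methylation_effect_on_cpg_step_means(self):
        # generated ME ensembles must show lower twist and higher roll than
        # WT at methylated CpG steps
        from dnamech import SystemLabel, default_system_spec
        kw = dict(n_frames=20000, seed=21)
        wt = generate_helical_ensemble(
            default_system_spec(SystemLabel("WT", "naked"), **kw))
        me = generate_helical_ensemble(
            default_system_spec(SystemLabel("ME", "naked"), **kw))
        me_steps = [s - 1 for s in (12, 14, 20, 24, 35)]
        d_twist = (me.series("twist")[:, me_steps].mean()
                   - wt.series("twist")[:, me_steps].mean())
        d_roll = (me.series("roll")[:, me_steps].mean()
                  - wt.series("roll")[:, me_steps].mean())
        assert d_twist < -1.0
        assert d_roll > 1.0


class TestGrooves:
    def test_fiber_duplex_minor_narrower_than_major(self, fiber_traj):
        frames = fit_base_pair_frames(fiber_traj)
        g = compute_grooves(fiber_traj, frames)
        major = np.nanmean(g[:, :, 0])
        minor = np.nanmean(g[:, :, 2])
        assert 0.0 < minor < major
        # canonical B-DNA ballpark
        assert 4.0 < minor < 8.0
        assert 9.0 < major < 14.0

    def test_known_strand_separation_widens_grooves_exactly(self):
        # untwisted ladder: both phosphate splines are straight parallel
        # lines, so pulling the strands +/- 1 A apart along the connector
        # direction (global y) must widen the groove by exactly 2 A
        spec = straight_spec()
        spec = spec.replace(mean_overrides=tuple(
            o if o.param != "twist" else
            type(o)("twist", o.positions, 0.0) for o in spec.mean_overrides))
        ens = generate_helical_ensemble(spec)
        traj = build_coordinates(ens, spec)
        frames = fit_base_pair_frames(traj, check_handedness=False)
        g0 = compute_grooves(traj, frames)
        coords = traj.coordinate_array().copy()
        u = traj.universe
        names = np.asarray(u.atoms.names)
        chains = np.asarray(u.atoms.chainIDs)
        for i in np.flatnonzero(names == "P"):
            coords[:, i, 1] += 1.0 if chains[i] == "A" else -1.0
        from dnamech import TrajectoryHandle
        widened = TrajectoryHandle.from_arrays(
            coords, list(names), list(u.atoms.resnames),
            list(u.atoms.resids), list(chains), traj.roles, timestep=1.0)
        g1 = compute_grooves(widened,
                             fit_base_pair_frames(widened,
                                                  check_handedness=False))
        interior = slice(5, -5)
        width0 = np.fmin(g0[:, interior, 0], g0[:, interior, 2])
        width1 = np.fmin(g1[:, interior, 0], g1[:, interior, 2])
        delta = np.nanmean(width1 - width0)
        assert delta == pytest.approx(2.0, abs=0.1)

    def test_rigid_motion_invariance(self, fiber_traj):
        frames = fit_base_pair_frames(fiber_traj)
        g0 = compute_grooves(fiber_traj, frames)
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        t = np.array([12.0, -7.0, 3.0])
        coords = fiber_traj.coordinate_array() @ R.T + t
        u = fiber_traj.universe
        from dnamech import TrajectoryHandle
        moved = TrajectoryHandle.from_arrays(
            coords, list(u.atoms.names), list(u.atoms.resnames),
            list(u.atoms.resids), list(u.atoms.chainIDs),
            fiber_traj.roles, timestep=1.0)
        g1 = compute_grooves(moved, fit_base_pair_frames(moved))
        interior = slice(3, -3)
        np.testing.assert_allclose(g1[:, interior], g0[:, interior],
                                   atol=1e-6, equal_nan=True)


class TestTorsions:
    def test_dihedral_matches_analytic_construction(self):
        # four atoms engineered so the dihedral IS the construction angle
        for theta in (-150.0, -70.0, 0.001, 35.0, 120.0):
            p0 = np.array([1.0, 0.0, 0.0])
            p1 = np.zeros(3)
            p2 = np.array([0.0, 0.0, 1.5])
            rad = np.deg2rad(theta)
            p3 = p2 + np.array([np.cos(rad), np.sin(rad), 0.0])
            assert dihedral(p0, p1, p2, p3) == pytest.approx(theta, abs=1e-6)

    @pytest.mark.parametrize("eps,zeta,state", [
        (-170.0, -100.0, "BI"),    # eps - zeta = -70 -> BI
        (-100.0, -170.0, "BII"),   # eps - zeta = +70 -> BII
        (170.0, -170.0, "BI"),     # raw +340 wraps to -20 -> BI
    ])
    def test_bi_bii_rule(self, eps, zeta, state):
        assert classify_bi_bii(eps, zeta) == state

    def test_torsions_defined_on_rebuilt_duplex(self, fiber_traj):
        angles, bii = compute_torsions(fiber_traj)
        assert angles.shape[1:] == (2, 49, 7)
        finite = np.isfinite(angles)
        # interior residues must have all six backbone torsions + chi
        assert finite[:, :, 2:-2, :].all()
        assert angles[finite].min() > -180.0
        assert angles[finite].max() <= 180.0
        assert bii.dtype == bool
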