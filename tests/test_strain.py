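"""Strain tensor pipeline: exact limits, polar rotation, curves, metrics."""

import dataclasses

import numpy as np
import pytest

import densefit as df
from densefit.strain import (
    DiastolicWindows,
    aggregate_curves,
    deformation_gradient,
    detect_windows,
    diastolic_metrics,
    lagrangian_strain,
    strain_rate,
    to_polar,
)


def traj_from(nodes, disp_frames):
    disp = np.stack(disp_frames)
    return df.LagrangianTrajectories(
        disp=disp, ref_positions=nodes.positions, times_ms=np.arange(disp.shape[0]) * 15.0
    )


class TestDeformationGradient:
    def test_zero_displacement_gives_identity(self, toy_nodes):
        traj = traj_from(toy_nodes, [np.zeros((toy_nodes.n, 2))] * 3)
        F, valid = deformation_gradient(traj, toy_nodes)
        assert valid.all()
        assert np.allclose(F, np.eye(2), atol=1e-12)

    def test_uniform_scaling_exact(self, toy_nodes):
        disp = 0.2 * toy_nodes.positions  # x = 1.2 X
        F, valid = deformation_gradient(
            traj_from(toy_nodes, [np.zeros_like(disp), disp]), toy_nodes
        )
        assert np.allclose(F[1][valid], 1.2 * np.eye(2), atol=1e-10)

    def test_matches_analytic_jacobian_on_phantom(
        self, noiseless_spec, truth, truth_trajectories, noiseless_data, interior_nodes
    ):
        # analytic Jacobian oracle on the exact displacement field
        _, _, nodes = noiseless_data
        F, valid = deformation_gradient(truth_trajectories, nodes)
        for t in (7, 14, 22):
            Ftrue = df.motion_jacobian(noiseless_spec, truth.positions, t)
            rel = np.linalg.norm(F[t] - Ftrue, axis=(1, 2)) / np.linalg.norm(Ftrue, axis=(1, 2))
            assert rel[interior_nodes].max() < 0.02

    def test_isolated_node_excluded(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = mask[0, 0] = True  # no neighbors within 1-node radius
        nodes = df.NodeSet.from_mask(mask, 1.0)
        traj = traj_from(nodes, [np.zeros((2, 2))])
        _, valid = deformation_gradient(traj, nodes)
        assert not valid.any()


class TestLagrangianStrain:
    def test_identity_gives_zero(self):
        assert np.allclose(lagrangian_strain(np.eye(2)), 0.0)

    @pytest.mark.parametrize("phi", [0.3, -1.2, 2.9])
    def test_rigid_rotation_strain_free(self, phi):
        c, s = np.cos(phi), np.sin(phi)
        R = np.array([[c, -s], [s, c]])
        assert np.abs(lagrangian_strain(R)).max() < 1e-12

    def test_uniform_scale_closed_form(self):
        E = lagrangian_strain(1.2 * np.eye(2))
        assert np.allclose(E, ((1.2**2 - 1) / 2) * np.eye(2))
        assert E[0, 0] == pytest.approx(0.22)

    def test_symmetric_by_construction(self, rng):
        F = rng.standard_normal((10, 2, 2))
        E = lagrangian_strain(F)
        assert np.allclose(E, np.swapaxes(E, -1, -2), atol=1e-12)


class TestToPolar:
    def test_theta_zero_is_identity(self, rng):
        E = rng.standard_normal((2, 2))
        E = (E + E.T) / 2
        Ep, theta = to_polar(E[None, None], np.array([[5.0, 0.0]]), np.zeros(2))
        assert theta[0] == 0.0
        assert np.allclose(Ep[0, 0], E)

    def test_quarter_turn_swaps_diagonal(self, rng):
        E = np.diag(rng.standard_normal(2))
        Ep, _ = to_polar(E[None, None], np.array([[0.0, 5.0]]), np.zeros(2))
        assert Ep[0, 0, 0, 0] == pytest.approx(E[1, 1])
        assert Ep[0, 0, 1, 1] == pytest.approx(E[0, 0])

    def test_trace_invariant(self, rng):
        E = rng.standard_normal((4, 2, 2))
        E = (E + np.swapaxes(E, -1, -2)) / 2
        pos = rng.uniform(-10, 10, (4, 2))
        Ep, _ = to_polar(E, pos, np.array([0.5, 0.5]))
        assert np.allclose(np.trace(Ep, axis1=-2, axis2=-1), np.trace(E, axis1=-2, axis2=-1))

    def test_center_coincident_node_rejected(self):
        with pytest.raises(ValueError, match="center"):
            to_polar(np.zeros((1, 1, 2, 2)), np.array([[1.0, 1.0]]), np.array([1.0, 1.0]))

    def test_pure_contraction_signs(self, noiseless_spec, truth, noiseless_data):
        # area-preserving contraction: wall thickens radially, shortens
        # circumferentially, at every node
        spec = dataclasses.replace(noiseless_spec, twist_deg=0.0)
        t = df.generate_ground_truth(spec)
        Ep, _ = to_polar(t.strain[14], t.positions, spec.center_xy)
        assert (Ep[:, 0, 0] > 0).all()  # Err
        assert (Ep[:, 1, 1] < 0).all()  # Ecc


class TestStrainRate:
    def test_constant_curve_zero_rate(self):
        assert np.allclose(strain_rate(np.full(10, -0.1), 15.0), 0.0)

    def test_step_arithmetic(self):
        # Ecc falls 0.03 over one 15 ms frame: -2.0 1/s
        rate = strain_rate(np.array([0.0, -0.03]), 15.0)
        assert rate[0] == pytest.approx(-2.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            strain_rate(np.array([0.1]), 15.0)

    def test_matches_analytic_rate_on_phantom(self, noiseless_spec, truth, noiseless_data):
        # discrete rate of the exact global Ecc curve vs the analytic
        # derivative, within O(TR) discretization error
        spec = noiseless_spec
        _, _, nodes = noiseless_data
        r = np.linalg.norm(truth.positions - spec.center_xy, axis=-1)
        a = df.activation(spec)
        ecc = np.array(
            [df.phantom.analytic_circumferential_strain(spec, r, ai).mean() for ai in a]
        )
        rate = strain_rate(ecc, spec.tr_ms)
        tf = np.linspace(0, (spec.n_frames - 1) * spec.tr_ms, 40001)
        af = df.phantom.activation_continuous(spec, tf)
        ecc_f = np.array(
            [df.phantom.analytic_circumferential_strain(spec, r, ai).mean() for ai in af]
        )
        rate_f = np.diff(ecc_f) / np.diff(tf) * 1000.0
        # compare at interval midpoints
        mid = (np.arange(spec.n_frames - 1) + 0.5) * spec.tr_ms
        analytic_mid = np.interp(mid, tf[:-1], rate_f)
        assert np.abs(rate - analytic_mid).max() < 0.08  # 1/s


class TestAggregation:
    def test_single_region_equals_global(self, noiseless_spec, truth_trajectories, noiseless_data):
        _, _, nodes = noiseless_data
        field = df.compute_strain_field(truth_trajectories, nodes, center=noiseless_spec.center_xy)
        curves = aggregate_curves(field, noiseless_spec.tr_ms, n_segments=1)
        assert np.allclose(curves.segment_ecc[0], curves.global_ecc)

    def test_axisymmetric_segments_agree(self, noiseless_spec, truth_trajectories, noiseless_data):
        # the default grid's mask is exactly 4-fold symmetric about the center,
        # so with 4 sectors the segment node sets map onto each other
        _, _, nodes = noiseless_data
        field = df.compute_strain_field(truth_trajectories, nodes, center=noiseless_spec.center_xy)
        curves = aggregate_curves(
            field, noiseless_spec.tr_ms, n_segments=4, ref_angle=np.pi / 4
        )
        spread = curves.segment_ecc.max(axis=0) - curves.segment_ecc.min(axis=0)
        assert spread.max() < 1e-6

    def test_sector_dependent_strain_recovered(self, rng):
        # constructed oracle: nodes in two sectors carry different Ecc levels
        nodes = df.NodeSet.from_mask(np.ones((8, 8), dtype=bool), 1.0)
        center = nodes.positions.mean(axis=0)
        rel = nodes.positions - center
        theta = np.arctan2(rel[:, 1], rel[:, 0])
        ecc_level = np.where((theta % (2 * np.pi)) < np.pi, -0.2, -0.05)
        F = np.zeros((2, nodes.n, 2, 2))
        E = np.zeros((2, nodes.n, 2, 2))
        Ep = np.zeros((2, nodes.n, 2, 2))
        Ep[1, :, 1, 1] = ecc_level
        field = df.StrainField(
            F=F, E=E, E_polar=Ep, valid=np.ones(nodes.n, dtype=bool), theta=theta, center=center
        )
        curves = aggregate_curves(field, 15.0, n_segments=2)
        for s in range(2):
            members = curves.segment_of_node == s
            assert curves.segment_ecc[s, 1] == pytest.approx(ecc_level[members].mean())

    def test_empty_segment_named_in_error(self):
        # all nodes in a half-plane: with many sectors some are empty
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, :] = True
        nodes = df.NodeSet.from_mask(mask, 1.0)
        theta = np.zeros(nodes.n)
        field = df.StrainField(
            F=np.zeros((1, nodes.n, 2, 2)),
            E=np.zeros((1, nodes.n, 2, 2)),
            E_polar=np.zeros((1, nodes.n, 2, 2)),
            valid=np.ones(nodes.n, dtype=bool),
            theta=theta,
            center=np.zeros(2),
        )
        with pytest.raises(ValueError, match="segment 1"):
            aggregate_curves(field, 15.0, n_segments=4)


class TestDiastolicMetrics:
    def test_flat_after_end_systole(self):
        ecc = np.concatenate([np.linspace(0, -0.2, 10), np.full(20, -0.2)])
        m = diastolic_metrics(ecc, 15.0, DiastolicWindows(9, 15, 25))
        assert m.pedsr == pytest.approx(0.0)
        assert m.diastasis_rate == pytest.approx(0.0)
        assert m.end_systolic_strain == pytest.approx(-0.2)

    def test_triangular_recovery_slope(self):
        # linear recovery of 0.01 strain per 15 ms frame: PEDSR = 2/3 1/s
        ecc = np.concatenate([np.linspace(0, -0.2, 11), -0.2 + 0.01 * np.arange(1, 10)])
        m = diastolic_metrics(ecc, 15.0, DiastolicWindows(10, 15, 18))
        assert m.pedsr == pytest.approx(0.01 / 0.015)

    def test_windows_outside_sequence_rejected(self):
        with pytest.raises(ValueError, match="window"):
            diastolic_metrics(np.zeros(10), 15.0, DiastolicWindows(3, 8, 25))

    def test_auto_windows_locate_end_systole(self):
        a = np.sin(np.linspace(0, np.pi, 30))
        w = detect_windows(-a)
        assert w.end_systole == np.argmax(a)
        assert w.end_systole < w.end_ewave <= w.end_diastasis <= 29

    def test_phantom_pedsr_tracks_analytic_peak(
        self, noiseless_spec, truth, truth_trajectories, noiseless_data
    ):
        # on exact trajectories the only losses are TR sampling and the
        # gradient discretization
        spec = noiseless_spec
        _, _, nodes = noiseless_data
        field = df.compute_strain_field(truth_trajectories, nodes, center=spec.center_xy)
        curves = aggregate_curves(field, spec.tr_ms)
        w = DiastolicWindows(spec.end_systole_frame, spec.end_ewave_frame, spec.end_diastasis_frame)
        m = diastolic_metrics(curves.global_ecc, spec.tr_ms, w)
        r = np.linalg.norm(truth.positions[field.valid] - spec.center_xy, axis=-1)
        tf = np.linspace(0, (spec.n_frames - 1) * spec.tr_ms, 20001)
        af = df.phantom.activation_continuous(spec, tf)
        ecc_f = (-af[:, None] * spec.contraction_constant / (2 * r[None, :] ** 2)).mean(axis=1)
        rate_f = np.diff(ecc_f) / np.diff(tf) * 1000.0
        sel = (tf[:-1] >= w.end_systole * spec.tr_ms) & (tf[:-1] <= w.end_ewave * spec.tr_ms)
        analytic_peak = rate_f[sel].max()
        assert m.pedsr == pytest.approx(analytic_peak, rel=0.10)


class TestFrameZeroContract:
    def test_strain_zero_at_reference_for_both_solvers(self, noiseless_data, rstls_solution):
        series, _, nodes = noiseless_data
        two = df.solve_two_step(series, nodes, lam=1.0)
        for traj in (rstls_solution, two):
            field = df.compute_strain_field(traj, nodes)
            assert np.allclose(field.E[0][field.valid], 0.0, atol=1e-12)
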