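"""Monodomain solver: conductivity tensors, activation maps, wave speeds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atriafiber import (EPParameters, TwoCurrentModel, box_mesh, compute_cv,
                        compute_lat, conductivity_tensor,
                        find_bb_stimulus_site, simulate_monodomain)
from atriafiber.ep import FrameError, LAT_SENTINEL
from atriafiber.laplace import SpecificationError

from conftest import axis_frame, bar_cv, run_bar


class TestConductivityTensor:
    def test_axis_aligned_frame_gives_diagonal(self):
        frame = axis_frame(1)
        t = conductivity_tensor(frame, EPParameters())
        np.testing.assert_allclose(t[0], np.diag([1.3342, 0.36, 0.36]),
                                   atol=1e-15)

    def test_isotropic_conductivities_give_identity(self):
        rng = np.random.default_rng(2)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        frame = axis_frame(1, q[:, 0], q[:, 1])
        frame.n[:] = np.cross(frame.f, frame.s)
        p = EPParameters(sigma_f=0.7, sigma_s=0.7, sigma_n=0.7)
        t = conductivity_tensor(frame, p)
        np.testing.assert_allclose(t[0], 0.7 * np.eye(3), atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_eigenpairs_match_frame(self, seed):
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        frame = axis_frame(1, q[:, 0], q[:, 1])
        frame.n[:] = np.cross(frame.f, frame.s)
        p = EPParameters()
        t = conductivity_tensor(frame, p)[0]
        w = np.sort(np.linalg.eigvalsh(t))
        np.testing.assert_allclose(
            w, sorted([p.sigma_f, p.sigma_s, p.sigma_n]), atol=1e-12)

    def test_non_orthonormal_frame_rejected(self):
        frame = axis_frame(1, (1, 0, 0), (0.5, 0.5, 0))
        with pytest.raises(FrameError):
            conductivity_tensor(frame, EPParameters())


class TestActivationTime:
    def test_linear_crossing_interpolated(self):
        times = np.array([10.0, 11.0])
        V = np.array([[-80.0], [20.0]])
        lat = compute_lat(V, times, threshold=-40.0)
        assert lat[0] == pytest.approx(10.4)

    def test_never_crossing_gives_sentinel(self):
        V = np.full((5, 2), -80.0)
        lat = compute_lat(V, np.arange(5.0))
        assert np.isnan(lat).all()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.1, 20.0))
    def test_translation_property(self, shift):
        times = np.linspace(0, 30, 61)
        V = -80.0 + 100.0 / (1 + np.exp(-(times[:, None] - 12.0) / 0.5))
        lat0 = compute_lat(V, times)
        lat1 = compute_lat(V, times + shift)
        assert lat1[0] - lat0[0] == pytest.approx(shift, abs=1e-9)

    def test_first_crossing_wins(self):
        times = np.arange(6.0)
        V = np.array([-80.0, 0.0, -80.0, -80.0, 0.0, 0.0])[:, None]
        lat = compute_lat(V, times)
        assert lat[0] == pytest.approx(0.5)


class TestConductionVelocity:
    def test_planar_lat_gives_constant_cv(self):
        mesh = box_mesh((4, 1, 1), (8, 2, 2))
        lat = 2.0 * mesh.nodes[:, 0]      # 2 ms per mm
        cv = compute_cv(mesh, lat)
        np.testing.assert_allclose(cv, 0.5, atol=1e-12)

    def test_constant_lat_gives_sentinel(self):
        mesh = box_mesh((4, 1, 1), (4, 2, 2))
        cv = compute_cv(mesh, np.full(mesh.n_nodes, 7.0))
        assert np.isnan(cv).all()

    def test_unactivated_nodes_poison_their_elements(self):
        mesh = box_mesh((4, 1, 1), (4, 2, 2))
        lat = 2.0 * mesh.nodes[:, 0]
        lat[0] = LAT_SENTINEL
        cv = compute_cv(mesh, lat)
        touched = np.any(mesh.elements == 0, axis=1)
        assert np.isnan(cv[touched]).all()
        assert np.isfinite(cv[~touched]).all()

    def test_cv_map_matches_two_probe_estimate(self, cable_runs):
        run = cable_runs["base"]
        cv_map = compute_cv(run["mesh"], run["lat"])
        mid = np.abs(run["mesh"].element_centroids()[:, 0] - 6.0) < 2.0
        assert np.nanmedian(cv_map[mid]) == pytest.approx(run["cv"], rel=0.03)


class TestMonodomain:
    def test_quiescence_without_stimulus(self):
        mesh = box_mesh((2, 1, 1), (4, 2, 2))
        frame = axis_frame(mesh.n_elements)
        p = EPParameters(stim_amplitude=0.0, stim_tag="x0", t_end=50.0)
        res = simulate_monodomain(mesh, conductivity_tensor(frame, p),
                                  TwoCurrentModel(), p)
        V = res.model.V_of(res.u_final)
        assert np.max(np.abs(V - res.model.V_rest)) < 0.5
        assert np.isnan(res.lat).all()

    def test_cv_scales_as_sqrt_sigma(self, cable_runs):
        ratio = cable_runs["quad"]["cv"] / cable_runs["base"]["cv"]
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_default_stimulus_captures_whole_slab(self, cable_runs):
        # Table-style stimulus: 1000 uA/cm^3 for 2 ms at one face
        assert np.isfinite(cable_runs["base"]["lat"]).all()

    def test_anisotropy_ratio(self, slab_aniso):
        expected = np.sqrt(1.3342 / 0.36)
        assert slab_aniso["cv_f"] / slab_aniso["cv_s"] == pytest.approx(
            expected, rel=0.07)

    def test_dt_refinement_changes_cv_little(self, cable_runs):
        mesh, res = run_bar(1.3342, dt=0.01)
        cv_fine = bar_cv(mesh, res.lat)
        assert cv_fine == pytest.approx(cable_runs["base"]["cv"], rel=0.02)

    def test_empty_stimulus_support_rejected(self):
        mesh = box_mesh((2, 1, 1), (2, 2, 2))
        frame = axis_frame(mesh.n_elements)
        p = EPParameters(stim_center=(100.0, 100, 100), stim_radius=0.5)
        with pytest.raises(SpecificationError, match="stimulus"):
            simulate_monodomain(mesh, conductivity_tensor(frame, p),
                                TwoCurrentModel(), p)

    def test_la_activates_fully_with_bb_stimulus(self, la_coarse):
        mesh = la_coarse["mesh"]
        p = EPParameters(dt=0.05, t_end=250.0)
        p.stim_nodes = find_bb_stimulus_site(mesh, la_coarse["fields"],
                                             radius=2.5)
        tensors = conductivity_tensor(la_coarse["frame"], p)
        res = simulate_monodomain(mesh, tensors, TwoCurrentModel(), p)
        lat = res.lat
        assert np.isfinite(lat).all()
        # ostium-to-tip propagation in the appendage
        tip_lat = lat[mesh.landmarks["laa_tip"]]
        phi1 = la_coarse["fields"].fields["phi1"].values
        ostium = np.abs(phi1 - 0.47) < 0.02
        assert tip_lat > np.nanmean(lat[ostium])
        # conduction-velocity map is positive wherever defined
        cv = compute_cv(mesh, lat)
        assert np.all(cv[np.isfinite(cv)] > 0)


class TestIonicContract:
    def test_rest_state_is_equilibrium(self):
        model = TwoCurrentModel()
        u = np.zeros(5)
        y = model.y_rest(5)
        assert np.max(np.abs(model.I_ion(y, u))) == 0.0
        dudt = -model.I_ion(y, u) / (model.chi * model.Cm)
        assert np.max(np.abs(dudt)) < 1e-12

    def test_gate_relaxation_exact_step(self):
        model = TwoCurrentModel()
        y = np.array([[0.5]])
        u = np.array([0.0])  # below gate: relax toward 1 with tau_open
        y2 = model.step_states(y, u, dt=10.0)
        expected = 1.0 + (0.5 - 1.0) * np.exp(-10.0 / model.tau_open)
        assert y2[0, 0] == pytest.approx(expected, rel=1e-12)
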