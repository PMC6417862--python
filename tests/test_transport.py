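"""Transport model: closed forms, PDE invariants, and depletion behavior."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from treadnet.transport import (ActinProfile, CofilinKinetics, GridSpec,
                                NetworkGeometry, ThresholdModel,
                                depletion_timecourse, quasi_steady_estimate,
                                simple_bound_profile, simple_equilibrium_length,
                                simulate_chamber)

from conftest import REF_A, REF_C0, REF_RB, REF_RU, REF_V


class TestSimpleModel:
    def test_fresh_actin_is_cofilin_free(self, ref_kinetics, constant_actin,
                                         ref_geometry):
        assert simple_bound_profile(ref_kinetics, constant_actin, ref_geometry,
                                    y=0.0, t=600.0) == 0.0

    def test_caption_parameters_load_to_3125_nM_per_um(self, ref_kinetics,
                                                       constant_actin, ref_geometry):
        # kB*C0*A*y/V with y = V * 1 min: one minute of loading
        val = simple_bound_profile(ref_kinetics, constant_actin, ref_geometry,
                                   y=1.16, t=120.0)
        assert val == pytest.approx(3.125, rel=1e-12)

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_linear_in_C0(self, scale):
        geo = NetworkGeometry(W=30.0, V=REF_V)
        act = ActinProfile(REF_A)
        base = simple_bound_profile(
            CofilinKinetics(C0=REF_C0, D=10, rB=REF_RB, rU=REF_RU), act, geo,
            y=1.0, t=600.0)
        scaled = simple_bound_profile(
            CofilinKinetics(C0=scale * REF_C0, D=10, rB=REF_RB, rU=REF_RU), act,
            geo, y=1.0, t=600.0)
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_rejects_out_of_range_and_degenerate_speed(self, ref_kinetics,
                                                       constant_actin):
        geo = NetworkGeometry(W=30.0, V=REF_V)
        with pytest.raises(ValueError):
            simple_bound_profile(ref_kinetics, constant_actin, geo, y=100.0, t=60.0)
        still = NetworkGeometry(W=30.0, V=0.0)
        with pytest.raises(ValueError):
            simple_bound_profile(ref_kinetics, constant_actin, still, y=0.0, t=60.0)

    def test_equilibrium_length_direct_and_scaling(self):
        thr = ThresholdModel(gamma=1.0)
        kin = CofilinKinetics(C0=1.0, D=10, rB=0.1 / 60, rU=0.0)
        geo = NetworkGeometry(W=30.0, V=1.0 / 60)
        # gamma*V/(kB*C0) with V=1/min and kB*C0=0.1/min
        assert simple_equilibrium_length(thr, kin, geo) == pytest.approx(10.0)
        half = CofilinKinetics(C0=0.5, D=10, rB=0.1 / 60, rU=0.0)
        assert simple_equilibrium_length(thr, half, geo) == pytest.approx(20.0)

    def test_no_finite_equilibrium_without_binding(self):
        thr = ThresholdModel(gamma=1.0)
        kin = CofilinKinetics(C0=0.0, D=10, rB=0.1, rU=0.0)
        geo = NetworkGeometry(W=30.0, V=0.02)
        assert math.isinf(simple_equilibrium_length(thr, kin, geo))

    def test_equilibrium_length_inverts_bound_profile_at_threshold(
            self, ref_kinetics, constant_actin, ref_geometry):
        """L* solves kB*C0*A*y/V = gamma*A; cross-check with a root finder."""
        thr = ThresholdModel(gamma=0.05)
        L_star = simple_equilibrium_length(thr, ref_kinetics, ref_geometry)
        t_big = 2 * L_star / ref_geometry.V

        def excess(y):
            cb = simple_bound_profile(ref_kinetics, constant_actin, ref_geometry,
                                      y, t_big)
            return cb - thr.gamma * constant_actin.A0

        root = brentq(excess, 1e-9, ref_geometry.length(t_big))
        assert L_star == pytest.approx(root, rel=1e-9)


class TestQuasiSteadyEstimate:
    def test_no_network_means_no_depletion(self, ref_kinetics, ref_geometry):
        cf, rate = quasi_steady_estimate(ref_kinetics, ref_geometry, L=0.0,
                                         A=REF_A)
        assert cf == pytest.approx(ref_kinetics.C0)
        assert rate == pytest.approx(ref_kinetics.rB * REF_A * ref_kinetics.C0)

    def test_fast_diffusion_restores_far_field(self):
        kin = CofilinKinetics(C0=0.2, D=1e9, rB=0.01, rU=0.0)
        cf, _ = quasi_steady_estimate(kin, NetworkGeometry(W=30, V=0.02), L=50.0,
                                      A=100.0)
        assert cf == pytest.approx(0.2, rel=1e-4)

    def test_direct_evaluation(self):
        kin = CofilinKinetics(C0=1.0, D=10.0, rB=0.00833, rU=0.0)
        cf, _ = quasi_steady_estimate(kin, NetworkGeometry(W=30, V=0.01), L=10.0,
                                      A=50.0, CB=0.0)
        assert cf == pytest.approx(10.0 / (10.0 + 50 * 30 * 10 * 0.00833), rel=1e-12)

    def test_estimates_decrease_with_length(self, ref_kinetics, ref_geometry):
        vals = [quasi_steady_estimate(ref_kinetics, ref_geometry, L, REF_A)
                for L in (1.0, 10.0, 40.0)]
        cfs = [v[0] for v in vals]
        rates = [v[1] for v in vals]
        assert cfs == sorted(cfs, reverse=True)
        assert rates == sorted(rates, reverse=True)


class TestChamberSimulation:
    def test_no_reaction_keeps_fields_uniform(self, constant_actin):
        kin = CofilinKinetics(C0=0.125, D=10.0, rB=0.0, rU=0.0)
        s = simulate_chamber(kin, NetworkGeometry(W=30, V=0.02), constant_actin,
                             t_end=200.0, grid=GridSpec(80, 80, 2.0))
        f = s.fields[-1]
        assert np.allclose(f.CF, 0.125, atol=1e-12)
        assert np.all(f.CB == 0.0)

    def test_closed_domain_conserves_total_cofilin(self, constant_actin):
        kin = CofilinKinetics(C0=0.125, D=5.0, rB=REF_RB, rU=REF_RU)
        s = simulate_chamber(kin, NetworkGeometry(W=20, V=0.02), constant_actin,
                             t_end=400.0, grid=GridSpec(40, 40, 2.0),
                             boundary="closed", output_times=[0, 100, 200, 400])
        totals = [f.total_cofilin() for f in s.fields]
        assert (max(totals) - min(totals)) / totals[0] < 1e-6

    def test_well_mixed_limit_reaches_detailed_balance(self, constant_actin):
        """Large D, closed box: CB/CF relaxes to rB*A/rU ~ 80.6."""
        kin = CofilinKinetics(C0=0.125, D=1000.0, rB=REF_RB, rU=REF_RU)
        s = simulate_chamber(kin, NetworkGeometry(W=20, V=0.0), constant_actin,
                             t_end=3000.0, grid=GridSpec(24, 24, 2.0),
                             boundary="closed", initial_length=24.0, dt=2.0)
        f = s.fields[-1]
        j_le = int(round(s.leading_edge_y / f.dx))
        react = f.mask.copy()
        react[j_le, :] = False  # the inflow row is held cofilin-free by design
        ratio = f.CB[react].mean() / f.CF[react].mean()
        assert ratio == pytest.approx(REF_RB * REF_A / REF_RU, rel=1e-3)

    def test_pure_diffusion_propagates_a_gaussian_exactly(self):
        """With no reaction, an initial Gaussian evolves as the 2D heat kernel."""
        grid = GridSpec(160, 160, 2.0)
        kin = CofilinKinetics(C0=0.0, D=10.0, rB=0.0, rU=0.0)
        x, y = grid.coords()
        jc = grid.ny // 2
        xx, yy = np.meshgrid(x - x[jc], y - y[jc])
        r2 = xx**2 + yy**2

        def heat_kernel(t):
            return 1.0 / (4 * np.pi * kin.D * t) * np.exp(-r2 / (4 * kin.D * t))

        t0, t1 = 10.0, 30.0
        s = simulate_chamber(kin, NetworkGeometry(W=30, V=0.0), ActinProfile(50.0),
                             t_end=t1 - t0, grid=grid, boundary="closed",
                             CF0=heat_kernel(t0), dt=0.25)
        f = s.fields[-1]
        analytic = heat_kernel(t1)
        assert np.abs(f.CF - analytic).max() < 0.02 * analytic.max()

    def test_leading_edge_inflow_is_cofilin_free(self, ref_kinetics, ref_geometry,
                                                 constant_actin):
        s = simulate_chamber(ref_kinetics, ref_geometry, constant_actin,
                             t_end=1200.0, grid=GridSpec(120, 120, 2.0))
        f = s.fields[-1]
        j_le = int(round(s.leading_edge_y / f.dx))
        i_mid = f.CF.shape[1] // 2
        j_down = j_le + int(round(2.0 / f.dx))
        assert f.CB[j_le, i_mid] < 0.01 * f.CB[j_down, i_mid] + 1e-15

    def test_fields_stay_nonnegative_and_bound_only_inside_mask(
            self, ref_kinetics, ref_geometry, constant_actin):
        s = simulate_chamber(ref_kinetics, ref_geometry, constant_actin,
                             t_end=600.0, grid=GridSpec(100, 100, 2.0),
                             output_times=[200, 400, 600])
        for f in s.fields:
            assert f.CF.min() >= 0 and f.CB.min() >= 0
            assert np.all(f.CB[~f.mask] == 0.0)

    def test_cfl_violation_rejected(self, ref_kinetics, constant_actin):
        geo = NetworkGeometry(W=30, V=0.5)
        with pytest.raises(ValueError, match="CFL"):
            simulate_chamber(ref_kinetics, geo, constant_actin, t_end=100.0,
                             grid=GridSpec(80, 80, 2.0), dt=30.0)


class TestDepletionTimecourse:
    def test_constant_without_reaction(self, constant_actin):
        kin = CofilinKinetics(C0=0.125, D=10.0, rB=0.0, rU=0.0)
        s = simulate_chamber(kin, NetworkGeometry(W=30, V=0.02), constant_actin,
                             t_end=300.0, grid=GridSpec(80, 80, 2.0),
                             output_times=[100, 200, 300])
        _, means = depletion_timecourse(s)
        assert np.allclose(means, 0.125, atol=1e-12)

    def test_mean_free_cofilin_decreases_while_growing(self, ref_kinetics,
                                                       ref_geometry, constant_actin):
        s = simulate_chamber(ref_kinetics, ref_geometry, constant_actin,
                             t_end=1800.0, grid=GridSpec(150, 150, 3.0),
                             output_times=list(np.linspace(150, 1800, 12)))
        _, means = depletion_timecourse(s)
        assert np.all(np.diff(means) < 0)

    def test_depletion_deepens_with_width_density_and_binding_rate(self,
                                                                   constant_actin):
        def final_mean(W=20.0, A=50.0, rB=REF_RB):
            kin = CofilinKinetics(C0=REF_C0, D=10.0, rB=rB, rU=REF_RU)
            s = simulate_chamber(kin, NetworkGeometry(W=W, V=REF_V),
                                 ActinProfile(A), t_end=1200.0,
                                 grid=GridSpec(120, 120, 2.0))
            _, m = depletion_timecourse(s)
            return m[-1]

        base = final_mean()
        assert final_mean(W=40.0) < base
        assert final_mean(A=100.0) < base
        assert final_mean(rB=2 * REF_RB) < base

    def test_empty_region_rejected(self, ref_kinetics, ref_geometry,
                                   constant_actin):
        s = simulate_chamber(ref_kinetics, ref_geometry, constant_actin,
                             t_end=120.0, grid=GridSpec(80, 80, 2.0))
        with pytest.raises(ValueError):
            depletion_timecourse(s, region=(500.0, 600.0, 500.0, 600.0))

    def test_pde_mean_within_factor_two_of_quasi_steady_oracle(self):
        """Frozen-growth steady state vs the closed-form estimate.

        The estimate is an order-of-magnitude balance; factor-two agreement
        holds in the moderate-depletion regime (depletion number up to ~2),
        which is where the sweep sits.
        """
        for W, L0, A in [(20.0, 5.0, 20.0), (20.0, 5.0, 10.0),
                         (30.0, 5.0, 10.0), (20.0, 10.0, 10.0)]:
            kin = CofilinKinetics(C0=REF_C0, D=10.0, rB=REF_RB, rU=0.0)
            geo = NetworkGeometry(W=W, V=0.0)
            s = simulate_chamber(kin, geo, ActinProfile(A), t_end=2500.0,
                                 grid=GridSpec(150, 150, 2.0),
                                 initial_length=L0, dt=2.5)
            f = s.fields[-1]
            pde_mean = f.CF[f.mask].mean()
            est, _ = quasi_steady_estimate(kin, geo, L=L0, A=A, CB=0.0)
            assert est / 2 < pde_mean < est * 2, (W, L0, A, pde_mean, est)


def test_actin_profile_validation_and_interpolation():
    with pytest.raises(ValueError):
        ActinProfile(50.0, y=[0, 10], A=[40.0, 30.0])  # A(0) != A0
    prof = ActinProfile(50.0, y=[0, 10, 20], A=[50.0, 45.0, 5.0])
    assert not prof.is_constant
    assert prof(5.0) == pytest.approx(47.5)
    assert prof(30.0) == pytest.approx(5.0)  # clamped


def test_kinetics_validation():
    with pytest.raises(ValueError):
        CofilinKinetics(C0=-1, D=10, rB=0.01, rU=0.0)
    with pytest.raises(ValueError):
        CofilinKinetics(C0=1, D=10, rB=0.01, rU=0.0, diffusion_correction=1.5)
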