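"""Unit tests for the seven-pool model: kinetics, turnover, derivatives,
carbon balance, and the steady-state solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mimicslite import (
    CalibrationMultiplierSet,
    apply_multipliers,
    fmet_fraction,
    microbial_turnover,
    steady_state,
    steady_state_by_integration,
    uptake_flux,
)
from mimicslite.core import (
    Forcing,
    PoolState,
    _fast_deriv,
    _make_rates,
    derivatives,
    km_value,
    litter_input_rate,
    vmax_rate,
)


def random_forcing(rng, params):
    return Forcing(
        temp=float(rng.uniform(-5, 25)),
        moisture=float(rng.uniform(0, 1)),
        litter_input=litter_input_rate(float(rng.uniform(100, 900)), params),
        lignin_n=float(rng.uniform(5, 120)),
        clay=float(rng.uniform(0, 0.4)),
    )


class TestFmet:
    def test_near_zero_lignin_gives_intercept(self, params):
        assert fmet_fraction(1e-12, params) == pytest.approx(params.f_met0)

    def test_clipped_at_floor_for_very_poor_litter(self, params):
        # the line goes negative well before lignin:N = 200
        assert fmet_fraction(200.0, params) == 0.01

    def test_higher_quality_litter_has_larger_metabolic_fraction(self, params):
        # extreme litters of the shipped site table: 12 (TREE) vs 112 (TALL)
        assert fmet_fraction(12.0, params) > fmet_fraction(112.0, params)
        assert fmet_fraction(112.0, params) == 0.01  # below the clip floor

    def test_monotone_non_increasing(self, params):
        grid = np.linspace(0.5, 150, 200)
        vals = [fmet_fraction(l, params) for l in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_non_positive_lignin_rejected(self, params):
        with pytest.raises(ValueError):
            fmet_fraction(0.0, params)


class TestUptake:
    def test_zero_substrate_gives_zero_flux(self, params):
        assert uptake_flux(1.0, 0.0, 15.0, 0.5, params, "r", "m") == 0.0

    def test_half_saturation_identity(self, params):
        km = km_value(params, 15.0, "r", "m")
        vmax = vmax_rate(params, 15.0, "r", "m")
        flux = uptake_flux(2.0, km, 15.0, 0.5, params, "r", "m")
        assert flux == pytest.approx(2.0 * vmax * 0.5 / 2.0, rel=1e-12)

    def test_vmax_reduction_is_forty_percent(self, params):
        scaled = vmax_rate(params, 10.0, "k", "s")
        unscaled_params = params.copy()
        unscaled_params.vmax_scale = 1.0
        assert scaled == pytest.approx(0.6 * vmax_rate(unscaled_params, 10.0, "k", "s"))

    def test_zero_when_any_factor_vanishes(self, params):
        assert uptake_flux(0.0, 1.0, 10.0, 0.5, params, "r", "m") == 0.0
        assert uptake_flux(1.0, 1.0, 10.0, 0.0, params, "r", "m") == 0.0

    def test_moisture_monotonicity(self, params):
        fluxes = [
            uptake_flux(1.0, 2.0, 12.0, m, params, "k", "s")
            for m in np.linspace(0, 1, 11)
        ]
        assert all(b >= a for a, b in zip(fluxes, fluxes[1:]))

    def test_negative_pool_rejected(self, params):
        with pytest.raises(ValueError):
            uptake_flux(-1.0, 1.0, 10.0, 0.5, params, "r", "m")


class TestTurnover:
    def test_zero_biomass(self):
        assert microbial_turnover(0.0, 1.5, 0.1, 1.0) == 0.0

    def test_linear_case(self):
        assert microbial_turnover(3.0, 1.0, 0.1, 1.0) == pytest.approx(0.3)

    def test_density_dependent_case(self):
        assert microbial_turnover(2.0, 1.5, 0.1, 1.0) == pytest.approx(
            2.0**1.5 * 0.1, rel=1e-12
        )

    def test_beta_one_reduces_to_linear(self, rng):
        for _ in range(20):
            mic, tau, fs = rng.uniform(0, 5), rng.uniform(0.01, 1), rng.uniform(0, 1)
            assert microbial_turnover(mic, 1.0, tau, fs) == pytest.approx(mic * tau * fs)

    def test_negative_biomass_rejected(self):
        with pytest.raises(ValueError):
            microbial_turnover(-0.1, 1.5, 0.1, 1.0)

    @settings(derandomize=True, max_examples=80)
    @given(
        mic=st.floats(min_value=0.0, max_value=50.0),
        beta=st.floats(min_value=1.0, max_value=2.0),
        tau=st.floats(min_value=1e-6, max_value=1.0),
        fs=st.floats(min_value=0.0, max_value=1.0),
    )
    def test_turnover_nonnegative_and_monotone_in_biomass(self, mic, beta, tau, fs):
        flux = microbial_turnover(mic, beta, tau, fs)
        assert flux >= 0.0
        assert microbial_turnover(mic + 1.0, beta, tau, fs) >= flux


class TestDerivatives:
    def test_zero_state_zero_input_is_inert(self, params):
        f = Forcing(temp=10.0, moisture=0.5, litter_input=0.0, lignin_n=25.0, clay=0.1)
        dy = derivatives(np.zeros(7), f, params)
        assert np.all(dy == 0.0)

    def test_carbon_conservation_random_states(self, params, rng):
        for _ in range(200):
            f = random_forcing(rng, params)
            y = rng.uniform(0, 10, 7)
            dy, resp = derivatives(y, f, params, return_respiration=True)
            residual = abs(f.litter_input - resp - dy.sum())
            assert residual <= 1e-10 * max(f.litter_input, 1.0)

    def test_one_step_euler_matches_manual_flux_evaluation(self, params):
        """Every flux recomputed by hand with the raw formulas, independent
        of the package's derivative assembly."""
        y = np.array([0.8, 2.5, 0.3, 0.4, 1.2, 1.5, 0.6])
        f = Forcing(temp=12.0, moisture=0.7,
                    litter_input=litter_input_rate(600.0, params),
                    lignin_n=28.0, clay=0.12)
        p = params
        fmet = min(max(p.f_met0 - p.f_met_slope * 28.0, 0.01), 0.99)

        def vmax(mod):
            return np.exp(p.v_slope * 12.0 + p.v_int) * p.a_v * mod * p.vmax_scale

        def km(slope, mod):
            return np.exp(slope * 12.0 + p.k_int) * p.a_k / mod

        u_rm = 0.3 * vmax(p.v_mod_m["r"]) * y[0] / (km(p.k_slope["m"], p.k_mod_m["r"]) + y[0]) * 0.7
        u_rs = 0.3 * vmax(p.v_mod_s["r"]) * y[1] / (km(p.k_slope["s"], p.k_mod_s["r"]) + y[1]) * 0.7
        u_km = 0.4 * vmax(p.v_mod_m["k"]) * y[0] / (km(p.k_slope["m"], p.k_mod_m["k"]) + y[0]) * 0.7
        u_ks = 0.4 * vmax(p.v_mod_s["k"]) * y[1] / (km(p.k_slope["s"], p.k_mod_s["k"]) + y[1]) * 0.7
        u_ra = 0.3 * vmax(p.v_mod_a["r"]) * y[6] / (p.k_o["r"] * km(p.k_slope["a"], p.k_mod_a["r"]) + y[6]) * 0.7
        u_ka = 0.4 * vmax(p.v_mod_a["k"]) * y[6] / (p.k_o["k"] * km(p.k_slope["a"], p.k_mod_a["k"]) + y[6]) * 0.7
        oxid = (0.3 * vmax(p.v_mod_s["r"]) * y[5] / (p.k_o["r"] * km(p.k_slope["s"], p.k_mod_s["r"]) + y[5]) * 0.7
                + 0.4 * vmax(p.v_mod_s["k"]) * y[5] / (p.k_o["k"] * km(p.k_slope["s"], p.k_mod_s["k"]) + y[5]) * 0.7)
        tau_r = p.tau_base["r"] * np.exp(p.tau_mod_r * fmet)
        tau_k = p.tau_base["k"] * np.exp(p.tau_mod_k * fmet)
        trn_r = 0.3**p.beta * tau_r
        trn_k = 0.4**p.beta * tau_k
        des = y[4] * p.d_base * np.exp(-p.d_clay * 0.12)
        inp_m, inp_s = f.litter_input * fmet, f.litter_input * (1 - fmet)
        expected = np.array([
            inp_m * 0.95 - u_rm - u_km,
            inp_s * 0.95 - u_rs - u_ks,
            0.55 * u_rm + 0.25 * u_rs + 0.55 * u_ra - trn_r,
            0.75 * u_km + 0.35 * u_ks + 0.75 * u_ka - trn_k,
            inp_m * 0.05 + trn_r * 0.30 + trn_k * 0.20 - des,
            inp_s * 0.05 + trn_r * 0.10 + trn_k * 0.20 - oxid,
            trn_r * 0.60 + trn_k * 0.60 + des + oxid - u_ra - u_ka,
        ])
        dy = derivatives(y, f, params)
        np.testing.assert_allclose(dy, expected, rtol=1e-12)
        # and the one-step Euler update
        np.testing.assert_allclose(y + 1.0 * dy, y + expected, rtol=1e-12)

    def test_fast_kernels_match_reference(self, params, rng):
        from mimicslite import _kernels

        for _ in range(30):
            f = random_forcing(rng, params)
            y = rng.uniform(0, 8, 7)
            rates = _make_rates(params, f)
            ref = derivatives(y, f, params, rates=rates)
            fast = np.array(_fast_deriv(params, f, rates)(0.0, y))
            np.testing.assert_allclose(fast, ref, rtol=1e-12, atol=1e-20)
            if _kernels.HAVE_NUMBA:
                out = np.empty(7)
                _kernels._rhs(y, _kernels.pack_coefficients(params, f, rates), out)
                np.testing.assert_allclose(out, ref, rtol=1e-12, atol=1e-20)

    def test_negative_state_rejected(self, params):
        f = Forcing(temp=10.0, moisture=0.5, litter_input=0.0, lignin_n=25.0, clay=0.1)
        with pytest.raises(ValueError):
            derivatives(np.array([-1.0, 0, 0, 0, 0, 0, 0]), f, params)

    def test_non_finite_forcing_rejected(self, params):
        with pytest.raises(ValueError):
            Forcing(temp=np.nan, moisture=0.5, litter_input=0.0, lignin_n=25.0, clay=0.1)


class TestSteadyState:
    def test_zero_litterfall_gives_empty_steady_state(self, tree, params):
        import dataclasses

        bare = dataclasses.replace(tree, litterfall=0.0)
        res = steady_state(bare, "mean", 30.0, params)
        assert res.pools.total == 0.0
        assert res.residual == 0.0

    def test_residual_below_tolerance(self, tree, params):
        res = steady_state(tree, "mean", 30.0, params)
        assert res.residual < 1e-8
        f = res.forcing
        dy = derivatives(res.pools, f, params)
        assert np.max(np.abs(dy)) < 1e-8 * f.litter_input

    def test_agrees_with_long_integration_oracle(self, tree, params):
        res = steady_state(tree, "mean", 30.0, params)
        oracle = steady_state_by_integration(tree, "mean", 30.0, params, years=500)
        np.testing.assert_allclose(
            res.pools.as_array(), oracle.as_array(), rtol=0.01
        )

    def test_pools_positive_and_viable(self, tree, params):
        res = steady_state(tree, "min", 12.0, params)
        assert np.all(res.pools.as_array() > 0)
        assert res.viable_r and res.viable_k

    def test_pool_state_rejects_negative_carbon(self):
        with pytest.raises(ValueError):
            PoolState(lit_m=-0.1)


class TestApplyMultipliers:
    def test_identity(self, params):
        out = apply_multipliers(params, CalibrationMultiplierSet.identity())
        assert out.to_dict() == params.to_dict()

    def test_first_calibrated_set_scales_the_four_parameters(self, params):
        mults = CalibrationMultiplierSet(1.33, 0.76, 1.76, 0.93)
        out = apply_multipliers(params, mults)
        assert out.tau_mod_r == pytest.approx(0.3 * 1.33)
        assert out.beta == pytest.approx(1.5 * 0.76)
        assert out.v_mod_m["r"] == pytest.approx(10.0 * 1.76)
        assert out.v_mod_m["k"] == pytest.approx(3.0 * 1.76)
        assert out.v_mod_s["r"] == pytest.approx(2.0 * 0.93)
        assert out.v_mod_s["k"] == pytest.approx(3.0 * 0.93)
        # everything else untouched
        assert out.cue == params.cue
        assert out.tau_base == params.tau_base

    def test_range_maximum_doubles_turnover_coefficient(self, params):
        out = apply_multipliers(params, CalibrationMultiplierSet(2.0, 1.0, 1.0, 1.0))
        assert out.tau_mod_r == pytest.approx(0.6)

    def test_out_of_range_rejected(self, params):
        with pytest.raises(ValueError):
            apply_multipliers(params, CalibrationMultiplierSet(2.5, 1.0, 1.0, 1.0))
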