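"""Atmospheric perturbation model: impulse response, burden recursion,
radiative balance, switchover detection and Monte-Carlo uncertainty."""
import numpy as np
import pytest

from wetlandghg.forcing import (
    GC_TO_KG_CH4,
    GC_TO_KG_CO2,
    AnnualFluxScenario,
    BurdenState,
    PerturbationParams,
    co2_impulse_response,
    mass_convert,
    radiative_balance,
    simulate_burdens,
    step_burdens,
    switchover,
    switchover_mc,
)


@pytest.fixture(scope="module")
def params():
    return PerturbationParams.default()


def random_params(rng):
    a = rng.dirichlet(np.ones(5))
    tau = np.r_[np.inf, 10 ** rng.uniform(0.5, 3, 4)]
    return PerturbationParams(
        co2_pool_fractions=a, co2_pool_lifetimes=tau,
        ch4_lifetime=rng.uniform(8, 15), ch4_oxidation_yield=rng.uniform(0, 1),
        re_co2=1.76e-15, re_ch4=1.28e-13,
    )


class TestParams:
    def test_default_invariants(self, params):
        assert params.co2_pool_fractions.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.isinf(params.co2_pool_lifetimes).sum() == 1
        assert params.ch4_lifetime == 12.4
        assert params.ch4_indirect_multiplier == 1.65

    @pytest.mark.parametrize("bad", [
        dict(co2_pool_fractions=[0.5, 0.4]),
        dict(ch4_lifetime=-1.0),
        dict(ch4_oxidation_yield=1.5),
        dict(re_co2=-1.0),
        dict(ch4_indirect_multiplier=0.5),
    ])
    def test_invalid_rejected(self, params, bad):
        kw = dict(
            co2_pool_fractions=params.co2_pool_fractions,
            co2_pool_lifetimes=params.co2_pool_lifetimes,
            ch4_lifetime=params.ch4_lifetime,
            ch4_oxidation_yield=params.ch4_oxidation_yield,
            re_co2=params.re_co2, re_ch4=params.re_ch4,
            ch4_indirect_multiplier=params.ch4_indirect_multiplier,
        )
        if "co2_pool_fractions" in bad:
            bad["co2_pool_lifetimes"] = [1.0, 2.0]
        kw.update(bad)
        with pytest.raises(ValueError):
            PerturbationParams(**kw)


class TestMassConvert:
    def test_molar_arithmetic(self):
        assert mass_convert(12.0, "co2") == pytest.approx(0.044)
        assert mass_convert(12.0, "ch4") == pytest.approx(0.016)

    def test_typical_annual_ch4_flux(self):
        # a 35 gC m-2 yr-1 CH4 emission in kg CH4
        assert mass_convert(35.0, "ch4") == pytest.approx(0.046667, rel=1e-4)

    def test_unknown_gas(self):
        with pytest.raises(ValueError):
            mass_convert(1.0, "h2o")


class TestImpulseResponse:
    def test_t0_is_one(self, params):
        assert co2_impulse_response(0.0, params) == pytest.approx(1.0, abs=1e-12)

    def test_asymptote_is_permanent_pool(self, params):
        perm = params.co2_pool_fractions[np.isinf(params.co2_pool_lifetimes)].sum()
        assert co2_impulse_response(1e6, params) == pytest.approx(perm, rel=1e-9)

    def test_term_by_term_oracle(self, params):
        t = 10.0
        expected = sum(
            a * (1.0 if np.isinf(tau) else np.exp(-t / tau))
            for a, tau in zip(params.co2_pool_fractions, params.co2_pool_lifetimes)
        )
        assert co2_impulse_response(t, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_t_rejected(self, params):
        with pytest.raises(ValueError):
            co2_impulse_response(-1.0, params)


class TestBurdenRecursion:
    def test_zero_in_zero_out(self, params):
        co2, ch4 = simulate_burdens(np.zeros(50), np.zeros(50), params)
        assert not co2.any() and not ch4.any()

    def test_co2_pulse_matches_closed_form(self, params):
        T = 200
        co2_in = np.zeros(T)
        co2_in[0] = 2.5
        co2_b, _ = simulate_burdens(co2_in, np.zeros(T), params)
        expected = 2.5 * co2_impulse_response(np.arange(T), params)
        np.testing.assert_allclose(co2_b, expected, rtol=1e-9)

    def test_ch4_pulse_carbon_ledger_closes(self, params):
        """With full oxidation, CH4-C + airborne CO2-C + removed CO2-C is conserved."""
        state = BurdenState.zero(params)
        pulse_kg_ch4 = 1.0
        pulse_c = pulse_kg_ch4 * 12.0 / 16.0
        removed_c = 0.0
        for t in range(150):
            state, info = step_burdens(state, 0.0, pulse_kg_ch4 if t == 0 else 0.0, params)
            removed_c += info["co2_removed"] * 12.0 / 44.0
            total_c = state.ch4 * 12.0 / 16.0 + state.co2 * 12.0 / 44.0 + removed_c
            assert total_c == pytest.approx(pulse_c, rel=1e-12)

    def test_shape_mismatch_rejected(self, params):
        with pytest.raises(ValueError):
            simulate_burdens(np.zeros(5), np.zeros(6), params)


class TestRadiativeBalance:
    def test_sustained_ch4_approaches_first_order_plateau(self, params):
        emission = 0.05  # kg CH4 m-2 yr-1 after conversion
        scn = AnnualFluxScenario(
            nee=[0.0], ch4=[emission / GC_TO_KG_CH4], horizon=200, mode="sustained"
        )
        traj = radiative_balance(scn, params)
        # steady state of x <- x e^{-1/tau} + E is E / (1 - e^{-1/tau})
        plateau = emission / (1.0 - np.exp(-1.0 / params.ch4_lifetime))
        assert traj.ch4_burden[-1] == pytest.approx(plateau, rel=1e-3)

    def test_uptake_only_scenario_cools(self, params):
        scn = AnnualFluxScenario(nee=[-400.0], ch4=[0.0], horizon=100)
        traj = radiative_balance(scn, params)
        assert (traj.forcing < 0).all()
        assert traj.switchover_year == 1

    def test_identical_baseline_cancels(self, params):
        scn = AnnualFluxScenario(nee=[-300.0, -350.0], ch4=[30.0, 40.0],
                                 baseline_nee=np.array([-300.0, -350.0]),
                                 baseline_ch4=np.array([30.0, 40.0]), horizon=50)
        traj = radiative_balance(scn, params)
        np.testing.assert_allclose(traj.delta_forcing, 0.0, atol=1e-25)

    def test_horizon_shorter_than_record_rejected(self):
        with pytest.raises(ValueError):
            AnnualFluxScenario(nee=np.zeros(10), ch4=np.zeros(10), horizon=5)

    def test_superposition_of_pulses(self, params):
        """Sustained trajectory equals the time-shifted sum of pulse trajectories."""
        rng = np.random.default_rng(5)
        T = 120
        nee = rng.normal(-300, 150, 6)
        ch4 = rng.uniform(10, 60, 6)
        scn = AnnualFluxScenario(nee=nee, ch4=ch4, horizon=T)
        traj = radiative_balance(scn, params)
        co2_in, ch4_in, _, _ = scn.inputs()
        total = np.zeros(T)
        for s in range(T):
            pulse_co2 = np.zeros(T - s)
            pulse_ch4 = np.zeros(T - s)
            pulse_co2[0], pulse_ch4[0] = co2_in[s], ch4_in[s]
            cb, mb = simulate_burdens(pulse_co2, pulse_ch4, params)
            total[s:] += params.re_co2 * cb + \
                params.re_ch4 * params.ch4_indirect_multiplier * mb
        np.testing.assert_allclose(traj.forcing, total, rtol=1e-9)


class TestSwitchover:
    def test_all_negative_is_year_one(self):
        assert switchover(-np.ones(200)) == 1

    def test_all_positive_is_undeterminable(self):
        assert switchover(np.ones(200)) is None

    def test_constructed_crossing(self):
        # crosses zero between years 40 and 41, never re-crosses
        delta = 40.5 - np.arange(1.0, 201.0)
        assert switchover(delta) == 41

    def test_persistent_rule_ignores_transient_dip(self):
        delta = np.ones(100)
        delta[10] = -1.0
        delta[60:] = -1.0
        assert switchover(delta, persistent=True) == 61
        assert switchover(delta, persistent=False) == 11


class TestSwitchoverMC:
    def test_zero_variance_degenerate_interval(self, params):
        mc = switchover_mc([-400.0, -400.0, -400.0], [35.0, 35.0, 35.0],
                           params=params, n=200, seed=1)
        assert mc.ci_width == 0.0
        assert mc.undefined_fraction == 0.0

    def test_variance_widens_interval(self, params):
        mc = switchover_mc([-300.0, -500.0, -400.0], [10.0, 60.0, 35.0],
                           params=params, n=400, seed=2)
        assert mc.ci_width > 0

    def test_no_ch4_uptake_record_switches_immediately(self, params):
        mc = switchover_mc([-300.0, -400.0], [0.0, 0.0], params=params, n=200, seed=3)
        assert (mc.years == 1).all()
        assert mc.ci == (1.0, 1.0)

    def test_single_year_record_warns(self, params):
        with pytest.warns(UserWarning):
            switchover_mc([-400.0], [35.0], params=params, n=50, seed=4)

    def test_more_ch4_never_shortens_switchover(self, params):
        """Holding NEE fixed, raising CH4 raises delta-forcing at every t."""
        prev = np.full(100, -np.inf)
        last_year = 0
        for ch4 in (0.0, 10.0, 30.0, 60.0):
            traj = radiative_balance(
                AnnualFluxScenario(nee=[-400.0], ch4=[ch4], horizon=100), params
            )
            assert (traj.delta_forcing >= prev - 1e-20).all()
            year = traj.switchover_year or 10**9
            assert year >= last_year
            prev, last_year = traj.delta_forcing, year
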