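"""Reaction network structure, Michaelis–Menten rate laws, and steady states."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from pyrflux.model import (
    FIXED_SPECIES,
    PARAM_NAMES,
    SPECIES,
    NetworkConfig,
    ParameterSet,
    PathwayState,
    SteadyStateError,
    build_network,
    reaction_rates,
    steady_state,
    time_derivatives,
)


def params_with(base: ParameterSet, **overrides) -> ParameterSet:
    values = base.to_dict()
    values.update(overrides)
    return ParameterSet.from_dict(values)


class TestNetworkStructure:
    def test_default_topology(self, network):
        assert len(SPECIES) == 9
        # 9 enzymatic reactions + 2 utilization drains
        assert len(network.reactions) == 11
        by_id = {r.id: r for r in network.reactions}
        # UMP has exactly one enzymatic inflow (r6) and one outflow (r10)
        assert by_id["r6"].products == ("ump",)
        assert by_id["r10"].substrates == ("ump",)
        producers = [r.id for r in network.reactions if "ump" in r.products]
        consumers = [r.id for r in network.reactions if "ump" in r.substrates]
        assert producers == ["r6"] and consumers == ["r10"]
        # CPSase carries the UTP modifier; ATCase does not by default
        assert by_id["r1"].modifiers == ("utp",)
        assert by_id["r2"].modifiers == ()

    def test_atcase_inhibition_flag(self, popt):
        net = build_network(NetworkConfig(utp_inhibits_atcase=True))
        by_id = {r.id: r for r in net.reactions}
        assert by_id["r2"].modifiers == ("utp",)
        rates_on = reaction_rates(PathwayState(np.full(9, 0.01)), popt, net)
        rates_off = reaction_rates(PathwayState(np.full(9, 0.01)), popt,
                                   build_network())
        assert rates_on["r2"] < rates_off["r2"]
        assert rates_on["r1"] == pytest.approx(rates_off["r1"])

    def test_zero_dilution_config(self, popt):
        net0 = build_network(NetworkConfig(dilution_rate=0.0))
        net = build_network()
        x = np.full(9, 0.05)
        d0 = net0.derivatives_array(x, popt.as_array())
        d = net.derivatives_array(x, popt.as_array())
        np.testing.assert_allclose(d0, d + 0.11 * x, rtol=1e-12)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="km2_substrate"):
            NetworkConfig(km2_substrate="prpp")

    def test_unreferenced_parameter_rejected(self):
        # removing both drains leaves g_pyr/K_Mp orphaned
        with pytest.raises(ValueError, match="referenced by no reaction"):
            build_network(NetworkConfig(drain_species=()))

    def test_parameter_set_validation(self):
        with pytest.raises(ValueError):
            ParameterSet(np.ones(27))
        bad = np.ones(28)
        bad[3] = -1.0
        with pytest.raises(ValueError):
            ParameterSet(bad)
        with pytest.raises(ValueError, match="missing"):
            ParameterSet.from_dict({n: 1.0 for n in PARAM_NAMES[:-1]})


class TestReactionRates:
    def test_zero_substrates_give_zero_flux(self, popt, network):
        rates = reaction_rates(PathwayState(np.zeros(9)), popt, network)
        enzymatic = {k: v for k, v in rates.items() if k != "r1"}
        assert all(v == 0 for v in enzymatic.values())
        assert rates["r1"] > 0  # clamped substrates keep CPSase running

    def test_saturation_limit(self, popt, network):
        x = np.full(9, 1e6)
        x[SPECIES.index("utp")] = 0.0  # no inhibition
        rates = reaction_rates(PathwayState(x), popt, network)
        assert rates["r4"] == pytest.approx(popt["vmax4"], rel=1e-5)
        assert rates["r10"] == pytest.approx(popt["vmax10"], rel=1e-5)

    def test_half_saturation_identity(self, popt, network):
        x = np.zeros(9)
        x[SPECIES.index("dho")] = popt["K_m4"]
        rates = reaction_rates(PathwayState(x), popt, network)
        assert rates["r4"] == pytest.approx(popt["vmax4"] / 2, rel=1e-12)

    def test_fluxes_bounded_by_vmax(self, popt, network):
        rng = np.random.default_rng(5)
        vmax_of = {"r1": "vmax1", "r2": "vmax2", "r3": "vmax3", "r4": "vmax4",
                   "r5": "vmax5", "r6": "vmax6", "r10": "vmax10", "r7": "vmax7",
                   "r8": "vmax8", "util_utp": "g_pyr", "util_ctp": "g_pyr"}
        for _ in range(25):
            x = rng.lognormal(-3, 2, size=9)
            rates = reaction_rates(PathwayState(x), popt, network)
            for rid, flux in rates.items():
                assert 0 <= flux <= popt[vmax_of[rid]]

    def test_monotone_saturation(self, popt, network):
        """Each flux is non-decreasing in its substrate, non-increasing in Km."""
        rng = np.random.default_rng(11)
        sub_of = {"r3": "ca", "r4": "dho", "r5": "oro", "r6": "omp",
                  "r10": "ump", "r7": "udp", "r8": "utp"}
        km_of = {"r3": "K_m3", "r4": "K_m4", "r5": "K_m5", "r6": "K_m6",
                 "r10": "K_m10", "r7": "K_m7", "r8": "K_m8"}
        for _ in range(10):
            x = rng.lognormal(-3, 2, size=9)
            for rid, sp in sub_of.items():
                x_hi = x.copy()
                x_hi[SPECIES.index(sp)] *= 1.01
                r_lo = reaction_rates(PathwayState(x), popt, network)[rid]
                r_hi = reaction_rates(PathwayState(x_hi), popt, network)[rid]
                assert r_hi >= r_lo
                p_hi = params_with(popt, **{km_of[rid]: popt[km_of[rid]] * 1.01})
                r_km = reaction_rates(PathwayState(x), p_hi, network)[rid]
                assert r_km <= r_lo

    def test_negative_concentration_rejected(self, popt, network):
        x = np.zeros(9)
        x[0] = 1e-3
        state = PathwayState(x)
        bad = x.copy()
        bad[1] = -1e-6
        with pytest.raises(ValueError):
            reaction_rates(bad, popt, network)
        with pytest.raises(ValueError):
            time_derivatives(bad, popt, network)
        reaction_rates(state, popt, network)  # non-negative passes


class TestTimeDerivatives:
    def test_dilution_only_limit(self, popt, network):
        """With vanishing enzyme activity, dX/dt -> -d*X for every species."""
        tiny = {n: 1e-30 for n in PARAM_NAMES if n.startswith(("vmax", "g_pyr"))}
        p = params_with(popt, **tiny)
        x = np.linspace(0.01, 0.09, 9)
        dx = time_derivatives(PathwayState(x), p, network)
        np.testing.assert_allclose(dx, -0.11 * x, rtol=1e-9)

    def test_derivative_vanishes_at_steady_state(self, base_result, popt, network):
        dx = time_derivatives(base_result.state, popt, network)
        assert np.max(np.abs(dx)) < 1e-10

    def test_exponential_relaxation_closed_form(self, popt, network):
        """Decoupled first species: X(t) = (v/d)(1 - exp(-d t)) analytically.

        With ATCase switched off (vmax2 -> 0) and nothing downstream, cp
        obeys dX/dt = v - d*X with constant inflow v; the integrated
        trajectory must match the closed form to 6 significant figures.
        """
        p = params_with(popt, vmax2=1e-30)
        v = reaction_rates(PathwayState(np.zeros(9)), p, network)["r1"]
        d = network.config.dilution_rate
        sol = solve_ivp(
            lambda t, y: network.derivatives_array(np.maximum(y, 0), p.as_array()),
            (0.0, 30.0), np.zeros(9), method="LSODA",
            t_eval=[2.0, 10.0, 30.0], rtol=1e-10, atol=1e-14)
        cp_num = sol.y[SPECIES.index("cp")]
        cp_exact = (v / d) * (1 - np.exp(-d * np.asarray(sol.t)))
        np.testing.assert_allclose(cp_num, cp_exact, rtol=1e-6)


class TestSteadyState:
    def test_residual_stability_and_positivity(self, base_result):
        assert base_result.residual < 1e-10
        assert base_result.stable
        assert np.all(base_result.state.as_array() > 0)
        assert np.all(base_result.eigenvalues.real < 0)

    def test_matches_reference_concentrations(self, base_result):
        from pyrflux.io import load_reference_steady_state
        ref = load_reference_steady_state().set_index("metabolite")
        for sp in ("ump", "udp", "utp", "ctp", "cp", "ca", "dho", "omp"):
            assert base_result[sp] == pytest.approx(
                ref.loc[sp, "model_concentration_mM"], rel=0.2)

    def test_closed_form_single_species(self, popt, network):
        """cp* = v/d exactly when the rest of the pathway is switched off."""
        p = params_with(popt, vmax2=1e-30)
        v = reaction_rates(PathwayState(np.zeros(9)), p, network)["r1"]
        res = steady_state(p, network)
        assert res["cp"] == pytest.approx(v / 0.11, rel=1e-8)
        assert res["ump"] < 1e-12

    def test_dilution_only_decays_to_zero(self, popt, network):
        tiny = {n: 1e-30 for n in PARAM_NAMES if n.startswith(("vmax", "g_pyr"))}
        res = steady_state(params_with(popt, **tiny), network)
        assert np.max(res.state.as_array()) < 1e-12

    def test_solver_route_equivalence(self, popt, network, base_result):
        """Long-time integration alone agrees with integrate-then-polish."""
        from pyrflux.model import _integrate_to_plateau
        plateau = _integrate_to_plateau(network, popt.as_array(),
                                        np.full(9, 1e-6), rate_tol=1e-11)
        np.testing.assert_allclose(plateau, base_result.state.as_array(),
                                   rtol=1e-6)

    def test_warm_start_returns_same_state(self, popt, network, base_result):
        warm = steady_state(popt, network, x0=base_result.state)
        np.testing.assert_allclose(warm.state.as_array(),
                                   base_result.state.as_array(), rtol=1e-9)

    def test_flux_balance_per_species(self, popt, network, base_result):
        """Net enzymatic inflow equals outflow plus dilution, per species."""
        rates = reaction_rates(base_result.state, popt, network)
        inflow = {sp: 0.0 for sp in SPECIES}
        outflow = {sp: 0.0 for sp in SPECIES}
        for rxn in network.reactions:
            for sp in rxn.products:
                inflow[sp] += rates[rxn.id]
            for sp in rxn.substrates:
                if sp in inflow:  # dynamic species only
                    outflow[sp] += rates[rxn.id]
        for sp in SPECIES:
            drain = 0.11 * base_result[sp]
            assert inflow[sp] == pytest.approx(outflow[sp] + drain, abs=1e-10)

    def test_failure_reports_last_state(self, network):
        # a pathological parameter set: all rates enormous, Kms tiny
        values = {n: (1e12 if n.startswith("vmax") else 1e-12)
                  for n in PARAM_NAMES}
        for n in FIXED_SPECIES:
            values[n] = 1.0
        values["g_pyr"] = 1e12
        values["K_utp"] = 1e-12
        try:
            steady_state(ParameterSet.from_dict(values), network)
        except SteadyStateError as err:
            assert err.last_state is not None
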