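"""Shared fixtures.

Expensive objects (the reference steady state, the sensitivity table at
the published optimum, the multistart ensemble, the synthetic recovery
fit, the null-calibration p-values) are session-scoped so each is
computed once for the whole suite.
"""

import numpy as np
import pytest

from pyrflux import build_network, steady_state
from pyrflux.calibration import ObservationSet, PriorSpec, multistart_fit
from pyrflux.io import (
    load_initial_parameters,
    load_optimized_parameters,
    load_reference_table,
)
from pyrflux.sensitivity import enzyme_influence, sensitivity_table


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def popt():
    """Published best-fit parameter values."""
    return load_optimized_parameters()


@pytest.fixture(scope="session")
def p0():
    """Experimentally referenced (prior-mode) parameter values."""
    return load_initial_parameters()


@pytest.fixture(scope="session")
def priors():
    return PriorSpec.from_reference_table()


@pytest.fixture(scope="session")
def obs():
    return ObservationSet()


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def base_result(popt, network):
    """Steady state at the published optimum."""
    return steady_state(popt, network)


@pytest.fixture(scope="session")
def sens_table_opt(popt, network):
    """Sensitivity table at the published optimum (1 % step)."""
    return sensitivity_table(popt, network)


@pytest.fixture(scope="session")
def influence_opt(sens_table_opt):
    return enzyme_influence(sens_table_opt)


@pytest.fixture(scope="session")
def ensemble25():
    """A 25-run multistart calibration ensemble with a fixed master seed."""
    return multistart_fit(25, seed=20260919)


@pytest.fixture(scope="session")
def recovery():
    """Calibration against noiseless synthetic observations from known truth.

    Returns (true_params, ensemble, influence_table) for a scenario with
    ground truth drawn 0.1 decades around the priors.  Three steady-state
    observations identify parameter combinations, not all 28 coordinates,
    so factor-2 recovery of individual parameters is only a meaningful
    claim inside this identifiable neighbourhood of the prior.
    """
    from pyrflux.synthetic import (
        generate_true_params,
        scenario_rngs,
        simulate_observations,
    )

    net = build_network()
    priors = PriorSpec.from_reference_table()
    rngs = scenario_rngs(7)
    truth = generate_true_params(priors, 0.1, rngs["params"])
    synthetic_obs = simulate_observations(truth, 0.0, rngs["noise"], net)
    ens = multistart_fit(3, seed=7, obs=synthetic_obs, priors=priors, network=net)
    infl = enzyme_influence(sensitivity_table(ens.best.params, net))
    return truth, ens, infl


@pytest.fixture(scope="session")
def null_pvalues(influence_opt):
    """Exact-permutation p-values for 1000 influence-independent dN/dS draws."""
    from pyrflux.selection import link_analysis
    from pyrflux.synthetic import generate_dnds

    rng = np.random.default_rng(20260920)
    pvals = []
    for _ in range(1000):
        rates = generate_dnds(influence_opt, beta=0.0, noise_sd=0.3, rng=rng)
        pvals.append(link_analysis(influence_opt, rates, subset="all").p_value)
    return np.asarray(pvals)
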