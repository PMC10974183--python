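import numpy as np
import pytest

import mixtox as m
from mixtox.io import effect_table
from mixtox.simulate import default_scenario, simulate_mixture, simulate_single


@pytest.fixture(scope="session")
def amp_curve():
    """Truth curve with EC50 = 1.18e-4 mol/L (Weibull, slope 3)."""
    return m.weibull_from_ec50(1.18e-4, 3.0)


@pytest.fixture(scope="session")
def czo_curve():
    """Truth curve with EC50 = 1.99e-4 mol/L (Weibull, slope 3)."""
    return m.weibull_from_ec50(1.99e-4, 3.0)


@pytest.fixture(scope="session")
def binary_ray(amp_curve, czo_curve):
    """0.20:0.80 fixed-ratio ray over the two truth curves."""
    return m.MixtureRay(
        [m.MixtureComponent("AMP", amp_curve), m.MixtureComponent("CZO", czo_curve)],
        (0.20, 0.80),
    )


def fit_components_from_singles(scenario):
    """Simulate singles under a scenario, fit each, return the fitted ray."""
    effs, _ = effect_table(simulate_single(scenario))
    comps = []
    for cid in scenario.truth:
        sub = effs[effs["treatment"] == cid]
        model = m.DoseResponseCurve().fit(
            sub["concentration"].to_numpy().reshape(-1, 1), sub["effect"]
        )
        comps.append(m.MixtureComponent(cid, model.params_))
    return m.MixtureRay(comps, scenario.fractions)


def assess_one_seed(interaction, seed, noise_sd=0.02, n_boot=500, levels=(0.5,)):
    """Full single-seed pipeline: simulate, fit components, assess mixture."""
    scenario = default_scenario(interaction=interaction, noise_sd=noise_sd, seed=seed)
    ray = fit_components_from_singles(scenario)
    eff, _ = effect_table(simulate_mixture(scenario))
    return m.assess(
        ray, eff["concentration"], eff["effect"],
        effect_levels=levels, n_boot=n_boot, seed=seed,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240314)
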