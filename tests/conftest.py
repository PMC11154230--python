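import numpy as np
import pytest

import fluxmodes as fm


@pytest.fixture(scope="session")
def aearm():
    return fm.make_aearm()


@pytest.fixture(scope="session")
def toy():
    return fm.make_toy_bifurcation()


@pytest.fixture(scope="session")
def toy_grid():
    return np.linspace(0.0, 2000.0, 100)


@pytest.fixture(scope="session")
def planted_three_regimes(toy):
    """3-regime toy ensemble: branch-1 dominant, branch-2 dominant, balanced."""
    regimes = [
        fm.PlantedRegime(0, {"k1": 100.0}, "branch-1 dominant"),
        fm.PlantedRegime(1, {"k2": 100.0}, "branch-2 dominant"),
        fm.PlantedRegime(2, {}, "balanced: both branches on par"),
    ]
    ensemble, truth = fm.planted_regime_ensemble(
        toy, regimes, fm.toy_nominal_params(), n_per_regime=50,
        jitter_sd=0.05, seed=42)
    return ensemble, truth


def random_network(rng, max_reactions=8):
    """A random small mass-action network for oracle comparisons."""
    n_species = rng.integers(3, 7)
    names = [f"X{i}" for i in range(n_species)]
    species = [fm.SpeciesDef(n, float(rng.uniform(1, 100))) for n in names]
    n_rxn = rng.integers(2, max_reactions + 1)
    reactions = []
    for j in range(n_rxn):
        reactants = {
            names[i]: int(rng.integers(1, 3))
            for i in rng.choice(n_species, size=rng.integers(1, 3), replace=False)
        }
        products = {
            names[i]: int(rng.integers(1, 3))
            for i in rng.choice(n_species, size=rng.integers(1, 3), replace=False)
        }
        reversible = bool(rng.random() < 0.5)
        reactions.append(fm.Reaction(
            id=f"r{j}", reactant_stoich=reactants, product_stoich=products,
            forward_rate_param=f"kf{j}", reversible=reversible,
            reverse_rate_param=f"kr{j}" if reversible else None))
    net = fm.ReactionNetwork(species, reactions)
    params = fm.ParameterVector({
        p: float(10.0 ** rng.uniform(-4, 1)) for p in net.parameter_names})
    state = rng.uniform(0.0, 50.0, size=n_species)
    return net, params, state
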