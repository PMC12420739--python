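"""Shared fixtures: the 6-pathway reference toy model and its simulations.

The expensive artefacts (5000-row flux sample sets and the knockout
profiles derived from them) are session-scoped and computed once.
"""

from __future__ import annotations

import pytest

from exobench import model as model_core
from exobench import simulate, synth


@pytest.fixture(scope="session")
def toy():
    """(raw model, ground truth) for the reference archetype mix, seed 42."""
    return synth.generate_toy_model(synth.ToyModelSpec(seed=42))


@pytest.fixture(scope="session")
def toy_model(toy):
    return toy[0]


@pytest.fixture(scope="session")
def toy_truth(toy):
    return toy[1]


@pytest.fixture(scope="session")
def toy_blocked(toy_model):
    return model_core.find_blocked_reactions(toy_model)


@pytest.fixture(scope="session")
def pruned(toy_model, toy_blocked):
    return model_core.prune_model(toy_model, toy_blocked)


@pytest.fixture(scope="session")
def sets_full(pruned):
    return model_core.reactions_to_metabolite_sets(pruned, include_side=True)


@pytest.fixture(scope="session")
def sets_no_side(pruned):
    return model_core.reactions_to_metabolite_sets(pruned, include_side=False)


@pytest.fixture(scope="session")
def background(pruned):
    return model_core.exchangeable_background(pruned)


@pytest.fixture(scope="session")
def biomass_floor(pruned):
    return 0.1 * pruned.max_biomass()


@pytest.fixture(scope="session")
def wt5000(pruned, biomass_floor):
    """Wild-type flux sample set at the benchmark's standard sample size."""
    return simulate.sample_fluxes(pruned, 5000, seed=42,
                                  biomass_floor=biomass_floor)


@pytest.fixture(scope="session")
def sim5000(pruned, wt5000):
    """(profiles, ledger) for every knockout scenario at n=5000, seed 42."""
    return simulate.run_all_scenarios(pruned, n_samples=5000, seed=42,
                                      wt_samples=wt5000)


@pytest.fixture(scope="session")
def wt300(pruned, biomass_floor):
    """A small wild-type sample set for cheap unit tests."""
    return simulate.sample_fluxes(pruned, 300, seed=7,
                                  biomass_floor=biomass_floor)
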