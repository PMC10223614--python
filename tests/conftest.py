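import logging

import numpy as np
import pytest

from gutflux.fba import TradeoffConfig, cooperative_tradeoff, fba
from gutflux.model import DietSpec, apply_diet, assemble_community
from gutflux.synthetic import (
    TaxonArchetype,
    generate_diet,
    generate_taxon_model,
    healthy_community,
)

# the ignored-diet-entry warnings are exercised explicitly in one test;
# silence them everywhere else
logging.getLogger("gutflux.model").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def healthy_western():
    """The calibrated healthy preset community on the western-style diet."""
    return healthy_community("western")


@pytest.fixture(scope="session")
def healthy_tradeoff(healthy_western):
    """Trade-off solution (tau=0.7) of the healthy preset, solved once."""
    return cooperative_tradeoff(healthy_western, TradeoffConfig(tau=0.7))


@pytest.fixture(scope="session")
def healthy_max_growth(healthy_western):
    return fba(healthy_western).community_growth


def chain_community(uptake_bound=None, secretion=1.0, growth_yield=0.05, n_taxa=1,
                    diet_bound=10.0, carbon="glc"):
    """Tiny linear-chain community: glucose -> biomass + acetate."""
    arch = TaxonArchetype(
        "chain", carbon, {"ac": secretion} if secretion else {},
        growth_yield=growth_yield,
        uptake_capacity=uptake_bound or 10.0,
    )
    models = [generate_taxon_model(arch)]
    if n_taxa > 1:
        models = [generate_taxon_model(arch)] * 1
    comm = assemble_community(models, np.ones(len(models)) / len(models))
    diet = DietSpec(
        "toy", {f"EX_{carbon}(e)": diet_bound}, {f"EX_{carbon}(e)": "carbohydrate"},
        {f"EX_{carbon}(e)": 0.72},
    )
    return apply_diet(comm, diet)


@pytest.fixture
def simple_chain():
    return chain_community()
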