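import numpy as np
import pytest

from auxopep import _align
from auxopep.model_io import GrowthMedium, MetabolicModel, Metabolite, Reaction
from auxopep.synthetic import make_catalog, make_samples


@pytest.fixture(scope="session", autouse=True)
def _compile_kernels():
    """Compile the numba alignment kernels once up front so individual
    test timings are meaningful."""
    _align.warm_up()


@pytest.fixture(scope="session")
def small_catalog():
    """12 genomes with planted auxotrophies and peptidase genes
    (completeness cycling 100/90/80), shared across read-only tests."""
    return make_catalog(12, seed=3)


@pytest.fixture(scope="session")
def small_study(small_catalog):
    catalog, models, scan_db, signal_table, truth = small_catalog
    table, metadata = make_samples(catalog, truth, n_per_region=5, seed=5)
    return catalog, models, scan_db, signal_table, truth, table, metadata


@pytest.fixture()
def chain_model():
    """Linear chain: substrate uptake -> transport -> biomass at yield 1;
    growth equals the permitted uptake rate."""
    mets = [
        Metabolite("s_e", "extracellular"),
        Metabolite("s_c", "cytosol"),
    ]
    rxns = [
        Reaction("EX_s", {"s_e": -1.0}, -1000.0, 1000.0),
        Reaction("T_s", {"s_e": -1.0, "s_c": 1.0}, 0.0, 1000.0),
        Reaction("biomass", {"s_c": -1.0}, 0.0, 1000.0),
    ]
    return MetabolicModel(
        model_id="chain",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="biomass",
        exchange_map={"s_e": "EX_s"},
        completeness=100.0,
    )


def random_bounded_model(rng: np.random.Generator, max_reactions: int = 8) -> MetabolicModel:
    """A random small stoichiometric network with finite bounds (so the
    LP is bounded) used for oracle-equivalence testing."""
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(n_mets, max_reactions + 1))
    mets = [Metabolite(f"m{i}", "cytosol") for i in range(n_mets)]
    rxns = []
    for j in range(n_rxns):
        stoich = {}
        for i in rng.choice(n_mets, size=int(rng.integers(1, min(3, n_mets) + 1)),
                            replace=False):
            coeff = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            stoich[f"m{int(i)}"] = coeff
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        if lb > ub:
            lb, ub = ub, lb
        rxns.append(Reaction(f"r{j}", stoich, lb, ub))
    return MetabolicModel(
        model_id="random",
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="r0",
        exchange_map={},
        completeness=100.0,
    )


@pytest.fixture()
def empty_medium():
    return GrowthMedium({})
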