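import numpy as np
import pandas as pd
import pytest

from traitnet import gp, structure, synthetic
from traitnet.synthetic import ScmEdge, ScmSpec
from traitnet.trait_io import TraitTable


def make_table(columns: dict, varieties=None, groups=None) -> TraitTable:
    """Build a TraitTable from plain column arrays (one variety per plant by
    default)."""
    df = pd.DataFrame(columns)
    n = len(df)
    if varieties is None:
        varieties = [f"V{i:04d}" for i in range(n)]
    if groups is None:
        groups = ["A"] * n
    return TraitTable(df, pd.Series([f"p{i}" for i in range(n)], name="plant_id"),
                      pd.Series(varieties, name="variety"),
                      pd.Series(groups, name="group"))


def chain_spec(noise_x=1.0, noise_yz=0.01, n_varieties=120, reps=2) -> ScmSpec:
    """Linear chain x -> y (coef 2) -> z (coef 3); total effect of x on z is 6."""
    return ScmSpec(
        node_names=["x", "y", "z"], tiers={"x": 0, "y": 1, "z": 2},
        edges=[ScmEdge("x", "y", "linear", 2.0), ScmEdge("y", "z", "linear", 3.0)],
        yield_node="z",
        noise_sd={"x": noise_x, "y": noise_yz, "z": noise_yz},
        variety_effect_sd={}, n_varieties=n_varieties, reps_per_variety=reps)


@pytest.fixture(scope="session")
def panel_sim():
    """One draw of the 8-node oilseed-rape-style panel (500 plants)."""
    spec = synthetic.default_panel_spec(n_varieties=100, reps_per_variety=5)
    return synthetic.generate_scm_table(spec, seed=11)


@pytest.fixture(scope="session")
def chain_network():
    """Near-noiseless linear chain with MAP-fitted GPs at y and z."""
    sim = synthetic.generate_scm_table(chain_spec(), seed=3)
    dag = structure.TraitDAG(nodes=["x", "y", "z"],
                             edges={("x", "y"), ("y", "z")})
    net = gp.fit_network(dag, sim.table, gp.SamplerConfig(mode="map", seed=0))
    return sim, net


@pytest.fixture(scope="session")
def tradeoff_panel():
    """Two yield parents on a hard negative trade-off line (b ~ -a) with true
    yield a - (a+b)^2: moving along the line raises yield, leaving it drops it."""
    r = np.random.default_rng(5)
    n = 120
    t = r.normal(0, 1, n)
    a = t + 0.05 * r.normal(0, 1, n)
    b = -t + 0.05 * r.normal(0, 1, n)
    yld = a - (a + b) ** 2 + 0.05 * r.normal(0, 1, n)
    return make_table({"a": a, "b": b, "yield": yld})
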