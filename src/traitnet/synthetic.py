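"""Structural-causal-model simulator for multi-trait glasshouse-style panels.

Generates plant-by-trait tables with the statistical structure the downstream
analysis assumes: a tiered trait hierarchy (architectural traits at tier 0 down
to a single seed-yield sink at the last tier), linear or saturating trait-trait
links including a configurable negative seed-number/seed-weight trade-off,
variety-level random intercepts shared across replicates (the genotype signal
that heritability estimation needs), two variety groups with optionally
perturbed link coefficients (a spring/winter analogue), and MCAR missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from traitnet.trait_io import TraitTable

EFFECT_TAGS = ("linear", "saturating")


@dataclass(frozen=True)
class ScmEdge:
    parent: str
    child: str
    effect: str  # "linear" or "saturating"
    coefficient: float

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_TAGS:
            raise ValueError(f"effect must be one of {EFFECT_TAGS}, got {self.effect!r}")


@dataclass
class ScmSpec:
    """Ground-truth generative model for a synthetic trait panel.

    ``tiers`` maps every node to a hierarchy level (0 = architectural traits,
    the highest level holds the single yield sink).  Edges must point from a
    lower-or-equal tier to their child's tier, never into tier 0, and the
    designated yield node has no children.
    """

    node_names: list[str]
    tiers: dict[str, int]
    edges: list[ScmEdge]
    yield_node: str
    noise_sd: dict[str, float] = field(default_factory=dict)
    variety_effect_sd: dict[str, float] = field(default_factory=dict)
    n_varieties: int = 94
    reps_per_variety: int = 5
    missing_rate: float = 0.0
    group_coef_shift: float = 0.0  # relative coefficient perturbation in group B

    def __post_init__(self) -> None:
        if len(set(self.node_names)) != len(self.node_names):
            raise ValueError("node names must be unique")
        if self.n_varieties <= 0 or self.reps_per_variety <= 0:
            raise ValueError("n_varieties and reps_per_variety must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.yield_node not in self.node_names:
            raise ValueError(f"yield node {self.yield_node!r} not among nodes")
        missing_tier = [v for v in self.node_names if v not in self.tiers]
        if missing_tier:
            raise ValueError(f"nodes without a tier: {missing_tier}")
        for e in self.edges:
            if e.parent not in self.node_names or e.child not in self.node_names:
                raise ValueError(f"edge {e.parent}->{e.child} uses unknown node")
            if self.tiers[e.child] == 0:
                raise ValueError(f"edge {e.parent}->{e.child} points into tier 0")
            if self.tiers[e.parent] > self.tiers[e.child]:
                raise ValueError(
                    f"edge {e.parent}->{e.child} goes from tier {self.tiers[e.parent]}"
                    f" down to tier {self.tiers[e.child]}")
            if e.parent == self.yield_node:
                raise ValueError("the yield node must be a sink")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set contains a cycle")
        for v in self.node_names:
            sd = self.noise_sd.get(v, 1.0)
            if sd <= 0:
                raise ValueError(f"noise_sd for {v!r} must be positive")
            if self.variety_effect_sd.get(v, 0.0) < 0:
                raise ValueError(f"variety_effect_sd for {v!r} must be non-negative")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        g.add_edges_from((e.parent, e.child) for e in self.edges)
        return g

    def true_edges(self) -> set[tuple[str, str]]:
        return {(e.parent, e.child) for e in self.edges}

    def to_json(self, path) -> None:
        payload = {
            "node_names": self.node_names,
            "tiers": self.tiers,
            "edges": [[e.parent, e.child, e.effect, e.coefficient] for e in self.edges],
            "yield_node": self.yield_node,
            "noise_sd": self.noise_sd,
            "variety_effect_sd": self.variety_effect_sd,
            "n_varieties": self.n_varieties,
            "reps_per_variety": self.reps_per_variety,
            "missing_rate": self.missing_rate,
            "group_coef_shift": self.group_coef_shift,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ScmSpec":
        with open(path) as fh:
            raw = json.load(fh)
        raw["edges"] = [ScmEdge(*e) for e in raw["edges"]]
        return cls(**raw)


@dataclass
class SimTraitData:
    """A simulated panel: the table, the generating spec, the drawn variety
    intercepts, and (after missingness injection) the boolean missing mask."""

    table: TraitTable
    truth: ScmSpec
    variety_effects: pd.DataFrame  # varieties x traits
    mask: pd.DataFrame | None = None  # True where a cell was masked


def default_panel_spec(n_varieties: int = 100, reps_per_variety: int = 5,
                       noise_sd: float = 0.5, variety_effect_sd: float = 0.3,
                       missing_rate: float = 0.0,
                       saturating: bool = False) -> ScmSpec:
    """An 8-node oilseed-rape-style trait hierarchy used throughout the tests.

    Architectural traits (branches, height) sit at tier 0; flower production at
    tier 1; pod and seed traits at tier 2, including the negative
    seed-number -> seed-weight (TGW) trade-off; seed yield is the tier-3 sink.
    """
    sat = "saturating" if saturating else "linear"
    nodes = ["branches", "height", "flowers", "pods", "pod_length",
             "seed_number", "tgw", "seed_yield"]
    tiers = {"branches": 0, "height": 0, "flowers": 1, "pods": 2,
             "pod_length": 2, "seed_number": 2, "tgw": 2, "seed_yield": 3}
    edges = [
        ScmEdge("branches", "flowers", sat, 1.2),
        ScmEdge("flowers", "pods", sat, 1.1),
        ScmEdge("flowers", "pod_length", sat, -1.0),
        ScmEdge("pods", "seed_number", sat, 1.0),
        ScmEdge("pod_length", "seed_number", sat, 1.0),
        ScmEdge("seed_number", "tgw", sat, -1.0),
        ScmEdge("seed_number", "seed_yield", sat, 1.0),
        ScmEdge("tgw", "seed_yield", sat, 1.0),
    ]
    return ScmSpec(
        node_names=nodes, tiers=tiers, edges=edges, yield_node="seed_yield",
        noise_sd={v: noise_sd for v in nodes},
        variety_effect_sd={v: variety_effect_sd for v in nodes},
        n_varieties=n_varieties, reps_per_variety=reps_per_variety,
        missing_rate=missing_rate)


def _standardise(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_scm_table(spec: ScmSpec, seed: int) -> SimTraitData:
    """Draw one panel from the structural causal model.

    Traits are generated in canonical (lexicographic) topological order so the
    output is invariant to the declaration order of nodes and edges.  Each
    trait is the sum of its parents' edge effects (linear: coefficient x
    parent; saturating: coefficient x tanh(standardised parent)), a per-variety
    random intercept shared across replicates, and independent Gaussian noise.
    If ``spec.missing_rate`` > 0 the table is then masked MCAR.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_varieties * spec.reps_per_variety
    varieties = [f"V{i:03d}" for i in range(spec.n_varieties)]
    variety_col = np.repeat(varieties, spec.reps_per_variety)
    # group analogue: first half of varieties are group A, second half group B
    half = spec.n_varieties // 2
    group_col = np.repeat(["A" if i < half else "B"
                           for i in range(spec.n_varieties)], spec.reps_per_variety)
    group_b_rows = group_col == "B"
    plant_id = np.array([f"{v}_r{j % spec.reps_per_variety}"
                         for j, v in enumerate(variety_col)])

    order = list(nx.lexicographical_topological_sort(spec.graph()))
    parent_edges: dict[str, list[ScmEdge]] = {v: [] for v in spec.node_names}
    for e in spec.edges:
        parent_edges[e.child].append(e)
    for v in parent_edges:  # canonical parent order
        parent_edges[v].sort(key=lambda e: e.parent)

    values: dict[str, np.ndarray] = {}
    veffects: dict[str, np.ndarray] = {}
    for v in order:
        ve_sd = spec.variety_effect_sd.get(v, 0.0)
        ve = rng.normal(0.0, ve_sd, size=spec.n_varieties) if ve_sd > 0 \
            else np.zeros(spec.n_varieties)
        veffects[v] = ve
        x = np.repeat(ve, spec.reps_per_variety) \
            + rng.normal(0.0, spec.noise_sd.get(v, 1.0), size=n)
        for e in parent_edges[v]:
            coef = np.full(n, e.coefficient)
            if spec.group_coef_shift:
                coef[group_b_rows] *= (1.0 + spec.group_coef_shift)
            if e.effect == "linear":
                x = x + coef * values[e.parent]
            else:
                x = x + coef * np.tanh(_standardise(values[e.parent]))
        values[v] = x

    table = TraitTable(
        pd.DataFrame({v: values[v] for v in sorted(spec.node_names)}),
        pd.Series(plant_id, name="plant_id"),
        pd.Series(variety_col, name="variety"),
        pd.Series(group_col, name="group"))
    sim = SimTraitData(
        table=table, truth=spec,
        variety_effects=pd.DataFrame(
            {v: veffects[v] for v in sorted(spec.node_names)}, index=varieties))
    if spec.missing_rate > 0:
        sim = inject_missingness(sim, spec.missing_rate,
                                 seed=int(rng.integers(0, 2**31 - 1)))
    return sim


def inject_missingness(data: SimTraitData, rate: float, seed: int) -> SimTraitData:
    """Mask each trait cell independently with probability ``rate`` (MCAR).

    The mask is resampled (up to 1000 tries) until every trait keeps at least
    one observed value and the table keeps at least one fully complete row.
    The realised mask is recorded on the returned object.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    table = data.table
    if rate == 0.0:
        return SimTraitData(table.copy(), data.truth, data.variety_effects.copy(),
                            mask=pd.DataFrame(False, index=table.values.index,
                                              columns=table.trait_names))
    rng = np.random.default_rng(seed)
    shape = table.values.shape
    for _ in range(1000):
        mask = rng.random(shape) < rate
        if (~mask).any(axis=0).all() and (~mask.any(axis=1)).any():
            break
    else:
        raise RuntimeError("could not draw an admissible missingness mask")
    vals = table.values.copy()
    vals[pd.DataFrame(mask, index=vals.index, columns=vals.columns)] = np.nan
    return SimTraitData(
        TraitTable(vals, table.plant_id, table.variety, table.group),
        data.truth, data.variety_effects.copy(),
        mask=pd.DataFrame(mask, index=vals.index, columns=table.trait_names))
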