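"""Do-style trait interventions propagated through the fitted network.

A trait is fixed to a grid of values spanning its observed range; sampled GP
predictions for its descendants are propagated through the DAG in topological
order (descendant parents take sampled values, all other parents keep their
observed in-planta values), pooled over base plants, posterior draws and
candidate networks, and summarised as quantile curves per descendant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from traitnet.gp import FittedTraitNetwork, predict_node
from traitnet.structure import TraitDAG
from traitnet.trait_io import TraitTable

QUANTILES = np.arange(0.1, 0.91, 0.1)


def descendants(dag: TraitDAG, node: str) -> set[str]:
    """All nodes reachable from ``node`` along directed edges (excl. itself)."""
    if node not in dag.nodes:
        raise ValueError(f"unknown node {node!r}")
    return set(nx.descendants(dag.graph(), node))


@dataclass
class InterventionResult:
    """Quantile curves of every descendant trait along an intervention grid.

    ``curves[trait]`` is an (n_grid x 9) matrix of the 10%..90% predictive
    quantiles, pooled over base plants, posterior draws and networks.
    """

    intervened_trait: str
    grid: np.ndarray
    curves: dict[str, np.ndarray]
    n_draws: int
    networks_averaged: int

    def median_curve(self, trait: str) -> np.ndarray:
        return self.curves[trait][:, 4]  # 50% is the middle of 10..90

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for trait, mat in self.curves.items():
            for gi, g in enumerate(self.grid):
                for qi, q in enumerate(QUANTILES):
                    rows.append({"trait": self.intervened_trait, "grid_value": g,
                                 "descendant": trait, "quantile": round(float(q), 2),
                                 "value": mat[gi, qi]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_tidy().to_csv(path, index=False)


def do_intervene(networks: list[FittedTraitNetwork] | FittedTraitNetwork,
                 trait: str, base_table: TraitTable, n_grid: int = 20,
                 n_draws: int = 1000, seed: int = 0,
                 max_base_rows: int | None = None) -> InterventionResult:
    """Predict the downstream consequences of fixing ``trait``.

    The grid spans the observed min/max of ``trait`` in ``base_table``.  For
    each network, grid value and base plant, descendants are predicted in
    topological order from their GPs, with parent values sampled where the
    parent is itself a descendant (or the intervened trait) and held at the
    plant's observed value otherwise.  ``n_draws`` is the total pooled draw
    count per grid point and network, spread across base plants.
    """
    if isinstance(networks, FittedTraitNetwork):
        networks = [networks]
    if not networks:
        raise ValueError("at least one fitted network is required")
    for net in networks:
        if trait not in net.dag.nodes:
            raise ValueError(f"trait {trait!r} missing from a network's DAG")
    if not base_table.is_complete():
        raise ValueError("base_table must be complete")
    obs = base_table.values[trait].to_numpy(dtype=float)
    grid = np.linspace(obs.min(), obs.max(), n_grid)
    rng = np.random.default_rng(seed)

    if max_base_rows is not None and base_table.n_plants > max_base_rows:
        keep = rng.choice(base_table.n_plants, size=max_base_rows, replace=False)
        base = base_table.values.iloc[np.sort(keep)].reset_index(drop=True)
    else:
        base = base_table.values.reset_index(drop=True)
    n_rows = len(base)

    pooled: dict[str, list[list[np.ndarray]]] = {}
    any_desc = False
    for net in networks:
        desc = descendants(net.dag, trait)
        if not desc:
            continue
        any_desc = True
        order = [v for v in nx.topological_sort(net.dag.graph()) if v in desc]
        k = max(1, int(np.ceil(n_draws / n_rows)))
        for gi, g in enumerate(grid):
            # sampled[v] has shape (k, n_rows): k independent trajectory blocks
            sampled: dict[str, np.ndarray] = {trait: np.full((k, n_rows), g)}
            for v in order:
                model = net.node_models[v]
                draws = np.empty((k, n_rows))
                for b in range(k):
                    cols = []
                    for p in model.parents:
                        if p in sampled:
                            cols.append(sampled[p][b])
                        else:
                            cols.append(base[p].to_numpy(dtype=float))
                    X_new = np.column_stack(cols)
                    draws[b] = predict_node(model, X_new, n_draws=1,
                                            seed=int(rng.integers(0, 2**31 - 1)))[0]
                sampled[v] = draws
                pooled.setdefault(v, [[] for _ in grid])[gi].append(draws.ravel())
    if not any_desc:
        warnings.warn(f"trait {trait!r} has no descendants in any network; "
                      "empty intervention result", stacklevel=2)
        return InterventionResult(intervened_trait=trait, grid=grid, curves={},
                                  n_draws=n_draws, networks_averaged=len(networks))
    curves = {}
    for v, per_grid in pooled.items():
        mat = np.empty((len(grid), len(QUANTILES)))
        for gi, chunks in enumerate(per_grid):
            allv = np.concatenate(chunks)
            mat[gi] = np.quantile(allv, QUANTILES)
        curves[v] = mat
    return InterventionResult(intervened_trait=trait, grid=grid, curves=curves,
                              n_draws=n_draws, networks_averaged=len(networks))
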