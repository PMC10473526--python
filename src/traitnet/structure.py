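"""Trait-network structure learning.

A Gaussian Bayesian network over the trait columns is scored by BIC (each node
a linear-Gaussian function of its parents) and the structure space is explored
by Tabu search under hierarchy constraints: a whitelist of edges that must be
present, a blacklist of forbidden edges, and an optional tier map that
auto-forbids edges from higher to lower tiers.  Arc probabilities come from
bootstrap resampling, and a consensus network from cross-fold averaging.
"""

from __future__ import annotations

import itertools
import json
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from traitnet.trait_io import TraitTable

Edge = tuple[str, str]


@dataclass
class EdgeConstraints:
    """Whitelist / blacklist edge constraints with optional tier ordering.

    When ``tier_map`` is given, any edge from a strictly higher tier to a lower
    tier is treated as blacklisted, encoding a predefined trait hierarchy.
    """

    whitelist: set[Edge] = field(default_factory=set)
    blacklist: set[Edge] = field(default_factory=set)
    tier_map: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.whitelist = {tuple(e) for e in self.whitelist}
        self.blacklist = {tuple(e) for e in self.blacklist}
        clash = self.whitelist & self.full_blacklist(
            {v for e in self.whitelist for v in e})
        if clash:
            raise ValueError(f"edges both whitelisted and blacklisted: {sorted(clash)}")
        g = nx.DiGraph(list(self.whitelist))
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("whitelist alone contains a cycle")

    def full_blacklist(self, nodes) -> set[Edge]:
        bl = set(self.blacklist)
        if self.tier_map is not None:
            for u, v in itertools.permutations(nodes, 2):
                tu, tv = self.tier_map.get(u), self.tier_map.get(v)
                if tu is not None and tv is not None and tu > tv:
                    bl.add((u, v))
        return bl

    @classmethod
    def from_csv(cls, whitelist_path=None, blacklist_path=None,
                 tier_map: dict[str, int] | None = None) -> "EdgeConstraints":
        """Read edge lists from CSVs with columns ``parent, child``."""
        def read(path):
            if path is None:
                return set()
            df = pd.read_csv(path)
            return {(str(r["parent"]), str(r["child"])) for _, r in df.iterrows()}
        return cls(whitelist=read(whitelist_path), blacklist=read(blacklist_path),
                   tier_map=tier_map)


@dataclass
class TraitDAG:
    """A directed acyclic trait graph with per-arc bootstrap probabilities."""

    nodes: list[str]
    edges: set[Edge]
    arc_probability: dict[Edge, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = {tuple(e) for e in self.edges}
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge set contains a cycle")
        for e, p in self.arc_probability.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"arc probability of {e} outside [0,1]: {p}")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(u for u, v in self.edges if v == node)

    def roots(self) -> list[str]:
        return [v for v in self.nodes if not self.parents(v)]

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges}

    def to_json(self, path) -> None:
        payload = {"nodes": self.nodes,
                   "edges": [{"parent": u, "child": v,
                              "probability": self.arc_probability.get((u, v))}
                             for u, v in sorted(self.edges)]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TraitDAG":
        with open(path) as fh:
            raw = json.load(fh)
        edges = {(e["parent"], e["child"]) for e in raw["edges"]}
        probs = {(e["parent"], e["child"]): e["probability"]
                 for e in raw["edges"] if e.get("probability") is not None}
        return cls(nodes=raw["nodes"], edges=edges, arc_probability=probs)

    def to_dot(self) -> str:
        lines = ["digraph traits {"]
        for v in self.nodes:
            lines.append(f'  "{v}";')
        for u, v in sorted(self.edges):
            p = self.arc_probability.get((u, v))
            label = f' [label="{p:.2f}", penwidth={0.5 + 3 * p:.2f}]' if p is not None else ""
            lines.append(f'  "{u}" -> "{v}"{label};')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# BIC scoring


def _local_bic(y: np.ndarray, X: np.ndarray | None, node: str) -> float:
    """BIC contribution of one node: maximised Gaussian log-likelihood of the
    node given its parents (OLS) minus (k/2) ln n, k = parents + intercept +
    variance."""
    n = y.shape[0]
    if X is None or X.shape[1] == 0:
        resid = y - y.mean()
        k = 2
    else:
        design = np.column_stack([np.ones(n), X])
        beta, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        if rank < design.shape[1]:
            raise ValueError(f"singular design for node '{node}' (collinear parents)")
        resid = y - design @ beta
        k = X.shape[1] + 2
    sigma2 = float(resid @ resid) / n
    sigma2 = max(sigma2, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return loglik - 0.5 * k * np.log(n)


class _Scorer:
    """Caches node-local BIC scores keyed by (node, parent set)."""

    def __init__(self, table: TraitTable, nodes: list[str]):
        self.cols = {v: table.values[v].to_numpy(dtype=float) for v in nodes}
        self.cache: dict[tuple[str, frozenset], float] = {}

    def local(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key not in self.cache:
            ps = sorted(parents)
            if len(set(ps)) < len(ps):
                raise ValueError(f"duplicate parent columns for node '{node}'")
            X = np.column_stack([self.cols[p] for p in ps]) if ps else None
            self.cache[key] = _local_bic(self.cols[node], X, node)
        return self.cache[key]

    def total(self, parent_sets: dict[str, frozenset]) -> float:
        return sum(self.local(v, ps) for v, ps in parent_sets.items())


def bic_score(dag: TraitDAG, table: TraitTable) -> float:
    """BIC of the whole network; decomposes additively over nodes."""
    if table.values.isna().any().any():
        raise ValueError("table must be complete (impute first)")
    missing = [v for v in dag.nodes if v not in table.trait_names]
    if missing:
        raise ValueError(f"DAG nodes absent from table: {missing}")
    scorer = _Scorer(table, dag.nodes)
    return scorer.total({v: frozenset(dag.parents(v)) for v in dag.nodes})


# ---------------------------------------------------------------------------
# Tabu search


def _creates_cycle(children: dict[str, set[str]], u: str, v: str) -> bool:
    """Would adding u->v create a cycle (is u reachable from v)?"""
    stack, seen = [v], set()
    while stack:
        w = stack.pop()
        if w == u:
            return True
        if w in seen:
            continue
        seen.add(w)
        stack.extend(children[w])
    return False


def tabu_search(table: TraitTable, constraints: EdgeConstraints | None = None,
                tabu_length: int = 10, max_stall: int = 15,
                seed: int = 0, nodes: list[str] | None = None) -> TraitDAG:
    """BIC-maximising Tabu search over DAGs via single-edge moves.

    Starts from the whitelist-only graph and repeatedly applies the best
    non-tabu addition/deletion/reversal that respects the constraints and
    acyclicity, accepting it even when it worsens the score; the reverse of
    each applied move is tabu for ``tabu_length`` steps (with aspiration: a
    tabu move beating the best score so far is allowed).  Stops after
    ``max_stall`` consecutive moves without improving the best score and
    returns the best DAG seen.
    """
    if constraints is None:
        constraints = EdgeConstraints()
    if nodes is None:
        nodes = list(table.trait_names)
    blacklist = constraints.full_blacklist(nodes)
    bad_white = constraints.whitelist & blacklist
    if bad_white:
        raise ValueError(f"whitelisted edges are forbidden: {sorted(bad_white)}")
    if table.values.isna().any().any():
        raise ValueError("table must be complete (impute first)")
    rng = np.random.default_rng(seed)
    scorer = _Scorer(table, nodes)
    tiers = constraints.tier_map or {}

    parents: dict[str, frozenset] = {v: frozenset() for v in nodes}
    children: dict[str, set[str]] = {v: set() for v in nodes}
    for u, v in constraints.whitelist:
        parents[v] = parents[v] | {u}
        children[u].add(v)

    def apply(move):
        kind, u, v = move
        if kind == "add":
            parents[v] |= {u}
            children[u].add(v)
        elif kind == "del":
            parents[v] -= {u}
            children[u].discard(v)
        else:  # rev: u->v becomes v->u
            parents[v] -= {u}
            children[u].discard(v)
            parents[u] |= {v}
            children[v].add(u)

    current = scorer.total(parents)
    best_score = current
    best_parents = dict(parents)
    tabu: deque = deque(maxlen=max(1, tabu_length))
    stall = 0

    def orient_pref(u: str, v: str) -> int:
        """Tie-break key favouring tier-increasing, then lexicographic, arcs."""
        tu, tv = tiers.get(u), tiers.get(v)
        if tu is not None and tv is not None and tu != tv:
            return 0 if tu < tv else 2
        return 0 if u < v else 1

    while True:
        candidates = []  # (delta, pref, jitter, move, local updates)
        for u, v in itertools.permutations(nodes, 2):
            if v in children[u]:  # edge u->v present: delete / reverse
                if (u, v) not in constraints.whitelist:
                    d = scorer.local(v, parents[v] - {u}) - scorer.local(v, parents[v])
                    candidates.append((d, 1, ("del", u, v)))
                    if (v, u) not in blacklist:
                        children[u].discard(v)
                        cyc = _creates_cycle(children, v, u)
                        children[u].add(v)
                        if not cyc:
                            d2 = (scorer.local(v, parents[v] - {u})
                                  - scorer.local(v, parents[v])
                                  + scorer.local(u, parents[u] | {v})
                                  - scorer.local(u, parents[u]))
                            candidates.append((d2, orient_pref(v, u), ("rev", u, v)))
            elif (u, v) not in blacklist and u not in parents[v]:
                if not _creates_cycle(children, u, v):
                    d = scorer.local(v, parents[v] | {u}) - scorer.local(v, parents[v])
                    candidates.append((d, orient_pref(u, v), ("add", u, v)))
        if not candidates:
            break
        jitter = rng.random(len(candidates))
        # round score deltas so score-equivalent moves (e.g. reversals of a
        # covered edge) are true ties, broken by orientation preference
        order = sorted(range(len(candidates)),
                       key=lambda i: (-round(candidates[i][0], 6),
                                      candidates[i][1], jitter[i]))
        chosen = None
        for i in order:
            d, _, move = candidates[i]
            if move not in tabu or current + d > best_score + 1e-12:
                chosen = (d, move)
                break
        if chosen is None:
            break
        d, move = chosen
        apply(move)
        current += d
        kind, u, v = move
        inverse = {"add": ("del", u, v), "del": ("add", u, v), "rev": ("rev", v, u)}[kind]
        tabu.append(inverse)
        if current > best_score + 1e-12:
            best_score = current
            best_parents = dict(parents)
            stall = 0
        else:
            stall += 1
            if stall >= max_stall:
                break

    edges = {(u, v) for v, ps in best_parents.items() for u in ps}
    return TraitDAG(nodes=list(nodes), edges=edges)


# ---------------------------------------------------------------------------
# Bootstrap arc probabilities and fold averaging


def _resolve_edges(candidates: dict[Edge, float], nodes: list[str],
                   constraints: EdgeConstraints) -> set[Edge]:
    """Greedy acyclic, constraint-consistent edge selection by descending
    probability; whitelist edges always included, blacklist always excluded."""
    blacklist = constraints.full_blacklist(nodes)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    g.add_edges_from(constraints.whitelist)
    ranked = sorted(candidates.items(), key=lambda kv: (-kv[1], kv[0]))
    for (u, v), _p in ranked:
        if (u, v) in g.edges or (u, v) in blacklist:
            continue
        if nx.has_path(g, v, u):
            continue  # would close a cycle; drop the weaker arc
        g.add_edge(u, v)
    return set(g.edges)


def bootstrap_arc_probabilities(table: TraitTable,
                                constraints: EdgeConstraints | None = None,
                                replicates: int = 500, seed: int = 0,
                                inclusion_threshold: float = 0.5,
                                tabu_length: int = 10, max_stall: int = 15) -> TraitDAG:
    """Estimate per-arc probabilities by bootstrap resampling of plants.

    Rows are resampled with replacement ``replicates`` times, the Tabu search
    rerun on each resample, and each arc's probability estimated as the
    fraction of replicate networks containing it.  The returned DAG keeps arcs
    with probability >= ``inclusion_threshold``, made acyclic and
    constraint-consistent.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if constraints is None:
        constraints = EdgeConstraints()
    rng = np.random.default_rng(seed)
    nodes = list(table.trait_names)
    counts: dict[Edge, int] = {}
    n = table.n_plants
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        boot = TraitTable(table.values.iloc[idx].reset_index(drop=True),
                          table.plant_id.iloc[idx].reset_index(drop=True),
                          table.variety.iloc[idx].reset_index(drop=True),
                          table.group.iloc[idx].reset_index(drop=True))
        dag = tabu_search(boot, constraints, tabu_length=tabu_length,
                          max_stall=max_stall, seed=int(rng.integers(0, 2**31 - 1)))
        for e in dag.edges:
            counts[e] = counts.get(e, 0) + 1
    probs = {e: c / replicates for e, c in counts.items()}
    for e in constraints.whitelist:
        probs[e] = 1.0
    keep = {e: p for e, p in probs.items() if p >= inclusion_threshold}
    edges = _resolve_edges(keep, nodes, constraints)
    return TraitDAG(nodes=nodes, edges=edges,
                    arc_probability={e: probs.get(e, 0.0) for e in probs})


@dataclass
class FoldAverageResult:
    fold_dags: list[TraitDAG]
    consensus: TraitDAG


def average_across_folds(table: TraitTable,
                         constraints: EdgeConstraints | None = None,
                         n_folds: int = 5, replicates: int = 500, seed: int = 0,
                         strength_threshold: float = 0.5,
                         majority_fraction: float = 0.5,
                         mode: str = "majority",
                         min_fold_rows: int = 10,
                         tabu_length: int = 10, max_stall: int = 15) -> FoldAverageResult:
    """Cross-fold model averaging of bootstrap networks.

    Rows are partitioned into ``n_folds`` folds stratified by variety (all
    replicates of a variety share a fold), the bootstrap procedure is run per
    fold, and a consensus DAG is formed from arcs identified consistently
    across folds.  ``mode='majority'`` keeps arcs whose bootstrap probability
    is >= ``strength_threshold`` in more than ``majority_fraction`` of folds;
    ``mode='pooled'`` keeps arcs whose fold-mean probability is >=
    ``strength_threshold``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if mode not in ("majority", "pooled"):
        raise ValueError("mode must be 'majority' or 'pooled'")
    if constraints is None:
        constraints = EdgeConstraints()
    rng = np.random.default_rng(seed)
    varieties = np.array(sorted(table.variety.unique()))
    rng.shuffle(varieties)
    assignment = {v: i % n_folds for i, v in enumerate(varieties)}
    fold_of_row = table.variety.map(assignment).to_numpy()
    fold_dags: list[TraitDAG] = []
    for f in range(n_folds):
        keep = fold_of_row == f
        if keep.sum() < min_fold_rows:
            raise ValueError(f"fold {f} has only {int(keep.sum())} rows "
                             f"(< {min_fold_rows})")
        fold_tbl = TraitTable(table.values.loc[keep].reset_index(drop=True),
                              table.plant_id.loc[keep].reset_index(drop=True),
                              table.variety.loc[keep].reset_index(drop=True),
                              table.group.loc[keep].reset_index(drop=True))
        fold_dags.append(bootstrap_arc_probabilities(
            fold_tbl, constraints, replicates=replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
            inclusion_threshold=strength_threshold,
            tabu_length=tabu_length, max_stall=max_stall))
    nodes = list(table.trait_names)
    all_arcs = set().union(*(set(d.arc_probability) for d in fold_dags)) \
        if fold_dags else set()
    mean_prob = {e: float(np.mean([d.arc_probability.get(e, 0.0) for d in fold_dags]))
                 for e in all_arcs}
    if mode == "majority":
        need = int(np.floor(majority_fraction * n_folds)) + 1
        keep_arcs = {e: mean_prob[e] for e in all_arcs
                     if sum(e in d.edges for d in fold_dags) >= need}
    else:
        keep_arcs = {e: p for e, p in mean_prob.items() if p >= strength_threshold}
    edges = _resolve_edges(keep_arcs, nodes, constraints)
    consensus = TraitDAG(nodes=nodes, edges=edges, arc_probability=mean_prob)
    return FoldAverageResult(fold_dags=fold_dags, consensus=consensus)


def skeleton_f1(estimated: TraitDAG, true_edges: set[Edge]) -> float:
    """F1 of the undirected skeleton against a ground-truth edge set."""
    est = estimated.skeleton()
    truth = {frozenset(e) for e in true_edges}
    tp = len(est & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(est)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)
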