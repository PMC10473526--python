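"""Per-node Gaussian-process regression with an ARD kernel.

Each non-root node of the trait DAG is modelled as a GP of the node on its
parent traits with the automatic-relevance-determination squared-exponential
kernel

    K_ij = alpha^2 exp(-1/2 sum_k ((x_ik - x_jk)/rho_k)^2) + delta_ij sigma^2,

one length-scale per parent, so irrelevant parents are suppressed
automatically.  Hyperparameters carry half-normal(0,1) priors on the scales
alpha and sigma and inverse-gamma(shape 5, scale 5) priors on each rho_k, and
are estimated either at the MAP (fast path) or by MAP-initialised ensemble
MCMC with split-Rhat convergence checks.  Inputs and outputs are standardised
to zero mean / unit variance before fitting so the priors are sensible across
traits measured in different units.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import emcee
import numpy as np
from scipy import optimize, stats

from traitnet.structure import TraitDAG
from traitnet.trait_io import TraitTable

_JITTER0 = 1e-8
_JITTER_MAX = 1e-4
_RHO_PRIOR = stats.invgamma(a=5.0, scale=5.0)  # mode = 5/6


@dataclass
class ArdHyper:
    """ARD kernel hyperparameters: signal amplitude, per-input length-scales,
    observation noise scale.  All strictly positive."""

    alpha: float
    rho: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if self.alpha <= 0 or self.sigma <= 0 or (self.rho <= 0).any():
            raise ValueError("all hyperparameters must be strictly positive")

    @property
    def q(self) -> int:
        return self.rho.shape[0]

    def to_vector(self) -> np.ndarray:
        return np.concatenate([[self.alpha], self.rho, [self.sigma]])

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "ArdHyper":
        v = np.asarray(v, dtype=float)
        return cls(alpha=float(v[0]), rho=v[1:-1].copy(), sigma=float(v[-1]))


def ard_kernel(X1: np.ndarray, X2: np.ndarray, hyper: ArdHyper,
               add_noise: bool = False) -> np.ndarray:
    """Evaluate the ARD squared-exponential kernel between two point sets.

    ``add_noise`` adds sigma^2 to the diagonal and is only meaningful when X1
    and X2 index the same points.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != hyper.q or X2.shape[1] != hyper.q:
        raise ValueError(
            f"input dimension {X1.shape[1]}/{X2.shape[1]} != length-scales {hyper.q}")
    Z1 = X1 / hyper.rho
    Z2 = X2 / hyper.rho
    d2 = (np.sum(Z1**2, axis=1)[:, None] + np.sum(Z2**2, axis=1)[None, :]
          - 2.0 * Z1 @ Z2.T)
    K = hyper.alpha**2 * np.exp(-0.5 * np.maximum(d2, 0.0))
    if add_noise:
        if X1.shape[0] != X2.shape[0]:
            raise ValueError("add_noise requires X1 and X2 to index the same points")
        K = K + hyper.sigma**2 * np.eye(X1.shape[0])
    return K


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    jitter = _JITTER0
    while jitter <= _JITTER_MAX:
        try:
            return np.linalg.cholesky(K + jitter * np.eye(K.shape[0])), jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"Cholesky failed after jitter escalation to {_JITTER_MAX}")


def gp_marginal_loglik(hyper: ArdHyper, X: np.ndarray, y: np.ndarray) -> float:
    """log N(y | 0, K(X,X) + sigma^2 I)."""
    y = np.asarray(y, dtype=float).ravel()
    K = ard_kernel(X, X, hyper, add_noise=True)
    L, _ = _chol_with_jitter(K)
    a = np.linalg.solve(L, y)
    n = y.shape[0]
    return float(-0.5 * a @ a - np.sum(np.log(np.diag(L))) - 0.5 * n * np.log(2 * np.pi))


def log_unnormalised_posterior(hyper: ArdHyper, X: np.ndarray, y: np.ndarray) -> float:
    """GP marginal log-likelihood plus log prior densities.

    Priors: half-normal(0,1) on alpha and sigma (the stated N(0,1) restricted
    to the positive axis, the only domain a scale can occupy) and
    inverse-gamma(shape 5, scale 5) on each length-scale.
    """
    lp = (stats.halfnorm.logpdf(hyper.alpha) + stats.halfnorm.logpdf(hyper.sigma)
          + float(np.sum(_RHO_PRIOR.logpdf(hyper.rho))))
    if not np.isfinite(lp):
        return -np.inf
    return gp_marginal_loglik(hyper, X, y) + lp


def _log_post_logspace(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                       jacobian: bool) -> float:
    """Posterior over log-hyperparameters; ``jacobian`` adds the change-of-
    variables term (needed for sampling, omitted for MAP in the original
    parameterisation)."""
    if np.any(theta > 10) or np.any(theta < -10):
        return -np.inf
    hyper = ArdHyper.from_vector(np.exp(theta))
    try:
        lp = log_unnormalised_posterior(hyper, X, y)
    except np.linalg.LinAlgError:
        return -np.inf
    if jacobian:
        lp += float(np.sum(theta))
    return lp


@dataclass
class SamplerConfig:
    """Fitting configuration for node GPs.

    mode 'map' computes a MAP point by multi-start L-BFGS; mode 'mcmc' runs
    MAP-initialised affine-invariant ensemble MCMC (4 independent ensembles,
    mirroring a 4-chain run, 1000 warm-up and 1000 sampling iterations by
    default) and retains a thinned posterior sample.
    """

    mode: str = "mcmc"
    n_chains: int = 4
    n_warmup: int = 1000
    n_samples: int = 1000
    max_draws: int = 400
    n_restarts: int = 3
    seed: int = 0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.mode not in ("map", "mcmc"):
            raise ValueError("mode must be 'map' or 'mcmc'")


@dataclass
class Standardisation:
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float

    def x_forward(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.x_mean) / self.x_scale

    def y_back(self, y: np.ndarray) -> np.ndarray:
        return y * self.y_scale + self.y_mean


@dataclass
class GpNodeModel:
    """Fitted GP for one DAG node given its parents (standardised space)."""

    node: str
    parents: list[str]
    X_train: np.ndarray
    y_train: np.ndarray
    hyper_draws: list[ArdHyper]
    standardisation: Standardisation
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X_train.shape[1] != len(self.parents):
            raise ValueError("X_train column count must equal number of parents")
        if not self.hyper_draws:
            raise ValueError("at least one hyperparameter draw is required")

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", True))

    def median_hyper(self) -> ArdHyper:
        """Element-wise posterior median (the draw itself in MAP mode)."""
        vs = np.stack([h.to_vector() for h in self.hyper_draws])
        return ArdHyper.from_vector(np.median(vs, axis=0))


def split_rhat(chains: np.ndarray) -> float:
    """Split-Rhat potential-scale-reduction over chains (chains x draws)."""
    m, n = chains.shape
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    mm, nn = split.shape
    means = split.mean(axis=1)
    W = split.var(axis=1, ddof=1).mean()
    B = nn * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (nn - 1) / nn * W + B / nn
    return float(np.sqrt(var_plus / W))


def _map_estimate(X: np.ndarray, y: np.ndarray, q: int, rng: np.random.Generator,
                  n_restarts: int) -> ArdHyper:
    base = np.log(np.concatenate([[1.0], np.full(q, 5.0 / 6.0), [0.5]]))
    starts = [base]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(base + rng.normal(0.0, 0.5, size=base.shape))
    best, best_val = None, np.inf

    def nll(theta):
        return -_log_post_logspace(theta, X, y, jacobian=False)

    for s in starts:
        res = optimize.minimize(nll, s, method="L-BFGS-B",
                                bounds=[(-8, 8)] * len(s))
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    return ArdHyper.from_vector(np.exp(best))


def fit_node_gp(node: str, parents: list[str], table: TraitTable,
                config: SamplerConfig | None = None) -> GpNodeModel:
    """Fit the ARD-kernel GP of ``node`` on its ``parents``.

    Inputs and output are standardised; the hyperparameter posterior is
    explored per ``config`` (MAP point or MAP-initialised ensemble MCMC with
    split-Rhat <= 1.05 required to mark the run converged).  Non-convergence
    does not raise: the model is returned flagged and the caller decides.
    """
    if not parents:
        raise ValueError("parents must be non-empty (roots use their empirical marginal)")
    if config is None:
        config = SamplerConfig()
    if table.values[parents + [node]].isna().any().any():
        raise ValueError("table must be complete (impute first)")
    t0 = time.perf_counter()
    Xr = table.values[list(parents)].to_numpy(dtype=float)
    yr = table.values[node].to_numpy(dtype=float)
    x_mean, x_scale = Xr.mean(axis=0), Xr.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean, y_scale = float(yr.mean()), float(yr.std()) or 1.0
    std = Standardisation(x_mean, x_scale, y_mean, y_scale)
    X = std.x_forward(Xr)
    y = (yr - y_mean) / y_scale
    q = len(parents)
    rng = np.random.default_rng(config.seed)
    map_hyper = _map_estimate(X, y, q, rng, config.n_restarts)
    diagnostics: dict = {"mode": config.mode, "n": len(y)}

    if config.mode == "map":
        draws = [map_hyper]
        diagnostics["converged"] = True
    else:
        ndim = q + 2
        nwalkers = max(2 * ndim + 2, 6)
        theta0 = np.log(map_hyper.to_vector())
        chains = []
        for c in range(config.n_chains):
            seed_c = (config.seed * 1000003 + 7919 * c) % (2**31)
            crng = np.random.default_rng(seed_c)
            p0 = theta0 + 0.05 * crng.standard_normal((nwalkers, ndim))
            sampler = emcee.EnsembleSampler(
                nwalkers, ndim, _log_post_logspace, args=(X, y, True))
            sampler.random_state = np.random.RandomState(seed_c).get_state()
            state = sampler.run_mcmc(p0, config.n_warmup, progress=False)
            sampler.reset()
            sampler.run_mcmc(state, config.n_samples, progress=False)
            chains.append(sampler.get_chain(flat=True))  # (iters*walkers, ndim)
        per_chain = np.stack(chains)  # (n_chains, draws, ndim)
        rhats = [split_rhat(per_chain[:, :, d]) for d in range(ndim)]
        diagnostics["rhat"] = {name: float(r) for name, r in zip(
            ["alpha"] + [f"rho_{p}" for p in parents] + ["sigma"], rhats)}
        diagnostics["converged"] = bool(max(rhats) <= config.rhat_threshold)
        pooled = per_chain.reshape(-1, ndim)
        take = np.linspace(0, pooled.shape[0] - 1,
                           min(config.max_draws, pooled.shape[0])).astype(int)
        draws = [ArdHyper.from_vector(np.exp(t)) for t in pooled[take]]
    diagnostics["fit_seconds"] = time.perf_counter() - t0
    return GpNodeModel(node=node, parents=list(parents), X_train=X, y_train=y,
                       hyper_draws=draws, standardisation=std,
                       diagnostics=diagnostics)


def _posterior_factors(model: GpNodeModel, hyper: ArdHyper):
    K = ard_kernel(model.X_train, model.X_train, hyper, add_noise=True)
    L, _ = _chol_with_jitter(K)
    alpha_vec = np.linalg.solve(L.T, np.linalg.solve(L, model.y_train))
    return L, alpha_vec


def posterior_mean_sd(model: GpNodeModel, X_new: np.ndarray,
                      hyper: ArdHyper | None = None,
                      include_noise: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian posterior predictive mean and sd at ``X_new`` (original units)
    under one hyperparameter setting (default: the posterior median)."""
    if hyper is None:
        hyper = model.median_hyper()
    Xs = model.standardisation.x_forward(np.atleast_2d(X_new))
    if Xs.shape[1] != len(model.parents):
        raise ValueError("X_new dimension mismatch")
    L, alpha_vec = _posterior_factors(model, hyper)
    Ks = ard_kernel(model.X_train, Xs, hyper)
    mean = Ks.T @ alpha_vec
    v = np.linalg.solve(L, Ks)
    var = hyper.alpha**2 - np.sum(v**2, axis=0)
    if include_noise:
        var = var + hyper.sigma**2
    var = np.maximum(var, 0.0)
    s = model.standardisation
    return s.y_back(mean), np.sqrt(var) * s.y_scale


def predict_node(model: GpNodeModel, X_new: np.ndarray, n_draws: int,
                 seed: int = 0, include_noise: bool = True) -> np.ndarray:
    """Posterior predictive draws (n_draws x rows) at ``X_new``, original units.

    Draws are spread over the retained hyperparameter draws; each draw samples
    the joint GP posterior (function values plus observation noise by default).
    """
    Xs = model.standardisation.x_forward(np.atleast_2d(X_new))
    if Xs.shape[1] != len(model.parents):
        raise ValueError("X_new dimension mismatch")
    rng = np.random.default_rng(seed)
    m = Xs.shape[0]
    out = np.empty((n_draws, m))
    hypers = model.hyper_draws
    which = rng.integers(0, len(hypers), size=n_draws) if len(hypers) > 1 \
        else np.zeros(n_draws, dtype=int)
    cache: dict[int, tuple] = {}
    for h_idx in np.unique(which):
        hyper = hypers[h_idx]
        L, alpha_vec = _posterior_factors(model, hyper)
        Ks = ard_kernel(model.X_train, Xs, hyper)
        mean = Ks.T @ alpha_vec
        v = np.linalg.solve(L, Ks)
        cov = ard_kernel(Xs, Xs, hyper) - v.T @ v
        cov = 0.5 * (cov + cov.T)
        Lc, _ = _chol_with_jitter(cov)
        cache[int(h_idx)] = (hyper, mean, Lc)
    for i in range(n_draws):
        hyper, mean, Lc = cache[int(which[i])]
        f = mean + Lc @ rng.standard_normal(m)
        if include_noise:
            f = f + hyper.sigma * rng.standard_normal(m)
        out[i] = f
    return model.standardisation.y_back(out)


@dataclass
class FittedTraitNetwork:
    """A DAG with a fitted GP per non-root node and empirical marginal samples
    for the roots."""

    dag: TraitDAG
    node_models: dict[str, GpNodeModel]
    root_samples: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for v in self.dag.nodes:
            parents = self.dag.parents(v)
            if parents:
                if v not in self.node_models:
                    raise ValueError(f"non-root node '{v}' has no fitted model")
                if list(self.node_models[v].parents) != parents:
                    raise ValueError(f"model parents for '{v}' disagree with DAG")
            elif v not in self.root_samples:
                raise ValueError(f"root node '{v}' has no empirical sample")


def fit_network(dag: TraitDAG, table: TraitTable,
                config: SamplerConfig | None = None) -> FittedTraitNetwork:
    """Fit a GP at every non-root node of ``dag``; roots keep their observed
    marginal sample."""
    if config is None:
        config = SamplerConfig()
    models: dict[str, GpNodeModel] = {}
    roots: dict[str, np.ndarray] = {}
    for i, v in enumerate(dag.nodes):
        parents = dag.parents(v)
        if parents:
            cfg = SamplerConfig(**{**config.__dict__, "seed": config.seed + i})
            models[v] = fit_node_gp(v, parents, table, cfg)
        else:
            roots[v] = table.values[v].to_numpy(dtype=float)
    return FittedTraitNetwork(dag=dag, node_models=models, root_samples=roots)


def save_network(network: FittedTraitNetwork, directory) -> None:
    """Serialise a fitted network: DAG JSON, per-node NPZ arrays, manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    network.dag.to_json(d / "dag.json")
    manifest = {"nodes": {}, "roots": list(network.root_samples)}
    for v, m in network.node_models.items():
        np.savez(d / f"node_{v}.npz", X_train=m.X_train, y_train=m.y_train,
                 hyper=np.stack([h.to_vector() for h in m.hyper_draws]),
                 x_mean=m.standardisation.x_mean, x_scale=m.standardisation.x_scale,
                 y_mean=m.standardisation.y_mean, y_scale=m.standardisation.y_scale)
        manifest["nodes"][v] = {"parents": m.parents, "diagnostics":
                                {k: val for k, val in m.diagnostics.items()}}
    for v, sample in network.root_samples.items():
        np.savez(d / f"root_{v}.npz", sample=sample)
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def load_network(directory) -> FittedTraitNetwork:
    d = Path(directory)
    dag = TraitDAG.from_json(d / "dag.json")
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    models: dict[str, GpNodeModel] = {}
    for v, meta in manifest["nodes"].items():
        z = np.load(d / f"node_{v}.npz")
        std = Standardisation(z["x_mean"], z["x_scale"],
                              float(z["y_mean"]), float(z["y_scale"]))
        draws = [ArdHyper.from_vector(row) for row in z["hyper"]]
        models[v] = GpNodeModel(node=v, parents=list(meta["parents"]),
                                X_train=z["X_train"], y_train=z["y_train"],
                                hyper_draws=draws, standardisation=std)
    roots = {v: np.load(d / f"root_{v}.npz")["sample"]
             for v in manifest["roots"]}
    return FittedTraitNetwork(dag=dag, node_models=models, root_samples=roots)
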