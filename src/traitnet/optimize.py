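"""Ideotype proposal by batch Bayesian optimisation over yield-parent traits.

The surrogate is the yield node's GP on its DAG parents (hyperparameters
frozen at their posterior medians).  Expected Improvement over the best
observed yield is maximised by multi-start bounded local search; batches use
the Constant Liar heuristic (pending proposals provisionally scored at the
maximum observed yield).  Because trait-trait correlations mean much of trait
space is unreachable by a real plant, an optional PCA constraint restricts the
search to the principal subspace explaining >95% of observed variation among
the yield parents, and proposals are transformed back to trait units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sciopt
from scipy import stats
from scipy.stats import qmc

from traitnet.gp import ArdHyper, GpNodeModel, _chol_with_jitter, ard_kernel


def expected_improvement(mean, sd, best_observed):
    """Closed-form EI: E[max(f - best, 0)] with f ~ N(mean, sd^2).

    Vectorised over ``mean``/``sd``; sd = 0 degenerates to max(mean-best, 0).
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if (sd < 0).any():
        raise ValueError("sd must be non-negative")
    imp = mean - best_observed
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, imp / np.where(sd > 0, sd, 1.0), 0.0)
        ei = np.where(sd > 0,
                      imp * stats.norm.cdf(z) + sd * stats.norm.pdf(z),
                      np.maximum(imp, 0.0))
    return ei if ei.shape else float(ei)


class GpSurrogate:
    """A GP predictor with frozen hyperparameters, supporting Constant-Liar
    augmentation of its training set.  Operates in original input units."""

    def __init__(self, X: np.ndarray, y: np.ndarray, hyper: ArdHyper,
                 y_offset: float | None = None,
                 noise_var: np.ndarray | None = None):
        self.X = np.atleast_2d(np.asarray(X, dtype=float)).copy()
        self.y = np.asarray(y, dtype=float).ravel().copy()
        self.hyper = hyper
        # GP prior mean: original-unit targets are not centred, so the
        # zero-mean prior applies to y - y_offset
        self.y_offset = float(np.mean(self.y)) if y_offset is None else y_offset
        # per-point observation noise: real measurements carry sigma^2,
        # Constant-Liar pseudo-observations are treated as near-noiseless
        self.noise_var = np.full(len(self.y), hyper.sigma**2) \
            if noise_var is None else np.asarray(noise_var, dtype=float).copy()
        self._refactor()

    @classmethod
    def from_node_model(cls, model: GpNodeModel) -> "GpSurrogate":
        """Freeze a fitted node model at its posterior-median hyperparameters.

        Training data are de-standardised so the surrogate works in trait
        units; the kernel hyperparameters are rescaled accordingly.
        """
        s = model.standardisation
        hyper = model.median_hyper()
        X = model.X_train * s.x_scale + s.x_mean
        y = s.y_back(model.y_train)
        scaled = ArdHyper(alpha=hyper.alpha * s.y_scale,
                          rho=hyper.rho * s.x_scale,
                          sigma=hyper.sigma * s.y_scale)
        return cls(X, y, scaled, y_offset=s.y_mean)

    def _refactor(self) -> None:
        K = ard_kernel(self.X, self.X, self.hyper) + np.diag(self.noise_var)
        self._L, _ = _chol_with_jitter(K)
        self._alpha_vec = np.linalg.solve(
            self._L.T, np.linalg.solve(self._L, self.y - self.y_offset))

    def predict(self, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Latent (noise-free) posterior mean and sd."""
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        Ks = ard_kernel(self.X, X_new, self.hyper)
        mean = self.y_offset + Ks.T @ self._alpha_vec
        v = np.linalg.solve(self._L, Ks)
        var = np.maximum(self.hyper.alpha**2 - np.sum(v**2, axis=0), 0.0)
        return mean, np.sqrt(var)

    def with_point(self, x: np.ndarray, y: float,
                   noise_var: float | None = None) -> "GpSurrogate":
        out = GpSurrogate.__new__(GpSurrogate)
        out.X = np.vstack([self.X, np.atleast_2d(x)])
        out.y = np.append(self.y, y)
        out.hyper = self.hyper
        out.y_offset = self.y_offset
        nv = self.hyper.sigma**2 if noise_var is None else noise_var
        out.noise_var = np.append(self.noise_var, nv)
        out._refactor()
        return out

    @property
    def dim(self) -> int:
        return self.X.shape[1]


@dataclass
class IdeotypeProposal:
    """One proposed trait combination with its predicted-yield summary."""

    trait_values: dict[str, float]
    predicted_yield_mean: float
    predicted_yield_sd: float
    ei_value: float
    exceedance_probability: float
    rank: int


def exceedance_probability(mean, sd, best_observed):
    """P(f > best) = Phi((mean - best)/sd) under the Gaussian surrogate."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (mean - best_observed) / np.where(sd > 0, sd, 1.0),
                     np.inf * np.sign(mean - best_observed))
    p = np.where(sd > 0, stats.norm.cdf(z), (mean > best_observed).astype(float))
    return p if p.shape else float(p)


def maximise_acquisition(surrogate: GpSurrogate, best_observed: float,
                         bounds: np.ndarray, restarts: int = 50,
                         seed: int = 0) -> tuple[np.ndarray, float]:
    """Maximise EI inside box bounds by multi-start bounded local search.

    Starts are a Latin hypercube plus the best observed training points; each
    runs a derivative-free bounded optimiser.  Returns (point, EI).
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    if np.all(hi <= lo):
        x = lo.copy()
        m, s = surrogate.predict(x)
        return x, float(expected_improvement(m, s, best_observed)[0])

    def neg_ei(x):
        m, s = surrogate.predict(np.clip(x, lo, hi))
        return -float(expected_improvement(m, s, best_observed)[0])

    sampler = qmc.LatinHypercube(d=surrogate.dim, seed=seed)
    starts = qmc.scale(sampler.random(restarts), lo, hi)
    in_box = np.all((surrogate.X >= lo) & (surrogate.X <= hi), axis=1)
    train_pts = surrogate.X[in_box]
    if len(train_pts):
        m_t, s_t = surrogate.predict(train_pts)
        ei_t = expected_improvement(m_t, s_t, best_observed)
        top = np.argsort(ei_t)[::-1][:5]
        starts = np.vstack([starts, train_pts[top]])
    best_x, best_val = None, np.inf
    box = [(float(a), float(b)) for a, b in zip(lo, hi)]
    margin = 1e-9 * np.maximum(hi - lo, 1.0)
    for x0 in starts:
        x0 = np.clip(x0, lo + margin, hi - margin)  # Powell misbehaves on bounds
        v0 = neg_ei(x0)
        if v0 < best_val:
            best_val, best_x = v0, x0.copy()
        res = sciopt.minimize(neg_ei, x0, method="Powell", bounds=box,
                              options={"xtol": 1e-6, "ftol": 1e-8, "maxiter": 500})
        xr = np.clip(res.x, lo, hi)
        vr = neg_ei(xr)  # re-evaluate: bounded Powell can report a worse point
        if vr < best_val:
            best_val, best_x = vr, xr
    return best_x, -best_val


def propose_batch_constant_liar(surrogate: GpSurrogate, best_observed: float,
                                bounds: np.ndarray, q: int = 10,
                                lie: float | None = None, seed: int = 0,
                                restarts: int = 50,
                                trait_names: list[str] | None = None
                                ) -> list[IdeotypeProposal]:
    """Propose a batch of q points sequentially under the Constant Liar.

    After each EI maximisation the proposal is appended to the surrogate's
    training set with response ``lie`` (default: the maximum observed yield)
    and the predictive equations refitted with hyperparameters frozen.
    Proposals are then ranked by exceedance probability under the original,
    lie-free surrogate (rank 1 = highest).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    if lie is None:
        lie = float(np.max(surrogate.y))
    if trait_names is None:
        trait_names = [f"x{i}" for i in range(surrogate.dim)]
    working = surrogate
    points = []
    for i in range(q):
        # i=0 reuses the caller's seed so a q=1 batch equals a single
        # acquisition maximisation exactly
        x, _ei = maximise_acquisition(working, best_observed, bounds,
                                      restarts=restarts,
                                      seed=(seed + 1000003 * i) % (2**31))
        points.append(x)
        # pending points are assumptions, not noisy measurements: insert them
        # near-noiselessly so EI collapses at already-proposed locations
        working = working.with_point(x, lie, noise_var=1e-10)
    X = np.vstack(points)
    mean, sd = surrogate.predict(X)
    ei = np.atleast_1d(expected_improvement(mean, sd, best_observed))
    exc = np.atleast_1d(exceedance_probability(mean, sd, best_observed))
    order = np.argsort(-exc, kind="stable")
    proposals = []
    for rank, i in enumerate(order, start=1):
        proposals.append(IdeotypeProposal(
            trait_values=dict(zip(trait_names, X[i])),
            predicted_yield_mean=float(mean[i]), predicted_yield_sd=float(sd[i]),
            ei_value=float(ei[i]), exceedance_probability=float(exc[i]),
            rank=rank))
    return proposals


# ---------------------------------------------------------------------------
# PCA correlation constraint


@dataclass
class PcBasis:
    """Orthonormal principal-component basis of the (standardised) yield-parent
    traits, truncated at the smallest component count explaining more than the
    variance threshold."""

    trait_names: list[str]
    loadings: np.ndarray  # traits x components (orthonormal columns)
    centre: np.ndarray
    scale: np.ndarray
    n_components: int
    variance_explained: float
    eigenvalues: np.ndarray = field(repr=False, default=None)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.atleast_2d(X) - self.centre) / self.scale
        return Z @ self.loadings[:, :self.n_components]

    def inverse(self, scores: np.ndarray, n_components: int | None = None) -> np.ndarray:
        k = self.n_components if n_components is None else n_components
        scores = np.atleast_2d(scores)
        Z = scores @ self.loadings[:, :k].T
        return Z * self.scale + self.centre


def build_pc_basis(table_values: pd.DataFrame, threshold: float = 0.95) -> PcBasis:
    """PCA of the correlation matrix of the given trait columns.

    Keeps the smallest number of components whose cumulative explained
    variance exceeds ``threshold``.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    X = table_values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("at least 2 rows required")
    centre = X.mean(axis=0)
    scale = X.std(axis=0)
    constant = [c for c, s in zip(table_values.columns, scale) if s == 0]
    if constant:
        raise ValueError(f"constant trait columns: {constant}")
    Z = (X - centre) / scale
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.maximum(evals[order], 0.0), evecs[:, order]
    cum = np.cumsum(evals) / evals.sum()
    n_comp = int(np.searchsorted(cum, threshold, side="right")) + 1
    n_comp = min(n_comp, len(evals))
    return PcBasis(trait_names=list(table_values.columns), loadings=evecs,
                   centre=centre, scale=scale, n_components=n_comp,
                   variance_explained=float(cum[n_comp - 1]),
                   eigenvalues=evals)


def optimise_in_pc_space(surrogate_on_pcs: GpSurrogate, basis: PcBasis,
                         bounds_original: np.ndarray, best_observed: float,
                         q: int = 10, lie: float | None = None, seed: int = 0,
                         restarts: int = 50) -> list[IdeotypeProposal]:
    """Constant-Liar batch proposal in the truncated PC basis.

    Per-component bounds are the observed score ranges (the surrogate's
    training scores); proposals are back-transformed to trait units and
    clipped to the observed per-trait [min, max].
    """
    score_bounds = np.column_stack([surrogate_on_pcs.X.min(axis=0),
                                    surrogate_on_pcs.X.max(axis=0)])
    pc_props = propose_batch_constant_liar(
        surrogate_on_pcs, best_observed, score_bounds, q=q, lie=lie, seed=seed,
        restarts=restarts,
        trait_names=[f"PC{i+1}" for i in range(surrogate_on_pcs.dim)])
    bounds_original = np.asarray(bounds_original, dtype=float)
    out = []
    for p in pc_props:
        scores = np.array([p.trait_values[f"PC{i+1}"]
                           for i in range(surrogate_on_pcs.dim)])
        x = basis.inverse(scores)[0]
        x = np.clip(x, bounds_original[:, 0], bounds_original[:, 1])
        out.append(IdeotypeProposal(
            trait_values=dict(zip(basis.trait_names, x)),
            predicted_yield_mean=p.predicted_yield_mean,
            predicted_yield_sd=p.predicted_yield_sd,
            ei_value=p.ei_value,
            exceedance_probability=p.exceedance_probability,
            rank=p.rank))
    return out


def proposals_to_frame(proposals: list[IdeotypeProposal]) -> pd.DataFrame:
    rows = []
    for p in sorted(proposals, key=lambda p: p.rank):
        row = {"rank": p.rank, **p.trait_values,
               "predicted_yield_mean": p.predicted_yield_mean,
               "predicted_yield_sd": p.predicted_yield_sd,
               "ei": p.ei_value,
               "exceedance_probability": p.exceedance_probability}
        rows.append(row)
    return pd.DataFrame(rows)
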