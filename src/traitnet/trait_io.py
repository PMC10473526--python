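"""Trait tables: I/O, normalising transforms, and predictive-mean-matching imputation.

A :class:`TraitTable` holds a plants x traits matrix of numeric measurements
(missing values allowed) together with per-plant labels (plant id, variety,
group).  Traits are made approximately normal by per-column invertible
transforms before network fitting, and missing cells are filled by chained
predictive mean matching so that every imputed value is an observed value from
the same column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

LABEL_COLUMNS = ["plant_id", "variety", "group"]
TRANSFORM_TAGS = ("identity", "log", "sqrt", "logit")


@dataclass
class TraitTable:
    """Plants x traits phenotype matrix with per-row labels.

    Parameters
    ----------
    values : pandas.DataFrame
        Numeric trait columns only; NaN marks a missing measurement.
    plant_id, variety, group : pandas.Series
        Per-row labels aligned with ``values``.
    """

    values: pd.DataFrame
    plant_id: pd.Series
    variety: pd.Series
    group: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("trait names must be unique")
        n = len(self.values)
        for name, lab in (("plant_id", self.plant_id), ("variety", self.variety),
                          ("group", self.group)):
            if len(lab) != n:
                raise ValueError(f"label '{name}' length {len(lab)} != {n} rows")
        if self.variety.isna().any():
            raise ValueError("every row must carry a variety label")
        non_numeric = [c for c in self.values.columns
                       if not pd.api.types.is_numeric_dtype(self.values[c])]
        if non_numeric:
            raise ValueError(f"non-numeric trait columns: {non_numeric}")

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_plants(self) -> int:
        return len(self.values)

    def copy(self) -> "TraitTable":
        return TraitTable(self.values.copy(), self.plant_id.copy(),
                          self.variety.copy(), self.group.copy())

    def select_group(self, group: str) -> "TraitTable":
        """Restrict to rows whose group label equals ``group``."""
        keep = (self.group == group).to_numpy()
        return TraitTable(self.values.loc[keep].reset_index(drop=True),
                          self.plant_id.loc[keep].reset_index(drop=True),
                          self.variety.loc[keep].reset_index(drop=True),
                          self.group.loc[keep].reset_index(drop=True))

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"plant_id": self.plant_id, "variety": self.variety,
                           "group": self.group})
        return pd.concat([df.reset_index(drop=True),
                          self.values.reset_index(drop=True)], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TraitTable":
        missing = [c for c in LABEL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing label columns: {missing}")
        traits = [c for c in df.columns if c not in LABEL_COLUMNS]
        values = df[traits].apply(pd.to_numeric)
        return cls(values.reset_index(drop=True),
                   df["plant_id"].astype(str).reset_index(drop=True),
                   df["variety"].astype(str).reset_index(drop=True),
                   df["group"].astype(str).reset_index(drop=True))

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class TransformSpec:
    """Per-trait normalising transform assignment.

    ``tags[t]`` is one of identity / log / sqrt / logit and ``offsets[t]`` is
    added to the column before the transform so that arguments lie strictly
    inside the transform's domain.
    """

    tags: dict[str, str]
    offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {t: tag for t, tag in self.tags.items() if tag not in TRANSFORM_TAGS}
        if bad:
            raise ValueError(f"unknown transform tags: {bad}")

    def tag(self, trait: str) -> str:
        return self.tags.get(trait, "identity")

    def offset(self, trait: str) -> float:
        return float(self.offsets.get(trait, 0.0))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"tags": self.tags,
                            "offsets": {k: float(v) for k, v in self.offsets.items()}},
                           fh)

    @classmethod
    def from_yaml(cls, path) -> "TransformSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(tags=dict(raw.get("tags", {})),
                   offsets=dict(raw.get("offsets", {})))


def _forward(x: np.ndarray, tag: str, offset: float, trait: str) -> np.ndarray:
    z = x + offset
    obs = z[~np.isnan(z)]
    if tag == "identity":
        return x.copy()
    if tag == "log":
        if (obs <= 0).any():
            raise ValueError(f"trait '{trait}': log requires positive values after offset")
        return np.log(z)
    if tag == "sqrt":
        if (obs < 0).any():
            raise ValueError(f"trait '{trait}': sqrt requires non-negative values after offset")
        return np.sqrt(z)
    if tag == "logit":
        if ((obs <= 0) | (obs >= 1)).any():
            raise ValueError(f"trait '{trait}': logit requires values in (0,1) after offset")
        return np.log(z / (1.0 - z))
    raise ValueError(f"unknown tag {tag!r}")


def _inverse(y: np.ndarray, tag: str, offset: float) -> np.ndarray:
    if tag == "identity":
        return y.copy()
    if tag == "log":
        return np.exp(y) - offset
    if tag == "sqrt":
        return np.square(y) - offset
    if tag == "logit":
        return 1.0 / (1.0 + np.exp(-y)) - offset
    raise ValueError(f"unknown tag {tag!r}")


def apply_transform(table: TraitTable, spec: TransformSpec) -> TraitTable:
    """Apply the per-trait transforms element-wise; missing cells stay missing."""
    out = table.values.copy()
    for trait in table.trait_names:
        col = out[trait].to_numpy(dtype=float)
        out[trait] = _forward(col, spec.tag(trait), spec.offset(trait), trait)
    return TraitTable(out, table.plant_id, table.variety, table.group)


def inverse_transform(table: TraitTable, spec: TransformSpec) -> TraitTable:
    """Invert :func:`apply_transform` (exact to numerical round-off)."""
    out = table.values.copy()
    for trait in table.trait_names:
        col = out[trait].to_numpy(dtype=float)
        out[trait] = _inverse(col, spec.tag(trait), spec.offset(trait))
    return TraitTable(out, table.plant_id, table.variety, table.group)


def select_transforms(table: TraitTable, min_obs: int = 10) -> TransformSpec:
    """Pick, per trait, the transform minimising absolute sample skewness.

    Ties are broken by the preference order identity > log > sqrt > logit.
    log and sqrt receive an offset when the column touches or crosses their
    domain boundary; logit is only considered for columns already in (0, 1).
    A constant column (skewness defined as 0) maps to identity.
    """
    tags: dict[str, str] = {}
    offsets: dict[str, float] = {}
    for trait in table.trait_names:
        col = table.values[trait].to_numpy(dtype=float)
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"trait '{trait}' has no observed values")
        if obs.size < min_obs:
            raise ValueError(f"trait '{trait}' has fewer than {min_obs} observed values")
        rng_width = float(np.ptp(obs))
        if rng_width == 0.0:
            tags[trait] = "identity"
            continue
        candidates: list[tuple[float, int, str, float]] = []
        for pref, tag in enumerate(("identity", "log", "sqrt", "logit")):
            off = 0.0
            if tag in ("log", "sqrt"):
                lo = obs.min()
                bound = 0.0
                if (tag == "log" and lo <= bound) or (tag == "sqrt" and lo < bound):
                    off = -lo + 1e-6 * rng_width
            elif tag == "logit" and (obs.min() <= 0 or obs.max() >= 1):
                continue
            try:
                tx = _forward(obs, tag, off, trait)
            except ValueError:
                continue
            if not np.all(np.isfinite(tx)):
                continue
            sk = stats.skew(tx)
            if np.ptp(tx) == 0:
                sk = 0.0
            candidates.append((abs(float(sk)), pref, tag, off))
        candidates.sort(key=lambda c: (round(c[0], 12), c[1]))
        _, _, tag, off = candidates[0]
        tags[trait] = tag
        if off:
            offsets[trait] = off
    return TransformSpec(tags=tags, offsets=offsets)


def _perturbed_ridge_fit(X: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                         ridge: float = 1e-5) -> tuple[np.ndarray, np.ndarray]:
    """Ridge-stabilised OLS with Bayesian-perturbed coefficients.

    Returns (beta_hat, beta_star): the point estimate used to rank donors and a
    posterior draw used to predict the missing cases, following the usual
    chained-equations convention.
    """
    n, p = X.shape
    A = X.T @ X + ridge * np.eye(p)
    beta_hat = np.linalg.solve(A, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = (resid @ resid) / rng.chisquare(dof) if dof > 0 else 1.0
    cov = sigma2 * np.linalg.inv(A)
    # symmetrise before Cholesky to kill round-off asymmetry
    cov = 0.5 * (cov + cov.T) + 1e-12 * np.eye(p)
    beta_star = beta_hat + np.linalg.cholesky(cov) @ rng.standard_normal(p)
    return beta_hat, beta_star


def impute_pmm(table: TraitTable, donors: int = 5, n_iterations: int = 5,
               seed: int = 0) -> TraitTable:
    """Impute missing trait cells by chained predictive mean matching.

    Each incomplete column is regressed on all other trait columns (complete
    cases, ridge-stabilised, posterior-perturbed coefficients); each missing
    cell receives the observed value of one of the ``donors`` cases with
    closest predicted mean, chosen uniformly at random.  ``n_iterations``
    sweeps are run.  Observed cells are never altered and every imputed value
    is an observed value of the same column.
    """
    if donors < 1:
        raise ValueError("donors must be >= 1")
    vals = table.values.to_numpy(dtype=float).copy()
    mask = np.isnan(vals)
    if not mask.any():
        return table.copy()
    n, m = vals.shape
    for j in range(m):
        n_obs = int((~mask[:, j]).sum())
        if n_obs == 0:
            raise ValueError(f"trait '{table.trait_names[j]}' has no observed values")
        if n_obs < donors:
            raise ValueError(
                f"trait '{table.trait_names[j]}': {n_obs} complete cases < donors={donors}")
    rng = np.random.default_rng(seed)
    # initial fill: column means of the observed values
    col_means = np.nanmean(vals, axis=0)
    filled = vals.copy()
    for j in range(m):
        filled[mask[:, j], j] = col_means[j]
    incomplete = [j for j in range(m) if mask[:, j].any()]
    for _ in range(n_iterations):
        for j in incomplete:
            obs_rows = ~mask[:, j]
            mis_rows = mask[:, j]
            others = [k for k in range(m) if k != j]
            X = np.column_stack([np.ones(n), filled[:, others]])
            y_obs = vals[obs_rows, j]
            beta_hat, beta_star = _perturbed_ridge_fit(X[obs_rows], y_obs, rng)
            pred_obs = X[obs_rows] @ beta_hat
            pred_mis = X[mis_rows] @ beta_star
            order = np.abs(pred_obs[None, :] - pred_mis[:, None])
            # k nearest observed donors per missing case
            idx = np.argsort(order, axis=1, kind="stable")[:, :donors]
            pick = rng.integers(0, donors, size=idx.shape[0])
            filled[mis_rows, j] = y_obs[idx[np.arange(idx.shape[0]), pick]]
    out = pd.DataFrame(filled, columns=table.trait_names)
    return TraitTable(out, table.plant_id, table.variety, table.group)
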