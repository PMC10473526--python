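"""Heritability partitioning and the mediated-pleiotropy association simulation.

Broad-sense heritability H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2) is estimated
from one-way ANOVA mean squares by variety, either on raw trait values
("total" heritability) or on trait-network residuals ("direct" heritability,
conditioning away variation transmitted through causal parent traits).  The
simulation component generates a parent trait driven by "parent SNPs", a child
trait driven by "child SNPs" plus gamma x parent, and non-causal SNPs, then
compares association scans of the child trait run raw versus on the residual
of child-on-parent regression: controlling for the upstream trait recovers
power for directly causal SNPs and stops indirectly acting (mediated
pleiotropy) SNPs masquerading as hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from traitnet.gp import FittedTraitNetwork, posterior_mean_sd
from traitnet.trait_io import TraitTable


@dataclass
class HeritabilityEstimate:
    trait: str
    H2: float
    sigma2_g: float
    sigma2_e: float
    mode: str  # "raw" or "residual"
    anova_p: float
    clipped: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.H2 <= 1.0):
            raise ValueError("H2 outside [0,1]")


def _anova_h2(values: np.ndarray, varieties: np.ndarray, trait: str,
              mode: str) -> HeritabilityEstimate:
    groups = pd.Series(values).groupby(pd.Series(varieties))
    counts = groups.count().to_numpy()
    if (counts >= 2).sum() < 2 or len(counts) < 2:
        raise ValueError("need >= 2 varieties with >= 2 replicates each")
    v = len(counts)
    n = int(counts.sum())
    grand = values.mean()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for _, g in groups))
    ms_g = ss_between / (v - 1)
    ms_e = ss_within / (n - v)
    r_bar = stats.hmean(counts)  # harmonic-mean replicates for unbalanced designs
    sigma2_g_raw = (ms_g - ms_e) / r_bar
    clipped = sigma2_g_raw < 0
    sigma2_g = max(0.0, sigma2_g_raw)
    sigma2_e = ms_e
    denom = sigma2_g + sigma2_e
    h2 = sigma2_g / denom if denom > 0 else 0.0
    f_stat = ms_g / ms_e if ms_e > 0 else np.inf
    p = float(stats.f.sf(f_stat, v - 1, n - v))
    return HeritabilityEstimate(trait=trait, H2=float(h2), sigma2_g=float(sigma2_g),
                                sigma2_e=float(sigma2_e), mode=mode, anova_p=p,
                                clipped=clipped)


def compute_residuals(network: FittedTraitNetwork, table: TraitTable) -> TraitTable:
    """Observed minus GP-posterior-mean prediction from parents, per non-root
    trait; root traits (and traits absent from the network) pass through."""
    if not table.is_complete():
        raise ValueError("table must be complete")
    out = table.values.copy()
    for trait in table.trait_names:
        if trait not in network.dag.nodes:
            continue
        parents = network.dag.parents(trait)
        if not parents:
            continue
        model = network.node_models[trait]
        X = table.values[parents].to_numpy(dtype=float)
        means = np.zeros(len(X))
        for h in model.hyper_draws:
            m, _ = posterior_mean_sd(model, X, hyper=h)
            means += m
        means /= len(model.hyper_draws)
        out[trait] = table.values[trait].to_numpy(dtype=float) - means
    return TraitTable(out, table.plant_id, table.variety, table.group)


def estimate_h2(table: TraitTable, trait: str, use_residuals: bool = False,
                network: FittedTraitNetwork | None = None) -> HeritabilityEstimate:
    """Broad-sense heritability of ``trait`` from one-way ANOVA by variety.

    With ``use_residuals`` the response is the trait-network residual ("direct"
    heritability); a trait without parents falls back to raw mode, since its
    residual equals its raw value.
    """
    mode = "raw"
    values = table.values[trait].to_numpy(dtype=float)
    if use_residuals:
        if network is None:
            raise ValueError("use_residuals requires a fitted network")
        if trait in network.dag.nodes and network.dag.parents(trait):
            values = compute_residuals(network, table).values[trait].to_numpy(dtype=float)
            mode = "residual"
    return _anova_h2(values, table.variety.to_numpy(), trait, mode)


def heritability_table(table: TraitTable, network: FittedTraitNetwork) -> pd.DataFrame:
    """Raw and residual H2 for every trait, with Benjamini-Hochberg adjusted
    ANOVA p-values on the raw scans."""
    rows = []
    for trait in table.trait_names:
        raw = estimate_h2(table, trait, use_residuals=False)
        res = estimate_h2(table, trait, use_residuals=True, network=network)
        rows.append({"trait": trait, "H2_raw": raw.H2,
                     "H2_residual": res.H2 if res.mode == "residual" else np.nan,
                     "anova_p": raw.anova_p})
    df = pd.DataFrame(rows)
    p = df["anova_p"].to_numpy()
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        prev = min(prev, p[i] * m / (rank_idx + 1))
        adj[i] = prev
    df["anova_p_adj"] = adj
    return df


# ---------------------------------------------------------------------------
# Mediated-pleiotropy simulation


@dataclass
class MediatedPleiotropySim:
    """Simulated genotypes and parent/child traits with known causal SNP sets.

    Genotypes are 0/1 Bernoulli(0.5) draws; the parent trait is a weighted sum
    of the parent SNPs plus noise, the child trait a weighted sum of the child
    SNPs plus gamma x parent plus noise; null SNPs affect neither.
    """

    genotypes: np.ndarray
    parent_trait: np.ndarray
    child_trait: np.ndarray
    parent_snps: np.ndarray
    child_snps: np.ndarray
    null_snps: np.ndarray
    parent_weights: np.ndarray
    child_weights: np.ndarray
    gamma: float
    sigma: float

    def __post_init__(self) -> None:
        all_idx = np.concatenate([self.parent_snps, self.child_snps, self.null_snps])
        if len(set(all_idx.tolist())) != self.genotypes.shape[1] \
                or len(all_idx) != self.genotypes.shape[1]:
            raise ValueError("SNP index sets must be disjoint and cover all SNPs")
        if not np.isin(self.genotypes, (0, 1)).all():
            raise ValueError("genotypes must be 0/1")


def simulate_mediated_pleiotropy(n_plants: int, n_parent_snps: int,
                                 n_child_snps: int, n_null_snps: int,
                                 gamma: float, sigma: float,
                                 weights_sd: float = 1.0,
                                 seed: int = 0) -> MediatedPleiotropySim:
    if min(n_plants, 1) < 1 or min(n_parent_snps, n_child_snps, n_null_snps) < 0:
        raise ValueError("counts must be non-negative (n_plants >= 1)")
    if sigma <= 0 or not np.isfinite(gamma) or not np.isfinite(sigma):
        raise ValueError("sigma must be positive and finite, gamma finite")
    rng = np.random.default_rng(seed)
    m = n_parent_snps + n_child_snps + n_null_snps
    G = rng.integers(0, 2, size=(n_plants, m)).astype(np.int8)
    parent_idx = np.arange(n_parent_snps)
    child_idx = np.arange(n_parent_snps, n_parent_snps + n_child_snps)
    null_idx = np.arange(n_parent_snps + n_child_snps, m)
    w_p = rng.normal(0.0, weights_sd, size=n_parent_snps)
    w_c = rng.normal(0.0, weights_sd, size=n_child_snps)
    p = G[:, parent_idx] @ w_p + rng.normal(0.0, sigma, size=n_plants)
    c = G[:, child_idx] @ w_c + gamma * p + rng.normal(0.0, sigma, size=n_plants)
    return MediatedPleiotropySim(genotypes=G, parent_trait=p, child_trait=c,
                                 parent_snps=parent_idx, child_snps=child_idx,
                                 null_snps=null_idx, parent_weights=w_p,
                                 child_weights=w_c, gamma=gamma, sigma=sigma)


@dataclass
class ScanResult:
    pvalues: np.ndarray       # NaN where a SNP was filtered out
    tested: np.ndarray        # indices of tested SNPs
    hits: np.ndarray          # indices of significant SNPs
    threshold: float          # Bonferroni per-test level alpha_fwer / m


def association_scan(trait_values: np.ndarray, genotypes: np.ndarray,
                     alpha_fwer: float = 0.1,
                     maf_min: float = 0.05) -> ScanResult:
    """Per-SNP simple linear regression with Bonferroni FWER control.

    SNPs with minor-allele frequency <= ``maf_min`` (including monomorphic
    SNPs) are excluded before testing; remaining SNPs get a two-sided t-test
    of the regression slope, and a hit requires p < alpha_fwer / m for m
    tested SNPs.
    """
    if not (0.0 < alpha_fwer < 1.0):
        raise ValueError("alpha_fwer must lie in (0,1)")
    y = np.asarray(trait_values, dtype=float).ravel()
    G = np.asarray(genotypes, dtype=float)
    if G.shape[0] != y.shape[0]:
        raise ValueError("trait and genotype row counts differ")
    n, m_all = G.shape
    freq = G.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    tested_mask = maf > maf_min
    pvals = np.full(m_all, np.nan)
    tested = np.flatnonzero(tested_mask)
    if tested.size:
        Gc = G[:, tested] - G[:, tested].mean(axis=0)
        yc = y - y.mean()
        sg = np.sqrt((Gc**2).sum(axis=0))
        sy = np.sqrt((yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Gc.T @ yc) / (sg * sy)
        r = np.clip(r, -1.0, 1.0)
        df = n - 2
        with np.errstate(divide="ignore"):
            t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
        pvals[tested] = 2.0 * stats.t.sf(np.abs(t), df)
    m = tested.size
    thr = alpha_fwer / m if m else 0.0
    hits = np.flatnonzero(pvals < thr)
    return ScanResult(pvalues=pvals, tested=tested, hits=hits, threshold=thr)


def power_experiment(gamma_grid, sigma_grid, n_reps: int = 50,
                     n_plants: int = 300, n_parent_snps: int = 10,
                     n_child_snps: int = 10, n_null_snps: int = 30,
                     weights_sd: float = 1.0, alpha_fwer: float = 0.1,
                     maf_min: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Raw-versus-residual association power over a (gamma, sigma) grid.

    For every grid cell, ``n_reps`` simulations are scanned on the child trait
    directly ("raw") and on the residual of the child-on-parent linear
    regression ("residual").  Power is the fraction of SNPs in each class
    (parent / child / null) flagged as hits.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gamma in np.atleast_1d(gamma_grid):
        for sigma in np.atleast_1d(sigma_grid):
            tallies = {("raw", k): 0 for k in ("parent", "child", "null")}
            tallies.update({("residual", k): 0 for k in ("parent", "child", "null")})
            fwer_any = {"raw": 0, "residual": 0}
            for _ in range(n_reps):
                sim = simulate_mediated_pleiotropy(
                    n_plants, n_parent_snps, n_child_snps, n_null_snps,
                    gamma=float(gamma), sigma=float(sigma),
                    weights_sd=weights_sd, seed=int(rng.integers(0, 2**31 - 1)))
                slope = (np.cov(sim.parent_trait, sim.child_trait)[0, 1]
                         / np.var(sim.parent_trait))
                resid = sim.child_trait - slope * sim.parent_trait
                for mode, y in (("raw", sim.child_trait), ("residual", resid)):
                    res = association_scan(y, sim.genotypes, alpha_fwer, maf_min)
                    hitset = set(res.hits.tolist())
                    tallies[(mode, "parent")] += len(hitset & set(sim.parent_snps.tolist()))
                    tallies[(mode, "child")] += len(hitset & set(sim.child_snps.tolist()))
                    null_hits = hitset & set(sim.null_snps.tolist())
                    tallies[(mode, "null")] += len(null_hits)
                    fwer_any[mode] += bool(null_hits)
            for mode in ("raw", "residual"):
                denom = {"parent": n_parent_snps, "child": n_child_snps,
                         "null": n_null_snps}
                for cls in ("parent", "child", "null"):
                    rows.append({"gamma": float(gamma), "sigma": float(sigma),
                                 "mode": mode, "snp_class": cls,
                                 "power": tallies[(mode, cls)] / (denom[cls] * n_reps),
                                 "fwer_null": fwer_any[mode] / n_reps})
    return pd.DataFrame(rows)


def genotypes_to_csv(sim: MediatedPleiotropySim, path) -> None:
    pd.DataFrame(sim.genotypes,
                 columns=[f"snp_{i}" for i in range(sim.genotypes.shape[1])]
                 ).to_csv(path, index=False)


def genotypes_to_vcf_like(sim: MediatedPleiotropySim, path) -> None:
    """Minimal VCF-like TSV (CHROM, POS, ID, then per-plant 0/1 calls)."""
    n, m = sim.genotypes.shape
    cols = {"CHROM": ["1"] * m, "POS": list(range(1, m + 1)),
            "ID": [f"snp_{i}" for i in range(m)]}
    for j in range(n):
        cols[f"plant_{j}"] = sim.genotypes[j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)
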