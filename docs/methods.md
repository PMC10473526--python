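# Methods

This note records the statistical models implemented in `traitnet`, the
defaults and why they were chosen, the numerical choices that matter, and the
limits of what the synthetic-data tests demonstrate.

## Data model and pre-processing

A panel is a plants × traits table with variety and group labels; varieties
are replicated (default 94 varieties × 5 replicates, mirroring a typical
glasshouse diversity panel) and cells may be missing. Traits are transformed
toward normality per column (identity, log, sqrt or logit, with an offset
where the domain requires one). When the user does not supply assignments,
`select_transforms` picks the tag minimising absolute sample skewness, with
ties broken identity > log > sqrt > logit; a constant column takes identity.

Missing cells are imputed by chained predictive mean matching: each incomplete
column is regressed on all other trait columns over complete cases
(ridge-stabilised with λ = 1e-5; coefficients perturbed by a posterior draw),
each missing case is matched to the `donors = 5` observed cases with closest
predicted mean, and one donor's observed value is copied at random;
`n_iterations = 5` sweeps. These are the conventional defaults of
chained-equations PMM. Only a single completed table is produced — imputation
uncertainty is not propagated into structure learning, a known limitation.
Imputation operates on transformed values; whether to impute before or after
transformation is genuinely open, and transformed-scale imputation was chosen
because the regressions behind PMM are linear.

## Structure learning

The trait network is a Gaussian Bayesian network: each node is Gaussian with
mean linear in its parents. The network score is BIC,

    score = Σ_nodes [ max log L(node | parents) − (k/2) ln n ],

with k = #parents + intercept + variance per node; it decomposes additively,
so single-edge moves are scored locally and cached. Tabu search starts from
the whitelist-only graph and applies the best non-tabu
addition/deletion/reversal respecting acyclicity, the blacklist, and the tier
map (edges from a higher to a lower tier are auto-forbidden); the inverse of
each move is tabu for `tabu_length = 10` steps (aspiration allows tabu moves
that beat the best score) and search stops after `max_stall = 15` moves
without improvement. These Tabu defaults are the standard ones for this
search; the data sizes here (≲ 30 nodes, ≲ 500 rows) make each run take
milliseconds.

Score-equivalent orientations (covered-edge reversals) are true ties after
rounding deltas to 1e-6; ties break toward the tier-increasing direction
when a tier map is given, else lexicographically. Without tiers a DAG is
identified only up to its Markov equivalence class, so same-tier edge
orientations should not be over-interpreted.

Arc probabilities are bootstrap frequencies: rows (plants) are resampled with
replacement — `replicates = 500` at analysis scale, 100 in the test suite —
and the search rerun per resample. The reported network keeps arcs with
probability ≥ 0.5, resolved greedily by descending probability with cycles
broken by dropping the weaker arc. Cross-fold averaging partitions varieties
(never their replicates separately, to prevent leakage) into 5 folds, runs
the bootstrap per fold, and keeps arcs present in a majority (≥ 3 of 5) of
fold networks; a pooled mode (mean fold probability ≥ 0.5) is available
behind a flag since "consistently across folds" admits both readings. Both
the 0.5 cut and the majority rule are configurable.

## Per-node Gaussian processes

Each non-root node is regressed on its parents with a GP under the ARD
squared-exponential kernel

    K_ij = α² exp(−½ Σ_k ((x_ik − x_jk)/ρ_k)²) + δ_ij σ²,

one length-scale per parent, so an irrelevant parent is suppressed by a large
ρ_k. Inputs and output are standardised to zero mean and unit variance before
fitting — necessary for fixed priors to be meaningful across traits measured
in different units. Priors: half-normal(0,1) on α and σ (a N(0,1) prior on a
strictly positive scale can only mean its positive restriction) and
inverse-gamma(shape 5, scale 5) on each ρ_k (mode 5/6, i.e. slightly under
one standardised unit). σ is a single homoscedastic noise scale per node; the
δ_ij in the kernel indexes data points, not distinct noise levels. A
heteroscedastic variant is out of scope.

Fitting modes: `map` (multi-start L-BFGS on log-hyperparameters; fast,
deterministic, the default in the test suite and CLI) and `mcmc`
(MAP-initialised affine-invariant ensemble sampling via emcee — 4 independent
ensembles mirroring a 4-chain run, 1000 warm-up and 1000 sampling iterations
by default, thinned to ≤ 400 retained draws). Convergence is declared when
split-R̂ ≤ 1.05 on every hyperparameter; a non-converged fit is returned
flagged rather than raised, leaving policy to the caller. Cholesky
factorisations carry jitter starting at 1e-8 and escalating ×10 to at most
1e-4 before erroring.

## Interventions

`do_intervene` fixes one trait to an `n_grid = 20`-point grid spanning its
observed range. For each network, grid value and base plant, descendants are
predicted in topological order: a descendant's parent takes the sampled value
if it is itself downstream of the intervention, and the plant's observed
value otherwise — non-descendants are never altered. Root traits are never
resampled. Draws pool over base plants (all plants of the group by default),
hyperparameter draws and candidate networks; `n_draws = 1000` pooled draws
per grid point and network keeps the Monte-Carlo error of the 10%/90%
quantiles well under 0.05 sd on the test fixtures. Results are 10–90%
quantile curves per descendant. This is population-level do-style prediction,
not individual-level counterfactual inference.

## Ideotype optimisation

The surrogate is the yield node's GP on its DAG parents only (controlling the
direct parents makes all other traits irrelevant to yield), with
hyperparameters frozen at their posterior medians — refitting per liar
insertion would be expensive and is not part of the Constant-Liar heuristic.
Expected Improvement against the best observed yield is maximised by
`restarts = 50` Latin-hypercube starts of a bounded derivative-free local
optimiser (Powell), with two safeguards found necessary in practice: starts
are nudged strictly inside the box (bounded Powell misbehaves when started on
a bound) and the returned point is never worse than any start or observed
training point. Proposals are constrained to the observed per-trait
[min, max].

Batches of `q = 10` use the Constant Liar: each accepted proposal is appended
to the surrogate's training set with response L = the maximum observed yield
and the predictive equations refitted. Pending points are assumptions rather
than noisy measurements, so they are inserted with near-zero observation
noise; this collapses EI at already-proposed locations and keeps batch
members distinct even on flat acquisition landscapes. Proposals are ranked by
exceedance probability P(f(x) > best observed) under the original lie-free
surrogate — EI is kept as metadata.

Because trait correlations make much of trait space unreachable, the
constrained mode runs the optimisation in the principal-component basis of
the yield parents (correlation-matrix PCA; smallest component count
explaining > 95% of variance), with per-component bounds equal to the
observed score ranges. Back-transformed proposals are additionally clipped to
the observed trait bounds; clipping rather than rejection was chosen so a
batch always returns q points.

## Heritability and the mediated-pleiotropy simulation

Broad-sense heritability comes from one-way ANOVA by variety:
σ_g² = max(0, (MS_genotype − MS_error)/r̄) with r̄ the harmonic mean of
replicates per variety (the standard unbalanced-design correction), σ_e² =
MS_error, H² = σ_g²/(σ_g² + σ_e²), with the F-test p-value attached and
negative-variance clipping flagged. "Direct" heritability replaces the
response by the trait minus its GP posterior-mean prediction from its
parents; a parentless trait falls back to the raw estimate, since its
residual equals its raw value.

The association simulation draws 0/1 genotypes iid Bernoulli(0.5): the parent
trait is a weighted sum of parent SNPs plus N(0, σ²) noise, the child trait a
weighted sum of child SNPs plus γ × parent plus noise, and null SNPs touch
neither. Weights are N(0, weights_sd²); defaults (300 plants, 10 parent + 10
child + 30 null SNPs, weights_sd = 1) place signals at detectable but not
trivial effect sizes, since the simulation's own weight scales are not pinned
down externally. Scans regress the trait on each SNP (MAF > 0.05 filter,
monomorphic SNPs dropped) with two-sided t-tests and Bonferroni control at
family-wise error 0.1. Residual scans use the residual of child-on-parent
ordinary least squares — the simulation's generative link is linear, so
linear residualisation is exact there; the real-trait path uses GP residuals.
The headline contrast reproduced by the tests: at γ = 3, σ = 0.1 the raw scan
mostly flags parent SNPs (mediated pleiotropy) while the residual scan
recovers child SNPs and drops parent SNPs to null levels, with neither mode
inflating null-SNP error.

## Synthetic panels: what they do and do not show

The generator draws traits in canonical topological order: each trait is the
sum of parent edge effects — linear (coefficient × parent) or saturating
(coefficient × tanh(standardised parent), a smooth bounded monotone stand-in
for the saturation seen in real trait-yield relationships) — plus a
per-variety random intercept shared across replicates (the genotype signal
heritability needs) and independent Gaussian noise. Missingness is MCAR, the
weakest mechanism PMM handles. Varieties split into two groups with
optionally perturbed coefficients, emulating spring/winter-type panels. The
default 8-node hierarchy (architectural traits → flowers → pod/seed traits →
yield) includes the negative seed-number → TGW trade-off.

Passing tests on these panels demonstrate correct inference when the model
family matches the generator: additive effects, Gaussian noise, no latent
confounders, no spatial design effects, MCAR missingness. They do not
demonstrate robustness to real measurement error structure, genotype ×
environment interaction, or unmeasured common causes — on real data an
inferred arc is a modelling statement conditional on the measured trait set,
not a verified mechanism.

## Reproducibility and scale

Every stochastic routine takes an explicit seed; the CLI derives per-stage
seeds from one global seed and writes manifests with input checksums, so
reruns are bit-identical. The test suite and the acceptance script run the
full pipeline at reduced scale — 100 bootstrap replicates instead of 500,
MAP instead of full MCMC, 5–20 simulation seeds per estimate — sizes chosen
so the whole suite completes in a few minutes on one CPU while leaving every
qualitative conclusion unchanged.
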