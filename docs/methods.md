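# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the known limitations of `ovarevo`. Nothing here
reports an empirical quantity that the tests or `scripts/acceptance.py`
do not themselves compute.

## Trait records and their statistics

A trait record is one literature-style observation: a single value, a
min–max range, or a mean with a deviation, with taxonomy at
species/genus/family/order rank, a reproductive-caste flag, a source id,
and an outlier flag. Intraspecific percent difference follows the two
printed forms: `100·(max−min)/median` for ranges (the median of a
two-value range is its midpoint — the only consistent reading) and
`100·(2·deviation)/mean` for mean-with-deviation records; several
independent records are first reduced to per-record point values (range →
midpoint, mean±dev → mean) and then summarized by `100·(max−min)/median`
with the sample median. A lone single-value record reports no variation
(0%).

Filtering removes records from non-reproductive individuals of eusocial
species (workers do not reflect the reproductive phenotype) and records
flagged as unvalidated outliers; every removal is written to an audit log.
Outliers are an input flag, not detected automatically — the cases they
model were identified by manual source checking, which code cannot
reproduce.

All continuous traits are analysed on the log10 scale, so aggregation to
a taxonomic rank averages **after** the transform (mean of logs, not log
of means). Two resampling protocols feed the replicated analyses:
*reshuffle* keeps exactly one record per taxon per iteration (propagating
record-level uncertainty), and *downsample-half* keeps ⌈k/2⌉ of each
family's k records (family-level analyses). Both are deterministic given
a seed.

## PGLS and the replicated protocol

The regression error covariance is the Brownian shared-path matrix; no
λ/κ/δ transforms are offered because the analysis this package implements
specifies pure BM covariance. The covariance is factorized by Cholesky;
failure raises rather than being repaired with a ridge, so pathological
trees surface loudly. The slope test is the conventional GLS Wald t with
n−2 df. The `sigma2` field of a fit is the unbiased (n−2)-denominator
residual rate, while the reported log-likelihood is evaluated at the ML
(n-denominator) rate, consistent with the likelihoods used for AICc
elsewhere.

Replicated regressions pair replicate *i* with posterior tree *i*, cycling
through the sample. Cycling (rather than sampling with replacement) uses
every tree equally often and makes runs reproducible; the pairing is a
config choice. Replicates with fewer than four matched taxa are skipped
and logged rather than fitted.

Phylogenetic residuals (trait ~ body size under the same covariance) are
used for size correction, and the trade-off regression runs residuals on
residuals. By the Frisch–Waugh argument this recovers the multiple-GLS
coefficient when both stages share one covariance, which the
slope-recovery checks confirm.

## Brownian-motion machinery

Likelihoods use the pruning recursion (merge child distributions,
accumulate contrast terms), which equals dense multivariate-normal
evaluation to 1e-8 and is linear in tree size. σ² is ML (denominator n),
matching AICc comparisons; REML is not used anywhere. Polytomies are
resolved internally with zero-length branches, which leaves the
likelihood unchanged. Zero-length cherries make the covariance singular
and raise an explicit error.

The two competing trade-off hypotheses are simulated as: *no correlation*
— an independent BM draw with parameters fitted to the observed response;
*strong trade-off* — `y = −x + ε` with ε a BM draw at the observed
regression's residual rate and the observed intercept as root state.
This is one concrete reading of "a strong correlation (slope of −1)";
the predictor is held at its observed values, only the response is
simulated.

### Adequacy bootstrap

The parametric bootstrap computes four statistics on ML-standardized
independent contrasts: mean squared contrast, coefficient of variation of
absolute contrasts (rate heterogeneity), the slope of absolute contrast
against node depth (trends), and the Kolmogorov distance to a standard
normal. This is a four-statistic reduction of the six-statistic approach
used with comparative model-adequacy packages, covering the rate,
heterogeneity, trend, and normality axes at desk scale. Each simulated
dataset is re-fitted before its statistics are computed, making all four
statistics scale- and location-invariant and hence exchangeable between
observed and simulated data under the true model — the calibration the
acceptance test verifies. One consequence: the mean-squared-contrast
statistic is pivotal under the ML refit (its value is `n/(n−1)` up to
floating-point noise for any dataset), so it carries no power against
rate heterogeneity here and its p-value can only be conservative; the CV
statistic is the one that detects clade rate shifts. Bootstrap p-values
are two-sided with an add-one correction, `min(1, 2·min(p_lo, p_hi))`.

## Mk model and ancestral states

Fitting maximizes the pruning likelihood over log rates (L-BFGS-B, rate
bounds 1e-9 to 1e4, two starts by default) for ER, SYM, or ARD
structures. The default structure for reconstruction is ARD with AICc
comparison available against ER/SYM; hidden rate classes are not
implemented (a limitation: the cited reconstruction software supports
them, but the conclusions rest on the reconstruction itself). The root
prior is uniform by default with a stationary option; transition matrices
come from an eigendecomposition of Q memoized per branch length, with
scipy's scaling-and-squaring `expm` as the fallback for defective or
ill-conditioned Q, and rows renormalized at ~1e-12. The unique
Strepsiptera ovary type is a fourth state, not a polytrophic subtype.
Marginal reconstruction combines upward (subtree) and downward
(rest-of-tree) passes; the replicated protocol refits and reconstructs
over cycled posterior trees with one state record per taxon resampled per
replicate, summarizing MAP-state frequencies for clades of the summary
tree.

## Multi-regime models and regime classification

BMS profiles the root state and one overall scale analytically and
optimizes only the (R−1) log rate ratios — bounded scalar optimization
for two regimes, Nelder–Mead above. Its likelihood is identical to BM on
a tree with regime-scaled branch lengths, verified against dense
evaluation. OU1/OUM require ultrametric trees, share a single stationary
α across regimes (OUM varies only θ), and tie the root state to the
root-regime optimum; given α, the optima are GLS-profiled and σ² is
concentrated out, leaving a 1-D bounded search over log α. Parameter
counts: BM1 k=2, BMS k=#regimes+1, OU1 k=3, OUM k=2+#regimes. The
decision rule declares a winner only when its AICc advantage exceeds 2 in
every iteration.

Rate-regime classification takes per-branch rates (imported from a TSV or
taken from the generator's realized rates), thresholds them at 1e-4, and
labels each branch variable (≥ threshold; ties go to variable because
invariance is the stronger claim) or invariant. A node's regime is the
regime of its subtending branch. Origins of invariance are branches
painted invariant below a variable parent (an invariant root counts as
one origin at the root); reversals are the converse.

`greedy_shift_search` is a desk-scale stand-in for reversible-jump
rate-shift MCMC: starting from single-rate BM it repeatedly adds the
clade-rooted shift (clades of ≥5 tips) that most improves AICc, stopping
when the best improvement is ≤ the threshold (default 2, reusing the
decision rule). **Known limitation:** because each step takes the best of
many candidate clades, the ΔAICc>2 stop rule does not control the
false-shift rate at the nominal level — spurious shifts appear in roughly
15% (24 tips) to 40% (64 tips) of single-rate datasets, a standard
multiple-comparison effect of stepwise information-criterion searches.
Raising the stop threshold (e.g. to 8) suppresses this below 10% at the
cost of power for weak shifts; the tests verify that behaviour and the
recovery of a planted 100× shift. Recovered shift locations are
identified up to partition equivalence (painting a clade or its
complement yields the same two-regime model).

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
are not tuned per experiment.

* **Tree**: pure-birth (Yule) with birth rate 1.0; 128 tips gives a
  height of ~4.5 time units and total length of ~127. The posterior-like
  sample is the base tree plus clones with mean-one lognormal
  branch-length jitter (sd 0.05) and one nearest-neighbour interchange
  each — enough topological and length uncertainty to exercise the
  replicated protocols without destroying the signal.
* **Ovariole number** (log10): regime-switching BM, root state 1.08
  (~12 ovarioles), σ²_variable = 0.2, σ²_invariant = 0. The
  variable→invariant hazard is `q₀·exp(−γ·x)` with q₀ = 0.25, γ = 2.0
  (the exponential form is the simplest positive, single-parameter shape
  for a hazard that falls with the trait value); the reverse hazard is
  constant, q_IV = 0.05. On 128-tip trees these rates realize on average
  about eight independent origins of invariance, an occasional reversal,
  and an invariant minority of tips — the qualitative picture the
  analysis expects. Simulation is Euler-discretized (base step 0.02,
  shortened adaptively so hazard×step < 0.01, hard hazard cap 1e6)
  because the value-dependent hazard makes waiting times non-exponential;
  each branch is labelled with its majority-duration regime and its
  time-averaged diffusion rate.
* **Companion traits**: body size is BM (σ² = 0.2, root 0.5); egg size is
  `−1·ovariole + 1·body + ε` with ε BM at rate 0.02 — a built-in
  trade-off of slope −1 at the latent level.
* **Records**: per species 1+Poisson(1) records as single values, ranges,
  or mean±dev with multiplicative intraspecific noise at CV 0.1. The CV
  is the generator's one free calibration knob (real intraspecific
  distributions are unknown beyond the 10–100% percent-difference
  summary); 0.1 puts the median percent difference of variable species at
  ~15–20% while keeping end-to-end slope recovery within ±0.1 of the
  generating slope. Ovariole totals are built as left+right ovary
  counts — symmetric (even total) with probability 0.7, off-by-one (odd)
  otherwise — reproducing both the even-value enrichment and the fact
  that asymmetry yields odd totals. Invariant-lineage species get
  identical, even totals of at most 14 (no invariant lineage exceeds
  seven ovarioles per ovary) and zero intraspecific variation.
  Eusocial-worker (rate 0.03) and outlier (rate 0.005) records are
  injected to exercise the filters.
* **Oogenesis mode**: four-state ER Mk at per-pair rate 0.025 from a
  panoistic root — about nine realized transitions on a 128-tip tree,
  enough shifts to count while keeping the root state recoverable.
* **Taxonomy**: genus/family/order labels come from clade cuts at 75%,
  50%, and 25% of tree height, giving nested, monophyletic ranks.

What the generator does **not** emulate: taxonomic misspellings and
synonymy (matching is exact after normalization), non-Gaussian trait
evolution, fossil/extinct sampling, correlated sampling effort across
clades, and body-size allometry beyond a linear log-log relation.
Passing tests therefore demonstrate the correctness and calibration of
the machinery under the stated generative assumptions, not robustness to
every property of real literature data. One visible instance: record
noise and integer quantization attenuate the recovered trade-off slope
(≈ −0.93 aggregated, ≈ −0.78 under one-record reshuffling, against a
generating −1), exactly as measurement error should.

## Pipeline

Stages run in dependency order (simulate → tables → pgls → hypothesis →
asr → regimes → adequacy → report); each stochastic stage receives
`global seed + fixed stage offset`, logged. Outputs are TSV/JSON plus
annotated newick for paintings; the run log records versions and seeds
but no timestamps, so reruns with one config are hash-identical, and the
manifest lists SHA-256 hashes of every output except itself. The
pipeline's ancestral-state stage defaults to the ER structure (the
replicated ARD fit is available but slow at desk scale). Exit codes: 0
ok, 1 stage failure, 2 config error.

## Problem sizes used in checks

Oracle comparisons run on trees of ≤50 tips (dense-matrix GLS, Mk
enumeration on ≤5 tips); calibration and power experiments use 500
simulations (type-I error at R=1000 regressions, slope recovery at
n=128, estimator bias at n=256, adequacy at n=32 with 99 bootstrap
draws), and the two-regime selection experiments use 200 simulations on
~44-tip trees with ≥20 tips per regime. These sizes give Monte-Carlo
standard errors comfortably inside the asserted bands while keeping the
whole suite under a minute of compute.
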