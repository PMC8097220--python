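# ovarevo

Phylogenetic comparative analysis of insect ovariole-number evolution.

Insect ovaries are built from egg-producing tubes called ovarioles, and the
total ovariole count is a classic proxy for potential offspring number in
life-history theory, which predicts a trade-off between the number and the
size of offspring. `ovarevo` implements the full comparative toolkit needed
to test that prediction and to characterize how ovariole number itself
evolves: literature-style trait-record processing, phylogenetic
generalized least squares (PGLS) regression replicated over a posterior
sample of trees, trait simulation under competing evolutionary hypotheses,
Mk-model ancestral-state reconstruction of oogenesis mode (the
presence/position of nurse cells), multi-regime Brownian-motion model
comparison, and classification of tree branches into *variable* versus
*invariant* rate regimes. A first-class synthetic-data generator emulates
a compiled literature dataset — integer ovariole counts enriched for even
totals, intraspecific noise in the reported 10–100% percent-difference
band, log-scale traits coupled by a trade-off slope, and regime-switching
rate heterogeneity whose variable→invariant hazard decays with the current
trait value — so that every stage of the analysis is testable without any
download.

It is written for comparative biologists and methods developers: the
library (`src/ovarevo/`) exposes each analysis step as a tested function,
the numbered scripts under `analysis/` rerun the whole study on a
synthetic dataset, and a thin CLI (`ovarevo`) orchestrates the pipeline
from a YAML config.

## The models

**PGLS.** For traits `y`, `x` on `n` species related by a tree with branch
lengths in time, errors are modelled as multivariate normal with
covariance `σ² C`, where `C[i,j]` is the root-to-MRCA shared path length
(the Brownian-motion covariance). The GLS estimate is
`β̂ = (XᵀC⁻¹X)⁻¹ XᵀC⁻¹y` with `X = [1, x]`, and the slope is tested with a
two-sided t statistic on `n−2` degrees of freedom. Size correction uses
*phylogenetic residuals*: the trade-off regression is run on the residuals
of each trait's PGLS against body size, under the same `C`. On a star
phylogeny PGLS reduces exactly to ordinary least squares.

**Brownian motion.** `z(t)` diffuses at rate `σ²` per unit branch length
from root state `z₀`; the ML estimates are `ẑ₀ = (1ᵀC⁻¹x)/(1ᵀC⁻¹1)` and
`σ̂² = (x−ẑ₀)ᵀC⁻¹(x−ẑ₀)/n`. Likelihoods are computed in linear time by
Felsenstein's pruning algorithm and agree with the dense multivariate
normal to 1e-8.

**Mk model.** Oogenesis modes (panoistic, polytrophic meroistic,
telotrophic meroistic, and the unique Strepsiptera arrangement) evolve by
a continuous-time Markov chain with rate matrix `Q` (ER/SYM/ARD
structures), `P(t) = exp(Qt)`. Marginal ancestral states combine upward
and downward partial likelihoods at every node.

**Multi-regime models.** Given a *regime painting* (a label on every
branch), `BMS` gives each regime its own Brownian rate — equivalent to BM
on a tree whose branch lengths are scaled per regime — and `OU1`/`OUM`
fit Ornstein–Uhlenbeck models with a shared pull `α` and one or
per-regime optima `θ`. Models are ranked by
`AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1)`, and a model is declared
significantly better only when its AICc advantage exceeds 2 in **every**
analysis iteration. Branches whose evolutionary rate falls below `10⁻⁴`
are classified *invariant*, and independent origins of invariance and
reversals are counted from parent–child regime changes.

## Worked example

Run the study on a synthetic 128-species dataset (scripts must run in
order; together they take about a minute):

```sh
cd analysis
python 01_make_dataset.py
python 03_tradeoff_pgls.py
python 06_rate_regimes.py
```

Output from an actual run:

```
dataset bundle written to results/run/bundle/
generating truth: 5 origins of invariance, 0 reversals, root regime variable, 9 regime-switch events

200 of 200 replicated regressions significant at alpha=0.01 (median slope -0.776; generating slope -1)

invariance evolved 6 times independently, with 1 reversals (threshold 0.0001)
model comparison winner: BMS (multi-rate BM beats single-rate by dAICc 920.3)
invariant-regime tips have lower log10 ovariole number by 0.22 (permutation p=0.0004, 41 invariant vs 87 variable tips)
```

Reading the numbers: every one of the 200 posterior-replicated
residual-PGLS regressions detects the egg-size/ovariole-number trade-off
built into the generator (median slope −0.776; record-level measurement
noise attenuates the generating slope of −1). Thresholding the realized
branch rates recovers a history in which invariant ovariole numbers arose
repeatedly and occasionally reverted (6 origins and 1 reversal counted on
the classified painting, against 5 origins in the generating truth — a
late switch inside a branch can register as an extra origin), a multi-rate
Brownian model outperforms a single-rate model by a ΔAICc of ~920, and
tips in the invariant regime carry significantly fewer ovarioles —
mirroring the value-dependent switching hazard that generated the data.
`04_hypothesis_tests.py` places the observed slope outside the
no-correlation simulations and inside the slope −1 envelope;
`05_oogenesis_asr.py` reconstructs the panoistic root state;
`07_model_adequacy.py` shows the contrast-based bootstrap rejecting the
single-rate BM fit once regime structure is present.

The same stages are available as CLI subcommands, e.g.

```sh
ovarevo all --outdir run --seed 1
ovarevo make-dataset --outdir run --seed 1
```

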