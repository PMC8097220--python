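"""Brownian-motion trait models: fitting, simulation, hypothesis studies,
and a parametric-bootstrap model-adequacy check.

Under Brownian motion a continuous trait diffuses along the tree at rate
``sigma2`` per unit branch length from a root state ``z0``; tip values are
jointly normal with covariance ``sigma2 * C`` (C the shared-path matrix).
The likelihood is evaluated in linear time by Felsenstein's pruning
(recursive merging of child distributions), which equals the dense
multivariate-normal evaluation.

The hypothesis study mirrors the false-positive / false-negative assessment
of a trade-off regression: simulate the response trait many times under
(i) no evolutionary correlation with the predictor and (ii) a strong
correlation (slope of -1 on the log-log scale), refit the regression to
each simulated dataset, and locate the observed slope within the two
simulated distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .pgls import pgls_fit
from .trees import CovarianceMatrix, Phylogeny, phylo_covariance

__all__ = [
    "BMError",
    "BMParams",
    "HypothesisStudy",
    "HYPOTHESES",
    "aicc",
    "fit_bm",
    "fit_bm_tree",
    "bm_loglik_tree",
    "pic_decompose",
    "simulate_bm",
    "simulate_under_hypothesis",
    "hypothesis_study",
    "adequacy_bootstrap",
]

HYPOTHESES = ("null_slope_0", "strong_slope_-1")


class BMError(ValueError):
    """Raised for degenerate Brownian-motion fits or inputs."""


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample-corrected AIC: -2*logLik + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise BMError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class BMParams:
    """ML Brownian-motion parameters for one trait on one tree."""

    sigma2: float  # rate per unit branch length (ML, denominator n)
    z0: float  # root state
    loglik: float
    n: int
    k: int = 2

    @property
    def aicc(self) -> float:
        return aicc(self.loglik, self.k, self.n)


def fit_bm(x, C: CovarianceMatrix) -> BMParams:
    """Closed-form ML fit: z0 is the GLS mean, sigma2 the ML rate.

    ``z0 = (1'C^-1 x)/(1'C^-1 1)``; ``sigma2 = (x-z0)'C^-1(x-z0)/n``.
    A constant trait gives a zero rate and a degenerate (infinite-density)
    likelihood, reported as an error.
    """
    x = np.asarray(x, dtype=float)
    n = C.n
    if x.shape != (n,):
        raise BMError(f"x must align with the {n} covariance tips")
    if n < 2:
        raise BMError("need at least 2 tips")
    try:
        L = linalg.cholesky(C.matrix, lower=True)
    except linalg.LinAlgError as exc:
        raise BMError(f"singular covariance: {exc}") from exc
    ones = np.ones(n)
    xw = linalg.solve_triangular(L, x, lower=True)
    ow = linalg.solve_triangular(L, ones, lower=True)
    z0 = float(ow @ xw / (ow @ ow))
    rw = xw - z0 * ow
    sigma2 = float(rw @ rw) / n
    if sigma2 <= 0:
        raise BMError("degenerate fit: trait has zero phylogenetic variance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return BMParams(sigma2=sigma2, z0=z0, loglik=float(loglik), n=n)


def pic_decompose(tree: Phylogeny, x: np.ndarray):
    """Felsenstein's pruning pass for a continuous trait.

    Returns ``(d, v, node_depth, mu_root, v_root)`` where ``d[k]`` are raw
    contrasts with variances ``v[k]`` (times sigma2), and ``node_depth[k]``
    the root-to-node depth at which contrast k was taken.  Polytomies are
    merged pairwise in child order, equivalent to a zero-length resolution.
    The unit-rate log-likelihood follows from these terms exactly.
    """
    x = np.asarray(x, dtype=float)
    tips = tree.tips
    if x.shape != (len(tips),):
        raise BMError("x must align with tree.tip_labels")
    depths = tree.depths()
    xs = {t.index: x[i] for i, t in enumerate(tips)}
    mu: dict[int, float] = {}
    vv: dict[int, float] = {}
    d_list, v_list, h_list = [], [], []
    for node in tree.postorder():
        if node.is_tip:
            mu[node.index] = xs[node.index]
            vv[node.index] = node.length or 0.0
            continue
        children = node.children
        m1, v1 = mu[children[0].index], vv[children[0].index]
        for child in children[1:]:
            m2, v2 = mu[child.index], vv[child.index]
            vsum = v1 + v2
            if vsum <= 0:
                raise BMError(
                    "zero-length cherry makes the covariance singular "
                    f"(node at depth {depths[node.index]:.6g})"
                )
            d_list.append(m1 - m2)
            v_list.append(vsum)
            h_list.append(depths[node.index])
            m1 = (m1 * v2 + m2 * v1) / vsum
            v1 = v1 * v2 / vsum
        mu[node.index] = m1
        vv[node.index] = v1 + (node.length or 0.0)
    root_i = tree.root.index
    return (
        np.asarray(d_list),
        np.asarray(v_list),
        np.asarray(h_list),
        mu[root_i],
        vv[root_i] - (tree.root.length or 0.0),
    )


def bm_loglik_tree(tree: Phylogeny, x, sigma2: float, z0: float) -> float:
    """Exact BM log-likelihood via pruning (linear time, no dense matrix)."""
    if sigma2 <= 0:
        raise BMError("sigma2 must be positive")
    d, v, _, mu_root, v_root = pic_decompose(tree, np.asarray(x, dtype=float))
    n = len(d) + 1
    quad = float(np.sum(d * d / v))
    sum_log_v = float(np.sum(np.log(v)))
    if v_root > 0:
        quad += (mu_root - z0) ** 2 / v_root
        sum_log_v += np.log(v_root)
        terms = n
    else:
        if abs(mu_root - z0) > 1e-12:
            return -np.inf
        terms = n - 1
    return -0.5 * (terms * np.log(2 * np.pi * sigma2) + sum_log_v + quad / sigma2)


def fit_bm_tree(tree: Phylogeny, x) -> BMParams:
    """ML BM fit via pruning; equals :func:`fit_bm` with the dense covariance."""
    d, v, _, mu_root, v_root = pic_decompose(tree, np.asarray(x, dtype=float))
    n = len(d) + 1
    quad = float(np.sum(d * d / v))
    if quad <= 0:
        raise BMError("degenerate fit: trait has zero phylogenetic variance")
    sigma2 = quad / n
    loglik = bm_loglik_tree(tree, x, sigma2, mu_root)
    return BMParams(sigma2=sigma2, z0=float(mu_root), loglik=float(loglik), n=n)


def simulate_bm(
    tree: Phylogeny,
    sigma2: float,
    z0: float,
    seed: int | np.random.Generator = 0,
    reps: int | None = None,
) -> np.ndarray:
    """Draw tip values by accumulating independent branch increments.

    Returns shape ``(n_tips,)`` aligned with ``tree.tip_labels`` (or
    ``(reps, n_tips)`` when ``reps`` is given).  Bit-reproducible per seed.
    """
    if sigma2 < 0:
        raise BMError("sigma2 must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = 1 if reps is None else reps
    n_nodes = len(tree.nodes)
    values = np.zeros((r, n_nodes))
    incr = rng.standard_normal((r, n_nodes))
    for node in tree.nodes:
        if node.is_root:
            values[:, node.index] = z0
        else:
            sd = np.sqrt(sigma2 * node.length)
            values[:, node.index] = values[:, node.parent.index] + sd * incr[:, node.index]
    tip_idx = [t.index for t in tree.tips]
    out = values[:, tip_idx]
    return out[0] if reps is None else out


def simulate_under_hypothesis(
    tree: Phylogeny,
    x_obs,
    hypothesis: str,
    fitted: BMParams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Simulate the response trait under a competing evolutionary hypothesis.

    ``null_slope_0``: an independent BM draw with the parameters fitted to
    the observed response.  ``strong_slope_-1``: ``y = -x_obs`` plus a BM
    residual draw whose rate is the observed regression's residual rate
    (``fitted.sigma2``) and whose root state is the observed intercept
    (``fitted.z0``).
    """
    if hypothesis not in HYPOTHESES:
        raise BMError(f"unknown hypothesis {hypothesis!r}; expected one of {HYPOTHESES}")
    x_obs = np.asarray(x_obs, dtype=float)
    noise = simulate_bm(tree, fitted.sigma2, fitted.z0, seed)
    if hypothesis == "null_slope_0":
        return noise
    return -1.0 * x_obs + noise


@dataclass
class HypothesisStudy:
    """Simulated slope/p distributions under one hypothesis, with the observed fit."""

    hypothesis: str
    slopes: np.ndarray
    pvalues: np.ndarray
    observed_slope: float
    observed_pvalue: float

    @property
    def n_sim(self) -> int:
        return len(self.slopes)

    @property
    def observed_quantile(self) -> float:
        """Fraction of simulated slopes at or below the observed slope."""
        return float(np.mean(self.slopes <= self.observed_slope))

    def observed_in_central(self, level: float = 0.95) -> bool:
        lo, hi = np.quantile(self.slopes, [(1 - level) / 2, 1 - (1 - level) / 2])
        return bool(lo <= self.observed_slope <= hi)


def hypothesis_study(
    tree: Phylogeny,
    x,
    y,
    S: int = 1000,
    seed: int | np.random.Generator = 0,
) -> dict[str, HypothesisStudy]:
    """False-positive / false-negative study for the trade-off regression.

    Fits the observed PGLS of y on x, then simulates y S times under each
    hypothesis (no correlation; strong slope -1), refitting the PGLS each
    time.  The predictor is held at its observed values throughout.
    """
    if S < 1:
        raise BMError("S must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = phylo_covariance(tree)
    obs = pgls_fit(x, y, C)
    null_params = fit_bm(y, C)
    strong_params = BMParams(
        sigma2=obs.sigma2, z0=obs.intercept, loglik=np.nan, n=obs.n
    )
    out = {}
    for hyp, params in (("null_slope_0", null_params), ("strong_slope_-1", strong_params)):
        slopes = np.empty(S)
        pvals = np.empty(S)
        for s in range(S):
            y_sim = simulate_under_hypothesis(tree, x, hyp, params, rng)
            fit = pgls_fit(x, y_sim, C)
            slopes[s] = fit.slope
            pvals[s] = fit.pvalue
        out[hyp] = HypothesisStudy(
            hypothesis=hyp,
            slopes=slopes,
            pvalues=pvals,
            observed_slope=obs.slope,
            observed_pvalue=obs.pvalue,
        )
    return out


# ---------------------------------------------------------------------------
# parametric-bootstrap adequacy
# ---------------------------------------------------------------------------

ADEQUACY_STATS = ("mean_sq_contrast", "cv_abs_contrast", "height_slope", "ks_normal")


def _contrast_stats(tree: Phylogeny, x: np.ndarray) -> dict[str, float]:
    """The four adequacy statistics on ML-standardized independent contrasts.

    Contrasts are standardized with the ML rate refit to the dataset at
    hand, so every statistic is invariant to the trait's scale and location
    and observed/simulated datasets are directly comparable.
    """
    d, v, h, mu_root, v_root = pic_decompose(tree, x)
    n = len(d) + 1
    quad = float(np.sum(d * d / v))
    if v_root > 0:
        quad_full = quad + 0.0  # root term vanishes at the ML root state
    else:
        quad_full = quad
    sigma2 = quad_full / n
    if sigma2 <= 0:
        raise BMError("constant trait: contrasts are all zero")
    u = d / np.sqrt(sigma2 * v)
    au = np.abs(u)
    mean_au = float(np.mean(au))
    cv = float(np.std(au, ddof=1) / mean_au) if mean_au > 0 else 0.0
    if np.ptp(h) > 0:
        slope = float(np.polyfit(h, au, 1)[0])
    else:
        slope = 0.0
    us = np.sort(u)
    grid = (np.arange(1, len(us) + 1)) / len(us)
    cdf = stats.norm.cdf(us)
    ks = float(np.max(np.maximum(np.abs(grid - cdf), np.abs(grid - 1.0 / len(us) - cdf))))
    return {
        "mean_sq_contrast": float(np.mean(u * u)),
        "cv_abs_contrast": cv,
        "height_slope": slope,
        "ks_normal": ks,
    }


def adequacy_bootstrap(
    tree: Phylogeny,
    x,
    fitted: BMParams | None = None,
    n_sim: int = 100,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Parametric-bootstrap adequacy of a BM fit, arbutus style (reduced).

    Computes four test statistics on the standardized independent contrasts
    of the observed data (mean squared contrast; coefficient of variation
    of absolute contrasts; slope of absolute contrast against node height;
    Kolmogorov distance of contrasts to a standard normal), simulates
    ``n_sim`` datasets under the fitted model, recomputes the statistics on
    each (refitting the rate), and returns a two-sided bootstrap p-value
    per statistic.
    """
    if n_sim <= 0:
        raise BMError("n_sim must be positive")
    if n_sim < 20:
        warnings.warn(f"n_sim={n_sim} gives coarse bootstrap p-values", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    work = tree.resolve_polytomies()
    if fitted is None:
        fitted = fit_bm_tree(work, x)
    obs = _contrast_stats(work, x)
    sims = simulate_bm(work, fitted.sigma2, fitted.z0, rng, reps=n_sim)
    sim_stats = {k: np.empty(n_sim) for k in ADEQUACY_STATS}
    for s in range(n_sim):
        st = _contrast_stats(work, sims[s])
        for k in ADEQUACY_STATS:
            sim_stats[k][s] = st[k]
    pvals = {}
    for k in ADEQUACY_STATS:
        lo = (1 + np.sum(sim_stats[k] <= obs[k])) / (1 + n_sim)
        hi = (1 + np.sum(sim_stats[k] >= obs[k])) / (1 + n_sim)
        pvals[k] = float(min(1.0, 2.0 * min(lo, hi)))
    return pvals
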