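"""Phylogenetic generalized least squares under Brownian-motion covariance.

PGLS regresses one trait on another while modelling the error covariance as
proportional to shared branch lengths: ``y = a + b*x + e`` with
``e ~ N(0, sigma2 * C)`` where ``C[i,j]`` is the root-to-MRCA path length of
tips i and j.  On a star phylogeny C is diagonal and PGLS reduces to
ordinary least squares.

Also provided: phylogenetic residuals (size correction before a trade-off
regression), and the replicated protocol that reruns a regression over a
posterior sample of trees while resampling trait records, counting how many
replicates are significant at a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .records import aggregate_by_rank, resample_records
from .trees import CovarianceMatrix, TreeSample, phylo_covariance, prune_and_match

__all__ = [
    "PGLSError",
    "PGLSFit",
    "ReplicateSummary",
    "pgls_fit",
    "phylogenetic_residuals",
    "residual_pgls",
    "replicate_pgls",
]


class PGLSError(ValueError):
    """Raised for degenerate PGLS inputs (singular covariance, constant x, n too small)."""


@dataclass
class PGLSFit:
    """A fitted PGLS regression of y on x."""

    slope: float
    intercept: float
    sigma2: float  # residual rate per unit branch length, (n-2) denominator
    loglik: float  # multivariate-normal log-likelihood at the ML residual rate
    pvalue: float  # two-sided t test of slope = 0, n-2 df
    n: int
    slope_se: float
    residuals: np.ndarray = field(repr=False)

    @property
    def df(self) -> int:
        return self.n - 2


@dataclass
class ReplicateSummary:
    """Outcome of a regression repeated over trees and resampled records."""

    slopes: np.ndarray
    pvalues: np.ndarray
    alpha: float
    n_skipped: int = 0
    skipped_reasons: list[str] = field(default_factory=list)

    @property
    def n_replicates(self) -> int:
        return len(self.slopes)

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.pvalues < self.alpha))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(self.n_replicates),
                "slope": self.slopes,
                "pvalue": self.pvalues,
                "significant": self.pvalues < self.alpha,
            }
        )


def _prepare(x, y, C: CovarianceMatrix):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = C.n
    if x.shape != (n,) or y.shape != (n,):
        raise PGLSError(f"x, y must align with the {n} covariance tips")
    try:
        L = linalg.cholesky(C.matrix, lower=True)
    except linalg.LinAlgError as exc:
        raise PGLSError(f"covariance is not positive definite: {exc}") from exc
    return x, y, L, n


def pgls_fit(x, y, C: CovarianceMatrix) -> PGLSFit:
    """GLS estimate of y = a + b*x + e, e ~ N(0, sigma2*C).

    The p-value is a two-sided t test with n-2 degrees of freedom on
    slope/SE(slope); the log-likelihood is evaluated at the ML residual
    rate (denominator n), while ``sigma2`` uses the unbiased n-2 form.
    """
    x, y, L, n = _prepare(x, y, C)
    if n < 4:
        raise PGLSError(f"need at least 4 taxa for a PGLS fit, got {n}")
    if np.ptp(x) == 0:
        raise PGLSError("predictor x is constant")
    X = np.column_stack([np.ones(n), x])
    # whiten: L^-1 X, L^-1 y
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    XtX = Xw.T @ Xw
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid = y - X @ beta
    rw = yw - Xw @ beta
    quad = float(rw @ rw)
    sigma2 = quad / (n - 2)
    sigma2_ml = quad / n
    cov_beta = sigma2 * linalg.inv(XtX)
    se = float(np.sqrt(cov_beta[1, 1]))
    if se == 0:
        pvalue = 0.0 if beta[1] != 0 else 1.0
    else:
        tstat = beta[1] / se
        pvalue = float(2 * stats.t.sf(abs(tstat), df=n - 2))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if sigma2_ml > 0:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    else:
        loglik = np.inf  # perfect fit: density degenerates
    return PGLSFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        sigma2=float(sigma2),
        loglik=float(loglik),
        pvalue=pvalue,
        n=n,
        slope_se=se,
        residuals=resid,
    )


def phylogenetic_residuals(trait, size, C: CovarianceMatrix) -> np.ndarray:
    """Residuals of the PGLS of ``trait`` on body ``size``.

    The residuals have GLS-weighted mean zero (1' C^-1 r = 0) and are the
    standard way to compare traits while accounting for body size.
    """
    fit = pgls_fit(size, trait, C)
    return fit.residuals


def residual_pgls(trait_a, trait_b, size, C: CovarianceMatrix) -> PGLSFit:
    """PGLS of residuals(trait_a ~ size) on residuals(trait_b ~ size)."""
    ra = phylogenetic_residuals(trait_a, size, C)
    rb = phylogenetic_residuals(trait_b, size, C)
    return pgls_fit(rb, ra, C)


def replicate_pgls(
    records_y: pd.DataFrame,
    records_x: pd.DataFrame,
    trees: TreeSample,
    R: int = 1000,
    alpha: float = 0.01,
    mode: str = "reshuffle",
    rank: str = "species",
    seed: int | np.random.Generator = 0,
    records_size: pd.DataFrame | None = None,
    trait_y: str | None = None,
    trait_x: str | None = None,
    trait_size: str | None = None,
) -> ReplicateSummary:
    """Repeat a (residual-)PGLS over a posterior sample with record resampling.

    Replicate i uses posterior tree i (cycled through the sample), resamples
    the record tables per ``mode`` (one record per taxon for species/genus
    analyses, per-family downsampling by half for family-level ones),
    aggregates to ``rank`` on the log10 scale, prunes the tree to the shared
    taxa, and fits y ~ x (or, when ``records_size`` is given, the PGLS of
    the two traits' phylogenetic residuals to body size).  Replicates with
    fewer than 4 matched taxa are skipped and logged.
    """
    if R < 1:
        raise PGLSError("R must be >= 1")
    if not 0 < alpha < 1:
        raise PGLSError("alpha must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    trait_y = trait_y or records_y["trait"].iloc[0]
    trait_x = trait_x or records_x["trait"].iloc[0]
    if records_size is not None:
        trait_size = trait_size or records_size["trait"].iloc[0]
    slopes, pvalues, skipped = [], [], []
    for i in range(R):
        tree = trees.cycled(i)
        tables = {"y": resample_records(records_y, mode, rank, rng),
                  "x": resample_records(records_x, mode, rank, rng)}
        if records_size is not None:
            tables["size"] = resample_records(records_size, mode, rank, rng)
        traits = {"y": trait_y, "x": trait_x, "size": trait_size}
        aggs = {}
        for key, tab in tables.items():
            agg, _ = aggregate_by_rank(tab, rank, traits[key])
            aggs[key] = agg.set_index("taxon")["log10_value"]
        taxa = set(tree.tip_labels)
        for s in aggs.values():
            taxa &= set(s.index)
        taxa = sorted(taxa)
        if len(taxa) < 4:
            skipped.append(f"replicate {i}: only {len(taxa)} matched taxa")
            continue
        sub = prune_and_match(tree, taxa)
        C = phylo_covariance(sub, taxa)
        try:
            if records_size is not None:
                fit = residual_pgls(
                    aggs["y"].loc[taxa].to_numpy(),
                    aggs["x"].loc[taxa].to_numpy(),
                    aggs["size"].loc[taxa].to_numpy(),
                    C,
                )
            else:
                fit = pgls_fit(aggs["x"].loc[taxa].to_numpy(), aggs["y"].loc[taxa].to_numpy(), C)
        except PGLSError as exc:
            skipped.append(f"replicate {i}: {exc}")
            continue
        slopes.append(fit.slope)
        pvalues.append(fit.pvalue)
    return ReplicateSummary(
        slopes=np.asarray(slopes),
        pvalues=np.asarray(pvalues),
        alpha=alpha,
        n_skipped=len(skipped),
        skipped_reasons=skipped,
    )
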