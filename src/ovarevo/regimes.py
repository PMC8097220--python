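"""Multi-regime trait-evolution models on painted trees.

A regime painting assigns a discrete label to every branch (keyed by the
child node's index).  Models:

``BM1``
    single-rate Brownian motion (the painting is ignored); k = 2.
``BMS``
    per-regime Brownian rates, equivalent to BM on a tree whose branch
    lengths are scaled by their regime's rate; k = #regimes + 1.
``OU1`` / ``OUM``
    Ornstein-Uhlenbeck with a single stationary pull ``alpha`` shared
    across regimes and one optimum (OU1, k = 3) or one optimum per regime
    (OUM, k = 2 + #regimes), on ultrametric trees, with the root state tied
    to the root regime's optimum.

Model comparison follows the AICc rule used for replicated analyses: a
model is declared significantly better only when its AICc advantage
exceeds two in every analysis iteration.

Also here: the binary variable/invariant rate-regime classification at a
rate threshold, counting of independent origins of invariance and
reversals, a greedy clade-rooted shift search (a desk-scale stand-in for
reversible-jump rate-shift MCMC), and the permutation comparison of trait
values between regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .brownian import BMError, aicc as _aicc, fit_bm
from .trees import CovarianceMatrix, Node, Phylogeny, phylo_covariance

__all__ = [
    "RegimeError",
    "ModelFit",
    "REGIME_MODELS",
    "VARIABLE",
    "INVARIANT",
    "RATE_THRESHOLD",
    "branch_painting",
    "fit_regime_model",
    "compare_models",
    "classify_rate_regimes",
    "count_regime_origins",
    "greedy_shift_search",
    "rate_state_correlation",
]

REGIME_MODELS = ("BM1", "BMS", "OU1", "OUM")
VARIABLE = "variable"
INVARIANT = "invariant"
RATE_THRESHOLD = 1e-4  # separates the two peaks of branch-rate estimates


class RegimeError(ValueError):
    """Raised for invalid paintings, model names, or undefined AICc."""


@dataclass
class ModelFit:
    """A fitted trait-evolution model with its AICc."""

    model: str
    params: dict[str, float]
    loglik: float
    k: int
    n: int

    @property
    def aicc(self) -> float:
        return _aicc(self.loglik, self.k, self.n)


def _check_painting(tree: Phylogeny, painting: Mapping[int, str]) -> list[str]:
    missing = [n.index for n in tree.nodes if not n.is_root and n.index not in painting]
    if missing:
        raise RegimeError(f"painting missing branches (node indices {missing[:5]}...)")
    return sorted({painting[n.index] for n in tree.nodes if not n.is_root})


def branch_painting(tree: Phylogeny, label: str) -> dict[int, str]:
    """A uniform painting of every branch with one label."""
    return {n.index: label for n in tree.nodes if not n.is_root}


def _regime_covariances(tree: Phylogeny, painting: Mapping[int, str], regimes: list[str]):
    """Per-regime shared-path matrices: C = sum_r sigma2_r * C_r."""
    tips = tree.tips
    order = {t.index: k for k, t in enumerate(tips)}
    n = len(tips)
    masks = np.zeros((len(tree.nodes), n), dtype=bool)
    for node in tree.postorder():
        if node.is_tip:
            masks[node.index, order[node.index]] = True
        if node.parent is not None:
            masks[node.parent.index] |= masks[node.index]
    Cr = {r: np.zeros((n, n)) for r in regimes}
    for node in tree.nodes:
        if node.is_root or not node.length:
            continue
        m = masks[node.index]
        Cr[painting[node.index]][np.ix_(m, m)] += node.length
    return Cr


def _gls_profile(C: np.ndarray, x: np.ndarray):
    """Profile z0 and the overall scale out of a BM-type likelihood.

    For x ~ N(z0*1, s*C): returns (z0_hat, s_hat, profile loglik).
    """
    n = len(x)
    L = linalg.cholesky(C, lower=True)
    ones = np.ones(n)
    xw = linalg.solve_triangular(L, x, lower=True)
    ow = linalg.solve_triangular(L, ones, lower=True)
    z0 = float(ow @ xw / (ow @ ow))
    rw = xw - z0 * ow
    s = float(rw @ rw) / n
    if s <= 0:
        raise BMError("degenerate fit: zero residual variance")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * np.log(2 * np.pi * s) + logdet + n)
    return z0, s, ll


def _fit_bms(tree: Phylogeny, x: np.ndarray, painting: Mapping[int, str]) -> ModelFit:
    regimes = _check_painting(tree, painting)
    n = len(x)
    Cr = _regime_covariances(tree, painting, regimes)
    mats = [Cr[r] for r in regimes]
    R = len(regimes)

    def assemble(log_ratios: np.ndarray) -> np.ndarray:
        ratios = np.concatenate([[1.0], np.exp(np.clip(log_ratios, -30.0, 30.0))])
        return sum(rho * M for rho, M in zip(ratios, mats))

    def neg_profile(log_ratios: np.ndarray) -> float:
        try:
            return -_gls_profile(assemble(np.atleast_1d(log_ratios)), x)[2]
        except (linalg.LinAlgError, BMError):
            return 1e12

    if R == 1:
        log_ratios = np.zeros(0)
    elif R == 2:
        res = optimize.minimize_scalar(
            lambda t: neg_profile(np.array([t])), bounds=(-25.0, 25.0), method="bounded",
            options={"xatol": 1e-8},
        )
        log_ratios = np.array([res.x])
    else:
        res = optimize.minimize(
            neg_profile, np.zeros(R - 1), method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        log_ratios = res.x
    C = assemble(log_ratios)
    z0, s, ll = _gls_profile(C, x)
    ratios = np.concatenate([[1.0], np.exp(log_ratios)])
    params = {"z0": z0}
    for r, rho in zip(regimes, ratios):
        params[f"sigma2_{r}"] = s * rho
    k = R + 1
    if n - k - 1 <= 0:
        raise RegimeError(f"AICc undefined: n={n}, k={k}")
    return ModelFit("BMS", params, float(ll), k, n)


def _ou_design(tree: Phylogeny, painting: Mapping[int, str], regimes: list[str], alpha: float):
    """OU mean weights and unit-rate covariance on an ultrametric painted tree."""
    tips = tree.tips
    n = len(tips)
    depths = tree.depths()
    T = tree.height
    idx = {r: j for j, r in enumerate(regimes)}
    W = np.zeros((n, len(regimes)))
    root_regime = painting.get(tree.root.index)
    for i, tip in enumerate(tips):
        node = tip
        path = []
        while node.parent is not None:
            path.append(node)
            node = node.parent
        for seg in path:  # tip -> root order
            t2 = depths[seg.index]
            t1 = depths[seg.parent.index]
            w = np.exp(-alpha * (T - t2)) - np.exp(-alpha * (T - t1))
            W[i, idx[painting[seg.index]]] += w
        # root state tied to the root regime's optimum
        rr = root_regime if root_regime is not None else painting[path[-1].index]
        W[i, idx[rr]] += np.exp(-alpha * T)
    # covariance: V0_ij = exp(-2 alpha (T - t_mrca)) * (1 - exp(-2 alpha t_mrca)) / (2 alpha)
    Cbm = phylo_covariance(tree).matrix  # t_mrca entries
    t_mrca = Cbm
    V0 = np.exp(-2 * alpha * (T - t_mrca)) * (1.0 - np.exp(-2 * alpha * t_mrca)) / (2 * alpha)
    return W, V0


def _fit_ou(tree: Phylogeny, x: np.ndarray, painting: Mapping[int, str], multi: bool,
            ultrametric_tol: float = 1e-6) -> ModelFit:
    if not tree.is_ultrametric(tol=ultrametric_tol):
        raise RegimeError("OU models require an ultrametric tree")
    if multi:
        regimes = _check_painting(tree, painting)
    else:
        regimes = ["all"]
        painting = branch_painting(tree, "all") | {tree.root.index: "all"}
    n = len(x)
    height = tree.height

    def profile(log_alpha: float):
        alpha = float(np.exp(log_alpha))
        W, V0 = _ou_design(tree, painting, regimes, alpha)
        L = linalg.cholesky(V0, lower=True)
        Ww = linalg.solve_triangular(L, W, lower=True)
        xw = linalg.solve_triangular(L, x, lower=True)
        theta, *_ = np.linalg.lstsq(Ww, xw, rcond=None)
        rw = xw - Ww @ theta
        s = float(rw @ rw) / n
        if s <= 0:
            raise BMError("degenerate OU fit")
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        ll = -0.5 * (n * np.log(2 * np.pi * s) + logdet + n)
        return ll, alpha, theta, s

    lo, hi = np.log(1e-9 / height), np.log(50.0 / height)
    res = optimize.minimize_scalar(
        lambda la: -profile(la)[0], bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8},
    )
    ll, alpha, theta, s = profile(res.x)
    params = {"alpha": alpha, "sigma2": s}
    if multi:
        for r, th in zip(regimes, theta):
            params[f"theta_{r}"] = float(th)
        k = 2 + len(regimes)
        name = "OUM"
    else:
        params["theta"] = float(theta[0])
        k = 3
        name = "OU1"
    if n - k - 1 <= 0:
        raise RegimeError(f"AICc undefined: n={n}, k={k}")
    return ModelFit(name, params, float(ll), k, n)


def fit_regime_model(
    tree: Phylogeny,
    x,
    painting: Mapping[int, str] | None = None,
    model: str = "BM1",
) -> ModelFit:
    """Fit one of BM1 / BMS / OU1 / OUM to tip values on a painted tree.

    ``x`` aligns with ``tree.tip_labels``.  BM1 ignores the painting; BMS
    and OUM require one.  OU models require an ultrametric tree.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (tree.n_tips,):
        raise RegimeError("x must align with tree.tip_labels")
    if model not in REGIME_MODELS:
        raise RegimeError(f"unknown model {model!r}; expected one of {REGIME_MODELS}")
    n = tree.n_tips
    if model == "BM1":
        bm = fit_bm(x, phylo_covariance(tree))
        if n - 3 <= 0:
            raise RegimeError(f"AICc undefined: n={n}, k=2")
        return ModelFit("BM1", {"sigma2": bm.sigma2, "z0": bm.z0}, bm.loglik, 2, n)
    if model == "OU1":
        return _fit_ou(tree, x, {}, multi=False)
    if painting is None:
        raise RegimeError(f"{model} requires a regime painting")
    if model == "BMS":
        return _fit_bms(tree, x, painting)
    return _fit_ou(tree, x, painting, multi=True)


def compare_models(
    iterations: Sequence[Sequence[ModelFit]], delta: float = 2.0
) -> tuple[pd.DataFrame, str | None]:
    """Apply the every-iteration AICc rule across analysis iterations.

    Each iteration is a list of ModelFits of the same data.  Returns a
    per-iteration table (model, AICc, dAICc vs the iteration's best, winner
    flag) and the name of the model whose advantage over every rival
    exceeds ``delta`` in every iteration, or None if no model qualifies.
    """
    if not iterations or any(len(fits) == 0 for fits in iterations):
        raise RegimeError("model comparison needs at least one non-empty iteration")
    rows = []
    per_iter_winner: list[str | None] = []
    for i, fits in enumerate(iterations):
        aiccs = {f.model: f.aicc for f in fits}
        best = min(aiccs, key=aiccs.get)
        second = min((v for m, v in aiccs.items() if m != best), default=np.inf)
        winner = best if second - aiccs[best] > delta else None
        per_iter_winner.append(winner)
        for f in fits:
            rows.append(
                {
                    "iteration": i,
                    "model": f.model,
                    "loglik": f.loglik,
                    "k": f.k,
                    "aicc": f.aicc,
                    "delta_aicc": f.aicc - aiccs[best],
                    "winner": f.model == winner,
                }
            )
    table = pd.DataFrame(rows)
    first = per_iter_winner[0]
    decision = first if first is not None and all(w == first for w in per_iter_winner) else None
    return table, decision


def classify_rate_regimes(
    branch_rates: Mapping, threshold: float = RATE_THRESHOLD
) -> dict:
    """Binary variable/invariant painting from per-branch evolutionary rates.

    A branch with rate >= threshold is ``variable``, below it ``invariant``
    (ties go to variable: invariance is the stronger claim).
    """
    out = {}
    for key, rate in branch_rates.items():
        if rate is None or (isinstance(rate, float) and np.isnan(rate)):
            raise RegimeError(f"missing rate for branch {key!r}")
        if rate < 0:
            raise RegimeError(f"negative rate for branch {key!r}")
        out[key] = VARIABLE if rate >= threshold else INVARIANT
    return out


def count_regime_origins(
    tree: Phylogeny,
    painting: Mapping[int, str],
    root_state: str = VARIABLE,
) -> tuple[int, int]:
    """Count independent origins of invariance and reversals to variability.

    An origin is a branch painted invariant whose parent branch (or the
    root state, for children of the root) is variable; a reversal is the
    converse.  An invariant root state counts as one origin at the root.
    ``painting`` must be binary over {variable, invariant}; the root's own
    state may be supplied in the painting (overriding ``root_state``).
    """
    labels = _check_painting(tree, painting)
    root = painting.get(tree.root.index, root_state)
    extra = ({root} | set(labels)) - {VARIABLE, INVARIANT}
    if extra:
        raise RegimeError(f"painting is not binary variable/invariant: extra labels {sorted(extra)}")
    origins = 1 if root == INVARIANT else 0
    reversals = 0
    for node in tree.nodes:
        if node.is_root:
            continue
        parent_state = painting.get(node.parent.index, root) if node.parent.is_root else painting[node.parent.index]
        state = painting[node.index]
        if parent_state == VARIABLE and state == INVARIANT:
            origins += 1
        elif parent_state == INVARIANT and state == VARIABLE:
            reversals += 1
    return origins, reversals


def greedy_shift_search(
    tree: Phylogeny,
    x,
    max_shifts: int = 5,
    min_clade_size: int = 5,
    delta: float = 2.0,
) -> tuple[dict[int, str], list[ModelFit]]:
    """Greedy clade-rooted rate-shift search with the AICc > ``delta`` stop rule.

    Starts from single-rate BM; each round tries giving every candidate
    clade (>= ``min_clade_size`` tips, not the whole tree) its own Brownian
    rate, keeps the single shift that most improves AICc, and stops when
    the best improvement is <= ``delta`` or ``max_shifts`` is reached.
    Returns the final painting and the fit trajectory.
    """
    x = np.asarray(x, dtype=float)
    if max_shifts < 0:
        raise RegimeError("max_shifts must be >= 0")
    base = fit_regime_model(tree, x, model="BM1")
    trajectory = [base]
    shifts: list[int] = []  # node indices whose clades carry their own regime

    def build_painting(shift_nodes: list[int]) -> dict[int, str]:
        painting = {}
        labels = {idx: f"shift_{j}" for j, idx in enumerate(shift_nodes)}

        def walk(node: Node, current: str) -> None:
            if node.index in labels:
                current = labels[node.index]
            if not node.is_root:
                painting[node.index] = current
            for child in node.children:
                walk(child, current)

        walk(tree.root, "background")
        return painting

    sets = tree.clade_tip_sets()
    candidates = [
        n.index
        for n in tree.nodes
        if not n.is_root and not n.is_tip and len(sets[n.index]) >= min_clade_size
    ]
    current_aicc = base.aicc
    while len(shifts) < max_shifts:
        best_fit, best_idx = None, None
        for idx in candidates:
            if idx in shifts:
                continue
            painting = build_painting(shifts + [idx])
            try:
                fit = fit_regime_model(tree, x, painting, model="BMS")
            except (RegimeError, BMError, linalg.LinAlgError):
                continue
            if best_fit is None or fit.aicc < best_fit.aicc:
                best_fit, best_idx = fit, idx
        if best_fit is None or current_aicc - best_fit.aicc <= delta:
            break
        shifts.append(best_idx)
        trajectory.append(best_fit)
        current_aicc = best_fit.aicc
    return build_painting(shifts), trajectory


def rate_state_correlation(
    tree: Phylogeny,
    painting: Mapping[int, str],
    values,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Do invariant-regime tips carry lower trait values than variable ones?

    Compares the (log-scale) trait mean of tips whose subtending branch is
    painted invariant against tips in the variable regime: difference of
    means (invariant minus variable) with a two-sided tip-permutation
    p-value.
    """
    values = np.asarray(values, dtype=float)
    tips = tree.tips
    if values.shape != (len(tips),):
        raise RegimeError("values must align with tree.tip_labels")
    _check_painting(tree, painting)
    groups = np.array([painting[t.index] for t in tips])
    inv = values[groups == INVARIANT]
    var = values[groups == VARIABLE]
    if len(inv) < 2 or len(var) < 2:
        raise RegimeError(
            f"need >= 2 tips per regime, got {len(inv)} invariant / {len(var)} variable"
        )
    obs = float(inv.mean() - var.mean())
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(inv)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(values)
        d = perm[:k].mean() - perm[k:].mean()
        if abs(d) >= abs(obs) - 1e-15:
            count += 1
    return {
        "delta_mean": obs,
        "pvalue": (count + 1) / (n_perm + 1),
        "n_invariant": int(len(inv)),
        "n_variable": int(len(var)),
    }
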