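"""Mk models and marginal ancestral-state reconstruction for oogenesis mode.

Insect oogenesis falls into discrete modes by the presence and position of
nurse cells: panoistic (no nurse cells), polytrophic meroistic (nurse cells
adjacent to each oocyte), telotrophic meroistic (nurse cells confined to
the germarium), and the unique meroistic arrangement of Strepsiptera,
treated as a fourth state.  Evolution between states follows a
continuous-time Markov chain with rate matrix Q (rows sum to zero), with
equal-rates (ER), symmetric (SYM), or all-rates-different (ARD) structure.

Likelihoods use Felsenstein's pruning algorithm with transition matrices
``P(t) = expm(Q t)`` computed by eigendecomposition (scaling-and-squaring
fallback for defective Q).  Marginal ancestral states combine the upward
(subtree) and downward (rest-of-tree) partial likelihoods at each node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .trees import Phylogeny, TreeSample, prune_and_match

__all__ = [
    "MkError",
    "OOGENESIS_MODES",
    "MK_STRUCTURES",
    "MkModel",
    "ASRResult",
    "build_q",
    "n_free_rates",
    "mk_loglik",
    "fit_mk",
    "marginal_asr",
    "count_state_transitions",
    "replicate_asr",
    "simulate_mk",
]

OOGENESIS_MODES = (
    "panoistic",
    "polytrophic_meroistic",
    "telotrophic_meroistic",
    "strepsiptera_meroistic",
)

MK_STRUCTURES = ("ER", "SYM", "ARD")

_RATE_LO, _RATE_HI = 1e-9, 1e4


class MkError(ValueError):
    """Raised for invalid Mk inputs or non-finite likelihoods."""


def n_free_rates(n_states: int, structure: str) -> int:
    if structure == "ER":
        return 1
    if structure == "SYM":
        return n_states * (n_states - 1) // 2
    if structure == "ARD":
        return n_states * (n_states - 1)
    raise MkError(f"unknown structure {structure!r}; expected one of {MK_STRUCTURES}")


def build_q(states: tuple[str, ...], structure: str, rates: np.ndarray) -> np.ndarray:
    """Assemble Q from the free rate vector; off-diagonals >= 0, rows sum to 0.

    Off-diagonal order is row-major over (i, j), i != j; SYM fills the upper
    triangle then mirrors; ER broadcasts the single rate.
    """
    k = len(states)
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (n_free_rates(k, structure),):
        raise MkError(f"{structure} with {k} states needs {n_free_rates(k, structure)} rates")
    if (rates < 0).any():
        raise MkError("rates must be non-negative")
    Q = np.zeros((k, k))
    if structure == "ER":
        Q[:] = rates[0]
    elif structure == "SYM":
        iu = np.triu_indices(k, 1)
        Q[iu] = rates
        Q.T[iu] = rates
    else:
        off = ~np.eye(k, dtype=bool)
        Q[off] = rates
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass
class MkModel:
    """A fitted (or specified) Mk model."""

    states: tuple[str, ...]
    Q: np.ndarray
    structure: str
    loglik: float = np.nan
    aicc: float = np.nan
    root_prior: str = "uniform"

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        k = len(self.states)
        if self.Q.shape != (k, k):
            raise MkError("Q shape must match the state count")
        off = self.Q[~np.eye(k, dtype=bool)]
        if (off < -1e-12).any():
            raise MkError("off-diagonal rates must be non-negative")
        if np.abs(self.Q.sum(axis=1)).max() > 1e-10:
            raise MkError("Q rows must sum to zero")

    @property
    def k_free(self) -> int:
        return n_free_rates(len(self.states), self.structure)


@dataclass
class ASRResult:
    """Marginal ancestral-state probabilities at every node."""

    states: tuple[str, ...]
    marginals: dict[int, np.ndarray]  # node index -> probability vector
    map_states: dict[int, str]
    root_prior: str


def _make_propagator(Q: np.ndarray):
    """Return a cached ``P(t) = expm(Q t)`` evaluator.

    Eigendecomposes Q once; falls back to scaling-and-squaring (scipy expm)
    when the eigendecomposition is defective or ill-conditioned.  Results
    are clipped to [0, 1] and renormalized row-wise (tolerance ~1e-12) and
    memoized per branch length.
    """
    use_eig = True
    try:
        w, U = np.linalg.eig(Q)
        Uinv = np.linalg.inv(U)
        if np.linalg.cond(U) > 1e8:
            use_eig = False
    except np.linalg.LinAlgError:
        use_eig = False
    cache: dict[float, np.ndarray] = {}

    def propagator(t: float) -> np.ndarray:
        P = cache.get(t)
        if P is not None:
            return P
        if use_eig:
            P = np.real((U * np.exp(w * t)) @ Uinv)
            if not np.isfinite(P).all():
                P = linalg.expm(Q * t)
        else:
            P = linalg.expm(Q * t)
        P = np.clip(P, 0.0, 1.0)
        P /= P.sum(axis=1, keepdims=True)
        cache[t] = P
        return P

    return propagator


def _transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """One-off ``P(t)``; prefer :func:`_make_propagator` inside loops."""
    return _make_propagator(Q)(t)


def _tip_likelihoods(tree: Phylogeny, tip_states, states) -> np.ndarray:
    """Partial likelihood rows for every node; tips one-hot, missing all-ones."""
    k = len(states)
    index = {s: i for i, s in enumerate(states)}
    L = np.ones((len(tree.nodes), k))
    seen = set()
    for tip in tree.tips:
        state = tip_states.get(tip.label)
        if state is None or (isinstance(state, float) and np.isnan(state)):
            continue
        if state not in index:
            raise MkError(f"tip {tip.label!r} has unknown state {state!r}")
        L[tip.index] = 0.0
        L[tip.index, index[state]] = 1.0
        seen.add(state)
    return L


def _root_prior_vector(prior: str, Q: np.ndarray, k: int) -> np.ndarray:
    if prior == "uniform":
        return np.full(k, 1.0 / k)
    if prior == "stationary":
        # left null vector of Q
        w, V = np.linalg.eig(Q.T)
        i = int(np.argmin(np.abs(w)))
        pi = np.real(V[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()
    raise MkError(f"unknown root prior {prior!r}")


def mk_loglik(
    tree: Phylogeny, tip_states: dict, model: MkModel
) -> float:
    """Pruning-algorithm log-likelihood of the tip states under ``model``."""
    k = len(model.states)
    L = _tip_likelihoods(tree, tip_states, model.states)
    prop = _make_propagator(model.Q)
    scale = 0.0
    for node in tree.postorder():
        if node.is_tip:
            continue
        part = np.ones(k)
        for child in node.children:
            P = prop(child.length or 0.0)
            part = part * (P @ L[child.index])
        m = part.max()
        if m <= 0:
            return -np.inf
        scale += np.log(m)
        L[node.index] = part / m
    prior = _root_prior_vector(model.root_prior, model.Q, k)
    lik = float(prior @ L[tree.root.index])
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + scale)


def fit_mk(
    tree: Phylogeny,
    tip_states: dict,
    structure: str = "ARD",
    root_prior: str = "uniform",
    seed: int | np.random.Generator = 0,
    n_starts: int = 2,
) -> MkModel:
    """ML Mk rates by bounded quasi-Newton optimization in log-rate space.

    Missing tip states are treated as uninformative (partial likelihood 1
    for every state).  When all observed tips share one state the ML rate
    sits at the lower bound; this boundary fit is returned with a warning.
    """
    observed = {s for s in (tip_states.get(t.label) for t in tree.tips) if s is not None}
    if not observed:
        raise MkError("no observed tip states")
    states = tuple(sorted(observed))
    k = len(states)
    m = n_free_rates(k, structure)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if len(observed) < 2:
        warnings.warn("all observed tips share one state: boundary fit at the minimum rate")
        model = MkModel(states, np.zeros((1, 1)), structure, root_prior=root_prior)
        ll = mk_loglik(tree, tip_states, model)
        model.loglik = ll
        model.aicc = _mk_aicc(ll, 1, tree.n_tips)
        return model

    def negloglik(log_rates: np.ndarray) -> float:
        Q = build_q(states, structure, np.exp(log_rates))
        ll = mk_loglik(tree, tip_states, MkModel(states, Q, structure, root_prior=root_prior))
        return -ll if np.isfinite(ll) else 1e12

    height = tree.height or 1.0
    base = 1.0 / height
    bounds = [(np.log(_RATE_LO), np.log(_RATE_HI))] * m
    best = None
    starts = [np.full(m, np.log(base))]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.log(base) + rng.uniform(-2, 2, size=m))
    for x0 in starts:
        res = optimize.minimize(negloglik, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    ll = -float(best.fun)
    if not np.isfinite(ll) or ll <= -1e11:
        raise MkError("non-finite Mk likelihood at the optimum")
    Q = build_q(states, structure, np.exp(best.x))
    model = MkModel(states, Q, structure, root_prior=root_prior)
    model.loglik = ll
    model.aicc = _mk_aicc(ll, m, tree.n_tips)
    return model


def _mk_aicc(loglik: float, k_free: int, n: int) -> float:
    if n - k_free - 1 <= 0:
        return np.nan
    return -2 * loglik + 2 * k_free + 2 * k_free * (k_free + 1) / (n - k_free - 1)


def marginal_asr(tree: Phylogeny, tip_states: dict, model: MkModel) -> ASRResult:
    """Marginal posterior state probabilities at every node.

    Combines the upward pass (likelihood of the subtree below each node
    given its state) with a downward pass carrying the likelihood of the
    rest of the tree and the root prior; each node's marginal sums to one.
    """
    k = len(model.states)
    down = _tip_likelihoods(tree, tip_states, model.states)  # subtree partials
    prop = _make_propagator(model.Q)
    # upward pass (tips -> root), unscaled but renormalized per node
    for node in tree.postorder():
        if node.is_tip:
            continue
        part = np.ones(k)
        for child in node.children:
            part = part * (prop(child.length or 0.0) @ down[child.index])
        s = part.sum()
        if s <= 0:
            raise MkError("zero likelihood during upward pass")
        down[node.index] = part / s
    prior = _root_prior_vector(model.root_prior, model.Q, k)
    up = np.ones((len(tree.nodes), k))
    up[tree.root.index] = prior
    marginals: dict[int, np.ndarray] = {}
    for node in tree.nodes:  # preorder: parents before children
        for child in node.children:
            # contribution of this node and all siblings of `child`
            above = up[node.index].copy()
            for sib in node.children:
                if sib is child:
                    continue
                above = above * (prop(sib.length or 0.0) @ down[sib.index])
            up[child.index] = above @ prop(child.length or 0.0)
        post = up[node.index] * down[node.index]
        s = post.sum()
        if s <= 0:
            raise MkError("zero posterior at a node")
        marginals[node.index] = post / s
    map_states = {
        i: model.states[int(np.argmax(p))] for i, p in marginals.items()
    }
    return ASRResult(model.states, marginals, map_states, model.root_prior)


def count_state_transitions(tree: Phylogeny, painting: dict[int, str]) -> dict:
    """Ordered-pair transition counts over a node-state painting.

    ``painting`` maps every node index to a state; a branch whose parent is
    painted a and child b (a != b) counts toward (a, b).
    """
    missing = [n.index for n in tree.nodes if n.index not in painting]
    if missing:
        raise MkError(f"painting missing node indices: {missing[:5]}")
    counts: dict[tuple[str, str], int] = {}
    for node in tree.nodes:
        if node.is_root:
            continue
        a, b = painting[node.parent.index], painting[node.index]
        if a != b:
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts


def simulate_mk(
    tree: Phylogeny,
    model: MkModel,
    root_state: str | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[int, str]:
    """Simulate states down the tree; returns a full node painting."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(model.states)
    index = {s: i for i, s in enumerate(model.states)}
    painting: dict[int, str] = {}
    if root_state is None:
        prior = _root_prior_vector(model.root_prior, model.Q, k)
        root_i = rng.choice(k, p=prior)
    else:
        root_i = index[root_state]
    painting[tree.root.index] = model.states[root_i]
    for node in tree.nodes:
        if node.is_root:
            continue
        P = _transition_matrix(model.Q, node.length or 0.0)
        pa = index[painting[node.parent.index]]
        painting[node.index] = model.states[rng.choice(k, p=P[pa])]
    return painting


def replicate_asr(
    trees: TreeSample,
    state_records: pd.DataFrame,
    R: int = 100,
    structure: str = "ARD",
    root_prior: str = "uniform",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Repeat fit + marginal ASR over a posterior sample with record resampling.

    ``state_records`` has columns (taxon, state), possibly several records
    per taxon; each replicate keeps one record per taxon at random and uses
    posterior tree i (cycled).  Returns per-clade MAP-state frequencies for
    every internal clade of the summary tree that is present in a replicate
    tree, plus the root.
    """
    if R < 1:
        raise MkError("R must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ref = trees.summary
    ref_sets = ref.clade_tip_sets()
    ref_internal = {ref_sets[n.index]: n.index for n in ref.internal_nodes}
    tally: dict[int, dict[str, int]] = {i: {} for i in ref_internal.values()}
    seen: dict[int, int] = {i: 0 for i in ref_internal.values()}
    n_failed = 0
    for i in range(R):
        tree = trees.cycled(i)
        picks = state_records.groupby("taxon", sort=True).sample(n=1, random_state=int(rng.integers(2**31)))
        tip_states = dict(zip(picks["taxon"], picks["state"]))
        try:
            model = fit_mk(tree, tip_states, structure=structure, root_prior=root_prior, seed=rng)
            asr = marginal_asr(tree, tip_states, model)
        except MkError:
            n_failed += 1
            continue
        sets = tree.clade_tip_sets()
        by_set = {sets[n.index]: n.index for n in tree.internal_nodes}
        for clade, ref_idx in ref_internal.items():
            node_idx = by_set.get(clade)
            if node_idx is None:
                continue
            state = asr.map_states[node_idx]
            seen[ref_idx] += 1
            tally[ref_idx][state] = tally[ref_idx].get(state, 0) + 1
    rows = []
    for clade, ref_idx in sorted(ref_internal.items(), key=lambda kv: kv[1]):
        total = seen[ref_idx]
        if total == 0:
            continue
        best_state, best_n = max(tally[ref_idx].items(), key=lambda kv: kv[1])
        rows.append(
            {
                "clade_index": ref_idx,
                "n_tips": len(clade),
                "n_replicates": total,
                "map_state": best_state,
                "map_frequency": best_n / total,
                "is_root": ref_idx == ref.root.index,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_failed"] = n_failed
    return out
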