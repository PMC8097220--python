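"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ovarevo.generate import sim_yule_tree
from ovarevo.trees import Phylogeny, phylo_covariance, read_newick

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def three_tip_tree() -> Phylogeny:
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree() -> Phylogeny:
    return read_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_tree(n_tips: int, seed: int) -> Phylogeny:
    return sim_yule_tree(n_tips, 1.0, seed)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def covariance_by_path_walking(tree: Phylogeny) -> np.ndarray:
    """Shared path length by explicit root-to-tip path enumeration."""

    def path(node):
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return list(reversed(out))

    tips = tree.tips
    n = len(tips)
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            pi, pj = path(tips[i]), path(tips[j])
            shared = 0.0
            for a, b in zip(pi, pj):
                if a is b:
                    shared += a.length
                else:
                    break
            C[i, j] = shared
    return C


def dense_gls_oracle(x: np.ndarray, y: np.ndarray, C: np.ndarray):
    """Naive matrix-inversion GLS of y on [1, x]; returns (intercept, slope, residuals)."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    Ci = np.linalg.inv(C)
    beta = np.linalg.inv(X.T @ Ci @ X) @ (X.T @ Ci @ y)
    return beta[0], beta[1], y - X @ beta


def mk_likelihood_enumeration(tree: Phylogeny, tip_states: dict, states, Q, prior):
    """Brute-force Mk likelihood: sum over all interior-state assignments."""
    import itertools

    from scipy.linalg import expm

    P = {n.index: expm(Q * n.length) for n in tree.nodes if not n.is_root}
    k = len(states)
    idx = {s: i for i, s in enumerate(states)}
    interior = [n for n in tree.nodes if not n.is_tip]
    total = 0.0
    tip_choices = {}
    for t in tree.tips:
        s = tip_states.get(t.label)
        tip_choices[t.index] = [idx[s]] if s is not None else list(range(k))
    for assign in itertools.product(range(k), repeat=len(interior)):
        amap = {n.index: a for n, a in zip(interior, assign)}

        def branch_prob(node):
            prob = 1.0
            for child in node.children:
                if child.is_tip:
                    p = sum(
                        P[child.index][amap[node.index], s] for s in tip_choices[child.index]
                    )
                else:
                    p = P[child.index][amap[node.index], amap[child.index]]
                    p *= branch_prob(child)
                prob *= p
            return prob

        total += prior[amap[tree.root.index]] * branch_prob(tree.root)
    return total


def transition_count_oracle(tree: Phylogeny, painting: dict):
    """Independent DFS edge scan of ordered state-pair transitions."""
    counts = {}

    def walk(node):
        for child in node.children:
            a, b = painting[node.index], painting[child.index]
            if a != b:
                counts[(a, b)] = counts.get((a, b), 0) + 1
            walk(child)

    walk(tree.root)
    return counts


def origin_reversal_oracle(tree: Phylogeny, painting: dict, root_state: str):
    """Independent recursive count of invariant origins and reversals."""
    result = {"origins": 1 if root_state == "invariant" else 0, "reversals": 0}

    def walk(node, parent_state):
        for child in node.children:
            s = painting[child.index]
            if parent_state == "variable" and s == "invariant":
                result["origins"] += 1
            if parent_state == "invariant" and s == "variable":
                result["reversals"] += 1
            walk(child, s)

    walk(tree.root, root_state)
    return result["origins"], result["reversals"]
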