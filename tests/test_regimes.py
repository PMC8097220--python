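"""Multi-regime models, AICc decision rule, and regime classification."""

import numpy as np
import pytest
from scipy import stats

from ovarevo.brownian import BMError, simulate_bm
from ovarevo.regimes import (
    INVARIANT,
    VARIABLE,
    ModelFit,
    RegimeError,
    branch_painting,
    classify_rate_regimes,
    compare_models,
    count_regime_origins,
    fit_regime_model,
    greedy_shift_search,
    rate_state_correlation,
)
from ovarevo.trees import Phylogeny, phylo_covariance

from conftest import origin_reversal_oracle, random_tree


def two_clade_painting(tree: Phylogeny):
    """Paint the larger root child's clade as one regime, the rest as another."""
    sets = tree.clade_tip_sets()
    child = max(tree.root.children, key=lambda c: len(sets[c.index]))
    painting = {}
    inside = set()
    stack = [child]
    while stack:
        n = stack.pop()
        inside.add(n.index)
        stack.extend(n.children)
    for n in tree.nodes:
        if n.is_root:
            continue
        painting[n.index] = "fast" if n.index in inside else "slow"
    mask = np.array([lbl in sets[child.index] for lbl in tree.tip_labels])
    return painting, mask


def simulate_bms(tree: Phylogeny, painting, rates: dict, z0: float, seed) -> np.ndarray:
    """Simulate multi-rate BM by scaling branch lengths per regime."""
    scaled = tree.copy()
    for node in scaled.nodes:
        if node.is_root:
            continue
        node.length = node.length * rates[painting[node.index]]
    return simulate_bm(scaled, 1.0, z0, seed)


class TestFitRegimeModel:
    def test_single_regime_bms_equals_bm1(self):
        tree = random_tree(20, 0)
        x = simulate_bm(tree, 0.5, 0.0, 1)
        bm1 = fit_regime_model(tree, x, model="BM1")
        bms = fit_regime_model(tree, x, branch_painting(tree, "all"), model="BMS")
        assert bms.loglik == pytest.approx(bm1.loglik, abs=1e-8)
        assert bms.k == 2 and bm1.k == 2

    def test_aicc_identity_on_every_fit(self):
        tree = random_tree(24, 1)
        x = simulate_bm(tree, 0.5, 0.0, 2)
        painting, _ = two_clade_painting(tree)
        for model in ("BM1", "BMS", "OU1", "OUM"):
            fit = fit_regime_model(tree, x, painting, model=model)
            expected = -2 * fit.loglik + 2 * fit.k + 2 * fit.k * (fit.k + 1) / (fit.n - fit.k - 1)
            assert fit.aicc == pytest.approx(expected, abs=1e-10)

    def test_ou1_approaches_bm1_at_vanishing_alpha(self):
        tree = random_tree(24, 2)
        x = simulate_bm(tree, 0.5, 0.0, 3)
        bm1 = fit_regime_model(tree, x, model="BM1")
        ou1 = fit_regime_model(tree, x, model="OU1")
        assert ou1.loglik >= bm1.loglik - 1e-4

    def test_bms_loglik_matches_dense_mvn(self):
        tree = random_tree(20, 3)
        painting, mask = two_clade_painting(tree)
        x = simulate_bms(tree, painting, {"fast": 2.0, "slow": 0.1}, 0.0, 4)
        fit = fit_regime_model(tree, x, painting, model="BMS")
        scaled = tree.copy()
        for node in scaled.nodes:
            if not node.is_root:
                node.length *= fit.params[f"sigma2_{painting[node.index]}"]
        C = phylo_covariance(scaled).matrix
        dense = stats.multivariate_normal.logpdf(x, mean=np.full(20, fit.params["z0"]), cov=C)
        assert fit.loglik == pytest.approx(dense, abs=1e-6)

    def test_nested_likelihood_ordering(self):
        for seed in range(5):
            tree = random_tree(16, 10 + seed)
            x = simulate_bm(tree, 0.5, 0.0, seed)
            painting, _ = two_clade_painting(tree)
            bm1 = fit_regime_model(tree, x, model="BM1")
            bms = fit_regime_model(tree, x, painting, model="BMS")
            assert bms.loglik >= bm1.loglik - 1e-6

    def test_ou_requires_ultrametric_tree(self):
        from ovarevo.trees import read_newick

        tree = read_newick("((A:1,B:2):1,(C:1,D:1):2);")
        with pytest.raises(RegimeError, match="ultrametric"):
            fit_regime_model(tree, np.array([0.0, 1.0, 2.0, 3.0]), model="OU1")

    def test_unknown_model_rejected(self):
        tree = random_tree(10, 4)
        with pytest.raises(RegimeError, match="unknown model"):
            fit_regime_model(tree, np.zeros(10), model="EB")


class TestCompareModels:
    @staticmethod
    def _fit(model, aicc_target, n=50):
        k = 2
        # invert the AICc identity to hit the target
        loglik = -(aicc_target - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2
        return ModelFit(model, {}, loglik, k, n)

    def test_clear_single_iteration_winner(self):
        table, decision = compare_models([[self._fit("BMS", 100), self._fit("BM1", 110)]])
        assert decision == "BMS"
        assert table[table["model"] == "BM1"]["delta_aicc"].iloc[0] == pytest.approx(10)

    def test_every_iteration_rule(self):
        iters = [
            [self._fit("BMS", 100), self._fit("BM1", 110)],
            [self._fit("BMS", 100), self._fit("BM1", 101.5)],
        ]
        _, decision = compare_models(iters)
        assert decision is None

    def test_empty_rejected(self):
        with pytest.raises(RegimeError):
            compare_models([])

    def test_power_against_strong_rate_contrast(self):
        tree = random_tree(44, 5)
        painting, _ = two_clade_painting(tree)
        wins = 0
        n_sims = 40
        for s in range(n_sims):
            x = simulate_bms(tree, painting, {"fast": 1.0, "slow": 0.01}, 0.0, 600 + s)
            bms = fit_regime_model(tree, x, painting, model="BMS")
            bm1 = fit_regime_model(tree, x, model="BM1")
            _, decision = compare_models([[bms, bm1]])
            wins += decision == "BMS"
        assert wins / n_sims >= 0.95


class TestClassify:
    def test_threshold_classification(self):
        painting = classify_rate_regimes({"b1": 1e-3, "b2": 1e-5}, threshold=1e-4)
        assert painting == {"b1": VARIABLE, "b2": INVARIANT}

    def test_tie_goes_to_variable(self):
        assert classify_rate_regimes({"b": 1e-4}, 1e-4) == {"b": VARIABLE}

    def test_zero_threshold_all_variable(self):
        out = classify_rate_regimes({"a": 0.0, "b": 5.0}, threshold=0.0)
        assert set(out.values()) == {VARIABLE}

    def test_missing_rate_raises(self):
        with pytest.raises(RegimeError, match="missing rate"):
            classify_rate_regimes({"a": np.nan})


class TestOrigins:
    def test_all_variable_has_none(self):
        tree = random_tree(10, 6)
        painting = {n.index: VARIABLE for n in tree.nodes if not n.is_root}
        assert count_regime_origins(tree, painting) == (0, 0)

    def test_hand_built_two_origins_one_reversal(self):
        from ovarevo.trees import read_newick

        tree = read_newick(
            "(((a:1,b:1):1,(c:1,d:1):1):1,((e:1,f:1):1,((g:1,h:1):1,(i:1,(j:1,(k:1,l:1):1):1):1):1):1);"
        )
        painting = {n.index: VARIABLE for n in tree.nodes if not n.is_root}
        sets = tree.clade_tip_sets()
        for n in tree.nodes:
            if n.is_root:
                continue
            clade = sets[n.index]
            # invariant clade 1: {a,b,c,d}; invariant clade 2: {g..l} with a
            # reversal on the {j,k,l} subclade
            if clade <= {"a", "b", "c", "d"}:
                painting[n.index] = INVARIANT
            if clade <= {"g", "h", "i", "j", "k", "l"}:
                painting[n.index] = INVARIANT
            if clade <= {"j", "k", "l"}:
                painting[n.index] = VARIABLE
        assert count_regime_origins(tree, painting) == (2, 1)

    def test_invariant_root_counts_one_origin(self):
        tree = random_tree(8, 7)
        painting = {n.index: INVARIANT for n in tree.nodes if not n.is_root}
        origins, reversals = count_regime_origins(tree, painting, root_state=INVARIANT)
        assert (origins, reversals) == (1, 0)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_paintings_match_oracle(self, seed):
        tree = random_tree(100, seed)
        rng = np.random.default_rng(seed)
        painting = {
            n.index: (INVARIANT if rng.random() < 0.3 else VARIABLE)
            for n in tree.nodes
            if not n.is_root
        }
        root = INVARIANT if rng.random() < 0.5 else VARIABLE
        assert count_regime_origins(tree, painting, root) == origin_reversal_oracle(
            tree, painting, root
        )

    def test_label_swap_symmetry(self):
        tree = random_tree(30, 8)
        rng = np.random.default_rng(8)
        painting = {
            n.index: (INVARIANT if rng.random() < 0.4 else VARIABLE)
            for n in tree.nodes
            if not n.is_root
        }
        swapped = {
            i: (VARIABLE if s == INVARIANT else INVARIANT) for i, s in painting.items()
        }
        o1, r1 = count_regime_origins(tree, painting, VARIABLE)
        o2, r2 = count_regime_origins(tree, swapped, INVARIANT)
        # swapping every label (and root) exchanges origins with reversals,
        # except the root-origin convention applies to the swapped root
        assert (o1, r1) == (r2 + 0, o2 - 1)

    def test_non_binary_rejected(self):
        tree = random_tree(6, 9)
        painting = {n.index: "weird" for n in tree.nodes if not n.is_root}
        with pytest.raises(RegimeError, match="binary"):
            count_regime_origins(tree, painting)


class TestGreedyShiftSearch:
    def test_zero_shift_boundary(self):
        tree = random_tree(16, 10)
        x = simulate_bm(tree, 0.5, 0.0, 11)
        painting, trajectory = greedy_shift_search(tree, x, max_shifts=0)
        assert len(trajectory) == 1 and trajectory[0].model == "BM1"
        assert set(painting.values()) == {"background"}

    def test_stop_threshold_controls_false_shifts(self):
        # searching over many candidate clades is a multiple-comparison
        # setting: spurious shifts under single-rate BM become rare once the
        # stop threshold is raised, and a stricter threshold never finds
        # more shifts than a looser one
        n_runs = 30
        hits_loose, hits_strict = 0, 0
        for s in range(n_runs):
            tree = random_tree(24, 700 + s)
            x = simulate_bm(tree, 0.5, 0.0, 800 + s)
            _, loose = greedy_shift_search(tree, x, max_shifts=3, delta=2.0)
            _, strict = greedy_shift_search(tree, x, max_shifts=3, delta=8.0)
            hits_loose += len(loose) > 1
            hits_strict += len(strict) > 1
            assert len(strict) <= len(loose)
        assert hits_strict / n_runs <= 0.10
        assert hits_strict <= hits_loose

    def test_recovers_planted_rate_shift(self):
        recovered = 0
        n_runs = 25
        for s in range(n_runs):
            tree = random_tree(32, 900 + s)
            painting, _ = two_clade_painting(tree)
            x = simulate_bms(tree, painting, {"fast": 1.0, "slow": 0.01}, 0.0, 1000 + s)
            found, trajectory = greedy_shift_search(tree, x, max_shifts=3, min_clade_size=5)
            if len(trajectory) == 1:
                continue
            # accept the fast clade's stem, a branch within one node of it,
            # or the sibling root clade (painting the complement yields the
            # identical two-regime partition)
            sets = tree.clade_tip_sets()
            fast_stem = max(tree.root.children, key=lambda c: len(sets[c.index]))
            shift_nodes = {i for i, lab in found.items() if lab.startswith("shift_")}
            zone = (
                {fast_stem.index}
                | {c.index for c in fast_stem.children}
                | {c.index for c in fast_stem.parent.children}
            )
            if shift_nodes & zone:
                recovered += 1
        assert recovered / n_runs >= 0.8


class TestRateStateCorrelation:
    def test_low_value_invariant_tips_detected(self):
        tree = random_tree(60, 12)
        rng = np.random.default_rng(12)
        values = rng.normal(1.5, 0.3, 60)
        painting = {}
        tips = tree.tips
        low = np.argsort(values)[:15]
        low_set = {tips[i].index for i in low}
        for n in tree.nodes:
            if n.is_root:
                continue
            painting[n.index] = INVARIANT if n.index in low_set else VARIABLE
        out = rate_state_correlation(tree, painting, values, n_perm=2000, seed=0)
        assert out["delta_mean"] < 0
        assert out["pvalue"] < 0.01

    def test_null_is_not_significant_on_average(self):
        tree = random_tree(40, 13)
        rng = np.random.default_rng(13)
        pvals = []
        for s in range(30):
            values = rng.normal(size=40)
            flags = rng.random(40) < 0.4
            painting = {}
            for i, t in enumerate(tree.tips):
                painting[t.index] = INVARIANT if flags[i] else VARIABLE
            for n in tree.nodes:
                if not n.is_root and n.index not in painting:
                    painting[n.index] = VARIABLE
            if flags.sum() < 2 or (~flags).sum() < 2:
                continue
            pvals.append(rate_state_correlation(tree, painting, values, n_perm=500, seed=s)["pvalue"])
        assert np.mean(np.array(pvals) < 0.05) < 0.2

    def test_single_tip_regime_rejected(self):
        tree = random_tree(10, 14)
        painting = {n.index: VARIABLE for n in tree.nodes if not n.is_root}
        painting[tree.tips[0].index] = INVARIANT
        with pytest.raises(RegimeError, match="2 tips per regime"):
            rate_state_correlation(tree, painting, np.zeros(10))
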