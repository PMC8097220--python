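"""Synthetic comparative datasets with the statistical structure the
analysis pipeline assumes.

The generator emulates a literature-compiled insect dataset: an ultrametric
phylogeny (pure-birth), a posterior-like sample of perturbed trees, a log10
ovariole-number trait evolving under regime-switching Brownian motion in
which the hazard of a variable -> invariant transition decays exponentially
with the current trait value, egg-size and body-size traits tied to
ovariole number by a log-log regression with a configurable slope, a
four-state oogenesis mode evolving under an Mk process, and a
literature-style record table with intraspecific noise, even-total
enrichment from the left+right ovary construction, eusocial-worker records
and outliers to exercise the filters.

Every generator is reproducible per seed; a ``make_dataset`` call writes a
bundle directory (trees/, records.tsv, modes.tsv, rates.tsv, truth.json)
in exactly the dialects the rest of the package consumes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mk as mkmod
from .records import make_records, write_records
from .regimes import INVARIANT, VARIABLE
from .trees import (
    Node,
    Phylogeny,
    TreeSample,
    branch_id_map,
    write_newick,
    write_tree_sample,
)

__all__ = [
    "GeneratorConfig",
    "RegimeSimResult",
    "sim_yule_tree",
    "sim_tree_posterior",
    "sim_regime_trait",
    "sim_record_table",
    "assign_taxonomy",
    "make_dataset",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    Rates are per unit branch length on trees whose height with the default
    birth rate (1.0) and 128 tips is about 4-5 time units.  The ovariole
    trait lives on the log10 scale; ``z0_ovariole`` of ~1.08 corresponds to
    a typical total of ~12 ovarioles.
    """

    n_tips: int = 128
    birth_rate: float = 1.0
    seed: int = 0
    # continuous traits (log10 scale)
    z0_ovariole: float = 1.08
    sigma2_variable: float = 0.2
    sigma2_invariant: float = 0.0
    z0_body: float = 0.5
    sigma2_body: float = 0.2
    slope: float = -1.0  # egg size on ovariole number (log-log)
    body_slope: float = 1.0  # egg size on body size (log-log)
    egg_intercept: float = -1.0
    residual_rate: float = 0.02  # BM rate of the egg-size residual
    # regime-switch process
    q0: float = 0.25  # base variable -> invariant hazard
    gamma: float = 2.0  # value dependence: hazard = q0 * exp(-gamma * x)
    q_iv: float = 0.05  # invariant -> variable hazard
    sim_dt: float = 0.02
    # oogenesis mode Mk process
    mk_rate: float = 0.025
    # record-table texture
    intraspecific_cv: float = 0.1
    even_total_prob: float = 0.7
    records_per_species_mean: float = 1.0  # extra records ~ Poisson(mean)
    eusocial_rate: float = 0.03
    outlier_rate: float = 0.005
    # posterior emulation
    n_posterior: int = 20
    length_jitter_sd: float = 0.05
    n_nni: int = 1

    def validate(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        for name in ("birth_rate", "sigma2_variable", "sigma2_invariant", "sigma2_body",
                     "residual_rate", "q0", "gamma", "q_iv", "mk_rate", "intraspecific_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("even_total_prob", "eusocial_rate", "outlier_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sim_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=0) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree with exactly ``n_tips`` tips.

    Starting from two lineages at the root, waiting times between
    speciations are Exp(k * birth_rate); a uniformly chosen lineage splits.
    After the last split the pendant branches are extended by one further
    exponential waiting time, keeping the tree ultrametric.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = _rng(seed)
    root = Node(None, None)
    active = [root.add_child(Node(None, 0.0)), root.add_child(Node(None, 0.0))]
    while len(active) < n_tips:
        wait = rng.exponential(1.0 / (len(active) * birth_rate))
        for lineage in active:
            lineage.length += wait
        i = rng.integers(len(active))
        parent = active.pop(i)
        active.extend([parent.add_child(Node(None, 0.0)), parent.add_child(Node(None, 0.0))])
    tail = rng.exponential(1.0 / (len(active) * birth_rate))
    for lineage in active:
        lineage.length += tail
    tmp = Phylogeny(root, validate=False)
    for i, tip in enumerate(tmp.tips):
        tip.label = f"t{i + 1:04d}"
    return Phylogeny(root)


def _random_nni(tree: Phylogeny, rng: np.random.Generator) -> None:
    """One nearest-neighbour interchange around a random internal branch."""
    internal_edges = [
        n for n in tree.nodes if not n.is_root and not n.is_tip
    ]
    if not internal_edges:
        return
    v = internal_edges[rng.integers(len(internal_edges))]
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    if not siblings or not v.children:
        return
    s = siblings[rng.integers(len(siblings))]
    c = v.children[rng.integers(len(v.children))]
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    c.parent, s.parent = u, v
    tree._reindex()


def sim_tree_posterior(
    tree: Phylogeny,
    n_trees: int = 20,
    length_jitter_sd: float = 0.05,
    n_nni: int = 1,
    seed=0,
) -> TreeSample:
    """Posterior-like sample: the base tree plus jittered/NNI-perturbed clones.

    Tree 0 is the unperturbed base (the designated summary tree); each
    further tree multiplies every branch length by a mean-one lognormal
    factor and applies ``n_nni`` random nearest-neighbour interchanges.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = _rng(seed)
    out = [tree.copy()]
    for _ in range(n_trees - 1):
        clone = tree.copy()
        if length_jitter_sd > 0:
            for node in clone.nodes:
                if node.is_root:
                    continue
                factor = math.exp(rng.normal(-0.5 * length_jitter_sd**2, length_jitter_sd))
                node.length *= factor
        for _ in range(n_nni):
            _random_nni(clone, rng)
        out.append(clone)
    return TreeSample(out, summary_index=0)


@dataclass
class RegimeSimResult:
    """Joint regime/trait simulation output."""

    tip_values: np.ndarray  # aligned with tree.tip_labels
    painting: dict[int, str]  # branch (and root) -> majority-duration regime
    branch_rates: dict[int, float]  # branch -> time-averaged diffusion rate
    transitions: list[dict] = field(default_factory=list)


_HAZARD_CAP = 1e6


def sim_regime_trait(
    tree: Phylogeny,
    sigma2_variable: float = 0.2,
    sigma2_invariant: float = 0.0,
    q0: float = 0.25,
    gamma: float = 2.0,
    q_iv: float = 0.05,
    z0: float = 1.08,
    root_regime: str = VARIABLE,
    dt: float = 0.02,
    seed=0,
) -> RegimeSimResult:
    """Regime-switching Brownian motion with a value-dependent switch hazard.

    Along each branch, in small Euler steps, the trait diffuses at the
    current regime's rate while the regime switches variable -> invariant
    with hazard ``q0 * exp(-gamma * x)`` (lower trait values switch more
    readily) and back with constant hazard ``q_iv``.  Steps are shortened
    adaptively so hazard * step < 0.01.  Each branch is labelled with its
    majority-duration regime and its time-averaged diffusion rate.
    """
    rng = _rng(seed)
    sig = {VARIABLE: sigma2_variable, INVARIANT: sigma2_invariant}
    values = {tree.root.index: z0}
    states = {tree.root.index: root_regime}
    painting: dict[int, str] = {tree.root.index: root_regime}
    branch_rates: dict[int, float] = {}
    transitions: list[dict] = []
    for node in tree.nodes:
        if node.is_root:
            continue
        x = values[node.parent.index]
        state = states[node.parent.index]
        remaining = node.length
        dur = {VARIABLE: 0.0, INVARIANT: 0.0}
        rate_time = 0.0
        while remaining > 1e-15:
            hazard = q0 * math.exp(-gamma * x) if state == VARIABLE else q_iv
            if hazard > _HAZARD_CAP:
                raise ValueError(
                    f"transition hazard {hazard:.3g} exceeds the step-size cap; "
                    "the value-dependent hazard is effectively unbounded here"
                )
            step = min(remaining, dt, 0.01 / hazard if hazard > 0 else remaining)
            x += math.sqrt(sig[state] * step) * rng.standard_normal()
            if hazard > 0 and rng.random() < hazard * step:
                new_state = INVARIANT if state == VARIABLE else VARIABLE
                transitions.append(
                    {"node": node.index, "from": state, "to": new_state, "x": x}
                )
                state = new_state
            dur[state] += step
            rate_time += sig[state] * step
            remaining -= step
        values[node.index] = x
        states[node.index] = state
        painting[node.index] = max(dur, key=dur.get) if node.length > 0 else states[node.parent.index]
        branch_rates[node.index] = rate_time / node.length if node.length > 0 else sig[state]
    tip_values = np.array([values[t.index] for t in tree.tips])
    return RegimeSimResult(tip_values, painting, branch_rates, transitions)


def assign_taxonomy(tree: Phylogeny) -> pd.DataFrame:
    """Nested genus/family/order labels from clade cuts at fixed depths.

    Tips in the same clade at 25% / 50% / 75% of tree height share an
    order / family / genus, mirroring a rank-structured sample of insects.
    """
    depths = tree.depths()
    height = tree.height
    cuts = {"order": 0.25 * height, "family": 0.5 * height, "genus": 0.75 * height}
    prefix = {"order": "o", "family": "f", "genus": "g"}
    rows = {t.label: {"species": t.label} for t in tree.tips}
    for rank, cut in cuts.items():
        counter = 0
        for node in tree.nodes:  # preorder: first crossing of the cut wins
            parent_d = depths[node.parent.index] if node.parent else 0.0
            if node.is_root:
                continue
            if parent_d < cut <= depths[node.index] or (node.is_tip and depths[node.index] < cut):
                counter += 1
                name = f"{prefix[rank]}{counter:03d}"
                stack = [node]
                while stack:
                    cur = stack.pop()
                    if cur.is_tip:
                        rows[cur.label][rank] = name
                    stack.extend(cur.children)
    return pd.DataFrame([rows[t.label] for t in tree.tips])


def _ovariole_total(latent_log10: float, invariant: bool) -> int:
    raw = 10.0 ** latent_log10
    if invariant:
        # invariant lineages: identical, symmetric (even) totals of at most 14
        return int(min(14, max(2, 2 * round(raw / 2.0))))
    return max(2, int(round(raw)))


def sim_record_table(
    tree: Phylogeny,
    latent: dict[str, np.ndarray],
    tip_regime: dict[str, str],
    config: GeneratorConfig,
    seed=0,
) -> pd.DataFrame:
    """Literature-style record table for the simulated traits.

    ``latent`` maps trait names to log10 tip values.  Ovariole totals are
    built as left+right ovary counts: symmetric (even total) with
    probability ``even_total_prob``, off by one (odd) otherwise.  Invariant
    species report one identical count with no intraspecific variation.
    Eusocial-worker and outlier records are injected at the configured
    rates to exercise the exclusion filters.
    """
    rng = _rng(seed)
    taxonomy = assign_taxonomy(tree).set_index("species")
    cv = config.intraspecific_cv
    rows: list[dict] = []
    for i, tip in enumerate(tree.tip_labels):
        tax = taxonomy.loc[tip]
        base = {"species": tip, "genus": tax["genus"], "family": tax["family"], "order": tax["order"]}
        invariant = tip_regime.get(tip) == INVARIANT
        # --- ovariole records -------------------------------------------
        x = float(latent["total_ovariole_number"][i])
        n_rec = 1 + rng.poisson(config.records_per_species_mean)
        if invariant:
            total = _ovariole_total(x, True)
            for j in range(n_rec):
                rows.append(base | {"trait": "total_ovariole_number", "kind": "single",
                                    "value": float(total), "caste": "reproductive",
                                    "source_id": f"src_{tip}_{j}"})
        else:
            for j in range(n_rec):
                noisy = x + math.log10(math.exp(cv * rng.standard_normal()))
                half = max(1, round(10.0 ** noisy / 2.0))
                even = rng.random() < config.even_total_prob
                total = 2 * half if even else 2 * half + 1
                kind = rng.choice(["single", "range", "mean_dev"], p=[0.6, 0.2, 0.2])
                rec = base | {"trait": "total_ovariole_number", "caste": "reproductive",
                              "source_id": f"src_{tip}_{j}"}
                if kind == "single":
                    rec |= {"kind": "single", "value": float(total)}
                elif kind == "range":
                    lo = max(2.0, round(total * (1 - cv)))
                    hi = max(lo, round(total * (1 + cv)))
                    rec |= {"kind": "range", "min": float(lo), "max": float(hi)}
                else:
                    rec |= {"kind": "mean_dev", "mean": float(total), "deviation": float(cv * total)}
                rows.append(rec)
            if rng.random() < config.eusocial_rate:
                rows.append(base | {"trait": "total_ovariole_number", "kind": "single",
                                    "value": max(1.0, round(0.1 * 10.0 ** x)),
                                    "caste": "non_reproductive", "source_id": f"src_{tip}_worker"})
            if rng.random() < config.outlier_rate:
                rows.append(base | {"trait": "total_ovariole_number", "kind": "single",
                                    "value": float(round(100.0 * 10.0 ** x)),
                                    "caste": "reproductive", "source_id": f"src_{tip}_outlier",
                                    "outlier": True})
        # --- continuous companion traits --------------------------------
        for trait in ("egg_volume_mm3", "dry_mass"):
            if trait not in latent:
                continue
            value = 10.0 ** float(latent[trait][i])
            rows.append(base | {"trait": trait, "kind": "single", "value": value,
                                "caste": "reproductive", "source_id": f"src_{tip}_{trait}"})
    return make_records(rows)


def make_dataset(config: GeneratorConfig, outdir: str | None = None) -> dict:
    """Generate a full synthetic bundle; optionally write it to ``outdir``.

    Returns a dict with the tree sample, record table, oogenesis-mode
    table, per-branch rates, the true painting, and the generating truth.
    When ``outdir`` is given, writes ``trees/summary.nwk``,
    ``trees/posterior.nwk``, ``records.tsv``, ``modes.tsv``, ``rates.tsv``
    and ``truth.json``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=8)
    tree = sim_yule_tree(config.n_tips, config.birth_rate, seeds[0])
    posterior = sim_tree_posterior(
        tree, config.n_posterior, config.length_jitter_sd, config.n_nni, seeds[1]
    )
    regime = sim_regime_trait(
        tree,
        sigma2_variable=config.sigma2_variable,
        sigma2_invariant=config.sigma2_invariant,
        q0=config.q0,
        gamma=config.gamma,
        q_iv=config.q_iv,
        z0=config.z0_ovariole,
        dt=config.sim_dt,
        seed=seeds[2],
    )
    from .brownian import simulate_bm  # local import to avoid cycle at module load

    body = simulate_bm(tree, config.sigma2_body, config.z0_body, seeds[3])
    resid = simulate_bm(tree, config.residual_rate, config.egg_intercept, seeds[4])
    egg = config.slope * regime.tip_values + config.body_slope * body + resid
    latent = {
        "total_ovariole_number": regime.tip_values,
        "egg_volume_mm3": egg,
        "dry_mass": body,
    }
    tip_regime = {t.label: regime.painting[t.index] for t in tree.tips}
    records = sim_record_table(tree, latent, tip_regime, config, seeds[5])
    # oogenesis modes under an equal-rates Mk process rooted in the
    # nurse-cell-free (panoistic) state
    Q = mkmod.build_q(mkmod.OOGENESIS_MODES, "ER", np.array([config.mk_rate]))
    mk_model = mkmod.MkModel(mkmod.OOGENESIS_MODES, Q, "ER")
    mode_painting = mkmod.simulate_mk(tree, mk_model, root_state="panoistic", seed=seeds[6])
    modes = pd.DataFrame(
        {"taxon": tree.tip_labels, "state": [mode_painting[t.index] for t in tree.tips]}
    )
    ids = branch_id_map(tree)
    rates = pd.DataFrame(
        {
            "branch": [ids[i] for i in sorted(ids)],
            "rate": [regime.branch_rates[i] for i in sorted(ids)],
        }
    )
    from .regimes import count_regime_origins

    origins, reversals = count_regime_origins(tree, regime.painting)
    truth = {
        "config": dataclasses.asdict(config),
        "painting": {ids[i]: regime.painting[i] for i in sorted(ids)},
        "root_regime": regime.painting[tree.root.index],
        "origins_of_invariance": origins,
        "reversals": reversals,
        "n_transition_events": len(regime.transitions),
        "mode_root_state": "panoistic",
    }
    bundle = {
        "tree": tree,
        "posterior": posterior,
        "records": records,
        "modes": modes,
        "rates": rates,
        "regime": regime,
        "latent": latent,
        "truth": truth,
    }
    if outdir is not None:
        os.makedirs(os.path.join(outdir, "trees"), exist_ok=True)
        with open(os.path.join(outdir, "trees", "summary.nwk"), "w") as fh:
            fh.write(write_newick(tree))
        with open(os.path.join(outdir, "trees", "posterior.nwk"), "w") as fh:
            fh.write(write_tree_sample(posterior))
        write_records(records, os.path.join(outdir, "records.tsv"))
        modes.to_csv(os.path.join(outdir, "modes.tsv"), sep="\t", index=False)
        rates.to_csv(os.path.join(outdir, "rates.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return bundle
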