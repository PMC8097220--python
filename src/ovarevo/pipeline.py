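"""Configuration-driven orchestration of the full analysis.

A :class:`RunConfig` (YAML or dict) names the stages to run, the input
bundle, the global seed, and the replication constants of the analysis
protocol: 1000 PGLS replicates over the posterior, significance threshold
0.01, 1000 hypothesis simulations, 100 ancestral-state replicates, the
1e-4 rate-regime threshold, and the AICc-greater-than-two decision rule.
Each stochastic stage derives its own seed from the global seed plus a
fixed stage offset, so a rerun with the same config reproduces every
output file hash-for-hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .brownian import adequacy_bootstrap, fit_bm_tree, hypothesis_study
from .generate import GeneratorConfig, make_dataset
from .mk import fit_mk, marginal_asr, count_state_transitions, replicate_asr
from .pgls import replicate_pgls
from .records import (
    aggregate_by_rank,
    filter_records,
    percent_difference_table,
    read_records,
    write_records,
)
from .regimes import (
    RegimeError,
    classify_rate_regimes,
    compare_models,
    count_regime_origins,
    fit_regime_model,
    rate_state_correlation,
)
from .trees import (
    branch_id_map,
    phylo_covariance,
    prune_and_match,
    read_newick,
    read_tree_sample,
    write_annotated_newick,
)

__all__ = ["ConfigError", "StageError", "RunConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = (
    "simulate",
    "tables",
    "pgls",
    "hypothesis",
    "asr",
    "regimes",
    "adequacy",
    "report",
)

# fixed per-stage seed offsets added to the global seed
STAGE_SEED_OFFSET = {name: 1000 * (i + 1) for i, name in enumerate(ALL_STAGES)}

TRAIT_Y = "egg_volume_mm3"
TRAIT_X = "total_ovariole_number"
TRAIT_SIZE = "dry_mass"


class ConfigError(ValueError):
    """Invalid run configuration (reported before any stage runs)."""


class StageError(RuntimeError):
    """A stage failed; the message points at the failing stage."""


@dataclass
class RunConfig:
    """Validated pipeline configuration with the protocol's default constants."""

    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    outdir: str = "ovarevo_run"
    bundle_dir: str | None = None  # defaults to <outdir>/bundle (simulate stage)
    seed: int = 0
    R: int = 1000  # PGLS replicates over the posterior
    alpha: float = 0.01  # significance threshold
    S: int = 1000  # hypothesis simulations per hypothesis
    asr_replicates: int = 100
    asr_structure: str = "ER"
    rate_threshold: float = 1e-4
    delta_aicc: float = 2.0
    rank: str = "species"
    resample_mode: str = "reshuffle"
    adequacy_sims: int = 200
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)

    def validate(self) -> None:
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("R", "S", "asr_replicates", "adequacy_sims"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.rate_threshold < 0:
            raise ConfigError("rate_threshold must be non-negative")
        if self.delta_aicc < 0:
            raise ConfigError("delta_aicc must be non-negative")
        try:
            GeneratorConfig(**self.generator).validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"generator config invalid: {exc}") from exc
        if "simulate" not in self.stages and self.bundle_dir is None:
            # bundle must already exist under outdir
            pass

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSET[stage]) % (2**31)

    @property
    def bundle(self) -> str:
        return self.bundle_dir or os.path.join(self.outdir, "bundle")


class _Run:
    """Shared state across stages of one pipeline run."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.log: list[str] = [
            f"ovarevo {__version__}",
            f"numpy {np.__version__}, pandas {pd.__version__}",
            f"global seed {config.seed}",
        ]
        self.outputs: list[str] = []
        os.makedirs(config.outdir, exist_ok=True)

    # -- helpers -----------------------------------------------------------
    def path(self, name: str) -> str:
        p = os.path.join(self.config.outdir, name)
        self.outputs.append(p)
        return p

    def write_json(self, name: str, payload: dict) -> None:
        with open(self.path(name), "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def load_bundle(self):
        b = self.config.bundle
        tree = read_newick(open(os.path.join(b, "trees", "summary.nwk")).read())
        posterior = read_tree_sample(path=os.path.join(b, "trees", "posterior.nwk"))
        records = read_records(os.path.join(b, "records.tsv"))
        modes = pd.read_csv(os.path.join(b, "modes.tsv"), sep="\t")
        rates = pd.read_csv(os.path.join(b, "rates.tsv"), sep="\t")
        return tree, posterior, records, modes, rates

    def matched_trait_vectors(self, tree, records):
        """Species-level log10 trait vectors on the taxa shared with the tree."""
        kept, _ = filter_records(records)
        aggs = {}
        for trait in (TRAIT_X, TRAIT_Y, TRAIT_SIZE):
            agg, _ = aggregate_by_rank(kept, "species", trait)
            aggs[trait] = agg.set_index("taxon")["log10_value"]
        taxa = set(tree.tip_labels)
        for s in aggs.values():
            taxa &= set(s.index)
        taxa = sorted(taxa)
        sub = prune_and_match(tree, taxa)
        order = sub.tip_labels
        return sub, {t: aggs[t].loc[order].to_numpy() for t in aggs}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order; return the manifest."""
    config.validate()
    run = _Run(config)
    stages = [s for s in ALL_STAGES if s in config.stages]
    for stage in stages:
        run.log.append(f"stage {stage}: seed {config.stage_seed(stage)}")
        try:
            _STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    # always finish with the log + manifest
    log_path = os.path.join(config.outdir, "run.log")
    with open(log_path, "w") as fh:
        fh.write("\n".join(run.log) + "\n")
    manifest = _manifest(config.outdir)
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def _manifest(outdir: str) -> dict:
    files = {}
    for root, _, names in os.walk(outdir):
        for name in sorted(names):
            if name == "manifest.json":
                continue
            p = os.path.join(root, name)
            rel = os.path.relpath(p, outdir)
            with open(p, "rb") as fh:
                files[rel] = hashlib.sha256(fh.read()).hexdigest()
    return {"files": files}


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    gen = GeneratorConfig(**{**cfg.generator, "seed": cfg.stage_seed("simulate")})
    make_dataset(gen, cfg.bundle)
    for root, _, names in os.walk(cfg.bundle):
        for name in names:
            run.outputs.append(os.path.join(root, name))
    run.log.append(f"simulate: bundle written ({gen.n_tips} tips, {gen.n_posterior} posterior trees)")


def _stage_tables(run: _Run) -> None:
    tree, _, records, _, _ = run.load_bundle()
    kept, audit = filter_records(records)
    write_records(kept, run.path("records_filtered.tsv"))
    audit.to_csv(run.path("filter_audit.tsv"), sep="\t", index=False)
    pdiff = percent_difference_table(kept, TRAIT_X)
    pdiff.to_csv(run.path("percent_difference.tsv"), sep="\t", index=False)
    for trait in (TRAIT_X, TRAIT_Y, TRAIT_SIZE):
        agg, errs = aggregate_by_rank(kept, run.config.rank, trait)
        agg.to_csv(run.path(f"aggregated_{trait}.tsv"), sep="\t", index=False)
        if len(errs):
            errs.to_csv(run.path(f"aggregation_errors_{trait}.tsv"), sep="\t", index=False)
    informative = pdiff[pdiff["informative"]]
    run.log.append(
        f"tables: {len(kept)}/{len(records)} records kept; "
        f"median percent difference {informative['percent_difference'].median():.1f}%"
    )


def _stage_pgls(run: _Run) -> None:
    cfg = run.config
    _, posterior, records, _, _ = run.load_bundle()
    kept, _ = filter_records(records)
    summary = replicate_pgls(
        kept[kept["trait"] == TRAIT_Y],
        kept[kept["trait"] == TRAIT_X],
        posterior,
        R=cfg.R,
        alpha=cfg.alpha,
        mode=cfg.resample_mode,
        rank=cfg.rank,
        seed=cfg.stage_seed("pgls"),
        records_size=kept[kept["trait"] == TRAIT_SIZE],
    )
    summary.to_frame().to_csv(run.path("pgls_replicates.tsv"), sep="\t", index=False)
    run.write_json(
        "pgls_summary.json",
        {
            "n_significant": summary.n_significant,
            "R": summary.n_replicates,
            "alpha": cfg.alpha,
            "median_slope": float(np.median(summary.slopes)) if summary.n_replicates else None,
            "n_skipped": summary.n_skipped,
        },
    )
    run.log.append(
        f"pgls: {summary.n_significant}/{summary.n_replicates} replicates significant at {cfg.alpha}"
    )


def _stage_hypothesis(run: _Run) -> None:
    cfg = run.config
    tree, _, records, _, _ = run.load_bundle()
    sub, vec = run.matched_trait_vectors(tree, records)
    C = phylo_covariance(sub)
    from .pgls import phylogenetic_residuals

    ry = phylogenetic_residuals(vec[TRAIT_Y], vec[TRAIT_SIZE], C)
    rx = phylogenetic_residuals(vec[TRAIT_X], vec[TRAIT_SIZE], C)
    studies = hypothesis_study(sub, rx, ry, S=cfg.S, seed=cfg.stage_seed("hypothesis"))
    rows = []
    for hyp, st in studies.items():
        for s in range(st.n_sim):
            rows.append({"hypothesis": hyp, "sim": s, "slope": st.slopes[s], "pvalue": st.pvalues[s]})
    pd.DataFrame(rows).to_csv(run.path("hypothesis_sims.tsv"), sep="\t", index=False)
    run.write_json(
        "hypothesis_summary.json",
        {
            hyp: {
                "observed_slope": st.observed_slope,
                "observed_pvalue": st.observed_pvalue,
                "observed_quantile": st.observed_quantile,
                "inside_central_95": st.observed_in_central(),
                "S": st.n_sim,
            }
            for hyp, st in studies.items()
        },
    )
    run.log.append(
        "hypothesis: observed slope {:.3f} at quantile {:.3f} (null) / {:.3f} (strong)".format(
            studies["null_slope_0"].observed_slope,
            studies["null_slope_0"].observed_quantile,
            studies["strong_slope_-1"].observed_quantile,
        )
    )


def _stage_asr(run: _Run) -> None:
    cfg = run.config
    tree, posterior, _, modes, _ = run.load_bundle()
    state_records = modes.rename(columns={modes.columns[0]: "taxon", modes.columns[1]: "state"})
    summary = replicate_asr(
        posterior,
        state_records,
        R=cfg.asr_replicates,
        structure=cfg.asr_structure,
        seed=cfg.stage_seed("asr"),
    )
    summary.to_csv(run.path("asr_clade_support.tsv"), sep="\t", index=False)
    tip_states = dict(zip(state_records["taxon"], state_records["state"]))
    model = fit_mk(tree, tip_states, structure=cfg.asr_structure, seed=cfg.stage_seed("asr"))
    asr = marginal_asr(tree, tip_states, model)
    painting = {i: asr.map_states[i] for i in asr.map_states}
    with open(run.path("asr_map.nwk"), "w") as fh:
        fh.write(write_annotated_newick(tree, {i: s for i, s in painting.items() if i != tree.root.index}, key="mode"))
    marg = pd.DataFrame(
        [
            {"node": i, **{s: p[j] for j, s in enumerate(model.states)}}
            for i, p in sorted(asr.marginals.items())
        ]
    )
    marg.to_csv(run.path("asr_marginals.tsv"), sep="\t", index=False)
    transitions = count_state_transitions(tree, painting)
    run.write_json(
        "asr_summary.json",
        {
            "root_map_state": asr.map_states[tree.root.index],
            "root_marginal": {
                s: float(asr.marginals[tree.root.index][j]) for j, s in enumerate(model.states)
            },
            "map_transitions": {f"{a}->{b}": n for (a, b), n in sorted(transitions.items())},
            "loglik": model.loglik,
            "aicc": model.aicc,
            "structure": model.structure,
        },
    )
    run.log.append(f"asr: root MAP state {asr.map_states[tree.root.index]}")


def _stage_regimes(run: _Run) -> None:
    cfg = run.config
    tree, _, records, _, rates = run.load_bundle()
    ids = branch_id_map(tree)
    by_id = {v: k for k, v in ids.items()}
    rate_map = dict(zip(rates["branch"], rates["rate"]))
    missing = [bid for bid in ids.values() if bid not in rate_map]
    if missing:
        raise StageError(f"rates table missing branches: {missing[:5]}")
    painting_by_id = classify_rate_regimes(
        {bid: rate_map[bid] for bid in ids.values()}, threshold=cfg.rate_threshold
    )
    painting = {by_id[bid]: lab for bid, lab in painting_by_id.items()}
    origins, reversals = count_regime_origins(tree, painting)
    with open(run.path("regime_painting.nwk"), "w") as fh:
        fh.write(write_annotated_newick(tree, painting, key="regime"))
    # model comparison on the species-level ovariole trait
    kept, _ = filter_records(records)
    agg, _ = aggregate_by_rank(kept, "species", TRAIT_X)
    series = agg.set_index("taxon")["log10_value"]
    taxa = sorted(set(tree.tip_labels) & set(series.index))
    sub = prune_and_match(tree, taxa)
    x = series.loc[sub.tip_labels].to_numpy()
    sub_paint = _transfer_painting(tree, painting, sub)
    fits = [
        fit_regime_model(sub, x, model="BM1"),
        fit_regime_model(sub, x, sub_paint, model="BMS"),
    ]
    table, decision = compare_models([fits], delta=cfg.delta_aicc)
    table.to_csv(run.path("model_comparison.tsv"), sep="\t", index=False)
    try:
        corr = rate_state_correlation(sub, sub_paint, x, seed=cfg.stage_seed("regimes"))
    except RegimeError as exc:
        # a realization may leave one regime with too few tips to compare
        corr = {"skipped": str(exc)}
    run.write_json(
        "regimes_summary.json",
        {
            "origins_of_invariance": origins,
            "reversals": reversals,
            "threshold": cfg.rate_threshold,
            "winner": decision,
            "delta_aicc_bm1_minus_bms": float(fits[0].aicc - fits[1].aicc),
            "rate_state_correlation": corr,
        },
    )
    run.log.append(
        f"regimes: {origins} origins of invariance, {reversals} reversals; winner {decision}"
    )


def _transfer_painting(tree, painting, sub):
    """Carry a branch painting onto a pruned tree via clade identity.

    A pruned branch may merge several original branches; it takes the label
    of the deepest surviving original branch (nearest the root), matching
    the regime in force where the lineage diverged.
    """
    sub_sets = sub.clade_tip_sets()
    kept_tips = frozenset(sub.tip_labels)
    full_sets = tree.clade_tip_sets()
    # for each restricted clade, remember the original branch with the
    # largest unrestricted clade (the deepest merged branch)
    best_by_restricted: dict[frozenset, int] = {}
    for i, s in full_sets.items():
        if i == tree.root.index or i not in painting:
            continue
        restricted = s & kept_tips
        if not restricted:
            continue
        cur = best_by_restricted.get(restricted)
        if cur is None or len(full_sets[i]) > len(full_sets[cur]):
            best_by_restricted[restricted] = i
    out = {}
    for node in sub.nodes:
        if node.is_root:
            if tree.root.index in painting:
                out[node.index] = painting[tree.root.index]
            continue
        best = best_by_restricted.get(sub_sets[node.index])
        if best is None:
            raise StageError("could not transfer painting onto pruned tree")
        out[node.index] = painting[best]
    return out


def _stage_adequacy(run: _Run) -> None:
    cfg = run.config
    tree, _, records, _, _ = run.load_bundle()
    kept, _ = filter_records(records)
    agg, _ = aggregate_by_rank(kept, "species", TRAIT_X)
    series = agg.set_index("taxon")["log10_value"]
    taxa = sorted(set(tree.tip_labels) & set(series.index))
    sub = prune_and_match(tree, taxa)
    x = series.loc[sub.tip_labels].to_numpy()
    fitted = fit_bm_tree(sub.resolve_polytomies(), x)
    pvals = adequacy_bootstrap(
        sub, x, fitted, n_sim=cfg.adequacy_sims, seed=cfg.stage_seed("adequacy")
    )
    run.write_json(
        "adequacy.json",
        {"pvalues": pvals, "n_sim": cfg.adequacy_sims, "sigma2": fitted.sigma2, "z0": fitted.z0},
    )
    run.log.append(
        "adequacy: min bootstrap p {:.3f}".format(min(pvals.values()))
    )


def _stage_report(run: _Run) -> None:
    run.log.append(f"report: {len(run.outputs)} output files")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "tables": _stage_tables,
    "pgls": _stage_pgls,
    "hypothesis": _stage_hypothesis,
    "asr": _stage_asr,
    "regimes": _stage_regimes,
    "adequacy": _stage_adequacy,
    "report": _stage_report,
}
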