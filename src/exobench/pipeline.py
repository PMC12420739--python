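"""End-to-end orchestration: model -> scenarios -> profiles -> enrichment ->
evaluation -> pathway properties -> TSV reports, driven by one config.

All stochastic stages derive their seeds from the single config seed (the
wild-type sample set is produced once and shared by every knockout, each
knockout sampler gets a stable per-pathway seed), so a run is reproducible
from (model, config, seed) alone.  The input model file is never modified;
knockouts are in-memory copies.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import enrich, evaluate, model as model_core, properties, simulate

__all__ = ["RunConfig", "validate_config", "run_benchmark", "load_model"]

log = logging.getLogger("exobench")

METHODS = ("ora", "gsea_signed", "gsea_absolute")


@dataclass
class RunConfig:
    """All benchmark constants in one place.

    Defaults are the benchmark's standard conditions: a 10% biomass floor
    for knockout viability, p <= 0.05 for both differential abundance and
    enrichment (uncorrected), at least 3 DA metabolites for an ORA-testable
    pathway, 1000 GSEA permutations, and |z| >= 2 for the uniqueness score.
    """

    model_path: str = ""
    side_compound_path: str | None = None
    category_path: str | None = None
    biomass_id: str = model_core.DEFAULT_BIOMASS_ID
    floor_fraction: float = 0.1
    n_samples: int = 5000
    thinning: int = 100
    seed: int = 42
    alpha_da: float = 0.05
    min_hits: int = 3
    alpha_enrich: float = 0.05
    n_perm: int = 1000
    z_thr: float = 2.0
    ora_da_stat: str = "signed"
    methods: tuple[str, ...] = METHODS
    out_dir: str = "exobench_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return validate_config(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


_RANGES = {
    "floor_fraction": (0.0, 1.0),
    "alpha_da": (0.0, 1.0),
    "alpha_enrich": (0.0, 1.0),
    "z_thr": (0.0, float("inf")),
}


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults, check ranges and report all problems at once."""
    known = set(RunConfig.__dataclass_fields__)
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.methods, list):
        cfg.methods = tuple(cfg.methods)
    for key, (lo, hi) in _RANGES.items():
        v = getattr(cfg, key)
        if not (lo <= v <= hi):
            errors.append(f"{key} = {v} outside [{lo}, {hi}]")
    if cfg.n_samples < 2:
        errors.append("n_samples must be >= 2")
    if cfg.n_perm < 1:
        errors.append("n_perm must be >= 1")
    if cfg.min_hits < 1:
        errors.append("min_hits must be >= 1")
    bad = set(cfg.methods) - set(METHODS)
    if bad:
        errors.append(f"unknown methods: {sorted(bad)}")
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return cfg


def load_model(config: RunConfig) -> model_core.MetabolicModel:
    return model_core.load_sbml(
        config.model_path,
        config.side_compound_path,
        config.category_path,
        biomass_id=config.biomass_id,
    )


def prepare(model: model_core.MetabolicModel):
    """Prune blocked reactions and derive sets and background."""
    blocked = model_core.find_blocked_reactions(model)
    pruned = model_core.prune_model(model, blocked)
    sets_full = model_core.reactions_to_metabolite_sets(pruned, include_side=True)
    sets_no_side = model_core.reactions_to_metabolite_sets(pruned, include_side=False)
    background = model_core.exchangeable_background(pruned)
    return pruned, sets_full, sets_no_side, background


def _enrich_profile(profile, sets_full, background, config: RunConfig):
    results = {}
    if "ora" in config.methods:
        results["ora"] = enrich.run_ora(
            profile, sets_full, background,
            alpha_da=config.alpha_da, min_hits=config.min_hits,
            da_stat=config.ora_da_stat,
        )
    for method, mode in (("gsea_signed", "signed"), ("gsea_absolute", "absolute")):
        if method in config.methods:
            results[method] = enrich.run_gsea(
                profile, sets_full, mode=mode, n_perm=config.n_perm,
                seed=simulate.scenario_seed(config.seed + 1, f"{method}:{profile.scenario}"),
            )
    return results


def run_benchmark(config: RunConfig, model=None, wt_samples=None) -> dict:
    """Run the whole benchmark and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory artefacts (pruned model, ledger,
    profiles, enrichment results, outcomes, summaries, properties table,
    comparison table, PCA) for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = load_model(config)
    pruned, sets_full, sets_no_side, background = prepare(model)
    log.info("model prepared: %d pathways (%d blocked), background %d",
             len(pruned.pathway_reactions), len(pruned.blocked_pathways),
             len(background))

    profiles, ledger = simulate.run_all_scenarios(
        pruned, n_samples=config.n_samples, seed=config.seed,
        floor_fraction=config.floor_fraction, thinning=config.thinning,
        wt_samples=wt_samples,
    )
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    ledger.to_csv(out / "scenario_ledger.tsv", sep="\t", index=False)
    _write_profiles(profiles, out / "profiles.tsv")
    model_core.write_gmt(sets_full, out / "pathway_sets.gmt")
    (out / "background.txt").write_text(
        "".join(f"{m}\n" for m in sorted(background)))

    # candidate universe for enrichment and FP/TN counting: the functional,
    # non-miscellaneous pathways (the ones that appear as scenarios)
    functional = frozenset(profiles)
    cand_full = model_core.MetabolitePathwaySets(
        {p: sets_full[p] for p in functional}, include_side=True)

    enrichment_rows = {m: [] for m in config.methods}
    outcomes: dict[str, list] = {m: [] for m in config.methods}
    for pid in sorted(profiles):
        results = _enrich_profile(profiles[pid], cand_full, background, config)
        for method, res in results.items():
            for pw, rec in sorted(res.per_pathway.items()):
                enrichment_rows[method].append({
                    "scenario": pid, "pathway": pw, "testable": rec.testable,
                    "p_value": rec.p_value, "es": rec.es, "n_hits": rec.n_hits,
                })
            outcomes[method].append(
                evaluate.classify_scenario(pid, res, alpha=config.alpha_enrich))

    summaries = []
    labels: dict[str, dict[str, str]] = {}
    outcome_rows = []
    for method in config.methods:
        if not outcomes[method]:
            continue
        pd.DataFrame(enrichment_rows[method]).to_csv(
            out / f"enrichment_{method}.tsv", sep="\t", index=False)
        summary = evaluate.aggregate(outcomes[method])
        cond = evaluate.conditional_tpr(outcomes[method])
        summaries.append({**asdict(summary), "conditional_tpr": cond})
        labels[method] = {o.scenario: o.target_label for o in outcomes[method]
                          if o.target_label in ("TP", "FN")}
        outcome_rows += [asdict(o) for o in outcomes[method]]
    summary_table = pd.DataFrame(summaries)
    summary_table.to_csv(out / "evaluation_summary.tsv", sep="\t", index=False)
    pd.DataFrame(outcome_rows).to_csv(out / "scenario_outcomes.tsv",
                                      sep="\t", index=False)

    # graph and metrics over the biologically meaningful pathways only
    # (miscellaneous transport/artificial pathways would dominate overlap)
    misc = pruned.miscellaneous_pathways
    graph_sets = model_core.MetabolitePathwaySets(
        {p: s for p, s in sets_no_side.items() if p not in misc},
        include_side=False)
    props = properties.properties_table(
        sets_full, graph_sets, background, profiles, thr=config.z_thr)
    props.to_csv(out / "pathway_properties.tsv", sep="\t")
    graph = properties.build_pathway_graph(graph_sets)
    nx.write_graphml(graph, out / "pathway_graph.graphml")
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in graph.edges(data=True)],
        columns=["pathway_a", "pathway_b", "shared_metabolites"])
    edges.to_csv(out / "pathway_graph_edges.tsv", sep="\t", index=False)

    comparison = properties.compare_tp_fn(props, labels)
    comparison.to_csv(out / "tp_fn_comparisons.tsv", sep="\t", index=False)

    dispersions = []
    for pid in sorted(profiles):
        rec = properties.ko_zscore_dispersion(pid, profiles[pid], sets_full)
        if rec is not None:
            dispersions.append({"scenario": pid, "sd": rec["sd"],
                                "n_metabolites": len(rec["zscores"]),
                                "n_outliers": len(rec["outliers"])})
    pd.DataFrame(dispersions).to_csv(out / "ko_dispersion.tsv", sep="\t",
                                     index=False)

    pca_out = None
    try:
        coords, loadings, explained = properties.pathway_pca(props)
        coords.to_csv(out / "pca_coordinates.tsv", sep="\t")
        loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        pca_out = (coords, loadings, explained)
    except ValueError as err:
        log.warning("PCA skipped: %s", err)

    (out / "run_info.json").write_text(json.dumps(stamp, indent=2))
    return {
        "model": pruned,
        "background": background,
        "sets_full": sets_full,
        "sets_no_side": sets_no_side,
        "ledger": ledger,
        "profiles": profiles,
        "outcomes": outcomes,
        "summaries": summary_table,
        "properties": props,
        "comparisons": comparison,
        "pca": pca_out,
    }


def _write_profiles(profiles, path) -> None:
    rows = [
        {"scenario": pid, "metabolite": met, "z": z}
        for pid in sorted(profiles)
        for met, z in sorted(profiles[pid].zscores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
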