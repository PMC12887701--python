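"""End-to-end orchestration of the synthetic demonstration pipeline.

Stages run in dependency order:
    synthio -> mr_engine -> network_integration -> enrichment ->
    pathway_ml -> gene_scoring -> chem_network -> invivo_de

Every stage writes plain-text outputs into the run directory and the
manifest records per-stage status, output hashes and the seeds used, so a
rerun with the same config is byte-identical (manifest timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import chem, enrichment, invivo, io, ml, mr, network, scoring, synthio

log = logging.getLogger(__name__)

STAGES = ["synthio", "mr_engine", "network_integration", "enrichment",
          "pathway_ml", "gene_scoring", "chem_network", "invivo_de"]


@dataclass
class RunConfig:
    """All pipeline thresholds (paper defaults) plus synthetic sizes."""

    seed: int = 0
    # mr_engine
    p_thresh: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 1000.0
    qualify_alpha: float = 0.05
    # network_integration
    walk_steps: int = 4
    flank_kb: float = 50.0
    # enrichment
    fdr_thresh: float = 0.05
    # pathway_ml
    cv_folds: int = 10
    f_alpha: float = 0.01
    top_models: int = 5
    rf_estimators: int = 100
    # gene_scoring
    top_frac: float = 0.01
    # chem_network
    top_hubs: int = 5
    # invivo_de
    deg_p: float = 0.05
    deg_lfc: float = 1.0
    # synthetic sizes
    n_trait_modules: int = 2
    traits_per_module: int = 3
    intra_edge_prob: float = 0.9
    inter_edge_prob: float = 0.0
    effect_size: float = 0.25
    n_instruments: int = 15
    gwas_n: int = 100_000
    n_genes: int = 300
    n_gene_sets: int = 10
    gene_set_size: int = 15
    n_expr_datasets: int = 2
    expr_cases: int = 40
    expr_controls: int = 40
    expr_effect_shift: float = 2.0
    n_chemicals: int = 25
    hub_degree: int = 12
    invivo_genes: int = 400
    invivo_n_per_group: int = 3
    invivo_n_degs: int = 40
    stages: list[str] = field(default_factory=lambda: list(STAGES))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all enabled stages; return (and write) the run manifest.

    A stage failure is recorded in the manifest and later stages are
    skipped; a stage whose inputs were produced by a disabled stage is
    recorded as "skipped: missing input".
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}, "outputs": {}}
    state: dict = {}
    failed = False
    for stage in STAGES:
        entry: dict = {"status": "pending"}
        manifest["stages"][stage] = entry
        if failed:
            entry["status"] = "skipped: upstream failure"
            continue
        if stage not in config.stages:
            entry["status"] = "disabled"
            continue
        runner = globals()[f"_stage_{stage}"]
        missing = [dep for dep in _STAGE_DEPS[stage] if dep not in state]
        if missing:
            entry["status"] = f"skipped: missing input from {missing[0]}"
            continue
        t0 = time.time()
        try:
            outputs = runner(config, out, state)
            entry["status"] = "completed"
            entry["outputs"] = sorted(outputs)
            for rel in outputs:
                manifest["outputs"][rel] = _sha256(out / rel)
        except Exception as exc:  # noqa: BLE001 - manifest records the failure
            log.error("stage %s failed: %s", stage, exc)
            entry["status"] = f"failed: {exc}"
            entry["traceback"] = traceback.format_exc()
            failed = True
        entry["seconds"] = round(time.time() - t0, 3)

    manifest["completed"] = sum(
        1 for s in manifest["stages"].values() if s["status"] == "completed")
    io.write_json(manifest, out / "manifest.json")
    return manifest


_STAGE_DEPS = {
    "synthio": [],
    "mr_engine": ["panel"],
    "network_integration": ["associations"],
    "enrichment": ["mapped_genes", "gene_sets"],
    "pathway_ml": ["enriched_sets", "expressions"],
    "gene_scoring": ["evaluations"],
    "chem_network": ["retained_genes", "chem_edges"],
    "invivo_de": ["invivo_matrix", "chem_edges"],
}


def _stage_synthio(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "synthio"
    d.mkdir(exist_ok=True)
    modules = tuple(
        tuple(f"M{m}T{t}" for t in range(cfg.traits_per_module))
        for m in range(cfg.n_trait_modules))
    gwas = synthio.GwasSimConfig(
        n_instruments=cfg.n_instruments, n_exposure=cfg.gwas_n,
        n_outcome=cfg.gwas_n, seed=cfg.seed)
    panel = synthio.simulate_trait_panel(synthio.TraitPanelSpec(
        modules=modules, intra_edge_prob=cfg.intra_edge_prob,
        inter_edge_prob=cfg.inter_edge_prob, effect_size=cfg.effect_size,
        gwas=gwas, seed=cfg.seed))
    state["panel"] = panel
    io.write_json(panel.truth(), d / "panel_truth.json")

    gene_sets = synthio.make_gene_sets(
        cfg.n_genes, cfg.n_gene_sets, cfg.gene_set_size, seed=cfg.seed)
    # planted set: the genes the simulated instruments map to, padded to size
    mapped = synthio.default_gene_names(cfg.n_instruments)
    pad = [g for g in synthio.default_gene_names(cfg.n_genes) if g not in mapped]
    planted = enrichment.GeneSet(
        name="SET_PLANTED", domain="BP",
        members=frozenset(mapped + pad[:max(0, cfg.gene_set_size - len(mapped))]))
    gene_sets = [planted] + gene_sets
    state["gene_sets"] = gene_sets
    io.write_gmt(gene_sets, d / "collection.gmt")

    annotation = synthio.make_annotation(cfg.n_genes)
    state["annotation"] = annotation
    io.write_bed(annotation, d / "annotation.bed")

    expressions = {}
    for j in range(cfg.n_expr_datasets):
        name = f"DS{j}"
        spec = synthio.ExprSimSpec(
            n_cases=cfg.expr_cases, n_controls=cfg.expr_controls,
            n_genes=cfg.n_genes, active_sets=("SET_PLANTED",),
            effect_shift=cfg.expr_effect_shift, seed=cfg.seed + 1000 + j)
        matrix, labels, truth = synthio.simulate_expression(spec, gene_sets)
        expressions[name] = (matrix, labels, truth)
        io.write_expression(matrix, labels, d / name)
        io.write_json(truth, d / f"{name}.truth.json")
    state["expressions"] = expressions

    pool = sorted(planted.members)
    # the planted hub targets the whole planted pathway so the downstream
    # prioritized genes are guaranteed to intersect its target set
    hub_spec = {"hub_chem": len(pool)}
    edges, chem_truth = synthio.simulate_chem_edges(
        cfg.n_chemicals, cfg.n_genes, hub_spec, seed=cfg.seed,
        hub_target_pool=pool)
    state["chem_edges"] = edges
    io.write_chem_edges(edges, d / "chem_edges.tsv")
    io.write_json(chem_truth, d / "chem_truth.json")

    rng = synthio.split_rng(cfg.seed, "invivo_spec")
    genes = synthio.default_gene_names(cfg.invivo_genes)
    picked = rng.choice(genes, size=cfg.invivo_n_degs, replace=False)
    signs = rng.choice([-1.0, 1.0], size=cfg.invivo_n_degs)
    deg_spec = {g: float(2.0 * s) for g, s in zip(picked, signs)}
    matrix, groups, truth = synthio.simulate_invivo(
        cfg.invivo_genes, cfg.invivo_n_per_group, deg_spec, seed=cfg.seed)
    state["invivo_matrix"] = (matrix, groups)
    matrix.to_csv(d / "invivo.expr.tsv", sep="\t", index_label="gene")
    groups.rename("group").to_frame().to_csv(
        d / "invivo.groups.tsv", sep="\t", index_label="sample")
    io.write_json(truth, d / "invivo_truth.json")

    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_mr_engine(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "mr"
    d.mkdir(exist_ok=True)
    panel = state["panel"]
    associations = []
    rows = []
    for (exp_name, out_name), (exp_df, out_df, ld) in panel.datasets.items():
        assoc = mr.run_mr(exp_df, out_df, ld,
                          exposure_name=exp_name, outcome_name=out_name,
                          direction="forward", source="panel",
                          p_thresh=cfg.p_thresh, r2_thresh=cfg.clump_r2,
                          window_kb=cfg.clump_window_kb)
        if assoc is None:
            continue
        associations.append(assoc)
        rows.append(assoc.to_dict())
    state["associations"] = associations
    est = pd.DataFrame(rows).drop(columns=["instruments"], errors="ignore")
    est.to_csv(d / "estimates.tsv", sep="\t", index=False)
    io.write_json([a.to_dict() for a in associations], d / "associations.json")
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_network_integration(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "network"
    d.mkdir(exist_ok=True)
    associations = state["associations"]
    graph = network.build_trait_graph(associations)
    if graph.number_of_nodes() == 0:
        raise RuntimeError("no qualified forward associations: empty trait graph")
    modules = network.detect_modules(graph, walk_steps=cfg.walk_steps, seed=cfg.seed)
    core = network.core_relationships(graph, modules)
    kept_fwd, _ = network.filter_bidirectional(associations, [], core)
    freq = network.snp_frequency(kept_fwd)

    panel = state["panel"]
    snp_pos = []
    seen = set()
    for (exp_name, _), (exp_df, _, _) in panel.datasets.items():
        for _, r in exp_df.iterrows():
            if r["snp"] in freq["snp"].values and r["snp"] not in seen:
                seen.add(r["snp"])
                snp_pos.append({"snp": r["snp"], "chr": r["chr"], "pos": r["pos"]})
    snp_df = pd.DataFrame(snp_pos, columns=["snp", "chr", "pos"])
    mapping = network.map_genes(snp_df, state["annotation"], flank_kb=cfg.flank_kb)
    mapped = sorted(mapping["gene"].dropna().unique().tolist())
    state["mapped_genes"] = mapped

    pd.DataFrame([{"trait": t, "module": m} for t, m in sorted(modules.items())]) \
        .to_csv(d / "modules.tsv", sep="\t", index=False)
    pd.DataFrame(sorted([c.exposure, c.outcome, c.module_id] for c in core),
                 columns=["exposure", "outcome", "module"]) \
        .to_csv(d / "core_relationships.tsv", sep="\t", index=False)
    freq.to_csv(d / "snp_frequency.tsv", sep="\t", index=False)
    mapping.to_csv(d / "snp_genes.tsv", sep="\t", index=False)
    edge_rows = [{"exposure": u, "outcome": v, "weight": w["weight"]}
                 for u, v, w in graph.edges(data=True)]
    pd.DataFrame(edge_rows, columns=["exposure", "outcome", "weight"]) \
        .to_csv(d / "trait_edges.tsv", sep="\t", index=False)
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_enrichment(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "enrichment"
    d.mkdir(exist_ok=True)
    table = enrichment.enrich(set(state["mapped_genes"]), state["gene_sets"],
                              fdr_thresh=cfg.fdr_thresh)
    table.to_csv(d / "enrichment.tsv", sep="\t", index=False)
    significant = table.loc[table["significant"], "set_name"].tolist()
    state["enriched_sets"] = significant
    io.write_json({"significant_sets": significant}, d / "significant.json")
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_pathway_ml(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "ml"
    d.mkdir(exist_ok=True)
    sets_by_name = {s.name: s for s in state["gene_sets"]}
    enriched = state["enriched_sets"]
    if not enriched:
        raise RuntimeError("no significantly enriched gene sets for ML stage")
    evaluations = []
    metric_rows = []
    for ds_name, (matrix, labels, _) in state["expressions"].items():
        for set_name in enriched:
            genes = sorted(sets_by_name[set_name].members)
            ev = ml.evaluate_pathway(
                matrix, labels, genes, dataset=ds_name, pathway=set_name,
                models=ml.default_model_suite(cfg.seed, cfg.rf_estimators),
                k=cfg.cv_folds, seed=cfg.seed, top_n=cfg.top_models)
            evaluations.append(ev)
            for m in ev.metrics:
                metric_rows.append({"dataset": ds_name, "pathway": set_name,
                                    "model": m.model, **m.as_dict(),
                                    "composite_rank": float(ev.composite[m.model])})
    state["evaluations"] = evaluations
    pd.DataFrame(metric_rows).to_csv(d / "metrics.tsv", sep="\t", index=False)
    imp_rows = []
    for ev in evaluations:
        for name, vec in ev.importances.items():
            for gene, v in vec.importances.items():
                imp_rows.append({"dataset": ev.dataset, "pathway": ev.pathway,
                                 "model": name, "method": vec.method,
                                 "gene": gene, "importance": v})
    pd.DataFrame(imp_rows).to_csv(d / "importance.tsv", sep="\t", index=False)
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_gene_scoring(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "scores"
    d.mkdir(exist_ok=True)
    records = scoring.build_score_records(state["evaluations"])
    prioritized = scoring.gene_prioritization(records, top_frac=cfg.top_frac)
    dss = scoring.dataset_specific_score(records)
    hgs = scoring.holistic_score(records)
    state["score_records"] = records
    state["retained_genes"] = sorted(
        {g for genes in scoring.retained_genes(prioritized).values() for g in genes})
    prioritized.to_csv(d / "gene_prioritization.tsv", sep="\t", index=False)
    dss.to_csv(d / "dataset_specific.tsv", sep="\t", index=False)
    hgs.to_csv(d / "holistic.tsv", sep="\t", index=False)
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_chem_network(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "chem"
    d.mkdir(exist_ok=True)
    edges = state["chem_edges"]
    prioritized = set(state["retained_genes"])
    hubs = chem.hub_chemicals(edges, prioritized, top_n=cfg.top_hubs)
    hub_df = pd.DataFrame([{"chemical": h.chemical, "degree": h.degree,
                            "rank": h.rank} for h in hubs])
    hub_df.to_csv(d / "hubs.tsv", sep="\t", index=False)

    hub_names = {h.chemical for h in hubs}
    sub = edges[edges["chemical_name"].isin(hub_names)]
    if len(sub):
        comms = chem.communities(sub, seed=cfg.seed)
        pd.DataFrame(sorted(comms.items()), columns=["node", "community"]) \
            .to_csv(d / "communities.tsv", sep="\t", index=False)
    graph, conv = chem.integrate_bipartite({"demo": (hubs, edges)})
    conv.to_csv(d / "convergence.tsv", sep="\t", index=False)
    edge_rows = [{"chemical": u if graph.nodes[u]["kind"] == "chemical" else v,
                  "gene": v if graph.nodes[u]["kind"] == "chemical" else u,
                  "diseases": ",".join(sorted(data["diseases"]))}
                 for u, v, data in graph.edges(data=True)]
    pd.DataFrame(edge_rows, columns=["chemical", "gene", "diseases"]) \
        .to_csv(d / "integrated_edges.tsv", sep="\t", index=False)
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]


def _stage_invivo_de(cfg: RunConfig, out: Path, state: dict) -> list[str]:
    d = out / "invivo"
    d.mkdir(exist_ok=True)
    matrix, groups = state["invivo_matrix"]
    table = invivo.differential_expression(matrix, groups)
    degs = invivo.call_degs(table, p_thresh=cfg.deg_p, lfc_thresh=cfg.deg_lfc)
    conn = chem.gene_connectivity(state["chem_edges"], genes=degs["degs"])
    ranking = invivo.comprehensive_score(degs["degs"], conn, table)
    table.to_csv(d / "de.tsv", sep="\t", index=False)
    io.write_json({"n_up": degs["n_up"], "n_down": degs["n_down"],
                   "degs": degs["degs"]}, d / "degs.json")
    ranking.to_csv(d / "target_ranking.tsv", sep="\t", index=False)
    return [str(p.relative_to(out)) for p in sorted(d.iterdir())]
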