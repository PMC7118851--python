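"""End-to-end orchestration: score genes, search modules, dual-evaluate,
measure centrality, enrich, and intersect with drug targets — writing every
stage's output plus a manifest of file hashes so a rerun can be verified
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import dms, drugs, dual_eval, enrichment, gene_scoring, io_formats, metrics

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Effective configuration of a full pipeline run.

    Input paths have no defaults; everything else does.  The resolved config
    is written next to the outputs as ``config.resolved.toml``.
    """

    network: str
    regions: str
    gwas1: str
    gwas2: str
    gmt: str
    drugs: str
    out: str
    window_bp: int = 50_000
    ld: str = "identity"  # or "block:RHO"
    method: str = "imhof"
    r: float = 0.1
    d: int = 1
    n_random: int = 100_000
    rng_seed: int = 42
    top_fraction: float = 0.01
    top_n_merge: int = 10
    disc_quantile: float = 0.99
    eval_quantile: float = 0.95
    top_per_namespace: int = 5
    min_term: int = 2
    max_term: int = 500
    term_size_limit: int | None = None
    central_threshold: float = 0.15

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        table = data.get("run", data)
        table.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(table) - known
        if unknown:
            from .errors import ConfigError

            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**table)

    def ld_provider(self) -> gene_scoring.LdProvider:
        if self.ld == "identity":
            return gene_scoring.identity_ld
        if self.ld.startswith("block:"):
            return gene_scoring.block_ld(float(self.ld.split(":", 1)[1]))
        from .errors import ConfigError

        raise ConfigError(f"unknown LD spec {self.ld!r}: use 'identity' or 'block:RHO'")

    def search_params(self) -> dms.SearchParams:
        return dms.SearchParams(
            r=self.r, d=self.d, n_random=self.n_random, rng_seed=self.rng_seed
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _write_resolved_config(config: RunConfig, path: Path) -> None:
    from .simulate import _toml_value

    with open(path, "w") as fh:
        fh.write("[run]\n")
        for f in dataclasses.fields(config):
            value = getattr(config, f.name)
            if value is None:
                continue
            fh.write(f"{f.name} = {_toml_value(value)}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Stage order: score-genes (x2 cohorts) -> dense module search (x2) ->
    dual evaluation (cohort 1 = discovery) -> betweenness on the merged
    significant network -> gene-set enrichment of the merged gene list ->
    drug-target overlap against both cohorts' top-1% module lists.
    """
    for field in ("network", "regions", "gwas1", "gwas2", "gmt", "drugs"):
        path = Path(getattr(config, field))
        if not path.exists():
            from .errors import InputError

            raise InputError(f"input file for {field!r} not found: {path}")

    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    t0 = time.time()

    def stage(name: str) -> None:
        logger.info("[%7.2fs] stage %s", time.time() - t0, name)

    regions = io_formats.read_gene_regions(config.regions)
    edge_list = io_formats.read_network(config.network)
    params = config.search_params()

    # --- gene scoring, one table per cohort
    scores = {}
    for i, gwas_path in ((1, config.gwas1), (2, config.gwas2)):
        stage(f"score-genes cohort {i}")
        gwas = io_formats.read_gwas(gwas_path)
        scores[i] = gene_scoring.score_genes(
            gwas.records,
            regions,
            ld_provider=config.ld_provider(),
            window_bp=config.window_bp,
            method=config.method,
        )
        outputs[f"scores{i}"] = outdir / f"scores{i}.tsv"
        io_formats.write_gene_scores(scores[i], outputs[f"scores{i}"])

    # --- dense module search per cohort
    graphs, modules = {}, {}
    for i in (1, 2):
        stage(f"dms cohort {i}")
        graphs[i] = dms.build_search_graph(edge_list.edges, scores[i])
        found = dms.search_all(graphs[i], params)
        modules[i], _ = dms.normalize_scores(found, graphs[i], params)
        outputs[f"modules{i}"] = outdir / f"modules{i}.tsv"
        io_formats.write_module_table(modules[i], outputs[f"modules{i}"])

    # --- dual evaluation: cohort 1 discovers, cohort 2 evaluates
    stage("dual-eval")
    records = dual_eval.evaluate_modules(modules[1], scores[2], params)
    records, _thresholds = dual_eval.select_significant(
        records, config.disc_quantile, config.eval_quantile
    )
    outputs["dual_eval"] = outdir / "dual_eval.tsv"
    dual_eval.records_to_frame(records).to_csv(
        outputs["dual_eval"], sep="\t", index=False, float_format="%.12g"
    )
    merged = dual_eval.merge_significant(records, graphs[1])
    if merged.number_of_nodes() == 0:
        # unreplicated run: report the merged top modules of the discovery cohort
        merged = dms.merge_modules(
            dms.rank_and_select(modules[1], top_n=config.top_n_merge), graphs[1]
        )

    # --- centrality
    stage("metrics")
    central_table = metrics.betweenness(merged)
    central_genes = metrics.classify_central(central_table, config.central_threshold)
    central_table["central"] = central_table["gene"].isin(central_genes)
    outputs["centrality"] = outdir / "centrality.tsv"
    central_table.to_csv(
        outputs["centrality"], sep="\t", index=False, float_format="%.12g"
    )
    metrics.attach_betweenness(merged, central_table)
    outputs["merged_graphml"] = outdir / "merged_modules.graphml"
    io_formats.export_network(merged, outputs["merged_graphml"], format="graphml")
    outputs["merged_sif"] = outdir / "merged_modules.sif"
    io_formats.export_network(merged, outputs["merged_sif"], format="sif")

    # --- enrichment of the merged gene list
    stage("enrich")
    collection = io_formats.read_gmt(config.gmt)
    universe = set().union(*(t.genes for t in collection))
    background = (set(scores[1]["gene"]) | set(scores[2]["gene"])) & universe
    query = set(merged.nodes) & background
    if query:
        report = enrichment.enrich_report(
            query,
            collection,
            background,
            top_per_namespace=config.top_per_namespace,
            min_term=config.min_term,
            max_term=config.max_term,
            term_size_limit=config.term_size_limit,
        )
        report = report.copy()
        report["contributing_genes"] = report["contributing_genes"].map(";".join)
    else:
        logger.warning("enrich: no merged gene lies in the annotation universe")
        report = pd.DataFrame(
            columns=["namespace", "term_id", "term_name", "k_overlap", "K_term",
                     "n_query", "N_background", "contributing_genes", "p", "p_adj"]
        )
    outputs["enrichment"] = outdir / "enrichment.tsv"
    report.to_csv(outputs["enrichment"], sep="\t", index=False, float_format="%.12g")

    # --- drug-target overlap against the top-1% lists of both cohorts
    stage("drug-overlap")
    drug_table = io_formats.read_drug_table(config.drugs)
    module_lists = {
        f"cohort{i}_top1pct": dms.rank_and_select(modules[i], config.top_fraction)
        for i in (1, 2)
    }
    hits = drugs.overlap_targets(
        drug_table,
        module_lists,
        {f"cohort{i}": scores[i] for i in (1, 2)},
    )
    outputs["drug_overlap"] = outdir / "drug_overlap.tsv"
    hits.to_csv(outputs["drug_overlap"], sep="\t", index=False, float_format="%.12g")

    # --- manifest + resolved config
    config_path = outdir / "config.resolved.toml"
    _write_resolved_config(config, config_path)
    manifest = {
        "stages": list(outputs),
        "files": {name: _sha256(path) for name, path in outputs.items()},
        "config": str(config_path.name),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    stage("done")
    return manifest
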