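"""Synthetic study generator: every input the pipeline needs, from one seed.

The generator emulates the statistical structure a two-cohort,
network-assisted GWAS analysis assumes:

* a connected scale-free PPI-like network (preferential attachment, m = 2
  edges per new node) on genes G0001...;
* a compact planted module: a connected gene set chosen by seeded BFS whose
  members carry elevated association signal.  The planted latent effect
  s_g ~ Normal(mu, 1) is shared between cohorts with weight sqrt(rho_cohort);
  each cohort adds its own sqrt(1 - rho_cohort)-weighted deviation plus unit
  background noise, and non-planted genes are standard normal.  Association
  p-values are one-sided upper tails p = 1 - Phi(z) throughout, so the chain
  p -> z -> Z_m is exactly coherent (real two-sided GWAS p-values should be
  converted on ingest);
* per-gene SNP-level p-values with equicorrelated within-gene LD, gene
  bodies of 20 kb laid out on 50-gene chromosomes, mostly 200 kb apart (no
  window sharing) with every eighth gene placed 60 kb downstream so that
  overlapping +/- 50 kb windows also occur;
* a GMT collection whose one "planted" 80-gene term contains 7 of the
  planted genes, plus 60 random terms across 3 namespaces;
* a drug->target table of 3 drugs and 4 distinct targets, 2 of them inside
  the planted module.

Every output is a pure function of (config, rng_seed): regenerating with the
same seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .gene_scoring import EXCLUSION_PG
from .io_formats import EdgeList, GeneRegion, GeneSet, GeneSetCollection, SnpRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "make_network",
    "make_regions",
    "plant_module",
    "make_cohort_scores",
    "make_snp_level",
    "make_gene_sets",
    "make_drug_table",
    "write_scenario",
]

GENE_BODY_BP = 20_000
GENE_SPACING_BP = 200_000  # start-to-start far spacing: +/-50 kb windows disjoint
CLOSE_GAP_BP = 60_000  # every 8th gene: windows overlap by 40 kb
GENES_PER_CHROM = 50


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions of the synthetic two-cohort scenario.

    Defaults are the conditions the validation suite runs under: 500 genes on
    a preferential-attachment network, a 10-gene planted module with latent
    mean shift mu = 2.5 (planted gene-level p-values of order 1e-2..1e-4),
    cross-cohort sharing rho_cohort = 0.8, and 10 equicorrelated SNPs per
    gene.
    """

    n_genes: int = 500
    network_model: str = "scale_free"  # or "erdos_renyi"
    attach_m: int = 2
    edge_p: float = 0.02
    k_planted: int = 10
    mu: float = 2.5
    rho_cohort: float = 0.8
    snps_per_gene: int = 10
    ld_rho: float = 0.0
    rng_seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise DomainError(f"n_genes must be >= 10, got {self.n_genes}")
        if not 1 <= self.k_planted <= self.n_genes:
            raise DomainError("k_planted must lie in [1, n_genes]")
        if not 0.0 <= self.rho_cohort <= 1.0:
            raise DomainError("rho_cohort must lie in [0, 1]")
        if not abs(self.ld_rho) < 1.0:
            raise DomainError("|ld_rho| must be < 1")
        if self.snps_per_gene < 1:
            raise DomainError("snps_per_gene must be >= 1")
        if self.network_model not in ("scale_free", "erdos_renyi"):
            raise DomainError(f"unknown network model {self.network_model!r}")

    @property
    def genes(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator component
    return np.random.default_rng(np.random.SeedSequence((config.rng_seed, stream)))


def make_network(config: ScenarioConfig) -> EdgeList:
    """Connected simple graph on G0001..; deterministic under the seed."""
    genes = config.genes
    if config.network_model == "scale_free":
        g = nx.barabasi_albert_graph(
            config.n_genes, config.attach_m, seed=int(config.rng_seed)
        )
    else:
        for attempt in range(100):
            g = nx.gnp_random_graph(
                config.n_genes, config.edge_p, seed=int(config.rng_seed) + attempt
            )
            if nx.is_connected(g):
                break
        else:
            raise DomainError(
                f"no connected Erdos-Renyi graph in 100 tries at edge_p={config.edge_p}"
            )
    mapping = {i: genes[i] for i in range(config.n_genes)}
    edges = {
        tuple(sorted((mapping[a], mapping[b]))) for a, b in g.edges() if a != b
    }
    return EdgeList(edges=edges, n_self_loops=0)


def plant_module(network: EdgeList, config: ScenarioConfig) -> set[str]:
    """A connected induced subgraph of size k_planted, by seeded random BFS."""
    g = nx.Graph()
    g.add_edges_from(network.edges)
    if not nx.is_connected(g):
        raise DomainError("plant_module requires a connected network")
    rng = _rng(config, stream=3)
    nodes = sorted(g)
    start = nodes[int(rng.integers(len(nodes)))]
    planted = [start]
    seen = {start}
    queue = [start]
    while queue and len(planted) < config.k_planted:
        node = queue.pop(0)
        neighbors = sorted(set(g.adj[node]) - seen)
        rng.shuffle(neighbors)
        for nb in neighbors:
            if len(planted) >= config.k_planted:
                break
            planted.append(nb)
            seen.add(nb)
            queue.append(nb)
    if len(planted) < config.k_planted:
        raise DomainError("BFS exhausted the graph before reaching k_planted")
    return set(planted)


def _cohort_z(planted: set[str], config: ScenarioConfig) -> dict[int, np.ndarray]:
    """Association z per gene for both cohorts, from one latent draw."""
    genes = config.genes
    is_planted = np.array([g in planted for g in genes])
    kp = int(is_planted.sum())
    rng = _rng(config, stream=7)
    s = rng.normal(config.mu, 1.0, kp)  # shared latent effect of planted genes
    e = rng.normal(0.0, 1.0, (2, kp))  # cohort-specific planted deviation
    bg = rng.normal(0.0, 1.0, (2, len(genes) - kp))  # background gene noise
    out = {}
    for i in (0, 1):
        z = np.empty(len(genes))
        # unit-variance planted mixture: rho_cohort = 1 makes the two cohorts'
        # planted z identical, rho_cohort = 0 makes them independent null draws
        z[is_planted] = (
            np.sqrt(config.rho_cohort) * s
            + np.sqrt(1.0 - config.rho_cohort) * e[i]
        )
        z[~is_planted] = bg[i]
        out[i + 1] = z
    return out


def make_cohort_scores(
    planted: set[str], config: ScenarioConfig, cohort_index: int
) -> pd.DataFrame:
    """Gene score table (gene, p_g, z, excluded) for cohort 1 or 2.

    Both cohorts derive from the same latent draw under one seed, so calling
    with cohort_index 1 and 2 yields the correlated pair.
    """
    if cohort_index not in (1, 2):
        raise DomainError(f"cohort_index must be 1 or 2, got {cohort_index}")
    z = _cohort_z(planted, config)[cohort_index]
    p_g = stats.norm.sf(z)
    return pd.DataFrame(
        {
            "gene": config.genes,
            "n_snps": 0,
            "T": np.nan,
            "p_g": p_g,
            "z": z,
            "excluded": p_g < EXCLUSION_PG,
        }
    )


def make_regions(config: ScenarioConfig) -> list[GeneRegion]:
    """Gene bodies laid out deterministically on synthetic chromosomes."""
    regions = []
    pos = 1_000_000
    for i, gene in enumerate(config.genes):
        chrom_idx, within = divmod(i, GENES_PER_CHROM)
        if within == 0:
            pos = 1_000_000
        elif within % 8 == 0:
            pos = regions[-1].end + CLOSE_GAP_BP  # close pair: windows overlap
        else:
            pos = regions[-1].start + GENE_SPACING_BP
        regions.append(
            GeneRegion(
                gene=gene,
                chrom=str(chrom_idx + 1),
                start=pos,
                end=pos + GENE_BODY_BP - 1,
            )
        )
    return regions


def make_snp_level(
    scores: pd.DataFrame,
    regions: list[GeneRegion],
    config: ScenarioConfig,
    cohort_index: int = 1,
    planted: set[str] | None = None,
) -> list[SnpRecord]:
    """SNP-level p-values whose per-gene aggregation targets the gene signal.

    Per gene, the SNP z-vector is multivariate normal with equicorrelation
    ``ld_rho`` and mean (target signal) / sqrt(m) on each of the m SNPs, so
    that the sum-of-chi-squares chain recovers approximately the gene-level
    signal; SNP p-values are one-sided upper tails.  When ``planted`` is
    given, only planted genes carry a mean shift and every other gene's SNPs
    are exactly null (their gene-level variability then arises from the SNP
    noise itself, keeping the aggregation chain calibrated).  SNP positions
    are uniform over the gene's +/- 45 kb neighbourhood, so close gene pairs
    share SNPs via window overlap while far pairs do not.
    """
    rng = _rng(config, stream=11 + cohort_index)
    z_gene = dict(zip(scores["gene"], scores["z"]))
    if planted is not None:
        z_gene = {g: (z if g in planted else 0.0) for g, z in z_gene.items()}
    m = config.snps_per_gene
    rho = config.ld_rho
    if rho < 0.0:
        raise DomainError("the SNP generator supports equicorrelation ld_rho >= 0 only")
    records = []
    for region in regions:
        lo = max(1, region.start - 45_000)
        hi = region.end + 45_000
        positions = np.sort(rng.integers(lo, hi + 1, size=m))
        common = rng.normal()
        indiv = rng.normal(size=m)
        mean = z_gene.get(region.gene, 0.0) / np.sqrt(m)
        z_snp = mean + np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indiv
        p = stats.norm.sf(z_snp)
        for j in range(m):
            records.append(
                SnpRecord(
                    snp_id=f"rs_{region.gene}_{j + 1}",
                    chrom=region.chrom,
                    pos=int(positions[j]),
                    p=float(np.clip(p[j], 1e-300, 1.0)),
                )
            )
    return records


def make_gene_sets(
    planted: set[str], all_genes: list[str], config: ScenarioConfig
) -> GeneSetCollection:
    """One 80-gene term holding 7 planted genes + 60 random terms, 3 namespaces."""
    rng = _rng(config, stream=17)
    namespaces = ["Molecular Function", "Biological Process", "Cellular Component"]
    planted_sorted = sorted(planted)
    n_in_term = min(7, len(planted_sorted))
    chosen = list(rng.choice(planted_sorted, size=n_in_term, replace=False))
    non_planted = sorted(set(all_genes) - planted)
    n_filler = min(80 - n_in_term, len(non_planted))
    filler = list(rng.choice(non_planted, size=n_filler, replace=False))
    collection: GeneSetCollection = [
        GeneSet(
            term_id="T_PLANTED",
            term_name="Biological Process",
            genes=frozenset(chosen + filler),
        )
    ]
    for t in range(60):
        size = int(rng.integers(10, 201))
        size = min(size, len(non_planted))
        genes = frozenset(rng.choice(non_planted, size=size, replace=False))
        collection.append(
            GeneSet(
                term_id=f"T{t + 1:04d}",
                term_name=namespaces[t % 3],
                genes=genes,
            )
        )
    return collection


def make_drug_table(
    planted: set[str], all_genes: list[str], config: ScenarioConfig
) -> pd.DataFrame:
    """3 drugs, 4 distinct targets, 2 targets inside the planted module."""
    rng = _rng(config, stream=19)
    planted_sorted = sorted(planted)
    non_planted = sorted(set(all_genes) - planted)
    in_module = list(rng.choice(planted_sorted, size=min(2, len(planted_sorted)), replace=False))
    outside = list(rng.choice(non_planted, size=2, replace=False))
    rows = [
        ("drug_alpha", "Alphanib", in_module[0]),
        ("drug_beta", "Betamab", outside[0]),
        ("drug_gamma", "Gammarate", in_module[-1]),
        ("drug_gamma", "Gammarate", outside[1]),
    ]
    return pd.DataFrame(rows, columns=["drug", "product", "target_gene"])


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full scenario; returns the path of every file."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    network = make_network(config)
    planted = plant_module(network, config)
    regions = make_regions(config)
    paths: dict[str, Path] = {}

    paths["network"] = outdir / "network.tsv"
    with open(paths["network"], "w") as fh:
        for a, b in sorted(network.edges):
            fh.write(f"{a}\t{b}\n")

    paths["regions"] = outdir / "regions.tsv"
    pd.DataFrame(
        [(r.gene, r.chrom, r.start, r.end) for r in regions],
        columns=["gene", "chrom", "start", "end"],
    ).to_csv(paths["regions"], sep="\t", index=False)

    for i in (1, 2):
        scores = make_cohort_scores(planted, config, cohort_index=i)
        paths[f"scores{i}"] = outdir / f"scores{i}.tsv"
        scores.to_csv(paths[f"scores{i}"], sep="\t", index=False, float_format="%.12g")
        snps = make_snp_level(scores, regions, config, cohort_index=i, planted=planted)
        paths[f"gwas{i}"] = outdir / f"cohort{i}.gwas.tsv"
        pd.DataFrame(
            [(s.snp_id, s.chrom, s.pos, s.p) for s in snps],
            columns=["snp", "chrom", "pos", "p"],
        ).to_csv(paths[f"gwas{i}"], sep="\t", index=False, float_format="%.12g")

    paths["gmt"] = outdir / "sets.gmt"
    with open(paths["gmt"], "w") as fh:
        for term in make_gene_sets(planted, config.genes, config):
            genes = "\t".join(sorted(term.genes))
            fh.write(f"{term.term_id}\t{term.term_name}\t{genes}\n")

    paths["drugs"] = outdir / "drugs.tsv"
    make_drug_table(planted, config.genes, config).to_csv(
        paths["drugs"], sep="\t", index=False
    )

    paths["scenario"] = outdir / "scenario.toml"
    with open(paths["scenario"], "w") as fh:
        fh.write("[scenario]\n")
        for f in dataclasses.fields(config):
            fh.write(f"{f.name} = {_toml_value(getattr(config, f.name))}\n")
        fh.write(f'planted_genes = {sorted(planted)!r}\n'.replace("'", '"'))
    logger.info("write_scenario: %d files written to %s", len(paths), outdir)
    return paths
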