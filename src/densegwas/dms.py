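"""Greedy dense module search over a node-weighted protein-interaction graph.

Every weighted gene seeds one module.  A module's raw score is

    Z_m = sum_i z_i / sqrt(k),

the sum of member node weights over the square root of the module size.
Starting from the seed, the candidate within graph distance ``d`` of the
current module that maximizes the new Z_m is added, but only while the new
score exceeds the old by a factor (1 + r); r = 0.1 and d = 1 by default.
Raw scores are standardized against random gene sets of matched size drawn
uniformly from the weighted genes (connectivity not required), yielding the
normalized score Z_N and the one-sided module p-value p_m = 1 - Phi(Z_N).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special

from .errors import ConfigError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "SearchParams",
    "Module",
    "build_search_graph",
    "module_score",
    "grow_module",
    "search_all",
    "normalize_scores",
    "module_pvalue",
    "module_log10_pvalue",
    "rank_and_select",
    "merge_modules",
]


@dataclass(frozen=True)
class SearchParams:
    """Tuning constants of the greedy search and the score normalization.

    r: required proportional improvement for accepting an expansion (> 0).
    d: candidate neighborhood order (1 = adjacent to the module; up to 2).
    n_random: random gene sets per module size for normalization (>= 1000).
    rng_seed: seed for the normalization sampler.
    """

    r: float = 0.1
    d: int = 1
    n_random: int = 100_000
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise ConfigError(f"expansion rate r must be > 0, got {self.r}")
        if self.d < 1:
            raise ConfigError(f"neighborhood order d must be >= 1, got {self.d}")
        if self.n_random < 1000:
            raise ConfigError(f"n_random must be >= 1000, got {self.n_random}")


@dataclass(frozen=True)
class Module:
    """A connected gene set grown from (and named by) its seed gene."""

    seed: str
    genes: tuple[str, ...]  # in order of addition; seed first
    Zm: float
    Zn: float | None = None
    pm: float | None = None

    @property
    def k(self) -> int:
        return len(self.genes)

    def __post_init__(self) -> None:
        if self.seed not in self.genes:
            raise DomainError(f"seed {self.seed} not among module genes")


def build_search_graph(
    edges: Iterable[tuple[str, str]], scores: pd.DataFrame
) -> nx.Graph:
    """Assemble the search graph: weighted, non-excluded genes only.

    Nodes carry attributes ``z`` and ``p_g``.  Genes absent from the score
    table (or excluded, p_g < 1e-12) cannot contribute to any Z_m and are
    deleted; the search space is the largest connected component of what
    remains plus any isolated weighted nodes.
    """
    usable = scores[scores["z"].notna() & ~scores["excluded"].astype(bool)]
    z = dict(zip(usable["gene"], usable["z"].astype(float)))
    pg = dict(zip(usable["gene"], usable["p_g"].astype(float)))

    g = nx.Graph()
    g.add_edges_from((a, b) for a, b in edges if a != b)
    g.remove_nodes_from([n for n in list(g) if n not in z])
    if g.number_of_nodes() > 0:
        components = sorted(nx.connected_components(g), key=lambda c: (len(c), min(c)))
        keep = components[-1] | {n for n in g if g.degree[n] == 0}
        g.remove_nodes_from([n for n in list(g) if n not in keep])
    nx.set_node_attributes(g, {n: z[n] for n in g}, "z")
    nx.set_node_attributes(g, {n: pg[n] for n in g}, "p_g")
    return g


def module_score(weights: Sequence[float]) -> float:
    """Raw module score Z_m = sum(weights) / sqrt(k)."""
    if len(weights) == 0:
        raise DomainError("module_score requires at least one weight")
    return float(np.sum(weights) / math.sqrt(len(weights)))


def _candidates(adj: dict[str, set[str]], members: set[str], d: int) -> set[str]:
    """Nodes within graph distance d of the module, excluding members."""
    frontier = members
    seen = set(members)
    out: set[str] = set()
    for _ in range(d):
        nxt = set()
        for node in frontier:
            nxt |= adj[node]
        nxt -= seen
        out |= nxt
        seen |= nxt
        frontier = nxt
    return out


def grow_module(graph: nx.Graph, seed: str, params: SearchParams) -> Module:
    """Greedy expansion from ``seed``.

    At each step every candidate within distance ``d`` of the module is
    scored; because all candidates enter a module of the same size, the best
    candidate is simply the one with the largest weight (ties broken by
    lexicographically smallest symbol).  It is accepted iff
    Z_new > Z_current * (1 + r); otherwise the search stops.
    """
    if seed not in graph or "z" not in graph.nodes[seed]:
        raise DomainError(f"seed {seed!r} is not a weighted node of the graph")
    z = {n: graph.nodes[n]["z"] for n in graph}
    adj = {n: set(graph.adj[n]) for n in graph}

    members = [seed]
    member_set = {seed}
    total = z[seed]
    z_cur = total
    while True:
        cand = _candidates(adj, member_set, params.d)
        if not cand:
            break
        best = min(cand, key=lambda gname: (-z[gname], gname))
        z_new = (total + z[best]) / math.sqrt(len(members) + 1)
        if z_new > z_cur * (1.0 + params.r):
            members.append(best)
            member_set.add(best)
            total += z[best]
            z_cur = z_new
        else:
            break
    return Module(seed=seed, genes=tuple(members), Zm=z_cur)


def search_all(graph: nx.Graph, params: SearchParams) -> list[Module]:
    """One module per weighted seed gene, in seed-symbol order."""
    seeds = sorted(n for n in graph if "z" in graph.nodes[n])
    if not seeds:
        raise DomainError("graph has no weighted node to seed from")
    modules = []
    for i, seed in enumerate(seeds, 1):
        modules.append(grow_module(graph, seed, params))
        if i % 1000 == 0:
            logger.info("search_all: %d/%d seeds grown", i, len(seeds))
    return modules


def null_score_stats(
    weights: np.ndarray, sizes: Sequence[int], n_random: int, rng_seed: int
) -> dict[int, tuple[float, float]]:
    """Mean and SD of Z_m over ``n_random`` uniform random gene sets per size.

    Sets of every requested size are read as prefixes of independently drawn
    random orderings of the weighted genes, so each size-k set is an exact
    uniform draw of k distinct genes while all sizes share one pass.
    """
    weights = np.asarray(weights, dtype=float)
    n = weights.size
    sizes = sorted(set(int(k) for k in sizes))
    if not sizes:
        return {}
    kmax = sizes[-1]
    if kmax > n:
        raise DomainError(f"cannot draw sets of size {kmax} from {n} weighted genes")
    rng = np.random.default_rng(rng_seed)
    sums = np.zeros(len(sizes))
    sumsqs = np.zeros(len(sizes))
    scale = np.sqrt(np.array(sizes, dtype=float))
    chunk = max(1, min(n_random, int(2e7 // max(n, 1))))
    done = 0
    while done < n_random:
        c = min(chunk, n_random - done)
        order = np.argsort(rng.random((c, n)), axis=1)[:, :kmax]
        csum = np.cumsum(weights[order], axis=1)
        for i, k in enumerate(sizes):
            zm = csum[:, k - 1] / scale[i]
            sums[i] += zm.sum()
            sumsqs[i] += (zm * zm).sum()
        done += c
    stats: dict[int, tuple[float, float]] = {}
    for i, k in enumerate(sizes):
        mean = sums[i] / n_random
        var = (sumsqs[i] - n_random * mean * mean) / (n_random - 1)
        stats[k] = (float(mean), float(math.sqrt(max(var, 0.0))))
    return stats


def normalize_scores(
    modules: Sequence[Module], graph: nx.Graph, params: SearchParams
) -> tuple[list[Module], dict[int, tuple[float, float]]]:
    """Standardize raw scores: Z_N = (Z_m - mean_k) / sd_k per module size k.

    mean_k / sd_k come from ``params.n_random`` uniform random sets of k
    weighted genes (connectivity not required), seeded by ``params.rng_seed``;
    the per-size statistics are returned alongside the updated modules.
    """
    if not modules:
        raise DomainError("no modules to normalize")
    weights = np.array([graph.nodes[n]["z"] for n in sorted(graph)])
    stats = null_score_stats(
        weights, [m.k for m in modules], params.n_random, params.rng_seed
    )
    for k, (_, sd) in stats.items():
        if sd == 0.0:
            raise DomainError(
                f"degenerate null at module size k={k}: all random-set scores equal"
            )
    out = []
    for m in modules:
        mean, sd = stats[m.k]
        zn = (m.Zm - mean) / sd
        out.append(replace(m, Zn=zn, pm=module_pvalue(zn)))
    return out, stats


def module_pvalue(Zn: float) -> float:
    """One-sided upper-tail module p-value p_m = 1 - Phi(Z_N).

    Evaluated through the complementary normal CDF; underflows to 0 only
    beyond Z_N ~ 38 (below the smallest subnormal double), where
    ``module_log10_pvalue`` remains exact.
    """
    if not math.isfinite(Zn):
        raise DomainError(f"Zn must be finite, got {Zn}")
    return float(special.ndtr(-Zn))


def module_log10_pvalue(Zn: float) -> float:
    """log10 of the one-sided module p-value, accurate for Z_N up to 40 and beyond."""
    if not math.isfinite(Zn):
        raise DomainError(f"Zn must be finite, got {Zn}")
    return float(special.log_ndtr(-Zn) / math.log(10.0))


def rank_and_select(
    modules: Sequence[Module],
    top_fraction: float = 0.01,
    top_n: int | None = None,
) -> list[Module]:
    """Top modules by normalized score (ties by seed symbol).

    Returns ceil(top_fraction * count) modules, or exactly ``top_n`` when
    given (top_fraction is then ignored).
    """
    if top_n is None and not 0.0 < top_fraction <= 1.0:
        raise ConfigError(f"top_fraction must be in (0, 1], got {top_fraction}")
    key = lambda m: (-(m.Zn if m.Zn is not None else m.Zm), m.seed)
    ranked = sorted(modules, key=key)
    count = top_n if top_n is not None else math.ceil(top_fraction * len(ranked))
    return ranked[: max(count, 0)]


def merge_modules(modules: Sequence[Module], graph: nx.Graph) -> nx.Graph:
    """Induced-union merge: all member genes plus every source-graph edge among them.

    Node attributes ``z`` and ``p_g`` are carried over from the source graph;
    ``n_modules`` counts in how many of the merged modules each gene appears.
    """
    if not modules:
        raise DomainError("merge_modules requires at least one module")
    union: set[str] = set()
    counts: dict[str, int] = {}
    for m in modules:
        union |= set(m.genes)
        for gene in m.genes:
            counts[gene] = counts.get(gene, 0) + 1
    merged = nx.Graph(graph.subgraph(union))
    for n in union:
        if n not in merged:
            merged.add_node(n, **graph.nodes.get(n, {}))
    nx.set_node_attributes(merged, counts, "n_modules")
    return merged


def modules_to_frame(modules: Sequence[Module]) -> pd.DataFrame:
    """Tabular view: seed, k, genes (semicolon-joined), Zm, Zn, pm."""
    return pd.DataFrame(
        {
            "seed": [m.seed for m in modules],
            "k": [m.k for m in modules],
            "genes": [";".join(m.genes) for m in modules],
            "Zm": [m.Zm for m in modules],
            "Zn": [m.Zn for m in modules],
            "pm": [m.pm for m in modules],
        }
    )


def modules_from_frame(frame: pd.DataFrame) -> list[Module]:
    """Inverse of :func:`modules_to_frame`."""
    out = []
    for row in frame.itertuples(index=False):
        zn = None if pd.isna(row.Zn) else float(row.Zn)
        pm = None if pd.isna(row.pm) else float(row.pm)
        out.append(
            Module(
                seed=row.seed,
                genes=tuple(str(row.genes).split(";")),
                Zm=float(row.Zm),
                Zn=zn,
                pm=pm,
            )
        )
    return out
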