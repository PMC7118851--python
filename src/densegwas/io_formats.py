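"""Readers and writers for every external file the pipeline touches.

Dialects, fixed by design:

* Tables are tab- or comma-delimited with a header row; the delimiter is
  auto-detected from the header line (override available).
* Coordinates are 1-based and inclusive on both ends.
* Gene identity is the bare symbol string, case-sensitive; an optional
  user-supplied alias map is applied at read time (no identifier service).
* GWAS rows with p outside (0, 1], a missing position, or a non-numeric
  p-value are dropped and counted, never silently discarded: every reader
  reports its drop/cleanup counts.
* Network exports: GraphML carries node attributes (z, p_g, betweenness,
  module membership); SIF carries topology only, one ``geneA pp geneB`` line
  per edge.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .errors import ConfigError, InputError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "GeneRegion",
    "GeneSet",
    "GeneSetCollection",
    "GwasTable",
    "EdgeList",
    "read_gwas",
    "read_network",
    "read_gene_regions",
    "read_gmt",
    "read_drug_table",
    "read_gene_scores",
    "write_gene_scores",
    "write_module_table",
    "read_module_table",
    "export_network",
]

DEFAULT_GWAS_COLUMNS = {"snp": "snp", "chrom": "chrom", "pos": "pos", "p": "p"}


@dataclass(frozen=True)
class SnpRecord:
    """One SNP-level association: identifier, position and p-value in (0, 1]."""

    snp_id: str
    chrom: str
    pos: int
    p: float


@dataclass(frozen=True)
class GeneRegion:
    """A gene body on a chromosome, 1-based inclusive coordinates."""

    gene: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    genes: frozenset[str]


GeneSetCollection = list[GeneSet]


@dataclass
class GwasTable:
    """Parsed GWAS summary statistics plus the count of dropped rows."""

    records: list[SnpRecord]
    n_dropped: int

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class EdgeList:
    """Undirected deduplicated edges (each stored as a sorted symbol pair)."""

    edges: set[tuple[str, str]]
    n_self_loops: int

    def __iter__(self):
        return iter(sorted(self.edges))

    def __len__(self) -> int:
        return len(self.edges)


def _sniff_sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    try:
        with open(path) as fh:
            header = fh.readline()
    except OSError as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    return "\t" if "\t" in header else ","


def _apply_alias(symbol: str, alias_map: Mapping[str, str] | None) -> str:
    if alias_map is None:
        return symbol
    return alias_map.get(symbol, symbol)


def read_gwas(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> GwasTable:
    """Read SNP-level summary statistics.

    ``column_map`` maps the logical names snp/chrom/pos/p to the file's
    header names.  Rows failing validation (p outside (0, 1], missing or
    non-numeric pos/p) are dropped and counted.
    """
    path = Path(path)
    cmap = dict(DEFAULT_GWAS_COLUMNS)
    if column_map:
        cmap.update(column_map)
    sep = _sniff_sep(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"GWAS file {path} is empty") from exc
    for logical, column in cmap.items():
        if column not in raw.columns:
            raise ConfigError(
                f"GWAS file {path} has no column {column!r} (mapped from {logical!r}); "
                f"available: {list(raw.columns)}"
            )
    if len(raw) == 0:
        raise InputError(f"GWAS file {path} contains a header but no data rows")

    pos = pd.to_numeric(raw[cmap["pos"]], errors="coerce")
    pval = pd.to_numeric(raw[cmap["p"]], errors="coerce")
    snp = raw[cmap["snp"]].fillna("")
    ok = (
        pos.notna()
        & (pos >= 1)
        & pval.notna()
        & (pval > 0.0)
        & (pval <= 1.0)
        & (snp.str.len() > 0)
    )
    n_dropped = int((~ok).sum())
    records = [
        SnpRecord(snp_id=s, chrom=str(c), pos=int(bp), p=float(pv))
        for s, c, bp, pv in zip(
            snp[ok], raw.loc[ok, cmap["chrom"]], pos[ok], pval[ok]
        )
    ]
    if n_dropped:
        logger.info("read_gwas(%s): dropped %d invalid rows", path, n_dropped)
    return GwasTable(records=records, n_dropped=n_dropped)


def read_network(
    path: str | Path,
    delimiter: str | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> EdgeList:
    """Read a two-column edge list of gene symbols (no header, extra columns ignored)."""
    path = Path(path)
    sep = _sniff_sep(path, delimiter)
    edges: set[tuple[str, str]] = set()
    n_self = 0
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split(sep)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(
                    f"expected at least two gene symbols in {path}", line=lineno
                )
            a = _apply_alias(parts[0].strip(), alias_map)
            b = _apply_alias(parts[1].strip(), alias_map)
            if a == b:
                n_self += 1
                continue
            edges.add((a, b) if a < b else (b, a))
    if n_lines == 0:
        warnings.warn(f"network file {path} is empty", stacklevel=2)
    if n_self:
        logger.info("read_network(%s): removed %d self-loops", path, n_self)
    return EdgeList(edges=edges, n_self_loops=n_self)


def read_gene_regions(
    path: str | Path,
    delimiter: str | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[GeneRegion]:
    """Read gene/chrom/start/end (header row; 1-based inclusive coordinates).

    Duplicate gene symbols keep the first occurrence (with a warning);
    start > end is a parse error naming the line.
    """
    path = Path(path)
    sep = _sniff_sep(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"gene region file {path} is empty") from exc
    for col in ("gene", "chrom", "start", "end"):
        if col not in raw.columns:
            raise ConfigError(f"gene region file {path} has no column {col!r}")
    regions: list[GeneRegion] = []
    seen: set[str] = set()
    n_dup = 0
    for i, row in enumerate(raw.itertuples(index=False)):
        lineno = i + 2  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"non-integer coordinate in {path}", line=lineno) from exc
        if start > end:
            raise ParseError(
                f"start {start} > end {end} for gene {row.gene} in {path}", line=lineno
            )
        gene = _apply_alias(str(row.gene), alias_map)
        if gene in seen:
            n_dup += 1
            continue
        seen.add(gene)
        regions.append(GeneRegion(gene=gene, chrom=str(row.chrom), start=start, end=end))
    if n_dup:
        warnings.warn(
            f"gene region file {path}: {n_dup} duplicate gene rows ignored (kept first)",
            stacklevel=2,
        )
    return regions


def read_gmt(
    path: str | Path, alias_map: Mapping[str, str] | None = None
) -> GeneSetCollection:
    """Read standard GMT: term_id TAB description TAB gene1 TAB gene2 ...

    Genes are deduplicated per term; a line with fewer than three fields is a
    parse error.  The description field conventionally carries the namespace
    label (e.g. a GO category) used by per-namespace enrichment reporting.
    """
    path = Path(path)
    collection: GeneSetCollection = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"GMT line needs term, description and >= 1 gene in {path}",
                    line=lineno,
                )
            term_id, name = parts[0], parts[1]
            if term_id in seen_ids:
                raise ParseError(f"duplicate term id {term_id!r} in {path}", line=lineno)
            seen_ids.add(term_id)
            genes = frozenset(
                _apply_alias(g.strip(), alias_map) for g in parts[2:] if g.strip()
            )
            if not genes:
                raise ParseError(f"term {term_id!r} has an empty gene list", line=lineno)
            collection.append(GeneSet(term_id=term_id, term_name=name, genes=genes))
    return collection


def read_drug_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a drug->target table with columns drug, product, target_gene.

    (drug, target_gene) pairs are deduplicated, keeping the first row.
    """
    path = Path(path)
    sep = _sniff_sep(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"drug table {path} is empty") from exc
    for col in ("drug", "product", "target_gene"):
        if col not in raw.columns:
            raise ConfigError(f"drug table {path} has no column {col!r}")
    before = len(raw)
    table = raw.drop_duplicates(subset=["drug", "target_gene"], keep="first")
    if len(table) < before:
        logger.info(
            "read_drug_table(%s): removed %d duplicate (drug, target) rows",
            path, before - len(table),
        )
    return table.reset_index(drop=True)


def write_gene_scores(scores: pd.DataFrame, path: str | Path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_gene_scores(path: str | Path) -> pd.DataFrame:
    scores = pd.read_csv(path, sep="\t")
    for col in ("gene", "p_g", "z"):
        if col not in scores.columns:
            raise ConfigError(f"gene score table {path} has no column {col!r}")
    if "excluded" not in scores.columns:
        scores["excluded"] = False
    scores["gene"] = scores["gene"].astype(str)
    scores["excluded"] = scores["excluded"].astype(bool)
    return scores


def write_module_table(modules, path: str | Path) -> None:
    from .dms import modules_to_frame

    modules_to_frame(modules).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_module_table(path: str | Path):
    from .dms import modules_from_frame

    return modules_from_frame(pd.read_csv(path, sep="\t"))


def export_network(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a (merged-module) network for downstream visualization tools.

    graphml: full topology + node attributes, round-trips through
    :func:`networkx.read_graphml`.  sif: ``geneA pp geneB`` lines, topology
    only.  tsv: two-column edge list, topology only.
    """
    path = Path(path)
    if graph.number_of_nodes() == 0:
        warnings.warn(f"exporting an empty network to {path}", stacklevel=2)
    if format == "graphml":
        nx.write_graphml(graph, path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{a} pp {b}\n")
            for n in sorted(graph.nodes):
                if graph.degree[n] == 0:
                    fh.write(f"{n}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
                fh.write(f"{a}\t{b}\n")
    else:
        raise ConfigError(f"unknown export format {format!r}: use graphml, sif or tsv")
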