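"""Gene-set over-representation analysis of module gene lists.

For a query of n genes drawn from a background universe of N genes, the
overlap k with a K-gene annotation term is referred to the hypergeometric
upper tail P(X >= k); p-values are corrected with the Benjamini-Hochberg
step-up within each annotation namespace (Molecular Function, Biological
Process, Cellular Component in GO-style collections).  The background is
always explicit: by convention the scored genes intersected with the
annotation universe, overridable by the caller.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_enrich", "bh_adjust", "enrich_report"]

_COLUMNS = [
    "term_id",
    "term_name",
    "k_overlap",
    "K_term",
    "n_query",
    "N_background",
    "contributing_genes",
    "p",
    "p_adj",
]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; monotone
    non-decreasing along the sorted order and idempotent.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0.0) or np.any(p > 1.0):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _term_rows(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    min_term: int,
    max_term: int,
) -> tuple[list[list], int]:
    n_query = len(query)
    n_bg = len(background)
    rows: list[list] = []
    n_skipped = 0
    for term in collection:
        term_genes = term.genes & background
        big_k = len(term_genes)
        if not min_term <= big_k <= max_term:
            n_skipped += 1
            continue
        contributing = sorted(query & term_genes)
        k = len(contributing)
        # P(X >= k) under Hypergeometric(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_query))
        p = min(max(p, 0.0), 1.0)
        rows.append(
            [term.term_id, term.term_name, k, big_k, n_query, n_bg, contributing, p]
        )
    return rows, n_skipped


def hypergeom_enrich(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    min_term: int = 2,
    max_term: int = 500,
) -> pd.DataFrame:
    """Test every term of the collection against a query gene set.

    Terms are intersected with the background before testing; terms whose
    intersected size falls outside [min_term, max_term] are excluded (and
    counted in ``DataFrame.attrs['n_terms_skipped']``).  BH adjustment here
    spans all retained terms; use :func:`enrich_report` for per-namespace
    correction.  Rows are sorted by p ascending.
    """
    if not query:
        raise DomainError("empty query gene set")
    if not background:
        raise DomainError("empty background gene universe")
    extra = query - background
    if extra:
        logger.warning(
            "hypergeom_enrich: %d query genes outside the background were dropped",
            len(extra),
        )
        query = query & background
        if not query:
            raise DomainError("no query gene lies in the background universe")
    rows, n_skipped = _term_rows(query, collection, background, min_term, max_term)
    table = pd.DataFrame(rows, columns=_COLUMNS[:-1])
    table["p_adj"] = bh_adjust(table["p"]) if len(table) else []
    table = table.sort_values(["p", "term_id"]).reset_index(drop=True)
    table.attrs["n_terms_skipped"] = n_skipped
    return table


def enrich_report(
    query: set[str],
    collection: GeneSetCollection,
    background: set[str],
    namespaces: Mapping[str, str] | None = None,
    top_per_namespace: int = 5,
    min_term: int = 2,
    max_term: int = 500,
    term_size_limit: int | None = None,
) -> pd.DataFrame:
    """Per-namespace enrichment report (top rows per annotation category).

    ``namespaces`` maps term_id -> category label; when omitted, the label is
    taken from the GMT description field.  Terms with an unknown/empty label
    are grouped under "unlabeled" with a warning.  BH adjustment is performed
    within each namespace independently (adjusted values in one namespace
    never depend on another's p-values), and the ``top_per_namespace``
    lowest-p rows are reported per namespace.  ``term_size_limit`` (e.g. 100)
    additionally caps the term size before testing when set.
    """
    labels: dict[str, str] = {}
    n_unlabeled = 0
    for term in collection:
        label = namespaces.get(term.term_id) if namespaces else term.term_name
        if not label:
            label = "unlabeled"
            n_unlabeled += 1
        labels[term.term_id] = label
    if n_unlabeled:
        warnings.warn(
            f"{n_unlabeled} terms had no namespace label; grouped under 'unlabeled'",
            stacklevel=2,
        )
    cap = max_term if term_size_limit is None else min(max_term, term_size_limit)
    pieces = []
    for namespace in sorted(set(labels.values())):
        sub = [t for t in collection if labels[t.term_id] == namespace]
        part = hypergeom_enrich(query, sub, background, min_term=min_term, max_term=cap)
        part.insert(0, "namespace", namespace)
        pieces.append(part.head(top_per_namespace))
    if not pieces:
        return pd.DataFrame(columns=["namespace", *_COLUMNS])
    return pd.concat(pieces, ignore_index=True)
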