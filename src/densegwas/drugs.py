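"""Overlap of module gene lists with a drug->target table.

The table is a user-supplied snapshot (drug, product, target_gene); for each
target found in at least one tracked module list, a hit row reports in how
many modules of each list the target occurs ("3/75"-style occurrence
fractions) and the target's gene-level p-value in each cohort.  A drug with
several targets emits one row per target.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import pandas as pd

from .dms import Module
from .errors import DomainError

__all__ = ["overlap_targets", "summarize_unique_targets"]


def overlap_targets(
    drug_table: pd.DataFrame,
    module_lists: Mapping[str, Sequence[Module]],
    score_tables: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Table-of-hits: one row per (drug, target) present in >= 1 tracked module.

    Columns: drug, product, target_gene, then ``in_<list>`` ("count/total")
    and ``n_<list>`` per module list, then ``p_g_<cohort>`` per score table
    (NaN when the gene was not scored in that cohort).  Output is sorted and
    independent of input row / list ordering.
    """
    if len(drug_table) == 0:
        raise DomainError("empty drug table")
    if not module_lists:
        raise DomainError("at least one module list is required")
    score_tables = score_tables or {}
    pg = {
        cohort: dict(zip(t["gene"], t["p_g"]))
        for cohort, t in score_tables.items()
    }
    membership = {
        name: [set(m.genes) for m in modules]
        for name, modules in module_lists.items()
    }
    rows = []
    for rec in drug_table.itertuples(index=False):
        target = rec.target_gene
        counts = {
            name: sum(target in genes for genes in sets)
            for name, sets in membership.items()
        }
        if not any(counts.values()):
            continue
        row: dict = {
            "drug": rec.drug,
            "product": rec.product,
            "target_gene": target,
        }
        for name in sorted(membership):
            row[f"in_{name}"] = f"{counts[name]}/{len(membership[name])}"
            row[f"n_{name}"] = counts[name]
        for cohort in sorted(pg):
            row[f"p_g_{cohort}"] = pg[cohort].get(target, float("nan"))
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["drug", "target_gene"]).reset_index(drop=True)
    return out


def summarize_unique_targets(drug_table: pd.DataFrame) -> int:
    """Number of distinct target genes in the drug table."""
    if len(drug_table) == 0:
        return 0
    return int(drug_table["target_gene"].nunique())
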