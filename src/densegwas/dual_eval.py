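"""Cross-cohort dual evaluation of discovery modules.

Modules found in a discovery cohort are re-scored with the evaluation
cohort's node weights (members missing from the evaluation table contribute
z = 0 but still count toward the module size), normalized against random
gene sets drawn from the evaluation table, and flagged significant when both
the discovery and the evaluation normalized scores clear empirical-quantile
thresholds.  Requiring both axes filters modules whose signal does not
replicate between cohorts.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .dms import Module, SearchParams, merge_modules, null_score_stats
from .errors import ConfigError, DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "DualEvalRecord",
    "evaluate_modules",
    "select_significant",
    "merge_significant",
]


@dataclass(frozen=True)
class DualEvalRecord:
    """A discovery module paired with its normalized evaluation score."""

    module: Module  # discovery Zn retained inside
    Zn_eval: float
    significant: bool | None = None


def evaluate_modules(
    discovery: Sequence[Module],
    eval_scores: pd.DataFrame,
    params: SearchParams,
) -> list[DualEvalRecord]:
    """Score each discovery module with the evaluation cohort's weights.

    Raw evaluation score = sum of member z (0 for genes absent from the
    evaluation table) / sqrt(k); normalized against ``params.n_random``
    uniform random sets drawn from the evaluation table's weighted genes
    (same scheme and seed policy as the discovery normalization).
    """
    if not discovery:
        raise DomainError("no discovery modules to evaluate")
    usable = eval_scores[
        eval_scores["z"].notna() & ~eval_scores["excluded"].astype(bool)
    ]
    z_eval = dict(zip(usable["gene"], usable["z"].astype(float)))
    if not z_eval:
        raise DomainError("evaluation score table has no usable gene weights")

    weights = np.array([z_eval[g] for g in sorted(z_eval)])
    stats = null_score_stats(
        weights, [m.k for m in discovery], params.n_random, params.rng_seed
    )
    records = []
    for m in discovery:
        raw = sum(z_eval.get(g, 0.0) for g in m.genes) / math.sqrt(m.k)
        mean, sd = stats[m.k]
        if sd == 0.0:
            raise DomainError(f"degenerate evaluation null at module size k={m.k}")
        records.append(DualEvalRecord(module=m, Zn_eval=(raw - mean) / sd))
    return records


def select_significant(
    records: Sequence[DualEvalRecord],
    disc_quantile: float = 0.99,
    eval_quantile: float = 0.95,
) -> tuple[list[DualEvalRecord], tuple[float, float]]:
    """Flag records clearing empirical quantiles on BOTH axes.

    significant = (discovery Zn >= disc_quantile of all discovery Zn) AND
    (Zn_eval >= eval_quantile of all Zn_eval).  Returns the flagged records
    and the two thresholds actually applied.
    """
    if not 0.0 < disc_quantile < 1.0 or not 0.0 < eval_quantile < 1.0:
        raise ConfigError(
            f"quantiles must lie in (0, 1), got {disc_quantile}, {eval_quantile}"
        )
    if not records:
        raise DomainError("no records to select from")
    disc = np.array([r.module.Zn for r in records], dtype=float)
    if np.any(np.isnan(disc)):
        raise DomainError("discovery modules must be normalized before selection")
    evl = np.array([r.Zn_eval for r in records], dtype=float)
    thr_d = float(np.quantile(disc, disc_quantile))
    thr_e = float(np.quantile(evl, eval_quantile))
    logger.info(
        "select_significant: discovery threshold %.4f (q=%.3f), "
        "evaluation threshold %.4f (q=%.3f)",
        thr_d, disc_quantile, thr_e, eval_quantile,
    )
    out = [
        replace(r, significant=bool(r.module.Zn >= thr_d and r.Zn_eval >= thr_e))
        for r in records
    ]
    return out, (thr_d, thr_e)


def merge_significant(
    records: Sequence[DualEvalRecord], graph: nx.Graph
) -> nx.Graph:
    """Induced-union merge of the significant discovery modules.

    With zero significant records an empty graph is returned with a warning
    (an unreplicated analysis is a result, not a crash).
    """
    significant = [r.module for r in records if r.significant]
    if not significant:
        warnings.warn("no significant dual-evaluation modules to merge", stacklevel=2)
        return nx.Graph()
    merged = merge_modules(significant, graph)
    logger.info(
        "merge_significant: %d modules merged into %d non-redundant genes",
        len(significant), merged.number_of_nodes(),
    )
    return merged


def records_to_frame(records: Sequence[DualEvalRecord]) -> pd.DataFrame:
    """Tabular view: seed, k, Zn_discovery, Zn_eval, significant."""
    return pd.DataFrame(
        {
            "seed": [r.module.seed for r in records],
            "k": [r.module.k for r in records],
            "Zn_discovery": [r.module.Zn for r in records],
            "Zn_eval": [r.Zn_eval for r in records],
            "significant": [r.significant for r in records],
        }
    )
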