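"""Gene-level association scores from SNP-level GWAS p-values.

SNPs are assigned to a gene if they fall inside the gene body extended by a
+/- 50 kb window.  Per gene, the sum-of-chi-squares (SOCS) statistic
T = sum_j Qinv(p_j) (Qinv = upper-tail inverse of the 1-df chi-square) is
referred to its null distribution, a linkage-disequilibrium-weighted mixture
of 1-df chi-squares with weights equal to the eigenvalues of the SNP
correlation matrix.  The resulting gene p-value p_g becomes a node weight
z = Phi^-1(1 - p_g) for the module search.

Genes with p_g < 1e-12 are flagged ``excluded`` and removed before module
search: such genes would dominate every module they can reach and turn the
search into single-gene lookups.
"""

from __future__ import annotations

import logging
import math
import warnings
from bisect import bisect_left, bisect_right
from collections.abc import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError
from .io_formats import GeneRegion, SnpRecord
from .quadform import imhof_sf, liu_sf

logger = logging.getLogger(__name__)

__all__ = [
    "map_snps_to_genes",
    "socs_statistic",
    "socs_pvalue",
    "score_genes",
    "weight_from_pg",
    "identity_ld",
    "block_ld",
    "EXCLUSION_PG",
    "PG_CLAMP",
]

#: genes below this gene-level p-value are removed before module search
EXCLUSION_PG = 1e-12
#: p_g = 1 is accepted but clamped before the normal quantile (which is -inf at 1)
PG_CLAMP = 1e-16

GeneSnpMap = dict[str, list[SnpRecord]]
LdProvider = Callable[[str, int], np.ndarray]


def identity_ld(gene: str, n_snps: int) -> np.ndarray:
    """LD provider assuming independent SNPs."""
    return np.eye(n_snps)


def block_ld(rho: float) -> LdProvider:
    """LD provider with constant pairwise correlation ``rho`` within each gene."""
    if not -1.0 < rho < 1.0:
        raise DomainError(f"block LD rho must be in (-1, 1), got {rho}")

    def provider(gene: str, n_snps: int) -> np.ndarray:
        m = np.full((n_snps, n_snps), rho)
        np.fill_diagonal(m, 1.0)
        return m

    return provider


def map_snps_to_genes(
    snps: Iterable[SnpRecord],
    regions: Iterable[GeneRegion],
    window_bp: int = 50_000,
) -> GeneSnpMap:
    """Assign each SNP to every gene whose +/- ``window_bp`` window contains it.

    A SNP may land in several genes' windows (overlapping windows) and then
    contributes to each of them.  Genes without any SNP are omitted from the
    returned map; their count is logged.
    """
    if window_bp < 0:
        raise DomainError(f"window_bp must be >= 0, got {window_bp}")
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for recs in by_chrom.values():
        recs.sort(key=lambda s: s.pos)

    mapping: GeneSnpMap = {}
    n_empty = 0
    for region in regions:
        recs = by_chrom.get(region.chrom, [])
        positions = [s.pos for s in recs]
        lo = bisect_left(positions, region.start - window_bp)
        hi = bisect_right(positions, region.end + window_bp)
        if hi > lo:
            mapping[region.gene] = recs[lo:hi]
        else:
            n_empty += 1
    if n_empty:
        logger.info("map_snps_to_genes: %d genes had no SNP in window", n_empty)
    return mapping


def socs_statistic(p_values: Sequence[float]) -> float:
    """Sum-of-chi-squares statistic T = sum_j Qinv(p_j); additive over SNPs."""
    if len(p_values) == 0:
        raise DomainError("a gene must have at least one SNP p-value")
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise DomainError("all SNP p-values must lie in (0, 1]")
    return float(stats.chi2.isf(p, df=1).sum())


def _ld_eigenvalues(ld: np.ndarray) -> np.ndarray:
    ld = np.asarray(ld, dtype=float)
    if ld.ndim != 2 or ld.shape[0] != ld.shape[1]:
        raise DomainError(f"LD matrix must be square, got shape {ld.shape}")
    if not np.allclose(ld, ld.T, atol=1e-10):
        raise DomainError("LD matrix must be symmetric")
    if np.any(np.abs(ld) > 1.0 + 1e-10):
        raise DomainError("LD entries must lie in [-1, 1]")
    lam = np.linalg.eigvalsh(ld)
    if lam.min() < -1e-8:
        raise DomainError(
            f"LD matrix not positive semi-definite (min eigenvalue {lam.min():.3g})"
        )
    return np.clip(lam, 0.0, None)


def socs_pvalue(T: float, ld: np.ndarray, method: str = "imhof") -> float:
    """P(sum_i lambda_i X_i > T) for eigenvalues lambda_i of ``ld``, X_i ~ chi2(1).

    When all nonzero eigenvalues coincide the mixture is an exactly scaled
    chi-square and is evaluated in closed form regardless of ``method``.
    ``imhof`` falls back to ``liu`` (with a warning) if the characteristic
    function inversion does not converge.  The result is clamped to (0, 1].
    """
    if T < 0:
        raise DomainError(f"SOCS statistic must be >= 0, got {T}")
    if method not in ("imhof", "liu"):
        raise DomainError(f"unknown method {method!r}: expected 'imhof' or 'liu'")
    lam = _ld_eigenvalues(ld)
    lam = lam[lam > 1e-12]
    if lam.size == 0:
        return 1.0
    if T == 0.0:
        return 1.0
    # equal-eigenvalue mixture is a scaled chi-square: P(c * chi2_m > T)
    if np.allclose(lam, lam[0], rtol=1e-12, atol=1e-12):
        p = float(stats.chi2.sf(T / lam[0], df=lam.size))
    elif method == "liu":
        p = liu_sf(T, lam)
    else:
        p, converged = imhof_sf(T, lam)
        if not converged:
            warnings.warn(
                "Imhof inversion did not converge; falling back to Liu approximation",
                RuntimeWarning,
                stacklevel=2,
            )
            p = liu_sf(T, lam)
    return float(min(max(p, 5e-324), 1.0))


def weight_from_pg(p_g: float) -> float:
    """Node weight z = Phi^-1(1 - p_g), the upper-tail standard normal quantile.

    p_g = 1 is legal input (a completely null gene) but the quantile is -inf
    there; such values are clamped to 1 - 1e-16 and the clamp is logged.
    """
    if not (0.0 < p_g <= 1.0) or not math.isfinite(p_g):
        raise DomainError(f"p_g must lie in (0, 1], got {p_g}")
    if p_g > 1.0 - PG_CLAMP:
        logger.debug("weight_from_pg: clamping p_g=%g to %g", p_g, 1.0 - PG_CLAMP)
        p_g = 1.0 - PG_CLAMP
    return float(stats.norm.isf(p_g))


def score_genes(
    gwas: Iterable[SnpRecord],
    regions: Sequence[GeneRegion],
    ld_provider: LdProvider = identity_ld,
    window_bp: int = 50_000,
    method: str = "imhof",
) -> pd.DataFrame:
    """Score every gene with >= 1 mapped SNP.

    Returns a DataFrame with columns ``gene, n_snps, T, p_g, z, excluded``,
    sorted by gene symbol.  A gene whose p-value computation fails is recorded
    as unscored (NaN row) rather than aborting the run.  Metadata (window,
    method, counts) is attached on ``DataFrame.attrs``.
    """
    mapping = map_snps_to_genes(gwas, regions, window_bp=window_bp)
    rows = []
    n_failed = 0
    for gene in sorted(mapping):
        snps = mapping[gene]
        pvals = [s.p for s in snps]
        try:
            T = socs_statistic(pvals)
            ld = ld_provider(gene, len(snps))
            p_g = socs_pvalue(T, ld, method=method)
            z = weight_from_pg(p_g)
            excluded = p_g < EXCLUSION_PG
            rows.append((gene, len(snps), T, p_g, z, excluded))
        except DomainError as exc:
            n_failed += 1
            logger.warning("score_genes: gene %s unscored: %s", gene, exc)
            rows.append((gene, len(snps), np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["gene", "n_snps", "T", "p_g", "z", "excluded"]
    )
    table.attrs.update(
        window_bp=window_bp,
        method=method,
        n_scored=int(table["p_g"].notna().sum()),
        n_excluded=int(table["excluded"].sum()),
        n_failed=n_failed,
    )
    logger.info(
        "score_genes: %d genes scored, %d excluded (p_g < %g), %d failed",
        table.attrs["n_scored"], table.attrs["n_excluded"], EXCLUSION_PG, n_failed,
    )
    return table
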