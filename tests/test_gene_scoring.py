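"""SNP-to-gene mapping, the SOCS statistic and its weighted-chi-square null."""

import math

import numpy as np
import pytest
from scipy import stats

from densegwas.errors import DomainError
from densegwas.gene_scoring import (
    block_ld,
    identity_ld,
    map_snps_to_genes,
    score_genes,
    socs_pvalue,
    socs_statistic,
    weight_from_pg,
)
from densegwas.io_formats import GeneRegion, SnpRecord
from densegwas.quadform import imhof_sf, liu_sf


def snp(i, chrom, pos, p):
    return SnpRecord(snp_id=f"rs{i}", chrom=str(chrom), pos=pos, p=p)


class TestMapSnpsToGenes:
    region = GeneRegion(gene="G1", chrom="1", start=100_000, end=120_000)

    def test_window_lower_bound_inclusive(self):
        mapping = map_snps_to_genes([snp(1, 1, 50_000, 0.5)], [self.region])
        assert list(mapping["G1"]) == [snp(1, 1, 50_000, 0.5)]

    def test_just_outside_window_excluded(self):
        assert map_snps_to_genes([snp(1, 1, 49_999, 0.5)], [self.region]) == {}

    def test_other_chromosome_excluded(self):
        assert map_snps_to_genes([snp(1, 2, 110_000, 0.5)], [self.region]) == {}

    def test_snp_shared_by_overlapping_windows(self):
        other = GeneRegion(gene="G2", chrom="1", start=160_000, end=180_000)
        mapping = map_snps_to_genes([snp(1, 1, 150_000, 0.2)], [self.region, other])
        assert set(mapping) == {"G1", "G2"}

    def test_snps_sorted_by_position(self):
        snps = [snp(1, 1, 115_000, 0.5), snp(2, 1, 105_000, 0.4)]
        mapping = map_snps_to_genes(snps, [self.region])
        assert [s.pos for s in mapping["G1"]] == [105_000, 115_000]


class TestSocsStatistic:
    # frozen from the standard 1-df chi-square quantile table
    def test_single_p(self):
        assert socs_statistic([0.05]) == pytest.approx(3.8414588206941285, rel=1e-10)

    def test_p_one_gives_zero(self):
        assert socs_statistic([1.0]) == 0.0

    def test_two_medians(self):
        assert socs_statistic([0.5, 0.5]) == pytest.approx(0.9098728462391448, rel=1e-10)

    def test_additive_over_concatenation(self):
        rng = np.random.default_rng(0)
        a, b = rng.uniform(0.01, 1, 5).tolist(), rng.uniform(0.01, 1, 7).tolist()
        assert socs_statistic(a + b) == pytest.approx(
            socs_statistic(a) + socs_statistic(b), rel=1e-12
        )

    @pytest.mark.parametrize("bad", [[], [0.0], [1.2], [-0.5], [float("nan")]])
    def test_domain_errors(self, bad):
        with pytest.raises(DomainError):
            socs_statistic(bad)


class TestSocsPvalue:
    def test_single_snp_reduces_to_chi2(self):
        assert socs_pvalue(3.8414588206941285, np.eye(1)) == pytest.approx(0.05, abs=1e-10)

    def test_two_independent_snps(self):
        assert socs_pvalue(5.991464547107983, np.eye(2)) == pytest.approx(0.05, abs=1e-10)

    def test_perfect_ld_collapses_to_one_df(self):
        # eigenvalues {2, 0}: P(2 chi2_1 > T) = P(chi2_1 > T/2)
        T = 2 * 3.8414588206941285
        assert socs_pvalue(T, np.ones((2, 2))) == pytest.approx(0.05, abs=1e-10)

    def test_perfect_ld_any_size(self):
        for m in (3, 5):
            T = stats.chi2.isf(0.01, 1) * m
            assert socs_pvalue(T, np.ones((m, m))) == pytest.approx(0.01, abs=1e-10)

    def test_monotone_in_T(self):
        ld = block_ld(0.4)("g", 4)
        ts = np.linspace(0.0, 30.0, 40)
        ps = [socs_pvalue(t, ld) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_non_psd_rejected(self):
        bad = np.array([[1.0, 0.9], [0.9, -1.0]])
        with pytest.raises(DomainError):
            socs_pvalue(1.0, bad)

    def test_liu_method_close_in_upper_tail(self):
        ld = block_ld(0.5)("g", 5)
        lam = np.linalg.eigvalsh(ld)
        T = float(lam.sum() * stats.chi2.isf(0.03, 1) + 8)
        assert socs_pvalue(T, ld, method="liu") == pytest.approx(
            socs_pvalue(T, ld, method="imhof"), abs=2e-3
        )


class TestQuadform:
    """The Imhof inversion against independent closed-form and MC oracles."""

    def test_equal_eigenvalues_match_scaled_chi2(self):
        # generic Imhof path (equal-lambda shortcut lives in socs_pvalue, not here)
        for m in (1, 2, 3, 5, 10):
            for q in (0.5, 0.9, 0.99, 0.999):
                c = 1.7
                x = c * stats.chi2.isf(1 - q, m)
                p, converged = imhof_sf(x, [c] * m)
                assert converged
                assert p == pytest.approx(stats.chi2.sf(x / c, m), abs=1e-9)

    def test_imhof_matches_monte_carlo(self):
        rng = np.random.default_rng(5)
        lam = np.array([3.0, 0.5, 0.2])
        Q = rng.chisquare(1, size=(400_000, 3)) @ lam
        for q in (0.1, 0.5, 0.9):
            x = float(np.quantile(Q, q))
            mc = float((Q > x).mean())
            assert imhof_sf(x, lam)[0] == pytest.approx(mc, abs=5e-3)

    # Liu is an upper-tail approximation: its absolute error against the exact
    # inversion shrinks as the tail deepens
    @pytest.mark.parametrize("target,tol", [(0.05, 1e-2), (0.01, 3e-3), (0.001, 5e-4)])
    def test_liu_agrees_with_imhof_in_upper_tail(self, target, tol):
        rng = np.random.default_rng(11)
        for _ in range(15):
            m = int(rng.integers(2, 11))
            rho = float(rng.uniform(0.0, 0.8))
            ld = rho * np.ones((m, m)) + (1 - rho) * np.eye(m)
            lam = np.linalg.eigvalsh(ld)
            lam = lam[lam > 1e-12]
            # invert the exact tail by bisection to land at p = target
            lo, hi = 0.0, 100.0 * lam.sum()
            for _ in range(50):
                mid = (lo + hi) / 2
                if imhof_sf(mid, lam)[0] > target:
                    lo = mid
                else:
                    hi = mid
            x = (lo + hi) / 2
            assert liu_sf(x, lam) == pytest.approx(target, abs=tol)


class TestWeightFromPg:
    def test_median_is_zero(self):
        assert weight_from_pg(0.5) == 0.0

    def test_upper_five_percent(self):
        assert weight_from_pg(0.05) == pytest.approx(1.6448536269514729, rel=1e-10)

    def test_pg_one_clamped(self):
        assert weight_from_pg(1.0) == pytest.approx(-8.209536151601387, rel=1e-9)

    def test_inverse_of_normal_sf(self):
        # exact inverse wherever p_g = 1 - Phi(z) is representable in double
        # precision; near z = -8 the p value sits ~1e-15 below 1.0 and the
        # round trip is limited by the spacing of doubles there
        for z in np.linspace(-5, 8, 27):
            assert weight_from_pg(float(stats.norm.sf(z))) == pytest.approx(
                z, abs=1e-9
            )
        assert weight_from_pg(float(stats.norm.sf(-8.0))) == pytest.approx(-8.0, abs=0.05)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.0001, float("nan")])
    def test_domain(self, bad):
        with pytest.raises(DomainError):
            weight_from_pg(bad)


class TestScoreGenes:
    def test_single_snp_identity_ld_is_identity_on_p(self):
        regions = [GeneRegion("G1", "1", 1000, 2000)]
        table = score_genes([snp(1, 1, 1500, 0.05)], regions)
        assert table.loc[0, "p_g"] == pytest.approx(0.05, abs=1e-10)
        assert not table.loc[0, "excluded"]

    def test_extreme_gene_flagged_excluded(self):
        regions = [GeneRegion("G1", "1", 1000, 2000)]
        table = score_genes([snp(1, 1, 1500, 5e-13)], regions)
        assert bool(table.loc[0, "excluded"])

    def test_shared_snp_contributes_to_both_genes(self):
        regions = [
            GeneRegion("G1", "1", 100_000, 120_000),
            GeneRegion("G2", "1", 160_000, 180_000),
        ]
        table = score_genes([snp(1, 1, 150_000, 0.01)], regions).set_index("gene")
        assert table.loc["G1", "T"] == pytest.approx(table.loc["G2", "T"], rel=1e-12)

    def test_null_chain_calibration_quick(self):
        # 400 null genes, 4 SNPs each, identity LD: p_g should look uniform
        rng = np.random.default_rng(123)
        regions, snps = [], []
        for i in range(400):
            start = 1_000_000 + i * 200_000
            regions.append(GeneRegion(f"G{i:04d}", "1", start, start + 20_000))
            for j in range(4):
                snps.append(
                    snp(f"{i}_{j}", 1, start + j * 5_000, float(rng.uniform(0, 1)))
                )
        table = score_genes(snps, regions)
        ks = stats.kstest(table["p_g"], "uniform")
        assert ks.pvalue > 0.01
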