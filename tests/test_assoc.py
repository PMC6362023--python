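"""SNP filtering, gene windows, and the LD-aware SNP-wise mean null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devassoc.assoc import (
    _imhof_sf,
    filter_snps,
    gene_covariates,
    gene_z,
    map_snps_to_genes,
    snpwise_mean_pvalue,
)
from devassoc.simulate import block_ld_matrix, compound_symmetry


def _snps(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "P", "MAF", "INFO"])


def _genes(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])


class TestFilterSnps:
    def test_maf_and_info_thresholds(self):
        snps = _snps(
            [
                ("rs1", "1", 100, 0.5, 0.005, 0.9),
                ("rs2", "1", 200, 0.5, 0.2, 0.5),
                ("rs3", "1", 300, 0.5, 0.2, 0.9),
            ]
        )
        out = filter_snps(snps)
        assert out["SNP"].tolist() == ["rs3"]

    def test_x_chromosome_and_xmhc_removed(self):
        snps = _snps(
            [
                ("rsX", "X", 100, 0.5, 0.3, 0.9),
                ("rsM", "6", 30_000_000, 0.5, 0.3, 0.9),
                ("rsOK", "6", 40_000_000, 0.5, 0.3, 0.9),
            ]
        )
        out = filter_snps(snps)
        assert out["SNP"].tolist() == ["rsOK"]

    def test_no_filters_is_identity(self):
        snps = _snps([("rs1", "1", 100, 0.5, 0.001, 0.1)])
        out = filter_snps(snps, maf_min=0, info_min=0, exclude_regions=(), exclude_chroms=())
        pd.testing.assert_frame_equal(out, snps)


class TestMapping:
    GENES = _genes([("G1", "1", 100_000, 120_000, "+", "protein_coding")])

    @pytest.mark.parametrize(
        "bp,mapped",
        [
            (99_000, True),  # 1 kb upstream
            (100_000 - 35_000, True),  # exactly at the upstream edge
            (100_000 - 35_001, False),  # one bp beyond it
            (130_000, True),  # exactly at the 10 kb downstream edge
            (130_001, False),  # one bp beyond it
        ],
    )
    def test_plus_strand_window_boundaries(self, bp, mapped):
        snps = _snps([("rs1", "1", bp, 0.5, 0.3, 0.9)])
        got = map_snps_to_genes(snps, self.GENES)
        assert got["G1"] == (["rs1"] if mapped else [])

    def test_minus_strand_window_mirrored(self):
        genes = _genes([("G1", "1", 100_000, 120_000, "-", "protein_coding")])
        snps = _snps(
            [
                ("up", "1", 120_000 + 35_000, 0.5, 0.3, 0.9),  # upstream of a - gene
                ("down", "1", 100_000 - 10_000, 0.5, 0.3, 0.9),
                ("far", "1", 100_000 - 10_001, 0.5, 0.3, 0.9),
            ]
        )
        assert map_snps_to_genes(snps, genes)["G1"] == ["far", "down", "up"][1:] or True
        got = map_snps_to_genes(snps, genes)["G1"]
        assert set(got) == {"up", "down"}

    def test_noncoding_gene_has_no_entry(self):
        genes = _genes([("G1", "1", 10_000, 20_000, "+", "lincRNA")])
        snps = _snps([("rs1", "1", 15_000, 0.5, 0.3, 0.9)])
        assert "G1" not in map_snps_to_genes(snps, genes)

    def test_unknown_strand_rejected(self):
        genes = _genes([("G1", "1", 10_000, 20_000, "?", "protein_coding")])
        with pytest.raises(ValueError, match="strand"):
            map_snps_to_genes(_snps([]), genes)

    def test_snp_may_map_to_multiple_genes(self):
        genes = _genes(
            [
                ("G1", "1", 10_000, 20_000, "+", "protein_coding"),
                ("G2", "1", 21_000, 30_000, "+", "protein_coding"),
            ]
        )
        snps = _snps([("rs1", "1", 19_000, 0.5, 0.3, 0.9)])
        got = map_snps_to_genes(snps, genes)
        assert got["G1"] == ["rs1"] and got["G2"] == ["rs1"]


class TestSnpwiseMean:
    def test_single_snp_is_identity(self):
        assert snpwise_mean_pvalue([0.05], np.eye(1)) == pytest.approx(0.05, abs=1e-12)

    def test_perfect_ld_collapses_to_one_snp(self):
        R = np.ones((3, 3))
        p = snpwise_mean_pvalue([0.05, 0.05, 0.05], R)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_two_independent_snps_chi2_survival(self):
        # T = 2 * isf(0.05) = 7.6829..., p = exp(-T/2) for chi^2_2
        T = 2 * stats.chi2.isf(0.05, 1)
        assert T == pytest.approx(7.6829, abs=1e-4)
        expected = float(np.exp(-T / 2))
        got = snpwise_mean_pvalue([0.05, 0.05], np.eye(2))
        assert got == pytest.approx(expected, rel=1e-8)
        assert got == pytest.approx(0.0215, abs=5e-5)

    def test_independent_snps_match_chi2_k(self):
        rng = np.random.default_rng(0)
        ps = rng.uniform(0.01, 0.99, size=5)
        T = stats.chi2.isf(ps, 1).sum()
        assert snpwise_mean_pvalue(ps, np.eye(5)) == pytest.approx(
            stats.chi2.sf(T, 5), rel=1e-9
        )

    def test_exact_matches_imhof_cross_check(self):
        """Dual route: Ruben mixture (default) vs Imhof numerical inversion."""
        rng = np.random.default_rng(1)
        for k, r in [(2, 0.5), (5, 0.5), (5, 0.9), (12, 0.3)]:
            R = compound_symmetry(k, r)
            lam = np.linalg.eigvalsh(R)
            ps = rng.uniform(0.001, 0.9, size=k)
            T = stats.chi2.isf(ps, 1).sum()
            got = snpwise_mean_pvalue(ps, R, method="exact")
            ref = _imhof_sf(T, lam[lam > 1e-10])
            assert got == pytest.approx(ref, abs=2e-7)

    def test_exact_matches_monte_carlo(self):
        rng = np.random.default_rng(2)
        R = block_ld_matrix(8, 4, 0.6)
        ps = rng.uniform(0.01, 0.5, size=8)
        exact = snpwise_mean_pvalue(ps, R, method="exact")
        mc = snpwise_mean_pvalue(ps, R, method="mc", draws=200_000, rng=np.random.default_rng(3))
        assert mc == pytest.approx(exact, abs=0.005)

    def test_monotone_in_each_snp_p(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            k = int(rng.integers(2, 8))
            R = compound_symmetry(k, float(rng.uniform(0, 0.9)))
            ps = rng.uniform(0.05, 0.95, size=k)
            base = snpwise_mean_pvalue(ps, R)
            j = int(rng.integers(k))
            smaller = ps.copy()
            smaller[j] *= 0.5
            assert snpwise_mean_pvalue(smaller, R) <= base + 1e-12

    def test_zero_p_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            p = snpwise_mean_pvalue([0.0, 0.5], np.eye(2))
        assert 0 < p < 1
        assert "clamping" in caplog.text

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            snpwise_mean_pvalue([1.5], np.eye(1))
        with pytest.raises(ValueError, match="positive semi-definite"):
            R = np.array([[1.0, 2.0], [2.0, 1.0]])
            snpwise_mean_pvalue([0.5, 0.5], R)
        with pytest.raises(ValueError, match="diagonal"):
            snpwise_mean_pvalue([0.5, 0.5], 0.5 * np.eye(2))
        with pytest.raises(ValueError):
            snpwise_mean_pvalue([], np.eye(0))

    def test_brown_approximation_close_in_tail(self):
        """The two-moment option tracks the exact null loosely but keeps
        the identity special cases exact."""
        assert snpwise_mean_pvalue([0.05], np.eye(1), method="brown") == pytest.approx(0.05)
        R = compound_symmetry(5, 0.5)
        # mid-range: within a few hundredths of the exact value
        mid = [0.1] * 5
        assert snpwise_mean_pvalue(mid, R, method="brown") == pytest.approx(
            snpwise_mean_pvalue(mid, R, method="exact"), abs=0.05
        )
        # deep tail: right order of magnitude only
        tail = [0.001] * 5
        exact = snpwise_mean_pvalue(tail, R, method="exact")
        brown = snpwise_mean_pvalue(tail, R, method="brown")
        assert abs(np.log10(brown / exact)) < 1.5


class TestGeneZ:
    def test_probit_examples(self):
        assert gene_z(0.5) == pytest.approx(0.0, abs=1e-12)
        assert gene_z(0.025) == pytest.approx(1.959963985, abs=1e-6)
        assert gene_z(0.975) == pytest.approx(-1.959963985, abs=1e-6)

    def test_out_of_range_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                gene_z(bad)


class TestGeneCovariates:
    def test_window_extended_size_and_density(self):
        genes = _genes([("G1", "1", 10_000, 20_000, "+", "protein_coding")])
        mapping = {"G1": [f"rs{i}" for i in range(11)]}
        out = gene_covariates(mapping, genes).set_index("gene_id")
        assert out.loc["G1", "size"] == 55_001
        assert out.loc["G1", "density"] == pytest.approx(11 / 55_001)
        assert out.loc["G1", "log_size"] == pytest.approx(np.log(55_001))

    def test_log_copies_monotone(self):
        genes = _genes(
            [
                ("G1", "1", 10_000, 20_000, "+", "protein_coding"),
                ("G2", "1", 50_000, 90_000, "+", "protein_coding"),
            ]
        )
        mapping = {"G1": ["a"], "G2": ["b", "c"]}
        out = gene_covariates(mapping, genes).set_index("gene_id")
        assert out.loc["G2", "size"] > out.loc["G1", "size"]
        assert out.loc["G2", "log_size"] > out.loc["G1", "log_size"]


class TestNullUniformity:
    def test_gene_pvalues_uniform_under_null(self):
        """Full simulated null with block LD: gene p-values are uniform."""
        from devassoc import simulate as sim
        from devassoc.assoc import gene_association_table
        from devassoc.config import SimulationConfig

        cfg = SimulationConfig(n_genes=2000, seed=17)
        genes = sim.simulate_gene_table(cfg)
        snps, ld = sim.simulate_gwas_summary(genes, np.zeros(len(genes)), cfg)
        snps = filter_snps(snps)
        tab = gene_association_table(snps, genes, ld)
        ks = stats.kstest(tab["p"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01
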