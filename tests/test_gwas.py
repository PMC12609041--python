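import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from priorgs import (
    BlinkConfig,
    TraitSpec,
    blink,
    select_pseudo_qtns,
    select_top_fraction,
    simulate_genotypes,
    simulate_phenotypes,
    single_marker_scan,
)
from priorgs.gwas import AssocResult

from conftest import make_geno


def adjusted(geno, values):
    return pd.DataFrame({"id": geno.ids, "trait": "t", "adjusted_value": values,
                         "n_records_used": 1})


class TestSingleMarkerScan:
    def test_reduces_to_simple_regression(self):
        g = simulate_genotypes(120, 60, seed=61)
        rng = np.random.default_rng(62)
        y = rng.normal(0, 1, 120)
        scan = single_marker_scan(g, adjusted(g, y))
        for j in [0, 7, 33]:
            snp = g.snps["id"].iloc[j]
            lr = stats.linregress(g.dosages[:, j], y)
            row = scan[scan["id"] == snp].iloc[0]
            assert row["p"] == pytest.approx(lr.pvalue, abs=1e-10)
            assert row["effect"] == pytest.approx(lr.slope, abs=1e-10)

    def test_planted_signal_attains_min_p(self):
        g = simulate_genotypes(200, 100, seed=63)
        rng = np.random.default_rng(64)
        q = g.snps["id"].iloc[42]
        y = 2.0 * g.dosages[:, 42] + rng.normal(0, 0.01, 200)
        scan = single_marker_scan(g, adjusted(g, y))
        assert scan.loc[scan["p"].idxmin(), "id"] == q

    def test_monomorphic_snp_untestable(self):
        d = np.array([[0.0, 1], [0, 2], [0, 1], [0, 0]])
        g = make_geno(d)
        scan = single_marker_scan(g, adjusted(g, [1.0, 2.0, 3.0, 4.0]))
        row = scan[scan["id"] == "s1"].iloc[0]
        assert row["effect"] == 0.0 and row["p"] == 1.0

    def test_covariate_snp_tested_against_rest(self):
        g = simulate_genotypes(150, 30, seed=65)
        rng = np.random.default_rng(66)
        y = 1.5 * g.dosages[:, 3] + rng.normal(0, 0.5, 150)
        q = g.snps["id"].iloc[3]
        scan = single_marker_scan(g, adjusted(g, y), covariate_qtns=[q])
        # the covariate itself keeps a meaningful (small) p-value
        assert scan.loc[scan["id"] == q, "p"].iloc[0] < 1e-10

    def test_null_pvalues_uniform(self):
        g = simulate_genotypes(500, 2000, seed=67)
        spec = TraitSpec(h2_true=0.0, rep_true=0.0, n_qtl=1, factor_sd=0.0,
                         records_per_individual=(1, 1, 1))
        records, _ = simulate_phenotypes(g, spec, seed=68)
        y = records.set_index("id").loc[g.ids, "value"].to_numpy()
        scan = single_marker_scan(g, adjusted(g, y))
        ks = stats.kstest(scan["p"], "uniform").statistic
        assert ks < 0.05


class TestSelectPseudoQtns:
    def test_matches_exhaustive_criterion_oracle(self):
        g = simulate_genotypes(100, 3, n_chrom=1, seed=71)
        rng = np.random.default_rng(72)
        y = 0.8 * g.dosages[:, 0] - 0.6 * g.dosages[:, 2] + rng.normal(0, 0.5, 100)
        pheno = adjusted(g, y)
        cfg = BlinkConfig(max_pseudo_qtns=3)
        scan = single_marker_scan(g, pheno)
        chosen = select_pseudo_qtns(scan, g, pheno, cfg)
        # oracle: refit every prefix of the p-ordered candidates, same penalty
        order = scan.sort_values(["p", "chrom", "pos"])["id"].tolist()
        cols = {s: j for j, s in enumerate(g.snps["id"])}
        best, best_crit = 0, math.inf
        for t in range(4):
            X = np.column_stack([np.ones(100)] + [g.dosages[:, cols[s]] for s in order[:t]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            ll = -0.5 * 100 * (math.log(2 * math.pi * rss / 100) + 1)
            crit = -2 * ll + 2 * t * math.log(100)
            if crit < best_crit - 1e-12:
                best, best_crit = t, crit
        assert chosen == order[:best]

    def test_perfect_ld_duplicate_never_retained(self):
        rng = np.random.default_rng(73)
        x = rng.binomial(2, 0.5, 200).astype(float)
        noise = rng.binomial(2, 0.5, 200).astype(float)
        g = make_geno(np.column_stack([x, x, noise]))
        y = x * 1.0 + rng.normal(0, 0.3, 200)
        pheno = adjusted(g, y)
        scan = single_marker_scan(g, pheno)
        chosen = select_pseudo_qtns(scan, g, pheno, BlinkConfig(ld_r2_max=0.7))
        assert not {"s1", "s2"} <= set(chosen)

    def test_null_selects_zero_mostly(self):
        zeros = 0
        for seed in range(10):
            g = simulate_genotypes(200, 50, seed=700 + seed)
            y = np.random.default_rng(800 + seed).normal(0, 1, 200)
            pheno = adjusted(g, y)
            scan = single_marker_scan(g, pheno)
            if select_pseudo_qtns(scan, g, pheno) == []:
                zeros += 1
        assert zeros >= 8

    def test_high_pvalues_select_none(self):
        # construct a response orthogonal to every marker: p-values all large
        g = make_geno([[0, 1], [1, 0], [2, 1], [1, 2], [0, 1], [1, 0], [2, 1], [1, 2]])
        y = np.array([1.0, -1, 1, -1, -1, 1, -1, 1])
        pheno = adjusted(g, y)
        scan = single_marker_scan(g, pheno)
        assert (scan["p"] >= 0.5).all()
        assert select_pseudo_qtns(scan, g, pheno) == []


class TestBlink:
    def test_single_iteration_equals_plain_scan(self):
        g = simulate_genotypes(150, 80, seed=74)
        rng = np.random.default_rng(75)
        y = 1.2 * g.dosages[:, 10] + rng.normal(0, 0.5, 150)
        pheno = adjusted(g, y)
        res = blink(g, pheno, BlinkConfig(max_iterations=1))
        plain = single_marker_scan(g, pheno)
        pd.testing.assert_frame_equal(res.results, plain)
        assert res.n_iterations == 1

    def test_planted_two_qtl_recovered(self):
        g = simulate_genotypes(300, 200, seed=76)
        rng = np.random.default_rng(77)
        qa, qb = 20, 150  # different chromosomes, unlinked
        y = 1.5 * g.dosages[:, qa] - 1.5 * g.dosages[:, qb] + rng.normal(0, 0.3, 300)
        res = blink(g, adjusted(g, y))
        names = {g.snps["id"].iloc[qa], g.snps["id"].iloc[qb]}
        assert names <= set(res.pseudo_qtns)
        assert res.converged

    def test_deterministic(self):
        g = simulate_genotypes(100, 60, seed=78)
        y = np.random.default_rng(79).normal(0, 1, 100)
        r1 = blink(g, adjusted(g, y))
        r2 = blink(g, adjusted(g, y))
        pd.testing.assert_frame_equal(r1.results, r2.results)
        assert r1.pseudo_qtns == r2.pseudo_qtns


class TestSelectTopFraction:
    @staticmethod
    def synthetic_assoc(m, seed=0):
        rng = np.random.default_rng(seed)
        res = pd.DataFrame({
            "chrom": np.repeat(1, m), "pos": np.arange(1, m + 1),
            "id": [f"s{j}" for j in range(m)],
            "effect": 0.0, "stat": 0.0, "p": rng.uniform(size=m),
        })
        return AssocResult(results=res)

    @pytest.mark.parametrize("fraction,expected", [
        (0.05, 3351), (0.10, 6702), (0.15, 10053), (0.20, 13404)])
    def test_panel_counts_at_67021(self, fraction, expected):
        assoc = self.synthetic_assoc(67021)
        assert len(select_top_fraction(assoc, fraction)) == expected

    def test_fraction_one_returns_genome_order(self):
        assoc = self.synthetic_assoc(50, seed=4)
        out = select_top_fraction(assoc, 1.0)
        assert out == assoc.results.sort_values(["chrom", "pos"])["id"].tolist()

    @pytest.mark.parametrize("m,fraction", [(101, 0.05), (67021, 0.1), (10, 0.35)])
    def test_exact_floor_size(self, m, fraction):
        assoc = self.synthetic_assoc(m, seed=m)
        assert len(select_top_fraction(assoc, fraction)) == math.floor(fraction * m)

    def test_ties_broken_by_genome_order(self):
        res = pd.DataFrame({"chrom": [2, 1, 1], "pos": [5, 9, 2],
                            "id": ["x", "y", "z"], "effect": 0.0, "stat": 0.0,
                            "p": [0.5, 0.5, 0.5]})
        assert select_top_fraction(AssocResult(results=res), 0.34) == ["z"]

    def test_zero_selection_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction(self.synthetic_assoc(10), 0.05)

    def test_conditioning_deflates_linked_markers(self):
        g = simulate_genotypes(400, 100, n_chrom=1, maf_range=(0.2, 0.5),
                               seed=80, ld_rho=0.9, ld_block_size=10)
        rng = np.random.default_rng(81)
        q = 25  # middle of a block
        y = 1.5 * g.dosages[:, q] + rng.normal(0, 0.5, 400)
        pheno = adjusted(g, y)
        unconditioned = single_marker_scan(g, pheno)
        conditioned = single_marker_scan(g, pheno, covariate_qtns=[g.snps["id"].iloc[q]])
        block = [g.snps["id"].iloc[j] for j in range(20, 30) if j != q]
        pu = unconditioned.set_index("id").loc[block, "p"].median()
        pc = conditioned.set_index("id").loc[block, "p"].median()
        assert pc > pu
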