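import numpy as np
import pandas as pd
import pytest

from priorgs import (
    TraitSpec,
    accuracy,
    blend,
    compare_scenarios,
    cross_validate,
    fit_repeatability_model,
    predict_gebv,
    promotion,
    run_scenarios,
    simulate_genotypes,
    simulate_phenotypes,
    vanraden,
)
from priorgs.gs_eval import assign_folds


def single_record_data(n=50, m=400, seed=120, h2=0.5):
    geno = simulate_genotypes(n, m, seed=seed)
    spec = TraitSpec(h2_true=h2, rep_true=h2, n_qtl=40, factor_sd=0.0,
                     records_per_individual=(1, 1, 1))
    records, truth = simulate_phenotypes(geno, spec, seed=seed + 1)
    return geno, records, truth


class TestPredictGebv:
    def test_translation_invariance(self):
        geno, records, _ = single_record_data()
        K = blend(vanraden(geno), 0.01)
        vc = (0.4, 0.0, 0.6)
        g0 = predict_gebv(records, K, ["year"], vc)
        shifted = records.assign(value=records["value"] + 123.4)
        g1 = predict_gebv(shifted, K, ["year"], vc)
        assert np.allclose(g0, g1, atol=1e-8)

    def test_gblup_equals_snp_blup_ridge(self):
        # kinship-based mixed-model solution == centered-marker ridge
        geno, records, _ = single_record_data(n=50, m=300, seed=130)
        K = vanraden(geno)  # unblended: identity must be exact
        s2a, s2e = 0.45, 0.55
        gebv = predict_gebv(records, K, [], (s2a, 0.0, s2e))

        y = records.set_index("id").loc[geno.ids, "value"].to_numpy()
        p = geno.allele_freqs()
        Z = geno.dosages - 2 * p
        c = 2 * np.sum(p * (1 - p))
        V = s2a * (Z @ Z.T) / c + s2e * np.eye(len(y))
        Vi = np.linalg.inv(V)
        one = np.ones(len(y))
        mu = (one @ Vi @ y) / (one @ Vi @ one)
        a_hat = np.linalg.solve(Z.T @ Z + (s2e * c / s2a) * np.eye(Z.shape[1]),
                                Z.T @ (y - mu))
        ridge_pred = Z @ a_hat
        assert np.allclose(gebv.loc[geno.ids].to_numpy(), ridge_pred, atol=1e-6)

    def test_zero_genetic_variance_gives_zero_gebv(self):
        geno, records, _ = single_record_data(n=30, m=100, seed=140)
        K = blend(vanraden(geno), 0.01)
        g = predict_gebv(records, K, ["year"], (0.0, 0.0, 1.0))
        assert np.all(g == 0)

    def test_unrecorded_individuals_predicted_through_kinship(self):
        geno, records, truth = single_record_data(n=200, m=600, seed=150)
        K = blend(vanraden(geno), 0.01)
        train = records[records["id"].isin(set(geno.ids[:150]))]
        vc = fit_repeatability_model(train, K, ["year"])
        gebv = predict_gebv(train, K, ["year"], vc)
        val = geno.ids[150:]
        tbv = truth.true_breeding_values.loc[val]
        assert np.corrcoef(gebv.loc[val], tbv)[0, 1] > 0.2

    def test_missing_individual_in_kinship_rejected(self):
        geno, records, _ = single_record_data(n=20, m=80, seed=160)
        K = blend(vanraden(geno), 0.01).reorder(geno.ids[:10])
        with pytest.raises(ValueError, match="absent"):
            predict_gebv(records, K, ["year"], (0.3, 0.0, 0.7))


class TestAccuracy:
    def test_hand_computed_value(self):
        a = np.array([1.0, 2, 3, 4])
        p = np.array([2.0, 4, 5, 9])
        cov = np.mean((a - a.mean()) * (p - p.mean()))
        oracle = cov / (a.std() * p.std())
        assert accuracy(a, p) == pytest.approx(oracle, abs=1e-12)

    def test_perfect_and_reversed(self):
        v = np.array([0.3, 1.2, -0.7, 2.2])
        assert accuracy(v, v) == pytest.approx(1.0)
        assert accuracy(v, -v) == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        a, p = rng.normal(size=30), rng.normal(size=30)
        assert accuracy(3.5 * a + 2, p) == pytest.approx(accuracy(a, p), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.ones(5), np.arange(5.0))


class TestCrossValidate:
    def test_fold_balance_103_individuals(self):
        folds = assign_folds(np.array([f"i{k}" for k in range(103)]), 5, seed=1)
        sizes = sorted(folds.value_counts().tolist(), reverse=True)
        assert sizes == [21, 21, 21, 20, 20]

    def test_deterministic_under_seed(self):
        geno = simulate_genotypes(100, 300, seed=170)
        records, _ = simulate_phenotypes(
            geno, TraitSpec(h2_true=0.4, rep_true=0.5, n_qtl=30), seed=171)
        K = blend(vanraden(geno), 0.01)
        r1 = cross_validate(records, K, seed=5)
        r2 = cross_validate(records, K, seed=5)
        assert np.array_equal(r1.fold_accuracies, r2.fold_accuracies)
        assert r1.fold_assignments.equals(r2.fold_assignments)

    def test_every_individual_in_exactly_one_fold(self):
        ids = np.array([f"i{k}" for k in range(57)])
        folds = assign_folds(ids, 5, seed=2)
        assert len(folds) == 57 and set(folds) == {1, 2, 3, 4, 5}


class TestPromotion:
    @pytest.mark.parametrize("acc,base,expected", [
        (0.742, 0.636, 16.67),
        (0.851, 0.775, 9.81),
        (0.5, 0.5, 0.0),
    ])
    def test_reference_arithmetic(self, acc, base, expected):
        assert promotion(acc, base) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            promotion(0.7, 0.0)


class TestCompareScenarios:
    def test_identical_values_share_letter(self):
        letters = compare_scenarios({"A": [0.5] * 5, "B": [0.5] * 5})
        assert letters == {"A": "a", "B": "a"}

    def test_large_separation_distinct_letters(self):
        rng = np.random.default_rng(4)
        letters = compare_scenarios({
            "low": 0.2 + 0.01 * rng.normal(size=5),
            "high": 0.9 + 0.01 * rng.normal(size=5),
        })
        assert set(letters["low"]) & set(letters["high"]) == set()

    def test_single_scenario(self):
        assert compare_scenarios({"only": [0.1, 0.2, 0.3]}) == {"only": "a"}

    def test_intermediate_overlap_shares_letter(self):
        rng = np.random.default_rng(5)
        groups = {
            "a": 0.80 + 0.02 * rng.normal(size=5),
            "ab": 0.77 + 0.02 * rng.normal(size=5),
            "b": 0.50 + 0.02 * rng.normal(size=5),
        }
        letters = compare_scenarios(groups)
        assert set(letters["a"]) & set(letters["ab"])
        assert not set(letters["a"]) & set(letters["b"])

    def test_unequal_replicates_rejected(self):
        with pytest.raises(ValueError):
            compare_scenarios({"A": [1, 2, 3], "B": [1, 2]})


class TestRunScenarios:
    def test_shared_folds_and_promotion_sign(self):
        geno = simulate_genotypes(120, 400, seed=180)
        records, truth = simulate_phenotypes(
            geno, TraitSpec(h2_true=0.4, rep_true=0.5, n_qtl=20,
                            qtl_effect_dist=("gamma", 1.0)), seed=181)
        G_all = blend(vanraden(geno), 0.01)
        prior = truth.qtl_ids
        rest = [i for i in geno.snps["id"] if i not in set(prior)]
        G1 = blend(vanraden(geno, prior, kind="prior"), 0.01)
        reports = run_scenarios(records, {"All": G_all, "QTL": G1}, seed=7)
        assert reports["All"].fold_assignments.equals(reports["QTL"].fold_assignments)
        assert reports["All"].promotion_pct == 0.0
        assert reports["QTL"].promotion_pct is not None
        assert all(r.letters for r in reports.values())
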