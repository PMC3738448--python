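"""Generator calibration: LD, errors, missingness, phenotype, statistics."""

import math

import numpy as np
import pytest

from locrank import analytic
from locrank.ld import (chain_ld_model, dosage_corr_from_latent,
                        latent_from_dosage_corr, two_causal_ld_model)
from locrank.records import scenario_config
from locrank.simulate import (association_scan, error_rate_for_mean_accuracy,
                              flip_accuracy, inject_errors, inject_missing,
                              logistic_intercept, mean_accuracy_of_error,
                              simulate_genotypes, simulate_phenotype)


class TestLdModel:
    def test_inversion_round_trip(self):
        for r in (0.3, 0.73, 0.95, 0.975):
            s = latent_from_dosage_corr(r, 0.05)
            assert dosage_corr_from_latent(s, 0.05) == pytest.approx(r,
                                                                     abs=2e-6)

    def test_perfect_target_gives_unit_latent(self):
        assert latent_from_dosage_corr(1.0, 0.2) == 1.0

    def test_infeasible_target_raises(self):
        # different MAFs bound the attainable dosage correlation below 1
        with pytest.raises(ValueError, match="infeasible"):
            latent_from_dosage_corr(0.99, 0.05, 0.4)

    def test_chain_spans_published_tagging_range(self):
        """0.975-adjacent chain of 10 SNPs: correlations to the causal end
        span ~0.80 to 0.975."""
        ld = chain_ld_model(10, 0.975, 0.95, 0.05)
        to_causal = ld.target_corr[0, 1:10]
        assert to_causal[0] == pytest.approx(0.975)
        assert to_causal[-1] == pytest.approx(0.975 ** 9, abs=1e-9)
        assert 0.78 < to_causal[-1] < 0.81

    def test_realized_dosage_correlations_match_targets(self):
        ld = chain_ld_model(4, 0.975, 0.95, 0.05)
        rng = np.random.default_rng(0)
        g = simulate_genotypes(ld, 400_000, rng)
        emp = np.corrcoef(g.T)
        assert np.abs(emp - ld.target_corr).max() < 0.005

    def test_two_causal_tree_hits_stated_targets(self):
        ld = two_causal_ld_model(11, 0.975, 0.95, 0.73, 0.05)
        a, b, tag = 0, 10, 11
        assert ld.target_corr[a, b] == pytest.approx(0.73)
        assert ld.target_corr[tag, b] == pytest.approx(0.95)
        assert np.linalg.eigvalsh(ld.latent_corr).min() > -1e-9


class TestGenotypes:
    def test_maf_recovered_within_binomial_bound(self):
        ld = chain_ld_model(3, 0.9, 0.8, 0.05)
        rng = np.random.default_rng(1)
        n = 50_000
        g = simulate_genotypes(ld, n, rng)
        freq = g.mean(axis=0) / 2
        bound = 4 * math.sqrt(0.05 * 0.95 / (2 * n))
        assert np.abs(freq - 0.05).max() < bound

    def test_independent_snps_uncorrelated(self):
        from locrank.ld import LdModel
        ld = LdModel(target_corr=np.eye(3), latent_corr=np.eye(3), maf=0.2,
                     causal_indices=(0,), tag_index=2)
        g = simulate_genotypes(ld, 50_000, np.random.default_rng(2))
        off = np.corrcoef(g.T) - np.eye(3)
        assert np.abs(off).max() < 0.02

    def test_seed_determinism(self):
        ld = chain_ld_model(3, 0.9, 0.8, 0.1)
        a = simulate_genotypes(ld, 100, np.random.default_rng(7))
        b = simulate_genotypes(ld, 100, np.random.default_rng(7))
        assert np.array_equal(a, b)


class TestErrors:
    def test_zero_rate_is_identity(self):
        g = np.random.default_rng(3).binomial(2, 0.3, size=(500, 2))
        obs, rho = inject_errors(g, np.zeros(2), np.random.default_rng(0))
        assert np.array_equal(obs, g)
        assert np.all(rho == 1.0)

    def test_flip_rates_reproduce_published_accuracies(self):
        """Per-allele flip rates 2% and 1% at low MAF give accuracies near
        the published 0.82 and 0.90 (exact closed form at MAF 4.8%)."""
        assert flip_accuracy(0.02, 0.048) == pytest.approx(0.82, abs=0.01)
        assert flip_accuracy(0.01, 0.048) == pytest.approx(0.90, abs=0.01)
        assert flip_accuracy(0.02, 0.05) == pytest.approx(0.82, abs=0.015)
        assert flip_accuracy(0.01, 0.05) == pytest.approx(0.90, abs=0.015)

    def test_realized_rho_matches_closed_form(self):
        rng = np.random.default_rng(4)
        n = 200_000
        g = rng.binomial(2, 0.05, size=(n, 2))
        obs, rho = inject_errors(g, np.array([0.02, 0.01]), rng)
        assert rho[0] == pytest.approx(flip_accuracy(0.02, 0.05), abs=0.01)
        assert rho[1] == pytest.approx(flip_accuracy(0.01, 0.05), abs=0.01)

    def test_mean_accuracy_calibration_round_trip(self):
        e = error_rate_for_mean_accuracy(0.82, 0.05)
        assert mean_accuracy_of_error(e, 0.05) == pytest.approx(0.82,
                                                                abs=1e-6)
        # heterogeneity U(0, 2e) is accuracy-convex: the calibrated mean
        # rate exceeds the fixed-rate solution
        e_fixed = error_rate_for_mean_accuracy(0.82, 0.05,
                                               heterogeneous=False)
        assert e > e_fixed

    def test_rates_out_of_range_rejected(self):
        g = np.zeros((10, 1), dtype=int)
        with pytest.raises(ValueError):
            inject_errors(g, np.array([0.6]), np.random.default_rng(0))


class TestMissing:
    def test_full_call_rate_no_missing(self):
        g = np.ones((200, 3), dtype=int)
        obs = inject_missing(g, np.ones(3), np.random.default_rng(0))
        assert not np.isnan(obs).any()

    def test_realized_call_rate_within_binomial_bound(self):
        rng = np.random.default_rng(5)
        n = 20_000
        g = np.ones((n, 2), dtype=int)
        obs = inject_missing(g, np.array([0.8, 0.95]), rng)
        cr = (~np.isnan(obs)).mean(axis=0)
        for target, got in zip((0.8, 0.95), cr):
            assert abs(got - target) < 4 * math.sqrt(
                target * (1 - target) / n)

    def test_joint_call_rate_factorizes_and_tag_exempt(self):
        rng = np.random.default_rng(6)
        n = 40_000
        g = np.ones((n, 3), dtype=int)
        obs = inject_missing(g, np.array([0.8, 0.9, 0.7]), rng, tag_index=2)
        ok = ~np.isnan(obs)
        assert ok[:, 2].all()
        joint = (ok[:, 0] & ok[:, 1]).mean()
        assert joint == pytest.approx(0.8 * 0.9, abs=0.01)


class TestPhenotype:
    def test_null_effect_equal_frequencies(self):
        ld = chain_ld_model(2, 0.9, 0.8, 0.2)
        g, y = simulate_phenotype(ld, (0.0,), 2000, 2000,
                                  np.random.default_rng(8))
        f_case = g[y == 1, 0].mean() / 2
        f_ctrl = g[y == 0, 0].mean() / 2
        assert abs(f_case - f_ctrl) < 4 * math.sqrt(0.2 * 0.8 / 2000)

    def test_rare_disease_case_frequency(self):
        """Under a rare disease, case allele frequency approaches
        p*OR / (1 - p + p*OR)."""
        ld = chain_ld_model(2, 0.9, 0.8, 0.05)
        g, y = simulate_phenotype(ld, (math.log(2.0),), 3000, 3000,
                                  np.random.default_rng(9), prevalence=0.01)
        f_case = g[y == 1, 0].mean() / 2
        expect = 0.05 * 2 / (0.95 + 0.05 * 2)
        assert f_case == pytest.approx(expect, abs=0.01)

    def test_balanced_cohort_intercept_and_determinism(self):
        assert logistic_intercept(0.05, (math.log(2),), None) == 0.0
        ld = chain_ld_model(2, 0.9, 0.8, 0.05)
        a = simulate_phenotype(ld, (math.log(2),), 200, 200,
                               np.random.default_rng(10))
        b = simulate_phenotype(ld, (math.log(2),), 200, 200,
                               np.random.default_rng(10))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSimDataset:
    def test_dataset_reflects_observation_model(self):
        cfg = scenario_config(3, n_total=600, seed=31, mean_accuracy=0.9,
                              mean_call_rate=0.9)
        from locrank.simulate import simulate_dataset
        ds = simulate_dataset(cfg)
        assert ds.true_dosages.shape == (600, 11)
        assert ds.observed_dosages.shape == (600, 11)
        assert ds.phenotype.sum() == 300
        assert ds.tag_index == 10 and ds.causal_indices == (0,)
        # tag unaffected by errors/missingness
        assert ds.realized_rho[10] == 1.0
        assert ds.realized_callrate[10] == 1.0
        assert (ds.realized_rho[:10] < 1.0).any()
        assert (ds.realized_callrate[:10] < 1.0).all()


class TestAssociationScan:
    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(11)
        n, reps = 300, 2000
        hits = 0
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        for _ in range(reps):
            y = np.zeros(n)
            y[rng.permutation(n)[:n // 2]] = 1
            z = association_scan(g, y)
            hits += abs(z[0]) > 1.959964
        p = hits / reps
        assert abs(p - 0.05) < 4 * math.sqrt(0.05 * 0.95 / reps)

    def test_causal_statistic_mean_matches_noncentrality(self):
        """Empirical mean of the causal SNP's Z matches the closed form for
        the balanced-cohort design."""
        ld = chain_ld_model(2, 0.9, 0.8, 0.05)
        rng = np.random.default_rng(12)
        n1 = n0 = 1250
        zs = []
        for _ in range(300):
            g, y = simulate_phenotype(ld, (math.log(2),), n1, n0, rng)
            zs.append(association_scan(g.astype(float), y)[0])
        # the balanced-cohort model has prevalence ~= 0.516 at these params
        q = 1 - 0.05
        pg = np.array([q * q, 2 * 0.05 * q, 0.05 ** 2])
        prev = float(pg @ (1 / (1 + np.exp(-math.log(2) * np.arange(3)))))
        mu = analytic.noncentrality(0.05, 2.0, n1, n0, prevalence=prev)
        se = np.std(zs) / math.sqrt(len(zs))
        assert np.mean(zs) == pytest.approx(mu, abs=max(3 * se, 0.02 * mu))

    def test_duplicated_column_identical_statistic(self):
        rng = np.random.default_rng(13)
        g = rng.binomial(2, 0.3, size=(400, 1)).astype(float)
        y = (rng.random(400) < 0.5).astype(float)
        z = association_scan(np.hstack([g, g]), y)
        assert z[0] == pytest.approx(z[1])

    def test_monomorphic_warns_and_zeroes(self):
        g = np.zeros((100, 1))
        y = np.r_[np.ones(50), np.zeros(50)]
        with pytest.warns(UserWarning, match="monomorphic"):
            z = association_scan(g, y)
        assert z[0] == 0.0

    def test_single_class_phenotype_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            association_scan(np.ones((10, 1)), np.ones(10))
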