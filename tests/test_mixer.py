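"""Elastic-net score combination: splitting, fitting, effect derivation, pipelines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prsmix.mixer import (
    MixWeights,
    SplitSpec,
    derive_snp_effects,
    fit_mixture,
    improvement_test,
    prsmix,
    prsmix_plus,
    split_samples,
)
from prsmix.pgs_io import HarmonizedScoring, VariantKey
from prsmix.prs_stats import partial_r2
from prsmix.scoring import ScorePanel, compute_prs


def make_panel(values, ids=None, traits=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"S{i}" for i in range(values.shape[1])]
    panel = ScorePanel(
        sample_ids=[f"ind{i}" for i in range(values.shape[0])],
        score_ids=ids,
        values=values,
    )
    if traits:
        panel.trait_labels = dict(zip(ids, traits))
    return panel


def make_harmonized(score_id, positions, weights):
    records = pd.DataFrame({
        "chrom": "1", "pos": positions,
        "ref": "A", "alt": "G", "weight": weights,
    })
    return HarmonizedScoring(score_id, records)


class TestSplit:
    def test_basic_partition(self):
        ids = [f"s{i}" for i in range(100)]
        y = np.random.default_rng(0).standard_normal(100)
        train, test = split_samples(ids, y, SplitSpec(seed=1))
        assert len(train) == 80 and len(test) == 20
        assert set(train).isdisjoint(test)
        assert sorted(train + test) == sorted(ids)

    def test_deterministic_given_seed(self):
        ids = [f"s{i}" for i in range(57)]
        y = np.arange(57, dtype=float)
        a = split_samples(ids, y, SplitSpec(seed=9))
        b = split_samples(ids, y, SplitSpec(seed=9))
        assert a == b
        c = split_samples(ids, y, SplitSpec(seed=10))
        assert a != c

    def test_stratified_prevalence_preserved(self):
        rng = np.random.default_rng(3)
        n = 1000
        y = (rng.random(n) < 0.10).astype(float)
        ids = [f"s{i}" for i in range(n)]
        train, test = split_samples(ids, y, SplitSpec(seed=4))
        pos = {s: i for i, s in enumerate(ids)}
        for part in (train, test):
            prev = y[[pos[s] for s in part]].mean()
            assert 0.09 <= prev <= 0.11

    def test_empty_stratum_raises(self):
        y = np.array([1.0] + [0.0] * 19)
        with pytest.raises(ValueError, match="stratum"):
            split_samples([f"s{i}" for i in range(20)], y, SplitSpec(seed=0))

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestFitMixture:
    def test_single_score_is_a_rescaling(self):
        rng = np.random.default_rng(5)
        n = 2000
        s = rng.standard_normal(n)
        y = 0.8 * s + 0.6 * rng.standard_normal(n)
        n_train = 1600
        panel = make_panel(s[:n_train, None], ids=["ONLY"])
        w = fit_mixture(panel, y[:n_train], seed=1)
        assert w.informative
        combined_test = s[n_train:] * w.alpha_adj[0]
        r2_combined = partial_r2(y[n_train:], combined_test).r2
        r2_single = partial_r2(y[n_train:], s[n_train:]).r2
        assert r2_combined == pytest.approx(r2_single, abs=1e-6)
        rank_corr = stats.spearmanr(
            combined_test, np.sign(w.alpha_adj[0]) * s[n_train:]
        ).statistic
        assert rank_corr == pytest.approx(1.0, abs=1e-12)

    def test_alpha_ratio_recovery(self):
        """Known 0.6/0.4 standardized mixture: recovered weight ratio near 1.5."""
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 5000
            z = rng.standard_normal((n, 2))
            y = 0.6 * z[:, 0] + 0.4 * z[:, 1] + rng.standard_normal(n)
            w = fit_mixture(make_panel(z), y, seed=seed)
            ratios.append(w.alpha_adj[0] / w.alpha_adj[1])
        assert 1.2 <= np.mean(ratios) <= 1.9

    def test_null_outcome_shrinks_weights(self):
        hits = 0
        reps = 10
        for seed in range(reps):
            rng = np.random.default_rng(200 + seed)
            z = rng.standard_normal((2000, 10))
            y = rng.standard_normal(2000)
            w = fit_mixture(make_panel(z), y, seed=seed)
            hits += np.all(np.abs(w.omega) <= 0.05)
        assert hits >= 0.9 * reps

    def test_alpha_adj_is_omega_over_sigma(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal((500, 3)) * np.array([1.0, 5.0, 0.2])
        y = z @ [0.5, 0.1, 1.0] + rng.standard_normal(500)
        w = fit_mixture(make_panel(z), y, seed=0)
        np.testing.assert_allclose(w.alpha_adj, w.omega / w.sigma)
        np.testing.assert_allclose(w.sigma, z.std(axis=0))

    def test_covariates_absorb_confounding(self):
        """With the covariate unpenalized, a covariate-driven outcome leaves scores near zero."""
        rng = np.random.default_rng(7)
        n = 2000
        c = rng.standard_normal(n)
        z = rng.standard_normal((n, 3)) + 0.5 * c[:, None]
        y = 2.0 * c + 0.3 * rng.standard_normal(n)
        w = fit_mixture(make_panel(z), y, covariates=c, seed=0)
        assert abs(w.covariate_coefs[0] - 2.0) < 0.05
        assert np.all(np.abs(w.omega) < 0.05)

    def test_zero_sd_score_named(self):
        z = np.column_stack([np.ones(100), np.random.default_rng(0).standard_normal(100)])
        with pytest.raises(ValueError, match="S0"):
            fit_mixture(make_panel(z), np.random.default_rng(1).standard_normal(100))

    def test_binary_family_recovers_signal(self):
        rng = np.random.default_rng(8)
        n = 800
        z = rng.standard_normal((n, 3))
        eta = 1.0 * z[:, 0] + 0.5 * z[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        w = fit_mixture(make_panel(z), y, family="binary", seed=0)
        assert w.informative
        assert w.omega[0] > w.omega[1] > abs(w.omega[2])


class TestDeriveSnpEffects:
    def test_identity_single_score(self):
        harm = make_harmonized("A", [10, 20, 30], [0.1, -0.2, 0.3])
        w = MixWeights(["A"], omega=[1.0], sigma=[1.0], mu=[0.0], alpha_adj=[1.0],
                       intercept=0.0, covariate_coefs=np.array([]), family="continuous")
        eff = derive_snp_effects(w, [harm])
        np.testing.assert_allclose(sorted(eff.gamma), sorted([0.1, -0.2, 0.3]))

    def test_absent_variant_contributes_zero(self):
        s1 = make_harmonized("A", [10], [0.2])
        s2 = make_harmonized("B", [20], [0.4])
        w = MixWeights(["A", "B"], omega=[0.5, 0.25], sigma=[1.0, 1.0], mu=[0, 0],
                       alpha_adj=[0.5, 0.25], intercept=0.0,
                       covariate_coefs=np.array([]), family="continuous")
        eff = derive_snp_effects(w, [s1, s2])
        gamma = dict(zip([k.pos for k in eff.variants], eff.gamma))
        assert gamma[10] == pytest.approx(0.10)
        assert gamma[20] == pytest.approx(0.10)

    def test_mismatched_ids_raise(self):
        w = MixWeights(["A"], omega=[1.0], sigma=[1.0], mu=[0.0], alpha_adj=[1.0],
                       intercept=0.0, covariate_coefs=np.array([]), family="continuous")
        with pytest.raises(ValueError, match="A"):
            derive_snp_effects(w, [make_harmonized("B", [10], [0.2])])

    def test_scoring_derived_file_equals_score_level_mixture(self, demo_study, demo_panel):
        """SNP-level gamma scoring equals the alpha-weighted score sum per sample."""
        genotypes, scorings, y, _ = demo_study
        w = fit_mixture(demo_panel, y, seed=3)
        eff = derive_snp_effects(w, scorings)
        snp_level, _ = compute_prs(genotypes, eff.to_harmonized())
        score_level = demo_panel.values @ w.alpha_adj
        np.testing.assert_allclose(snp_level, score_level, atol=1e-8)


class TestPipelines:
    def test_noise_score_downweighted_and_no_loss(self, demo_study, demo_panel):
        genotypes, scorings, y, cov = demo_study
        rng = np.random.default_rng(13)
        noise = rng.standard_normal(len(y))
        panel = make_panel(
            np.column_stack([demo_panel.values[:, :3], noise]),
            ids=["PRS001", "PRS002", "PRS003", "NOISE"],
            traits=["trait_specific"] * 4,
        )
        panel.sample_ids = demo_panel.sample_ids
        res = prsmix(panel, "trait_specific", y, cov, SplitSpec(seed=2), rule=None)
        alpha = dict(zip(res.weights.score_ids, res.weights.alpha_adj))
        informative_scale = np.max(np.abs(res.weights.omega))
        assert abs(alpha["NOISE"]) < 0.1 * informative_scale / res.weights.sigma.min()
        assert res.test_accuracy.r2 > 0.5 * res.best_single_test_accuracy.r2

    def test_trait_label_matching_case_normalized(self, demo_study, demo_panel):
        _, _, y, cov = demo_study
        panel = make_panel(demo_panel.values[:, :2], ids=["A", "B"],
                           traits=["Height", "height"])
        panel.sample_ids = demo_panel.sample_ids
        res = prsmix(panel, "HEIGHT", y, cov, SplitSpec(seed=1), rule=None)
        assert set(res.retained_ids) == {"A", "B"}

    def test_unknown_trait_raises(self, demo_study, demo_panel):
        _, _, y, _ = demo_study
        with pytest.raises(ValueError, match="no score annotated"):
            prsmix(demo_panel, "no_such_trait", y)

    def test_single_score_panel_equals_best_single(self, demo_study, demo_panel):
        _, _, y, cov = demo_study
        panel = demo_panel.subset_scores(["PRS001"])
        res = prsmix(panel, "trait_specific", y, cov, SplitSpec(seed=4), rule=None)
        assert res.best_single_id == "PRS001"
        assert res.test_accuracy.r2 == pytest.approx(
            res.best_single_test_accuracy.r2, abs=1e-6
        )

    def test_prsmix_plus_equals_prsmix_on_same_inputs(self, demo_study, demo_panel):
        _, _, y, cov = demo_study
        panel = demo_panel.subset_scores(["PRS001", "PRS002", "PRS003"])
        a = prsmix(panel, "trait_specific", y, cov, SplitSpec(seed=5), rule=None)
        b = prsmix_plus(panel, y, cov, SplitSpec(seed=5), rule=None)
        np.testing.assert_allclose(a.weights.omega, b.weights.omega)
        assert a.test_accuracy.r2 == pytest.approx(b.test_accuracy.r2)

    def test_prsmix_plus_exploits_cross_trait_signal(self, demo_study, demo_panel):
        _, _, y, cov = demo_study
        mix = prsmix(demo_panel, "trait_specific", y, cov, SplitSpec(seed=6), rule=None)
        plus = prsmix_plus(demo_panel, y, cov, SplitSpec(seed=6), rule=None)
        assert plus.test_accuracy.r2 >= mix.test_accuracy.r2 - 0.02

    def test_order_invariance(self, demo_study, demo_panel):
        _, _, y, cov = demo_study
        shuffled = demo_panel.subset_scores(
            ["PRS003", "PRS001", "PRS002", "PRS006", "PRS004", "PRS005"]
        )
        a = prsmix_plus(demo_panel, y, cov, SplitSpec(seed=8), rule=None)
        b = prsmix_plus(shuffled, y, cov, SplitSpec(seed=8), rule=None)
        assert a.test_accuracy.r2 == pytest.approx(b.test_accuracy.r2, abs=1e-6)
        alpha_a = dict(zip(a.weights.score_ids, a.weights.alpha_adj))
        alpha_b = dict(zip(b.weights.score_ids, b.weights.alpha_adj))
        for sid in alpha_a:
            assert alpha_a[sid] == pytest.approx(alpha_b[sid], abs=1e-6)


class TestImprovementTest:
    def test_identical_vectors_degenerate(self):
        res = improvement_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.mean_ratio == 1.0
        assert res.p_value == 1.0
        assert res.degenerate

    def test_textbook_t_statistic(self):
        """Hand-computed one-sample t-test of ratios [1.1, 1.2, 1.3] against 1."""
        res = improvement_test([1.1, 1.2, 1.3], [1.0, 1.0, 1.0])
        assert res.mean_ratio == pytest.approx(1.2)
        t_hand = 0.2 / (0.1 / np.sqrt(3))
        p_hand = 2 * stats.t.sf(t_hand, df=2)
        assert res.p_value == pytest.approx(p_hand, rel=1e-9)
        half = stats.t.ppf(0.975, 2) * 0.1 / np.sqrt(3)
        assert res.ci95 == (pytest.approx(1.2 - half), pytest.approx(1.2 + half))

    def test_scale_invariance(self):
        a = improvement_test([0.1, 0.2, 0.4], [0.08, 0.19, 0.3])
        b = improvement_test([1.0, 2.0, 4.0], [0.8, 1.9, 3.0])
        np.testing.assert_allclose(a.fold_ratios, b.fold_ratios)
        assert a.p_value == pytest.approx(b.p_value)

    def test_non_positive_r2_rejected(self):
        with pytest.raises(ValueError):
            improvement_test([0.1, 0.0], [0.1, 0.1])
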