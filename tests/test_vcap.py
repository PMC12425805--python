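"""Kinship construction, matched background sampling, REML, trait sims."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from pancistrome.vcap import (
    af_bin,
    build_kinship,
    distance_bin,
    matching_cells,
    recovery_experiment,
    reml_fit,
    reml_loglik,
    sample_matched_background,
    simulate_structured_genotypes,
    simulate_traits,
    vcap_permutations,
)


class TestBuildKinship:
    def test_single_marker_hand_computation(self):
        # genotypes (0, 1), centred: z = (-0.5, 0.5); K scaled to diag mean 1
        K = build_kinship(np.array([[0.0], [1.0]]))
        assert np.allclose(K, [[1.0, -1.0], [-1.0, 1.0]])

    def test_identical_individuals_have_identical_rows(self, rng):
        X = rng.integers(0, 2, size=(5, 40)).astype(float)
        X[3] = X[1]
        K = build_kinship(X)
        assert np.allclose(K[1], K[3])
        assert np.allclose(K[1, 3], K[1, 1])

    def test_matches_brute_force_cross_product(self, rng):
        X = rng.integers(0, 2, size=(12, 60)).astype(float)
        K = build_kinship(X)
        Z = X - X.mean(axis=0)
        brute = np.zeros((12, 12))
        for i in range(12):
            for j in range(12):
                brute[i, j] = sum(Z[i, m] * Z[j, m] for m in range(60))
        brute /= np.trace(brute) / 12
        assert np.allclose(K, brute)
        assert np.allclose(np.diag(K).mean(), 1.0)
        assert np.allclose(K, K.T)

    def test_zero_variance_markers_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            build_kinship(np.ones((4, 3)))


class TestMatchedBackground:
    def _sites(self, rng, n, prefix):
        dist = rng.choice([0, 500, 1500, 2500, 5500, 12000], size=n)
        return pd.DataFrame(
            {
                "site_id": [f"{prefix}{i}" for i in range(n)],
                "allele_freq": rng.uniform(0.08, 0.92, size=n),
                "dist_to_gene": dist,
            }
        )

    def test_bin_definitions(self):
        assert af_bin([0.24]).tolist() == [2]  # [0.2, 0.3)
        assert distance_bin([0]).tolist() == [0]  # intragenic
        assert distance_bin([1500]).tolist() == [2]  # 1-2 kb
        assert distance_bin([500]).tolist() == [1]  # 0-1 kb
        assert distance_bin([12000]).tolist() == [11]  # >10 kb

    def test_histograms_exactly_equal(self, rng):
        all_sites = self._sites(rng, 4000, "s")
        bqtl = all_sites.sample(300, random_state=1)
        bg_ids = sample_matched_background(bqtl, all_sites, rng)
        bg = all_sites.set_index("site_id").loc[bg_ids].reset_index()
        h_b = matching_cells(bqtl.reset_index(drop=True)).value_counts()
        h_g = matching_cells(bg).value_counts()
        assert h_b.sort_index().equals(h_g.sort_index())

    def test_background_disjoint_from_bqtl_and_unique(self, rng):
        all_sites = self._sites(rng, 3000, "s")
        bqtl = all_sites.sample(200, random_state=2)
        bg_ids = sample_matched_background(bqtl, all_sites, rng)
        assert len(bg_ids) == len(bqtl)
        assert not bg_ids.duplicated().any()
        assert not set(bg_ids) & set(bqtl["site_id"])

    def test_different_seeds_same_histogram_different_sets(self, rng):
        all_sites = self._sites(rng, 3000, "s")
        bqtl = all_sites.sample(200, random_state=3)
        bg1 = sample_matched_background(bqtl, all_sites, np.random.default_rng(1))
        bg2 = sample_matched_background(bqtl, all_sites, np.random.default_rng(2))
        assert set(bg1) != set(bg2)
        b1 = all_sites.set_index("site_id").loc[bg1].reset_index()
        b2 = all_sites.set_index("site_id").loc[bg2].reset_index()
        assert (
            matching_cells(b1).value_counts().sort_index()
            .equals(matching_cells(b2).value_counts().sort_index())
        )

    def test_empty_cell_falls_back_with_warning(self, rng):
        bqtl = pd.DataFrame(
            {"site_id": ["b0", "b1"], "allele_freq": [0.25, 0.25],
             "dist_to_gene": [1500, 1500]}
        )
        # pool has no 1-2 kb sites at that AF bin; nearest distance bin holds them
        pool = pd.DataFrame(
            {"site_id": ["p0", "p1", "p2"], "allele_freq": [0.22, 0.28, 0.21],
             "dist_to_gene": [2500, 2500, 500]}
        )
        with pytest.warns(UserWarning, match="falling back"):
            bg = sample_matched_background(bqtl, pd.concat([bqtl, pool]), rng)
        assert len(bg) == 2


class TestRemlFit:
    def test_iid_noise_gives_near_zero_component(self, rng):
        """A pure-noise trait attributes ~nothing to the kinship.

        Averaged over several independent null traits: a single fit has
        a boundary-truncated sampling distribution whose upper tail
        occasionally exceeds any small cut-off.
        """
        X = simulate_structured_genotypes(400, 500, rng)
        K = build_kinship(X)
        ests = [reml_fit(rng.standard_normal(400), [K]) for _ in range(8)]
        assert np.mean([e.proportions[0] for e in ests]) <= 0.05
        assert all(e.converged for e in ests)

    def test_pure_genetic_trait_gives_proportion_one(self, rng):
        X = simulate_structured_genotypes(200, 500, rng)
        K = build_kinship(X)
        y = simulate_traits([K], [1.0, 0.0], 1, rng)["trait01"]
        est = reml_fit(y, [K])
        assert est.proportions[0] >= 0.95

    def test_variances_non_negative_and_proportions_sum_to_one(self, rng):
        X = simulate_structured_genotypes(100, 300, rng)
        K = build_kinship(X)
        est = reml_fit(rng.standard_normal(100), [K])
        assert est.variances.min() >= 0 and est.residual >= 0
        assert est.proportions.sum() + est.residual_proportion == pytest.approx(1.0)

    def test_invariant_to_trait_rescaling(self, rng):
        X = simulate_structured_genotypes(150, 400, rng)
        K = build_kinship(X)
        y = simulate_traits([K], [0.5, 0.5], 1, rng)["trait01"]
        e1 = reml_fit(y, [K])
        e2 = reml_fit(2.0 * y, [K])
        assert np.allclose(e1.proportions, e2.proportions, atol=1e-5)

    def test_missing_individuals_are_dropped(self, rng):
        X = simulate_structured_genotypes(80, 300, rng)
        K = build_kinship(X)
        y = simulate_traits([K], [0.5, 0.5], 1, rng)["trait01"].to_numpy()
        y_missing = y.copy()
        y_missing[:10] = np.nan
        est_full = reml_fit(y[10:], [K[10:, 10:]])
        est_masked = reml_fit(y_missing, [K])
        assert np.allclose(est_full.proportions, est_masked.proportions, atol=1e-8)

    def test_constant_trait_rejected(self, rng):
        K = build_kinship(simulate_structured_genotypes(30, 100, rng))
        with pytest.raises(ValueError, match="variance"):
            reml_fit(np.ones(30), [K])

    def test_agrees_with_derivative_free_oracle_on_small_problems(self, rng):
        """REML proportions match a Nelder-Mead maximisation of the same
        restricted likelihood within 1e-3 on n <= 50 toys."""
        for trial in range(3):
            n = 30 + 10 * trial
            X = simulate_structured_genotypes(n, 200, rng, n_clusters=4)
            K = build_kinship(X)
            y = simulate_traits([K], [0.5, 0.5], 1, rng)["trait01"].to_numpy()
            est = reml_fit(y, [K], tol=1e-10)
            comps = [K, np.eye(n)]
            res = minimize(
                lambda ls: -reml_loglik(np.exp(ls), y, comps),
                np.log([np.var(y) / 2] * 2),
                method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000),
            )
            s = np.exp(res.x)
            assert est.proportions[0] == pytest.approx(s[0] / s.sum(), abs=1e-3)
            # the hill climber never beats the oracle's optimum meaningfully
            assert est.loglik >= -res.fun - 1e-6


class TestSimulateTraits:
    def test_pure_residual_set_is_standard_normal(self, rng):
        K = build_kinship(simulate_structured_genotypes(300, 200, rng))
        traits = simulate_traits([K], [0.0, 1.0], 50, rng)
        pooled = traits.to_numpy().ravel()
        assert abs(pooled.mean()) < 0.02
        assert abs(pooled.var() - 1.0) < 0.05

    def test_unit_total_variance(self, rng):
        # mean sample variance over 1,000 traits stays within +/-0.1 of 1
        Ks = [build_kinship(simulate_structured_genotypes(200, 300, rng))
              for _ in range(2)]
        traits = simulate_traits(Ks, [0.4, 0.3, 0.3], 1000, rng)
        v = traits.var(axis=0, ddof=1)
        assert abs(v.mean() - 1.0) < 0.1

    def test_component_covariance_matches_h2_times_kinship(self, rng):
        K = build_kinship(simulate_structured_genotypes(60, 300, rng))
        h2 = 0.7
        traits = simulate_traits([K], [h2, 1 - h2], 3000, rng).to_numpy()
        emp = np.cov(traits)
        expected = h2 * K + (1 - h2) * np.eye(60)
        err = np.abs(emp - expected).max()
        assert err < 0.25  # Monte-Carlo error at 3000 draws

    def test_invalid_heritabilities_rejected(self, rng):
        K = np.eye(4)
        with pytest.raises(ValueError):
            simulate_traits([K], [-0.1, 1.1], 1, rng)
        with pytest.raises(ValueError):
            simulate_traits([K], [0.8, 0.8], 1, rng)


class TestRecoveryExperiment:
    def test_null_set_recovers_zero_components(self, rng):
        Ks = [build_kinship(simulate_structured_genotypes(400, 600, rng))
              for _ in range(2)]
        report = recovery_experiment(Ks, [(0.0, 0.0)], n_traits_per_set=10, rng=rng)
        comps = report[report["component"] != "residual"]
        assert (comps["mean_estimate"] <= 0.05).all()

    def test_permuting_trait_breaks_recovery(self, rng):
        """Shuffling individuals destroys the kinship-trait covariance,
        a negative control for the variance attribution."""
        X = simulate_structured_genotypes(300, 600, rng)
        K = build_kinship(X)
        y = simulate_traits([K], [0.8, 0.2], 1, rng)["trait01"].to_numpy()
        est = reml_fit(y, [K])
        perm = rng.permutation(300)
        est_perm = reml_fit(y[perm], [K])
        assert est.proportions[0] > 0.5
        assert est_perm.proportions[0] < 0.15


class TestVcapPermutations:
    def _panel(self, rng, n_sites=300, n_lines=40):
        geno = pd.DataFrame(
            simulate_structured_genotypes(n_sites, n_lines, rng, n_clusters=4),
            index=pd.Index([f"s{i}" for i in range(n_sites)], name="site_id"),
        )
        sites = pd.DataFrame(
            {
                "site_id": geno.index,
                "allele_freq": geno.mean(axis=1).to_numpy(),
                "dist_to_gene": rng.choice([0, 500, 1500, 5500], size=n_sites),
            }
        )
        return geno, sites

    def test_bqtl_kinship_built_once_and_reused(self, rng, monkeypatch):
        """The bQTL kinship is byte-identical across permutations: it is
        constructed exactly once while the background and rest kinships
        are rebuilt per permutation."""
        import pancistrome.vcap as vcap_mod

        geno, sites = self._panel(rng)
        bqtl_sites = sites.sample(60, random_state=5)
        traits = pd.DataFrame({"t1": rng.standard_normal(40)})
        calls = []
        real = vcap_mod.build_kinship
        monkeypatch.setattr(
            vcap_mod, "build_kinship",
            lambda X: calls.append(np.asarray(X).shape) or real(X),
        )
        out = vcap_permutations(bqtl_sites, sites, geno, traits, n_perm=3, rng=rng)
        assert set(out["component"]) == {"bqtl", "background", "rest", "residual"}
        assert out["permutation"].nunique() == 3
        # one bQTL build + (background, rest) per permutation
        assert len(calls) == 1 + 2 * 3
        assert sum(1 for s in calls if s[1] == 300 - 2 * 60) == 3  # rest sets

    def test_single_permutation_equals_end_to_end_run(self, rng):
        geno, sites = self._panel(rng)
        bqtl_sites = sites.sample(50, random_state=6)
        traits = pd.DataFrame({"t1": rng.standard_normal(40)})
        out = vcap_permutations(
            bqtl_sites, sites, geno, traits, n_perm=1,
            rng=np.random.default_rng(9),
        )
        assert len(out) == 4
        assert out["proportion"].sum() == pytest.approx(1.0)
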