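import numpy as np
import pandas as pd
import pytest

from facetshift.comparative import (
    PGLS, ancestral_reconstruction, blomberg_k, lambda_transform,
    lambda_upper_bound, pagel_lambda, run_comparative_suite,
)
from facetshift.synthetic import simulate_pure_birth, simulate_traits
from facetshift.trees import FacetTree


class TestPagelLambda:
    def test_recovers_brownian_signal(self):
        hats = []
        for seed in range(8):
            t = simulate_pure_birth(100, 1.0, seed=seed)
            x = simulate_traits(t, 1.0, 1.0, seed=100 + seed)["trait0"].to_numpy()
            hats.append(pagel_lambda(t, x).estimate)
        assert 0.8 <= np.mean(hats) <= 1.15

    def test_shuffling_destroys_signal(self):
        hats = []
        rng = np.random.default_rng(5)
        for seed in range(8):
            t = simulate_pure_birth(100, 1.0, seed=seed)
            x = simulate_traits(t, 1.0, 1.0, seed=200 + seed)["trait0"].to_numpy()
            hats.append(pagel_lambda(t, rng.permutation(x)).estimate)
        assert np.mean(hats) < 0.2

    def test_star_tree_reports_flat_likelihood(self, rng):
        star = FacetTree.star([f"s{i}" for i in range(10)])
        res = pagel_lambda(star, rng.standard_normal(10))
        assert res.flat_likelihood
        assert res.p_value == 1.0

    def test_likelihood_at_optimum_dominates_endpoints(self, tree20, rng):
        x = simulate_traits(tree20, 0.6, 1.0, seed=1)["trait0"].to_numpy()
        res = pagel_lambda(tree20, x)
        c = tree20.cov_matrix()
        from facetshift.comparative import _gls_mean_rate

        ll0 = _gls_mean_rate(x, lambda_transform(c, 0.0))[2]
        ll1 = _gls_mean_rate(x, lambda_transform(c, 1.0))[2]
        assert res.loglik >= ll0 - 1e-9
        assert res.loglik >= ll1 - 1e-9

    def test_constant_trait_rejected(self, tree20):
        with pytest.raises(ValueError, match="constant"):
            pagel_lambda(tree20, np.ones(20))

    def test_lambda_upper_bound_at_least_one_for_ultrametric(self, tree20):
        assert lambda_upper_bound(tree20.cov_matrix()) >= 1.0


class TestBlombergK:
    def test_brownian_expectation_near_one(self):
        ks = []
        for seed in range(20):
            t = simulate_pure_birth(50, 1.0, seed=seed)
            x = simulate_traits(t, 1.0, 1.0, seed=300 + seed)["trait0"].to_numpy()
            ks.append(blomberg_k(t, x, n_permutations=50, seed=seed).estimate)
        assert 0.8 <= np.mean(ks) <= 1.2

    def test_brownian_trait_is_significant(self):
        t = simulate_pure_birth(60, 1.0, seed=2)
        x = simulate_traits(t, 1.0, 1.0, seed=3)["trait0"].to_numpy()
        res = blomberg_k(t, x, n_permutations=500, seed=0)
        assert res.p_value < 0.05

    def test_permutation_p_is_seed_deterministic(self, tree20, rng):
        x = rng.standard_normal(20)
        a = blomberg_k(tree20, x, n_permutations=200, seed=9)
        b = blomberg_k(tree20, x, n_permutations=200, seed=9)
        assert a.p_value == b.p_value and a.estimate == b.estimate

    def test_constant_trait_rejected(self, tree20):
        with pytest.raises(ValueError):
            blomberg_k(tree20, np.full(20, 3.3))


class TestAncestralReconstruction:
    def test_two_tip_symmetry(self):
        t = FacetTree.from_newick("(A:1,B:1);")
        # need >= 2 tips only for reconstruction; root = midpoint by symmetry
        anc = ancestral_reconstruction(t, np.array([0.0, 2.0]))
        assert anc.root_estimate == pytest.approx(1.0)

    def test_root_matches_closed_form_gls_mean(self, rng):
        t = simulate_pure_birth(6, 1.0, seed=11)
        x = rng.standard_normal(6)
        anc = ancestral_reconstruction(t, x)
        c = t.cov_matrix()
        vi = np.linalg.inv(c)
        one = np.ones(6)
        mu = float(one @ vi @ x / (one @ vi @ one))
        assert anc.root_estimate == pytest.approx(mu, abs=1e-10)

    def test_internal_states_match_direct_gls_prediction(self, rng):
        t = simulate_pure_birth(7, 1.0, seed=13)
        x = rng.standard_normal(7)
        anc = ancestral_reconstruction(t, x)
        c = t.cov_matrix()
        vi = np.linalg.inv(c)
        one = np.ones(7)
        mu = float(one @ vi @ x / (one @ vi @ one))
        depths = t.node_depths()

        def ancestors(v):
            out = set()
            while v != -1:
                out.add(v)
                v = t.parent[v]
            return out

        for pos, u in enumerate(anc.node_ids):
            anc_u = ancestors(u)
            cov = np.empty(7)
            for j in range(7):
                anc_j = ancestors(j)
                # cov(u, tip j) under BM = depth of the deepest common ancestor
                cov[j] = depths[u] if u in anc_j else max(
                    depths[w] for w in (anc_u & anc_j))
            expect = mu + cov @ vi @ (x - mu)
            assert anc.estimates[pos] == pytest.approx(expect, abs=1e-8)

    def test_constant_trait_gives_constant_states(self, tree20):
        anc = ancestral_reconstruction(tree20, np.full(20, 5.0))
        assert np.allclose(anc.estimates, 5.0)

    def test_variances_non_negative_and_zero_informative_limit(self, tree20, rng):
        anc = ancestral_reconstruction(tree20, rng.standard_normal(20))
        assert np.all(anc.variances >= 0.0)


class TestPGLS:
    def test_identity_covariance_equals_ols(self, rng):
        star = FacetTree.star([f"s{i}" for i in range(30)], branch_length=1.0)
        x = rng.standard_normal((30, 2))
        y = 1.5 * x[:, 0] - 0.5 * x[:, 1] + rng.standard_normal(30)
        fit = PGLS(star, transform="none").fit(x, y)
        design = np.column_stack([np.ones(30), x])
        beta = np.linalg.lstsq(design, y, rcond=None)[0]
        assert np.allclose(fit.params_, beta, atol=1e-8)
        # SEs match the OLS formulas too
        resid = y - design @ beta
        s2 = resid @ resid / (30 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(design.T @ design)))
        assert np.allclose(fit.se_, se, atol=1e-8)

    def test_kappa_zero_equals_direct_equal_branch_gls(self, rng):
        t = simulate_pure_birth(25, 1.0, seed=17)
        x = rng.standard_normal((25, 2))
        y = x[:, 0] + rng.standard_normal(25)
        fit = PGLS(t, transform="kappa", grid_points=3).fit(x, y)
        if fit.transform_param_ == pytest.approx(0.0, abs=1e-9):
            # covariance with every branch set to unit length
            b = t.tip_sets().astype(float)
            v = b.T @ b
            chol = np.linalg.cholesky(v)
            xw = np.linalg.solve(chol, np.column_stack([np.ones(25), x]))
            yw = np.linalg.solve(chol, y)
            beta = np.linalg.lstsq(xw, yw, rcond=None)[0]
            assert np.allclose(fit.params_, beta, atol=1e-8)

    def test_kappa_zero_covariance_is_split_counts(self):
        t = simulate_pure_birth(10, 1.0, seed=3)
        from facetshift.comparative import _transformed_cov

        v = _transformed_cov(t, t.cov_matrix(), "kappa", 0.0)
        b = t.tip_sets().astype(float)
        nonzero = (t.lengths > 0).astype(float)
        expect = b.T @ (nonzero[:, None] * b)
        assert np.allclose(v, expect)

    def test_known_slope_recovered_with_brownian_noise(self):
        t = simulate_pure_birth(50, 1.0, seed=23)
        rng = np.random.default_rng(23)
        x = rng.standard_normal(50)
        noise = simulate_traits(t, 1.0, 0.5, seed=24)["trait0"].to_numpy()
        y = 2.0 * x + noise
        fit = PGLS(t, transform="lambda").fit(x[:, None], y)
        lo, hi = fit.conf_int()[1]
        assert lo <= 2.0 <= hi

    def test_singular_design_names_columns(self, rng):
        star = FacetTree.star([f"s{i}" for i in range(12)])
        x = pd.DataFrame({"a": rng.standard_normal(12)})
        x["b"] = 2.0 * x["a"]
        with pytest.raises(ValueError, match="collinear"):
            PGLS(star, transform="none").fit(x, rng.standard_normal(12))

    def test_best_transform_beats_each_family(self, rng):
        t = simulate_pure_birth(30, 1.0, seed=31)
        x = rng.standard_normal((30, 1))
        y = simulate_traits(t, 1.0, 1.0, seed=32)["trait0"].to_numpy() + x[:, 0]
        best = PGLS(t, transform="best").fit(x, y)
        for fam in ("lambda", "kappa", "delta"):
            single = PGLS(t, transform=fam).fit(x, y)
            assert best.loglik_ >= single.loglik_ - 1e-6

    def test_summary_table_shape(self, rng):
        star = FacetTree.star([f"s{i}" for i in range(15)])
        x = pd.DataFrame(rng.standard_normal((15, 2)), columns=["u", "v"])
        fit = PGLS(star, transform="none").fit(x, rng.standard_normal(15))
        tab = fit.summary()
        assert list(tab.columns) == ["Estimate", "Std. Error", "t value", "Pr(>|t|)"]
        assert list(tab.index) == ["(Intercept)", "u", "v"]


class TestSuite:
    def make_inputs(self, n=16, seed=0):
        t = simulate_pure_birth(n, 1.0, seed=seed)
        rng = np.random.default_rng(seed + 1)
        traits = pd.DataFrame({
            "body_length_mm": rng.uniform(25, 85, n),
            "flight_months": rng.integers(2, 10, n).astype(float),
            "lentic": rng.integers(0, 2, n).astype(float),
            "lotic": rng.integers(0, 2, n).astype(float),
        }, index=t.tip_labels)
        traits.loc[traits["lentic"] + traits["lotic"] == 0, "lentic"] = 1.0
        shifts = pd.DataFrame({
            "species": t.tip_labels, "scenario": "S", "period": "2050",
            "relative_area_change": rng.uniform(0.3, 2.0, n),
            "centroid_difference": rng.uniform(1e4, 3e5, n),
            "altitude_difference": rng.normal(50, 30, n),
        })
        return t, traits, shifts

    def test_single_stratum_bundle(self):
        t, traits, shifts = self.make_inputs()
        out = run_comparative_suite(shifts, traits, t, n_permutations=50, seed=0)
        sig = out["signal"]
        assert set(sig["stratum"]) == {"all"}
        # lambda and K for each of the three responses
        assert len(sig) == 6
        assert not out["pgls"].empty

    def test_small_stratum_skipped(self):
        t, traits, shifts = self.make_inputs()
        out = run_comparative_suite(shifts, traits, t,
                                    subsets={"all": t.tip_labels, "tiny": t.tip_labels[:2]},
                                    n_permutations=50, seed=0)
        assert out["skipped_strata"] == ["tiny"]

    def test_pruning_commutes_with_analysis(self):
        t, traits, shifts = self.make_inputs(n=20, seed=3)
        members = t.tip_labels[:12]
        via_subset = run_comparative_suite(shifts, traits, t,
                                           subsets={"sub": members},
                                           n_permutations=50, seed=1)
        pruned = t.prune(members)
        direct = run_comparative_suite(shifts[shifts.species.isin(members)],
                                       traits.loc[members], pruned,
                                       n_permutations=50, seed=1)
        a = via_subset["signal"].drop(columns="stratum")
        b = direct["signal"].drop(columns="stratum")
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_trait_driven_shift_is_detected(self):
        # response built from flight months: PGLS should flag it
        t = simulate_pure_birth(40, 1.0, seed=8)
        rng = np.random.default_rng(9)
        traits = pd.DataFrame({
            "body_length_mm": rng.uniform(25, 85, 40),
            "flight_months": rng.integers(2, 11, 40).astype(float),
            "lentic": rng.integers(0, 2, 40).astype(float),
            "lotic": np.ones(40),
        }, index=t.tip_labels)
        y = 0.4 * traits["flight_months"] + 0.3 * rng.standard_normal(40)
        shifts = pd.DataFrame({
            "species": t.tip_labels, "scenario": "S", "period": "2050",
            "relative_area_change": y.to_numpy(),
        })
        out = run_comparative_suite(shifts, traits, t, responses=["relative_area_change"],
                                    n_permutations=50, seed=2)
        row = out["pgls"].query("term == 'flight_months'").iloc[0]
        assert row["Pr(>|t|)"] < 0.05
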