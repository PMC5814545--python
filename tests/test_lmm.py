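"""Mixed-model machinery: standardization, REML estimation against
closed-form and brute-force oracles, BLUP/SEP identities and prediction for
phenotype-masked individuals."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize

import opvardec as ov
from opvardec import lmm as L

from conftest import make_trial


def _oneway_frame(n_groups=50, per_group=10, s2_between=0.3, s2_within=0.7,
                  seed=9):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups), per_group)
    u = rng.normal(0, np.sqrt(s2_between), n_groups)
    y = 1.0 + u[groups] + rng.normal(0, np.sqrt(s2_within), len(groups))
    return pd.DataFrame(
        {
            "individual": [f"i{k}" for k in range(len(groups))],
            "family": "X",
            "site": "S1",
            "block": [f"g{g}" for g in groups],
            "trait": y,
        }
    ), y.reshape(n_groups, per_group)


def _design_parts(spec, data):
    y_all = data[spec.trait].astype(float).to_numpy()
    obs = ~np.isnan(y_all)
    X, _ = L._fixed_design(data, obs)
    designs = L._build_designs(spec, data, obs)
    return y_all[obs], X, [d.Q for d in designs]


class TestStandardize:
    def test_site_wise_zero_mean_unit_sd(self, trial):
        data = trial["data"]
        for _, grp in data.groupby("site"):
            assert grp["trait_std"].mean() == pytest.approx(0, abs=1e-12)
            assert grp["trait_std"].std(ddof=1) == pytest.approx(1, rel=1e-12)

    def test_single_site_equals_global_zscore(self):
        df = pd.DataFrame(
            {"site": "S1", "trait": [1.0, 2.0, 4.0, 5.0]}, index=range(4)
        )
        std, stats = ov.standardize_phenotypes(df, "trait")
        z = (df["trait"] - df["trait"].mean()) / df["trait"].std(ddof=1)
        np.testing.assert_allclose(std.to_numpy(), z.to_numpy())
        assert stats.loc["S1", "n"] == 4

    def test_heteroscedastic_sites_pooled_to_unit_variance(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(
            {
                "site": np.repeat(["S1", "S2"], 400),
                "trait": np.concatenate(
                    [rng.normal(10, 1, 400), rng.normal(30, 6, 400)]
                ),
            }
        )
        std, _ = ov.standardize_phenotypes(df, "trait")
        assert std.var(ddof=1) == pytest.approx(1.0, rel=0.01)

    def test_zero_site_variance_is_error(self):
        df = pd.DataFrame({"site": "S1", "trait": [2.0, 2.0, 2.0]},
                          index=range(3))
        with pytest.raises(ValueError, match="zero phenotypic variance"):
            ov.standardize_phenotypes(df, "trait")


class TestREMLOracles:
    def test_balanced_oneway_equals_anova_estimators(self):
        """On a balanced one-way layout REML equals the closed-form ANOVA
        estimators (MSB - MSW)/n and MSW."""
        df, ymat = _oneway_frame()
        spec = ov.ModelSpec(
            "oneway", "trait",
            [ov.RandomTerm("r(s)", None, "block_within_site")],
            fixed_terms=("intercept",),
        )
        fit = ov.reml_fit(spec, df, compute_blups=False)
        n_groups, per_group = ymat.shape
        group_means = ymat.mean(axis=1)
        msb = per_group * group_means.var(ddof=1)
        msw = ((ymat - group_means[:, None]) ** 2).sum() / (
            n_groups * (per_group - 1)
        )
        assert fit.components["r(s)"].estimate == pytest.approx(
            (msb - msw) / per_group, abs=1e-3
        )
        assert fit.residual.estimate == pytest.approx(msw, abs=1e-3)

    def test_loglik_matches_brute_force_for_every_model(self):
        """The REML log-likelihood agrees with a direct dense evaluation
        (plain inverses and determinants) on an n = 48 instance of each of
        the four model specifications."""
        trial = make_trial(n_families=4, offspring_per_family=12,
                           n_markers=300, pollen_pool_size=30,
                           full_sib_excess=0.3, n_causal=60, seed=5)
        for name in ov.MODEL_NAMES:
            spec = ov.model_spec(name, trial["kernels"], trait="trait_std")
            y, X, Qs = _design_parts(spec, trial["data"])
            theta = np.linspace(0.1, 0.4, len(Qs) + 1)
            ll = L.reml_log_likelihood(theta, Qs, y, X)
            V = theta[-1] * np.eye(len(y))
            for t, Q in zip(theta[:-1], Qs):
                V = V + t * Q
            Vi = np.linalg.inv(V)
            C = X.T @ Vi @ X
            P = Vi - Vi @ X @ np.linalg.inv(C) @ X.T @ Vi
            brute = -0.5 * (
                np.linalg.slogdet(V)[1] + np.linalg.slogdet(C)[1] + y @ P @ y
            )
            assert ll == pytest.approx(brute, abs=1e-6), name

    def test_optimum_matches_derivative_free_search(self):
        """AI-REML lands on the same maximum as a Nelder-Mead search over
        log-variances on a well-identified n = 100 pedigree model."""
        trial = make_trial(n_families=10, offspring_per_family=10,
                           n_markers=800, pollen_pool_size=60,
                           full_sib_excess=0.8, n_causal=150,
                           var_components={"additive": 0.45, "dominance": 0.0,
                                           "axa": 0.0, "axe": 0.25, "dxe": 0.0,
                                           "block": 0.05, "residual": 0.25},
                           seed=31)
        spec = ov.model_spec("ABLUP", trial["kernels"], trait="trait_std")
        fit = ov.reml_fit(spec, trial["data"], compute_blups=False)
        y, X, Qs = _design_parts(spec, trial["data"])
        res = optimize.minimize(
            lambda lt: -L.reml_log_likelihood(np.exp(lt), Qs, y, X),
            np.log(np.full(len(Qs) + 1, np.var(y) / (len(Qs) + 1))),
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-12, "xatol": 1e-8},
        )
        nm_theta = np.exp(res.x)
        ai_theta = np.array(
            [fit.components[k].estimate for k in fit.components]
            + [fit.residual.estimate]
        )
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-5)
        np.testing.assert_allclose(ai_theta, nm_theta, atol=1e-3)

    def test_constant_response_floors_everything(self, trial):
        data = trial["data"].copy()
        data["trait_std"] = 3.14
        spec = ov.model_spec("GBLUP-A", trial["kernels"], trait="trait_std")
        fit = ov.reml_fit(spec, data)
        assert all(v.estimate == 0 and v.se == 0 for v in
                   fit.components.values())
        assert fit.residual.estimate == 0
        assert all((s == 0).all() for s in fit.blup.values())

    def test_loglik_trace_non_decreasing(self, trial_fits):
        for fit in trial_fits.values():
            ll = fit.loglik_trace
            assert all(b >= a - 1e-8 for a, b in zip(ll, ll[1:]))

    def test_ablup_gblup_share_code_path(self, trial):
        """ABLUP and GBLUP-A differ only in the kernel argument."""
        spec_a = ov.model_spec("ABLUP", trial["kernels"], trait="trait_std")
        spec_g = ov.model_spec("GBLUP-A", trial["kernels"], trait="trait_std")
        assert [t.label for t in spec_a.random_terms] == \
            [t.label for t in spec_g.random_terms]
        assert [t.grouping for t in spec_a.random_terms] == \
            [t.grouping for t in spec_g.random_terms]
        assert spec_a.random_terms[0].kernel.kind == "A"
        assert spec_g.random_terms[0].kernel.kind == "G_add"


class TestBLUP:
    def test_blups_match_mixed_model_equations(self):
        """BLUPs from the V-inverse route equal the direct solution of
        Henderson's mixed-model equations on a small instance."""
        trial = make_trial(n_families=5, offspring_per_family=8,
                           n_markers=400, n_causal=80, seed=23)
        data, kernels = trial["data"], trial["kernels"]
        spec = ov.ModelSpec(
            "toy", "trait_std",
            [ov.RandomTerm("a", kernels["G_add"])],
            fixed_terms=("intercept", "site"),
        )
        s2a, s2e = 0.4, 0.6
        fit = ov.reml_fit(spec, data,
                          fix_components={"a": s2a, "residual": s2e})
        K = kernels["G_add"].values
        n = len(data)
        y = data["trait_std"].to_numpy()
        site = pd.Categorical(data["site"])
        X = np.column_stack(
            [np.ones(n)] + [(site == lev).astype(float)
                            for lev in site.categories[1:]]
        )
        Z = np.eye(n)  # data rows are in kernel order by construction
        lam = s2e / s2a
        Kinv = np.linalg.inv(K)
        top = np.hstack([X.T @ X, X.T @ Z])
        bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Kinv])
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(np.vstack([top, bot]), rhs)
        u_mme = sol[X.shape[1]:]
        u_pkg = fit.blup["a"].reindex(data["individual"]).to_numpy()
        np.testing.assert_allclose(u_pkg, u_mme, atol=1e-8)

    def test_gblup_equals_ridge_regression_blup(self):
        """Additive GBLUP breeding values equal per-marker ridge-regression
        effects summed per individual when G = ZZ'/c and the ridge penalty
        is matched (20 x 100 instance, 1e-6)."""
        rng = np.random.default_rng(17)
        n, m = 20, 100
        M = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        p = M.mean(axis=0) / 2
        Zc = M - 2 * p
        c = 2 * np.sum(p * (1 - p))
        ids = [f"i{k}" for k in range(n)]
        K = ov.RelationshipMatrix(ids, Zc @ Zc.T / c, "G_add")
        y = rng.normal(0, 1, n)
        df = pd.DataFrame({"individual": ids, "family": "F", "site": "S1",
                           "block": "B1", "trait": y})
        s2a, s2e = 0.5, 0.3
        spec = ov.ModelSpec("g", "trait", [ov.RandomTerm("a", K)],
                            fixed_terms=("intercept",))
        fit = ov.reml_fit(spec, df,
                          fix_components={"a": s2a, "residual": s2e})
        # independent ridge route in marker space
        V = s2a * K.values + s2e * np.eye(n)
        X = np.ones((n, 1))
        beta = np.linalg.solve(X.T @ np.linalg.solve(V, X),
                               X.T @ np.linalg.solve(V, y))
        resid = y - X @ beta
        lam = s2e / (s2a / c)
        b_hat = np.linalg.solve(Zc.T @ Zc + lam * np.eye(m), Zc.T @ resid)
        np.testing.assert_allclose(
            fit.blup["a"].to_numpy(), Zc @ b_hat, atol=1e-6
        )

    def test_blups_center_near_zero(self, trial_fits):
        fit = trial_fits["GBLUP-A"]
        u = fit.blup["a"]
        assert abs(u.sum()) <= 1e-6 * len(u) * max(u.std(), 1e-12)

    def test_floored_additive_gives_zero_blups_and_seps(self, trial):
        """With sigma2_a at the floor every breeding value and its
        prediction SE are zero (the full-shrinkage limit)."""
        rng = np.random.default_rng(6)
        data = trial["data"].copy()
        data["trait_std"] = rng.normal(0, 1, len(data))
        spec = ov.ModelSpec(
            "noise", "trait_std",
            [ov.RandomTerm("a", trial["kernels"]["G_add"]),
             ov.RandomTerm("r(s)", None, "block_within_site")],
        )
        fit = ov.reml_fit(
            spec, data,
            fix_components={"a": 0.0, "r(s)": 0.01, "residual": 1.0},
        )
        assert np.allclose(fit.blup["a"], 0)
        assert np.allclose(fit.sep["a"], 0)

    def test_seps_positive_and_below_prior_sd(self, trial_fits):
        fit = trial_fits["GBLUP-A"]
        s2a = fit.components["a"].estimate
        sep = fit.sep["a"].to_numpy()
        diag = np.diag(fit.spec.random_terms[0].kernel.values)
        assert (sep >= 0).all()
        assert (sep <= np.sqrt(s2a * diag) + 1e-8).all()


class TestPredictMasked:
    def test_ablup_masked_family_predicts_zero(self, trial):
        """A whole maternal family held out under the pedigree model has
        zero relatedness to training: predicted BVs equal the model mean."""
        data = trial["data"].copy()
        fam = data["family"] == data["family"].iloc[0]
        data.loc[fam, "trait_std"] = np.nan
        spec = ov.model_spec("ABLUP", trial["kernels"], trait="trait_std")
        pred, _ = ov.predict_masked(spec, data)
        assert len(pred) == int(fam.sum())
        np.testing.assert_allclose(pred.to_numpy(), 0.0, atol=1e-12)

    def test_gblup_masked_family_predicts_nonzero(self, trial):
        data = trial["data"].copy()
        fam = data["family"] == data["family"].iloc[0]
        data.loc[fam, "trait_std"] = np.nan
        spec = ov.model_spec("GBLUP-A", trial["kernels"], trait="trait_std")
        pred, _ = ov.predict_masked(spec, data)
        assert pred.abs().max() > 1e-3

    def test_duplicated_genotype_gets_training_tree_bv(self):
        """A masked individual with a genotype identical to a training tree
        receives (via the kernel) that tree's breeding value."""
        trial = make_trial(n_families=6, offspring_per_family=10,
                           n_markers=500, n_causal=100, seed=37)
        ds = trial["dataset"]
        codes = ds.genotypes.codes.copy()
        codes[1] = codes[0]  # individual 1 becomes a clone of individual 0
        clone_geno = ov.GenotypeMatrix(
            list(ds.genotypes.individual_ids), list(ds.genotypes.marker_ids),
            codes,
        )
        kernels = ov.standard_kernels(clone_geno, ds.pedigree,
                                      epsilon=1e-10)
        data = trial["data"].copy()
        data.loc[data.index[1], "trait_std"] = np.nan
        spec = ov.model_spec("GBLUP-A", kernels, trait="trait_std")
        pred, fit = ov.predict_masked(spec, data)
        clone_id = ds.genotypes.individual_ids[1]
        twin_id = ds.genotypes.individual_ids[0]
        assert pred[clone_id] == pytest.approx(fit.blup["a"][twin_id],
                                               abs=1e-6)

    def test_masking_nothing_equals_full_fit(self, trial, trial_fits):
        spec = ov.model_spec("GBLUP-A", trial["kernels"], trait="trait_std")
        pred, fit = ov.predict_masked(spec, trial["data"])
        assert len(pred) == 0
        pd.testing.assert_series_equal(
            fit.blup["a"], trial_fits["GBLUP-A"].blup["a"]
        )

    def test_all_masked_is_error(self, trial):
        data = trial["data"].copy()
        data["trait_std"] = np.nan
        spec = ov.model_spec("GBLUP-A", trial["kernels"], trait="trait_std")
        with pytest.raises(ValueError, match="mask"):
            ov.predict_masked(spec, data)
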