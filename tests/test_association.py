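"""EB region summaries, the longitudinal family LMM, and the 2-df Wald test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ibdassoc as ia
from ibdassoc.association import (_FamilyBlocks, bonferroni_alpha, eb_summarize,
                                  fit_lmm, loglik_at, rare_count, wald_2df)
from ibdassoc.association import test_regions as run_region_association
from ibdassoc.regions import Region


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

class TestEBSummarize:
    def test_balanced_matches_closed_form_ml(self):
        """Balanced one-way random-effects ML has a closed form.

        With zero-mean data, the within part depends only on s2e and the
        means part only on v = s2b + s2e/m, so the ML is
        s2e = SSW/(n(m-1)), v = mean(zbar^2), s2b = v - s2e/m.
        """
        rng = np.random.default_rng(0)
        n, m = 20, 5
        p = rng.uniform(0.2, 0.8, m)
        g = rng.binomial(2, p[None, :], size=(n, m))
        while np.any((g.mean(0) == 0) | (g.mean(0) == 2 * 1.0)):
            g = rng.binomial(2, p[None, :], size=(n, m))
        ebs = eb_summarize(g, range(m), [str(i) for i in range(n)])

        phat = g.mean(0) / 2
        z = (g - 2 * phat) / np.sqrt(2 * phat * (1 - phat))
        zbar = z.mean(1)
        ssw = ((z - zbar[:, None]) ** 2).sum()
        s2e = ssw / (n * (m - 1))
        v = (zbar ** 2).mean()
        s2b = v - s2e / m
        assert ebs.sigma2_e == pytest.approx(s2e, rel=1e-4)
        assert ebs.sigma2_b == pytest.approx(s2b, rel=1e-3, abs=1e-6)
        shrink = m * s2b / (m * s2b + s2e)
        assert np.allclose(ebs.eb.to_numpy(), shrink * zbar, atol=1e-5)

    def test_identical_genotypes_boundary(self):
        g = np.tile([0, 1, 2, 1], (10, 1))  # identical rows -> zbar all equal
        ebs = eb_summarize(g, range(4), [str(i) for i in range(10)])
        assert ebs.boundary
        assert np.all(ebs.eb == 0.0)

    def test_no_shrinkage_limit(self):
        """Strong between-individual signal: EB approaches the raw mean."""
        rng = np.random.default_rng(1)
        n, m = 30, 6
        # individuals alternate between all-ref and all-alt: huge between-var
        g = np.where((np.arange(n) % 2)[:, None].astype(bool),
                     2, 0) * np.ones((n, m), dtype=int)
        g[0, 0] = 1  # keep polymorphic variation within a column
        ebs = eb_summarize(g, range(m), [str(i) for i in range(n)])
        phat = g.mean(0) / 2
        z = (g - 2 * phat) / np.sqrt(2 * phat * (1 - phat))
        zbar = z.mean(1)
        assert np.allclose(ebs.eb.to_numpy(), zbar, rtol=0.05, atol=0.02)

    def test_monomorphic_region_raises(self):
        g = np.zeros((5, 3), dtype=int)
        with pytest.raises(ValueError, match="polymorphic"):
            eb_summarize(g, range(3), list("abcde"))

    def test_missing_individual_gets_zero(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.4, (10, 4)).astype(float)
        g[3, :] = np.nan
        ebs = eb_summarize(g, range(4), [str(i) for i in range(10)])
        assert ebs.eb.iloc[3] == 0.0
        assert ebs.m_obs.iloc[3] == 0


class TestRareCount:
    def _panel_geno(self):
        # marker 0 common, markers 1-2 rare
        g = np.zeros((100, 3), dtype=float)
        g[:, 0] = np.random.default_rng(3).binomial(2, 0.4, 100)
        g[0, 1] = 1.0
        g[1, 2] = 2.0
        return g

    def test_counts(self):
        g = self._panel_geno()
        rb = rare_count(g, range(3), [str(i) for i in range(100)], 0.05)
        assert rb.n_rare_markers == 2
        assert rb.s.iloc[0] == 1.0
        assert rb.s.iloc[1] == 2.0
        assert rb.s.iloc[2] == 0.0

    def test_no_rare_markers(self):
        g = np.tile([0.0, 1.0, 2.0], (30, 1)).T.reshape(30, 3)[:, :1]
        g = np.random.default_rng(4).binomial(2, 0.5, (30, 1)).astype(float)
        rb = rare_count(g, [0], [str(i) for i in range(30)], 0.01)
        assert rb.n_rare_markers == 0
        assert np.all(rb.s == 0.0)

    def test_dosage_fraction(self):
        g = np.zeros((50, 1), dtype=float)
        g[0, 0] = 0.4
        rb = rare_count(g, [0], [str(i) for i in range(50)], 0.05)
        assert rb.s.iloc[0] == pytest.approx(0.4)

    def test_missing_imputed_by_marker_mean(self):
        g = np.zeros((10, 1), dtype=float)
        g[0, 0] = 1.0
        g[1, 0] = np.nan
        rb = rare_count(g, [0], [str(i) for i in range(10)], 0.2)
        assert rb.s.iloc[1] == pytest.approx(1.0 / 9.0)


# ---------------------------------------------------------------------------
# Stage 2
# ---------------------------------------------------------------------------

def _simple_long_data(seed=0, n_fam=30, T=4):
    """Independent families of two unrelated founders, T waves each."""
    from ibdassoc.pedigree import Individual, Pedigree
    rng = np.random.default_rng(seed)
    inds, rows = [], []
    for f in range(n_fam):
        fam = f"f{f}"
        for j, sex in (("a", "male"), ("b", "female")):
            iid = f"{fam}{j}"
            inds.append(Individual(iid, fam, sex=sex))
            age0 = rng.uniform(30, 60)
            smoke = int(rng.random() < 0.3)
            for t in range(1, T + 1):
                rows.append((fam, iid, t, np.nan, age0 + 5 * t, smoke))
    ped = Pedigree(inds)
    pheno = pd.DataFrame(rows, columns=["family_id", "individual_id",
                                        "timepoint", "dbp", "age", "smoke"])
    return ped, pheno, rng


class TestFitLMM:
    def test_collapses_to_ols(self):
        """T=1, sigma_u2 = 0, iso residual: GLS reduces to plain OLS."""
        ped, pheno, rng = _simple_long_data(seed=5, n_fam=40, T=1)
        pheno["dbp"] = 70 + 0.3 * pheno["age"] + rng.normal(0, 3, len(pheno))
        R = ia.relationship_matrix(ped)
        fit = fit_lmm(pheno, R, n_timepoints=1, sigma_e_structure="iso",
                      constrain_sigma_u2=0.0)
        X = np.column_stack([np.ones(len(pheno)), pheno["age"], pheno["smoke"]])
        y = pheno["dbp"].to_numpy()
        b_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert np.allclose(fit.beta.to_numpy(), b_ols, atol=1e-8)

    def test_iso_sigma_u_zero_matches_ols_T4(self):
        """Equal-diagonal residual and no family effect: independent errors."""
        ped, pheno, rng = _simple_long_data(seed=6, n_fam=25, T=4)
        pheno["dbp"] = 70 + 0.2 * pheno["age"] + rng.normal(0, 2, len(pheno))
        R = ia.relationship_matrix(ped)
        fit = fit_lmm(pheno, R, sigma_e_structure="iso", constrain_sigma_u2=0.0)
        X = np.column_stack([np.ones(len(pheno)), pheno["age"], pheno["smoke"]])
        b_ols, *_ = np.linalg.lstsq(X, pheno["dbp"].to_numpy(), rcond=None)
        assert np.allclose(fit.beta.to_numpy(), b_ols, atol=1e-6)

    def test_scale_equivariance_of_likelihood(self):
        """Doubling y with (sigma_u2, Sigma_e) scaled by 4 doubles the
        profiled GLS coefficients exactly — the model's scale equivariance."""
        ped, pheno, rng = _simple_long_data(seed=7, n_fam=20, T=4)
        pheno["dbp"] = 70 + rng.normal(0, 3, len(pheno))
        R = ia.relationship_matrix(ped)
        df = pheno.copy()
        df["_t"] = df["timepoint"].astype(int) - 1
        X = np.column_stack([np.ones(len(df)), df["age"], df["smoke"]])
        y = df["dbp"].to_numpy()
        Se = ia.simulate._default_sigma_e()
        b1 = _FamilyBlocks(df, X, y, R, 4)
        b2 = _FamilyBlocks(df, X, 2 * y, R, 4)
        _, beta1, _ = b1.nll(5.0, Se)
        _, beta2, _ = b2.nll(20.0, 4 * Se)
        assert np.allclose(beta2, 2 * beta1, rtol=1e-6, atol=1e-10)

    def test_scale_equivariance_of_fit(self):
        """The fitted estimates track the exact equivariance up to
        optimizer tolerance."""
        ped, pheno, rng = _simple_long_data(seed=7, n_fam=20, T=4)
        pheno["dbp"] = 70 + rng.normal(0, 3, len(pheno))
        R = ia.relationship_matrix(ped)
        f1 = fit_lmm(pheno, R)
        pheno2 = pheno.copy()
        pheno2["dbp"] = 2 * pheno2["dbp"]
        f2 = fit_lmm(pheno2, R)
        assert np.allclose(f2.beta.to_numpy(), 2 * f1.beta.to_numpy(),
                           rtol=1e-3, atol=1e-3)
        # scaling y by c shifts the ML log-likelihood by exactly -N log c;
        # individual Sigma_e entries sit on a flat ridge at this sample size
        # and are not compared entrywise
        assert f2.loglik == pytest.approx(f1.loglik - f1.n_obs * math.log(2),
                                          abs=1e-3)
        assert np.trace(f2.sigma_e) == pytest.approx(4 * np.trace(f1.sigma_e),
                                                     rel=0.1)

    def test_loglik_matches_brute_force_mvn(self):
        """Structured likelihood equals a dense MVN built from first principles,
        including with missing rows (row-deletion under MAR)."""
        cfg = ia.SimConfig(n_families=4, n_markers=20, n_rare_background=0,
                           seed=8)
        ds = ia.simulate_dataset(cfg)
        pheno = ds.phenotypes.drop(index=[3, 17, 40]).reset_index(drop=True)
        R = ia.relationship_matrix(ds.pedigree, ds.ids)
        df = pheno.copy()
        df["_t"] = df["timepoint"].astype(int) - 1
        X = np.column_stack([np.ones(len(df)), df["age"], df["smoke"]])
        y = df["dbp"].to_numpy()
        blocks = _FamilyBlocks(df, X, y, R, 4)
        s2u, Se = 7.0, ia.simulate._default_sigma_e()
        nll, beta, _ = blocks.nll(s2u, Se)

        # dense oracle: V over all rows from the definition
        fams = df["family_id"].to_numpy()
        iids = df["individual_id"].to_numpy()
        t = df["_t"].to_numpy()
        n = len(df)
        V = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if fams[i] == fams[j]:
                    V[i, j] += s2u * R.loc[iids[i], iids[j]]
                if iids[i] == iids[j]:
                    V[i, j] += Se[t[i], t[j]]
        resid = y - X @ beta
        expect = -stats.multivariate_normal(mean=np.zeros(n), cov=V).logpdf(resid)
        # blocks.nll profiles beta; at the same beta the quadratic agrees
        assert nll == pytest.approx(expect, abs=1e-6)

    def test_cross_check_statsmodels_random_intercept(self):
        """With R = I and iso residual, the model is a per-individual random
        intercept; statsmodels MixedLM is the independent oracle."""
        import statsmodels.api as sm
        ped, pheno, rng = _simple_long_data(seed=9, n_fam=30, T=4)
        iids = pheno["individual_id"].unique()
        u = dict(zip(iids, rng.normal(0, 2, len(iids))))
        pheno["dbp"] = (65 + 0.25 * pheno["age"] + 1.5 * pheno["smoke"]
                        + pheno["individual_id"].map(u)
                        + rng.normal(0, 1.5, len(pheno)))
        R = ia.relationship_matrix(ped)
        fit = fit_lmm(pheno, R, sigma_e_structure="iso")

        md = sm.MixedLM.from_formula("dbp ~ age + smoke", data=pheno,
                                     groups=pheno["individual_id"])
        sf = md.fit(reml=False)
        assert np.allclose(fit.beta[["intercept", "age", "smoke"]].to_numpy(),
                           sf.params[["Intercept", "age", "smoke"]].to_numpy(),
                           atol=1e-3)
        assert fit.sigma_u2 == pytest.approx(float(sf.cov_re.iloc[0, 0]),
                                             rel=1e-2, abs=1e-3)
        assert fit.loglik == pytest.approx(float(sf.llf), abs=1e-3)

    def test_ml_dominates_generative_truth(self):
        cfg = ia.SimConfig(n_families=15, n_markers=50, n_rare_background=0,
                           seed=10)
        ds = ia.simulate_dataset(cfg)
        R = ia.relationship_matrix(ds.pedigree, ds.ids)
        fit = fit_lmm(ds.phenotypes, R)
        truth = {"intercept": cfg.beta0 + cfg.beta_smoke * 0,  # smoke is a covariate
                 "age": cfg.beta_age, "smoke": cfg.beta_smoke}
        truth["intercept"] = cfg.beta0
        ll_truth = loglik_at(ds.phenotypes, R, truth, cfg.sigma_u2, cfg.sigma_e)
        assert np.isfinite(ll_truth)
        assert fit.loglik >= ll_truth

    def test_nonpsd_R_rejected(self):
        ped, pheno, rng = _simple_long_data(seed=11, n_fam=5, T=2)
        pheno["dbp"] = rng.normal(size=len(pheno))
        R = ia.relationship_matrix(ped)
        R.iloc[0, 1] = R.iloc[1, 0] = 5.0
        with pytest.raises(ValueError, match="positive semidefinite"):
            fit_lmm(pheno, R, n_timepoints=2)

    def test_single_family_rejected(self):
        ped, pheno, rng = _simple_long_data(seed=12, n_fam=1, T=2)
        pheno["dbp"] = rng.normal(size=len(pheno))
        with pytest.raises(ValueError, match="2 families"):
            fit_lmm(pheno, ia.relationship_matrix(ped), n_timepoints=2)


class TestWald:
    def test_null_point(self):
        W, p = wald_2df(np.zeros(2), np.eye(2))
        assert W == 0.0 and p == 1.0

    def test_unit_case(self):
        W, p = wald_2df(np.array([1.0, 0.0]), np.eye(2))
        assert W == pytest.approx(1.0)
        assert p == pytest.approx(math.exp(-0.5), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_explicit_2x2_inverse(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(2, 2))
        cov = A @ A.T + 0.1 * np.eye(2)
        b = rng.normal(size=2)
        W, p = wald_2df(b, cov)
        a, bb, c, d = cov[0, 0], cov[0, 1], cov[1, 0], cov[1, 1]
        inv = np.array([[d, -bb], [-c, a]]) / (a * d - bb * c)
        assert W == pytest.approx(float(b @ inv @ b), rel=1e-12)
        assert p == pytest.approx(math.exp(-W / 2), rel=1e-9)

    def test_reparameterization_invariance(self):
        """W is unchanged by any nonsingular linear map of (eb, s)."""
        rng = np.random.default_rng(13)
        cfg = ia.SimConfig(n_families=12, n_markers=60, n_rare_background=10,
                           seed=13, effect_beta2=2.0, causal_maf=0.1)
        ds = ia.simulate_dataset(cfg)
        idx = np.flatnonzero((ds.panel["cm"] >= 100) & (ds.panel["cm"] <= 110))
        ebs = eb_summarize(ds.genotypes, idx, ds.ids)
        rb = rare_count(ds.genotypes, idx, ds.ids, 0.05)
        R = ia.relationship_matrix(ds.pedigree, ds.ids)

        A = np.array([[2.0, 0.5], [-1.0, 1.5]])  # nonsingular
        eb2 = A[0, 0] * ebs.eb + A[0, 1] * rb.s
        s2 = A[1, 0] * ebs.eb + A[1, 1] * rb.s

        def joint_wald(e, s):
            f = fit_lmm(ds.phenotypes, R, eb=e, s=s)
            sub = f.cov_beta.loc[["eb", "s"], ["eb", "s"]].to_numpy()
            return wald_2df(f.beta[["eb", "s"]].to_numpy(), sub)[0]

        assert joint_wald(ebs.eb, rb.s) == pytest.approx(
            joint_wald(eb2, s2), rel=1e-4)

    def test_singular_covariance_raises(self):
        with pytest.raises(np.linalg.LinAlgError, match="beta2-only"):
            wald_2df(np.ones(2), np.ones((2, 2)))


class TestTestRegionsAndBonferroni:
    def test_zero_polymorphic_region_flagged(self):
        cfg = ia.SimConfig(n_families=4, n_markers=40, n_rare_background=0,
                           seed=14)
        ds = ia.simulate_dataset(cfg)
        R = ia.relationship_matrix(ds.pedigree, ds.ids)
        bad = Region("3", 10, 20, 0.0, 0.0, 2)  # empty interval
        out = run_region_association([bad], ds.phenotypes, ds.genotypes,
                                     ds.panel, ds.ids, R)
        assert len(out) == 1
        assert out.loc[0, "flagged"] != ""
        assert np.isnan(out.loc[0, "p_joint"])

    def test_full_table_shape(self):
        cfg = ia.SimConfig(n_families=10, n_markers=150, seed=15,
                           effect_beta2=4.0, causal_maf=0.08)
        ds = ia.simulate_dataset(cfg)
        R = ia.relationship_matrix(ds.pedigree, ds.ids)
        lo, hi = cfg.causal_region
        cm = ds.panel["cm"].to_numpy()
        bps = ds.panel["bp"].to_numpy()
        sel = (cm >= lo) & (cm <= hi)
        reg = Region("3", int(bps[sel].min()), int(bps[sel].max()), lo, hi, 2)
        out = run_region_association([reg], ds.phenotypes, ds.genotypes,
                                     ds.panel, ds.ids, R, rare_maf_max=0.2)
        row = out.iloc[0]
        for col in ("p_beta2", "p_beta3", "p_joint", "p_beta2_only"):
            assert 0 <= row[col] <= 1
        assert row["converged"]

    @pytest.mark.parametrize("n,expected_exact,expected_presented", [
        (7, 0.05 / 7, 7e-3),
        (8, 0.00625, 6e-3),
        (1, 0.05, 5e-2),
    ])
    def test_bonferroni(self, n, expected_exact, expected_presented):
        exact, presented = bonferroni_alpha(0.05, n)
        assert exact == pytest.approx(expected_exact, rel=1e-12)
        assert presented == pytest.approx(expected_presented, rel=1e-12)

    def test_bonferroni_zero_regions(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
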