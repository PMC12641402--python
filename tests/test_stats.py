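"""Mixed-model battery, FDR, post hoc effect sizes, region-wise regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
import statsmodels.api as sm

from dysconn import stats as st


def simulate_longitudinal(
    rng,
    n_subjects=12,
    session_shift=0.0,
    re_sd=0.5,
    resid_sd=0.5,
    hemispheres=("L", "R"),
):
    """Direct draw from the random-intercept model the battery assumes."""
    rows = []
    for i in range(n_subjects):
        b = rng.normal(0, re_sd)
        cov = {
            "age": rng.normal(35, 8), "sex": rng.choice(["F", "M"]),
            "cpz": abs(rng.normal(400, 150)), "trainings": rng.integers(20, 60),
            "group": "AET" if i % 2 == 0 else "FSBT",
        }
        for ses, shift in (("baseline", 0.0), ("followup", session_shift)):
            for hemi in hemispheres:
                rows.append({
                    "subject": f"s{i}", "session": ses, "hemisphere": hemi,
                    "dci": 2.0 + b + shift + rng.normal(0, resid_sd), **cov,
                })
    return pd.DataFrame(rows)


class TestFdrBh:
    def test_worked_example(self):
        np.testing.assert_allclose(
            st.fdr_bh([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones_and_empty(self):
        np.testing.assert_array_equal(st.fdr_bh([1.0, 1.0, 1.0]), [1, 1, 1])
        assert st.fdr_bh([]).size == 0

    def test_q_dominates_p_and_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            q = st.fdr_bh(p)
            assert (q >= p - 1e-15).all()
            assert (q <= 1.0).all()
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(q, ref, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            st.fdr_bh([0.1, 1.2])


class TestLmm:
    def test_constant_response_gives_degenerate_zero_fit(self, rng):
        df = simulate_longitudinal(rng)
        df["dci"] = 3.0
        fit = st.fit_dci_lmm(df)
        assert fit.session_coef == 0.0
        assert fit.re_var == 0.0 and fit.resid_var == 0.0
        assert fit.singular

    def test_session_shift_recovered_within_two_se(self, rng):
        delta = -0.8
        hits = 0
        for _ in range(40):
            df = simulate_longitudinal(rng, session_shift=delta)
            fit = st.fit_dci_lmm(df)
            hits += abs(fit.session_coef - delta) <= 2 * fit.session_se
        assert hits >= 36  # ~95% nominal coverage

    def test_null_session_pvalues_roughly_uniform(self, rng):
        ps = []
        for _ in range(150):
            fit = st.fit_dci_lmm(simulate_longitudinal(rng))
            ps.append(fit.session_p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_boundary_random_intercept_reproduces_ols(self, rng):
        """When the random-intercept variance estimate hits zero, the mixed
        model's fixed effects equal ordinary least squares."""
        for _ in range(30):
            df = simulate_longitudinal(rng, re_sd=0.0)
            fit = st.fit_dci_lmm(df)
            if fit.re_var < 1e-10:
                break
        else:
            pytest.fail("no boundary fit found")
        enc = st._encode_design(df)
        cols = st._fixed_columns(enc, st.LMM_COVARIATES)
        for c in cols:
            if c != "session_followup":
                v = enc[c].to_numpy(float)
                if not set(np.unique(v)) <= {0.0, 1.0}:
                    enc[c] = (v - v.mean()) / v.std()
        ols = sm.OLS(enc["dci"], sm.add_constant(enc[cols])).fit()
        assert fit.session_coef == pytest.approx(ols.params["session_followup"], abs=1e-6)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 8"):
            st.fit_dci_lmm(simulate_longitudinal(rng, n_subjects=5))


class TestPosthoc:
    def test_reduction_of_one_total_sd_gives_d_near_minus_one(self, rng):
        ds = []
        for _ in range(30):
            df = simulate_longitudinal(
                rng, session_shift=-1.0, re_sd=np.sqrt(0.5), resid_sd=np.sqrt(0.5)
            )
            fit = st.fit_dci_lmm(df)
            ds.append(st.posthoc_session(df, fit).cohen_d)
        assert np.mean(ds) == pytest.approx(-1.0, abs=0.15)

    def test_session_label_swap_flips_d_exactly(self, rng):
        df = simulate_longitudinal(rng, session_shift=-0.7)
        fit = st.fit_dci_lmm(df)
        d = st.posthoc_session(df, fit).cohen_d
        swapped = df.assign(
            session=df["session"].map({"baseline": "followup", "followup": "baseline"})
        )
        fit2 = st.fit_dci_lmm(swapped)
        d2 = st.posthoc_session(swapped, fit2).cohen_d
        assert d2 == pytest.approx(-d, abs=1e-8)

    def test_ci_brackets_d(self, rng):
        df = simulate_longitudinal(rng, session_shift=-0.5)
        fit = st.fit_dci_lmm(df)
        ph = st.posthoc_session(df, fit)
        assert ph.ci95[0] <= ph.cohen_d <= ph.ci95[1]

    def test_zero_variance_rejected(self, rng):
        df = simulate_longitudinal(rng)
        df["dci"] = 1.0
        fit = st.fit_dci_lmm(df)
        with pytest.raises(ValueError, match="undefined"):
            st.posthoc_session(df, fit)


class TestBattery:
    def test_thirteen_scopes_fitted_once_each(self, small_scored, small_study):
        _, dci_df, _ = small_scored
        battery, fits, _ = st.dci_battery(dci_df, small_study.covariates)
        assert len(battery) == 13
        assert battery["scope"].is_unique
        assert set(fits) == set(battery["scope"])
        # q respects p and BH monotonicity on the sorted scale
        assert (battery["q"] >= battery["session_p"] - 1e-15).all()

    def test_planted_default_mode_reduction_detected(self, small_scored, small_study):
        _, dci_df, _ = small_scored
        battery, _, posthocs = st.dci_battery(dci_df, small_study.covariates)
        row = battery.set_index("scope").loc["default-mode"]
        assert row["session_coef"] < 0
        assert row["q"] < 0.05
        assert posthocs["default-mode"].cohen_d < 0


class TestSessionEffectMap:
    def test_single_region_matches_direct_mixedlm_refit(self, rng):
        df = simulate_longitudinal(rng, session_shift=-0.6, hemispheres=("L",))
        dcc = df.rename(columns={"dci": "rA"})[["subject", "session", "rA"]]
        cov = df.drop(columns=["dci", "session", "hemisphere"]).drop_duplicates("subject")
        res = st.session_effect_map(dcc, cov)
        # independent refit of the same per-region model
        from statsmodels.regression.mixed_linear_model import MixedLM

        enc = st._encode_design(dcc.merge(cov, on="subject"))
        cols = ["session_followup", "age", "sex_male", "cpz", "trainings", "group_fsbt"]
        for c in cols[1:]:
            v = enc[c].to_numpy(float)
            if not set(np.unique(v)) <= {0.0, 1.0}:
                enc[c] = (v - v.mean()) / v.std()
        exog = sm.add_constant(enc[cols].to_numpy(), has_constant="add")
        fit = MixedLM(enc["rA"].to_numpy(), exog, groups=enc["subject"].to_numpy()
                      ).fit(reml=True, method="bfgs")
        t_direct = fit.fe_params[1] / np.asarray(fit.bse_fe)[1]
        assert res.loc[0, "statistic"] == pytest.approx(-t_direct, rel=1e-4)
        assert res.loc[0, "statistic"] > 0  # reduction -> positive statistic

    def test_planted_network_regions_lead_the_map(self, small_scored, small_study):
        """Regions of the planted default-mode network dominate the top decile
        of the session-effect map (>= 3x their base rate)."""
        _, _, dcc_df = small_scored
        res = st.session_effect_map(dcc_df, small_study.covariates)
        meta = small_study.spec.region_meta.set_index("region_id")
        res["network"] = res["region"].map(meta["network"])
        top = res.nlargest(max(1, len(res) // 10), "statistic")
        base_rate = (res["network"] == "default-mode").mean()
        top_rate = (top["network"] == "default-mode").mean()
        assert top_rate >= 3 * base_rate

    def test_rank_deficient_design_rejected(self, rng):
        df = simulate_longitudinal(rng, hemispheres=("L",))
        df["trainings"] = df["age"]  # alias two covariates
        dcc = df.rename(columns={"dci": "rA"})[["subject", "session", "rA"]]
        cov = df.drop(columns=["dci", "session", "hemisphere"]).drop_duplicates("subject")
        with pytest.raises(ValueError, match="rank-deficient|aliased"):
            st.session_effect_map(dcc, cov)


class TestClinicalRegression:
    def _setup(self, rng, n=12, n_regions=5):
        change = pd.DataFrame(
            rng.normal(size=(n, n_regions)), columns=[f"r{i}" for i in range(n_regions)]
        )
        change.insert(0, "subject", [f"s{i}" for i in range(n)])
        cov = pd.DataFrame({
            "subject": change["subject"],
            "age": rng.normal(35, 8, n), "sex": rng.choice(["F", "M"], n),
            "cpz": abs(rng.normal(400, 150, n)),
        })
        return change, cov

    def test_noise_free_coupling_recovers_beta_exactly(self, rng):
        change, cov = self._setup(rng)
        s = 1.7
        clinical = pd.DataFrame({"subject": change["subject"],
                                 "GAF": s * change["r2"],
                                 "PANSS": rng.normal(size=12),
                                 "cognition": rng.normal(size=12)})
        maps = st.voxelwise_clinical_regression(change, clinical, cov)
        gaf = maps["GAF"].set_index("region")
        assert gaf.loc["r2", "beta"] == pytest.approx(s, abs=1e-10)
        assert gaf.loc["r2", "p"] < 1e-10

    def test_beta_matches_normal_equations_oracle(self, rng):
        change, cov = self._setup(rng, n=10, n_regions=1)
        clinical = pd.DataFrame({"subject": change["subject"],
                                 "GAF": rng.normal(size=10),
                                 "PANSS": rng.normal(size=10),
                                 "cognition": rng.normal(size=10)})
        maps = st.voxelwise_clinical_regression(
            change, clinical, cov, covariate_names=("age",)
        )
        x = np.column_stack([np.ones(10), change["r0"], cov["age"]])
        beta = np.linalg.solve(x.T @ x, x.T @ clinical["GAF"].to_numpy())
        assert maps["GAF"]["beta"].iloc[0] == pytest.approx(beta[1], abs=1e-10)

    def test_threshold_masks_nonsignificant_regions(self, rng):
        change, cov = self._setup(rng)
        clinical = pd.DataFrame({"subject": change["subject"],
                                 "GAF": rng.normal(size=12),
                                 "PANSS": rng.normal(size=12),
                                 "cognition": rng.normal(size=12)})
        maps = st.voxelwise_clinical_regression(change, clinical, cov)
        gaf = maps["GAF"]
        masked = gaf["beta_thresholded"].isna()
        np.testing.assert_array_equal(masked, gaf["p"] >= 0.05)

    def test_too_few_subjects_rejected(self, rng):
        change, cov = self._setup(rng, n=5)
        clinical = pd.DataFrame({"subject": change["subject"],
                                 "GAF": rng.normal(size=5),
                                 "PANSS": rng.normal(size=5),
                                 "cognition": rng.normal(size=5)})
        with pytest.raises(ValueError, match="too few"):
            st.voxelwise_clinical_regression(change, clinical, cov)
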