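import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sstkit.config import CohortConfig, ConfigurationError, DesignConfig
from sstkit.cohort_analysis import (DegenerateDesignError,
                                    bmi_ssrt_correlation, build_analysis_table,
                                    classify_overweight, fit_mixed_model,
                                    mad_outlier_rule, outlier_sensitivity,
                                    required_n_correlation)
from sstkit.power import exact_correlation_power, fisher_z_required_n
from sstkit.qc import apply_exclusions
from sstkit.race_sim import (participants_to_frame, sample_cohort_profiles,
                             simulate_cohort)


def _analysis_table(seed, cohort_config=None, design=None):
    cfg = cohort_config or CohortConfig()
    profiles = sample_cohort_profiles(cfg, rng_seed=seed)
    trials = simulate_cohort(profiles, design or DesignConfig(), rng_seed=seed + 1)
    clean = apply_exclusions(trials, participants_to_frame(profiles))
    return build_analysis_table(clean.estimates, clean.participants)


@pytest.fixture(scope="module")
def default_table(default_cohort):
    _, profiles, trials, participants = default_cohort
    clean = apply_exclusions(trials, participants)
    return build_analysis_table(clean.estimates, clean.participants)


class TestClassifyOverweight:
    def test_examples(self):
        assert classify_overweight(29.28)
        assert not classify_overweight(24.99)
        assert classify_overweight(25.0)  # threshold inclusive

    def test_vectorized(self):
        out = classify_overweight([20.0, 25.0, 30.0])
        assert out.tolist() == [False, True, True]

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_overweight(0.0)
        with pytest.raises(ValueError):
            classify_overweight([-3.0, 25.0])


class TestMixedModel:
    def test_condition_effect_recovered(self, default_table):
        eff = fit_mixed_model(default_table, "ssrt")
        row = eff[eff["effect"] == "condition"].iloc[0]
        assert row["estimate"] > 0  # gamified coded +1
        assert row["p"] < 0.05
        assert row["df_num"] == 1

    def test_overweight_effect_recovered_go_rt(self, default_table):
        eff = fit_mixed_model(default_table, "go_rt")
        row = eff[eff["effect"] == "overweight"].iloc[0]
        assert row["estimate"] > 0
        assert row["p"] < 0.05

    def test_all_terms_present(self, default_table):
        eff = fit_mixed_model(default_table, "ssrt")
        assert set(eff["effect"]) == {
            "age", "condition", "overweight", "stimulus",
            "condition:overweight", "condition:stimulus",
            "overweight:stimulus", "condition:overweight:stimulus"}
        assert ((eff["p"] >= 0) & (eff["p"] <= 1)).all()

    def test_containment_df(self, default_table):
        eff = fit_mixed_model(default_table, "ssrt")
        n_subj = default_table[default_table["valid"]]["participant_id"].nunique()
        row = eff.set_index("effect")
        assert row.loc["condition", "df_den"] == n_subj - 5

    def test_constant_response_rejected(self, default_table):
        tab = default_table.copy()
        tab["ssrt_ms"] = 300.0
        with pytest.raises(DegenerateDesignError):
            fit_mixed_model(tab, "ssrt")

    def test_single_group_rejected(self, default_table):
        tab = default_table[default_table["group"] == "gamified"]
        with pytest.raises(DegenerateDesignError, match="group"):
            fit_mixed_model(tab, "ssrt")

    def test_unknown_response_rejected(self, default_table):
        with pytest.raises(ValueError):
            fit_mixed_model(default_table, "accuracy")

    @staticmethod
    def _design_arrays(table):
        df = table[table["valid"] & table["ssrt_ms"].notna()]
        y = df["ssrt_ms"].to_numpy(float)
        g = np.where(df["group"] == "gamified", 1.0, -1.0)
        o = np.where(df["overweight"], 1.0, -1.0)
        s = np.where(df["category"] == "control", 1.0, -1.0)
        age_c = df["age"].to_numpy(float) - df["age"].mean()
        X = np.column_stack([np.ones_like(y), age_c, g, o, s,
                             g * o, g * s, o * s, g * o * s])
        return X, y, df["participant_id"].to_numpy()

    @staticmethod
    def _naive_dense_wald_f(X, y, groups):
        """Reference REML Wald F: explicit per-group dense matrices."""
        from scipy import optimize

        labels = pd.unique(groups)
        blocks = [np.flatnonzero(groups == lab) for lab in labels]
        n, p = X.shape

        def pieces(theta):
            XtWX = np.zeros((p, p))
            XtWy = np.zeros(p)
            logdet_v = 0.0
            for idx in blocks:
                Vi = np.eye(len(idx)) + theta * np.ones((len(idx), len(idx)))
                Wi = np.linalg.inv(Vi)
                logdet_v += np.linalg.slogdet(Vi)[1]
                XtWX += X[idx].T @ Wi @ X[idx]
                XtWy += X[idx].T @ Wi @ y[idx]
            beta = np.linalg.solve(XtWX, XtWy)
            rss = 0.0
            for idx in blocks:
                Wi = np.linalg.inv(np.eye(len(idx))
                                   + theta * np.ones((len(idx), len(idx))))
                ri = y[idx] - X[idx] @ beta
                rss += ri @ Wi @ ri
            crit = ((n - p) * np.log(rss) + logdet_v
                    + np.linalg.slogdet(XtWX)[1])
            return crit, beta, XtWX, rss

        res = optimize.minimize_scalar(lambda u: pieces(np.exp(u))[0],
                                       bounds=(-25, 25), method="bounded",
                                       options={"xatol": 1e-12})
        theta = float(np.exp(res.x))
        crit, beta, XtWX, rss = pieces(theta)
        crit0, beta0, XtWX0, rss0 = pieces(0.0)
        if crit0 < crit:
            beta, XtWX, rss = beta0, XtWX0, rss0
        sigma2 = rss / (n - p)
        cov = sigma2 * np.linalg.inv(XtWX)
        return beta ** 2 / np.diag(cov)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_reference_implementations(self, seed):
        # six-decimal agreement with a naive dense REML reference, plus a
        # coarser cross-check against statsmodels MixedLM (whose fixed-effect
        # covariance comes from the joint information matrix and agrees
        # only to ~1e-3)
        from statsmodels.regression.mixed_linear_model import MixedLM

        table = _analysis_table(seed,
                                CohortConfig.null(n_per_group=30),
                                DesignConfig(n_trials=128))
        # unbalance the table to exercise the missing-category path
        table = table.drop(table.index[5])
        eff = fit_mixed_model(table, "ssrt")

        X, y, groups = self._design_arrays(table)
        F_naive = self._naive_dense_wald_f(X, y, groups)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = MixedLM(y, X, groups=groups).fit(reml=True)
        F_sm = (np.asarray(m.fe_params) ** 2
                / np.diag(np.asarray(m.cov_params())[:9, :9]))
        for i, (_, row) in enumerate(eff.iterrows(), start=1):
            p_naive = stats.f.sf(F_naive[i], 1, row["df_den"])
            assert row["p"] == pytest.approx(p_naive, abs=1e-6)
            p_sm = stats.f.sf(F_sm[i], 1, row["df_den"])
            assert row["p"] == pytest.approx(p_sm, abs=5e-4)

    def test_parameter_recovery_over_replicates(self):
        # scaled-down recovery study: condition (+86) and overweight (+35)
        # latent shifts are recovered in sign and magnitude
        diffs_c, diffs_o = [], []
        ss = np.random.SeedSequence(555)
        for child in ss.spawn(25):
            s1, s2 = (int(x) for x in child.generate_state(2))
            from sstkit.config import GroupConfig
            cfg = CohortConfig(groups={
                "gamified": GroupConfig(n=30, go_shift_ms=196.0,
                                        ssrt_shift_ms=86.0),
                "nongamified": GroupConfig(n=30),
            })
            profiles = sample_cohort_profiles(cfg, s1)
            trials = simulate_cohort(profiles, DesignConfig(n_trials=128), s2)
            clean = apply_exclusions(trials, participants_to_frame(profiles))
            table = build_analysis_table(clean.estimates, clean.participants)
            eff = fit_mixed_model(table, "ssrt").set_index("effect")
            diffs_c.append(2 * eff.loc["condition", "estimate"])
            diffs_o.append(2 * eff.loc["overweight", "estimate"])
        assert np.mean(np.array(diffs_c) > 0) >= 0.9
        assert abs(np.mean(diffs_c) - 86) < 3 * np.std(diffs_c) / np.sqrt(25) + 10
        assert abs(np.mean(diffs_o) - 35) < 3 * np.std(diffs_o) / np.sqrt(25) + 10


class TestCorrelation:
    def test_perfect_line(self):
        tab = pd.DataFrame({
            "participant_id": [f"p{i}" for i in range(6)],
            "bmi": np.linspace(20, 30, 6),
            "ssrt_ms": np.linspace(250, 400, 6),
            "valid": True,
        })
        res = bmi_ssrt_correlation(tab)
        assert res.r == pytest.approx(1.0)
        assert res.n == 6

    def test_matches_pingouin_reference(self, default_table):
        pingouin = pytest.importorskip("pingouin")
        res = bmi_ssrt_correlation(default_table)
        df = default_table[default_table["valid"]
                           & default_table["ssrt_ms"].notna()]
        ref = pingouin.corr(df["bmi"], df["ssrt_ms"], method="pearson")
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        lo, hi = ref[ci_col].iloc[0]
        assert res.ci_low == pytest.approx(lo, abs=6e-3)  # pingouin rounds CIs
        assert res.ci_high == pytest.approx(hi, abs=6e-3)
        assert res.p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-10)

    def test_positive_slope_detected(self, default_table):
        # default config carries a +35 ms overweight shift: r should be > 0
        res = bmi_ssrt_correlation(default_table)
        assert res.r > 0

    def test_ci_covers_point(self, default_table):
        res = bmi_ssrt_correlation(default_table)
        assert res.ci_low < res.r < res.ci_high

    def test_null_coverage(self):
        # CI coverage under the null, on profile-level tables (latent SSRT,
        # no trial noise); scaled to 300 replicates
        cfg = CohortConfig.null(n_per_group=24)
        covered = 0
        n_rep = 300
        ss = np.random.SeedSequence(8080)
        for child in ss.spawn(n_rep):
            profiles = sample_cohort_profiles(cfg, int(child.generate_state(1)[0]))
            tab = pd.DataFrame({
                "participant_id": [p.id for p in profiles],
                "bmi": [p.bmi for p in profiles],
                "ssrt_ms": [p.ssrt_true_mean for p in profiles],
                "valid": True,
            })
            res = bmi_ssrt_correlation(tab)
            covered += res.ci_low <= 0 <= res.ci_high
        assert 0.92 <= covered / n_rep <= 0.98

    def test_zero_variance_rejected(self):
        tab = pd.DataFrame({"participant_id": list("abcd"), "bmi": 22.0,
                            "ssrt_ms": [300.0, 310, 290, 305], "valid": True})
        with pytest.raises(DegenerateDesignError):
            bmi_ssrt_correlation(tab)

    def test_too_few_records_rejected(self):
        tab = pd.DataFrame({"participant_id": list("abc"),
                            "bmi": [20.0, 22, 24],
                            "ssrt_ms": [300.0, 310, 290], "valid": True})
        with pytest.raises(DegenerateDesignError):
            bmi_ssrt_correlation(tab)


class TestOutlierSensitivity:
    def _table(self, extra_ssrt=None):
        rng = np.random.default_rng(42)
        n = 60
        bmi = rng.uniform(19, 33, n)
        ssrt = 250 + 4 * bmi + rng.normal(0, 25, n)
        if extra_ssrt is not None:
            ssrt[0] = extra_ssrt
        return pd.DataFrame({"participant_id": [f"p{i}" for i in range(n)],
                             "bmi": bmi, "ssrt_ms": ssrt, "valid": True})

    def test_no_outliers_idempotent(self):
        tab = self._table()
        assert outlier_sensitivity(tab).r == pytest.approx(
            bmi_ssrt_correlation(tab).r)

    def test_extreme_value_removed(self):
        clean_r = bmi_ssrt_correlation(self._table()).r
        tab = self._table(extra_ssrt=250 + 10 * 300)  # ~10 SD outlier
        before = bmi_ssrt_correlation(tab).r
        after = outlier_sensitivity(tab)
        assert after.n == len(tab) - 1
        assert abs(after.r - clean_r) < abs(before - clean_r)

    def test_n_reflects_removals(self):
        tab = self._table()
        rule = lambda v: np.arange(v.size) >= 6  # drop first six records
        res = outlier_sensitivity(tab, rule=rule)
        assert res.n == len(tab) - 6

    def test_rule_removing_all_rejected(self):
        tab = self._table()
        with pytest.raises(DegenerateDesignError):
            outlier_sensitivity(tab, rule=lambda v: np.zeros(v.size, bool))


class TestRequiredN:
    def test_exact_reproduces_49(self):
        assert required_n_correlation(0.35, 0.05, 0.80, "one") == 49

    def test_fisher_z_gives_50(self):
        # closed form n = ((z95 + z80)/atanh(rho))^2 + 3, rounded up
        assert required_n_correlation(0.35, 0.05, 0.80, "one",
                                      method="fisher_z") == 50
        assert fisher_z_required_n(0.35, 0.05, 0.80, "one") == 50

    def test_strong_effect_floors(self):
        assert required_n_correlation(0.999, 0.05, 0.80, "one") == 4

    def test_minimality(self):
        n = required_n_correlation(0.35, 0.05, 0.80, "one")
        assert exact_correlation_power(0.35, n) >= 0.80
        assert exact_correlation_power(0.35, n - 1) < 0.80

    def test_monotone_in_rho(self):
        ns = [required_n_correlation(r, 0.05, 0.80, "one")
              for r in (0.2, 0.35, 0.5)]
        assert ns[0] > ns[1] > ns[2]

    def test_two_sided_needs_more(self):
        assert (required_n_correlation(0.35, 0.05, 0.80, "two")
                > required_n_correlation(0.35, 0.05, 0.80, "one"))

    def test_exact_power_matches_monte_carlo(self):
        # independent Monte-Carlo oracle for the exact power integral
        rng = np.random.default_rng(7)
        rho, n, reps = 0.35, 49, 4000
        x = rng.standard_normal((reps, n))
        y = rho * x + np.sqrt(1 - rho ** 2) * rng.standard_normal((reps, n))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        r = (xm * ym).sum(1) / np.sqrt((xm ** 2).sum(1) * (ym ** 2).sum(1))
        t = r * np.sqrt(n - 2) / np.sqrt(1 - r ** 2)
        mc = float(np.mean(t > stats.t.ppf(0.95, n - 2)))
        assert exact_correlation_power(rho, n) == pytest.approx(mc, abs=0.02)

    def test_invalid_inputs_rejected(self):
        for bad in [dict(rho=0.0), dict(rho=1.2), dict(alpha=0.0),
                    dict(power=1.0), dict(sided="three")]:
            kwargs = dict(rho=0.35, alpha=0.05, power=0.8, sided="one")
            kwargs.update(bad)
            with pytest.raises(ConfigurationError):
                required_n_correlation(**kwargs)


class TestBuildAnalysisTable:
    def test_columns_and_overweight(self, default_table):
        assert set(default_table.columns) >= {
            "participant_id", "group", "overweight", "bmi", "age", "category",
            "mean_go_rt_ms", "ssrt_ms", "valid"}
        assert (default_table["overweight"]
                == (default_table["bmi"] >= 25)).all()
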