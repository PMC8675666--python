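import math
import warnings

import numpy as np
import pandas as pd
import pytest

from ssgnet.inference import (ModelSpec, SingularFitWarning, analyze_metric,
                              bootstrap_ci, categorize_f2, fit_lmm, local_f2,
                              lrt)


def clustered_rows(n_groups=24, per_group=8, group_sd=0.8, shift=0.0,
                   seed=0, group="team"):
    """Balanced 4-level-factor data with a genuine random intercept."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        u = rng.normal(0, group_sd)
        for r in range(per_group):
            level = r % 4
            rows.append({group: f"G{g:02d}", "week": str(level),
                         "y": u + shift * level + rng.normal()})
    return pd.DataFrame(rows)


@pytest.fixture(scope="module")
def fits():
    df = clustered_rows(shift=0.3, seed=42)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SingularFitWarning)
        full = fit_lmm(df, response="y", fixed=("week",), group="team")
        null = fit_lmm(df, response="y", fixed=(), group="team")
    return df, full, null


class TestFitLMM:
    def test_matches_statsmodels_ml(self, fits):
        """Profiled ML agrees with statsmodels MixedLM (ML) to high
        precision on a well-conditioned fixture."""
        smf = pytest.importorskip("statsmodels.formula.api")
        df, full, null = fits
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_full = smf.mixedlm("y ~ C(week)", df,
                                  groups=df["team"]).fit(reml=False)
            sm_null = smf.mixedlm("y ~ 1", df,
                                  groups=df["team"]).fit(reml=False)
        assert full.llf == pytest.approx(sm_full.llf, abs=1e-5)
        assert null.llf == pytest.approx(sm_null.llf, abs=1e-5)
        assert full.sigma2_resid == pytest.approx(sm_full.scale, rel=1e-4)
        assert full.sigma2_group == pytest.approx(
            float(sm_full.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-6)
        assert full.params.to_numpy() == pytest.approx(
            sm_full.fe_params.to_numpy(), abs=1e-6)

    def test_constant_response_degenerate(self):
        df = clustered_rows(seed=1)
        df["y"] = 5.0
        fit = fit_lmm(df, response="y", fixed=("week",), group="team")
        assert fit.sigma2_resid == 0.0 and fit.sigma2_group == 0.0
        assert fit.params["Intercept"] == 5.0

    def test_boundary_fit_warns_and_equals_ols(self):
        df = clustered_rows(group_sd=0.0, seed=2)
        with pytest.warns(SingularFitWarning):
            fit = fit_lmm(df, response="y", fixed=("week",), group="team")
        assert fit.sigma2_group == 0.0
        # boundary ML fit coincides with OLS
        X = np.column_stack([np.ones(len(df))] + [
            (df["week"] == str(l)).to_numpy(float) for l in (1, 2, 3)])
        beta = np.linalg.lstsq(X, df["y"].to_numpy(), rcond=None)[0]
        assert fit.params.to_numpy() == pytest.approx(beta, abs=1e-8)

    def test_recovers_known_shift(self):
        """A +1.0 shift on the top factor level is recovered."""
        df = clustered_rows(shift=0.0, seed=3)
        df.loc[df["week"] == "3", "y"] += 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingularFitWarning)
            fit = fit_lmm(df, response="y", fixed=("week",), group="team")
        assert fit.params["week[3]"] == pytest.approx(1.0, abs=0.25)

    def test_random_effect_absorbs_clustering(self):
        """With strong player clustering, the mixed fit attributes most
        variance to the group component, shrinking the residual well
        below the pooled OLS residual variance."""
        df = clustered_rows(group_sd=2.0, seed=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingularFitWarning)
            fit = fit_lmm(df, response="y", fixed=("week",), group="team")
        ols_resid_var = df.groupby("week")["y"].transform(
            lambda s: s - s.mean()).var()
        assert fit.sigma2_group > 1.0
        assert fit.sigma2_resid < 0.6 * ols_resid_var

    def test_model_spec_population_filter(self):
        df = clustered_rows(seed=5)
        df["band"] = np.where(df["team"] < "G12", "Early", "Late")
        df["player_id"] = df["team"]
        spec = ModelSpec(response="y", fixed=("week",), group="player_id",
                         population="early_only")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingularFitWarning)
            fit = fit_lmm(df, spec)
        assert fit.n_obs == (df["band"] == "Early").sum()

    def test_maturation_requires_pooled(self):
        with pytest.raises(ValueError, match="pooled"):
            ModelSpec(response="y", fixed=("band",), population="early_only")


class TestLRT:
    def test_identical_models(self, fits):
        _, full, _ = fits
        stat, df, p = lrt(full, full)
        assert stat == 0.0 and df == 0 and p == 1.0

    def test_df_counts_factor_levels(self, fits):
        _, full, null = fits
        stat, df, p = lrt(full, null)
        assert df == 3  # dropping a 4-level factor
        assert 0 <= p <= 1

    def test_non_nested_rejected(self):
        df = clustered_rows(seed=6)
        df["other"] = df["week"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingularFitWarning)
            a = fit_lmm(df, response="y", fixed=("week",), group="team")
            b = fit_lmm(df, response="y", fixed=("other",), group="team")
        with pytest.raises(ValueError, match="nested"):
            lrt(a, b)

    def test_detects_real_effect(self, fits):
        _, full, null = fits
        stat, df, p = lrt(full, null)
        assert p < 0.01


class TestLocalF2:
    def test_reduced_equals_full_is_zero(self, fits):
        _, full, null = fits
        assert local_f2(full, full, null) == 0.0

    def test_positive_for_real_effect(self, fits):
        _, full, null = fits
        assert local_f2(full, null, null) > 0.02

    def test_saturated_model_inf(self, fits):
        _, full, null = fits
        import dataclasses
        sat = dataclasses.replace(full, sigma2_resid=0.0)
        assert math.isinf(local_f2(sat, null, null))


class TestCategorize:
    @pytest.mark.parametrize("f2, cat", [
        (0.0, "negligible"), (0.01, "negligible"),
        (0.02, "small"), (0.12, "small"),
        (0.13, "medium"), (0.25, "medium"),
        (0.26, "large"), (0.27, "large"), (5.0, "large"),
    ])
    def test_left_closed_bins(self, f2, cat):
        assert categorize_f2(f2) == cat

    def test_alternative_thresholds(self):
        assert categorize_f2(0.30, thresholds=(0.02, 0.15, 0.35)) == "medium"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            categorize_f2(-0.1)


class TestBootstrapCI:
    def test_same_seed_identical(self):
        df = clustered_rows(n_groups=12, per_group=4, shift=0.4, seed=7)
        kw = dict(response="y", fixed=("week",), effect="week",
                  group="team", B=100, seed=99)
        assert bootstrap_ci(df, **kw) == bootstrap_ci(df, **kw)

    def test_interval_brackets_point_estimate(self):
        df = clustered_rows(n_groups=16, per_group=8, shift=0.5, seed=8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", SingularFitWarning)
            full = fit_lmm(df, response="y", fixed=("week",), group="team")
            null = fit_lmm(df, response="y", fixed=(), group="team")
        f2 = local_f2(full, null, null)
        lo, hi = bootstrap_ci(df, "y", ("week",), "week", group="team",
                              B=200, seed=1)
        assert lo <= f2 <= hi

    def test_single_cluster_flagged(self):
        df = clustered_rows(n_groups=1, per_group=16, seed=9)
        with pytest.warns(UserWarning, match="cluster"):
            lo, hi = bootstrap_ci(df, "y", ("week",), "week", group="team",
                                  B=100, seed=0)
        assert lo == pytest.approx(hi, abs=1e-12)

    def test_b_too_small_rejected(self):
        df = clustered_rows(seed=10)
        with pytest.raises(ValueError):
            bootstrap_ci(df, "y", ("week",), "week", group="team", B=10)


class TestAnalyzeMetric:
    def test_effect_rows_complete(self):
        df = clustered_rows(shift=0.5, seed=11)
        df["player_id"] = df["team"]
        out = analyze_metric(df, "y", ("week",), group="player_id",
                             bootstrap_B=100, seed=3)
        t = out[0]
        assert t.effect == "week" and t.df == 3
        assert t.ci_low <= t.f2 <= t.ci_high
        assert t.category in ("negligible", "small", "medium", "large")
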