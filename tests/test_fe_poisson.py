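"""Estimator: closed-form oracles, formulation equivalence, sandwich variance."""

import numpy as np
import pandas as pd
import pytest

import aidimpact as ai
from aidimpact.exceptions import RankError
from aidimpact.fe_poisson import FitResult, cluster_vcov, build_design

from conftest import make_panel, toy_2x2_panel, toy_spec


# ---------------------------------------------------------------------------
# Closed-form and cross-implementation oracles
# ---------------------------------------------------------------------------


def test_two_by_two_ratio_of_ratios():
    """The 2x2 FE-Poisson exposure coefficient is the log ratio of ratios."""
    panel = toy_2x2_panel(control_rates=(100, 100), treated_rates=(100, 80))
    f = ai.fit(panel, toy_spec())
    assert f.params["exposure_high"] == pytest.approx(np.log(0.8), abs=1e-8)
    assert np.exp(f.params["exposure_high"]) == pytest.approx(0.80, abs=1e-8)


def test_absorb_and_dummy_formulations_agree(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    spec = ai.ModelSpec(outcome="all_age")
    fa = ai.fit(d, spec, method="absorb")
    fd = ai.fit(d, spec, method="dummies")
    assert np.allclose(fa.params.to_numpy(), fd.params.to_numpy(), atol=1e-6)
    assert np.allclose(fa.alpha.to_numpy(), fd.alpha.to_numpy(), atol=1e-6)


def test_matches_statsmodels_glm(small_panel):
    """Independent oracle: statsmodels GLM Poisson with explicit dummies."""
    import statsmodels.api as sm

    d = ai.dichotomize_covariates(small_panel)
    spec = ai.ModelSpec(outcome="all_age")
    mine = ai.fit(d, spec)
    design = build_design(d, spec)
    dummies = pd.get_dummies(design.frame["country_id"], dtype=float)
    X = np.hstack([design.X, dummies.to_numpy()])
    ref = sm.GLM(design.y, X, family=sm.families.Poisson(),
                 offset=design.offset).fit()
    assert np.allclose(mine.params.to_numpy(), ref.params[:design.X.shape[1]],
                       atol=1e-6)


def test_offset_and_count_scale_invariance():
    """Rescaling denominators, or all pseudo-counts, leaves beta unchanged."""
    panel = toy_2x2_panel(treated_rates=(100, 73))
    base = ai.fit(panel, toy_spec()).params

    scaled = panel.data.copy()
    for c in ("population", "live_births", "all_age_deaths", "usaid_total"):
        scaled[c] *= 7.0  # rate unchanged: deaths and denominator co-scale
    f2 = ai.fit(make_panel(scaled), toy_spec()).params
    assert np.allclose(base.to_numpy(), f2.to_numpy(), atol=1e-8)

    bumped = panel.data.copy()
    bumped["all_age_deaths"] *= 1.7  # absorbed by the country intercepts
    bumped["all_age_rate"] *= 1.7
    f3 = ai.fit(make_panel(bumped), toy_spec()).params
    assert np.allclose(base.to_numpy(), f3.to_numpy(), atol=1e-8)


def test_collinear_design_names_aliased_column(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    d.data["gini_copy"] = d.data["gini"]
    spec = ai.ModelSpec(outcome="all_age",
                        covariates=("gini", "gini_copy", "piped_water"))
    with pytest.raises(RankError, match="gini"):
        ai.fit(d, spec)


def test_all_zero_countries_dropped(small_panel):
    panel = small_panel.subset(np.ones(small_panel.n_obs, dtype=bool))
    zero = panel.data["country_id"] == panel.countries[0]
    panel.data.loc[zero, ["hiv_deaths", "hiv_rate"]] = 0.0
    f = ai.fit(ai.dichotomize_covariates(panel), ai.ModelSpec(outcome="hiv"))
    assert f.dropped_countries == [panel.countries[0]]
    assert f.n_clusters == len(panel.countries) - 1


# ---------------------------------------------------------------------------
# Cluster-robust variance
# ---------------------------------------------------------------------------


def _pooled_poisson(rng, n=300):
    x = rng.normal(size=n)
    pc = rng.uniform(0.0, 10.0, size=n)  # independent continuous exposure
    mu = np.exp(0.3 + 0.5 * x - 0.05 * pc)
    y = rng.poisson(mu).astype(float)
    df = pd.DataFrame({
        "country_id": [f"C{i:04d}" for i in range(n)], "year": 2001,
        "income_group": "low", "population": 1000.0, "live_births": 30.0,
        "usaid_pc": pc, "all_age_deaths": y,
        "all_age_rate": y, "x": x,
    })
    df["usaid_total"] = df["usaid_pc"] * df["population"]
    df.loc[df.index[: n // 2], "year"] = 2002  # satisfy the 2-year invariant
    return make_panel(df, covariates=("x",))


def test_cluster_reduces_to_hc_with_singleton_clusters(rng):
    """One observation per cluster: the clustered sandwich equals the
    heteroskedasticity-robust one, including the small-sample factor."""
    panel = _pooled_poisson(rng)
    spec = ai.ModelSpec(outcome="all_age", exposure="continuous",
                        covariates=("x",), time_controls="none",
                        fixed_effects="none", offset_mode="rate")
    f = ai.fit(panel, spec)
    vc = cluster_vcov(f, cluster="country").to_numpy()
    vh = cluster_vcov(f, cluster="obs").to_numpy()
    assert np.allclose(vc, vh, rtol=1e-10)


def test_duplicating_rows_within_cluster_preserves_beta_and_se():
    """Brute-force oracle on a 6-row toy: duplicating every observation
    within its cluster changes neither beta nor the clustered SEs."""
    df = toy_2x2_panel(treated_rates=(100, 85)).data
    extra = df.iloc[:2].copy()  # give cluster A a third year for asymmetry
    extra["year"] = 2003
    df6 = pd.concat([df, extra], ignore_index=True)
    df6 = df6.drop_duplicates(["country_id", "year"])
    panel6 = make_panel(df6)
    spec = toy_spec(time_controls="none")
    f1 = ai.fit(panel6, spec)

    doubled = pd.concat([df6, df6.assign(year=df6["year"] + 10)],
                        ignore_index=True)
    f2 = ai.fit(make_panel(doubled), spec)
    assert np.allclose(f1.params.to_numpy(), f2.params.to_numpy(), atol=1e-8)
    assert np.allclose(f1.se.to_numpy(), f2.se.to_numpy(), rtol=1e-6)

    # explicit matrix computation of the sandwich on the small fit
    inter = f1.internals
    a = 0.0
    W = inter.weights * inter.mu
    codes = inter.group_codes
    n_g = len(inter.group_ids)
    wsum = np.bincount(codes, weights=W, minlength=n_g)
    means = np.vstack([np.bincount(codes, weights=W * inter.X[:, j], minlength=n_g)
                       / wsum for j in range(inter.X.shape[1])]).T
    Xc = inter.X - means[codes]
    s = inter.weights * (inter.y - inter.mu)
    A = Xc.T @ (Xc * W[:, None])
    U = np.vstack([np.bincount(codes, weights=s * Xc[:, j], minlength=n_g)
                   for j in range(Xc.shape[1])]).T
    V = np.linalg.inv(A) @ (U.T @ U) @ np.linalg.inv(A) * n_g / (n_g - 1)
    assert np.allclose(f1.vcov.to_numpy(), V, rtol=1e-8)


def test_cluster_se_matches_model_se_under_independence(rng):
    """Independent, correctly specified Poisson data: robust and
    model-based SEs agree within 10% at large n."""
    panel = _pooled_poisson(rng, n=4000)
    spec = ai.ModelSpec(outcome="all_age", exposure="continuous",
                        covariates=("x",), time_controls="none",
                        fixed_effects="none", offset_mode="rate")
    f = ai.fit(panel, spec)
    robust = f.se.to_numpy()
    model = np.sqrt(np.diag(f.vcov_model.to_numpy()))
    assert np.allclose(robust / model, 1.0, atol=0.10)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def test_rr_table_arithmetic(fit_all_age):
    f = FitResult(
        params=pd.Series({"exposure_high": -0.1625}),
        vcov=pd.DataFrame([[0.045 ** 2]], index=["exposure_high"],
                          columns=["exposure_high"]),
        vcov_model=pd.DataFrame([[0.045 ** 2]], index=["exposure_high"],
                                columns=["exposure_high"]),
        alpha=pd.Series(dtype=float), n_obs=1, n_clusters=1, loglik=0.0,
        converged=True, n_iter=1, spec=ai.ModelSpec(), exposure_terms=["exposure_high"],
        dropped_countries=[])
    row = ai.rr_table(f).iloc[0]
    assert row["label"] == "0.85 (0.78–0.93)"
    assert row["ci_low"] <= row["rr"] <= row["ci_high"]

    # zero coefficient gives RR 1 with a CI symmetric around 1 on log scale
    f.params[:] = 0.0
    row0 = ai.rr_table(f).iloc[0]
    assert row0["rr"] == pytest.approx(1.0)
    assert row0["ci_low"] * row0["ci_high"] == pytest.approx(1.0)

    # widening SE widens the interval monotonically
    real = ai.rr_table(fit_all_age)
    assert (real["ci_low"] <= real["rr"]).all() and (real["rr"] <= real["ci_high"]).all()


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def test_stratified_reduces_to_full_fit(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    spec = ai.ModelSpec(outcome="all_age")
    full = ai.fit(d, spec)
    res = ai.fit_stratified(d, spec, {"all": list(d.countries)})
    assert np.allclose(res.fits["all"].params.to_numpy(), full.params.to_numpy())


def test_stratified_fits_are_local(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    spec = ai.ModelSpec(outcome="all_age")
    countries = list(d.countries)
    half = len(countries) // 2
    strata = {"first": countries[:half], "second": countries[half:]}
    res = ai.fit_stratified(d, spec, strata)
    solo = ai.fit(d.subset(d.data["country_id"].isin(strata["first"]).to_numpy()),
                  spec)
    assert np.allclose(res.fits["first"].params.to_numpy(), solo.params.to_numpy(),
                       atol=1e-8)


def test_stratified_recovers_effect_ordering():
    """Two country blocks generated with different true effects: the
    stratified fits recover which stratum has the stronger effect."""
    wins = 0
    for seed in range(5):
        cfg_strong = ai.GeneratorConfig(n_countries=60, year_end=2012, seed=900 + seed)
        cfg_strong.true_rr["all_age"] = {"low": 0.90, "intermediate": 0.82, "high": 0.70}
        cfg_weak = ai.GeneratorConfig(n_countries=60, year_end=2012, seed=950 + seed)
        strong, _ = ai.generate_panel(cfg_strong)
        weak, _ = ai.generate_panel(cfg_weak)
        weak.data["country_id"] = "W" + weak.data["country_id"]
        combined = make_panel(pd.concat([strong.data, weak.data], ignore_index=True),
                              outcomes=strong.outcomes,
                              covariates=strong.covariates)
        d = ai.dichotomize_covariates(combined)
        strata = {"strong": list(strong.countries),
                  "weak": list(weak.countries)}  # ids already W-prefixed
        res = ai.fit_stratified(d, ai.ModelSpec(outcome="all_age"), strata)
        wins += (res.fits["strong"].params["exposure_high"]
                 < res.fits["weak"].params["exposure_high"])
    assert wins >= 3


def test_income_stratification_runs(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    res = ai.fit_stratified(d, ai.ModelSpec(outcome="all_age"), "income")
    assert len(res.fits) + len(res.skipped) == d.data["income_group"].nunique()


def test_negative_binomial_on_poisson_data(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    spec = ai.ModelSpec(outcome="all_age")
    pois = ai.fit(d, spec)
    nb = ai.negative_binomial_fit(d, spec)
    assert nb.dispersion is not None and nb.dispersion < 1e-3
    assert np.exp(nb.params["exposure_high"]) == pytest.approx(
        np.exp(pois.params["exposure_high"]), rel=0.02)


def test_negative_binomial_on_overdispersed_data():
    cfg = ai.GeneratorConfig(n_countries=100, year_end=2012, seed=13,
                             dispersion="nb", nb_size=50.0)
    panel, _ = ai.generate_panel(cfg)
    d = ai.dichotomize_covariates(panel)
    spec = ai.ModelSpec(outcome="all_age")
    pois = ai.fit(d, spec)
    nb = ai.negative_binomial_fit(d, spec)
    assert nb.dispersion == pytest.approx(1.0 / 50.0, rel=0.5)
    # point estimates agree within Monte-Carlo error...
    se_nb = np.sqrt(nb.vcov_model.loc["exposure_high", "exposure_high"])
    assert abs(nb.params["exposure_high"] - pois.params["exposure_high"]) < 3 * se_nb
    # ...while the model-based (non-robust) variances differ materially
    v_p = pois.vcov_model.loc["exposure_high", "exposure_high"]
    v_nb = nb.vcov_model.loc["exposure_high", "exposure_high"]
    assert v_nb > 2.0 * v_p


def test_population_weighting_runs(small_panel):
    d = ai.dichotomize_covariates(small_panel)
    f = ai.fit(d, ai.ModelSpec(outcome="all_age", weights="population"))
    assert np.isfinite(f.params.to_numpy()).all()
    assert np.isfinite(f.se.to_numpy()).all()


def test_rate_mode_matches_offset_mode_on_balanced_toy():
    panel = toy_2x2_panel(treated_rates=(100, 80))
    f_off = ai.fit(panel, toy_spec(offset_mode="offset"))
    f_rate = ai.fit(panel, toy_spec(offset_mode="rate"))
    # equal denominators: identical exposure coefficient either way
    assert f_rate.params["exposure_high"] == pytest.approx(
        f_off.params["exposure_high"], abs=1e-8)
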