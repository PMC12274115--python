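"""Microsimulation forecast: extrapolation oracles, scenario logic, MC."""

import numpy as np
import pandas as pd
import pytest

import aidimpact as ai
from aidimpact.exceptions import ExtrapolationError, ScenarioError
from aidimpact.forecast import CohortProjection, _scenario_design


@pytest.fixture(scope="module")
def cohort(paper_like, dichotomized):
    panel, _ = paper_like
    return ai.build_cohort(panel, medians=dichotomized.metadata["covariate_medians"])


@pytest.fixture(scope="module")
def forecast_result(fit_all_age, cohort):
    return ai.run_forecast(fit_all_age, cohort, n_sims=400, seed=8)


# ---------------------------------------------------------------------------
# Extrapolation
# ---------------------------------------------------------------------------


def test_constant_history_projects_constant():
    s = pd.Series(5.0, index=range(2010, 2022))
    proj = ai.extrapolate_covariate(s, [2024, 2030], scale="positive")
    assert np.allclose(proj.to_numpy(), 5.0)


def test_exact_line_continues_exactly():
    # closed-form OLS on a noiseless line reproduces the line
    years = np.arange(2012, 2022)
    slope, intercept = 0.03, -58.0
    s = pd.Series(np.exp(intercept + slope * years), index=years)
    proj = ai.extrapolate_covariate(s, [2025, 2030], scale="positive")
    expected = np.exp(intercept + slope * np.array([2025, 2030]))
    assert np.allclose(proj.to_numpy(), expected, rtol=1e-10)


def test_share_projection_stays_bounded():
    years = np.arange(2010, 2022)
    s = pd.Series(np.minimum(0.5 + 0.045 * (years - 2010), 0.999), index=years)
    proj = ai.extrapolate_covariate(s, range(2024, 2031), scale="proportion")
    assert (proj <= 1.0).all() and (proj >= 0.0).all()


def test_short_history_rejected():
    with pytest.raises(ExtrapolationError):
        ai.extrapolate_covariate(pd.Series([1.0, 2.0], index=[2001, 2002]),
                                 [2024], scale="positive")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def test_cohort_geometry(cohort, paper_like):
    panel, _ = paper_like
    assert len(cohort.data) == len(panel.countries) * 7  # 2024..2030
    assert set(cohort.data["year"]) == set(range(2024, 2031))
    assert (cohort.data["provenance"] == "extrapolated").all()
    assert cohort.data[list(cohort.medians)].isin([0.0, 1.0]).all().all()


def test_cohort_overlapping_horizon_keeps_observed_values(paper_like, dichotomized):
    panel, _ = paper_like
    c = ai.build_cohort(panel, horizon=(2019, 2023),
                        medians=dichotomized.metadata["covariate_medians"])
    obs = c.data[c.data["year"] <= 2021]
    assert (obs["provenance"] == "observed").all()
    merged = obs.merge(panel.data, on=["country_id", "year"],
                       suffixes=("_cohort", ""))
    assert np.allclose(merged["population_cohort"], merged["population"])
    assert (c.data[c.data["year"] > 2021]["provenance"] == "extrapolated").all()


def test_cohort_denominators_continue_growth(cohort, paper_like):
    panel, _ = paper_like
    # populations grow monotonically in the generator; projections continue
    pop = cohort.data.pivot(index="country_id", columns="year", values="population")
    assert (pop.diff(axis=1).iloc[:, 1:] > 0).all().all()


def test_cohort_reference_funding_is_last_observed(cohort, paper_like):
    panel, _ = paper_like
    last = panel.data[panel.data["year"] == panel.data["year"].max()]
    ref = last.set_index("country_id")["usaid_pc"]
    pd.testing.assert_series_equal(
        cohort.reference_usaid_pc.sort_index(), ref.sort_index(),
        check_names=False)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


def test_business_as_usual_keeps_reference_categories(cohort):
    df = ai.apply_scenario(cohort, ai.ScenarioSpec.business_as_usual(range(2024, 2031)))
    ref_cat = ai.categorize_exposure(cohort.reference_usaid_pc.to_numpy(),
                                     cohort.scheme)
    ref = pd.Series(ref_cat, index=cohort.reference_usaid_pc.index)
    assert (df["exposure_category"].to_numpy()
            == ref.loc[df["country_id"]].to_numpy()).all()


def test_termination_year_is_all_baseline(cohort):
    df = ai.apply_scenario(cohort, ai.ScenarioSpec.defunding(range(2024, 2031)))
    y2026 = df[df["year"] == 2026]
    assert (y2026["usaid_pc"] == 0.0).all()
    assert (y2026["exposure_category"] == "baseline").all()


def test_cut_multiplier_band_arithmetic():
    # 0.17 x 20.45 = 3.4765, which sits in the [1.97, 3.97) band
    assert 0.17 * 20.45 == pytest.approx(3.4765)
    assert ai.categorize_exposure(0.17 * 20.45) == "low"


def test_missing_multiplier_rejected(cohort):
    scen = ai.ScenarioSpec("partial", {2024: 1.0})
    with pytest.raises(ScenarioError, match="2025|no multiplier"):
        ai.apply_scenario(cohort, scen)


def test_negative_multiplier_rejected():
    with pytest.raises(ScenarioError):
        ai.ScenarioSpec("bad", {2024: -0.1})


# ---------------------------------------------------------------------------
# Monte-Carlo projection
# ---------------------------------------------------------------------------


def _toy_fit_and_cohort(rr_high=0.85):
    """3 countries, one year, all in the high band at reference funding;
    a hand-built fit with known coefficients and zero covariance."""
    spec = ai.ModelSpec(outcome="all_age", covariates=(), time_controls="none")
    params = pd.Series({"exposure_low": -0.05, "exposure_intermediate": -0.08,
                        "exposure_high": np.log(rr_high)})
    zero = pd.DataFrame(np.zeros((3, 3)), index=params.index, columns=params.index)
    alpha = pd.Series({"A": np.log(8.0), "B": np.log(12.0), "C": np.log(5.0)})
    fit = ai.FitResult(params=params, vcov=zero, vcov_model=zero, alpha=alpha,
                       n_obs=3, n_clusters=3, loglik=0.0, converged=True,
                       n_iter=1, spec=spec,
                       exposure_terms=list(params.index), dropped_countries=[])
    rows = []
    for cid, pop in (("A", 1e6), ("B", 2e6), ("C", 5e5)):
        for year in (2024, 2025):
            rows.append({"country_id": cid, "year": year, "income_group": "low",
                         "population": pop, "live_births": pop / 30,
                         "provenance": "extrapolated"})
    cohort = CohortProjection(
        data=pd.DataFrame(rows),
        reference_usaid_pc=pd.Series({"A": 10.0, "B": 8.0, "C": 20.0}),
        reference_year=2023, medians={}, scheme=ai.ExposureScheme(),
        outcomes={"all_age": "population"})
    return fit, cohort


def test_point_projection_matches_closed_form():
    """With known coefficients, excess deaths equal sum mu*(RR_cf/RR_bau - 1)."""
    fit, cohort = _toy_fit_and_cohort(rr_high=0.85)
    scenarios = (ai.ScenarioSpec.business_as_usual((2024, 2025)),
                 ai.ScenarioSpec("cut", {2024: 1.0, 2025: 0.0}))
    res = ai.run_forecast(fit, cohort, scenarios, n_sims=5, seed=0)
    rates = {"A": 8.0, "B": 12.0, "C": 5.0}
    pops = {"A": 1e6, "B": 2e6, "C": 5e5}
    mu_bau = sum(r * 0.85 * pops[c] / 1000 for c, r in rates.items())
    mu_cut = sum(r * pops[c] / 1000 for c, r in rates.items())
    i25 = list(res.years).index(2025)
    assert res.point["business_as_usual"][i25] == pytest.approx(mu_bau, rel=1e-12)
    assert res.point["cut"][i25] == pytest.approx(mu_cut, rel=1e-12)
    # zero vcov: every draw identical to the point
    assert np.allclose(res.draws["cut"], res.point["cut"][None, :])


def test_single_band_mrr_is_inverse_rr():
    fit, cohort = _toy_fit_and_cohort(rr_high=0.85)
    scenarios = (ai.ScenarioSpec.business_as_usual((2024, 2025)),
                 ai.ScenarioSpec("cut", {2024: 0.0, 2025: 0.0}))
    res = ai.run_forecast(fit, cohort, scenarios, n_sims=5, seed=0)
    mrr = ai.mortality_rate_ratio(res, baseline="business_as_usual", cut="cut",
                                  report_years=(2024, 2025))
    assert np.allclose(mrr["mrr"], 1.0 / 0.85)


def test_identical_scenarios_zero_excess(fit_all_age, cohort):
    scenarios = (ai.ScenarioSpec.business_as_usual(range(2024, 2031)),
                 ai.ScenarioSpec("same", {y: 1.0 for y in range(2024, 2031)}))
    res = ai.run_forecast(fit_all_age, cohort, scenarios, n_sims=50, seed=1)
    assert np.array_equal(res.draws["business_as_usual"], res.draws["same"])
    table = ai.excess_summary(res, baseline="business_as_usual", cut="same")
    assert (table["excess"] == 0.0).all()
    assert (table["ci_low"] == 0.0).all() and (table["ci_high"] == 0.0).all()


def test_seed_determinism(fit_all_age, cohort):
    r1 = ai.run_forecast(fit_all_age, cohort, n_sims=100, seed=4)
    r2 = ai.run_forecast(fit_all_age, cohort, n_sims=100, seed=4)
    for name in r1.draws:
        assert np.array_equal(r1.draws[name], r2.draws[name])
        assert np.array_equal(r1.point[name], r2.point[name])


def test_cumulative_equals_sum_of_annual(forecast_result):
    table = ai.excess_summary(forecast_result)
    annual = table.iloc[:-1]["excess"].sum()
    assert table.iloc[-1]["excess"] == pytest.approx(annual, rel=1e-12)
    # the cumulative UI is the percentile of the per-draw annual sums
    dr = (forecast_result.draws["defunding"] - forecast_result.draws["business_as_usual"])
    idx = [list(forecast_result.years).index(y) for y in range(2025, 2031)]
    cum = dr[:, idx].sum(axis=1)
    lo, hi = np.percentile(cum, [2.5, 97.5])
    assert table.iloc[-1]["ci_low"] == pytest.approx(lo)
    assert table.iloc[-1]["ci_high"] == pytest.approx(hi)


def test_defunding_never_reduces_deaths(forecast_result):
    """All fitted exposure RRs < 1: weaker funding cannot lower deaths."""
    excess = (forecast_result.point["defunding"]
              - forecast_result.point["business_as_usual"])
    assert (excess >= 0).all()
    mrr = ai.mortality_rate_ratio(forecast_result)
    assert (mrr["mrr"] >= 1.0).all()


def test_ui_stable_when_doubling_draws(fit_all_age, cohort):
    r500 = ai.run_forecast(fit_all_age, cohort, n_sims=500, seed=9)
    r1000 = ai.run_forecast(fit_all_age, cohort, n_sims=1000, seed=9)
    t500 = ai.excess_summary(r500).iloc[-1]
    t1000 = ai.excess_summary(r1000).iloc[-1]
    assert t1000["ci_low"] == pytest.approx(t500["ci_low"], rel=0.02)
    assert t1000["ci_high"] == pytest.approx(t500["ci_high"], rel=0.02)
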