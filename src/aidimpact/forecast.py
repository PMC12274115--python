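"""Ex-ante microsimulation: funding-cut scenarios projected to 2030.

Two-stage design. Stage one builds a synthetic cohort of all countries for
the projection horizon (2024-2030 by default) by extrapolating every
modelled covariate and denominator per country — a linear trend on a
transformed scale (logit for bounded shares, log for positive quantities)
over the most recent ten observed years — and freezing the retrospective
dichotomisation medians and exposure cut points. Stage two predicts deaths
from the retrospective fit under alternative funding paths: a
business-as-usual scenario holding each country's per-capita funding at its
last observed level, and a defunding scenario (83% cut in 2025, full
termination 2026-2030 by default), with coefficient uncertainty propagated
by Monte-Carlo draws shared across scenarios within each draw (common
random numbers), so excess-death uncertainty reflects the scenario
contrast rather than independent sampling noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ExtrapolationError, ForecastError, ScenarioError
from .attribution import _coef_draws
from .fe_poisson import FitResult, build_design
from .paneldata import (
    COVARIATE_SCALES,
    ExposureScheme,
    Panel,
    categorize_exposure,
    dichotomize_covariates,
)

log = logging.getLogger("aidimpact")

DEFAULT_HORIZON = (2024, 2030)
REPORT_YEARS = tuple(range(2025, 2031))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Per-year multipliers on each country's reference per-capita funding."""

    name: str
    multipliers: dict[int, float]

    def __post_init__(self):
        if any(m < 0 for m in self.multipliers.values()):
            raise ScenarioError(f"scenario {self.name!r} has negative multipliers")

    def multiplier(self, year: int) -> float:
        if year not in self.multipliers:
            raise ScenarioError(f"scenario {self.name!r} has no multiplier for {year}")
        return self.multipliers[year]

    @classmethod
    def business_as_usual(cls, years=range(2024, 2031)) -> "ScenarioSpec":
        return cls("business_as_usual", {int(y): 1.0 for y in years})

    @classmethod
    def defunding(cls, years=range(2024, 2031), cut_year: int = 2025,
                  cut_multiplier: float = 0.17) -> "ScenarioSpec":
        """83% cut in the cut year, termination afterwards."""
        mult = {}
        for y in years:
            y = int(y)
            if y < cut_year:
                mult[y] = 1.0
            elif y == cut_year:
                mult[y] = cut_multiplier
            else:
                mult[y] = 0.0
        return cls("defunding", mult)


# ---------------------------------------------------------------------------
# Covariate extrapolation
# ---------------------------------------------------------------------------

_EPS = 1e-6


def _to_transformed(values, scale):
    v = np.asarray(values, dtype=float)
    if scale == "proportion":
        return np.log(np.clip(v, _EPS, 1 - _EPS) / (1 - np.clip(v, _EPS, 1 - _EPS)))
    if scale == "percent":
        p = np.clip(v / 100.0, _EPS, 1 - _EPS)
        return np.log(p / (1 - p))
    if scale == "positive":
        return np.log(np.maximum(v, _EPS))
    return v


def _from_transformed(z, scale):
    z = np.asarray(z, dtype=float)
    if scale == "proportion":
        return 1.0 / (1.0 + np.exp(-z))
    if scale == "percent":
        return 100.0 / (1.0 + np.exp(-z))
    if scale == "positive":
        return np.exp(z)
    return z


def extrapolate_covariate(series: pd.Series, horizon, scale: str = "identity",
                          lookback: int = 10) -> pd.Series:
    """Project a per-country series over future years by linear trend.

    The trend is an OLS line on the transformed scale (logit for bounded
    shares, log for positive quantities, identity otherwise) over the most
    recent ``lookback`` observed years, continued over ``horizon`` and
    back-transformed — which also clips projections to the admissible
    range (a share never exceeds 1). Needs at least 3 history points.
    """
    s = pd.Series(series).dropna().sort_index()
    if len(s) < 3:
        raise ExtrapolationError(
            f"need >=3 history points to extrapolate, got {len(s)}")
    recent = s.iloc[-lookback:]
    years = recent.index.to_numpy(dtype=float)
    z = _to_transformed(recent.to_numpy(), scale)
    slope, intercept = np.polyfit(years, z, 1)
    horizon = np.asarray(list(horizon), dtype=float)
    proj = _from_transformed(intercept + slope * horizon, scale)
    return pd.Series(proj, index=horizon.astype(int))


# ---------------------------------------------------------------------------
# Cohort construction
# ---------------------------------------------------------------------------


@dataclass
class CohortProjection:
    """Panel-shaped future records with frozen retrospective metadata."""

    data: pd.DataFrame                       # includes a 'provenance' column
    reference_usaid_pc: pd.Series            # per country, last observed year
    reference_year: int
    medians: dict[str, float]
    scheme: ExposureScheme
    outcomes: dict[str, str]
    excluded: dict[str, str] = field(default_factory=dict)


def build_cohort(panel: Panel, horizon: tuple[int, int] = DEFAULT_HORIZON,
                 medians: dict[str, float] | None = None,
                 scheme: ExposureScheme | None = None,
                 covariates=None, lookback: int = 10) -> CohortProjection:
    """Synthetic cohort for the projection horizon.

    ``panel`` must be the raw (not yet dichotomised) retrospective panel;
    covariates are extrapolated on their natural scale and then
    dichotomised with the retrospective medians (frozen, not re-estimated).
    Horizon years already observed are copied through unchanged and tagged
    ``observed``. Countries lacking usable look-back history are excluded
    with a logged reason.
    """
    covariates = tuple(covariates or panel.covariates)
    scheme = scheme or ExposureScheme()
    if medians is None:
        medians = dichotomize_covariates(panel, covariates).metadata["covariate_medians"]
    df = panel.data
    last_obs = int(df["year"].max())
    years = np.arange(horizon[0], horizon[1] + 1)
    future_years = years[years > last_obs]
    observed_years = years[years <= last_obs]

    series_cols = {c: COVARIATE_SCALES.get(c, "identity") for c in covariates}
    series_cols["population"] = "positive"
    series_cols["live_births"] = "positive"
    present = {c: s for c, s in series_cols.items() if c in df.columns}

    rows = []
    excluded: dict[str, str] = {}
    ref_pc = {}
    for cid, sub in df.groupby("country_id"):
        sub = sub.sort_values("year").set_index("year")
        hist_ok = all(sub[c].dropna().iloc[-lookback:].notna().sum() >= 3
                      for c in present)
        if not hist_ok or sub["usaid_pc"].dropna().empty:
            excluded[cid] = "insufficient look-back history"
            continue
        ref_pc[cid] = float(sub["usaid_pc"].dropna().iloc[-1])
        proj = {c: extrapolate_covariate(sub[c], future_years, scale=s,
                                         lookback=lookback)
                for c, s in present.items()}
        for y in years:
            if y in observed_years:
                rec = {c: float(sub.loc[y, c]) for c in present}
                prov = "observed"
            else:
                rec = {c: float(proj[c].loc[y]) for c in present}
                prov = "extrapolated"
            rec.update(country_id=cid, year=int(y),
                       income_group=sub["income_group"].iloc[-1],
                       provenance=prov)
            rows.append(rec)
    if excluded:
        log.info("cohort excludes %d countries: %s", len(excluded),
                 list(excluded)[:5])
    if not rows:
        raise ExtrapolationError("no country has sufficient look-back history")
    out = pd.DataFrame(rows).sort_values(["country_id", "year"]).reset_index(drop=True)
    # dichotomise with the frozen retrospective medians
    for cov in covariates:
        if cov in out.columns:
            out[cov] = (out[cov] > medians[cov]).astype(float)
    return CohortProjection(
        data=out,
        reference_usaid_pc=pd.Series(ref_pc, name="usaid_pc"),
        reference_year=last_obs,
        medians=dict(medians),
        scheme=scheme,
        outcomes=dict(panel.outcomes),
        excluded=excluded,
    )


def apply_scenario(cohort: CohortProjection, scenario: ScenarioSpec,
                   scheme: ExposureScheme | None = None) -> pd.DataFrame:
    """Cohort records with scenario funding and frozen-cut exposure bands."""
    scheme = scheme or cohort.scheme
    df = cohort.data.copy()
    mult = np.array([scenario.multiplier(int(y)) for y in df["year"]])
    ref = cohort.reference_usaid_pc.loc[df["country_id"]].to_numpy()
    df["usaid_pc"] = mult * ref
    df["exposure_category"] = categorize_exposure(df["usaid_pc"].to_numpy(), scheme)
    return df


# ---------------------------------------------------------------------------
# Monte-Carlo projection
# ---------------------------------------------------------------------------


@dataclass
class ForecastResult:
    """Per-scenario, per-year, per-draw projected deaths for one outcome."""

    outcome: str
    years: np.ndarray
    point: dict[str, np.ndarray]             # scenario -> (n_years,)
    draws: dict[str, np.ndarray]             # scenario -> (n_sims, n_years)
    denominators: np.ndarray                 # (n_years,), shared by scenarios
    n_sims: int
    seed: int | None
    level: float = 0.95


def _scenario_design(fit: FitResult, df: pd.DataFrame):
    """Design matrix for cohort rows, aligned to the fitted coefficients.

    Future years carry zero on every shock dummy; in year-dummy mode the
    last fitted year's dummy is carried forward unchanged (the fit's secular
    level continues, per the frozen-coefficients contract).
    """
    design = build_design(df, fit.spec, drop_empty_exposure=False)
    Xdf = pd.DataFrame(design.X, columns=design.columns, copy=False)
    X = Xdf.reindex(columns=fit.params.index, fill_value=0.0)
    if fit.spec.time_controls == "years" and fit.internals is not None:
        last = int(fit.internals.frame["year"].max())
        col = f"year_{last}"
        if col in X.columns:
            X.loc[design.frame["year"].to_numpy() > last, col] = 1.0
    alpha = fit.alpha.loc[design.frame["country_id"]].to_numpy() \
        if fit.spec.fixed_effects == "country" \
        else np.full(len(design.frame), float(fit.alpha.iloc[0]))
    return design.frame, X.to_numpy(), alpha + design.offset


def run_forecast(fit: FitResult, cohort: CohortProjection, scenarios=None,
                 n_sims: int = 1000, seed: int | None = 0,
                 level: float = 0.95, which: str = "full") -> ForecastResult:
    """Project deaths per year under each scenario with shared coefficient
    draws (common random numbers across scenarios within a draw)."""
    if scenarios is None:
        yrs = range(int(cohort.data["year"].min()), int(cohort.data["year"].max()) + 1)
        scenarios = (ScenarioSpec.business_as_usual(yrs), ScenarioSpec.defunding(yrs))
    outcome = fit.spec.outcome
    denom_col = cohort.outcomes.get(outcome, "population")
    years = np.sort(cohort.data["year"].unique())
    rng = np.random.default_rng(seed)
    draws = _coef_draws(fit, n_sims, rng, which=which)

    point: dict[str, np.ndarray] = {}
    sim: dict[str, np.ndarray] = {}
    denominators = None
    for scen in scenarios:
        df = apply_scenario(cohort, scen)
        # prediction designs need outcome placeholder columns
        df[f"{outcome}_deaths"] = 0.0
        df[f"{outcome}_rate"] = 0.0
        frame, X, base = _scenario_design(fit, df)
        year_codes = pd.Categorical(frame["year"], categories=years).codes
        n_years = len(years)
        mu_point = np.exp(base + X @ fit.params.to_numpy())
        point[scen.name] = np.bincount(year_codes, weights=mu_point,
                                       minlength=n_years)
        eta = base[None, :] + draws @ X.T
        mu = np.exp(eta)
        agg = np.zeros((n_sims, n_years))
        for j in range(n_years):
            agg[:, j] = mu[:, year_codes == j].sum(axis=1)
        sim[scen.name] = agg
        if denominators is None:
            denominators = np.bincount(
                year_codes, weights=frame[denom_col].to_numpy(dtype=float),
                minlength=n_years)
    return ForecastResult(outcome=outcome, years=years, point=point, draws=sim,
                          denominators=denominators, n_sims=n_sims, seed=seed,
                          level=level)


def _scenario_pair(result: ForecastResult, baseline: str | None, cut: str | None):
    names = list(result.point)
    if len(names) < 2:
        raise ForecastError("need at least 2 scenarios to compare")
    baseline = baseline or ("business_as_usual" if "business_as_usual" in names
                            else names[0])
    cut = cut or next(n for n in names if n != baseline)
    return baseline, cut


def excess_summary(result: ForecastResult, baseline: str | None = None,
                   cut: str | None = None,
                   report_years=REPORT_YEARS) -> pd.DataFrame:
    """Annual and cumulative excess deaths (cut minus baseline) with
    percentile uncertainty intervals.

    The cumulative row is the per-draw sum of annual excess over the report
    years, then percentiles — so cumulative equals the sum of annual rows
    exactly at the point estimate and within every draw.
    """
    baseline, cut = _scenario_pair(result, baseline, cut)
    years = [y for y in report_years if y in set(result.years)]
    idx = [int(np.where(result.years == y)[0][0]) for y in years]
    pt = result.point[cut][idx] - result.point[baseline][idx]
    dr = result.draws[cut][:, idx] - result.draws[baseline][:, idx]
    tail = 100 * (1 - result.level) / 2
    lo, hi = np.percentile(dr, [tail, 100 - tail], axis=0)
    rows = [{"year": str(y), "excess": float(p), "ci_low": float(l),
             "ci_high": float(h)} for y, p, l, h in zip(years, pt, lo, hi)]
    cum = dr.sum(axis=1)
    clo, chi = np.percentile(cum, [tail, 100 - tail])
    rows.append({"year": f"{min(years)}–{max(years)}", "excess": float(pt.sum()),
                 "ci_low": float(clo), "ci_high": float(chi)})
    out = pd.DataFrame(rows)
    out["label"] = [f"{r.excess:,.0f} ({r.ci_low:,.0f}–{r.ci_high:,.0f})"
                    for r in out.itertuples()]
    return out


def mortality_rate_ratio(result: ForecastResult, baseline: str | None = None,
                         cut: str | None = None,
                         report_years=REPORT_YEARS) -> pd.DataFrame:
    """Per-year mortality rate ratio (cut vs baseline) with percentile UI.

    Scenarios share denominators, so the ratio of rates equals the ratio of
    deaths within each year and draw."""
    baseline, cut = _scenario_pair(result, baseline, cut)
    years = [y for y in report_years if y in set(result.years)]
    idx = [int(np.where(result.years == y)[0][0]) for y in years]
    base_pt = result.point[baseline][idx]
    if np.any(base_pt <= 0):
        bad = years[int(np.argmax(base_pt <= 0))]
        raise ForecastError(f"zero baseline deaths in {bad}: rate ratio undefined")
    pt = result.point[cut][idx] / base_pt
    dr = result.draws[cut][:, idx] / result.draws[baseline][:, idx]
    tail = 100 * (1 - result.level) / 2
    lo, hi = np.percentile(dr, [tail, 100 - tail], axis=0)
    return pd.DataFrame({"year": years, "mrr": pt, "ci_low": lo, "ci_high": hi})
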