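"""Causal-robustness toolkit: matched difference-in-differences and the
negative-control harness.

The matched DiD compares the change in log mortality between a baseline
year and an end year across countries with medium/high funding coverage
versus low coverage, after pairing countries on a logistic propensity
score (greedy 1:1 nearest-neighbour on the logit score, without
replacement, caliper 0.2 SD of the logit score). Because the primary model
is a log-link rate model, the double difference of log rates is directly
comparable to a fitted log rate ratio.

The negative-control harness refits the primary model on injury mortality
— an outcome development aid is not expected to move — and flags residual
bias whenever any exposure-band confidence interval excludes 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import EmptyMatchError, SeparationError
from .fe_poisson import FitResult, ModelSpec, fit, rr_table
from .paneldata import ExposureScheme, Panel

log = logging.getLogger("aidimpact")


# ---------------------------------------------------------------------------
# Treatment definition and propensity model
# ---------------------------------------------------------------------------


def coverage_treatment(panel: Panel, scheme: ExposureScheme | None = None) -> pd.Series:
    """Medium/high-coverage indicator per country.

    A country counts as medium/high coverage when its mean per-capita
    funding over the study period reaches the low/intermediate band cut;
    everything below is low coverage."""
    scheme = scheme or ExposureScheme()
    means = panel.data.groupby("country_id")["usaid_pc"].mean()
    return (means >= scheme.cuts[1]).astype(int)


@dataclass
class PropensityResult:
    scores: pd.Series        # P(treated | x), indexed by country id
    params: pd.Series
    treatment: pd.Series


def propensity_model(records: pd.DataFrame, treatment: pd.Series,
                     covariates) -> PropensityResult:
    """Logistic regression of treatment on baseline-year covariates.

    ``records`` holds one row per country (the baseline year). Perfect
    separation is reported as an error naming the offending covariate."""
    covariates = list(covariates)
    df = records.set_index("country_id") if "country_id" in records.columns else records
    y = treatment.loc[df.index].to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("both treatment groups must be non-empty")
    X = sm.add_constant(df[covariates].astype(float), has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params = pd.Series(res.params, index=X.columns)
        fitted = pd.Series(np.asarray(res.predict(X)), index=df.index)
    except Exception as exc:  # statsmodels raises on hard separation
        raise SeparationError(f"propensity model failed: {exc}") from exc
    slopes = params.drop("const")
    if np.abs(slopes).max() > 15:
        worst = slopes.abs().idxmax()
        raise SeparationError(
            f"perfect separation on covariate {worst!r}", covariate=worst)
    return PropensityResult(scores=fitted, params=params,
                            treatment=pd.Series(y, index=df.index))


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchedSet:
    pairs: dict[str, str]          # treated id -> control id
    scores: pd.Series
    caliper: float
    n_unmatched: int

    @property
    def treated_ids(self):
        return list(self.pairs)

    @property
    def control_ids(self):
        return list(self.pairs.values())


def _logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def match(propensity: PropensityResult, caliper_sd: float = 0.2,
          caliper: float | None = None) -> MatchedSet:
    """Greedy 1:1 nearest-neighbour matching on the logit score.

    Treated countries are processed in descending score order (hardest to
    match first), each taking its nearest un-used control within the
    caliper; ties break on country id order. Default caliper: 0.2 SD of
    the logit scores."""
    scores = propensity.scores.sort_index()
    lscore = pd.Series(_logit(scores.to_numpy()), index=scores.index)
    if caliper is None:
        caliper = caliper_sd * float(lscore.std(ddof=1))
    treated = [c for c in scores.index if propensity.treatment.loc[c] == 1]
    controls = {c for c in scores.index if propensity.treatment.loc[c] == 0}
    order = sorted(treated, key=lambda c: (-lscore.loc[c], c))
    pairs: dict[str, str] = {}
    unmatched = 0
    for t in order:
        if not controls:
            unmatched += 1
            continue
        cands = sorted(controls, key=lambda c: (abs(lscore.loc[c] - lscore.loc[t]), c))
        best = cands[0]
        if abs(lscore.loc[best] - lscore.loc[t]) <= caliper:
            pairs[t] = best
            controls.discard(best)
        else:
            unmatched += 1
    if not pairs:
        raise EmptyMatchError("no control within the caliper of any treated country")
    if unmatched:
        log.info("%d treated countries left unmatched", unmatched)
    return MatchedSet(pairs=pairs, scores=scores, caliper=float(caliper),
                      n_unmatched=unmatched)


def standardized_mean_difference(x_treated, x_control) -> float:
    """SMD = (mean_t - mean_c) / sqrt((var_t + var_c)/2); shared by the
    pre- and post-match balance reports."""
    x_t = np.asarray(x_treated, dtype=float)
    x_c = np.asarray(x_control, dtype=float)
    pooled = np.sqrt((x_t.var(ddof=1) + x_c.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / pooled)


def balance_table(records: pd.DataFrame, covariates, propensity: PropensityResult,
                  matched: MatchedSet | None = None) -> pd.DataFrame:
    """Covariate SMDs before and (if a matched set is given) after matching."""
    df = records.set_index("country_id") if "country_id" in records.columns else records
    treated = propensity.treatment[propensity.treatment == 1].index
    control = propensity.treatment[propensity.treatment == 0].index
    rows = []
    for cov in covariates:
        pre = standardized_mean_difference(df.loc[treated, cov], df.loc[control, cov])
        row = {"covariate": cov, "smd_pre": pre}
        if matched is not None:
            row["smd_post"] = standardized_mean_difference(
                df.loc[matched.treated_ids, cov], df.loc[matched.control_ids, cov])
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Difference-in-differences
# ---------------------------------------------------------------------------


@dataclass
class DiDResult:
    effect: float            # double difference on log rates
    se: float
    ci_low: float
    ci_high: float
    n_pairs: int
    ratio: float             # exp(effect), comparable to a rate ratio

    def to_dict(self) -> dict:
        return {"effect": self.effect, "se": self.se, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "n_pairs": self.n_pairs,
                "ratio": self.ratio}


def did_estimate(panel: Panel, matched: MatchedSet, pre_year: int = 2001,
                 post_year: int = 2021, outcome: str = "all_age",
                 level: float = 0.95) -> DiDResult:
    """Matched-pair DiD on log mortality rates.

    Per pair: (log y_treated,post - log y_treated,pre) - (same for the
    matched control); the estimate is the pair mean, the SE comes from the
    pair-level distribution. Pairs with a zero rate in any cell are
    dropped (log-undefined) with a logged count."""
    rates = panel.data.pivot_table(index="country_id", columns="year",
                                   values=f"{outcome}_rate")
    dds = []
    dropped = 0
    for t, c in matched.pairs.items():
        try:
            cells = [rates.loc[t, post_year], rates.loc[t, pre_year],
                     rates.loc[c, post_year], rates.loc[c, pre_year]]
        except KeyError:
            dropped += 1
            continue
        if any(pd.isna(v) or v <= 0 for v in cells):
            dropped += 1
            continue
        dds.append((np.log(cells[0]) - np.log(cells[1]))
                   - (np.log(cells[2]) - np.log(cells[3])))
    if dropped:
        log.info("DiD dropped %d pairs with missing or zero rates", dropped)
    if not dds:
        raise EmptyMatchError("no pair has both years with positive rates")
    dds = np.asarray(dds)
    eff = float(dds.mean())
    se = float(dds.std(ddof=1) / np.sqrt(len(dds))) if len(dds) > 1 else 0.0
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2)
    return DiDResult(effect=eff, se=se, ci_low=eff - z * se, ci_high=eff + z * se,
                     n_pairs=len(dds), ratio=float(np.exp(eff)))


def matched_did(panel: Panel, outcome: str = "all_age", pre_year: int = 2001,
                post_year: int = 2021, scheme: ExposureScheme | None = None,
                covariates=None) -> tuple[DiDResult, MatchedSet, PropensityResult]:
    """End-to-end PSM + DiD: treatment from funding coverage, propensity on
    baseline-year covariates, greedy matching, matched-pair DiD."""
    scheme = scheme or ExposureScheme()
    covariates = tuple(covariates or panel.covariates)
    treatment = coverage_treatment(panel, scheme)
    baseline = panel.data[panel.data["year"] == pre_year]
    prop = propensity_model(baseline, treatment, covariates)
    matched = match(prop)
    did = did_estimate(panel, matched, pre_year, post_year, outcome)
    return did, matched, prop


# ---------------------------------------------------------------------------
# Negative control
# ---------------------------------------------------------------------------


@dataclass
class NegativeControlReport:
    passed: bool
    table: pd.DataFrame      # injuries RRs (and primary RRs when provided)
    fit: FitResult


def negative_control_check(panel: Panel, spec: ModelSpec | None = None,
                           primary_fit: FitResult | None = None,
                           outcome: str = "injuries") -> NegativeControlReport:
    """Refit the primary model on the negative-control outcome.

    PASS means every exposure-band 95% CI covers 1 — i.e. no spurious
    funding 'effect' on an outcome aid should not move. A failing check is
    a report, not an exception."""
    spec = replace(spec or ModelSpec(), outcome=outcome)
    nc_fit = fit(panel, spec)
    table = rr_table(nc_fit)
    table = table[table["term"].isin(nc_fit.exposure_terms)].reset_index(drop=True)
    table = table.rename(columns={c: f"control_{c}" for c in
                                  ("rr", "ci_low", "ci_high", "p", "label")})
    passed = bool(((table["control_ci_low"] <= 1.0) &
                   (table["control_ci_high"] >= 1.0)).all())
    if primary_fit is not None:
        prim = rr_table(primary_fit)
        prim = prim[prim["term"].isin(primary_fit.exposure_terms)]
        table = table.merge(
            prim[["term", "rr", "ci_low", "ci_high", "label"]].rename(
                columns={c: f"primary_{c}" for c in ("rr", "ci_low", "ci_high", "label")}),
            on="term", how="left")
    return NegativeControlReport(passed=passed, table=table, fit=nc_fit)
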