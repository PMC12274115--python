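"""Fixed-effects Poisson / negative-binomial estimation with cluster-robust
variance.

The estimator maximises the (quasi-)Poisson log-likelihood of a log-link
rate model with country intercepts,

    E[y_it] = exp(alpha_i + x_it' beta) * offset_it,

either by absorbing the country intercepts (profiling them out of the
likelihood, the default) or by explicit country dummy variables; the two
parameterisations are mathematically identical and are cross-checked in the
test-suite. Outcomes may be non-integer pseudo-counts (age-standardised
rate x denominator / 1000): the score equations are well-defined for
real-valued y and inference rests on the sandwich variance, i.e. a
quasi-likelihood contract.

Robust variance defaults to clustering by country: panel outcomes are
serially correlated within country, so observation-level
heteroskedasticity-robust standard errors would be anti-conservative. The
sandwich is A^-1 B A^-1 with B built from within-cluster summed score
contributions and a G/(G-1) small-sample factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.special import gammaln, xlogy

from .exceptions import EstimationError, RankError, SchemaError, VarianceError
from .paneldata import (
    DEFAULT_COVARIATES,
    DEFAULT_SHOCK_PERIODS,
    ExposureScheme,
    Panel,
    categorize_exposure,
    shock_dummies,
)

log = logging.getLogger("aidimpact")

MAX_ITER = 100
LL_RTOL = 1e-8


# ---------------------------------------------------------------------------
# Model specification
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """What to regress on what.

    ``offset_mode='offset'`` models death counts with log(denominator/1000)
    as offset; ``'rate'`` models the standardised rate directly with no
    offset — both are supported because either could sit behind a published
    rate-ratio table, and the exposure coefficients are identical up to the
    weighting of cells.
    """

    outcome: str = "all_age"
    exposure: str = "categorical"          # "categorical" | "continuous"
    scheme: ExposureScheme = field(default_factory=ExposureScheme)
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    time_controls: str = "shocks"          # "shocks" | "years" | "none"
    shock_periods: tuple[tuple[int, int], ...] = DEFAULT_SHOCK_PERIODS
    fixed_effects: str = "country"         # "country" | "none"
    family: str = "poisson"                # "poisson" | "nb"
    weights: str | None = None             # None | "population"
    offset_mode: str = "offset"


EXPOSURE_PREFIX = "exposure_"


# ---------------------------------------------------------------------------
# Design construction (shared with attribution and forecast stages)
# ---------------------------------------------------------------------------


@dataclass
class Design:
    frame: pd.DataFrame          # the rows actually used
    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    offset: np.ndarray           # log offset
    weights: np.ndarray
    group_codes: np.ndarray
    group_ids: np.ndarray
    exposure_columns: list[str]


def build_design(panel: Panel | pd.DataFrame, spec: ModelSpec,
                 drop_empty_exposure: bool = True) -> Design:
    """Assemble y, X, offset, weights and country grouping for a ModelSpec.

    Rows with any missing modelled variable are dropped (logged). Exposure
    bands absent from the data contribute no column.
    """
    df = panel.data if isinstance(panel, Panel) else panel
    if isinstance(panel, Panel):
        if spec.outcome not in panel.outcomes:
            raise SchemaError(f"outcome {spec.outcome!r} not registered in panel")
        denom_col = panel.outcomes[spec.outcome]
    else:
        denom_col = "live_births" if spec.outcome in ("under5", "infancy", "preschool") \
            else "population"
    dcol, rcol = f"{spec.outcome}_deaths", f"{spec.outcome}_rate"
    needed = ["country_id", "year", "usaid_pc", *spec.covariates]
    if spec.offset_mode == "rate":
        needed.append(rcol)
    else:
        needed += [dcol, denom_col]
    if spec.weights == "population":
        needed.append("population")
    missing = [c for c in dict.fromkeys(needed) if c not in df.columns]
    if missing:
        raise SchemaError(f"panel lacks columns required by the model: {missing}")

    use = df[list(dict.fromkeys(needed))].copy()
    keep = use.notna().all(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("dropping %d rows with missing modelled variables", n_drop)
    df = df.loc[keep].reset_index(drop=True)

    cols: dict[str, np.ndarray] = {}
    if spec.exposure == "categorical":
        cat = categorize_exposure(df["usaid_pc"].to_numpy(), spec.scheme)
        exposure_columns = []
        for band in ("low", "intermediate", "high"):
            ind = (cat == band).astype(float)
            name = EXPOSURE_PREFIX + band
            if ind.any() or not drop_empty_exposure:
                cols[name] = ind
                exposure_columns.append(name)
            else:
                log.info("exposure band %r absent from data; no column emitted", band)
    elif spec.exposure == "continuous":
        cols["usaid_pc"] = df["usaid_pc"].to_numpy(dtype=float)
        exposure_columns = ["usaid_pc"]
    else:
        raise SchemaError(f"unknown exposure coding {spec.exposure!r}")

    for cov in spec.covariates:
        cols[cov] = df[cov].to_numpy(dtype=float)

    if spec.time_controls != "none":
        mode = "years" if spec.time_controls == "years" else "shocks"
        td = shock_dummies(df["year"].to_numpy(), spec.shock_periods, mode=mode)
        for c in td.columns:
            v = td[c].to_numpy()
            if v.any():  # periods outside the panel window contribute nothing
                cols[c] = v
            else:
                log.info("time control %r is all-zero in this panel; dropped", c)

    X = np.column_stack(list(cols.values())) if cols else np.empty((len(df), 0))

    if spec.offset_mode == "rate":
        y = df[rcol].to_numpy(dtype=float)
        offset = np.zeros(len(df))
    else:
        y = df[dcol].to_numpy(dtype=float)
        offset = np.log(df[denom_col].to_numpy(dtype=float) / 1000.0)

    if spec.weights == "population":
        w = df["population"].to_numpy(dtype=float)
        w = w / w.mean()
    elif spec.weights is None:
        w = np.ones(len(df))
    else:
        raise SchemaError(f"unknown weights option {spec.weights!r}")

    if spec.fixed_effects == "country":
        codes, ids = pd.factorize(df["country_id"], sort=True)
    elif spec.fixed_effects == "none":
        codes, ids = np.zeros(len(df), dtype=int), np.array(["_intercept"])
    else:
        raise SchemaError(f"unknown fixed_effects option {spec.fixed_effects!r}")

    return Design(frame=df, y=y, X=X, columns=list(cols), offset=offset,
                  weights=w, group_codes=codes, group_ids=np.asarray(ids),
                  exposure_columns=exposure_columns)


# ---------------------------------------------------------------------------
# Fit result
# ---------------------------------------------------------------------------


@dataclass
class FitInternals:
    X: np.ndarray
    columns: list[str]
    y: np.ndarray
    mu: np.ndarray
    offset: np.ndarray
    weights: np.ndarray
    group_codes: np.ndarray
    group_ids: np.ndarray
    hessian: np.ndarray          # profile information for beta
    frame: pd.DataFrame


@dataclass
class FitResult:
    """Log-rate-ratio coefficients with cluster-robust covariance."""

    params: pd.Series
    vcov: pd.DataFrame
    vcov_model: pd.DataFrame
    alpha: pd.Series
    n_obs: int
    n_clusters: int
    loglik: float
    converged: bool
    n_iter: int
    spec: ModelSpec
    exposure_terms: list[str]
    dropped_countries: list[str]
    dispersion: float | None = None
    internals: FitInternals | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov.to_numpy())), index=self.params.index)

    def rate_ratios(self) -> pd.Series:
        return np.exp(self.params)


# ---------------------------------------------------------------------------
# Family helpers
# ---------------------------------------------------------------------------


def _loglik(y, mu, w, family, a):
    if family == "poisson":
        return float(np.sum(w * (xlogy(y, mu) - mu - gammaln(y + 1.0))))
    inv_a = 1.0 / a
    return float(np.sum(w * (gammaln(y + inv_a) - gammaln(inv_a) - gammaln(y + 1.0)
                             + xlogy(y, a * mu) - (y + inv_a) * np.log1p(a * mu))))


def _score_scale(y, mu, a):
    """(y - mu)/(1 + a*mu): the GLM working residual numerator for NB2/Poisson."""
    return (y - mu) / (1.0 + a * mu)


def _working_weight(mu, a):
    return mu / (1.0 + a * mu)


def _update_alpha(alpha, beta, design: Design, family, a):
    """Profile the group intercepts at fixed beta.

    Closed form for Poisson; a couple of scalar Newton steps per group for
    the negative binomial (whose alpha score is not separable)."""
    eta_x = design.X @ beta + design.offset
    codes, w, y = design.group_codes, design.weights, design.y
    n_g = len(design.group_ids)
    if family == "poisson":
        num = np.bincount(codes, weights=w * y, minlength=n_g)
        den = np.bincount(codes, weights=w * np.exp(eta_x), minlength=n_g)
        with np.errstate(divide="ignore"):
            return np.log(num / den)
    for _ in range(3):
        mu = np.exp(eta_x + alpha[codes])
        sc = np.bincount(codes, weights=w * _score_scale(y, mu, a), minlength=n_g)
        info = np.bincount(codes, weights=w * _working_weight(mu, a), minlength=n_g)
        alpha = alpha + sc / np.maximum(info, 1e-300)
    return alpha


def _check_rank(design: Design) -> None:
    """Detect columns aliased after the within transformation."""
    X = design.X
    if X.shape[1] == 0:
        return
    codes = design.group_codes
    n_g = len(design.group_ids)
    counts = np.bincount(codes, minlength=n_g).astype(float)
    means = np.zeros((n_g, X.shape[1]))
    for j in range(X.shape[1]):
        means[:, j] = np.bincount(codes, weights=X[:, j], minlength=n_g) / counts
    Xc = X - means[codes]
    _, R, piv = sla.qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(Xc.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > max(tol, 1e-10)))
    if rank < X.shape[1]:
        aliased = [design.columns[j] for j in piv[rank:]]
        raise RankError(f"perfectly collinear design; aliased columns: {aliased}",
                        aliased=aliased)


# ---------------------------------------------------------------------------
# Core fitter
# ---------------------------------------------------------------------------


def fit(panel: Panel | pd.DataFrame, spec: ModelSpec | None = None,
        method: str = "absorb", dispersion: float | None = None,
        keep_internals: bool = True) -> FitResult:
    """Fit the fixed-effects model of ``spec`` by maximum (quasi-)likelihood.

    ``method='absorb'`` profiles the country intercepts out of the
    likelihood; ``method='dummies'`` carries them as explicit columns. Both
    give identical coefficients. ``dispersion`` fixes the NB2 dispersion
    parameter (used internally by :func:`negative_binomial_fit`).
    """
    spec = spec or ModelSpec()
    design = build_design(panel, spec)

    # countries with all-zero outcome carry no information about beta
    n_g = len(design.group_ids)
    ysum = np.bincount(design.group_codes, weights=design.weights * design.y,
                       minlength=n_g)
    dead_groups = np.flatnonzero(ysum <= 0)
    dropped = [str(design.group_ids[g]) for g in dead_groups]
    if dropped and spec.fixed_effects == "country":
        log.info("dropping %d countries with all-zero outcome: %s",
                 len(dropped), dropped[:5])
        keep = ~np.isin(design.group_codes, dead_groups)
        frame = design.frame.loc[keep].reset_index(drop=True)
        codes, ids = pd.factorize(frame["country_id"], sort=True)
        design = Design(frame=frame, y=design.y[keep], X=design.X[keep],
                        columns=design.columns, offset=design.offset[keep],
                        weights=design.weights[keep], group_codes=codes,
                        group_ids=np.asarray(ids),
                        exposure_columns=design.exposure_columns)
    if len(design.group_ids) < 2 and spec.fixed_effects == "country":
        raise EstimationError("fewer than 2 countries with events")
    _check_rank(design)

    family = spec.family if dispersion is None else "nb"
    a = float(dispersion) if dispersion is not None else 0.0
    if spec.family == "nb" and dispersion is None:
        return negative_binomial_fit(panel, spec, method=method,
                                     keep_internals=keep_internals)

    beta, alpha, mu, ll, n_iter, converged, trace = _maximize(
        design, family, a, method)
    if not converged:
        raise EstimationError(
            f"no convergence after {MAX_ITER} iterations", trace=trace)

    W = design.weights * _working_weight(mu, a)
    Xc = _within_center(design.X, design.group_codes, len(design.group_ids), W)
    H = Xc.T @ (Xc * W[:, None])

    params = pd.Series(beta, index=design.columns)
    vcov_model = pd.DataFrame(_safe_inv(H), index=design.columns, columns=design.columns)
    internals = FitInternals(X=design.X, columns=design.columns, y=design.y,
                             mu=mu, offset=design.offset, weights=design.weights,
                             group_codes=design.group_codes, group_ids=design.group_ids,
                             hessian=H, frame=design.frame)
    result = FitResult(
        params=params,
        vcov=vcov_model,  # placeholder, replaced below
        vcov_model=vcov_model,
        alpha=pd.Series(alpha, index=design.group_ids),
        n_obs=len(design.y),
        n_clusters=len(design.group_ids),
        loglik=ll,
        converged=converged,
        n_iter=n_iter,
        spec=spec,
        exposure_terms=list(design.exposure_columns),
        dropped_countries=dropped,
        dispersion=a if family == "nb" else None,
        internals=internals,
    )
    result.vcov = cluster_vcov(result)
    if not keep_internals:
        result.internals = replace(internals, X=np.empty((0, 0)),
                                   frame=internals.frame.iloc[:0])
    return result


def _within_center(X, codes, n_g, W):
    """Subtract W-weighted group means from each column of X."""
    if X.shape[1] == 0:
        return X
    wsum = np.bincount(codes, weights=W, minlength=n_g)
    means = np.zeros((n_g, X.shape[1]))
    for j in range(X.shape[1]):
        means[:, j] = np.bincount(codes, weights=W * X[:, j], minlength=n_g)
    means /= np.maximum(wsum, 1e-300)[:, None]
    return X - means[codes]


def _safe_inv(H):
    try:
        return sla.inv(H)
    except sla.LinAlgError:  # pragma: no cover - rank guard runs first
        return np.linalg.pinv(H)


def _maximize(design: Design, family: str, a: float, method: str):
    if method == "dummies":
        return _maximize_dummies(design, family, a)
    if method != "absorb":
        raise ValueError(f"unknown method {method!r}")
    y, X, w = design.y, design.X, design.weights
    codes, n_g = design.group_codes, len(design.group_ids)
    beta = np.zeros(X.shape[1])
    alpha = _update_alpha(np.zeros(n_g), beta, design, "poisson", 0.0)
    mu = np.exp(X @ beta + design.offset + alpha[codes])
    ll = _loglik(y, mu, w, family, a)
    trace = [ll]
    for it in range(1, MAX_ITER + 1):
        alpha = _update_alpha(alpha, beta, design, family, a)
        mu = np.exp(X @ beta + design.offset + alpha[codes])
        W = w * _working_weight(mu, a)
        Xc = _within_center(X, codes, n_g, W)
        score = Xc.T @ (w * _score_scale(y, mu, a))
        H = Xc.T @ (Xc * W[:, None])
        if X.shape[1]:
            try:
                step = sla.solve(H, score, assume_a="pos")
            except sla.LinAlgError:
                step = np.linalg.lstsq(H, score, rcond=None)[0]
        else:
            step = np.zeros(0)
        # step-halving line search on the profile likelihood
        scale = 1.0
        for _ in range(30):
            beta_new = beta + scale * step
            alpha_new = _update_alpha(alpha, beta_new, design, family, a)
            mu_new = np.exp(X @ beta_new + design.offset + alpha_new[codes])
            ll_new = _loglik(y, mu_new, w, family, a)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta, alpha, mu = beta_new, alpha_new, mu_new
        trace.append(ll_new)
        if abs(ll_new - ll) <= LL_RTOL * (abs(ll) + 1.0):
            return beta, alpha, mu, ll_new, it, True, trace
        ll = ll_new
    return beta, alpha, mu, ll, MAX_ITER, False, trace


def _maximize_dummies(design: Design, family: str, a: float):
    """Newton iterations on the explicit [X, country-dummy] design."""
    y, X, w = design.y, design.X, design.weights
    codes, n_g = design.group_codes, len(design.group_ids)
    D = np.zeros((len(y), n_g))
    D[np.arange(len(y)), codes] = 1.0
    Z = np.hstack([X, D])
    p = X.shape[1]
    theta = np.concatenate([np.zeros(p),
                            _update_alpha(np.zeros(n_g), np.zeros(p), design,
                                          "poisson", 0.0)])
    mu = np.exp(Z @ theta + design.offset)
    ll = _loglik(y, mu, w, family, a)
    trace = [ll]
    for it in range(1, MAX_ITER + 1):
        W = w * _working_weight(mu, a)
        score = Z.T @ (w * _score_scale(y, mu, a))
        H = Z.T @ (Z * W[:, None])
        try:
            step = sla.solve(H, score, assume_a="pos")
        except sla.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        scale = 1.0
        for _ in range(30):
            theta_new = theta + scale * step
            mu_new = np.exp(Z @ theta_new + design.offset)
            ll_new = _loglik(y, mu_new, w, family, a)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        theta, mu = theta_new, mu_new
        trace.append(ll_new)
        if abs(ll_new - ll) <= LL_RTOL * (abs(ll) + 1.0):
            return theta[:p], theta[p:], mu, ll_new, it, True, trace
        ll = ll_new
    return theta[:p], theta[p:], mu, ll, MAX_ITER, False, trace


# ---------------------------------------------------------------------------
# Cluster-robust variance
# ---------------------------------------------------------------------------


def cluster_vcov(fit_result: FitResult, cluster: str = "country") -> pd.DataFrame:
    """Sandwich variance A^-1 B A^-1 for the slope coefficients.

    ``cluster='country'`` sums score contributions within country before
    the outer product (the default; valid under arbitrary within-country
    correlation), with small-sample factor G/(G-1). ``cluster='obs'`` is
    the observation-level HC sandwich with factor n/(n-1), provided for
    comparison.
    """
    inter = fit_result.internals
    if inter is None:
        raise VarianceError("fit was stored without internals")
    a = fit_result.dispersion or 0.0
    X, y, mu, w = inter.X, inter.y, inter.mu, inter.weights
    codes, n_g = inter.group_codes, len(inter.group_ids)
    W = w * _working_weight(mu, a)
    s = w * _score_scale(y, mu, a)
    Xc = _within_center(X, codes, n_g, W)
    cols = inter.columns
    Ainv = _safe_inv(inter.hessian)

    if cluster == "country":
        # cluster on the country column of the fitted frame (identical to
        # the FE groups when country intercepts are in the model, but also
        # correct for pooled fits); the slope block of the full sandwich
        # equals the sandwich on the within-residualised regressors.
        ccodes, cids = pd.factorize(inter.frame["country_id"], sort=True)
        G = len(cids)
        if G < 2:
            raise VarianceError("clustered variance needs at least 2 clusters")
        U = np.zeros((G, X.shape[1]))
        for j in range(X.shape[1]):
            U[:, j] = np.bincount(ccodes, weights=s * Xc[:, j], minlength=G)
        B = U.T @ U
        factor = G / (G - 1.0)
    elif cluster == "obs":
        n = len(y)
        if n < 2:
            raise VarianceError("HC variance needs at least 2 observations")
        Us = Xc * s[:, None]
        B = Us.T @ Us
        factor = n / (n - 1.0)
    else:
        raise ValueError(f"unknown cluster option {cluster!r}")
    V = factor * (Ainv @ B @ Ainv)
    V = 0.5 * (V + V.T)
    return pd.DataFrame(V, index=cols, columns=cols)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def rr_table(fit_result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Rate ratios exp(beta) with Wald confidence intervals and p values.

    The ``label`` column renders each row in the conventional
    "RR (lower-upper)" style at two decimal places.
    """
    z = stats.norm.ppf(0.5 + level / 2.0)
    beta = fit_result.params
    se = fit_result.se
    rr = np.exp(beta)
    lo = np.exp(beta - z * se)
    hi = np.exp(beta + z * se)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.norm.sf(np.abs(zstat))
    out = pd.DataFrame({"term": beta.index, "rr": rr.to_numpy(),
                        "ci_low": lo.to_numpy(), "ci_high": hi.to_numpy(),
                        "p": p})
    out["label"] = [f"{r:.2f} ({l:.2f}–{h:.2f})"
                    for r, l, h in zip(out["rr"], out["ci_low"], out["ci_high"])]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass
class StratifiedResult:
    fits: dict[str, FitResult]
    skipped: dict[str, str]


def fit_stratified(panel: Panel, spec: ModelSpec, strata: str | dict) -> StratifiedResult:
    """Independent fits per country stratum.

    ``strata`` may be ``'income'`` (the income-group column), the name of a
    covariate (countries split at the median of their period-mean value,
    e.g. ``'gdp_pc'``, ``'gini'``), or an explicit mapping name -> list of
    country ids. Strata failing the fit preconditions are skipped, not
    raised.
    """
    df = panel.data
    if isinstance(strata, dict):
        if not strata:
            raise ValueError("empty strata map")
        assignment = dict(strata)
    elif strata == "income":
        assignment = {
            g: sub["country_id"].unique().tolist()
            for g, sub in df.groupby("income_group")
        }
    else:
        if strata not in df.columns:
            raise SchemaError(f"stratum variable {strata!r} not in panel")
        means = df.groupby("country_id")[strata].mean()
        med = means.median()
        assignment = {
            f"low_{strata}": means.index[means <= med].tolist(),
            f"high_{strata}": means.index[means > med].tolist(),
        }
    fits: dict[str, FitResult] = {}
    skipped: dict[str, str] = {}
    for name, countries in assignment.items():
        sub = panel.subset(df["country_id"].isin(countries).to_numpy())
        if sub.data["country_id"].nunique() < 2:
            skipped[name] = "fewer than 2 countries"
            continue
        try:
            fits[name] = fit(sub, spec)
        except (EstimationError, RankError, VarianceError) as exc:
            skipped[name] = str(exc)
    return StratifiedResult(fits=fits, skipped=skipped)


def negative_binomial_fit(panel: Panel | pd.DataFrame, spec: ModelSpec | None = None,
                          method: str = "absorb", max_outer: int = 30,
                          keep_internals: bool = True) -> FitResult:
    """NB2 fixed-effects fit with the dispersion estimated from the data.

    Alternates the coefficient fit at fixed dispersion with a Pearson
    moment update of the dispersion (solving sum (y-mu)^2/(mu(1+a mu)) =
    residual d.o.f.), the standard quasi-NB2 recipe. A dispersion pinned at
    the lower bound means the data show no overdispersion beyond Poisson.
    """
    from scipy.optimize import brentq

    spec = spec or ModelSpec()
    spec = replace(spec, family="poisson")  # inner fits run at fixed dispersion
    a = 1e-8
    for _ in range(max_outer):
        result = fit(panel, spec, method=method, dispersion=a,
                     keep_internals=True)
        inter = result.internals
        y, mu, w = inter.y, inter.mu, inter.weights
        dof = max(len(y) - inter.X.shape[1] - len(inter.group_ids), 1)

        def pearson_gap(disp):
            return float(np.sum(w * (y - mu) ** 2 / (mu * (1.0 + disp * mu))) - dof)

        if pearson_gap(0.0) <= 0.0:
            a_new = 1e-8  # no overdispersion beyond Poisson
        else:
            hi = 1e-6
            while pearson_gap(hi) > 0.0 and hi < 1e4:
                hi *= 10.0
            a_new = float(brentq(pearson_gap, 0.0, hi)) if hi < 1e4 else 1e4
            a_new = max(a_new, 1e-8)
        if abs(a_new - a) <= 1e-6 * (a + 1e-6):
            a = a_new
            break
        a = a_new
    result = fit(panel, spec, method=method, dispersion=a,
                 keep_internals=keep_internals)
    result.spec = replace(spec, family="nb")
    return result
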