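"""Country-year panel model, I/O, and variable construction.

The analysis operates on a longitudinal ecological panel: one row per
country-year carrying outcome-specific death counts and age-standardised
rates, denominators (population, or live births for under-five outcomes),
total development-aid disbursement and its per-capita value, and a set of
socioeconomic / health-system covariates.

Variable-construction rules implemented here:

* per-capita exposure = total disbursement / population;
* exposure categorised into four funding bands (baseline / low /
  intermediate / high) at quartile cut points estimated from the
  low-income-country distribution (defaults $1.97 / $3.97 / $7.10);
* covariates dichotomised at their pooled median over the study window;
* shock-period indicator columns for years of global economic or health
  crisis, or alternatively a full set of year dummies.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateDistributionError,
    IntegrityError,
    SchemaError,
)

log = logging.getLogger("aidimpact")

# ---------------------------------------------------------------------------
# Column conventions and defaults
# ---------------------------------------------------------------------------

ID_COLUMNS = ("country_id", "year", "income_group")
DENOMINATOR_COLUMNS = ("population", "live_births")
FUNDING_COLUMNS = ("usaid_total", "usaid_pc")

INCOME_GROUPS = ("low", "lower-middle", "upper-middle", "high")

#: covariate name -> measurement scale, used to pick the transform for
#: trend extrapolation (logit for bounded shares, log for positive rates).
COVARIATE_SCALES: dict[str, str] = {
    "gini": "proportion",            # 0-1
    "primary_education": "percent",  # 0-100
    "education_expenditure": "percent",
    "piped_water": "percent",
    "adequate_sanitation": "percent",
    "literacy": "percent",
    "nurses": "positive",            # per 1000 population
    "hospital_beds": "positive",
    "health_expenditure": "positive",   # % GDP, effectively unbounded
    "military_expenditure": "positive",
    "gdp_pc": "positive",
    "fertility": "positive",
}

#: control variables of the default adjusted model (the displayed set).
DEFAULT_COVARIATES = (
    "gini",
    "primary_education",
    "education_expenditure",
    "piped_water",
    "adequate_sanitation",
    "nurses",
    "hospital_beds",
    "health_expenditure",
    "military_expenditure",
)

#: default shock periods: global economic / health crises.
DEFAULT_SHOCK_PERIODS = ((2008, 2009), (2013, 2014), (2015, 2016), (2020, 2021))
#: alternative period set (single crisis years).
ALT_SHOCK_PERIODS = ((2007, 2008), (2015, 2015), (2020, 2020), (2021, 2021))

EXPOSURE_LABELS = ("baseline", "low", "intermediate", "high")

YEAR_MIN, YEAR_MAX = 2001, 2030


# ---------------------------------------------------------------------------
# Exposure scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExposureScheme:
    """Three increasing cut points defining the four funding bands.

    Bands are half-open: [0, c1) baseline, [c1, c2) low, [c2, c3)
    intermediate, [c3, inf) high, so a value exactly at a cut belongs to
    the upper band (1.96 -> baseline, 1.97 -> low under the defaults).
    """

    cuts: tuple[float, float, float] = (1.97, 3.97, 7.10)
    percentile_definition: str = "linear-interpolation"

    def __post_init__(self):
        c1, c2, c3 = self.cuts
        if not (0 < c1 < c2 < c3):
            raise ValueError(f"cuts must be strictly increasing and positive, got {self.cuts}")

    @property
    def labels(self) -> tuple[str, ...]:
        return EXPOSURE_LABELS

    def categorize(self, usaid_pc):
        """Map per-capita funding to its band label (vectorised)."""
        return categorize_exposure(usaid_pc, self)

    def to_dict(self) -> dict:
        return {
            "cuts": list(self.cuts),
            "labels": list(EXPOSURE_LABELS),
            "percentile_definition": self.percentile_definition,
        }


def categorize_exposure(usaid_pc, scheme: ExposureScheme | None = None):
    """Assign per-capita funding values to the four exposure bands.

    Accepts a scalar (returns a label string) or an array-like (returns an
    object array of labels). Negative input is rejected.
    """
    scheme = scheme or ExposureScheme()
    x = np.asarray(usaid_pc, dtype=float)
    if np.any(x < 0):
        raise ValueError("usaid_pc must be non-negative")
    idx = np.searchsorted(np.asarray(scheme.cuts), x, side="right")
    if np.ndim(usaid_pc) == 0:
        return EXPOSURE_LABELS[int(idx)]
    return np.asarray(EXPOSURE_LABELS, dtype=object)[idx]


def compute_usaid_pc(usaid_total: float, population: float) -> float:
    """Per-capita funding: total disbursement divided by population."""
    total = np.asarray(usaid_total, dtype=float)
    pop = np.asarray(population, dtype=float)
    if np.any(pop <= 0):
        raise ValueError("population must be positive")
    if np.any(total < 0):
        raise ValueError("usaid_total must be non-negative")
    out = total / pop
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------


@dataclass
class PanelSchema:
    """Column mapping for a wide delimited panel file.

    ``outcomes`` maps each outcome name to its denominator column; the file
    is expected to carry ``<outcome>_deaths`` and/or ``<outcome>_rate``
    columns for every registered outcome.
    """

    outcomes: dict[str, str]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    delimiter: str = ","

    @classmethod
    def infer(cls, columns, delimiter=",") -> "PanelSchema":
        """Infer outcomes and covariates from column names."""
        outcomes = {}
        for c in columns:
            if c.endswith("_deaths"):
                name = c[: -len("_deaths")]
                denom = "live_births" if name in ("under5", "infancy", "preschool") else "population"
                outcomes[name] = denom
        known = set(ID_COLUMNS) | set(DENOMINATOR_COLUMNS) | set(FUNDING_COLUMNS)
        covs = tuple(
            c
            for c in columns
            if c not in known and not c.endswith(("_deaths", "_rate"))
        )
        return cls(outcomes=outcomes, covariates=covs, delimiter=delimiter)


@dataclass
class Panel:
    """A validated country-year panel.

    ``data`` is a wide DataFrame (one row per country-year) sorted by
    (country_id, year); ``outcomes`` maps outcome name -> denominator
    column; ``metadata`` accumulates provenance (exposure cuts, covariate
    medians, dropped-row log) across pipeline stages.
    """

    data: pd.DataFrame
    outcomes: dict[str, str]
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    shock_periods: tuple[tuple[int, int], ...] = DEFAULT_SHOCK_PERIODS
    metadata: dict = field(default_factory=dict)

    # -- convenience ------------------------------------------------------
    @property
    def countries(self) -> np.ndarray:
        return self.data["country_id"].unique()

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    @property
    def n_obs(self) -> int:
        return len(self.data)

    def deaths(self, outcome: str) -> pd.Series:
        return self.data[f"{outcome}_deaths"]

    def denominator(self, outcome: str) -> pd.Series:
        return self.data[self.outcomes[outcome]]

    def rate(self, outcome: str) -> pd.Series:
        return self.data[f"{outcome}_rate"]

    def subset(self, mask) -> "Panel":
        return replace(self, data=self.data.loc[mask].reset_index(drop=True),
                       metadata=dict(self.metadata))

    def validate(self) -> "Panel":
        _validate_panel(self)
        return self


def _validate_panel(panel: Panel) -> None:
    df = panel.data
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    dup = df.duplicated(subset=["country_id", "year"])
    if dup.any():
        first = df.loc[dup, ["country_id", "year"]].iloc[0]
        raise IntegrityError(
            f"duplicate (country, year) pair: ({first['country_id']!r}, {int(first['year'])})"
        )
    if df["country_id"].nunique() < 2:
        raise IntegrityError("panel needs at least 2 countries for fixed effects")
    if df["year"].nunique() < 2:
        raise IntegrityError("panel needs at least 2 years for fixed effects")
    years = df["year"].to_numpy()
    if years.min() < YEAR_MIN or years.max() > YEAR_MAX:
        raise IntegrityError(
            f"years must lie within [{YEAR_MIN}, {YEAR_MAX}], got "
            f"[{years.min()}, {years.max()}]"
        )
    bad_rows = []
    for outcome, denom in panel.outcomes.items():
        dcol, rcol = f"{outcome}_deaths", f"{outcome}_rate"
        if dcol in df.columns and (df[dcol] < 0).any():
            bad_rows.append(f"negative deaths in {dcol}")
        if denom in df.columns and (df[denom] <= 0).any():
            bad_rows.append(f"non-positive denominator {denom} for outcome {outcome}")
        if dcol in df.columns and rcol in df.columns and denom in df.columns:
            implied = 1000.0 * df[dcol] / df[denom]
            rel = np.abs(implied - df[rcol]) / np.maximum(np.abs(df[rcol]), 1e-300)
            off = rel > 1e-9
            # zero-rate cells compare absolutely
            off &= ~((df[rcol] == 0) & (df[dcol] == 0))
            if off.any():
                i = int(np.flatnonzero(off.to_numpy())[0])
                row = df.iloc[i]
                bad_rows.append(
                    f"rate/deaths mismatch for {outcome} at "
                    f"({row['country_id']!r}, {int(row['year'])})"
                )
    if {"usaid_total", "usaid_pc", "population"} <= set(df.columns):
        implied = df["usaid_total"] / df["population"]
        rel = np.abs(implied - df["usaid_pc"]) / np.maximum(df["usaid_pc"].abs(), 1e-12)
        off = (rel > 1e-9) & ~((df["usaid_pc"] == 0) & (df["usaid_total"] == 0))
        if off.any():
            i = int(np.flatnonzero(off.to_numpy())[0])
            row = df.iloc[i]
            bad_rows.append(
                f"usaid_pc != usaid_total/population at ({row['country_id']!r}, {int(row['year'])})"
            )
    if "usaid_total" in df.columns and (df["usaid_total"] < 0).any():
        bad_rows.append("negative usaid_total")
    if bad_rows:
        raise ValueError("invalid panel values: " + "; ".join(bad_rows))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_panel(path, schema: PanelSchema | None = None) -> Panel:
    """Read a wide delimited country-year panel and validate it.

    Rows failing value invariants are reported with their (country, year)
    address; structural violations (missing columns, duplicate keys, too
    few units) raise SchemaError / IntegrityError.
    """
    delimiter = schema.delimiter if schema is not None else ","
    df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    if schema is None:
        schema = PanelSchema.infer(df.columns)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    for outcome in schema.outcomes:
        if f"{outcome}_deaths" not in df.columns and f"{outcome}_rate" not in df.columns:
            missing.append(f"{outcome}_deaths|{outcome}_rate")
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df.sort_values(["country_id", "year"]).reset_index(drop=True)
    panel = Panel(
        data=df,
        outcomes=dict(schema.outcomes),
        covariates=tuple(schema.covariates),
    )
    return panel.validate()


def write_panel(panel: Panel, path, delimiter: str = ",") -> None:
    """Re-export a panel in the wide delimited dialect (round-trip safe)."""
    panel.data.to_csv(path, sep=delimiter, index=False)


def write_metadata(panel: Panel, path) -> None:
    """Dump accumulated panel metadata (cuts, medians, drop log) as JSON."""
    with open(path, "w") as fh:
        json.dump(panel.metadata, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# Variable construction
# ---------------------------------------------------------------------------


def quartile_thresholds(panel: Panel, reference_group: str = "low") -> ExposureScheme:
    """Exposure cut points: quartiles of per-capita funding in a reference
    income group (default: low-income countries).

    Percentiles use linear interpolation between order statistics; the
    definition is recorded on the returned scheme so alternatives can be
    compared.
    """
    sub = panel.data.loc[panel.data["income_group"] == reference_group, "usaid_pc"]
    sub = sub.dropna()
    if len(sub) == 0:
        raise DegenerateDistributionError(f"no records in income group {reference_group!r}")
    if sub.nunique() < 4:
        raise DegenerateDistributionError(
            f"need >=4 distinct usaid_pc values in the {reference_group!r} subset, "
            f"got {sub.nunique()}"
        )
    c1, c2, c3 = np.percentile(sub.to_numpy(), [25, 50, 75])
    if not (c1 < c2 < c3):
        raise DegenerateDistributionError(
            f"degenerate funding distribution: quartiles {c1:.4g}/{c2:.4g}/{c3:.4g} not distinct"
        )
    return ExposureScheme(cuts=(float(c1), float(c2), float(c3)))


def dichotomize_covariates(panel: Panel, covariates=None,
                           medians: dict[str, float] | None = None) -> Panel:
    """Replace each covariate by the indicator value > pooled median.

    The median is computed once per covariate over all country-years of the
    study window (or taken from ``medians`` when freezing retrospective
    medians for a projection). Values exactly at the median map to 0.
    Already-binary covariates pass through unchanged, making the operation
    idempotent.
    """
    covariates = tuple(covariates or panel.covariates)
    df = panel.data.copy()
    out_medians: dict[str, float] = {}
    for cov in covariates:
        if cov not in df.columns:
            raise SchemaError(f"covariate {cov!r} not in panel")
        col = df[cov]
        if col.notna().sum() < 2:
            raise ValueError(f"covariate {cov!r} has fewer than 2 non-missing values")
        vals = col.dropna().unique()
        if set(np.unique(vals)).issubset({0.0, 1.0}):
            # already an indicator; keep as-is (idempotence)
            out_medians[cov] = float(medians[cov]) if medians and cov in medians else 0.5
            continue
        med = float(medians[cov]) if medians and cov in medians else float(col.median())
        ind = (col > med).astype(float)
        if ind.nunique() < 2:
            warnings.warn(f"covariate {cov!r} has no variation after dichotomization")
        df[cov] = ind
        out_medians[cov] = med
    meta = dict(panel.metadata)
    meta["covariate_medians"] = out_medians
    return replace(panel, data=df, metadata=meta)


def shock_dummies(years, shock_periods=DEFAULT_SHOCK_PERIODS, mode: str = "shocks",
                  reference_year: int | None = None) -> pd.DataFrame:
    """Indicator columns for crisis periods, or a full year-dummy set.

    ``mode='shocks'`` gives one column per configured period; ``mode='years'``
    gives an indicator per year with the reference year (default: earliest)
    dropped for identifiability.
    """
    years = np.asarray(years, dtype=int)
    if mode == "years":
        uniq = np.sort(np.unique(years))
        ref = reference_year if reference_year is not None else int(uniq[0])
        cols = {f"year_{y}": (years == y).astype(float) for y in uniq if y != ref}
        return pd.DataFrame(cols, index=pd.RangeIndex(len(years)))
    if mode != "shocks":
        raise ValueError(f"unknown time-control mode {mode!r}")
    cols = {}
    for start, end in shock_periods:
        name = f"shock_{start}" if start == end else f"shock_{start}_{end}"
        cols[name] = ((years >= start) & (years <= end)).astype(float)
    return pd.DataFrame(cols, index=pd.RangeIndex(len(years)))
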