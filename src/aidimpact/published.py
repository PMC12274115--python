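"""Published headline estimates, kept as reference data.

These are the printed summary numbers of the published aid-and-mortality
analysis this package operationalises. They are inputs for consistency
checks (cumulative sums of printed annual rows, percent changes of printed
means), not outputs of this package: the package's own estimates come from
data it is given, and at desk scale that means synthetic panels.

Monetary amounts are constant US dollars; mortality rates are per 1000
population (all-age, age-standardised) or per 1000 live births
(under-five).
"""

from __future__ import annotations

import pandas as pd

#: Projected annual excess deaths, defunding versus business-as-usual,
#: point (95% uncertainty interval), 2025-2030.
FORECAST_EXCESS_ALL_AGE = pd.DataFrame(
    {
        "year": [2025, 2026, 2027, 2028, 2029, 2030],
        "excess": [1_776_539, 2_499_525, 2_477_031, 2_454_816, 2_432_809, 2_411_030],
        "ci_low": [967_604, 1_521_410, 1_507_936, 1_494_286, 1_480_850, 1_467_499],
        "ci_high": [2_496_308, 3_490_070, 3_458_985, 3_428_201, 3_396_272, 3_366_678],
    }
)

FORECAST_EXCESS_UNDER5 = pd.DataFrame(
    {
        "year": [2025, 2026, 2027, 2028, 2029, 2030],
        "excess": [689_900, 828_970, 798_188, 768_294, 739_719, 712_098],
        "ci_low": [436_368, 575_089, 553_276, 531_228, 513_316, 494_694],
        "ci_high": [911_004, 1_078_316, 1_039_475, 1_003_073, 962_867, 926_596],
    }
)

#: Printed cumulative 2025-2030 excess deaths (point, UI).
FORECAST_CUMULATIVE_ALL_AGE = (14_051_750, 8_475_990, 19_662_191)
FORECAST_CUMULATIVE_UNDER5 = (4_537_157, 3_124_796, 5_910_791)

#: Adjusted exposure-band rate ratios (95% CI), all-age and under-five.
RATE_RATIOS = pd.DataFrame(
    {
        "outcome": ["all_age", "all_age", "all_age", "under5", "under5", "under5"],
        "category": ["low", "intermediate", "high"] * 2,
        "rr": [0.94, 0.91, 0.85, 0.86, 0.80, 0.68],
        "ci_low": [0.89, 0.85, 0.78, 0.78, 0.68, 0.566],
        "ci_high": [0.99, 0.97, 0.93, 0.96, 0.93, 0.81],
    }
)

#: Retrospective deaths averted 2001-2021 (point, 95% CI).
AVERTED_ALL_AGE = (91_839_663, 85_690_135, 98_291_626)
AVERTED_UNDER5 = (30_391_980, 26_023_132, 35_482_636)

#: Descriptive means (mean per country-year) in 2001 and 2021.
DESCRIPTIVE_MEANS = pd.DataFrame(
    {
        "variable": ["all_age_rate", "under5_rate", "usaid_pc",
                     "gdp_pc", "adequate_sanitation"],
        "mean_2001": [11.65, 73.71, 1.38, 5984.6, 46.37],
        "mean_2021": [10.19, 37.61, 2.71, 13432.6, 77.47],
        "printed_change_pct": [-13, -49, 97, 124, 67],
    }
).set_index("variable")

#: Panel geometry of the retrospective analysis.
N_OBSERVATIONS = 2793
N_COUNTRIES = 133
STUDY_YEARS = (2001, 2021)

#: Exposure band cut points (USD per capita per year).
EXPOSURE_CUTS = (1.97, 3.97, 7.10)


def cumulative_from_annual(annual: pd.DataFrame) -> float:
    """Cumulative excess deaths implied by the annual point rows."""
    return float(annual["excess"].sum())


def mean_annual_excess(annual: pd.DataFrame, years=range(2026, 2031)) -> float:
    """Average annual excess over the post-cut steady years."""
    sub = annual[annual["year"].isin(list(years))]
    return float(sub["excess"].mean())


def percent_change(mean_start: float, mean_end: float) -> float:
    """Percent change between two printed period means."""
    return 100.0 * (mean_end - mean_start) / mean_start
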