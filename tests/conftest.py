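"""Shared fixtures: a paper-like synthetic panel, its fits, and tiny toys."""

import numpy as np
import pandas as pd
import pytest

import aidimpact as ai
from aidimpact.paneldata import Panel


@pytest.fixture(scope="session")
def paper_like():
    """Default-geometry panel (133 countries, 2001-2021) with truth sidecar."""
    return ai.generate_panel(ai.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def dichotomized(paper_like):
    panel, _ = paper_like
    return ai.dichotomize_covariates(panel)


@pytest.fixture(scope="session")
def fit_all_age(dichotomized):
    return ai.fit(dichotomized, ai.ModelSpec(outcome="all_age"))


@pytest.fixture(scope="session")
def small_panel():
    """Compact panel for fast CLI / stage tests."""
    cfg = ai.GeneratorConfig(n_countries=40, year_end=2012, seed=7)
    return ai.generate_panel(cfg)[0]


def make_panel(df: pd.DataFrame, outcomes=None, covariates=()) -> Panel:
    """Wrap a hand-built frame as a validated Panel."""
    outcomes = outcomes or {"all_age": "population"}
    return Panel(data=df.sort_values(["country_id", "year"]).reset_index(drop=True),
                 outcomes=dict(outcomes), covariates=tuple(covariates)).validate()


def toy_2x2_panel(control_rates=(100.0, 100.0), treated_rates=(100.0, 80.0),
                  denom=1.0e6):
    """Two countries, two periods; country B exposed (high band) in period 2.

    The fixed-effects exposure coefficient has the closed form
    log[(treated_2/treated_1) / (control_2/control_1)]."""
    rows = []
    for cid, rates, pc in (("A", control_rates, (0.0, 0.0)),
                           ("B", treated_rates, (0.0, 10.0))):
        for year, rate, usaid in zip((2001, 2002), rates, pc):
            rows.append({
                "country_id": cid, "year": year, "income_group": "low",
                "population": denom, "live_births": denom / 40.0,
                "usaid_pc": usaid, "usaid_total": usaid * denom,
                "all_age_deaths": rate * denom / 1000.0,
                "all_age_rate": rate,
            })
    return make_panel(pd.DataFrame(rows))


def toy_spec(**kw):
    """ModelSpec for covariate-free toys with a period dummy."""
    defaults = dict(outcome="all_age", covariates=(), time_controls="years")
    defaults.update(kw)
    return ai.ModelSpec(**defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
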