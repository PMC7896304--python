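"""Species-richness aggregation and national covariate regressions.

Per-cell richness is the count of species whose ensemble binary map marks
the cell suitable.  Percentage change from current to future is computed
per cell (undefined where current richness is zero), averaged unweighted
over each country's defined cells, and the national mean change is
regressed on governance score, log per-capita GDP, or log per-capita CO2
emissions with a Gaussian GLM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ensemble.model import EnsembleProjection
from .world.covariates import CountryCovariates
from .world.regions import RegionMaps

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = {
    "governance": "governance",  # derived mean of the six indicators
    "gdp": "gdp_per_capita",
    "co2": "co2_per_capita",
}
LOG_COVARIATES = ("gdp", "co2")


def richness_map(projections: list[EnsembleProjection]) -> np.ndarray:
    """Per-cell count of species with suitable climate (binary sum)."""
    if not projections:
        raise ValueError("no projections given")
    shape = projections[0].binary.shape
    out = np.zeros(shape, dtype=int)
    for p in projections:
        out += p.binary.astype(int)
    return out


def percent_change_map(current: np.ndarray, future: np.ndarray) -> np.ndarray:
    """100 * (future - current) / current; nan where current == 0."""
    if current.shape != future.shape:
        raise ValueError("richness maps must share a grid")
    out = np.full(current.shape, np.nan)
    ok = current > 0
    out[ok] = 100.0 * (future[ok] - current[ok]) / current[ok]
    return out


def national_mean_change(
    change: np.ndarray, regions: RegionMaps
) -> pd.DataFrame:
    """Unweighted country mean over defined cells.

    Countries with zero defined cells are omitted (logged).  Columns:
    country, mean_pct_change, n_cells.
    """
    rows = []
    for c in range(regions.n_countries):
        vals = change[regions.country_of == c]
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            logger.info("country %d has no defined cells; omitted", c)
            continue
        rows.append(
            {"country": c, "mean_pct_change": float(vals.mean()),
             "n_cells": len(vals)}
        )
    return pd.DataFrame(rows, columns=["country", "mean_pct_change", "n_cells"])


def governance_score(cov: CountryCovariates) -> pd.Series:
    """Mean of the six governance indicators per country, in [-2.5, 2.5]."""
    return cov.governance_score()


@dataclass
class CovariateModelResults:
    """Fitted national-covariate regression (Gaussian GLM)."""

    covariate: str
    slope: float
    intercept: float
    conf_int: tuple[float, float]  # 95% CI of the slope
    p_value: float
    n_countries: int
    results: object  # underlying statsmodels results

    def summary(self) -> str:
        lo, hi = self.conf_int
        return (
            f"mean % richness change ~ {self.covariate}: "
            f"slope {self.slope:.4f} [{lo:.4f}, {hi:.4f}], "
            f"p = {self.p_value:.3g}, n = {self.n_countries}"
        )


def fit_covariate_model(
    change_table: pd.DataFrame,
    covariates: CountryCovariates,
    covariate: str,
    min_countries: int = 10,
) -> CovariateModelResults:
    """Regress national mean percentage richness change on one covariate.

    ``covariate`` is one of 'governance', 'gdp', 'co2'; monetary and
    emissions covariates are natural-log transformed.  Requires at least
    ``min_countries`` countries with both a change value and a covariate.
    """
    if covariate not in COVARIATE_COLUMNS:
        raise ValueError(f"unknown covariate {covariate!r}")
    tab = change_table.set_index("country")
    if covariate == "governance":
        x = governance_score(covariates)
    else:
        x = covariates.table[COVARIATE_COLUMNS[covariate]]
        x = np.log(x)
    joined = tab.join(x.rename("x"), how="inner").dropna(
        subset=["mean_pct_change", "x"]
    )
    if len(joined) < min_countries:
        raise ValueError(
            f"covariate model needs >= {min_countries} countries, "
            f"got {len(joined)}"
        )
    X = sm.add_constant(joined["x"].to_numpy())
    model = sm.GLM(joined["mean_pct_change"].to_numpy(), X,
                   family=sm.families.Gaussian())
    res = model.fit()
    ci = res.conf_int()[1]
    return CovariateModelResults(
        covariate=covariate,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        conf_int=(float(ci[0]), float(ci[1])),
        p_value=float(res.pvalues[1]),
        n_countries=len(joined),
        results=res,
    )
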