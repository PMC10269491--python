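"""Calibration of the clock constants from a referent population.

Each variable is z-scored against the band's sample moments, an
ordinary-least-squares line of the z-scored variable on age gives the
per-year slope k_X and intercept n_X, and the scaling factor and
constant

    k = 1 / sum_X |k_X|,        C = -k * sum_X sgn(k_X) * n_X

force the least-squares line of the resulting score on chronological
age to be the identity in the calibrating sample.  The two age bands
are calibrated separately because several biomarkers trend differently
in young adults and in late middle age.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import VARIABLES, AgeBand, BandLabel, CalibrationConstants


@dataclass(frozen=True)
class NormalizedFit:
    """OLS fit of one z-scored variable on age: X_norm = k_x * a + n_x."""

    variable: str
    k_x: float
    n_x: float


@dataclass
class ReferentPopulation:
    """A band-restricted calibration sample.

    ``records`` must contain columns ``age``, ``RTL``, ``Fe``, ``TIBC``
    and ``F`` (iron variables in ug/dL, ferritin in ug/L).  Missing
    values are permitted per variable; each moment and slope is then
    estimated on that variable's available subsample.
    """

    records: pd.DataFrame
    band: AgeBand

    def __post_init__(self) -> None:
        missing = {"age", "RTL", "Fe", "TIBC", "F"} - set(self.records.columns)
        if missing:
            raise ValueError(f"population table missing column(s): {sorted(missing)}")
        ages = self.records["age"].dropna()
        if ((ages < self.band.lower) | (ages > self.band.upper)).any():
            raise ValueError(
                f"ages outside band [{self.band.lower}, {self.band.upper}] present; "
                "band-assign before calibrating"
            )
        if ages.nunique() < 3:
            raise ValueError("need at least 3 records with non-identical ages")


def assign_band(frame: pd.DataFrame, band: AgeBand) -> tuple[ReferentPopulation, int]:
    """Restrict a table to one band; returns (population, n excluded)."""
    inside = frame["age"].between(band.lower, band.upper)
    excluded = int((~inside).sum())
    return ReferentPopulation(frame.loc[inside].reset_index(drop=True), band), excluded


def zscore(x, mu: float, sigma: float):
    """Standard z-score (x - mu) / sigma; sigma must be positive."""
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return (np.asarray(x, dtype=float) - mu) / sigma if np.ndim(x) else (x - mu) / sigma


def estimate_moments(population: ReferentPopulation) -> dict:
    """Sample mean and SD (n-1 denominator) per variable, age included."""
    moments = {}
    columns = {"RTL": "RTL", "Fe": "Fe", "TIBC": "TIBC", "F": "F", "a": "age"}
    for var, col in columns.items():
        values = population.records[col].dropna().to_numpy(dtype=float)
        if values.size < 2:
            raise ValueError(f"variable {var}: fewer than 2 observations")
        mu = float(np.mean(values))
        sigma = float(np.std(values, ddof=1))
        if sigma == 0:
            raise ValueError(f"variable {var} is constant; sigma = 0")
        moments[var] = (mu, sigma)
    return moments


def fit_normalized_slope(ages, xnorm, variable: str = "X") -> NormalizedFit:
    """OLS line of a z-scored variable on age."""
    ages = np.asarray(ages, dtype=float)
    xnorm = np.asarray(xnorm, dtype=float)
    if ages.shape != xnorm.shape:
        raise ValueError("ages and xnorm must have equal length")
    if np.unique(ages).size < 2:
        raise ValueError("need at least 2 distinct ages for a linear fit")
    slope, intercept = np.polyfit(ages, xnorm, 1)
    return NormalizedFit(variable, float(slope), float(intercept))


def _sgn(x: float, variable: str = "") -> float:
    if x == 0:
        warnings.warn(f"slope k_{variable or 'X'} is exactly zero; sgn(0) taken as +1")
        return 1.0
    return math.copysign(1.0, x)


def compute_k(slopes: dict) -> float:
    """Scaling factor k = 1 / sum_X |k_X|."""
    total = sum(k_x * _sgn(k_x, var) for var, k_x in slopes.items() if k_x != 0)
    if total == 0:
        raise ValueError("all slopes are zero; k undefined")
    return 1.0 / total


def compute_C(k: float, fits: dict) -> float:
    """Constant C = -k * sum_X sgn(k_X) * n_X."""
    if not k > 0:
        raise ValueError(f"k must be positive, got {k}")
    return -k * sum(_sgn(fit.k_x, var) * fit.n_x for var, fit in fits.items())


def calibrate(population: ReferentPopulation) -> CalibrationConstants:
    """Derive clock constants from a referent band sample.

    Moments and slopes are estimated per variable on its available
    subsample; the identity property (score regresses one-for-one on
    age) holds exactly on complete-case samples.  The life-expectancy
    adjustments are left at zero — they describe the study population,
    not the referent, and are set downstream.
    """
    moments = estimate_moments(population)
    columns = {"RTL": "RTL", "Fe": "Fe", "TIBC": "TIBC", "F": "F", "a": "age"}
    fits: dict[str, NormalizedFit] = {}
    for var, col in columns.items():
        mask = population.records[col].notna() & population.records["age"].notna()
        ages = population.records.loc[mask, "age"].to_numpy(dtype=float)
        values = population.records.loc[mask, col].to_numpy(dtype=float)
        mu, sigma = moments[var]
        fits[var] = fit_normalized_slope(ages, zscore(values, mu, sigma), var)
    k = compute_k({var: fit.k_x for var, fit in fits.items()})
    C = compute_C(k, fits)
    return CalibrationConstants(
        band=population.band,
        mu={var: moments[var][0] for var in VARIABLES},
        sigma={var: moments[var][1] for var in VARIABLES},
        slope={var: fits[var].k_x for var in VARIABLES},
        intercept={var: fits[var].n_x for var in VARIABLES},
        k=k,
        C=C,
    )
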