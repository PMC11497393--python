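"""Clearance / utilization kinetics: log-linear exponential-decay fits.

A metabolite cleared (or consumed) at a constant fractional rate decays
geometrically, ``C(t) = C0 * exp(-k t)``; on the log scale this is a
straight line, so the rate is estimated by ordinary least squares of
``ln(value)`` on time.  Replicates at a time point are independent
observations (they come from independent animals).  Compartments are
compared by a joint regression ``ln(value) ~ time + compartment +
time x compartment``: the interaction coefficient is exactly the slope
difference, with its t-test p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


@dataclass
class DecayFit:
    """Log-linear decay fit for one metabolite in one compartment."""

    compartment: str
    metabolite: str
    slope: float  # per-minute rate on the log scale; negative = decay
    intercept: float  # log initial level
    slope_se: float
    r_squared: float
    n_points: int

    @property
    def halflife(self) -> float:
        """Half-life in minutes (infinite for non-decaying series)."""
        return np.log(2) / -self.slope if self.slope < 0 else np.inf

    def ci95(self) -> tuple[float, float]:
        from scipy import stats as sps

        tcrit = sps.t.ppf(0.975, self.n_points - 2)
        return (self.slope - tcrit * self.slope_se, self.slope + tcrit * self.slope_se)

    def summary(self) -> str:
        lo, hi = self.ci95()
        return (f"{self.metabolite} in {self.compartment}: slope "
                f"{self.slope:+.4f}/min (SE {self.slope_se:.4f}, 95% CI "
                f"[{lo:+.4f}, {hi:+.4f}]), R²={self.r_squared:.3f}, "
                f"n={self.n_points}")


def fit_decay(times, values, compartment: str = "", metabolite: str = "",
              log_scale: bool = True) -> DecayFit:
    """OLS of ``ln(value)`` (or raw value) on time.

    Requires strictly positive values (log undefined otherwise) and at
    least three distinct time points.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape:
        raise ValueError("times and values must align")
    if len(np.unique(t)) < 3:
        raise ValueError("fit_decay requires >=3 distinct time points")
    if log_scale:
        if (v <= 0).any():
            raise ValueError("values must be strictly positive for the log-scale fit")
        y = np.log(v)
    else:
        y = v
    X = sm.add_constant(t)
    res = sm.OLS(y, X).fit()
    slope_se = float(res.bse[1])
    if slope_se == 0:
        slope_se = np.finfo(float).tiny  # noiseless series: SE underflows to 0
    return DecayFit(compartment, metabolite, float(res.params[1]),
                    float(res.params[0]), slope_se,
                    1.0 if res.centered_tss == 0 else float(res.rsquared), len(t))


def fit_decay_table(series: pd.DataFrame, log_scale: bool = True) -> list[DecayFit]:
    """Fit every (compartment, metabolite) series of a long-format table.

    Expects columns (compartment, metabolite, time, value).
    """
    fits = []
    for (comp, met), grp in series.groupby(["compartment", "metabolite"], sort=False):
        fits.append(fit_decay(grp["time"], grp["value"], comp, met, log_scale))
    return fits


@dataclass
class DecayComparison:
    """Slope difference between two compartments with its test."""

    compartment_a: str
    compartment_b: str
    slope_a: float
    slope_b: float
    slope_difference: float  # slope_b - slope_a (interaction coefficient)
    difference_se: float
    p_value: float

    def summary(self) -> str:
        return (f"{self.compartment_b} vs {self.compartment_a}: Δslope "
                f"{self.slope_difference:+.4f}/min (SE {self.difference_se:.4f}), "
                f"p = {self.p_value:.4g}")


def compare_decay(series: pd.DataFrame, pair: tuple[str, str],
                  metabolite: str | None = None) -> DecayComparison:
    """Interaction test for different decay dynamics in two compartments.

    Joint OLS ``ln(value) ~ time + compartment + time x compartment`` on
    the long-format series; the interaction coefficient equals
    ``slope(B) - slope(A)`` exactly, reported with its t-test p-value.
    """
    a, b = pair
    if a == b:
        raise ValueError("cannot compare a compartment with itself")
    sub = series[series["compartment"].isin(pair)]
    if metabolite is not None:
        sub = sub[sub["metabolite"] == metabolite]
    for comp in pair:
        grp = sub[sub["compartment"] == comp]
        if len(np.unique(grp["time"])) < 3:
            raise ValueError(f"compartment {comp!r} needs >=3 distinct time points")
        if (grp["value"] <= 0).any():
            raise ValueError(f"compartment {comp!r} has non-positive values")
    t = sub["time"].to_numpy(dtype=float)
    y = np.log(sub["value"].to_numpy(dtype=float))
    is_b = (sub["compartment"] == b).to_numpy(dtype=float)
    X = sm.add_constant(np.column_stack([t, is_b, t * is_b]))
    res = sm.OLS(y, X).fit()
    fit_a = fit_decay(t[is_b == 0], np.exp(y[is_b == 0]), a, metabolite or "")
    fit_b = fit_decay(t[is_b == 1], np.exp(y[is_b == 1]), b, metabolite or "")
    return DecayComparison(a, b, fit_a.slope, fit_b.slope,
                           float(res.params[3]), float(res.bse[3]),
                           float(res.pvalues[3]))
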