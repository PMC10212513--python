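"""Plate/cuvette quantification: H2O2 calibration, rate extraction,
percent-of-vehicle and percent-reduction scaling, 4PL dose-response
fitting with residual-rate subtraction, and site-IQ rate attribution.

Conventions: fluorescence in AFU; rates in AFU/min until calibrated to
pmol H2O2/min via a spike calibration; the regression window over
recording cycles is inclusive on both ends (the default [5, 18] uses 14
points of a 25-cycle trace); IC50s are labelled nominal because they
reflect added, not measured, suppressor concentrations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger("retscope.bulkassays")

DEFAULT_CYCLE_WINDOW = (5, 18)  # inclusive cycle indices (1-based)


@dataclass
class RateResult:
    raw_slope: float  # AFU/min
    slope_se: float
    n_points: int
    calibrated_rate: float | None = None  # pmol H2O2/min
    background_subtracted: bool = False
    percent_vehicle: float | None = None


@dataclass
class CalibrationCurve:
    slope: float  # AFU/pmol
    r_squared: float
    n_spikes: int

    def to_pmol_per_min(self, afu_per_min: float) -> float:
        return afu_per_min / self.slope


@dataclass
class FourPLFit:
    """Variable-slope four-parameter logistic fit.

    Oriented for suppression curves: ``rate(0) = top``, high-dose plateau
    ``bottom``, ``bottom <= top`` after orientation normalization.  IC50s
    are nominal (added concentrations).
    """

    top: float
    bottom: float
    ic50: float
    hill: float
    residual_subtracted: bool
    covariance: np.ndarray
    param_se: np.ndarray

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("ic50 must be > 0")

    def predict(self, conc) -> np.ndarray:
        return fourpl_model(np.asarray(conc, dtype=float),
                            self.top, self.bottom, self.ic50, self.hill)


@dataclass
class PercentReduction:
    values: np.ndarray  # % reduction vs time, not clipped
    zero_ref: float
    full_ref: float


# --------------------------------------------------------------------------
# calibration and rates
# --------------------------------------------------------------------------

def calibrate_h2o2(
    spike_amounts: Sequence[float], responses: Sequence[float]
) -> CalibrationCurve:
    """Least-squares slope through the origin of AFU step vs pmol spike.

    Steps are fluorescence differences, hence offset-free; a warning is
    issued when the responses are not monotone in the spike amounts.
    """
    x = np.asarray(spike_amounts, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 calibration spikes")
    order = np.argsort(x)
    if np.any(np.diff(y[order]) < 0):
        logger.warning("calibration responses are not monotone in spike amount")
    slope = float((x * y).sum() / (x * x).sum())
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(slope=slope, r_squared=r2, n_spikes=int(x.size))


def fit_rate(
    trace: pd.DataFrame,
    cycle_window: tuple = DEFAULT_CYCLE_WINDOW,
) -> RateResult:
    """OLS fluorescence slope over an inclusive cycle window, in AFU/min.

    ``trace`` needs columns ``cycle``, ``seconds``, ``fluorescence_afu``.
    Offset-invariant: adding a constant to the trace leaves the slope
    unchanged.
    """
    lo, hi = cycle_window
    sel = trace[(trace["cycle"] >= lo) & (trace["cycle"] <= hi)]
    if len(sel) < 3:
        raise ValueError(
            f"cycle window [{lo}, {hi}] holds {len(sel)} points; need >= 3"
        )
    t_min = sel["seconds"].to_numpy(dtype=float) / 60.0
    y = sel["fluorescence_afu"].to_numpy(dtype=float)
    n = len(sel)
    tc = t_min - t_min.mean()
    slope = float((tc * y).sum() / (tc * tc).sum())
    resid = y - (y.mean() + slope * tc)
    dof = n - 2
    se = (
        math.sqrt(float((resid**2).sum()) / dof / float((tc * tc).sum()))
        if dof > 0
        else float("nan")
    )
    return RateResult(raw_slope=slope, slope_se=se, n_points=n)


def rates_by_well(
    table: pd.DataFrame, cycle_window: tuple = DEFAULT_CYCLE_WINDOW
) -> pd.DataFrame:
    """Per-well slope table from a tidy well x cycle fluorescence table."""
    rows = []
    for well, grp in table.groupby("well", sort=False):
        rr = fit_rate(grp, cycle_window)
        rows.append(
            {
                "well": well,
                "role": grp["role"].iloc[0],
                "condition": grp["condition"].iloc[0] if "condition" in grp else "",
                "concentration_nM": (
                    grp["concentration_nM"].iloc[0]
                    if "concentration_nM" in grp
                    else np.nan
                ),
                "raw_slope_afu_per_min": rr.raw_slope,
                "slope_se": rr.slope_se,
                "n_points": rr.n_points,
            }
        )
    return pd.DataFrame(rows)


def percent_vehicle(
    sample_rates: Sequence[float],
    vehicle_rates: Sequence[float],
    background_rates: Sequence[float] | float,
) -> np.ndarray:
    """Background-subtracted rates as percent of the vehicle mean.

    ``100 * (sample - matched background) / mean(vehicle - matched
    background)``.  ``background_rates`` may be a scalar, one value per
    sample, or a (sample_bg, vehicle_bg) pair of arrays.
    """
    s = np.asarray(sample_rates, dtype=float)
    v = np.asarray(vehicle_rates, dtype=float)
    if isinstance(background_rates, tuple):
        bg_s, bg_v = (np.asarray(b, dtype=float) for b in background_rates)
    else:
        bg_s = np.asarray(background_rates, dtype=float)
        bg_v = bg_s if bg_s.ndim == 0 else float(bg_s.mean())
    denom = float((v - bg_v).mean())
    if denom <= 0:
        raise ValueError("vehicle mean rate <= 0 after background subtraction")
    return 100.0 * (s - bg_s) / denom


def percent_reduction(
    trace: np.ndarray, zero_ref: float, full_ref: float
) -> PercentReduction:
    """Scale a redox trace between the 0% and 100%-reduction references.

    Values may transiently exceed [0, 100] and are reported as-is.
    """
    if full_ref <= zero_ref:
        raise ValueError("full_ref must exceed zero_ref")
    values = 100.0 * (np.asarray(trace, dtype=float) - zero_ref) / (full_ref - zero_ref)
    return PercentReduction(values=values, zero_ref=zero_ref, full_ref=full_ref)


# --------------------------------------------------------------------------
# dose-response
# --------------------------------------------------------------------------

def fourpl_model(conc, top, bottom, ic50, hill):
    conc = np.asarray(conc, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(conc > 0, (conc / ic50) ** hill, 0.0 if hill > 0 else np.inf)
    return bottom + (top - bottom) / (1.0 + ratio)


def fit_4pl(
    concentrations: Sequence[float],
    rates: Sequence[float],
    subtract_residual: bool = False,
) -> FourPLFit:
    """Variable-slope 4PL fit of rate vs concentration.

    Nonlinear least squares with a deterministic multi-start over the
    Hill slope; IC50 is fitted on a log scale.  With
    ``subtract_residual`` the fitted bottom plateau (the rate left at
    saturating suppressor) is subtracted and the curve refit with the
    bottom pinned at 0, leaving only the site-specific signal, before the
    IC50 is read.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(rates, dtype=float)
    if c.size < 5:
        raise ValueError("need at least 5 concentrations spanning the transition")
    if np.any(c < 0):
        raise ValueError("concentrations must be >= 0")

    pos = c[c > 0]
    ic50_start = float(np.exp(np.log(pos).mean()))
    span_lo, span_hi = float(pos.min()), float(pos.max())

    def model_free(conc, top, bottom, log_ic50, hill):
        return fourpl_model(conc, top, bottom, math.exp(log_ic50), hill)

    def model_bottom0(conc, top, log_ic50, hill):
        return fourpl_model(conc, top, 0.0, math.exp(log_ic50), hill)

    def run(model, p0_list, names):
        best = None
        for p0 in p0_list:
            try:
                popt, pcov = curve_fit(model, c, y_fit, p0=p0, maxfev=20000)
            except RuntimeError:
                continue
            resid = y_fit - model(c, *popt)
            ss = float((resid**2).sum())
            if best is None or ss < best[2]:
                best = (popt, pcov, ss)
        if best is None:
            raise RuntimeError("4PL fit failed from all starts")
        return best

    y_fit = y
    top0, bot0 = float(y.max()), float(y.min())
    p0s = [
        (top0, bot0, math.log(ic50_start), h) for h in (0.5, 1.0, 2.0)
    ]
    popt, pcov, _ = run(model_free, p0s, None)
    top, bottom, log_ic50, hill = popt
    # orientation normalization: exchanging (top, bottom) with hill -> -hill
    # leaves residuals unchanged; report the suppression orientation
    if hill < 0:
        top, bottom, hill = bottom, top, -hill
    ic50 = math.exp(log_ic50)
    if not (span_lo / 100.0 <= ic50 <= span_hi * 100.0):
        raise RuntimeError(
            f"no identifiable transition: fitted IC50 {ic50:.3g} far outside "
            f"the dosed range [{span_lo:.3g}, {span_hi:.3g}]"
        )
    resid_sd = float(np.std(y - fourpl_model(c, top, bottom, ic50, hill)))
    if abs(top - bottom) <= 3.0 * resid_sd:
        raise RuntimeError(
            f"no identifiable transition: fitted amplitude {top - bottom:.3g} "
            f"is within the residual noise (sd {resid_sd:.3g})"
        )

    if subtract_residual:
        y_fit = y - bottom
        p0s = [(top - bottom, math.log(ic50), hill)]
        popt, pcov, _ = run(model_bottom0, p0s, None)
        top, log_ic50, hill = popt
        bottom = 0.0
        if hill < 0:
            # degenerate refit orientation; flip back
            hill = -hill
        ic50 = math.exp(log_ic50)

    se = np.sqrt(np.diag(pcov))
    # translate the log-ic50 SE to the concentration scale
    if subtract_residual:
        param_se = np.array([se[0], 0.0, ic50 * se[1], se[2]])
    else:
        param_se = np.array([se[0], se[1], ic50 * se[2], se[3]])
    return FourPLFit(
        top=float(top),
        bottom=float(bottom),
        ic50=float(ic50),
        hill=float(hill),
        residual_subtracted=bool(subtract_residual),
        covariance=pcov,
        param_se=param_se,
    )


def site_iq_rate(total_rate: float, rate_with_saturating_s1qel: float) -> float:
    """Rate attributed to site IQ: total minus the S1QEL-resistant rate.

    Both inputs must be background-subtracted and in the same units.
    Negative differences are floored at 0 with a warning.
    """
    diff = float(total_rate) - float(rate_with_saturating_s1qel)
    if diff < 0:
        logger.warning(
            "suppressed rate exceeds total (%.3g > %.3g); site-IQ rate floored at 0",
            rate_with_saturating_s1qel,
            total_rate,
        )
        return 0.0
    return diff
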