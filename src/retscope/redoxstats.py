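"""Pixelwise NAD(P)H log2-fold analysis and the RET-fraction estimator.

The core inference chain of the cell arm:

1. pixelwise log2-fold intensity changes between a registered
   before/after frame pair, restricted to a mitochondrial mask and
   binned into a histogram;
2. a mock (vehicle) pair fitted with a single Gaussian by binned
   maximum likelihood -- the null distribution of intensity changes due
   to noise, motility and redox fluctuations;
3. the challenge pair fitted with a constrained two-component Gaussian
   mixture (non-responder + responder, both components sharing the mock
   sigma);
4. the fraction of mitochondrial pixels undergoing oxidation estimated
   as the *excess* of observed pixel counts over the fitted model in the
   far-left tail (below ``mu_nonresp - k * sigma_mock``, k = 2 by
   default);
5. per-object direction calls (forward / reverse / stalled) from
   thresholded log2-fold changes.

Numerical note: the binned likelihood carries a tiny fixed uniform
contamination term (``CONTAMINATION_ETA`` spread over the bins) so that
pixels far outside the Gaussian bulk -- exactly the pixels the excess
estimator is designed to count -- cannot drive the fit's log-likelihood
to minus infinity or drag the component means into the tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

logger = logging.getLogger("retscope.redoxstats")

DEFAULT_BIN_WIDTH = 0.05  # log2-fold units
DEFAULT_EPSILON_AFU = 1.0  # intensity floor added to both frames
CONTAMINATION_ETA = 1e-3  # uniform outlier mass in the binned likelihood
DEFAULT_TAIL_SIGMA_MULTIPLE = 2.0
DEFAULT_DIRECTION_SE_MULTIPLE = 1.5  # c in threshold = c * average SE, c in [1, 2]

DIRECTION_CLASSES = ("fet", "stalled", "ret")


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class LogFoldHistogram:
    """Binned pixelwise log2-fold intensity changes."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int
    source: str = "treated"  # or "mock"
    cell_id: str | int | None = None
    values: np.ndarray | None = None  # raw per-pixel values, optional

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if int(self.counts.sum()) != self.n_pixels:
            raise ValueError("counts must sum to n_pixels")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("bin width must be uniform")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @classmethod
    def from_values(
        cls,
        values: np.ndarray,
        bin_width: float = DEFAULT_BIN_WIDTH,
        source: str = "treated",
        cell_id=None,
    ) -> "LogFoldHistogram":
        values = np.asarray(values, dtype=float).ravel()
        lo = math.floor(values.min() / bin_width) * bin_width - bin_width
        hi = math.ceil(values.max() / bin_width) * bin_width + bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        counts, edges = np.histogram(values, bins=edges)
        return cls(
            bin_edges=edges,
            counts=counts,
            n_pixels=int(values.size),
            source=source,
            cell_id=cell_id,
            values=values,
        )


@dataclass
class NullFit:
    """Single-Gaussian fit of a mock log2-fold histogram."""

    mu0: float
    sigma0: float
    log_likelihood: float
    converged: bool = True


@dataclass
class TwoComponentFit:
    """Constrained two-Gaussian fit (both components share the mock sigma)."""

    w_nonresp: float
    w_resp: float
    mu_nonresp: float
    mu_resp: float
    sigma: float
    log_likelihood: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(self.w_nonresp + self.w_resp, 1.0, abs_tol=1e-9):
            raise ValueError("component weights must sum to 1")


@dataclass
class RETFractionEstimate:
    """Excess-pixel-count estimate of the oxidising subpopulation.

    ``fraction`` is a pixel fraction of the mitochondrial mask; equating
    it with a mitochondrion fraction assumes equal mean mitochondrial
    area across classes.
    """

    fraction: float
    threshold: float  # log2-fold cut used
    threshold_sigma_multiple: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class DirectionCall:
    object_id: int
    delta: float  # log2-fold
    call: str
    threshold: float


# --------------------------------------------------------------------------
# pixelwise and per-cell fold changes
# --------------------------------------------------------------------------

def pixel_log2fold(
    before: np.ndarray,
    after: np.ndarray,
    mask: np.ndarray,
    eps: float = DEFAULT_EPSILON_AFU,
    bin_width: float = DEFAULT_BIN_WIDTH,
    source: str = "treated",
    cell_id=None,
) -> LogFoldHistogram:
    """Histogram of ``log2((after + eps) / (before + eps))`` over a mask."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mitochondrial mask")
    b = np.asarray(before, dtype=float)[mask]
    a = np.asarray(after, dtype=float)[mask]
    floored = np.mean(a <= 0)
    if floored > 0.01:
        logger.warning(
            "%.1f%% of masked after-frame pixels at the intensity floor; "
            "noise floor may be too high",
            100 * floored,
        )
    values = np.log2((a + eps) / (b + eps))
    return LogFoldHistogram.from_values(
        values, bin_width=bin_width, source=source, cell_id=cell_id
    )


def mock_scale_factor(null: NullFit) -> float:
    """Common linear factor for the after-frame so the mock mode sits at 0."""
    return 2.0 ** (-null.mu0)


def cell_delta_f_over_f0(
    before: np.ndarray, after: np.ndarray, cell_labels: np.ndarray
) -> pd.DataFrame:
    """Per-cell ``(mean_after - mean_before) / mean_before``.

    ``cell_labels`` is a label image (0 = background).  Cells with zero
    mean baseline intensity are excluded with a warning.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    labels = np.asarray(cell_labels)
    rows = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        sel = labels == cid
        mb = float(before[sel].mean())
        ma = float(after[sel].mean())
        if mb <= 0:
            logger.warning("cell %s has zero baseline mean; excluded", cid)
            continue
        rows.append({"cell": int(cid), "mean_before": mb, "mean_after": ma,
                     "dff": (ma - mb) / mb})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# binned maximum-likelihood fits
# --------------------------------------------------------------------------

def _bin_probs_gauss(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (edges - mu) / sigma
    cdf = norm.cdf(z)
    return np.diff(cdf)


def _binned_nll(counts: np.ndarray, probs: np.ndarray) -> float:
    """Multinomial negative log-likelihood with a uniform contamination floor."""
    nbins = len(counts)
    p = (1.0 - CONTAMINATION_ETA) * probs + CONTAMINATION_ETA / nbins
    p = p / p.sum()
    return float(-(counts * np.log(p)).sum())


def fit_null(hist: LogFoldHistogram) -> NullFit:
    """Fit a single Gaussian to a binned histogram by maximum likelihood."""
    if hist.n_pixels < 100:
        raise ValueError("need at least 100 pixels for a null fit")
    occupied = np.count_nonzero(hist.counts)
    if occupied < 2:
        raise ValueError("degenerate histogram: a single occupied bin")
    centers = hist.centers
    w = hist.counts / hist.n_pixels
    mu_start = float((w * centers).sum())
    var_start = float((w * (centers - mu_start) ** 2).sum())
    sig_start = max(math.sqrt(max(var_start, 1e-12)), hist.bin_width / 4)

    def nll(params):
        mu, logsig = params
        return _binned_nll(hist.counts, _bin_probs_gauss(hist.bin_edges, mu, math.exp(logsig)))

    res = optimize.minimize(
        nll,
        x0=[mu_start, math.log(sig_start)],
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
    )
    mu, logsig = res.x
    return NullFit(
        mu0=float(mu),
        sigma0=float(math.exp(logsig)),
        log_likelihood=float(-res.fun),
        converged=bool(res.success),
    )


def fit_two_normals(hist: LogFoldHistogram, sigma0: float) -> TwoComponentFit:
    """Constrained two-Gaussian fit of a binned histogram.

    Maximizes the binned likelihood over (responder weight,
    non-responder mean, responder mean) with both component sigmas fixed
    to the mock ``sigma0`` and the identifiability constraint
    ``mu_resp >= mu_nonresp``.  A deterministic multi-start grid guards
    against local optima.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be > 0")
    if hist.n_pixels < 100:
        raise ValueError("need at least 100 pixels for a mixture fit")
    centers = hist.centers
    edges = hist.bin_edges

    def nll(params):
        wlogit, mu_non, delta = params
        w_resp = 1.0 / (1.0 + math.exp(-wlogit))
        p = (1 - w_resp) * _bin_probs_gauss(edges, mu_non, sigma0) + (
            w_resp
        ) * _bin_probs_gauss(edges, mu_non + delta, sigma0)
        return _binned_nll(hist.counts, p)

    lo, hi = float(centers[0]), float(centers[-1])
    span = hi - lo
    w_hist = hist.counts / hist.n_pixels
    mean_c = float((w_hist * centers).sum())
    mode_c = float(centers[int(np.argmax(hist.counts))])
    starts = []
    for mu_non in (0.0, mode_c, mean_c - 0.3):
        for delta in (0.1, math.log2(1.5), 1.0):
            for w in (0.3, 0.7):
                starts.append((math.log(w / (1 - w)), mu_non, delta))

    best = None
    any_success = False
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0=np.asarray(x0),
            method="L-BFGS-B",
            bounds=[(-12, 12), (lo, hi), (0.0, max(span, 0.1))],
        )
        if best is None or res.fun < best.fun:
            best = res
        any_success = any_success or bool(res.success)
    if best is None:
        raise RuntimeError("two-component fit failed from all starts")
    wlogit, mu_non, delta = best.x
    w_resp = 1.0 / (1.0 + math.exp(-wlogit))
    fit = TwoComponentFit(
        w_nonresp=float(1 - w_resp),
        w_resp=float(w_resp),
        mu_nonresp=float(mu_non),
        mu_resp=float(mu_non + delta),
        sigma=float(sigma0),
        log_likelihood=float(-best.fun),
        converged=any_success,
    )
    if not any_success:
        raise RuntimeError(
            f"two-component fit did not converge from any start; best partial "
            f"fit: {fit}"
        )
    return fit


def expected_counts(hist: LogFoldHistogram, fit: TwoComponentFit) -> np.ndarray:
    """Expected per-bin counts under a two-component fit (incl. floor)."""
    p = fit.w_nonresp * _bin_probs_gauss(hist.bin_edges, fit.mu_nonresp, fit.sigma)
    p = p + fit.w_resp * _bin_probs_gauss(hist.bin_edges, fit.mu_resp, fit.sigma)
    nbins = len(hist.counts)
    p = (1.0 - CONTAMINATION_ETA) * p + CONTAMINATION_ETA / nbins
    p = p / p.sum()
    return hist.n_pixels * p


# --------------------------------------------------------------------------
# excess-pixel-count estimator
# --------------------------------------------------------------------------

def excess_oxidised_fraction(
    hist: LogFoldHistogram,
    fit: TwoComponentFit,
    null: NullFit,
    k: float = DEFAULT_TAIL_SIGMA_MULTIPLE,
) -> RETFractionEstimate:
    """Excess pixel count below ``mu_nonresp - k * sigma_mock``.

    Over bins with center below the threshold, sums
    ``max(observed - expected_under_fit, 0)`` and divides by the masked
    pixel count.  The threshold is measured from the non-responder
    center, i.e. oxidation is counted relative to the unresponsive
    population.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    threshold = fit.mu_nonresp - k * null.sigma0
    exp = expected_counts(hist, fit)
    sel = hist.centers < threshold
    excess = np.maximum(hist.counts[sel] - exp[sel], 0.0).sum()
    return RETFractionEstimate(
        fraction=float(excess / hist.n_pixels),
        threshold=float(threshold),
        threshold_sigma_multiple=float(k),
        n_pixels=hist.n_pixels,
    )


def pool_fractions(fractions: Sequence[float]) -> tuple:
    """Unweighted mean and SE of per-cell fractions."""
    arr = np.asarray(list(fractions), dtype=float)
    if arr.size == 0:
        raise ValueError("no fractions to pool")
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return mean, se


# --------------------------------------------------------------------------
# direction calls
# --------------------------------------------------------------------------

def direction_threshold(repeated: np.ndarray, c: float = DEFAULT_DIRECTION_SE_MULTIPLE) -> float:
    """Threshold = ``c`` times the average SE of repeated determinations.

    ``repeated`` is (n_objects, n_repeats) of post-challenge log2-fold
    determinations; ``c`` defaults to 1.5 (midway in the 1-2 range).
    """
    repeated = np.atleast_2d(np.asarray(repeated, dtype=float))
    if repeated.shape[1] < 2:
        raise ValueError(
            "fewer than 2 repeated determinations: SE unavailable, "
            "supply an explicit threshold"
        )
    se = repeated.std(axis=1, ddof=1) / math.sqrt(repeated.shape[1])
    return float(c * se.mean())


def classify_direction(
    deltas: np.ndarray, threshold: float
) -> list:
    """Three-way per-object call from log2-fold changes at challenge.

    fet if delta > +threshold, ret if delta < -threshold, else stalled.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    calls = []
    for i, d in enumerate(np.asarray(deltas, dtype=float)):
        if d > threshold:
            call = "fet"
        elif d < -threshold:
            call = "ret"
        else:
            call = "stalled"
        calls.append(DirectionCall(object_id=i, delta=float(d), call=call,
                                   threshold=float(threshold)))
    return calls


def direction_fractions(
    replicate_deltas: Sequence[np.ndarray], threshold: float
) -> pd.DataFrame:
    """Per-class fractions with SE across replicate fields."""
    per_rep = []
    for deltas in replicate_deltas:
        calls = classify_direction(deltas, threshold)
        n = len(calls)
        per_rep.append(
            {c: sum(1 for k in calls if k.call == c) / n for c in DIRECTION_CLASSES}
        )
    tab = pd.DataFrame(per_rep)
    mean = tab.mean(axis=0)
    se = (
        tab.std(axis=0, ddof=1) / math.sqrt(len(tab))
        if len(tab) > 1
        else pd.Series(np.nan, index=tab.columns)
    )
    out = pd.DataFrame({"fraction": mean, "se": se})
    out.index.name = "call"
    out.attrs["n_replicates"] = len(tab)
    return out


def call_bulk_trace(
    trace: np.ndarray, challenge_index: int, threshold: float, steady_points: int = 3
) -> str:
    """Direction call for a bulk redox trace.

    Compares the post-challenge steady value (mean of the last
    ``steady_points`` samples) with the value immediately before the
    challenge; a decrease beyond the threshold is the RET diagnostic
    (matrix NADH oxidising after the Q-site block).
    """
    trace = np.asarray(trace, dtype=float)
    pre = trace[challenge_index - 1]
    post = trace[-steady_points:].mean()
    delta = post - pre
    if delta > threshold:
        return "fet"
    if delta < -threshold:
        return "ret"
    return "stalled"


def per_mito_dnadh(
    delta_f: np.ndarray, population_mean_pre: float, floor: float = 1e-6
) -> np.ndarray:
    """Population-normalized log2-fold change per object.

    ``log2(1 + dF / population_mean_pre)``.  Normalizing by the
    population mean baseline (rather than each object's own, possibly
    near-zero, baseline) keeps values finite for dim mitochondria and
    symmetric for symmetric intensity changes.
    """
    if population_mean_pre <= 0:
        raise ValueError("population_mean_pre must be > 0")
    ratio = 1.0 + np.asarray(delta_f, dtype=float) / population_mean_pre
    n_clip = int(np.sum(ratio <= floor))
    if n_clip:
        logger.warning("%d objects clipped at the log floor", n_clip)
    return np.log2(np.maximum(ratio, floor))
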