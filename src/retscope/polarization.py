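"""Nernst-based relative membrane potentials and subpopulation gating.

Single-mitochondrion TMRM intensities are converted to relative membrane
potentials with the decade form of the Nernst relation,
``61 mV * log10(F_num / F_den)``.  Potentials are relative throughout:
polarization by glutamate+malate (G+M) is referenced to succinate
(values <= 0 mean *less* polarized than with succinate) and the G3P
response is the hyperpolarization relative to G+M.  Gates in the
(G+M-vs-succinate, G3P-vs-G+M) plane assign each mitochondrion to one of
four response classes; the gates are declared arbitrary and are
configurable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("retscope.polarization")

NERNST_SLOPE_MV = 61.0

POLARIZATION_CLASSES = (
    "medium_medium",
    "strong_gm_weak_g3p",
    "ret_like",
    "nonresponsive",
)


def relative_polarization(f_num, f_den) -> float | np.ndarray:
    """Relative membrane potential, mV: ``61 * log10(f_num / f_den)``.

    Additive over chained ratios; a tenfold intensity ratio is one Nernst
    decade, 61 mV.  Raises on non-positive intensities.
    """
    f_num = np.asarray(f_num, dtype=float)
    f_den = np.asarray(f_den, dtype=float)
    if np.any(f_num <= 0) or np.any(f_den <= 0):
        bad = np.nonzero(np.atleast_1d((f_num <= 0) | (f_den <= 0)))[0]
        raise ValueError(
            f"non-positive TMRM intensity for record(s) {bad.tolist()}"
        )
    out = NERNST_SLOPE_MV * np.log10(f_num / f_den)
    return float(out) if out.ndim == 0 else out


def normalize_trace(
    trace: np.ndarray, frame_background: float, trace_max: float
) -> tuple:
    """Normalize a trace between frame background and its own maximum.

    Returns ``(values in [0, 1], responsive)``.  If the maximum does not
    exceed the background the mitochondrion is flagged nonresponsive and
    the trace is set to 0.
    """
    trace = np.asarray(trace, dtype=float)
    if trace_max <= frame_background:
        logger.warning("trace max <= background; flagged nonresponsive")
        return np.zeros_like(trace), False
    out = (trace - frame_background) / (trace_max - frame_background)
    return np.clip(out, 0.0, 1.0), True


@dataclass(frozen=True)
class GateSet:
    """Rectangular gates partitioning the polarization plane.

    x is polarization by G+M referenced to succinate (mV, <= 0);
    y is hyperpolarization by G3P referenced to G+M (mV).

    - y < g3p_floor_mv            -> nonresponsive (little G3P response)
    - x >  gm_split_mv, y < g3p_split_mv -> strong_gm_weak_g3p
    - x <= gm_split_mv, y >= g3p_split_mv -> ret_like
    - otherwise                   -> medium_medium

    The partition is exhaustive and overlap-free for any threshold choice
    with ``g3p_floor_mv < g3p_split_mv``.
    """

    gm_split_mv: float = -30.0
    g3p_split_mv: float = 20.0
    g3p_floor_mv: float = 5.0

    def __post_init__(self) -> None:
        if not self.g3p_floor_mv < self.g3p_split_mv:
            raise ValueError("g3p_floor_mv must be below g3p_split_mv")

    def classify(self, pol_gm_vs_succ: float, pol_g3p_vs_gm: float) -> str:
        x, y = pol_gm_vs_succ, pol_g3p_vs_gm
        if y < self.g3p_floor_mv:
            return "nonresponsive"
        if x > self.gm_split_mv and y < self.g3p_split_mv:
            return "strong_gm_weak_g3p"
        if x <= self.gm_split_mv and y >= self.g3p_split_mv:
            return "ret_like"
        return "medium_medium"


@dataclass
class PolarizationRecord:
    """Per-mitochondrion TMRM intensities and derived relative potentials."""

    mito_id: int
    f_tmrm: Mapping[str, float]
    pol_gm_vs_succ: float  # mV; <= 0 means less polarized than with succinate
    pol_g3p_vs_gm: float  # mV hyperpolarization on G3P
    mito_class: str = ""


def records_from_traces(
    traces: pd.DataFrame,
    gates: GateSet | None = None,
    gm_label: str = "gm",
    g3p_label: str = "g3p",
    succ_label: str = "succ",
) -> list:
    """Build polarization records from an extracted-trace table.

    ``traces`` must hold background-subtracted mean TMRM intensities with
    one column per condition (as produced by ``imgproc.extract_traces``).
    Rows with non-positive intensity in any required condition are skipped
    with a warning (no potential can be computed for them).
    """
    gates = gates or GateSet()
    records = []
    for roi, row in traces.iterrows():
        f = {c: float(row[c]) for c in (gm_label, g3p_label, succ_label)}
        if any(v <= 0 for v in f.values()):
            logger.warning("mitochondrion %s has non-positive intensity; skipped", roi)
            continue
        x = relative_polarization(f[gm_label], f[succ_label])
        y = relative_polarization(f[g3p_label], f[gm_label])
        records.append(
            PolarizationRecord(
                mito_id=int(roi),
                f_tmrm=f,
                pol_gm_vs_succ=x,
                pol_g3p_vs_gm=y,
                mito_class=gates.classify(x, y),
            )
        )
    return records


def classify_population(
    replicates: Sequence[Sequence[PolarizationRecord]],
    gates: GateSet | None = None,
) -> pd.DataFrame:
    """Class fractions with SE over experimental replicates.

    Each replicate's records are gated and reduced to class fractions
    (summing to 1); the table reports mean and SE across replicates.  With
    a single replicate the SE is reported as absent (NaN).  Empty
    replicates are excluded with a warning.
    """
    gates = gates or GateSet()
    per_rep = []
    for i, records in enumerate(replicates):
        if len(records) == 0:
            logger.warning("replicate %d is empty; excluded", i)
            continue
        counts = {c: 0 for c in POLARIZATION_CLASSES}
        for rec in records:
            cls = rec.mito_class or gates.classify(
                rec.pol_gm_vs_succ, rec.pol_g3p_vs_gm
            )
            counts[cls] += 1
        n = sum(counts.values())
        per_rep.append({c: counts[c] / n for c in POLARIZATION_CLASSES})
    if not per_rep:
        raise ValueError("no non-empty replicates")
    tab = pd.DataFrame(per_rep)
    mean = tab.mean(axis=0)
    se = (
        tab.std(axis=0, ddof=1) / math.sqrt(len(tab))
        if len(tab) > 1
        else pd.Series(np.nan, index=tab.columns)
    )
    out = pd.DataFrame({"fraction": mean, "se": se})
    out.index.name = "class"
    out.attrs["n_replicates"] = len(tab)
    return out
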