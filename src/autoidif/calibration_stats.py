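"""Steady-state cross-calibration of the IDIF against blood samples.

After bolus passage (150-300 s by default) the tracer concentration in
arterial blood is spatially homogeneous, so the image-derived curve and the
blood samples - drawn at a distant site with different delay/dispersion -
can be compared free of bolus dynamics.  Per subject i:

    cc_i     = mean(AIF_i) / mean(IDIF_i)
    sigma_i  = sd(AIF_i)/mean(IDIF_i) + sd(IDIF_i)*mean(AIF_i)/mean(IDIF_i)^2

(the error propagation is linear, not in quadrature), where the standard
deviations are computed after removing any remaining linear trend over
time.  The group factor is the reliability-weighted average with weights
w_i = 1/sigma_i, and its standard error is n / sum(1/sigma_i), which is
algebraically identical to sum(w_i*sigma_i)/sum(w_i).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .core_io import TimeActivityCurve
from .gtm_extraction import IDIFResult

__all__ = [
    "SteadyStateWindow",
    "SteadyStateStats",
    "SubjectCalibration",
    "GroupCalibration",
    "steady_state_stats",
    "subject_cc",
    "group_cc",
    "auc",
    "ia_ea_ratio",
]

log = logging.getLogger(__name__)

ZERO_SIGMA_WEIGHT_CAP = 1e12  # weight for sigma(cc_i)=0 subjects (noise-free data)


@dataclass
class SteadyStateWindow:
    """Steady-state interval (s post injection), default 150-300 s."""

    t_start: float = 150.0
    t_end: float = 300.0

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("window start must precede window end")

    def contains(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=np.float64)
        return (times >= self.t_start) & (times <= self.t_end)


@dataclass
class SteadyStateStats:
    mean: float          # kBq/mL, of the raw in-window values
    sd_detrended: float  # kBq/mL, residual SD after linear detrend
    n_points: int


@dataclass
class SubjectCalibration:
    subject_id: str
    cc_i: float
    sigma_cc_i: float
    aif: SteadyStateStats
    idif: SteadyStateStats


@dataclass
class GroupCalibration:
    cc: float
    sigma_cc: float
    n: int
    cc_i: np.ndarray
    sigma_cc_i: np.ndarray
    weights: np.ndarray
    t_statistic: float = float("nan")  # one-sample t-test of cc_i vs 1 (two-tailed)
    p_value: float = float("nan")


def steady_state_stats(tac: TimeActivityCurve, window: SteadyStateWindow,
                       detrend: bool = True) -> SteadyStateStats:
    """In-window mean and linearly detrended SD (n-1 denominator).

    The mean uses the raw values; only the fluctuation estimate is
    detrended, because a residual slow trend would otherwise inflate the
    apparent unreliability.
    """
    keep = window.contains(tac.times)
    if keep.sum() < 2:
        raise ValueError(
            f"need >= 2 points inside [{window.t_start}, {window.t_end}] s, "
            f"got {int(keep.sum())}"
        )
    t = tac.times[keep]
    v = tac.values[keep]
    if detrend:
        slope, intercept = np.polyfit(t, v, 1)
        resid = v - (slope * t + intercept)
    else:
        resid = v - v.mean()
    return SteadyStateStats(float(v.mean()), float(np.std(resid, ddof=1)), int(keep.sum()))


def subject_cc(aif: SteadyStateStats, idif: SteadyStateStats,
               subject_id: str = "") -> SubjectCalibration:
    """Subject cross-calibration factor and its linearly propagated error."""
    if idif.mean <= 0:
        raise ValueError("mean IDIF must be positive to form cc")
    cc_i = aif.mean / idif.mean
    sigma = aif.sd_detrended / idif.mean + idif.sd_detrended * aif.mean / idif.mean**2
    return SubjectCalibration(subject_id, float(cc_i), float(sigma), aif, idif)


def group_cc(subjects: list[SubjectCalibration],
             zero_sigma_weight: float = ZERO_SIGMA_WEIGHT_CAP) -> GroupCalibration:
    """Reliability-weighted group cross-calibration factor.

    Weights are w_i = 1/sigma(cc_i); subjects with exactly zero sigma
    (noise-free synthetic data) receive a large capped weight so the
    average stays finite.  The group standard error n/sum(1/sigma) uses the
    same capped weights, keeping the algebraic identity with
    sum(w_i*sigma_i)/sum(w_i) intact.
    """
    if not subjects:
        raise ValueError("no subjects")
    cc_i = np.array([s.cc_i for s in subjects])
    sig = np.array([s.sigma_cc_i for s in subjects])
    if np.any(sig < 0):
        raise ValueError("negative sigma(cc_i)")
    if np.any(sig == 0):
        log.warning("%d subject(s) with sigma(cc_i)=0: capped weight applied",
                    int((sig == 0).sum()))
    w = np.where(sig > 0, 1.0 / np.where(sig > 0, sig, 1.0), zero_sigma_weight)
    cc = float((w * cc_i).sum() / w.sum())
    sigma_cc = float(len(subjects) / w.sum())
    if len(subjects) >= 2 and np.std(cc_i) > 0:
        t_stat, p_val = sp_stats.ttest_1samp(cc_i, 1.0)
    else:
        t_stat, p_val = float("nan"), float("nan")
    return GroupCalibration(cc, sigma_cc, len(subjects), cc_i, sig, w,
                            float(t_stat), float(p_val))


def auc(tac: TimeActivityCurve, t0: float, t1: float) -> float:
    """Trapezoidal area under the curve (kBq*s/mL) over [t0, t1].

    When integrating from t0 = 0 and the first sample lies later, a virtual
    (0, 0) point is prepended (activity starts at zero at injection).  The
    integral is truncated at the last sample if the curve ends before t1.
    """
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    keep = (tac.times >= t0) & (tac.times <= t1)
    if not keep.any():
        raise ValueError("no samples inside the integration range")
    t = tac.times[keep]
    v = tac.values[keep]
    if t0 == 0.0 and t[0] > 0.0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    return float(np.trapezoid(v, t))


def ia_ea_ratio(result: IDIFResult, window: SteadyStateWindow) -> float:
    """Steady-state ratio of intra- to extraarterial concentration."""
    keep = window.contains(result.idif.times) & result.valid
    if not keep.any():
        raise ValueError("no valid frames inside the steady-state window")
    ea = float(result.extraarterial.values[keep].mean())
    if ea == 0:
        raise ValueError("zero mean extraarterial concentration")
    return float(result.idif.values[keep].mean()) / ea
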