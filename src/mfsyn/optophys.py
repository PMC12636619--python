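"""FRAP normalization and hyperbolic fitting; iGluSnFR release metrics.

FRAP traces are normalized as
``FRAP(t) = (F_bleach(t) - F_background(t)) / (F_nonbleached(t) - F_background(t))``
and the post-bleach recovery is fit with the hyperbolic model
``F(t') = f0 + (R/100 - f0) * t' / (t_half + t')`` where ``t'`` is time since
bleach, ``R`` the recovery extent in percent and ``t_half`` the half-time.

iGluSnFR traces (dF/F0 at 100 Hz) are analyzed per ROI: the noise SD comes
from the 500 ms pre-stimulus baseline, a response to an action potential is
the maximum within 10 ms after the stimulus and counts as detected when it
exceeds 4x the noise SD.  Derived metrics are the paired-pulse ratio
(second/first peak), the ROI response class, the cumulative release over a
train, and the synaptic-vesicle replenishment rate (SVRR), the slope of a
line fit to the cumulative signal over the last 30 APs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError


@dataclass(frozen=True)
class FrapTrace:
    """Raw FRAP intensity series (equal-length bleach/non-bleached/background
    ROIs) with the bleach time separating pre- and post-bleach phases."""

    times_s: np.ndarray
    f_bleach: np.ndarray
    f_nonbleached: np.ndarray
    f_background: np.ndarray
    bleach_time_s: float

    def __post_init__(self):
        n = len(self.times_s)
        if not (len(self.f_bleach) == len(self.f_nonbleached) == len(self.f_background) == n):
            raise ValidationError("FRAP series must have equal lengths")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValidationError("times must be strictly increasing")


@dataclass(frozen=True)
class FrapFit:
    recovery_percent: float
    t_half_s: float
    f0: float


@dataclass(frozen=True)
class GluTrace:
    """dF/F0 trace sampled at uniform rate with stimulus times."""

    dff0: np.ndarray
    times_s: np.ndarray
    stim_times_s: np.ndarray
    baseline_window_s: float = 0.5


@dataclass(frozen=True)
class ResponseSet:
    peaks: np.ndarray      # per-AP in-window maximum dF/F0
    detected: np.ndarray   # per-AP boolean, peak > k * noise SD
    noise_sd: float


@dataclass(frozen=True)
class PprResult:
    ppr: float | None      # None unless both APs detected
    roi_class: str         # first_only | second_only | both | none


def normalize_frap(trace: FrapTrace) -> np.ndarray:
    """Apply the background-and-reference normalization frame by frame."""
    denom = trace.f_nonbleached - trace.f_background
    bad = np.flatnonzero(denom == 0)
    if bad.size:
        raise ValidationError(f"zero normalization denominator at frame {bad[0]}")
    return (trace.f_bleach - trace.f_background) / denom


def fit_frap(normalized: np.ndarray, times_s: np.ndarray, bleach_time_s: float,
             fit_f0: bool = False) -> FrapFit:
    """Fit the hyperbolic recovery model to the post-bleach phase.

    The post-bleach floor f0 is fixed at the first post-bleach sample by
    default, which removes the degeneracy between f0 and the recovery extent
    on short traces; ``fit_f0`` frees it as a third parameter.
    """
    normalized = np.asarray(normalized, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    post = times_s > bleach_time_s
    if post.sum() < 10:
        raise ValidationError("need >= 10 post-bleach frames")
    tp = times_s[post] - bleach_time_s
    yp = normalized[post]
    f0 = float(yp[0])
    t_half0 = float(np.median(tp))

    try:
        if fit_f0:
            def model(t, r, t_half, f0_):
                return f0_ + (r / 100.0 - f0_) * t / (t_half + t)
            popt, _ = curve_fit(model, tp, yp, p0=[max(yp[-1], f0) * 100.0, t_half0, f0],
                                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                                maxfev=20000)
            r, t_half, f0 = popt
        else:
            def model(t, r, t_half):
                return f0 + (r / 100.0 - f0) * t / (t_half + t)
            popt, _ = curve_fit(model, tp, yp, p0=[max(yp[-1], f0) * 100.0, t_half0],
                                bounds=([-np.inf, 1e-9], [np.inf, np.inf]),
                                maxfev=20000)
            r, t_half = popt
    except RuntimeError as exc:
        raise FitError(f"hyperbolic FRAP fit did not converge: {exc}")
    return FrapFit(float(r), float(t_half), float(f0))


def compute_dff0(raw: np.ndarray, times_s: np.ndarray, baseline_window_s: float = 0.5,
                 background: np.ndarray | None = None) -> np.ndarray:
    """Normalize a raw ROI series to its pre-stimulus baseline.

    F0 is the mean over the initial ``baseline_window_s``.  When a dark
    background trace is supplied its mean is subtracted from the series
    first (stand-in for the acquisition software's background correction,
    whose exact form is tool-specific); otherwise no background handling
    is applied.
    """
    raw = np.asarray(raw, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if background is not None:
        raw = raw - float(np.mean(background))
    base = times_s < baseline_window_s
    if base.sum() < 5:
        raise ValidationError("baseline window must contain >= 5 frames")
    f0 = raw[base].mean()
    if f0 <= 0:
        raise ValidationError(f"non-positive baseline F0 = {f0:g}")
    return (raw - f0) / f0


def detect_responses(trace: GluTrace, k: float = 4.0, sync_window_s: float = 0.010
                     ) -> ResponseSet:
    """Per-AP peak detection against k times the baseline noise SD.

    The noise SD is the baseline-window SD of this ROI's dF/F0.  For each
    stimulus the response is the maximum dF/F0 within ``sync_window_s``
    after the stimulus time (inclusive window end), detected iff it exceeds
    ``k`` times the noise SD.
    """
    y = np.asarray(trace.dff0, dtype=float)
    t = np.asarray(trace.times_s, dtype=float)
    base = t < trace.baseline_window_s
    sd = float(y[base].std(ddof=1)) if base.sum() > 1 else 0.0
    peaks, detected = [], []
    for ts in np.asarray(trace.stim_times_s, dtype=float):
        win = (t >= ts) & (t <= ts + sync_window_s)
        pk = float(y[win].max()) if win.any() else 0.0
        peaks.append(pk)
        detected.append(pk > k * sd)
    return ResponseSet(np.array(peaks), np.array(detected, dtype=bool), sd)


def paired_pulse_ratio(responses: ResponseSet) -> PprResult:
    """PPR (peak2/peak1) and the ROI response class for a two-AP protocol."""
    if len(responses.peaks) != 2:
        raise ValidationError("paired-pulse analysis needs exactly 2 stimuli")
    d1, d2 = responses.detected
    if d1 and d2:
        return PprResult(float(responses.peaks[1] / responses.peaks[0]), "both")
    if d1:
        return PprResult(None, "first_only")
    if d2:
        return PprResult(None, "second_only")
    return PprResult(None, "none")


def cumulative_release(responses: ResponseSet) -> np.ndarray:
    """Running sum of per-AP peaks; undetected APs contribute zero."""
    if len(responses.peaks) < 2:
        raise ValidationError("need a train of >= 2 APs")
    contrib = np.where(responses.detected, responses.peaks, 0.0)
    return np.cumsum(contrib)


def svrr(cumulative: np.ndarray, last_n: int = 30) -> float:
    """Replenishment rate: OLS slope of the cumulative signal over the final
    ``last_n`` stimuli (stimulus number as abscissa)."""
    cumulative = np.asarray(cumulative, dtype=float)
    if len(cumulative) < last_n:
        raise ValidationError(f"need >= {last_n} points, got {len(cumulative)}")
    y = cumulative[-last_n:]
    x = np.arange(len(cumulative) - last_n, len(cumulative), dtype=float) + 1
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)
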