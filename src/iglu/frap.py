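"""FRAP normalization, single-exponential fitting and mobility metrics.

A FRAP experiment yields three raw intensity channels over time: the
bleached region of interest, an unbleached reference region (correcting for
acquisition photobleaching), and a background region.  The recovery curve is
computed by double normalization,

    F(t) = [mean_pre(ref') / ref'(t)] * [roi'(t) / mean_pre(roi')],

where primes denote background-subtracted channels and ``mean_pre`` averages
all pre-bleach frames (the bleach scans themselves belong to neither
segment).  By construction the pre-bleach mean of F is 1 and any
multiplicative acquisition-bleach trend shared by ROI and reference cancels.

Recovery is fit with a single exponential,

    F(t) = Finf - (Finf - F0) * exp(-(t - t_bleach)/tau),

on the post-bleach samples.  The mobile fraction is (Finf - F0)/(1 - F0) on
the double-normalized scale and the immobile fraction is its complement —
the gap between the pre-bleach baseline and the recovery asymptote.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["FRAPCurve", "FRAPFit", "double_normalize", "fit_frap", "quality_metrics", "analyze_frap"]


@dataclass
class FRAPCurve:
    """Raw FRAP triplet: ROI, reference and background channels.

    ``bleach_end_index`` is the index of the first post-bleach sample; all
    earlier samples are pre-bleach (bleach scans are not sampled).
    """

    times: np.ndarray
    roi_raw: np.ndarray
    ref_raw: np.ndarray
    bg_raw: np.ndarray
    bleach_end_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_raw = np.asarray(self.roi_raw, dtype=float)
        self.ref_raw = np.asarray(self.ref_raw, dtype=float)
        self.bg_raw = np.asarray(self.bg_raw, dtype=float)
        n = self.times.size
        for name in ("roi_raw", "ref_raw", "bg_raw"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length does not match times")
        if not 0 < self.bleach_end_index < n:
            raise ValueError("bleach_end_index must leave a non-empty pre-bleach segment")
        if np.any(self.ref_raw <= self.bg_raw):
            raise ValueError("reference must exceed background pointwise")

    @property
    def n_pre(self) -> int:
        return self.bleach_end_index

    @property
    def post_times(self) -> np.ndarray:
        return self.times[self.bleach_end_index :]


@dataclass
class FRAPFit:
    """Single-exponential recovery fit.

    tau is the recovery time constant (s); F0 and Finf the fitted first
    post-bleach level and asymptote on the double-normalized scale;
    mobile_fraction + immobile_fraction == 1 exactly.
    """

    tau: float
    F0: float
    Finf: float
    mobile_fraction: float
    immobile_fraction: float
    r_squared: float
    converged: bool = True
    message: str = ""


def double_normalize(curve: FRAPCurve) -> np.ndarray:
    """Double-normalized recovery series (pre-bleach mean exactly 1)."""
    roi = curve.roi_raw - curve.bg_raw
    ref = curve.ref_raw - curve.bg_raw
    if np.any(ref <= 0):
        raise ValueError("background-subtracted reference must stay positive")
    pre = slice(0, curve.bleach_end_index)
    roi_pre = roi[pre].mean()
    ref_pre = ref[pre].mean()
    if roi_pre <= 0:
        raise ValueError("pre-bleach ROI signal must be positive")
    return (ref_pre / ref) * (roi / roi_pre)


def fit_frap(
    times: np.ndarray,
    F: np.ndarray,
    bleach_end_index: int,
) -> FRAPFit:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Initialization: F0 from the first post-bleach sample, Finf from the mean
    of the last 10% of samples, tau from the time to half recovery divided by
    ln 2.  Bounds: tau in (0, 10x post-bleach span], Finf in [0, 1.5].
    Non-convergence returns a flagged fit (``converged=False``) carrying the
    solver message rather than raising.
    """
    times = np.asarray(times, dtype=float)
    F = np.asarray(F, dtype=float)
    post_t = times[bleach_end_index:]
    post_f = F[bleach_end_index:]
    if post_t.size < 5:
        raise ValueError("need at least 5 post-bleach samples to fit")
    t_bleach = post_t[0]
    tr = post_t - t_bleach
    span = tr[-1] if tr[-1] > 0 else 1.0

    f0_init = float(post_f[0])
    if f0_init >= 1.0:
        raise ValueError("first post-bleach sample is not below baseline: no bleach")
    n_tail = max(1, post_f.size // 10)
    finf_init = float(post_f[-n_tail:].mean())

    gap = finf_init - f0_init
    if abs(gap) < 1e-10:
        # fully immobile: no recovery amplitude, tau unidentifiable
        return FRAPFit(
            tau=math.inf,
            F0=f0_init,
            Finf=finf_init,
            mobile_fraction=0.0,
            immobile_fraction=1.0,
            r_squared=1.0,
            converged=True,
            message="no recovery: immobile curve",
        )
    half = f0_init + 0.5 * gap
    above = np.flatnonzero(post_f >= half) if gap > 0 else np.flatnonzero(post_f <= half)
    t_half = tr[above[0]] if above.size else span / 4.0
    tau_init = max(t_half / math.log(2.0), 1e-6 * span)

    def model(t, finf, f0, tau):
        return finf - (finf - f0) * np.exp(-t / tau)

    try:
        popt, _ = curve_fit(
            model,
            tr,
            post_f,
            p0=[finf_init, f0_init, tau_init],
            bounds=([0.0, -0.5, 1e-12], [1.5, 1.0, 10.0 * span]),
            maxfev=20000,
        )
        finf, f0, tau = (float(v) for v in popt)
        converged, message = True, ""
    except RuntimeError as err:  # solver failed: flag, report initial guesses
        finf, f0, tau = finf_init, f0_init, tau_init
        converged, message = False, str(err)

    resid = post_f - model(tr, finf, f0, tau)
    ss_tot = float(np.sum((post_f - post_f.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    mobile = (finf - f0) / (1.0 - f0) if f0 < 1.0 else 0.0
    return FRAPFit(
        tau=tau,
        F0=f0,
        Finf=finf,
        mobile_fraction=mobile,
        immobile_fraction=1.0 - mobile,
        r_squared=r2,
        converged=converged,
        message=message,
    )


def quality_metrics(curve: FRAPCurve) -> dict:
    """Bleach depth and gap ratio of a FRAP acquisition.

    ``bleach_depth`` is the normalized fluorescence drop at the first
    post-bleach frame, 1 - F(bleach_end).  ``gap_ratio`` compares the
    background-subtracted reference totals after versus before the bleach,
    quantifying the share of the total probe pool lost to the bleach.
    """
    F = double_normalize(curve)
    ref = curve.ref_raw - curve.bg_raw
    pre = ref[: curve.bleach_end_index].mean()
    post = ref[curve.bleach_end_index :].mean()
    return {
        "bleach_depth": float(1.0 - F[curve.bleach_end_index]),
        "gap_ratio": float(post / pre),
    }


def analyze_frap(curve: FRAPCurve) -> tuple[np.ndarray, FRAPFit, dict]:
    """Convenience wrapper: normalize, fit and compute quality metrics."""
    F = double_normalize(curve)
    fit = fit_frap(curve.times, F, curve.bleach_end_index)
    return F, fit, quality_metrics(curve)
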