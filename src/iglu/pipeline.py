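"""Detection pipeline for single-synapse glutamate-sensor recordings.

The pipeline mirrors a failure-analysis workflow for iGluSnFR movies acquired
at 50 Hz: circular ROIs (2 µm diameter) are drawn around fluorescence maxima
located during high-frequency stimulation, per-ROI intensity traces are
extracted, linearly detrended and smoothed, and quantal release events are
detected against a moving baseline.  Spontaneous events are threshold
crossings k standard deviations above a trailing 4-s moving average; evoked
events are time-locked to field stimuli (success iff the response window
within 0.3 s of the stimulus exceeds the same threshold).  Release
probability is the fraction of stimuli with a detected response; spontaneous
frequency is events per second.

Conventions
-----------
* Frames are 0-based; frame ``i`` of a trace with origin ``t0`` and sampling
  interval ``dt`` has timestamp ``t0 + i*dt``.  All times are seconds,
  amplitudes are background-subtracted arbitrary units (not dF/F).
* Detectors take the *background-subtracted, unsmoothed* trace.  Smoothing
  (3- or 5-point centred moving mean) is applied internally to the series on
  which threshold crossings are evaluated, while the noise scale is a robust
  SD (1.4826 x MAD) of the unsmoothed trace over the same trailing window, so
  the threshold is expressed in raw-noise units.  Measuring the SD on the
  smoothed series instead would triple the effective false-event rate at a
  3-SD threshold, far above realistic per-synapse spontaneous rates.
* Event amplitudes are read off the unsmoothed trace at the detected peak, so
  that on clean data amplitude recovery is limited only by 50-Hz sampling of
  the event kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Trace",
    "ROISet",
    "DetectionParams",
    "SynapseSummary",
    "EVENT_COLUMNS",
    "events_frame",
    "empty_events",
    "find_rois",
    "extract_trace",
    "subtract_background",
    "smooth",
    "detect_spontaneous",
    "detect_evoked",
    "release_probability",
    "spontaneous_frequency",
    "summarize_synapse",
    "compare_pre_post",
    "coverslip_summarize",
]

#: canonical event-table schema shared by generators and detectors
EVENT_COLUMNS = ("time_s", "amplitude", "kind", "synapse_id")

# robust-SD scale factor: SD = MAD_SCALE * median(|x - median(x)|) for Gaussian x
MAD_SCALE = 1.4826


def events_frame(
    times: Sequence[float],
    amplitudes: Sequence[float],
    kind: str | Sequence[str],
    synapse_id: int | Sequence[int] = 0,
) -> pd.DataFrame:
    """Assemble an event table with the canonical column layout."""
    times = np.asarray(times, dtype=float)
    n = times.size
    if isinstance(kind, str):
        kind = [kind] * n
    if np.isscalar(synapse_id):
        synapse_id = [int(synapse_id)] * n
    df = pd.DataFrame(
        {
            "time_s": times,
            "amplitude": np.asarray(amplitudes, dtype=float),
            "kind": list(kind),
            "synapse_id": list(synapse_id),
        }
    )
    return df.sort_values("time_s", kind="stable", ignore_index=True)


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {"time_s": pd.Series(dtype=float), "amplitude": pd.Series(dtype=float),
         "kind": pd.Series(dtype=object), "synapse_id": pd.Series(dtype=int)}
    )


@dataclass
class Trace:
    """Uniformly sampled fluorescence time series for one ROI."""

    values: np.ndarray
    dt: float = 0.02
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite values")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    def index_of(self, t: float) -> int:
        """Nearest frame index of time ``t`` (must fall inside the trace)."""
        i = int(round((t - self.t0) / self.dt))
        if i < 0 or i >= self.values.size:
            raise ValueError(f"time {t} s outside trace span")
        return i


@dataclass
class ROISet:
    """Circular ROIs: centers in µm and a common diameter."""

    centers: np.ndarray  # (n, 2) as (x, y) µm
    diameter: float = 2.0

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")

    def __len__(self) -> int:
        return self.centers.shape[0]


@dataclass
class DetectionParams:
    """Thresholding parameters of the event detectors.

    k
        threshold in robust-SD multiples above the moving baseline.
    baseline_window
        trailing moving-average window, seconds.
    evoked_window
        post-stimulus response window, seconds.
    smooth_points
        centred moving-mean width (3 or 5 samples).
    refractory
        minimum separation of spontaneous events; closer peaks merge, the
        larger one is kept.
    """

    k: float = 3.0
    baseline_window: float = 4.0
    evoked_window: float = 0.3
    smooth_points: int = 3
    refractory: float = 0.1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")
        if self.baseline_window <= 0 or self.evoked_window <= 0:
            raise ValueError("windows must be positive")
        if self.smooth_points not in (3, 5):
            raise ValueError("smooth_points must be 3 or 5")
        if self.refractory < 0:
            raise ValueError("refractory must be non-negative")


@dataclass
class SynapseSummary:
    """Per-synapse release metrics from one recording."""

    pr: float
    spont_freq: float
    mean_amp: float
    n_stims: int
    duration: float
    n_successes: int = 0
    n_spont: int = 0
    synapse_id: int = 0


# ---------------------------------------------------------------------------
# ROI selection and trace extraction
# ---------------------------------------------------------------------------

def _pixel_centers(n: int, pixel_size: float) -> np.ndarray:
    return (np.arange(n) + 0.5) * pixel_size


def find_rois(
    stack: np.ndarray,
    stim_interval: tuple[int, int],
    pixel_size: float,
    diameter: float = 2.0,
    min_separation: float = 2.0,
    min_prominence: float | None = None,
) -> ROISet:
    """Locate synaptic ROIs as local maxima of the stimulation-summed image.

    Frames ``stim_interval[0]:stim_interval[1]`` are summed; local maxima
    above ``min_prominence`` (default: 10% of the summed image's dynamic
    range above its minimum) become ROI centers, greedily pruned so that
    centers are at least ``min_separation`` µm apart with the brightest peak
    winning.
    """
    from skimage.feature import peak_local_max

    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, y, x)")
    f0, f1 = stim_interval
    if not (0 <= f0 < f1 <= stack.shape[0]):
        raise ValueError("stim_interval outside stack")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")

    summed = stack[f0:f1].sum(axis=0)
    rng_ = float(summed.max() - summed.min())
    if rng_ == 0.0:
        warnings.warn("flat summed image: no ROIs found", stacklevel=2)
        return ROISet(np.empty((0, 2)), diameter)
    if min_prominence is None:
        min_prominence = 0.1 * rng_
    min_dist_px = max(1, int(np.ceil(min_separation / pixel_size)))
    # peak_local_max orders peaks by intensity, enforcing min_distance greedily
    peaks = peak_local_max(
        summed,
        min_distance=min_dist_px,
        threshold_abs=float(summed.min()) + min_prominence,
        exclude_border=False,
    )
    if peaks.size == 0:
        warnings.warn("no local maxima above prominence: empty ROI set", stacklevel=2)
        return ROISet(np.empty((0, 2)), diameter)
    ys = _pixel_centers(stack.shape[1], pixel_size)[peaks[:, 0]]
    xs = _pixel_centers(stack.shape[2], pixel_size)[peaks[:, 1]]
    return ROISet(np.column_stack([xs, ys]), diameter)


def extract_trace(
    stack: np.ndarray,
    center: Sequence[float],
    diameter: float,
    pixel_size: float,
    dt: float = 0.02,
    t0: float = 0.0,
) -> Trace:
    """Mean intensity per frame over pixels whose centers lie in the ROI disk."""
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, y, x)")
    cx, cy = float(center[0]), float(center[1])
    xs = _pixel_centers(stack.shape[2], pixel_size)
    ys = _pixel_centers(stack.shape[1], pixel_size)
    r = diameter / 2.0
    if not (0.0 <= cx <= stack.shape[2] * pixel_size and 0.0 <= cy <= stack.shape[1] * pixel_size):
        raise ValueError("ROI center outside image")
    mask = (xs[None, :] - cx) ** 2 + (ys[:, None] - cy) ** 2 <= r**2
    if not mask.any():
        raise ValueError("ROI contains no pixel centers")
    vals = stack[:, mask].mean(axis=1)
    return Trace(vals, dt=dt, t0=t0)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def subtract_background(trace: Trace) -> Trace:
    """Remove the ordinary-least-squares line fit over the full trace.

    Makes detection invariant to any affine trend in the raw signal (constant
    offsets and slow linear drifts of the background).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 samples to fit a line")
    t = trace.times
    slope, intercept = np.polyfit(t, trace.values, 1)
    return Trace(trace.values - (intercept + slope * t), dt=trace.dt, t0=trace.t0)


def smooth(trace: Trace, smooth_points: int = 3) -> Trace:
    """Centred moving mean over 3 or 5 samples; edge windows shrink."""
    if smooth_points not in (3, 5):
        raise ValueError("smooth_points must be 3 or 5")
    sm = (
        pd.Series(trace.values)
        .rolling(smooth_points, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return Trace(sm, dt=trace.dt, t0=trace.t0)


def _trailing_stats(values: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Trailing-window mean and robust SD for each frame.

    Entry ``i`` (for ``i >= window``) summarises ``values[i-window:i]`` — the
    window strictly precedes the frame, so an event never inflates its own
    baseline or threshold.  Entries ``i < window`` are NaN.
    """
    n = values.size
    base = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    if n <= window:
        return base, sd
    win = sliding_window_view(values, window)  # row j = values[j:j+window]
    med = np.median(win, axis=1)
    mad = np.median(np.abs(win - med[:, None]), axis=1)
    means = win.mean(axis=1)
    base[window:] = means[: n - window]
    sd[window:] = MAD_SCALE * mad[: n - window]
    return base, sd


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def detect_spontaneous(
    trace: Trace,
    params: DetectionParams | None = None,
    synapse_id: int = 0,
) -> pd.DataFrame:
    """Detect spontaneous quantal events on a background-subtracted trace.

    Samples of the smoothed trace exceeding ``baseline + k*SD`` (trailing
    moving average / trailing robust SD of the raw trace) are grouped into
    runs; each run yields one event at its smoothed maximum; events closer
    than the refractory interval merge, keeping the larger peak.  Amplitude
    is the unsmoothed maximum around the peak minus the local baseline.
    """
    params = params or DetectionParams()
    window = int(round(params.baseline_window / trace.dt))
    if len(trace) <= window:
        raise ValueError("trace shorter than the baseline window")

    smoothed = smooth(trace, params.smooth_points).values
    base, sd = _trailing_stats(trace.values, window)
    with np.errstate(invalid="ignore"):
        above = smoothed > base + params.k * sd
    above &= ~np.isnan(base)

    half = params.smooth_points // 2
    peaks: list[tuple[int, float]] = []  # (frame, smoothed height above baseline)
    for s, e in _runs(above):
        p = s + int(np.argmax(smoothed[s:e]))
        peaks.append((p, smoothed[p] - base[p]))

    # refractory merge: sweep in time, keep the larger of two close peaks
    refr = int(round(params.refractory / trace.dt))
    merged: list[tuple[int, float]] = []
    for p, h in peaks:
        if merged and p - merged[-1][0] < refr:
            if h > merged[-1][1]:
                merged[-1] = (p, h)
        else:
            merged.append((p, h))

    times, amps = [], []
    for p, _h in merged:
        lo = max(0, p - half)
        hi = min(len(trace), p + half + 1)
        amps.append(float(trace.values[lo:hi].max() - base[p]))
        times.append(trace.t0 + p * trace.dt)
    if not times:
        return empty_events()
    return events_frame(times, amps, "spontaneous", synapse_id)


def detect_evoked(
    trace: Trace,
    stim_times: Sequence[float],
    params: DetectionParams | None = None,
    synapse_id: int = 0,
) -> pd.DataFrame:
    """Detect evoked successes time-locked to each stimulus.

    For each stimulus, the baseline and robust SD come from the trailing
    ``baseline_window`` ending at the stimulus frame (response excluded); the
    stimulus is a success iff the smoothed trace within ``evoked_window`` of
    the stimulus exceeds ``baseline + k*SD``.  One event per successful
    stimulus, at the response-window maximum.
    """
    params = params or DetectionParams()
    stim_times = np.asarray(stim_times, dtype=float)
    if stim_times.size == 0:
        return empty_events()
    if np.any(np.diff(stim_times) <= params.evoked_window):
        raise ValueError(
            "inter-stimulus interval shorter than the evoked response window; "
            "response windows would overlap"
        )
    window = int(round(params.baseline_window / trace.dt))
    resp = int(round(params.evoked_window / trace.dt))
    smoothed = smooth(trace, params.smooth_points).values
    half = params.smooth_points // 2

    times, amps = [], []
    for st in stim_times:
        i = trace.index_of(st)
        if i < window:
            raise ValueError(
                f"stimulus at {st} s precedes a full baseline window "
                f"({params.baseline_window} s)"
            )
        win = trace.values[i - window : i]
        b = float(win.mean())
        med = np.median(win)
        sd = MAD_SCALE * float(np.median(np.abs(win - med)))
        hi = min(len(trace), i + resp + 1)
        seg = smoothed[i:hi]
        if seg.size == 0:
            continue
        p = i + int(np.argmax(seg))
        if smoothed[p] > b + params.k * sd:
            lo = max(i, p - half)
            up = min(hi, p + half + 1)
            times.append(trace.t0 + p * trace.dt)
            amps.append(float(trace.values[lo:up].max() - b))
    if not times:
        return empty_events()
    return events_frame(times, amps, "evoked", synapse_id)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def release_probability(evoked: pd.DataFrame, stim_times: Sequence[float]) -> float:
    """Detected responses divided by the number of stimulations (exact ratio)."""
    n_stims = len(stim_times)
    if n_stims == 0:
        raise ValueError("no stimulations: release probability undefined")
    n_succ = len(evoked)
    if n_succ > n_stims:
        raise ValueError("more successes than stimulations")
    return n_succ / n_stims


def spontaneous_frequency(events: pd.DataFrame, duration: float) -> float:
    """Event count divided by recording duration, Hz."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(events) / duration


def summarize_synapse(
    evoked: pd.DataFrame,
    spont: pd.DataFrame,
    stim_times: Sequence[float],
    duration: float,
    synapse_id: int = 0,
) -> SynapseSummary:
    """Bundle Pr, spontaneous frequency and mean amplitude for one synapse."""
    amps = pd.concat([evoked, spont])["amplitude"] if (len(evoked) or len(spont)) else pd.Series(dtype=float)
    pr = release_probability(evoked, stim_times) if len(stim_times) else 0.0
    return SynapseSummary(
        pr=pr,
        spont_freq=spontaneous_frequency(spont, duration),
        mean_amp=float(amps.mean()) if len(amps) else 0.0,
        n_stims=len(stim_times),
        duration=duration,
        n_successes=len(evoked),
        n_spont=len(spont),
        synapse_id=synapse_id,
    )


def compare_pre_post(pre: SynapseSummary, post: SynapseSummary) -> dict:
    """Post/pre ratios of Pr, spontaneous frequency and mean amplitude.

    A metric whose pre-bleach value is zero cannot be normalized; it is
    reported as NaN with an ``excluded`` flag rather than raising, matching
    per-synapse normalization workflows where such synapses are dropped from
    the ratio statistics but still counted.
    """
    if pre.synapse_id != post.synapse_id:
        raise ValueError("pre/post summaries refer to different synapses")

    def ratio(a: float, b: float) -> tuple[float, bool]:
        if b == 0:
            return float("nan"), True
        return a / b, False

    rel_pr, ex_pr = ratio(post.pr, pre.pr)
    rel_fr, ex_fr = ratio(post.spont_freq, pre.spont_freq)
    rel_am, ex_am = ratio(post.mean_amp, pre.mean_amp)
    return {
        "synapse_id": pre.synapse_id,
        "relative_pr": rel_pr,
        "relative_freq": rel_fr,
        "relative_amp": rel_am,
        "excluded_pr": ex_pr,
        "excluded_freq": ex_fr,
        "excluded_amp": ex_am,
    }


def coverslip_summarize(
    summaries: Iterable[SynapseSummary] | pd.DataFrame,
    grouping: Mapping[int, object] | Sequence[object],
) -> pd.DataFrame:
    """Unweighted per-coverslip means of the per-synapse metrics.

    Statistics downstream are computed on coverslip averages rather than on
    individual synapses, so each coverslip contributes one row (with its
    synapse count) regardless of how many synapses it holds.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "synapse_id": s.synapse_id,
                    "pr": s.pr,
                    "spont_freq": s.spont_freq,
                    "mean_amp": s.mean_amp,
                }
                for s in summaries
            ]
        )
    if df.empty:
        warnings.warn("no synapses to summarize", stacklevel=2)
        return pd.DataFrame(columns=["coverslip", "pr", "spont_freq", "mean_amp", "n_synapses"])
    if isinstance(grouping, Mapping):
        df["coverslip"] = df["synapse_id"].map(grouping)
    else:
        df["coverslip"] = list(grouping)
    if df["coverslip"].isna().any():
        raise ValueError("every synapse must map to a coverslip")
    out = (
        df.groupby("coverslip", sort=True)
        .agg(
            pr=("pr", "mean"),
            spont_freq=("spont_freq", "mean"),
            mean_amp=("mean_amp", "mean"),
            n_synapses=("synapse_id", "size"),
        )
        .reset_index()
    )
    return out
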