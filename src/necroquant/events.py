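"""Per-cell necrosis time-series analysis.

A necrotic touch neuron shows three ordered events during late
embryogenesis: a rise of cytoplasmic Ca2+ (reporter transients reaching
1.4-5x background), distinct cell swelling, and finally surface PS
exposure. This module detects those events on background-relative
intensity traces and radius tracks, characterizes Ca2+ peaks, and computes
windowed trapezoidal integrals of relative-intensity traces on their native
irregular time grid (units: fold*minutes).

Times are minutes post-first embryonic division. The default recording
schedule samples every 2.5 min on [560, 680] and every 5 min on [685, 900];
a trace must carry at least 10 time points to qualify for integral or
regression analysis (the curve-inclusion rule used when focal drift drops
frames).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RECORD_START",
    "FAST_END",
    "SLOW_START",
    "RECORD_END",
    "FULL_WINDOW",
    "PERIOD1",
    "PERIOD2",
    "MIN_TRACE_POINTS",
    "default_time_grid",
    "IntensityTrace",
    "EventTimes",
    "PeakMetrics",
    "TimeWindow",
    "CohortRatio",
    "detect_onset",
    "detect_swelling",
    "integrate_trace",
    "peak_metrics",
    "integral_ratio",
]

# Recording schedule and named analysis windows (minutes post-1st division).
RECORD_START = 560.0
FAST_END = 680.0
SLOW_START = 685.0
RECORD_END = 900.0
FAST_DT = 2.5
SLOW_DT = 5.0

MIN_TRACE_POINTS = 10


@dataclass(frozen=True)
class TimeWindow:
    """Named integration window with bounds in minutes."""

    name: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError("window lower bound must be below upper bound")


FULL_WINDOW = TimeWindow("full", 560.0, 800.0)
PERIOD1 = TimeWindow("period1", 560.0, 695.0)  # up to mean visible-swelling time
PERIOD2 = TimeWindow("period2", 696.0, 800.0)  # PS becomes detectable and grows


def default_time_grid() -> np.ndarray:
    """The default acquisition grid: 2.5-min steps on [560, 680], then
    5-min steps on [685, 900]."""
    fast = np.arange(RECORD_START, FAST_END + FAST_DT / 2, FAST_DT)
    slow = np.arange(SLOW_START, RECORD_END + SLOW_DT / 2, SLOW_DT)
    return np.concatenate([fast, slow])


@dataclass(frozen=True)
class IntensityTrace:
    """Background-relative intensity versus time for one cell and channel."""

    times: np.ndarray
    values: np.ndarray
    cell_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.size == 0 or t.shape != v.shape:
            raise ValueError("times and values must be matching nonempty 1-D arrays")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("relative intensities must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def qualifies(self) -> bool:
        """Curve-inclusion rule: at least 10 usable time points."""
        return self.n_points >= MIN_TRACE_POINTS


@dataclass(frozen=True)
class EventTimes:
    """Onset times (minutes) of the three necrosis events; None = not seen."""

    ca_onset: float | None = None
    swelling_onset: float | None = None
    ps_onset: float | None = None

    def ordered(self) -> bool:
        """Whether the present events respect Ca <= swelling <= PS."""
        seq = [t for t in (self.ca_onset, self.swelling_onset, self.ps_onset) if t is not None]
        return all(a <= b for a, b in zip(seq, seq[1:]))


@dataclass(frozen=True)
class PeakMetrics:
    """One supra-threshold excursion of a trace."""

    peak_value: float
    peak_time: float
    duration: float


def detect_onset(
    trace: IntensityTrace, threshold_fold: float = 1.2, min_run: int = 2
) -> float | None:
    """First time the trace exceeds ``threshold_fold`` for >= ``min_run``
    consecutive samples; None if it never does.

    The default threshold (1.2-fold of background) is the level that
    Ca2+ traces of ER-store-deficient (*crt-1*-like) cells never exceed, so
    it separates genuine release transients from baseline fluctuation.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    above = trace.values > threshold_fold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_run:
            return float(trace.times[i - min_run + 1])
    return None


def detect_swelling(
    times: np.ndarray, radii: np.ndarray, fold_threshold: float = 1.2
) -> float | None:
    """First time the equivalent cell radius exceeds ``fold_threshold`` times
    its initial value; None if the cell never swells."""
    times = np.asarray(times, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if times.shape != radii.shape or times.ndim != 1 or times.size == 0:
        raise ValueError("times and radii must be matching nonempty 1-D arrays")
    r0 = radii[0]
    if r0 <= 0:
        raise ValueError("initial radius must be positive")
    idx = np.nonzero(radii > fold_threshold * r0)[0]
    return float(times[idx[0]]) if idx.size else None


def integrate_trace(
    trace: IntensityTrace,
    window: TimeWindow = FULL_WINDOW,
    *,
    edge_mode: str = "interpolate",
    require_qualified: bool = True,
) -> float:
    """Trapezoidal integral of a relative-intensity trace over a window.

    Parameters
    ----------
    edge_mode : {"interpolate", "observed"}
        ``interpolate`` (default) linearly interpolates the trace to the
        exact window bounds; ``observed`` integrates only between observed
        samples inside the window (no interpolation across the edges).
    require_qualified : bool
        Enforce the >= 10-point curve-inclusion rule; pass False to
        integrate short traces anyway.

    Returns the integral in fold*minutes.
    """
    if require_qualified and not trace.qualifies:
        raise ValueError(
            f"trace has {trace.n_points} < {MIN_TRACE_POINTS} points; "
            "set require_qualified=False to integrate anyway"
        )
    if edge_mode not in ("interpolate", "observed"):
        raise ValueError("edge_mode must be 'interpolate' or 'observed'")
    t, v = trace.times, trace.values
    lo, hi = window.lower, window.upper
    if hi <= t[0] or lo >= t[-1]:
        raise ValueError("window lies outside the trace's time support")
    if lo < t[0] or hi > t[-1]:
        lo, hi = max(lo, float(t[0])), min(hi, float(t[-1]))
        warnings.warn(
            f"trace does not cover the full window; truncated to [{lo}, {hi}]",
            stacklevel=2,
        )
    inner = (t > lo) & (t < hi)
    if edge_mode == "interpolate":
        tt = np.concatenate([[lo], t[inner], [hi]])
        vv = np.concatenate([[np.interp(lo, t, v)], v[inner], [np.interp(hi, t, v)]])
    else:
        keep = (t >= lo) & (t <= hi)
        tt, vv = t[keep], v[keep]
        if tt.size < 2:
            raise ValueError("fewer than 2 observed points inside the window")
    return float(np.trapezoid(vv, tt))


def _crossing_time(t0: float, v0: float, t1: float, v1: float, level: float) -> float:
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def peak_metrics(trace: IntensityTrace, threshold_fold: float = 1.2) -> list[PeakMetrics]:
    """One record per maximal run of samples above the threshold.

    Durations are measured between the linearly interpolated threshold
    crossings flanking each run, so even a single supra-threshold sample
    has positive width; runs touching the trace ends start or stop at the
    end sample.
    """
    t, v = trace.times, trace.values
    above = v > threshold_fold
    peaks: list[PeakMetrics] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        start = (
            _crossing_time(t[i - 1], v[i - 1], t[i], v[i], threshold_fold) if i > 0 else float(t[0])
        )
        end = (
            _crossing_time(t[j], v[j], t[j + 1], v[j + 1], threshold_fold)
            if j + 1 < n
            else float(t[-1])
        )
        k = i + int(np.argmax(v[i : j + 1]))
        peaks.append(
            PeakMetrics(peak_value=float(v[k]), peak_time=float(t[k]), duration=end - start)
        )
        i = j + 1
    return peaks


@dataclass(frozen=True)
class CohortRatio:
    """Integral summary of a test cohort relative to a reference cohort."""

    percent: float
    test_mean: float
    test_sem: float
    reference_mean: float
    reference_sem: float
    n_test: int
    n_reference: int


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def integral_ratio(test: np.ndarray, reference: np.ndarray) -> CohortRatio:
    """Cohort mean integral of ``test`` as a percentage of ``reference``."""
    test = np.asarray(test, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if test.size == 0 or reference.size == 0:
        raise ValueError("both cohorts must be nonempty")
    ref_mean = reference.mean()
    if ref_mean <= 0:
        raise ValueError("reference cohort mean must be positive")
    return CohortRatio(
        percent=100.0 * test.mean() / ref_mean,
        test_mean=float(test.mean()),
        test_sem=_sem(test),
        reference_mean=float(ref_mean),
        reference_sem=_sem(reference),
        n_test=test.size,
        n_reference=reference.size,
    )
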