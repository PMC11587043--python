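"""Segmentation of constant-power plus all-out (CPT) traces.

Two rules, both operating on sample-aligned boundaries:

* **task failure** -- the prescribed power is considered lost at the start of
  the first contiguous run of at least ``lapse_s`` seconds in which power
  stays below ``prescribed_power - tolerance_w``.  The band is one-sided:
  over-performing never signals failure.
* **asymptote plateau** -- the all-out decline has levelled out at the
  earliest time from which every sliding least-squares window of
  ``window_s`` seconds inside a ``hold_s``-second hold has absolute slope
  at most ``slope_w_per_s``.

All thresholds are explicit parameters (and pipeline-config keys) because
the underlying protocol describes the events qualitatively; the defaults
here are the package's operationalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import PowerTrace

__all__ = [
    "SegmentationError",
    "CptSegmentation",
    "detect_failure",
    "detect_plateau",
    "segment_cpt",
]


class SegmentationError(RuntimeError):
    """Raised when a segmentation rule cannot be satisfied on a trace."""


@dataclass(frozen=True)
class CptSegmentation:
    """Boundary times of the three CPT phases, at sample resolution."""

    t_fail: float
    t_plateau_start: float
    t_end: float
    tolerance_w: float
    plateau_rule: dict

    def __post_init__(self) -> None:
        if not (0 < self.t_fail <= self.t_plateau_start <= self.t_end):
            raise SegmentationError("segmentation boundaries out of order")


def _first_run_start(below: np.ndarray, min_len: int) -> int | None:
    """Index of the first run of >= min_len consecutive True values."""
    if min_len <= 1:
        hits = np.flatnonzero(below)
        return int(hits[0]) if hits.size else None
    x = below.astype(np.int64)
    # vectorized run-length: cumulative count of Trues, reset at every False
    csum = np.cumsum(x)
    reset = np.where(x == 0, csum, 0)
    run = csum - np.maximum.accumulate(reset)
    hits = np.flatnonzero(run >= min_len)
    if hits.size == 0:
        return None
    return int(hits[0]) - min_len + 1


def detect_failure(trace: PowerTrace, prescribed_power: float,
                   tolerance_w: float = 10.0, lapse_s: float = 10.0) -> float:
    """Time at which the prescribed power is first lost for ``lapse_s``.

    Returns the start time of the first contiguous run of at least
    ``lapse_s`` seconds with power below ``prescribed_power - tolerance_w``.

    Raises
    ------
    SegmentationError
        If the trace never leaves the maintenance band for long enough, or
        is shorter than ``lapse_s``.
    """
    if prescribed_power <= 0:
        raise ValueError("prescribed_power must be > 0")
    if trace.duration < lapse_s:
        raise SegmentationError("trace shorter than the failure lapse")
    below = trace.power < prescribed_power - tolerance_w
    min_len = max(1, int(np.ceil(lapse_s * trace.fs - 1e-9)))
    # Count a sample as covering one sampling interval; a run of min_len
    # samples spans lapse_s seconds under the half-open interval convention.
    idx = _first_run_start(below, min_len)
    if idx is None:
        raise SegmentationError("no failure found: power never left the maintenance band")
    return float(trace.time[idx])


def _window_slopes(power: np.ndarray, fs: float, m: int) -> np.ndarray:
    """Least-squares slope (W/s) of every length-``m`` sample window."""
    t = np.arange(m) / fs
    tc = t - t.mean()
    weights = tc / np.sum(tc * tc)
    # slope_i = sum_j weights[j] * power[i + j]
    return np.convolve(power, weights[::-1], mode="valid")


def detect_plateau(trace: PowerTrace, t_fail: float, window_s: float = 60.0,
                   slope_w_per_s: float = 0.1, hold_s: float = 60.0) -> tuple[float, float]:
    """Locate the post-failure asymptote plateau.

    Returns ``(t_plateau_start, t_end)`` where ``t_plateau_start`` is the
    earliest time at or after ``t_fail`` from which every sliding
    ``window_s`` window inside the following ``hold_s`` seconds has
    least-squares slope within ``slope_w_per_s``, and ``t_end`` is the end
    of the flat region (at least ``t_plateau_start + hold_s``, extended to
    the trace end while windows stay flat).
    """
    if window_s > hold_s:
        raise ValueError("window_s must not exceed hold_s")
    fs = trace.fs
    i_fail = trace.index_at(t_fail)
    if trace.t_end - trace.time[i_fail] < hold_s:
        raise SegmentationError("not enough data after failure for the plateau hold")
    m = int(round(window_s * fs)) + 1  # samples per window, inclusive ends
    slopes = _window_slopes(trace.power, fs, m)  # start index i covers [i, i+m-1]
    flat = np.abs(slopes) <= slope_w_per_s
    # A candidate start i qualifies if window starts i .. i + r are all flat,
    # with r chosen so the last window ends hold_s after the candidate start.
    r = int(round((hold_s - window_s) * fs))
    n_starts = flat.size
    if i_fail >= n_starts:
        raise SegmentationError("not enough data after failure for the plateau hold")
    # runs[i] = number of consecutive flat windows starting at i
    rev = flat[::-1].astype(np.int64)
    csum = np.cumsum(rev)
    reset = np.where(rev == 0, csum, 0)
    runs = (csum - np.maximum.accumulate(reset))[::-1]
    candidates = np.flatnonzero(runs[i_fail:] >= r + 1)
    if candidates.size == 0:
        raise SegmentationError("no plateau satisfying the slope rule before trace end")
    ok = i_fail + int(candidates[0])
    run_end = ok + int(runs[ok]) - 1  # last flat window start in the run
    i_end = min(run_end + m - 1, trace.n - 1)
    return float(trace.time[ok]), float(trace.time[i_end])


def segment_cpt(trace: PowerTrace, prescribed_power: float,
                tolerance_w: float = 10.0, lapse_s: float = 10.0,
                window_s: float = 60.0, slope_w_per_s: float = 0.1,
                hold_s: float = 60.0) -> CptSegmentation:
    """Compose failure and plateau detection into a full CPT segmentation."""
    t_fail = detect_failure(trace, prescribed_power, tolerance_w, lapse_s)
    t_plateau, t_end = detect_plateau(trace, t_fail, window_s, slope_w_per_s, hold_s)
    return CptSegmentation(
        t_fail=t_fail,
        t_plateau_start=t_plateau,
        t_end=t_end,
        tolerance_w=tolerance_w,
        plateau_rule={"window_s": window_s, "slope_w_per_s": slope_w_per_s,
                      "hold_s": hold_s},
    )
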