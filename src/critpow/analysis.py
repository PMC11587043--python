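"""End-power (EP) and W' measurements for all-out and constant-power tests.

The two protocol quantities computed here are:

* **EP** -- mean power over the final 30 s of an all-out effort; the stable
  end power of a 3-minute all-out test estimates critical power.
* **W'** -- the power-time integral above a reference power.  For the 3MT
  the reference is the test's own EP.  For a constant-power plus all-out
  test (CPT) the integral is split at task failure into a *constant-power*
  component (work above the reference while the prescribed power was held)
  and an *unaccounted* component (work above the reference during the
  post-failure all-out decline to the asymptote); their sum is the total W'.

For CPTs the reference EP is normally the athlete's 3MT EP.  When the
prescribed power sits barely above the reference, second-to-second power
fluctuation can drive the constant-power integral negative; in that case
both components are recomputed against the test's own EP (the fallback),
which is flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .segmentation import CptSegmentation
from .trace import DURATION_BINS, PowerTrace, TestMeta

__all__ = [
    "AnalysisError",
    "ThreeMtResult",
    "CptResult",
    "integrate_above",
    "analyze_3mt",
    "analyze_cpt",
    "duration_bin",
    "DEFAULT_BIN_EDGES_S",
]

#: Half-open bin edges (s) on the constant-phase duration: [0,60), [60,180),
#: [180,360), [360,inf) map to the four duration bins.
DEFAULT_BIN_EDGES_S = (60.0, 180.0, 360.0)


class AnalysisError(RuntimeError):
    """Raised when a trace cannot support the requested measurement."""


@dataclass(frozen=True)
class ThreeMtResult:
    """EP and W' of a 3-minute all-out test."""

    ep: float
    w_prime: float
    ep_window_s: float
    test_duration_s: float

    def __post_init__(self) -> None:
        if self.w_prime < 0 and not np.isclose(self.w_prime, 0.0):
            raise AnalysisError("3MT w_prime must be >= 0")


@dataclass(frozen=True)
class CptResult:
    """W' partition of one constant-power plus all-out test.

    ``total_w_prime`` is always exactly ``constant_w_prime +
    unaccounted_w_prime``; it is computed, never stored independently.
    """

    ep_individual: float
    ep_reference: float
    constant_w_prime: float
    unaccounted_w_prime: float
    used_fallback: bool
    duration_bin: str
    constant_duration_s: float
    prescribed_rectangle_j: Optional[float] = None

    @property
    def total_w_prime(self) -> float:
        return self.constant_w_prime + self.unaccounted_w_prime

    def __post_init__(self) -> None:
        if self.duration_bin not in DURATION_BINS:
            raise AnalysisError(f"unknown duration bin {self.duration_bin!r}")


def duration_bin(constant_duration_s: float,
                 bin_edges_s: tuple[float, ...] = DEFAULT_BIN_EDGES_S) -> str:
    """Duration bin label for a constant-phase duration (half-open edges)."""
    idx = int(np.searchsorted(bin_edges_s, constant_duration_s, side="right"))
    return DURATION_BINS[idx]


def _value_at(trace: PowerTrace, t: float) -> float:
    """Linearly interpolated power at time ``t``."""
    return float(np.interp(t, trace.time, trace.power))


def integrate_above(trace: PowerTrace, reference: float,
                    t0: Optional[float] = None, t1: Optional[float] = None,
                    clip_negative: bool = False) -> float:
    """Trapezoidal integral of ``power - reference`` over ``[t0, t1]``, joules.

    Endpoints not on the sample grid are linearly interpolated.  With
    ``clip_negative`` the contribution of each sampling interval is floored
    at zero before summation; by default the integral is signed, so
    sub-reference excursions subtract (which is what makes a negative
    constant-power W' detectable).
    """
    eps = 1e-9
    if t0 is None:
        t0 = trace.t_start
    if t1 is None:
        t1 = trace.t_end
    if t0 >= t1:
        raise AnalysisError("integration window must satisfy t0 < t1")
    if t0 < trace.t_start - eps or t1 > trace.t_end + eps:
        raise AnalysisError("integration window outside trace")
    inside = (trace.time > t0 + eps) & (trace.time < t1 - eps)
    t = np.concatenate(([t0], trace.time[inside], [t1]))
    y = np.concatenate(([_value_at(trace, t0)], trace.power[inside],
                        [_value_at(trace, t1)])) - reference
    dt = np.diff(t)
    contrib = 0.5 * (y[:-1] + y[1:]) * dt
    if clip_negative:
        contrib = np.clip(contrib, 0.0, None)
    return float(np.sum(contrib))


def _tail_mean(trace: PowerTrace, t_end: float, window_s: float) -> float:
    """Mean power over the samples in ``[t_end - window_s, t_end]``."""
    sel = (trace.time >= t_end - window_s - 1e-9) & (trace.time <= t_end + 1e-9)
    return float(np.mean(trace.power[sel]))


def analyze_3mt(trace: PowerTrace, ep_window_s: float = 30.0,
                clip_negative: bool = False) -> ThreeMtResult:
    """EP (mean of the final ``ep_window_s``) and W' (integral above EP)."""
    if trace.duration < ep_window_s:
        raise AnalysisError("trace shorter than the EP window")
    ep = _tail_mean(trace, trace.t_end, ep_window_s)
    w_prime = integrate_above(trace, ep, trace.t_start, trace.t_end,
                              clip_negative=clip_negative)
    return ThreeMtResult(ep=ep, w_prime=w_prime, ep_window_s=ep_window_s,
                         test_duration_s=trace.duration)


def analyze_cpt(trace: PowerTrace, meta: TestMeta, seg: CptSegmentation,
                ep_reference: float, ep_window_s: float = 30.0,
                clip_negative: bool = False,
                bin_edges_s: tuple[float, ...] = DEFAULT_BIN_EDGES_S) -> CptResult:
    """Partition a CPT into constant-power and unaccounted W'.

    ``ep_reference`` is the reference power against which work is counted
    (normally the athlete's 3MT EP).  If the constant-power component comes
    out negative, both components are recomputed against the test's own EP
    and the result is flagged ``used_fallback``.
    """
    if ep_reference <= 0:
        raise AnalysisError("ep_reference must be > 0")
    if seg.t_end - seg.t_plateau_start < ep_window_s:
        raise AnalysisError("plateau shorter than the EP window")
    ep_individual = _tail_mean(trace, seg.t_end, ep_window_s)

    def _parts(ref: float) -> tuple[float, float]:
        constant = integrate_above(trace, ref, trace.t_start, seg.t_fail,
                                   clip_negative=clip_negative)
        unaccounted = integrate_above(trace, ref, seg.t_fail, seg.t_end,
                                      clip_negative=clip_negative)
        return constant, unaccounted

    constant, unaccounted = _parts(ep_reference)
    used_fallback = False
    ref_used = ep_reference
    if constant < 0:
        constant, unaccounted = _parts(ep_individual)
        used_fallback = True
        ref_used = ep_individual

    constant_duration = seg.t_fail - trace.t_start
    rectangle = None
    if meta.prescribed_power is not None:
        rectangle = (meta.prescribed_power - ref_used) * constant_duration
    return CptResult(
        ep_individual=ep_individual,
        ep_reference=ref_used,
        constant_w_prime=constant,
        unaccounted_w_prime=unaccounted,
        used_fallback=used_fallback,
        duration_bin=duration_bin(constant_duration, bin_edges_s),
        constant_duration_s=constant_duration,
        prescribed_rectangle_j=rectangle,
    )
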