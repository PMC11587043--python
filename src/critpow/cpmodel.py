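"""Two-parameter critical-power model fitted from (power, duration) points.

The power-1/time linearization of the hyperbolic power-duration
relationship,

    P = CP + W' * (1 / t),

is fitted by ordinary least squares of power on reciprocal duration: the
intercept is critical power CP (watts) and the slope is the anaerobic work
capacity W' (joules).  The model object follows the usual build-then-fit
pattern: construct a :class:`CriticalPowerModel` from data, call
:meth:`~CriticalPowerModel.fit`, and read estimates, standard errors and
diagnostics off the returned :class:`CriticalPowerFit`, which also provides
power prescription and time-to-exhaustion prediction.

The equivalent work-time form  W = CP * t + W'  is available as a
cross-check (:func:`fit_work_time`); on well-conditioned data the two forms
agree closely, and on model-generated data both are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CriticalPowerModel",
    "CriticalPowerFit",
    "fit_power_inverse_time",
    "fit_work_time",
]


@dataclass(frozen=True)
class CriticalPowerFit:
    """Estimates and diagnostics of a two-parameter critical-power fit."""

    cp: float
    w_prime: float
    se_cp: float
    se_w_prime: float
    r_squared: float
    n_points: int
    form: str = "power-1/time"
    warnings_: tuple[str, ...] = field(default_factory=tuple)

    def prescribe_power(self, target_tte_s: float) -> float:
        """Power (W) predicted to exhaust the athlete in ``target_tte_s``.

        ``P = CP + W'/t``.  Targets outside 60-600 s draw a warning: the
        hyperbola is only trusted for exhaustion in roughly 1-10 minutes.
        """
        if target_tte_s <= 0:
            raise ValueError("target time to exhaustion must be > 0")
        if not 60.0 <= target_tte_s <= 600.0:
            warnings.warn("target time to exhaustion outside the 60-600 s "
                          "range where the model is trusted", stacklevel=2)
        return self.cp + self.w_prime / target_tte_s

    def predicted_tte(self, power: float) -> float:
        """Predicted time to exhaustion (s) at ``power``: W'/(P - CP)."""
        if power <= self.cp:
            raise ValueError("power at or below CP: infinite predicted duration")
        return self.w_prime / (power - self.cp)

    def predict(self, durations: Iterable[float]) -> np.ndarray:
        d = np.asarray(list(durations), dtype=float)
        return self.cp + self.w_prime / d

    def summary(self) -> str:
        lines = [
            "Critical-power model ({})".format(self.form),
            "  n points   : {}".format(self.n_points),
            "  CP         : {:10.2f} W   (SE {:.2f})".format(self.cp, self.se_cp),
            "  W'         : {:10.1f} J   (SE {:.1f})".format(self.w_prime, self.se_w_prime),
            "  R-squared  : {:10.6f}".format(self.r_squared),
        ]
        for w in self.warnings_:
            lines.append("  warning    : " + w)
        return "\n".join(lines)


class CriticalPowerModel:
    """Critical-power model over (power, duration) exhaustion points.

    Parameters
    ----------
    points : sequence of (power_w, duration_s)
        One point per exhaustive test: the power held and the duration for
        which it was maintained.  At least two points with distinct
        durations are required.
    """

    def __init__(self, points: Sequence[tuple[float, float]]):
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
            raise ValueError("need at least 2 (power, duration) points")
        power, duration = arr[:, 0], arr[:, 1]
        if np.any(duration <= 0):
            raise ValueError("durations must be > 0")
        if np.unique(duration).size < 2:
            raise ValueError("durations must include at least 2 distinct values "
                             "(otherwise the design is singular)")
        self.power = power
        self.duration = duration

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, power_col: str = "power_w",
                       duration_col: str = "duration_s") -> "CriticalPowerModel":
        return cls(list(zip(df[power_col].astype(float), df[duration_col].astype(float))))

    @classmethod
    def from_cpt_tests(cls, tests: Iterable[tuple[float, float]]) -> "CriticalPowerModel":
        """Build from (prescribed_power, maintained_duration) pairs of CPTs."""
        return cls(list(tests))

    def fit(self) -> CriticalPowerFit:
        """Unweighted OLS of power on 1/duration."""
        x = sm.add_constant(1.0 / self.duration)
        # errstate guards the zero-residual-df case (exactly 2 points)
        with np.errstate(divide="ignore", invalid="ignore"):
            res = sm.OLS(self.power, x).fit()
            se = np.nan_to_num(np.asarray(res.bse, dtype=float))
            r2 = float(res.rsquared)
        cp, w_prime = float(res.params[0]), float(res.params[1])
        notes = []
        if cp <= 0:
            notes.append("fitted CP is not positive")
        if w_prime <= 0:
            notes.append("fitted W' is not positive")
        return CriticalPowerFit(
            cp=cp, w_prime=w_prime,
            se_cp=float(se[0]), se_w_prime=float(se[1]),
            r_squared=min(max(r2, 0.0), 1.0),
            n_points=int(self.power.size),
            warnings_=tuple(notes),
        )


def fit_power_inverse_time(points: Sequence[tuple[float, float]]) -> CriticalPowerFit:
    """Convenience wrapper: fit the power-1/time form on a point list."""
    return CriticalPowerModel(points).fit()


def fit_work_time(points: Sequence[tuple[float, float]]) -> CriticalPowerFit:
    """Cross-check fit of the work-time form ``W = CP * t + W'``.

    Work (P * t, joules) is regressed on duration: the slope is CP and the
    intercept is W'.  Used to confirm the power-1/time estimates; the two
    linearizations weight the points differently, so agreement is expected
    only on well-conditioned data.
    """
    model = CriticalPowerModel(points)
    work = model.power * model.duration
    x = sm.add_constant(model.duration)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(work, x).fit()
        se = np.nan_to_num(np.asarray(res.bse, dtype=float))
        r2 = float(res.rsquared)
    w_prime, cp = float(res.params[0]), float(res.params[1])
    notes = []
    if cp <= 0:
        notes.append("fitted CP is not positive")
    if w_prime <= 0:
        notes.append("fitted W' is not positive")
    return CriticalPowerFit(
        cp=cp, w_prime=w_prime,
        se_cp=float(se[1]), se_w_prime=float(se[0]),
        r_squared=min(max(r2, 0.0), 1.0),
        n_points=int(model.power.size),
        form="work-time",
        warnings_=tuple(notes),
    )
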