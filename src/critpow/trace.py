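"""Power-trace containers and CSV input/output.

A test is represented by a :class:`PowerTrace` (sampled power output of one
ergometer effort) together with a :class:`TestMeta` describing what kind of
test it was.  Traces are stored on disk as plain CSV with ``#``-prefixed
``key: value`` metadata lines ahead of the header, so a file is fully
self-describing and round-trips bit-faithfully.

Units are fixed throughout the package: seconds, watts, joules, rpm.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "TraceError",
    "PowerTrace",
    "TestMeta",
    "AthleteResult",
    "DURATION_BINS",
    "TEST_KINDS",
    "read_trace",
    "write_trace",
]

TEST_KINDS = ("3MT", "CPT")

#: Duration bins used to classify constant-power tests by the length of the
#: maintained (constant-power) phase.
DURATION_BINS = ("<1 min", "1-3 min", "3-6 min", ">6 min")


class TraceError(ValueError):
    """Raised when a trace or its metadata violates an invariant."""


def _infer_fs(time: np.ndarray) -> float:
    """Sampling rate from the median time step.

    The acquisition rate is nominally uniform; steps deviating from the
    median by more than 1% are rejected rather than repaired.
    """
    dt = np.diff(time)
    med = float(np.median(dt))
    if med <= 0:
        raise TraceError("non-monotonic time")
    if np.any(np.abs(dt - med) > 0.01 * med):
        raise TraceError("non-uniform sampling: time steps vary by more than 1%")
    return 1.0 / med


@dataclass(frozen=True, eq=False)
class PowerTrace:
    """Uniformly sampled (time, power[, cadence]) record of one test.

    Parameters
    ----------
    time : array of float
        Sample times in seconds from test start; strictly increasing,
        first sample >= 0.
    power : array of float
        Power output in watts per sample; finite and >= 0.
    cadence : array of float, optional
        Pedalling cadence in rpm per sample.
    fs : float, optional
        Sampling rate in Hz.  Inferred from the median time step when not
        given; a hard error is raised if the steps vary by more than 1%.
    """

    time: np.ndarray
    power: np.ndarray
    cadence: Optional[np.ndarray] = None
    fs: Optional[float] = None

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "power", power)
        if time.ndim != 1 or power.ndim != 1 or time.shape != power.shape:
            raise TraceError("time and power must be 1-d arrays of equal length")
        if time.size < 2:
            raise TraceError("trace must contain at least 2 samples")
        if not np.all(np.isfinite(time)):
            raise TraceError("non-finite time value")
        if time[0] < 0:
            raise TraceError("first time must be >= 0")
        if np.any(np.diff(time) <= 0):
            raise TraceError("non-monotonic time")
        if not np.all(np.isfinite(power)):
            raise TraceError("non-finite power value")
        if np.any(power < 0):
            raise TraceError("negative power")
        if self.cadence is not None:
            cad = np.asarray(self.cadence, dtype=float)
            if cad.shape != time.shape:
                raise TraceError("cadence length mismatch")
            object.__setattr__(self, "cadence", cad)
        fs = self.fs
        if fs is None:
            fs = _infer_fs(time)
        elif fs <= 0:
            raise TraceError("fs must be positive")
        object.__setattr__(self, "fs", float(fs))

    # -- convenience ------------------------------------------------------

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def t_start(self) -> float:
        return float(self.time[0])

    @property
    def t_end(self) -> float:
        return float(self.time[-1])

    @property
    def duration(self) -> float:
        """Span between first and last sample, in seconds."""
        return float(self.time[-1] - self.time[0])

    def index_at(self, t: float) -> int:
        """Index of the first sample with time >= ``t`` (within a half step)."""
        i = int(np.searchsorted(self.time, t - 0.5 / self.fs))
        return min(i, self.n - 1)

    def equals(self, other: "PowerTrace") -> bool:
        """Sample-by-sample equality (used by round-trip checks)."""
        if not np.array_equal(self.time, other.time):
            return False
        if not np.array_equal(self.power, other.power):
            return False
        if (self.cadence is None) != (other.cadence is None):
            return False
        if self.cadence is not None and not np.array_equal(self.cadence, other.cadence):
            return False
        return True


@dataclass(frozen=True)
class TestMeta:
    """Descriptive metadata for one test.

    ``prescribed_power`` is the commanded power in watts and is required
    for constant-power (CPT) tests; a 3-minute all-out test (3MT) has none.
    """

    athlete_id: str
    test_kind: str
    prescribed_power: Optional[float] = None
    preferred_cadence: Optional[float] = None
    session_date: Optional[str] = None

    def __post_init__(self) -> None:
        if self.test_kind not in TEST_KINDS:
            raise TraceError(f"test_kind must be one of {TEST_KINDS}, got {self.test_kind!r}")
        if self.test_kind == "CPT":
            if self.prescribed_power is None or self.prescribed_power <= 0:
                raise TraceError("CPT requires prescribed_power > 0")


@dataclass
class AthleteResult:
    """All per-athlete estimates: traditional fit, 3MT, and binned CPTs.

    ``cpt_results`` maps a duration bin (one of :data:`DURATION_BINS`) to the
    analyzed constant-power test that fell in that bin.
    """

    athlete_id: str
    traditional_fit: object = None  # CriticalPowerFit
    three_mt: object = None  # ThreeMtResult
    cpt_results: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.cpt_results:
            if key not in DURATION_BINS:
                raise TraceError(f"unknown duration bin {key!r}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_META_FLOAT_KEYS = ("prescribed_power", "preferred_cadence")


def _meta_to_lines(meta: TestMeta) -> list[str]:
    lines = []
    for f in fields(TestMeta):
        value = getattr(meta, f.name)
        if value is None:
            continue
        lines.append(f"# {f.name}: {value!r}" if isinstance(value, float) else f"# {f.name}: {value}")
    return lines


def _parse_meta(lines: list[str]) -> TestMeta:
    kv: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or ":" not in body:
            continue
        key, _, value = body.partition(":")
        kv[key.strip()] = value.strip()
    if "athlete_id" not in kv or "test_kind" not in kv:
        raise TraceError("metadata must provide athlete_id and test_kind")
    kwargs: dict = {"athlete_id": kv["athlete_id"], "test_kind": kv["test_kind"]}
    for key in _META_FLOAT_KEYS:
        if key in kv:
            kwargs[key] = float(kv[key])
    if "session_date" in kv:
        kwargs["session_date"] = kv["session_date"]
    return TestMeta(**kwargs)


def write_trace(trace: PowerTrace, meta: TestMeta, path) -> None:
    """Write a trace and its metadata to ``path`` as annotated CSV.

    Floats are written with ``repr`` (shortest round-trip representation),
    so ``read_trace(write_trace(x)) == x`` to full precision.
    """
    path = Path(path)
    buf = io.StringIO()
    for line in _meta_to_lines(meta):
        buf.write(line + "\n")
    columns = ["time_s", "power_w"]
    arrays = [trace.time, trace.power]
    if trace.cadence is not None:
        columns.append("cadence_rpm")
        arrays.append(trace.cadence)
    buf.write(",".join(columns) + "\n")
    for row in zip(*arrays):
        buf.write(",".join(repr(float(v)) for v in row) + "\n")
    path.write_text(buf.getvalue(), encoding="utf-8")


def read_trace(path) -> tuple[PowerTrace, TestMeta]:
    """Read an annotated CSV written by :func:`write_trace` (or compatible).

    The file must have columns ``time_s, power_w`` and optionally
    ``cadence_rpm``; metadata comes from leading ``# key: value`` lines.
    Invalid files are rejected, never repaired.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    meta_lines = [ln for ln in text.splitlines() if ln.startswith("#")]
    meta = _parse_meta(meta_lines)
    df = pd.read_csv(io.StringIO(text), comment="#", float_precision="round_trip")
    for col in ("time_s", "power_w"):
        if col not in df.columns:
            raise TraceError(f"missing required column {col!r}")
    cadence = df["cadence_rpm"].to_numpy() if "cadence_rpm" in df.columns else None
    trace = PowerTrace(
        time=df["time_s"].to_numpy(),
        power=df["power_w"].to_numpy(),
        cadence=cadence,
    )
    return trace, meta
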