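"""Synthetic ergometer tests with known ground truth.

The generator emulates the two test protocols the analysis chain consumes,
under the two-parameter critical-power model (CP, W'):

* a 3-minute all-out test (3MT): an isokinetic sprint whose mean power decays
  exponentially from an instantaneous peak ``p_max`` toward CP with time
  constant ``tau = w_prime / (p_max - cp)``, so the work above CP over an
  unbounded horizon equals W' exactly;
* a constant-power plus all-out test (CPT): a constant phase at the prescribed
  power held until task failure, an all-out exponential decline toward CP, and
  a terminal plateau at CP.

Task failure occurs when the fraction ``1 - f_unspent`` of W' has been spent
at the prescribed power, i.e. at ``t_fail = (1 - f_unspent) * w_prime /
(prescribed - cp)``.  Failure is modelled as an abrupt loss of the supra-CP
margin: the mean power drops instantly by ``failure_drop`` of ``(prescribed -
cp)`` and then decays exponentially, with the decline time constant chosen so
that the work above CP in the decline equals the unspent fraction
``f_unspent * w_prime`` in closed form.  The instantaneous drop is what makes
task failure a well-defined event: by definition the athlete can no longer
hold the prescribed power, so the mean trace leaves the maintenance band at
``t_fail`` rather than drifting out of it gradually.

Every simulated test carries a ``truth`` record with the analytic values of
the quantities the downstream analysis estimates, so each stage of the chain
can be tested against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .trace import PowerTrace, TestMeta

__all__ = [
    "AthleteProfile",
    "SimulatedTest",
    "simulate_3mt",
    "simulate_cpt",
    "simulate_cohort",
    "DEFAULT_T_TARGETS",
    "SPRINT_TAU_S",
]

#: Default time-to-exhaustion targets (s) for the four prescribed powers of a
#: simulated visit series; one per duration bin (<1, 1-3, 3-6, >6 min).
DEFAULT_T_TARGETS = (45.0, 120.0, 270.0, 480.0)

#: Default sprint-decline time constant (s) used to derive ``p_max`` from CP
#: and W' when no peak power is given.  With tau = 25 s an all-out effort has
#: spent >98% of W' by 100 s, consistent with anaerobic capacity being
#: depleted within 90-120 s of maximal exercise.
SPRINT_TAU_S = 25.0


@dataclass(frozen=True)
class AthleteProfile:
    """True simulator parameters for one athlete.

    Parameters
    ----------
    cp : float
        True critical power, watts.
    w_prime : float
        True anaerobic work capacity, joules.
    p_max : float, optional
        Instantaneous peak power, watts (> cp).  Defaults to
        ``cp + w_prime / SPRINT_TAU_S``.
    f_unspent : float
        Fraction of W' remaining at constant-power task failure, in [0, 1).
        Models the observation that W' need not be fully depleted when the
        prescribed power can no longer be held.
    noise_sd : float
        SD of additive Gaussian power noise, watts (clipped at 0 W).
    cadence : float
        Nominal cadence, rpm (emitted as constant plus small jitter).
    seed : int
        Base RNG seed; simulation is deterministic given the seed.
    """

    cp: float
    w_prime: float
    p_max: Optional[float] = None
    f_unspent: float = 0.2
    noise_sd: float = 0.0
    cadence: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cp", "w_prime", "f_unspent", "noise_sd", "cadence"):
            object.__setattr__(self, name, float(getattr(self, name)))
        if self.p_max is not None:
            object.__setattr__(self, "p_max", float(self.p_max))
        if self.cp <= 0:
            raise ValueError("cp must be > 0")
        if self.w_prime <= 0:
            raise ValueError("w_prime must be > 0")
        if self.p_max is None:
            object.__setattr__(self, "p_max", self.cp + self.w_prime / SPRINT_TAU_S)
        if self.p_max <= self.cp:
            raise ValueError("p_max must exceed cp")
        if not 0.0 <= self.f_unspent < 1.0:
            raise ValueError("f_unspent must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class SimulatedTest:
    """A simulated trace plus the analytic ground truth behind it."""

    trace: PowerTrace
    meta: TestMeta
    truth: dict = field(default_factory=dict)


def _emit(profile: AthleteProfile, time: np.ndarray, mean_power: np.ndarray,
          seed: Optional[int], fs: float) -> PowerTrace:
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    power = mean_power
    if profile.noise_sd > 0:
        power = np.clip(mean_power + rng.normal(0.0, profile.noise_sd, mean_power.size), 0.0, None)
    cadence = np.full(time.size, profile.cadence) + rng.normal(0.0, 0.5, time.size)
    return PowerTrace(time=time, power=power, cadence=cadence, fs=fs)


def simulate_3mt(profile: AthleteProfile, duration_s: float = 180.0,
                 fs: float = 1.0, seed: Optional[int] = None,
                 athlete_id: str = "sim") -> SimulatedTest:
    """Simulate a 3-minute all-out test.

    The noise-free mean curve is ``P(t) = cp + (p_max - cp) exp(-t / tau)``
    with ``tau = w_prime / (p_max - cp)``, so the integral above CP over
    [0, inf) equals W' analytically.
    """
    if duration_s < 60:
        raise ValueError("3MT duration must be >= 60 s")
    tau = profile.w_prime / (profile.p_max - profile.cp)
    n = int(round(duration_s * fs))
    time = np.arange(n + 1) / fs
    mean = profile.cp + (profile.p_max - profile.cp) * np.exp(-time / tau)
    trace = _emit(profile, time, mean, seed, fs)
    meta = TestMeta(athlete_id=athlete_id, test_kind="3MT",
                    preferred_cadence=profile.cadence)
    truth = {
        "cp": profile.cp,
        "w_prime": profile.w_prime,
        "p_max": profile.p_max,
        "tau_s": tau,
        # Work above CP within the finite test horizon.
        "w_prime_within_test": profile.w_prime * -math.expm1(-duration_s / tau),
    }
    return SimulatedTest(trace=trace, meta=meta, truth=truth)


def simulate_cpt(profile: AthleteProfile, prescribed_power: float,
                 fs: float = 1.0, plateau_hold_s: float = 120.0,
                 failure_drop: float = 0.5, decline_cut_w: float = 1.0,
                 seed: Optional[int] = None,
                 athlete_id: str = "sim") -> SimulatedTest:
    """Simulate a constant-power plus all-out test.

    Three phases:

    1. constant: mean power = ``prescribed_power`` until
       ``t_fail = (1 - f_unspent) * w_prime / (prescribed_power - cp)``;
    2. all-out decline: mean ``P(t) = cp + A exp(-(t - t_fail)/tau2)`` with
       initial amplitude ``A = (1 - failure_drop) * (prescribed_power - cp)``
       and ``tau2 = f_unspent * w_prime / A``, so the supra-CP work in the
       decline equals ``f_unspent * w_prime``; the decline is cut once the
       mean is within ``decline_cut_w`` of CP (default 1 W) to keep the
       trace finite, and the discarded tail is accounted for in the truth
       record;
    3. plateau: mean power = CP for ``plateau_hold_s``.

    The truth record carries ``failure_time_s``, ``constant_w_prime_true =
    (1 - f_unspent) * w_prime`` and ``unaccounted_w_prime_true`` equal to the
    decline work exactly as integrated (truncated tail removed).
    """
    cp, wp = profile.cp, profile.w_prime
    if prescribed_power <= cp:
        raise ValueError("prescribed_power must exceed cp (finite time to exhaustion)")
    if not 0.0 < failure_drop < 1.0:
        raise ValueError("failure_drop must be in (0, 1)")
    margin = prescribed_power - cp
    t_fail = (1.0 - profile.f_unspent) * wp / margin

    amp = (1.0 - failure_drop) * margin
    if profile.f_unspent > 0 and amp > decline_cut_w:
        tau2 = profile.f_unspent * wp / amp
        decline_s = tau2 * math.log(amp / decline_cut_w)
    else:
        # Degenerate decline: nothing left to spend (or the post-failure
        # amplitude is already below the cut) -- jump straight to plateau.
        tau2 = None
        decline_s = 0.0

    # Snap phase boundaries to the sample grid (boundaries at sample times).
    n_fail = int(math.ceil(t_fail * fs - 1e-9))
    n_decline = int(math.ceil(decline_s * fs - 1e-9))
    n_plateau = int(round(plateau_hold_s * fs))
    n = n_fail + n_decline + n_plateau
    time = np.arange(n + 1) / fs
    mean = np.full(n + 1, cp, dtype=float)
    mean[:n_fail] = prescribed_power
    if n_decline > 0:
        t_dec = time[n_fail:n_fail + n_decline]
        mean[n_fail:n_fail + n_decline] = cp + amp * np.exp(-(t_dec - t_fail) / tau2)

    decline_end_s = (n_fail + n_decline) / fs
    if tau2 is not None:
        # Supra-CP work in the decline up to the grid-snapped cut, exact.
        unacc_true = amp * tau2 * -math.expm1(-(decline_end_s - t_fail) / tau2)
    else:
        unacc_true = 0.0

    trace = _emit(profile, time, mean, seed, fs)
    meta = TestMeta(athlete_id=athlete_id, test_kind="CPT",
                    prescribed_power=prescribed_power,
                    preferred_cadence=profile.cadence)
    truth = {
        "cp": cp,
        "w_prime": wp,
        "failure_time_s": t_fail,
        "decline_end_s": decline_end_s,
        "plateau_start_s": decline_end_s,
        "constant_w_prime_true": (1.0 - profile.f_unspent) * wp,
        "unaccounted_w_prime_true": unacc_true,
        "total_w_prime_true": (1.0 - profile.f_unspent) * wp + unacc_true,
        "tau2_s": tau2,
    }
    return SimulatedTest(trace=trace, meta=meta, truth=truth)


def simulate_cohort(n_athletes: int, seed: int = 0,
                    cp_range: tuple[float, float] = (230.0, 330.0),
                    w_prime_range: tuple[float, float] = (8000.0, 20000.0),
                    noise_sd: float = 5.0, f_unspent: float = 0.2,
                    fs: float = 1.0,
                    t_targets: tuple[float, ...] = DEFAULT_T_TARGETS) -> list[dict]:
    """Simulate a cohort: one 3MT plus one CPT per duration-bin target each.

    CP is drawn uniformly over ``cp_range`` (watts) and W' over
    ``w_prime_range`` (joules); the default ranges bracket the magnitudes
    typical of trained cyclists.  Prescribed powers are computed from the
    athlete's true parameters as ``cp + w_prime / t_target`` so that
    exhaustion lands in the intended bin.  Deterministic given ``seed``.

    Returns a list of per-athlete records with keys ``athlete_id``,
    ``profile``, ``three_mt`` and ``cpts`` (list of :class:`SimulatedTest`).
    """
    if n_athletes < 1:
        raise ValueError("n_athletes must be >= 1")
    if not (cp_range[0] < cp_range[1] and w_prime_range[0] < w_prime_range[1]):
        raise ValueError("invalid parameter ranges")
    ss = np.random.SeedSequence(seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    # One child seed per test, kept below 2**31.
    test_seeds = ss.generate_state(n_athletes * (1 + len(t_targets))) % (2 ** 31)
    cohort = []
    k = 0
    for i in range(n_athletes):
        cp = param_rng.uniform(*cp_range)
        wp = param_rng.uniform(*w_prime_range)
        profile = AthleteProfile(cp=cp, w_prime=wp, f_unspent=f_unspent,
                                 noise_sd=noise_sd, seed=int(test_seeds[k]))
        athlete_id = f"sim{i:03d}"
        three = simulate_3mt(profile, fs=fs, seed=int(test_seeds[k]),
                             athlete_id=athlete_id)
        k += 1
        cpts = []
        for t_target in t_targets:
            power = cp + wp / t_target
            cpts.append(simulate_cpt(profile, prescribed_power=power, fs=fs,
                                     seed=int(test_seeds[k]),
                                     athlete_id=athlete_id))
            k += 1
        cohort.append({"athlete_id": athlete_id, "profile": profile,
                       "three_mt": three, "cpts": cpts})
    return cohort
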