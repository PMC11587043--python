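# Methods

## The model

All estimation in `critpow` rests on the two-parameter critical-power
model: above the critical power CP (W), work is drawn from a finite
capacity W′ (J), and exhaustion at a constant power P > CP occurs after
`t = W′/(P − CP)` seconds. Linearized as `P = CP + W′·(1/t)`, the model is
fitted by unweighted ordinary least squares of power on reciprocal
duration (`CriticalPowerModel.fit`); the intercept is CP, the slope W′,
and standard errors come from the regression. The equivalent work–time
form `W = CP·t + W′` is provided as a cross-check only — the two
linearizations weight points differently, so they are expected to agree
only on well-conditioned data. Three-parameter extensions (finite maximal
power) and any W′-balance recovery modelling are out of scope.

Points are fitted with no weighting and must include at least two distinct
durations. A fit with non-positive CP or W′ is returned with a warning
flag rather than rejected: implausible estimates are data, not errors.

## Test protocols and their measurements

**3-minute all-out test (3MT).** End power EP = arithmetic mean of the
samples in the final 30 s (`ep_window_s`, default 30 s); W′ = trapezoidal
power–time integral above EP over the whole test. EP estimates CP; the
integral above EP estimates W′.

**Constant-power plus all-out test (CPT).** The trace is segmented into a
constant-power phase, an all-out decline, and a terminal plateau:

* *Task failure* is the start of the first contiguous run of at least
  `lapse_s` (default 10 s) with power below `prescribed − tolerance_w`
  (default 10 W). The band is one-sided because over-performance never
  signals failure; the lapse is consecutive, not cumulative.
* *Plateau onset* is the earliest time from which every sliding
  least-squares window of `plateau_window_s` (default 60 s) within a
  `plateau_hold_s` hold (default 60 s) has |slope| ≤ `slope_w_per_s`
  (default 0.1 W/s). The window length equals the hold by default: with
  second-by-second power noise of realistic size (≈5 W SD), the slope
  estimator over a 30-s window has a standard error (≈0.11 W/s) larger
  than the threshold itself, so a conjunction of many short windows would
  essentially never fire; a 60-s window brings the slope SE to ≈0.04 W/s
  and makes the rule usable on real-noise traces. The flat region is
  extended sample-by-sample to the trace end while windows stay flat.

Work above the reference power is then split at the failure time:
`constant_w_prime` integrates `[0, t_fail]`, `unaccounted_w_prime`
integrates `[t_fail, t_end]`, and `total_w_prime` is exactly their sum
(computed, never stored). The reference is the athlete's 3MT EP by
default. When the constant-power component comes out negative — possible
when the prescribed power sits barely above the reference and fluctuation
drags the average below it — both components are recomputed against the
test's own EP and the result is flagged `used_fallback`; recomputing both
components (not just the constant one) keeps the total internally
consistent. Tests are binned by the maintained duration with half-open
edges at 60, 180 and 360 s (`<1`, `1-3`, `3-6`, `>6` min).

The pipeline also accepts `w_prime_reference: traditional_cp`, which
integrates against the athlete's fitted traditional CP instead of the 3MT
EP. Because W′ is defined relative to CP, this is the appropriate
reference when the question is how well the protocol recovers a known W′
(it isolates W′ recovery from end-power bias); the recovery evaluation
(`evaluate_recovery`) and the acceptance script use it, while the default
remains the protocol's own 3MT EP.

## Numerical choices

* **Integration** is trapezoidal on the sample grid, with linear
  interpolation at window endpoints that fall between samples. For an
  exponential decline with time constant τ the relative error is
  ≈ Δt²/(12τ²): ≈0.008% at 1 Hz and τ ≈ 33 s, measured against fine-grid
  quadrature by the acceptance script.
* **Signed vs clipped integrals**: by default sub-reference excursions
  subtract (`clip_negative: false`), which is what makes a negative
  constant-power W′ detectable and the fallback well defined. Clipping,
  when enabled, floors each sampling interval's trapezoidal contribution
  at zero.
* **Sampling**: traces are validated as uniformly sampled (time steps
  within 1% of the median); the rate is inferred from the median step
  (1 Hz is the usual ergometer export). Nothing is resampled or repaired.
* **Ties** in segmentation are broken by "first qualifying run/window
  wins"; all boundaries land on sample times.
* **Summary rendering** uses the sample (n−1) SD and rounds only at render
  time; all internal arithmetic is at full precision.

## Group statistics

Condition comparisons use a one-way repeated-measures ANOVA under compound
symmetry. Complete balanced tables use the classical within-subject
decomposition (numerator df k−1, denominator df (n−1)(k−1)), which is the
exact likelihood answer under that covariance structure; unbalanced tables
fall back to a subject-random-intercept linear mixed model (REML) with a
Wald F whose denominator df is N − n_subjects − (k−1).

Many-to-one post hoc comparisons against a control condition use Dunnett's
procedure: under compound symmetry the k−1 contrast statistics are
equicorrelated multivariate t with correlation 1/2 and the model's error
df. `P(max|T_j| ≤ q)` is evaluated by deterministic quadrature
(Gauss–Hermite in the shared normal factor, an equal-weight quantile rule
in the pooled-scale factor; accurate to ~1e−5 and cross-checked in the
tests against scipy's Monte-Carlo multivariate-t CDF). Adjusted p-values
are `1 − P(max|T| ≤ |t_obs|)`; by the union bound they never exceed the
Bonferroni adjustment `min(1, k·p_raw)` on the same family, a property the
test suite and acceptance script verify empirically. A 2000-replicate null
simulation (28 subjects × 6 conditions) confirms the family-wise error
sits at the nominal 5%. Sphericity corrections beyond compound symmetry
are not implemented.

## The simulator

The synthetic-data generator (`critpow.simulate`) produces the traces the
analysis chain assumes, with analytic ground truth:

* **3MT**: mean power `cp + (p_max − cp)·exp(−t/τ)` with
  `τ = w_prime/(p_max − cp)`, so the supra-CP work over an unbounded
  horizon is exactly W′. When no peak power is given, `p_max` defaults to
  `cp + w_prime/25` (τ = 25 s), consistent with anaerobic capacity being
  effectively depleted within 90–120 s of all-out exercise.
* **CPT**: constant power until `t_fail = (1 − f_unspent)·w_prime/(P − cp)`,
  then an exponential all-out decline toward CP, then a CP plateau.
  Failure is modelled as an abrupt loss of half the supra-CP margin
  (`failure_drop = 0.5`): by definition the athlete can no longer produce
  the prescribed power at failure, so the mean trace steps below the
  maintenance band at `t_fail` rather than drifting out of it. The decline
  time constant is `f_unspent·w_prime/A` (A the post-drop amplitude), so
  the decline's supra-CP work equals the unspent fraction of W′ in closed
  form. The decline is cut where the mean comes within 1 W of CP to keep
  traces finite; the truncated tail is removed from the truth record, so
  truth is exact as integrated.
* `f_unspent` (default 0.2) encodes that roughly a fifth of W′ typically
  remains unspent at constant-power task failure — the quantity the
  unaccounted W′ is designed to capture.
* Noise is additive iid Gaussian per sample (default SD 5 W in cohort
  simulation, a realistic second-to-second power fluctuation), clipped at
  0 W. Cadence is a constant with small jitter; the analysis never
  consumes it numerically.
* **Cohorts** draw CP uniformly from 230–330 W and W′ from 8–20 kJ
  (magnitudes typical of trained cyclists) and prescribe four CPT powers
  as `cp + w_prime/t_target` for targets of 45, 120, 270 and 480 s — one
  per duration bin, with failure at `(1 − f_unspent)·t_target` safely
  inside each bin. Everything is deterministic given the seed.

What the simulator does **not** emulate: pacing behaviour, cadence–power
coupling, oxygen-uptake kinetics, drift or autocorrelated noise, a brief
struggle phase before failure, or any physiological depression of the
all-out end power below CP. Passing recovery tests therefore shows the
chain is correct under the stated model, not that real athletes satisfy
the model.

## Problem sizes

The recovery studies use 100-athlete cohorts (one 3MT plus four CPTs each,
1 Hz traces), the segmentation study 50 replicates of the mid-range test,
and the statistics calibration 2000 null replicates — sizes at which the
Monte-Carlo bands in the tests are comfortably narrow while the whole
acceptance run stays in the seconds range on a single core.

## Known limitations

* With noise, failure detection on tests whose prescribed power sits close
  to CP (the >6-min bin at the default 10-W band) can lag true failure by
  tens of seconds, because the post-failure mean power hovers near the
  band edge; detection never fires early and duration bins are preserved,
  but individual maintained durations for such tests are upper estimates.
  This mirrors the genuine ambiguity of task failure at barely-supra-CP
  intensities.
* The slope-based plateau rule triggers where the decline's remaining
  supra-CP amplitude falls below ≈ `slope·window/(1 − exp(−window/τ₂))`,
  i.e. slightly before a strict asymptote; the flat-region extension to
  the trace end makes the unaccounted integral insensitive to this.
* The 3MT EP carries a small positive finite-horizon bias (the mean curve
  has not fully reached CP by 150–180 s); with the default simulator
  profiles it is under ~1 W, but it grows quickly with τ. This is why
  recovery evaluation references the traditional CP.
* Only the two-parameter model is supported; durations far outside
  1–10 min draw a prescription warning rather than a refusal.
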