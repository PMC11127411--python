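# Methods

## The derivation chain

The pipeline computes global oxygen delivery from two independent bedside
monitors sampled at different rates. Per synchronized grid point,

DO₂ = CO · SpHb · SpO₂ · 1.34 · 10  (mL O₂/min),

with CO in L/min, SpHb in g/dL, SpO₂ a fraction in [0, 1]. The constant
1.34 mL/g is hemoglobin's maximal O₂-binding capacity; ×10 converts g/dL to
g/L. The dissolved-oxygen term (0.003 × PaO₂) is deliberately omitted — it
contributes ~1–2% in normoxia and requires an arterial blood gas, defeating
the non-invasive premise. Absolute DO₂ in mL/min is the primary output;
indexed DO₂ (mL/min/m²) is emitted only when a body surface area is supplied,
since BSA is an optional refinement rather than a monitored signal.

### Stream dialects

The vendor serial formats are proprietary, so the package defines a documented
stand-in dialect per device that preserves the two parsing *strategies* the
problem forces:

- **MSPC (co-oximeter), 1 s cadence**: `HH:MM:SS label=value ...`. Labels are
  configurable; SpO₂ is a percent on the wire and a fraction internally.
  Session time is seconds since the first accepted line; a backward clock jump
  exceeding 12 h is treated as a midnight wrap (+24 h).
- **ECS (cardiac-output monitor), 2 s cadence**: whitespace-separated unlabeled
  numeric tokens, no timestamp. CO is read from a configurable 0-based token
  index (default 3); time is reconstructed as `arrival_index × cadence`.

Malformed lines are logged, counted and skipped — serial capture is lossy and
a session should only fail when CO is persistently undetectable, not on a
single corrupt line. Written streams round-trip through the parsers exactly at
the dialect's printed precision (2 decimals; SpO₂ therefore has 10⁻⁴
resolution as a fraction).

### Synchronization

One frame per ECS sample, at the ECS timestamp. SpHb/SpO₂ come from the most
recent MSPC sample with timestamp ≤ t whose age is at most a staleness bound
(default 2 s, the ECS period; the boundary is inclusive, so an exact tie and
an age-2 sample both count). The rule is causal — implementable in real time —
and reduces to plain 2:1 decimation at nominal cadences. Frames missing any
component are retained, flagged invalid, and propagate as missing DO₂. The
alternative (nearest-sample, two-sided) was rejected because it is
non-causal; the implementation rides on `pandas.merge_asof` and is checked in
the tests against an exhaustive O(n·m) search.

### Aggregation

- **Trend**: half-open 20-s windows `[k·20, (k+1)·20)`; each window with ≥1
  non-missing DO₂ emits the mean of its non-missing values; a trailing partial
  window is emitted like any other. The n-weighted mean of window means equals
  the overall mean by construction (tested).
- **Session summary**: arithmetic mean and 10th centile of the non-missing
  DO₂ values. The centile uses linear interpolation between closest ranks
  (rank h = (n−1)p + 1 on the sorted sample — numpy's default), fixed so test
  expectations are exact. Valid monitoring duration is
  `n_valid_frames × grid_step / 60` minutes.
- **Failure**: a session fails when fewer than 10% of ECS lines yield a
  parseable CO (`NO_CO_SIGNAL`) or no valid frames exist (`NO_VALID_FRAMES`).
  The 10% floor is a package choice — the underlying reports state only that
  sessions failed through machine-interface and cuff problems — and is
  configurable.

## Agreement statistics

Sensor-vs-laboratory hemoglobin agreement follows the classic Bland-Altman
formulation on differences d = SpHb − labHb: bias = mean(d), SD with the n−1
denominator, limits of agreement bias ± 1.96·SD (fixed multiplier, not
t-based small-sample limits). The one-sample t-test of d against 0 and the
paired t-test of the two columns are algebraically identical; both are
reported and their equality is a standing test invariant. Lab draws pair with
the nearest-in-time SpHb value within a configurable window (default 5 min);
each pairing is independent, so one SpHb value may serve several draws, and
no repeated-measures correction is applied. Group comparisons (e.g. AKI vs
non-AKI session metrics) default to Welch's t-test, avoiding the
equal-variance assumption; the degenerate all-constant case is fixed by
convention (equal means → p = 1, unequal → p = 0).

## The scenario simulator

The simulator emulates what the pipeline consumes — two text streams — not
cardiovascular physiology. Per session, baselines are drawn uniformly within
textbook adult normal ranges: CO 4–8 L/min, SpHb 8–14 g/dL (a realistic
post-cardiac-surgery hemoglobin band), SpO₂ 95–100%. Shaping:

- **Profiles**: `RANDOM_NORMAL_RANGE` is flat; `UPTREND`/`DOWNTREND` apply a
  linear DO₂ drift of ±0.1 of baseline per hour by default (chosen once as a
  pronounced but non-clipping slope over a ~6 h session). The drift factor is
  split as a square root between CO and SpHb so noise-free DO₂ drifts by
  exactly the configured fraction.
- **Dips**: multiplicative CO reductions over an interval (transient
  low-output episodes).
- **Noise**: multiplicative Gaussian, 2% SD per emitted sample per parameter,
  independently on CO, SpHb and SpO₂; values clip at 0 and SpO₂ at 1.
- **Gaps** (bypass, transfer): both monitors stop emitting. Because the ECS
  dialect forces `time = arrival_index × cadence`, a gap compresses capture
  time; the simulator therefore stamps *both* streams on the capture-relative
  clock (the j-th emitted MSPC line carries j seconds) so the streams stay
  co-registered across gaps. Parameter values are still evaluated at real
  session time, and the truth table keeps both clocks (`t_s`, `t_real_s`). A
  gap whose boundaries are not multiples of the 2-s cadence can leave a
  sub-2-s cross-stream offset — within the staleness bound, so alignment
  survives.
- **CO malfunction**: every ECS CO token becomes a non-numeric sentinel
  (`--`), which downstream parsing rejects line-by-line until failure
  detection reports `NO_CO_SIGNAL`.

Identical seed + config give byte-identical streams. Cohorts derive
per-session seeds from a master seed; profiles are apportioned to exact
counts by largest remainder and shuffled; AKI labels attach to DOWNTREND
sessions; wear minutes are drawn Normal(378, 93) (the reported monitoring-
duration distribution), clipped at 0.

**What passing tests do and do not show.** The simulator has no baroreflex,
no pump physics, no inter-parameter correlation and stationary noise; passing
recovery tests demonstrates that the *pipeline* is lossless and correctly
aligned under known ground truth, not that the dialect or noise model matches
any real device.

## Numerical choices and degenerate inputs

- Saturation noise truncates at 100%: with baseline SpO₂ = 1 the expected
  observed mean is reduced by the half-normal factor σ/√(2π); recovery tests
  use this closed-form corrected mean.
- Empty sessions yield a failed summary with missing statistics; empty ECS
  input yields zero frames; Bland-Altman requires n ≥ 2 (SD undefined below).
- Printed precisions in the cohort report: success rate to the nearest whole
  percent, AKI incidence to one decimal; raw values are always emitted
  alongside.
- The sensor-wear safety boundary is strict: 480 min is compliant, anything
  above alerts.

## Problem sizes

The test suite and the acceptance script run on scaled-down sessions chosen
as the package's own defaults: 60–300 s sessions for round-trip, cadence and
coverage checks (the properties are cadence arithmetic, independent of
length); a 2000-s constant session (1000 frames) for mean recovery under
noise; 600-s sessions for the 61-session cohort; 1800–3600 s for trend-slope
and group-contrast sign checks, where the drift needs room to dominate
baseline variability; 5000 synthetic Hb pairs for bias/LoA recovery.

## Known limitations

- The dialects are stand-ins; real integrations must re-specify
  `DialectConfig` against actual device output.
- ECS time is positional, so any dropped ECS line silently shifts subsequent
  capture time; the package reports rejected-line counts so such shifts are
  visible, but it does not re-anchor clocks (no cross-correlation alignment).
- Bland-Altman treats all pairs as independent; repeated measures within a
  patient are not modelled.
- Indexed DO₂ requires a caller-supplied BSA; no demographic estimation is
  performed.
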