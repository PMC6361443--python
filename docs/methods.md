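# Methods

## The activity metric

The basic signal is the capacitance of 12 planar electrodes under the cage
floor, sampled every 250 ms. Animal movement near an electrode changes its
capacitance; stationary animals (and everything else in the cage) only
offset it. The pipeline therefore works on the absolute first difference
per electrode: an **activation event** is one electrode–sample pair whose
absolute difference exceeds a noise threshold θ_e.

Binned activity is reported as the *fraction of valid electrode-pair slots
in the bin that carry an event*. This choice is bounded in [0, 1], makes
the all-electrode ("global") series exactly the slot-weighted mean of any
partition of electrodes (the conservation law the floor-area decomposition
relies on), and yields magnitudes of the order 0.1 at the nocturnal peak
for the default simulator settings. With every slot valid it coincides with
the mean over electrodes of per-electrode activity, so nothing depends on
whether one thinks of the metric as a sum or an average.

Conventions, fixed once:

- a pair exists only when its two samples are ≤ `max_pair_gap` apart
  (default 500 ms, i.e. twice the sampling period); differencing never
  spans recording gaps;
- a pair belongs to the bin containing its **later** sample; the first
  sample of a contiguous segment yields no pair, so a fully covered minute
  holds 240 pair slots per electrode;
- non-finite readings invalidate their pairs on that electrode only, and
  are removed from numerator *and* denominator;
- bins with zero valid slots are present but missing (NaN), never zero;
  summaries weight by valid-slot counts.

## Thresholds

Two policies are supported:

- **fixed** — θ is given in sensor units and applied to the absolute
  difference directly. A fixed θ = 4σ against i.i.d. per-sample noise of
  scale σ fires at the Gaussian-difference tail rate
  2Φ(−4/√2) ≈ 0.468 % — the analytic empty-cage limit the tests check.
- **k·sigma (default, k = 4)** — θ_e = k × 1.4826 × MAD of the *first
  differences* in a quiescent window (default: 4–8 h after lights-on, the
  mid-day rest block; falls back to the whole recording). Note the unit
  convention: here k multiplies the robust scale of the **differenced**
  noise (σ√2 for i.i.d. sample noise), so the default policy is a factor
  √2 more conservative than a fixed 4σ per-sample threshold. Thresholds
  are per-electrode by default; a global (median) variant is available.

## FWHM response quantification

For an event at time t₀ on the minute-binned global series:

1. smooth with a centered 30-min moving average (truncated windows at the
   edges, missing bins excluded per window; the even window covers
   [i−15, i+14]);
2. find the peak in the event-specific search window — lights-on ±3 h;
   lights-off [0, 720] min (the full dark period, since slow-ramp
   phenotypes peak past 400 min); cage-change [0, 6 h]; all configurable;
3. collect maximal runs of minutes **strictly above** half the peak (ties
   at exactly half are excluded); merge runs separated by fewer than
   5 minutes (a 4-min dip merges, a 5-min dip does not); keep the run
   containing the maximum (first maximum wins on ties);
4. report the run extent (count of minutes, last − first + 1) as the
   response duration, the mean of the smoothed trace over the run as
   average-in-FWHM, and the time of the (first) maximum as time-to-peak.

The 90th-percentile metrics are computed, by default, as the 90th
percentile of the smoothed values in the search window, with time-to-p90
the first minute at or above that level. The alternative reading — first
time reaching 0.9 × peak — is available via `p90_mode="fraction_of_peak"`.
The distribution reading was chosen because reported p90 values in this
paradigm sit near 85 % of the peak, which a literal 0.9 × peak cannot
produce; both interpretations are exposed so users can pick.

The dark-period ("lights-off") profile averages the raw minute trace
across selected complete 720-min dark periods *first*, then smooths and
rescales so the maximum is exactly 1.0, and computes the metrics on this
week-averaged trace. A per-week mode (quantify each dark period, then
aggregate with `aggregate_responses`) is also available; the week-averaged
default matches how such profiles are usually displayed.

## Labels and summaries

Day/night labels come from the instant-transition light schedule (default
12/12, lights-on 06:00 UTC). Cycle labels come from the intervention
calendar: week *i* starts at cage-change anchor *i*, and weekday-of-cycle
0 is the calendar day of the anchor (bins before the first anchor get −1).
Day/night fraction tables and heat-map rows use 24-h periods anchored at
lights-on, so each period holds one complete light and one complete dark
phase; actigram hours are likewise anchored at lights-on (day trace) and
lights-off (night trace). Cycle normalisation divides each bin by the mean
over non-missing bins of its cycle, so every cycle has unit mean by
construction; zero-mean windows are marked non-normalisable rather than
divided.

## The simulator

The generator produces the statistical structure the analysis assumes,
with ground truth for recovery tests. It is a mechanism, not a fit: no
real recordings were used, and presets are qualitative mimics of reported
phenotypes.

**Movement.** Each of the `n_mice = 5` mice is a two-state semi-Markov
walker. A resting mouse stays put and becomes active with per-second
hazard `peak_hazard × λ(τ) × Πg(t)`; an active mouse takes Gaussian steps
(`step_sigma = 2 cm` per axis per 250-ms tick, reflected at the walls of a
32 × 16 cm ≈ 512 cm² floor) and reverts to rest with constant hazard
(mean active bout `mean_active_s = 20 s`). `peak_hazard = 0.009 s⁻¹`
puts the stationary active probability near 0.15 at the template peak and
near 0.015 at daytime rest — producing nocturnal peak activity near 0.1
and strongly night-dominant fractions.

**Circadian template.** λ(τ) is piecewise-linear in log-intensity over
circadian time with named knots: post-lights-on burst (0.60) decaying to
the daytime rest level (0.08) within 60 min; night onset (0.35) at
lights-off ramping to the unit peak at `time_to_peak` minutes into the
dark period; a 30-min post-peak shoulder mirroring the ramp's log-slope
(so the peak is locally symmetric and a centered moving average leaves its
location unbiased — the intended time-to-peak is then exactly the peak of
the expected smoothed activity); decline to a late-night level (0.30) by
roughly lights-off + 8.5 h; anticipatory rise (0.55) from 90 min before
lights-on. A biphasic variant (early peak, dip, main peak) models the
bi-phasic dark-period phenotype.

**Interventions.** Events multiply the hazard with
`g(dt) = 1 + (peak_gain − 1)e^(−dt/τ)` (cage-change: gain 3.5, τ = 2 h;
weighing: gain 2, τ = 1 h), optionally plus a multi-day carry-over term
(male-like preset: gain 1.8, τ = 1.3 d) and a boxcar shape for scenarios
with a sharply defined true response duration. The default calendar places
a cage-change every 7 days at 10:00 starting on the first recording day (a
Thursday) and a weighing 4 days later; presets: `CNR-like` (time-to-peak
120 min, higher overall hazard), `KI-like` (440 min), `JAX-like`
(biphasic, main peak 400 min), `male-KI-like` (carry-over), `biweekly`
(14-day cycles), `no-intervention` (anchors kept for labelling, no
behavioural effect — the negative control).

**Signal.** Electrode e reads `baseline + Σ_m coupling_m ·
exp(−d²(m,e)/2s²) + N(0, σ_e²)` with an isotropic Gaussian proximity
kernel of scale `s = 3 cm` (of the order of the electrode pitch — local
enough that a mouse over one electrode row leaves neighbouring rows
essentially silent), per-mouse couplings log-normal around 60 sensor
units, and per-electrode noise σ_e drawn once per run from a narrow
log-normal around 1. Only movement changes the kernel term, so resting
mice cancel in the first difference — exactly the property the metric
exploits.

**Determinism and streaming.** All randomness flows from one
`numpy.random.Generator` seeded by the caller; draws are consumed in fixed
6-h chunks, so identical seeds give identical signals and the streamed
pipeline (`simulate_activity`, which carries the last sample across chunk
seams) equals detection on the concatenated table. The per-tick loop is
compiled with numba.

**What the generator does not emulate.** Inter-mouse interaction
(huddling, following), bedding/enrichment artefacts, sensor drift and
temperature effects, estrous cycling, and any physical calibration of
capacitance units. Passing recovery tests therefore demonstrates that the
*pipeline* measures what the *model* generates — not that the model
reproduces any particular real cage.

## Numerical choices and degenerate inputs

- Peak ties: earliest maximum wins (`nanargmax`). Strict `>` at half-max.
- Smoothing at series edges truncates the window; only the first/last
  15 min of a window are affected.
- All-missing search windows yield a no-response sentinel (`None`);
  zero-activity dark periods are flagged non-normalisable.
- Empty cages, empty calendars, and bins with no valid slots are all
  legal inputs and propagate as missingness, never as silent zeros.
- Validation is total: a raw file either yields a valid table or a
  diagnostic (fatal for schema/monotonicity violations, counted rejects
  for unparseable timestamps).

## Problem sizes used in the tests

The validation suite simulates at desk scale, chosen to keep every run
deterministic and fast while leaving comfortable statistical margins:
4 simulated weeks for time-to-peak recovery (28 dark periods, tolerance
±20 min against truth), 2-week runs for the carry-over and negative
control checks (50 replicates, 300 permutations each), 40-min empty-cage
runs for the analytic noise limit (≥10⁵ pairs, 3 binomial SE), 200
random tables against the detection pair-loop oracle and 500 random
series against the FWHM block enumerator (exact agreement required).

## Known limitations

- The activity unit is an artifact convention (fraction of slots); no
  physical capacitance calibration exists, so only internally consistent
  comparisons are meaningful.
- Rank-based longitudinal hypothesis tests (ATS-type) are deliberately out
  of scope; the longitudinal table is an export for external tools.
- The raw-signal CSV dialect is self-defined, not a reconstruction of any
  vendor export format.
- Per-animal attribution is impossible by design: the metric pools all
  mice in the cage.
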