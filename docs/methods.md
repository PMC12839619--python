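# Methods

## The monitoring problem

Clinical laboratories produce a continuous stream of patient results per
analyte. Systematic analytical error — a calibration shift, reagent-lot
change, or slow instrument drift — moves that whole stream up or down,
but conventional internal QC samples the instrument only at discrete
times. Patient-based real-time quality control (PBRTQC) instead monitors
a rolling statistic of the patient results themselves and alarms when it
leaves control limits. This package implements a complete
transform–truncate–alarm PBRTQC workflow: preprocessing that makes the
stream tractable for mean-style statistics, three monitors, labelled
error simulation to measure detection performance, a composite objective,
and a grid-search optimizer with an independent validation stage.

## Preprocessing: transform and truncate

Raw analyte streams are strictly positive and right-skewed with long
upper tails. Two preprocessing stages are fitted on the bias-free
training half and frozen thereafter, so all monitoring is causal:

* **Box-Cox transform.** The exponent λ is estimated by maximum
  likelihood (`scipy.stats.boxcox_llf` maximized with a bounded scalar
  search on λ ∈ [−5, 5]; a bounded search is used because bracket-based
  optimizers can fail on near-symmetric low-CV streams whose likelihood
  is very flat). When |λ̂| < 0.05 the natural log is used instead — the
  conventional cut for the log fallback. If the input contains
  non-positive values, an offset of `1e-6 × median(|x|) − min(x)` is
  added first. The aim is variance stabilization, not strict normality.
* **Truncation with value replacement (Winsorizing).** Values beyond the
  empirical `factor` and `1 − factor` quantiles of the *training*
  transformed stream are clamped to those bounds. The factor is a
  per-tail fraction (0.02 clamps 2% low and 2% high); factor 0 is a
  no-op. Quantiles use linear interpolation between order statistics
  everywhere in the package. An IQR-based trimming helper exists for
  histogram inspection only and never feeds modelling.

## Monitors and the alarm rule

All statistics run on the transformed, Winsorized stream:

* **MA** — trailing moving average over `window` results (undefined for
  the first `window − 1` positions);
* **MQ** — trailing moving quantile (same window convention, same
  quantile definition as the truncation stage);
* **EWMA** — `s_t = λ·x_t + (1 − λ)·s_{t−1}` with `s_1 = x_1`. Seeding
  at the first observation (rather than the training mean) keeps the
  statistic causal with no training-mean leakage; it is defined at every
  position.

Control limits are `mean ± multiplier × SD` of the *statistic's own*
empirical distribution on the bias-free training stream (warm-up
positions excluded, sample SD with ddof 1), with separate upper (a) and
lower (b) multipliers; on that scale 1.64/1.96/3 behave as z-quantile
multipliers. An alarm requires `k` consecutive points strictly outside
the limits; a qualifying run may mix sides and is retrospectively
attributed to its first point. Limits, truncation bounds and the
transform are frozen from training and applied unchanged to any
validation stream.

A known interaction worth naming: a truncation clamp that lies *inside*
a control limit (e.g. a 2%-tail clamp at ≈ ±2.05 SD of the values with a
3-SD limit on a weakly smoothed statistic) makes that side of the chart
unreachable — the monitor is structurally blind to one error direction
while showing an excellent false-alarm record. The selection stage below
is designed not to reward this.

## Error simulation

Scenarios copy a bias-free stream and multiply labelled contiguous
segments by `1 + direction × magnitude` on the **original measurement
scale** (percent bias is only physically meaningful pre-transform).
Defaults follow the study design: five magnitudes (10/30/50/70/90%) ×
two directions = ten scenarios; five segments of 100–300 consecutive
results per scenario; inner gaps of 250–500 error-free results (a
550–600 alternative is provided as `WIDE_GAP_RANGE`). The leading gap is
drawn uniformly from [0, 100] — realized leading gaps in this design are
small — and the trailing gap absorbs the remainder, so it is the largest
block. Placement checks analytically that the *minimal* layout fits and
then rejection-samples draws that overshoot the stream length; with the
default geometry on 3500 records a rejection is vanishingly rare. The
increase/decrease scenarios of one magnitude share one layout, and the
training and validation halves share layouts too, so layout-summary rows
come in identical pairs.

Drift scenarios replace the step with a baseline–drift–plateau profile:
at 0-based in-segment position *i* the bias fraction is
`baseline + (max − baseline) · min(i, ramp) / ramp`, i.e. a minor
baseline deviation (default 2%) climbing linearly over `ramp_length`
observations (default 100) to the plateau. With `baseline = max` this
degenerates exactly to the step model. When `ramp_length` equals the
shortest segment, the final point sits one ramp-step below the plateau;
the default geometry keeps ramps strictly shorter than segments.

## Metrics and the composite score

Per scenario, with warm-up positions excluded from every numerator and
denominator:

* **Sensitivity** (default, observation level): alarmed-and-biased /
  biased observations. A segment-level mode (detected segments / total)
  is available; observation level is the default because averaged
  segment counts over small suites quantize too coarsely to be a useful
  ranking signal.
* **FPR**: alarmed-and-unbiased / unbiased observations. Runs that start
  in a gap and extend into a segment count toward FPR (and do not count
  as detection — the run-start rule is applied literally).
* **MNPed**: a segment is detected when an alarm-run *start* falls
  inside it; its delay is that start minus the segment start (0 when the
  run begins at error onset). MNPed is the median delay over detected
  segments; `None` when nothing is detected. A `penalize_missed` policy
  substituting the segment length for misses is available.

The composite objective is

    ME_Score = 0.0005·Sensitivity + 0.999·(1 − FPR) − 0.0005·Sigmoid(MNPed)
    Sigmoid(m) = 1 / (1 + exp(−0.05·(m − 101)))

The weights deliberately make the false-alarm term dominant (alarm
fatigue is the practical failure mode of high-frequency monitoring); the
logistic penalty discounts delays smoothly around 101 patients. An
undefined MNPed contributes the maximal penalty (sigmoid = 1), so
missing every error can never score above detecting them slowly.

Across scenarios, sensitivity and FPR are unweighted means; MNPed is the
median of per-segment delays pooled over scenarios. The summary exposes
both an aggregate-then-score ME_Score (computed from the aggregated
triple) and a score-then-average variant (mean of per-scenario scores).
Published summary tables of this design are internally inconsistent on
this point: evaluating the printed formula directly on a printed row
triple (sensitivity 0.7677, FPR 0.0016, MNPed 5) gives ≈ 0.9978, not the
≈ 0.9922 printed beside it — the printed composites were presumably
produced from unprinted per-scenario values. Neither path here claims to
reproduce such printed composites; the discrepancy is pinned by a test.

## Optimization

The grid search evaluates every parameter combination on the training
suite. Default axes: window {3, 5, 10, 20, 50}; MQ quantile
{0.25, 0.5, 0.75}; EWMA smoothing 0.1–0.9 in steps of 0.1; truncation
factor {0, 0.01, 0.02, 0.05}; a, b ∈ {1.64, 1.96, 2.58, 3}; k
{1, 3, 5, 10} — all overridable. A `reduced` preset (smoothing
{0.5, 0.7, 0.9}, truncation {0, 0.02}, a, b ∈ {1.96, 3}, k {3, 5},
windows {3, 5, 10}, quantile {0.5}) keeps full runs interactive while
retaining the strong high-smoothing/3-SD/k = 5 corner. Evaluation is a
pure map over configurations (joblib-parallelizable; results are
order-independent), and degenerate configurations (zero statistic SD)
are recorded as failed with a diagnostic rather than silently dropped;
they rank last and never reach stage 2.

Selection is two-stage. Stage 1 ranks by training ME_Score and retains
the top 5% (never fewer than 20). Stage 2 re-sorts the retained set by
clinical priority — FPR ascending, then sensitivity descending, then
MNPed ascending, then a deterministic config-field tie-break — and
returns the head. **FPR is compared at a granularity of 1e-3**, the
operationally acceptable false-alarm tolerance in this setting. This is
a deliberate design choice: a finite evaluation (≈ 35 000 scored
observations) cannot resolve FPR below one alarm per suite, and a raw
lexicographic comparison lets sampling zeros — including the
direction-blind clamp pathology described above, which earns FPR exactly
0 with sensitivity ≈ 0.5 — outrank configurations that are vastly more
sensitive and operationally indistinguishable on false alarms. At 1e-3
granularity a genuinely lower-FPR configuration (0.001 vs 0.002) still
wins outright regardless of sensitivity. The granularity is a parameter
of `two_stage_select`.

Validation recomputes all metrics on the held-out half with every fitted
quantity frozen; no parameter is touched.

## Synthetic data

The generator samples a log-normal parameterized by the clinically
familiar median and fractional CV (`σ = sqrt(log(1 + cv²))`,
`μ = log(median)`), optionally contaminated: a fraction
`min(0.05, 0.02·skew_strength)` of records is inflated by
`1 + Exp(skew_strength)`, thickening the upper tail without moving the
bulk. Presets: `tsh_like` (median 1.8, CV 0.60, skew_strength 1.0 —
high-variability immunoassay-like, Box-Cox λ̂ far below 1) and `pt_like`
(median 12 s, CV 0.03, skew_strength 0.2 — tight coagulation-time-like).
The medians and CVs are the package's own calibration to the qualitative
shape of such analytes; real streams add features the generator omits —
diurnal and case-mix structure, autocorrelation, duplicate/reflex
testing, instrument switches — so passing tests demonstrate correct
mechanics and achievable operating points on realistic marginals, not
field performance on any particular instrument.

Timestamps, when generated, are strictly increasing integers; ordering
is all the pipeline uses them for.

## Problem sizes and numerics

The reference experiment uses 7000 records split 1:1 (3500 + 3500), ten
scenarios per half, and the reduced EWMA grid (48 configurations) — it
completes in a couple of seconds, and the full 2304-configuration EWMA
grid on the same data runs in under a minute on one core. Determinism:
one run seed drives named substreams (data synthesis, layouts, misc)
via `numpy.random.default_rng`; identical seeds give byte-identical
exported tables. Degenerate inputs raise typed errors
(`ConfigurationError`, `InputError`, `DegenerateDataError`,
`OptimizationError`) rather than propagating NaNs. Warm-up positions are
excluded from limit fitting, can never alarm, and are excluded from
metric denominators.

## Known limitations

* Only contiguous proportional biases (step or ramp) are simulated — no
  intermittent, random-magnitude, or preanalytical error models.
* One analyte, one instrument per run; no multi-instrument
  harmonization.
* CUSUM-style monitors and time-varying EWMA limit widths are out of
  scope.
* The ME_Score weights are fixed conventions, not formally optimized;
  alternative clinical priorities require re-weighting.
* With observation-level sensitivity, retrospective run-start labelling
  can report MNPed = 0 whenever a run begins exactly at error onset,
  which flatters detection timeliness for large biases.
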