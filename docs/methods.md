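# Methods

## Assay geometry and units

All computation assumes the standard geometry of the combined OHP /
turbidity assay: absorbance at 405 nm sampled every 12 s for 1 h
(301 readings), triplicate wells per condition, each condition run with
and without t-PA. Times are seconds internally; the reporting layer
prints minutes. Clotting rate is reported in AU/min — the published
tables print the slope without units, and AU/min is the convention that
makes a ~0.18 AU rise over ~6 min self-consistent with a slope of ~0.03.

## Turbidity parameter extraction

**Baseline and Abs-sum.** The Abs-sum AUC is the plain summation
Σ max(Aᵢ − b, 0) with b the median of the first `baseline_window_n`
(default 10) readings. Summation, not trapezoidal integration: the
quantity's unit is "summed AU" and scales with the number of readings.
Baseline subtraction (floored at zero) keeps the AUC independent of
optical offsets; the raw sum is exposed separately (`raw_abs_sum`) for
audit.

**Onset (lag time).** The curve is smoothed with a centered moving
average (`smoothing_window_n` = 5 readings); onset is the first reading
whose smoothed value exceeds baseline + `onset_threshold_au` (0.01 AU)
and stays above for `onset_min_consecutive` (3) readings. For onset
detection only, the baseline is re-estimated in two passes (provisional
minimum of the early window → provisional crossing → median of all
clearly pre-onset readings): the panel's fastest clots start rising
inside the nominal 2-min baseline window, where a plain first-n median
would be contaminated, while on slow curves the second pass averages a
long pre-onset stretch and so *reduces* baseline noise. A record with no
sustained crossing inside the window is ND.

**Plateau (TTP, max Abs).** Local slopes are the gradient of the
smoothed curve, lightly re-smoothed. The plateau is the first run of
three consecutive post-onset readings whose slope is at most
`plateau_slope_fraction` (5 %) of the peak growth-phase slope; TTP is
the first reading of that run. Max Abs is the median of the three
plateau readings minus the lag-phase turbidity (the detection baseline —
not the absorbance at the detected onset reading, which already sits one
threshold above baseline and would bias max Abs low by ~6 %). A curve
that never flattens within the record is ND.

**Rate and slope time.** Clotting rate is the least-squares slope of the
raw absorbance over [lag, TTP]; slope time is TTP − lag. A growth window
holding fewer than two readings is ND.

**ND propagation.** A condition is ND for reporting when at least half
of its replicates are ND (= the 2-of-3 rule at standard triplicates).
ND rows still report the Abs-sum as a diagnostic.

## Potentials

OCP and OHP are replicate mean ± SD (sample SD, n−1; a single replicate
reports SD 0) of the Abs-sum in the two arms. OFP is computed from the
replicate means, OFP = (1 − OHP/OCP) × 100 %, with its SD propagated to
first order from the OCP/OHP spreads assuming independence. Computing
OFP from means rather than per-replicate keeps the estimate defined even
when individual t-PA wells lyse to baseline, and the condition-level
mean ± SD presentation does not constrain the aggregation order. OCP = 0
makes the ratio undefined: OFP is then ND, not an exception. ±t-PA wells
are paired by condition identity, not plate position.

The normal range is the per-parameter min–max envelope over repeated PNP
runs (≥ 2 runs required; ND runs excluded per parameter with a warning).
Classification against the range is inclusive at the bounds. Fold-change
prose claims ("2.5-fold shortened") use the PNP *mean* as reference —
with the published means, 10 min / 4.0 min reproduces the printed
2.5-fold exactly, which the min–max envelope does not — and are
directional by explicit argument: shortening = reference/value, increase
= value/reference. Decimal claims round to one decimal; "two-fold"-style
claims round to the nearest 0.5 first.

## Synthetic generator

**Curve model.** A(t) = baseline + max_rise · g(t) · l(t) + ε(t), with
ε i.i.d. Gaussian (default SD 0.003 AU, consistent with the small
published within-triplicate spreads), l(t) = 1 before the lysis onset
and exp(−λ·(t − onset)) after (λ = `lysis_rate_per_min`, onset at clot
completion), and g a compact-support sigmoid: the integral of a
trapezoidal slope profile (corners of 10 % of the rise support each).
This shape was chosen over a logistic deliberately: the latent
parameters are *defined* as what the analyzer measures, and a logistic
cannot simultaneously place the onset-threshold crossing at the nominal
lag, the 5 %-slope point at lag + rise duration, and the least-squares
growth slope at the nominal rate. The profile anchors are calibrated
per curve — a fixed-point loop against a continuous model of the
detector, then a short refinement against the actual discrete detector —
so that the noise-free analysis returns the latent lag, TTP and rate up
to reading quantization. Identical (kinetics, sampling, seed) gives
bit-identical curves; batch simulation derives per-well seeds from the
master seed via numpy's `SeedSequence`.

**Recovery guarantees.** Noise-free, over a grid spanning the published
kinetic ranges (lag 0.7–24 min, rate 0.006–0.09 AU/min, two plateau
heights; 300+ cases), detected lag and TTP are within 6 s of the latent
values and the rate within ~8 %. Two envelope restrictions apply, both
properties of 12-s sampling rather than of this implementation: the
growth phase must span at least ~12 readings (144 s) — a shorter rise
cannot be localized to ±1 reading by any smoothed threshold/slope
detector, and the published fastest combinations (slope time ~1.2 min)
are below this floor — and the onset must clear the baseline window
(lag ≥ 0.15 × rise duration + 48 s; the panel satisfies this, since its
fast onsets pair with fast rises). Under noise the ±1-reading claim does
not survive: the plateau's slope-threshold crossing jitters by several
readings even at 0.0005 AU noise. At the default 0.003 AU the measured
envelope (10 seeds × grid) is: lag error ≤ 12 s in ≥ 95 % of curves,
TTP error 90th percentile ≈ 37 s, rate error 95th percentile ≈ 9 %.
The test suite asserts the strict bounds noise-free and these percentile
bounds (with margin) at default noise.

**Dose–response layer.** Each agent contributes a saturating Hill drive;
FVIII-deficient plasma sits at a latent reference whose onset (7200 s)
lies beyond any practical record, i.e. no aggregation. Lag shortens as
lag_def / (1 + Σ drives), rate and max rise grow multiplicatively from
deficient references (0.002 AU/min, 0.10 AU). An SIA × aPCC interaction
term (product of two Hill shapes) adds to the lag and rate drives and
divides the max rise — the published combinations clot faster *and*
plateau lower than either single agent, the turbidimetric signature of
dense, thin-fibered clots. Single-agent Hill constants were derived in
closed form from the published single-agent means; the seven interaction
constants were then least-squares fitted to the ten combination rows
with the singles frozen (a free joint fit degenerates and loses the SIA
dose-dependence). The calibration is deliberately loose — combination
lags match published means within ~25 %, and rFVIIa + SIA combinations
overshoot the published improvement by ~30–40 % because pure additivity
is too strong there — and lives in one place (`simulate._DEFAULTS`).
Structurally the model guarantees: dose-monotonicity of lag and rate,
ND for FVIII-deficient / SIA 10 nM / aPCC ≤ 50 mU/mL / rFVIIa ≤ 1.75
µg/mL alone, and strict synergy lag(SIA+aPCC) < min(single agents).

The default lysis rate (0.06/min) is set so noise-free PNP defaults give
OFP ≈ 60 %, matching the value implied by the published PNP means
(239 and 92.2 → 61.4 %). PNP maps to fixed reference kinetics (lag
600 s, rate 0.03 AU/min, rise 0.18 AU over a 0.05 AU baseline).

**What the generator does not emulate.** Plateau drift, instrument
artifacts (well edge effects, evaporation), non-exponential or
TAFI-modulated lysis, correlated noise, and any mechanistic coagulation
biochemistry (no thrombin generation model). Passing tests therefore
demonstrate the *analysis* is correct and internally consistent on
curves with the assumed structure — not that the dose–response
calibration is mechanistically faithful, nor how detectors behave on
pathological real-world curve shapes.

## Fiber thickness

Per-clot measurement sets (nominally 50 fibers) reduce to arithmetic
mean ± sample SD. The synthetic generator draws from a normal truncated
below at 1 length unit (rejection sampling): published SDs are large
relative to means (e.g. 220 ± 123), so an untruncated normal would
produce non-physical values. Units are opaque; cross-clot ratios are
unit-free. The per-fiber interpretation of the published SD is an
assumption (the source does not state whether SD is across fibers or
imaging locations).

## Numerical and formatting choices

- Written tables use 10 significant digits; round-trip error is < 1e-9 AU.
- Output CSVs carry `#`-prefixed provenance headers (version, seed,
  config digest); all readers skip `#` lines.
- Table rows follow the published arrangement: PNP, deficient plasma,
  SIA, aPCC, aPCC + SIA, rFVIIa, rFVIIa + SIA, doses descending.
- Degenerate inputs: curves need ≥ 2 readings and strictly increasing
  times (validation error, never silent repair); empty write sets,
  < 2 PNP runs, and single fiber measurements are errors; ND is a value
  everywhere downstream of detection.
- Simulation problem sizes in the test suite (180-curve panel, ~300-case
  recovery grid, 200-seed fiber check) keep the full suite under ~10 s
  on one CPU.
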