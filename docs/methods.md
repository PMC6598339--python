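# Methods

## The measurement being emulated

An optical coagulometer running an APTT assay records absorbance
against time: the trace sits at a reagent baseline, rises as fibrin
polymerizes, and plateaus when clotting completes.  Clot waveform
analysis (CWA) reads quantitative features off this trace and its
derivatives — the first derivative is the coagulation *velocity*, the
second the coagulation *acceleration*.  The ten parameters used here
are the peak times of the positive acceleration peak (2ndDP1), the
velocity peak (1stDP) and half fibrin formation (1/2FF); the peak
heights of 2ndDP1, 1stDP, the negative deceleration peak (2ndDP2,
reported as the magnitude "NH") and 1/2FF; and the FWHM widths of the
1stDP, 2ndDP1 and 2ndDP2.  A *biphasic* waveform — an abnormal
pre-clot drift preceding the main transition, associated with DIC —
is flagged separately.

## Curve model

The generator represents a clotting curve as a Richards (generalized
logistic) sigmoid plus baseline and an optional pre-clot ramp:

    y(t) = B + c·min(t, t_b) + A·(1 + ν·exp(−(t−m)/s))^(−1/ν)

with amplitude `A` (mabs), velocity-peak time `m` (s), time scale `s`
(s), asymmetry `ν`, baseline `B`, ramp slope `c` (mabs/s, the biphasic
signature) and noise sd `σ` (additive i.i.d. Gaussian).  Useful facts,
exact for every ν:

- the velocity peak is at `t = m` with height `(A/s)·(1+ν)^(−(1+ν)/ν)`;
- the acceleration extrema satisfy `w² − (3+ν)w + 1 = 0` in
  `w = exp(−(t−m)/s)`, giving `t_2nd1 = m − s·ln w₊` and
  `t_2nd2 = m − s·ln w₋`;
- half formation is at `t = m − s·ln(expm1(ν ln 2)/ν)`.

`ν = 1` is the symmetric logistic; `ν → 0` the Gompertz limit.  The
domain is extended to `ν ∈ (−0.5, ∞)`: negative ν produces a finite
onset lag and a long saturation tail, which is required because the
published healthy-volunteer medians place 1/2FF well *after* the
velocity peak — the ratio `(t_halfFF−t_1st)/(t_1st−t_2nd1)` reaches at
most 0.381 for ν ≥ 0 but equals 0.688 in the healthy-volunteer column.
Below ν = −0.5 the acceleration peak degenerates onto the onset
singularity, so that bound is enforced.

The analyzer prints derivative peak heights in "mabs" although they
are dimensionally mabs/s and mabs/s²; per-preset scale factors `k1`,
`k2` absorb the unknown instrument normalization.  Because each group
preset is calibrated independently, physical derivative units are not
comparable across groups; the pipeline therefore converts extracted
heights back to display units with each sample's known factors.

## Calibration

`calibrate_preset` fits `(m, s, ν, k1, k2)` (with `A` tied to twice
the 1/2FF height) to any subset of the six peak-time/height targets by
deterministic least squares on transformed parameters (`log s`,
`ν = exp(θ)−0.5`, `log k`), starting from `m = t_1st`,
`s = (t_1st−t_2nd1)/ln(2+√3)`, `ν = 1`, `k1 = k2 = 1`.  With all six
targets the system is exactly determined and converges to machine
precision for every published column; a residual above 1% raises a
calibration error with diagnostics.  Peak widths and NH are *not*
calibration targets — the budget is exhausted — and are emergent:
model widths are narrower than the published ones, and the model ties
NH to the 2ndDP1 height through ν (the ratio approaches 1 as ν → 1),
so the published NH ordering between the non-DIC and pre-DIC groups
is not reproduced.  These are known residual mismatches, not bugs.

## Extraction

Derivatives come from Savitzky–Golay local-polynomial filters (base
window 0.9 s, order 4 at the 0.1-s read interval — chosen so the
sharpest calibrated acceleration peak, FWHM ≈ 1.9 s, keeps its height
within 1% on a noiseless trace).  Differentiating amplifies noise as
1/dt² on the second derivative, so peak measurement is
noise-adaptive: the per-sample noise sd is estimated robustly from
second differences (`1.4826·median|Δ²y|/√6`), each peak is located on
the most-smoothed member of a window ladder (0.9–7.5 s), and its
height and time are read from the shortest window whose predicted
derivative noise (filter coefficient norm × noise estimate) is below
1% of the peak height, with three-point parabolic sub-sample
refinement.  On noiseless traces this reduces to the base window.  At
the default generator noise (0.5 mabs) all parameters are recovered
within a few percent except the height of intrinsically sharp
(healthy-volunteer-like) acceleration peaks, which sit below the noise
floor at any admissible window and are attenuated up to ~30%; group
orderings and correlation signs are unaffected.

Other conventions: the observed amplitude is plateau minus baseline
(medians of the first and last second of the trace); 1/2FF is the
first crossing of baseline plus half the observed rise (linear
interpolation); widths are FWHM between sustained half-height
crossings (hysteresis of one smoothing window against noise),
right-censored at the 200-s acquisition end with the width reported
as the window length and a censored flag, matching how the published
width entries cap at exactly 200; a curve rising less than 20 mabs is
a no-coagulation failure.  The biphasic flag is raised when the
least-squares slope of the pre-clot segment exceeds 0.2 mabs/s or the
acceleration curve is doubled before the velocity peak; the segment
ends at whichever comes first of `t_2nd1 − 2·(smoothing window)` and
the onset of measurable formation (1% of the rise), so the foot of
the sigmoid itself is never read as a ramp, and the flag is a
tri-state (undetermined when the segment is shorter than the
smoothing window).

## Synthetic cohort

Group sizes (121 non-DIC, 25 pre-DIC, 35 DIC without and 30 DIC with
hypofibrinogenemia, plus 30 healthy volunteers), the underlying-
disease count table, the infectious quotas of the two DIC subgroups
(28/35, 13/30), the outcome split and the hemoglobin split are
reproduced exactly by deterministic allocation; lab values (platelets,
PT ratio, FDP, fibrinogen, age) are drawn from log-normals fitted by
method of quantiles (`log-sd = ln(q75/q25)/(2·z₀.₇₅)`) to the
published group medians and quartiles.  The published outcome and Hb
counts total 213 against 211 enrolled; the cohort uses 55
non-survivors and 56 Hb < 8 g/dl within the 211 patients.  Healthy-
volunteer labs and the per-stratum hemoglobin distributions are not
published; normal adult reference values are used and affect no
comparison of interest.

Each patient's curve preset is the group preset with multiplicative
log-normal jitter (fractional sd 0.2) on amplitude, center and time
scale — median-preserving, so group medians still match the published
columns.  No joint patient-level model is published; outcome and low
hemoglobin are assigned by rank-weighted sampling without replacement
(weights `exp(−3·normalized rank)` of the analytic velocity-peak
height), a modelling convention that reproduces the *direction* of
the published stratified contrasts, and bleeding/organ-failure flags
are set with probability 0.7 in DIC-with-hypofibrinogenemia and
infectious-DIC patients respectively.  Because labs are drawn
marginally, a patient's JMHLW score computed from their sampled labs
need not match their a-priori group label; group-level summaries and
correlations are the supported use, not per-patient label agreement.
What passing tests show, therefore, is that the pipeline recovers the
structure put into the generator — not that real APTT traces obey
this curve family, and not patient-level realism of joint lab-
waveform distributions.

## Scoring and statistics

The JMHLW score sums banded points (platelets ≤12/≤8/≤5 ×10⁴/µl →
1/2/3; FDP ≥10/≥20/≥40 µg/ml → 1/2/3; fibrinogen ≤150/≤100 mg/dl →
1/2; PT ratio ≥1.25/≥1.67 → 1/2) plus one point each for underlying
disease, bleeding and organ failure; scores <6 / =6 / ≥7 classify as
non-DIC / pre-DIC / DIC, and fibrinogen <200 mg/dl marks
hypofibrinogenemia.  The band table ships as an editable config; the
hematologic-disorder variant (platelet and bleeding items excluded,
cuts 3/4) is available behind a switch, off by default.  The
enrollment screen is the printed disjunction with strict
inequalities.

Group contrasts use the two-sided Mann–Whitney U-test: exact
enumeration of all labelings (midranks under ties) when the pooled
size is ≤16, otherwise a continuity-corrected normal approximation
with tie-corrected variance and, for tie-free data, an Edgeworth
kurtosis term (exact null excess kurtosis
`−(6/5)(n²+m²+nm+n+m)/(nm(N+1))`), which keeps the approximation
within 0.02 absolute of the exact p down to three observations per
group.  Summaries are medians with linear-interpolation quartiles;
parameter-score association is Pearson r with the least-squares line
`parameter = a·score + b` and a t-distribution p; stars follow the
strict `*** <0.001 / ** <0.01 / * <0.05` mapping.  No
multiple-testing correction is applied, matching the emulated
analysis.

## Problem sizes and determinism

The default end-to-end run (241 subjects, one 2001-sample curve each)
completes in a few seconds; acceptance round-trips use 30 noiseless
curves per preset and 10⁵ draws for the lab-model check.  Every
random draw flows from a single seed through `numpy` Generators;
identical seeds give byte-identical outputs, and a run manifest
(seed, settings, versions) is written alongside the report tables.

## Known limitations

- Peak widths and NH are emergent, not calibrated (see above); width
  medians are systematically narrower than the published ones.
- Sharp acceleration-peak heights are attenuated under noise (noise
  floor of local-polynomial differentiation at 0.1-s sampling).
- The biphasic mechanism (VLDL–CRP complex optics) is not modelled;
  only its waveform signature (a pre-clot ramp) is emulated.
- Lab values are sampled marginally per group; no longitudinal
  (pre-DIC → DIC) trajectories are generated.
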