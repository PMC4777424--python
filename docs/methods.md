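# Methods

This note documents the models inside `hbforecast`: what is assumed, which
parameters matter, what the synthetic cohorts do and do not emulate, and
where genuinely open design choices were resolved.

## The prediction problem

For a hemodialysis patient observed at time *t* (the date of a monthly
hemoglobin measurement), predict

ΔHb = Hb(t + 3 months) − Hb(t)   [g/dL]

from (i) the previous 90 days of history — administered IV darbepoetin and
iron, last available labs (ferritin, TSAT, albumin, phosphate, CRP),
session-level dialysis summaries (mean/SD eKt/V, weights, duration,
sessions/week) and static covariates — and (ii) the *next* 90 days of
darbepoetin/iron dosing. In a retrospective extract the future doses are
known; in deployment they are the candidate prescription being evaluated.
The 3-month horizon is not arbitrary: it spans one erythrocyte generation
(≈13 days marrow maturation + 60–90 days circulating lifespan in ESRD), so
Hb at *t*+3 months is almost entirely produced by dosing inside the window
the features describe.

## Cohort simulator

The simulator is a test harness that reproduces the *statistical shape* of
a dialysis EHR extract, not a physiological PK/PD contribution. Per patient
and per day *d*:

- **Exposure** E(d) = E(d−1)·2^(−1/t½) + dose(d), with t½ = 1 day for IV
  darbepoetin. Equivalently E(d) = Σ doses·2^(−Δt/t½), the form exposed as
  `esa_exposure` (additive in doses, by construction).
- **Marrow output** p(d) = p₀ + s·g(E(d − ℓ))·f_iron(d), where ℓ ≈ 13 days
  is the maturation lag, g(x) = x/(x+K) a saturating (Emax) dose–response
  with K = 4 µg-equivalents chosen so a typical 20 µg/week schedule sits
  mid-curve (this saturation is what produces hyporesponders), and
  f_iron = min(1, TSAT/20%) an iron-availability gate. A linear g is
  available for verification (it makes the Hb increment an exact
  convolution of a boxcar with the lagged exponential exposure, which the
  tests exploit).
- **Iron store** S(d) = S(d−1)·(1−0.005) + iron dose(d), mapped to
  TSAT = 45·S/(S+900) % and ferritin = 0.4·S µg/L. At the default
  ~33 mg/week this settles near TSAT ≈ 23 %, ferritin ≈ 380 µg/L.
- **Hemoglobin** Hb(d) = Σ_{k=d−L+1..d} p(k) + event terms, clamped to
  [3, 20] g/dL, with L the patient's red-cell lifespan (drawn uniformly in
  [60, 90] days). Constant production therefore gives the closed form
  Hb = p·L exactly.
- **Adverse events** (hospitalization −U(0.5,3) g/dL, transfusion
  +U(1,4), intercurrent −U(0.3,1.5); Poisson-dated at 0.6/0.15/0.4 per
  patient-year) contribute their full effect on the event day and decay
  linearly to zero over one red-cell lifespan — transfused cells die off
  and event-related losses recover. Laboratory errors (0.15/patient-year)
  corrupt a single monthly observation with an aberrant recorded value in
  U(5.5,8) or U(15,18) g/dL and never touch the true series.
- **Observation**: one Hb per calendar month on a per-patient lab day, with
  Gaussian assay noise of SD 0.5 g/dL (the commonly quoted intra-individual
  variability); ferritin/TSAT monthly, albumin/phosphate/CRP quarterly;
  sessions Mon/Wed/Fri.
- **Dosing controller**: after each monthly Hb the weekly darbepoetin level
  moves by 2.5 µg (5 µg when more than 1 g/dL outside the band) toward the
  10–12 g/dL target, capped at 200 µg/week; weekly iron moves by 25 mg on
  TSAT < 20 % / > 35 %. Real clinics' prescription logic is unknown; this
  controller is a stand-in whose purpose is to make dose history correlate
  with Hb history and to generate realistic Hb cycling.

Calibration targets were the cohort-level descriptive statistics the
simulator is meant to emulate: mean Hb ≈ 11 g/dL with SD ≈ 1.5, a
3-month Hb-variation SD near 1.6 g/dL, and a weekly darbepoetin median of
~20–30 µg. With the defaults the generated cohorts sit at Hb 10.9 ± 1.5
and ΔHb SD ≈ 1.6–1.9. Covariate distributions (age 62 ± 15, 39 % female,
eKt/V 1.38, session length 226 min, vintage 3.1 y, modality and access
mix) follow the published baseline profile of large European HD cohorts.
About 20 % of patients leave before 6 months, 3 % are incident (<90 days
vintage) and 10 % start without ESA, so the inclusion filters have real
work to do.

**What the simulator does not emulate**: multi-compartment erythropoiesis,
bleeding/hemolysis dynamics, inflammation-driven ESA resistance changing
over time, measurement schedules drifting with clinical state
(informative observation), or inter-clinic practice variation. Passing
tests on synthetic cohorts therefore demonstrate that the *pipeline* is
correct and that the *regressor can recover known signal* — not that the
accuracy numbers transfer to any particular clinical population.

## Record construction

- Windows are half-open: lookback (t−90 d, t], lookforward (t, t+90 d] —
  anchor-day doses count once, toward history.
- The target pairs the anchor with the Hb measurement nearest to t+90 days
  within ±15 days; records without a match are kept but flagged invalid and
  excluded from training/testing.
- "Three months" is operationalized as 90 days throughout.
- Inclusion filters run in a fixed order (each patient reports its first
  violated rule): ≥6 calendar months follow-up and ≥90 days vintage; ≥1 IV
  darbepoetin administration; no single administration >400 µg darbepoetin
  or >300 mg iron (a per-dose plausibility screen).
- Last-available lab values may be missing in a window; imputation (by
  training-split medians) is deferred to the model pipeline so the records
  table remains an honest image of the raw data.
- `sessions_per_week` divides by the *covered span* (first in-window
  session to the anchor, inclusive), so a patient dialyzed thrice weekly
  scores ≈3 whether present for the whole window or only part of it.

## Regressor

Architecture is fixed at two hidden layers of 10 tanh units with a linear
output. Features: 19 numeric (median-imputed), sex/diabetes as indicators,
modality and access one-hot — 27 columns, standardized; all statistics come
from the training split only. Weights initialize uniformly in
±1/√fan_in from a seeded generator.

Training minimizes full-batch MSE. The default driver is L-BFGS (scipy's
minimizer fed with the package's own backpropagation gradient, which is
verified against central finite differences at 1e−6 relative error);
gradient descent with momentum (lr 0.05, momentum 0.9) is available. Early
stopping monitors an inner 15 % validation slice of the training split
(max 2000 iterations, patience 50) and restores the best-validation
weights. A constant training target short-circuits to a bias-only fit. The
60/40 split is record-level by default — records of one patient can land on
both sides, an intentional mirror of the evaluation design this package
reproduces; a patient-level split is provided as the methodologically safer
option for honest generalization claims.

## Evaluation conventions

- Error = observed − predicted Hb(t+3), everywhere. Under this convention
  shrinkage makes the lowest observed-Hb quartile's mean signed error
  negative and the highest positive; `signed_error_by_quartile` also
  accepts the `pred_minus_obs` convention, since published reports differ
  in which difference they print.
- Bland–Altman: OLS of (obs − pred) on (obs + pred)/2; the slope p-value is
  a two-sided t-test. Analytic anchor cases: perfect predictions give slope
  0, a constant predictor exactly 2, a half-shrunk predictor exactly 2/3.
- "Within ±1.5 g/dL" uses strict inequality; large-error attribution uses
  strict |error| > 1.5 g/dL, credits every event type dated in
  (t, t+3 mo] (a record may count toward several types), and labels
  flagged records without any event "unexplained".
- Per-patient bins [0,0.5), [0.5,1), [1,1.5), [1.5,∞) g/dL partition
  per-patient MAEs.
- Ebben cycling uses a closed [10, 13] g/dL band (boundary values are
  in-band) over 6-month sliding windows of consecutive monthly values;
  a missing month breaks the chain.
- Error histograms use 0.25 g/dL bins.

## Reproducibility and problem sizes

Every stochastic component draws from `numpy.random.Generator` streams
spawned from one seed; the pipeline derives per-stage seeds (all < 2³¹)
from a single global seed, and identical config+seed yields byte-identical
CSV/JSON artifacts. The default evaluation scale — 300 patients over 3
years, ≈8,000 valid records — was chosen as the smallest cohort at which
the learnability and smoothing-effect analyses are stable across seeds;
simulation plus training completes in well under a minute on one CPU.

## Known limitations

- The simulator's dose–response and iron sub-models are deliberately
  minimal; parameter recovery (e.g., estimating a patient's true ESA
  sensitivity) is not a supported use.
- Record-level splitting leaks patient identity between train and test;
  accuracy under the patient-level split is systematically worse and is the
  number to quote for new-patient generalization.
- The attribution analysis is associational: an event inside the window
  explains a large error only in the sense of co-occurrence.
- Calendar months vary in length; the 90-day convention introduces ±2-day
  jitter relative to "3 calendar months", absorbed by the ±15-day pairing
  tolerance.
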