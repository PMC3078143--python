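# Methods

## Short-term variability

The package's central statistic is the short-term variability of an
interval series, STV = Σ|D_{n+1} − D_n| / (30√2), the mean orthogonal
distance of Poincaré points from the identity line. The customary "30
consecutive beats" phrasing is ambiguous: 30 beats yield only 29
successive differences, so either the normaliser overstates the count or
the window holds 31 beats. `qtvar` defaults to a **matched** 31-beat
window (30 differences), under which the printed normaliser is the true
difference count and the sum formula and the Poincaré-distance
formulation coincide exactly — an identity the test suite checks to
1e−9 relative on random windows. The **literal** 30-beat convention (29
differences, same 30√2 normaliser) is exposed through
`AnalysisConfig(mode="literal")`; it scales STV by 29/30 in expectation,
which is the entire difference between the modes.

One shared window per subject feeds everything: interval means, heart
rate (60000 / mean RR), the four QTc formulas (applied to the window
means, not beat-by-beat) and both STV values. The window is the first
contiguous run of all-normal beats of the required length — the simplest
deterministic policy; a lowest-variance-window policy was considered and
rejected because it biases STV downward by construction.

## Preprocessing

Exclusion mirrors common resting-ECG practice:

- **ectopic_excess** — ectopic fraction strictly greater than 5%
  (`ectopic_threshold=0.05`). The strict inequality matters at the
  boundary: exactly 2/40 = 5% is retained.
- **noise_excess** — unreadable-beat fraction strictly greater than 5%.
  "Excessive noise" is qualitative in clinical descriptions; the 5%
  fraction-of-unreadable-beats operationalisation is this package's
  choice (`noise_threshold`).
- **too_short** — no clean window of the required length exists.

Ectopy detection itself is rarely specified in cohort reports, so a
standard prematurity/delay criterion is used: a beat whose RR deviates
from the running median of the previous five non-ectopic RR values by
more than 20% (`ectopic_tolerance=0.20`) is re-annotated ectopic.
Flagged beats are withheld from the running buffer (one extrasystole
must not poison the reference for its neighbours), beats before five
non-ectopic predecessors are never flagged, and pre-existing annotations
are never un-flagged — which makes the detector idempotent, a property
under test. Note the filter's known behaviour at the tails: a subject
with genuinely extreme sinus arrhythmia (marginal RR SD approaching 20%
of the mean RR over a 5-beat median) can accumulate false ectopic flags
and, rarely, cross the exclusion threshold; this is a real property of
prematurity filters, not an artifact.

## QTc

Bazett (QT/√RR) is dimensionally inconsistent when RR is left in ms; RR
is taken in seconds (RR/1000), consistent with the explicit /1000 in the
Fridericia form, and outputs stay in ms. All four formulas reduce to the
identity at RR = 1000 ms and are strictly decreasing in RR at fixed QT —
both properties are tested.

## Statistics

Group values are reported as mean ± SEM (sample SD, n−1 denominator).
"Student's t-test" is read as the equal-variance pooled test
(df = n_a + n_b − 2); Welch's form is behind a flag. Repeated player
sessions are compared with a one-way ANOVA followed by a paired t-test
on subject-matched values, and an exploratory three-cell ANOVA is
reported alongside, since study descriptions rarely pin down which
comparisons the ANOVA preceded. A paired comparison whose differences
are constant and nonzero raises a documented degenerate-data error
rather than returning an infinite statistic. Histogram bins are
half-open `[k·b, (k+1)·b)` anchored at 0 (edge convention unspecified in
figure legends; anchoring at 0 makes bins reproducible across groups),
with b = 10 ms for QT and 0.5 ms for STV_QT. No multiple-testing
correction is applied, matching the study design the package reproduces.

## Synthetic cohorts

Real delineated ECG recordings for the motivating cohort are not
publicly deposited, so the generator produces interval series with the
statistical structure the analysis assumes:

- **Per-beat noise.** RR and QT fluctuate independently around
  subject-level means as stationary Gaussian AR(1) processes with lag-1
  correlation ρ (default 0; resting series are treated as white at this
  window length because no autocorrelation data are available to
  calibrate against). The marginal SD is set in closed form from the
  target STV: for m successive differences,
  E[STV] = (m/30)·σ·√(2(1−ρ)/π), hence
  σ = target·(30/m)·√(π/(2(1−ρ))) — at ρ = 0, σ = target·√(π/2)
  (e.g. 4.39 ms for a 3.5 ms target, 6.02 ms for 4.8 ms). The closed
  form follows from E|N(0, 2σ²(1−ρ))| and is verified against
  Monte-Carlo simulation in the tests.
- **Between-subject heterogeneity** is drawn on the scales cohorts are
  summarised on — heart rate in bpm and rate-corrected QT in ms — so
  group-mean HR and QT are unbiased for the scenario targets; drawing
  raw RR means instead would inflate mean HR via Jensen's inequality by
  ~1–2 bpm at realistic SDs. The subject QT mean follows the subject RR
  mean through a Fridericia-inverse coupling
  qt = qtc·(rr/1000)^(1/3); the population qtc is calibrated by
  Gauss–Hermite quadrature over the heart-rate distribution so E[QT]
  hits the target despite the nonlinearity. Coupling acts at the
  subject-mean level only — beat-level QT fluctuations are independent
  of RR fluctuations, so the two STV targets are independently
  controllable (tested: doubling target STV_RR leaves recovered STV_QT
  unchanged).
- **Trait standardisation.** By default the subject-level z-scores of a
  group are standardised to empirical mean 0 / SD 1 (the
  `mvrnorm(empirical=TRUE)` convention), so the realised cohort moments
  equal the scenario targets and a fixed-seed round-trip reproduces the
  group means up to within-subject estimation noise only. Individual
  subjects remain Gaussian draws. Set
  `GeneratorConfig(standardize_traits=False)` to study cohort-to-cohort
  sampling variability instead.
- **Pairing.** Players share subject ids and trait z-scores across rest
  and post-game scenarios, giving a repeated-measures design with
  rank-identical traits (cross-session trait correlation 1 — an
  idealisation; real test–retest correlations are below 1, so simulated
  paired tests are anticonservative relative to reality).
- **Ectopy.** Contamination is injected as isolated 40%-premature RR
  beats left annotated `normal`, so the preprocessing stage has to find
  them; injected counts are Binomial(n_beats, rate), placed non-adjacent
  and after beat 5.

### The packaged scenario

`scenarios/soccer_cohort.yaml` encodes the three-cell study: controls
(HR 72 bpm, QT 390 ms, STV_QT 3.5 ms), players at rest (61 bpm, 419 ms,
4.8 ms) and players post-game (STV_QT 4.3 ms), n = 76 per cell, 300
beats per recording (about five minutes at these rates), ectopic rate 0.
Between-subject SDs are set so simulated SEMs at n = 76 approximate the
reported ones (SD = SEM·√76, e.g. 0.87 ms for control STV_QT) — they are
calibration, not measured ground truth. Post-game HR (78 bpm) and QT
(386 ms, the coupling law at the players' rest-session QTc of ~421 ms)
and all STV_RR targets (25 / 40 / 25 ms, chosen to mirror the
qualitative pattern that players' RR variability is elevated at rest and
back near control level post-game, at magnitudes typical of young-adult
resting sinus arrhythmia) are assumed values, flagged as such in the
scenario file.

### What passing tests do and do not show

The generator emulates second-order structure only: means, variances,
lag-1 autocorrelation, Gaussian shape. It does not model respiratory
sinus arrhythmia, QT/RR hysteresis, beat-level QT–RR coupling (exposed
as a knob in principle but defaulting to 0), circadian or recovery
transients within a recording, or non-Gaussian heavy tails of real STV
distributions. Pipeline correctness and calibration results on these
cohorts therefore validate the computations, not any physiological
claim; on real data the matched/literal window choice, the delineator's
QT quality, and hysteresis effects can all shift absolute STV values.

## Numerical choices

- Intervals are quantised to 0.1 ms at generation and on CSV output
  (1 kHz-class acquisition), making I/O round-trips exact; the
  quantisation noise (SD ≈ 0.03 ms) is negligible against calibrated
  interval SDs.
- Generated QT is clamped below 0.9·RR so injected premature beats
  cannot violate the containment invariant.
- Heart-rate draws are floored at 30 bpm (and the calibration quadrature
  applies the same floor); at packaged SDs the floor is effectively
  never hit.
- Problem sizes in the test suite (window counts, replicate counts,
  subject counts) are chosen so each statistical assertion sits several
  Monte-Carlo SDs inside its band: e.g. 10⁴ windows for the closed-form
  E[STV] check (MC error ≈ 0.14% against a 2% band) and 500 zero-
  heterogeneity subjects for generator recovery (≈ 0.9% against 2%).
- All randomness flows from a single master seed through
  `numpy.random.SeedSequence` spawning — per-subject streams are
  independent and the cohort CSV is byte-identical across re-runs.

## Known limitations

- The exclusion stage sees only annotations and RR prematurity; it
  cannot distinguish atrial from ventricular ectopy, and it does not
  repair (interpolate) ectopic beats — subjects are either retained or
  dropped.
- `stv` is strict about window length by design; it does not silently
  rescale for other window sizes.
- The pipeline is lead-agnostic: it starts from delineated intervals
  and inherits whatever single-lead or multi-lead convention the
  delineator used.
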