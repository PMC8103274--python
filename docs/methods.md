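# Methods

## Problem and scope

`vrmotor` implements a quantitative battery for parkinsonian motor
dysfunction measured with seated virtual-reality tasks, a semiquantitative
analysis of striatal dopamine-transporter SPECT, and the statistical layer
that compares the two modalities for detecting a clinically important
difference (CID) in motor dysfunction and for predicting the UPDRS-III
motor score. Because no patient-level data is available, a seeded synthetic
cohort generator reproduces the statistical structure the analysis assumes,
so every stage can be exercised and tested end to end.

## VR measures

**VR Time (bradykinesia).** Each slicing attempt is an event log
(`session_start`, three `item_cut` events for bread/carrot/cucumber,
`session_end`); the attempt duration is `session_end − session_start`.
The per-hand VR Time reduces two attempts with a configurable aggregate
(default mean; `best` and `sum` available) since the original protocol does
not state the reduction.

**VR ADL Score (spills).** A virtual mug holds ten cylinders of liquid.
Whenever the mug's tilt from vertical exceeds a threshold (default 30°,
configurable — the protocol says only "a set threshold"), liquid drains:
one cylinder per 0.25 s of *cumulative* exceedance time (quantised, the
fractional remainder carries across episodes; both the quantum and the rule
are configurable). The attempt score is the cylinders remaining (0–10); the
per-hand score is the mean of exactly five attempts. Exceedance time uses a
sample-and-hold convention: the interval `[t_i, t_{i+1})` counts iff sample
`i` is above threshold. An independent per-sample event simulation is kept
in the test suite as the oracle for this quantised rule.

**Tremor spectra.** A 10-s controller recording at a nominal 90 Hz is
trimmed of its first 3 s (arm-placement artifact), linearly interpolated
onto a uniform 90 Hz grid, and linearly detrended per axis. The power
spectral density is a one-sided Welch estimate — Hann window, 256-sample
segments (≈2.84 s), 50% overlap, per-segment linear detrend, density
scaling (PSD integral ≈ signal variance). None of these estimator settings
is dictated by the protocol; they are conventional defaults giving a
0.35 Hz resolution bin. Features are the largest in-band PSD value across
the three *position* axes (m²/Hz) and its frequency (Hz). The analysis band
defaults to 0.5–12 Hz, wide enough for classic 4–6 Hz parkinsonian tremor
and the slower peaks seen in cohort means. The protocol mentions "angular
data" but reports position units; both streams are carried in the data
model, position is analysed by default. If the in-band peak does not exceed
a configurable noise floor (default 0, i.e. only an identically-zero
spectrum), the frequency is reported as a NaN sentinel while the power is
still reported. Only the second trial per hand and condition enters the
analysis; trial 1 is recorded but unused, mirroring the acquisition
protocol.

## SPECT semiquantification

From volume-of-interest mean counts (striatum, caudate, putamen per
hemisphere plus an occipital background reference):

- SBR = target/reference − 1;
- putamen-to-caudate ratio (on SBRs by default);
- z = (SBR − normative mean)/normative SD, age-matched against a normative
  table shipped as an editable CSV. The bundled table
  (`data/normative_synthetic.csv`) is synthetic — plausible healthy means
  with a mild age decline in 4 age bands — because vendor normative
  databases are proprietary.

**Enrolment gate.** A scan is "normal" when the putamen z-score exceeds a
threshold (default −2) on *both* sides; such patients are excluded from the
analysis cohort, with the excluded ids logged. The vendor cutoff behind the
original exclusions is unpublished; −2 is the conventional abnormality
bound. The gate is idempotent and every quantity is invariant under a
common positive rescaling of all counts.

## Statistics

- **CID label:** UPDRS-III > 10, strict.
- **Laterality:** Student's t-test per variable, two-sample equal-variance
  by default (paired available; zero-variance paired differences are
  flagged degenerate rather than producing NaNs).
- **Classification:** linear-kernel SVM (C = 1), features standardised on
  the training portion; posterior scores by a sigmoid (Platt) fit to the
  training decision values; evaluated by resubstitution and by stratified
  5-fold cross-validation (shuffled, seeded), each patient scored in the
  fold where it was held out.
- **ROC/AUC:** Mann–Whitney AUC with ties counted half; the standard error
  and 95% CI come from the placement (DeLong) variance. Correlated AUCs are
  compared with the placement-based two-sided z-test, which respects
  within-patient correlation of the two markers. This is a deliberate
  substitution for binormal ROC software used historically; p-values from
  the two approaches are not numerically interchangeable. Comparisons run
  on the subset of patients holding scores under both modalities.
- **Logistic regression:** maximum-likelihood fit with intercept of the CID
  label on age, male sex, right-hand dominance, PD-medication flag, and
  the cross-validated VR and SPECT SVM scores; Wald SEs, OR = exp(beta),
  two-sided Wald p. Complete/quasi-complete separation is detected and
  flagged on the result (with small cohorts and a strong VR score this is
  the expected regime; the coefficients are then reported but unstable).
- **Regression:** linear-kernel SVM regression (C = 1, ε = 0.1) of
  UPDRS-III. Rows with missing features are dropped first. A full-data fit
  gives the resubstitution MSE and the "all" split; a stratified (by CID)
  70/30 hold-out gives train/test splits. R² per split is the squared
  Pearson correlation of predicted vs observed with the two-sided p of zero
  correlation; 1 − SSE/SST is reported alongside (they differ out of
  sample).

Spectral peak powers enter the model feature matrices as log10(power +
1e-12): the raw powers span orders of magnitude, and the downstream linear
models standardise columns. The laterality table reports raw powers in
m²/Hz.

## Synthetic cohort

One latent severity S per patient, Beta(1, 1) by default, drives all
modalities:

- **UPDRS-III** = clip(round(53·S^γ + N(0, 3)), 0, 132), with γ ≈ 1.98
  solved so that P(UPDRS > 10) equals the target CID prevalence 0.57 under
  uniform S. Means and ranges land near the reference cohort (≈17 ± 15,
  0–53).
- **Tremor:** one tremor frequency per patient, uniform on 2–6 Hz;
  amplitude `amp_max·S²` (default amp_max 4 mm) injected as a sinusoid on
  one position axis plus 0.5 mm white noise and a small sub-band drift.
  Quadratic growth in S makes spectral power span orders of magnitude, as
  real cohort tables show.
- **Slicing:** duration = 40 + 70·S seconds ± N(0, 12), floored at 5 s.
- **ADL tilt:** |Ornstein–Uhlenbeck| process (mean reversion 2 s⁻¹) whose
  stationary RMS is 0.8·S rad; spill exposure grows stochastically with S.
- **SPECT:** per-side caudate SBR = 2.1 − 0.5·S + N(0, 0.65); putamen =
  caudate × ratio with ratio = 0.95 − 0.08·S + N(0, 0.09); striatum a
  0.45/0.55 caudate/putamen blend. VOI counts are reconstructed from the
  SBRs with a random reference level so the quantification path is
  exercised. The severity slope is deliberately small relative to the
  noise: the implied severity–SBR correlation is ≈0.2 in magnitude, the
  weak coupling reported for dopamine-transporter binding vs motor score in
  large PD cohorts. This asymmetry — VR tightly coupled to S, SPECT weakly —
  is the mechanism behind the qualitative VR > SPECT pattern the analysis
  reproduces.
- **Lateralisation:** one signed asymmetry per patient (|m| uniform on
  0.05–0.35) lowers the affected putamen's ratio by (1 − m) and raises
  tremor amplitude and tilt instability on the contralateral hand.
- **Demographics:** age N(64.5, 12.4²) clipped to 36–85; sex, handedness
  and medication are independent Bernoulli draws (48%, 86%, 27%). The
  medication flag is independent of severity, so adding it to SPECT
  features should not (and does not) move the AUC.
- **Missing VR data** is simulated at the pipeline level as
  missing-completely-at-random per patient (default rate 16/44 ≈ 0.36,
  matching the fraction of scans without complete VR data in the reference
  cohort); the true missingness mechanism ("time constraints") is
  unknowable.

Everything is a pure function of (config, seed) via `SeedSequence`
spawning; cohorts, CSVs and reports are byte-reproducible.

**What the generator does not emulate:** biomechanical arm dynamics,
harmonic or re-emergent tremor, tracking dropouts and sensor jitter,
age/cognition effects on task performance, correlated missingness, and any
image-level SPECT physics (reconstruction, attenuation, partial-volume
effects). Passing tests therefore demonstrate correctness of the estimators
and the analysis plumbing under the stated statistical model — not clinical
validity on real recordings.

## Numerical choices

- Resampling grid: `n = round((t_end − t_start_trim)·rate) + 1` uniform
  points; a 10-s, 90-Hz trace trimmed at 3 s yields exactly 630 samples.
- Spill quantisation uses `floor(total/drain + 1e-12)` so exact multiples
  of the quantum drain deterministically despite float accumulation.
- AUC CI is normal on the AUC scale, clipped to [0, 1]; a zero AUC
  difference reports p = 1 exactly, and a zero-variance nonzero difference
  reports p = 0 with an infinite z (degenerate, not an error).
- Constant predictions in a regression split report R² = 0, p = 1 with a
  degenerate flag instead of NaN.
- CSVs are written with shortest round-trip float reprs and read with
  pandas' `round_trip` parser, making `read(write(x)) == x` exact.

## Problem sizes in the shipped checks

The repeated-cohort comparison uses 100 cohorts of n = 44; null
calibrations use 50 seeds at n = 400 (classification) and n = 200
(regression); the spill-rule oracle equivalence uses 1,000 random traces;
AUC pair-counting is exhaustive over all labelings up to n = 12. These
sizes were chosen to make the Monte-Carlo means stable to well under the
asserted margins.

## Known limitations

- The placement-based correlated-AUC test is asymptotic; at n ≈ 30–44 its
  p-values are approximate (the power check in the tests is the relevant
  guarantee, not exactness).
- With strong VR coupling, logistic fits are frequently (quasi-)separated;
  the separation flag, not the coefficient table, is the reliable output in
  that regime.
- The laterality table reuses the two-sample t-test default even though the
  left/right measurements are paired within patients; paired mode is
  available but the original analysis' pairing is unstated.
- Hold-out R² at test sizes of 8–13 patients has large seed-to-seed
  variance; only means over many cohorts are asserted.
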