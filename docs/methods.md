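# Methods

## Model and assumptions

Preferences over two-component reward bundles are generated by a hyperbolic
utility surface

    u(qA, qB) = a·qB + b·qA + c·qA·qB

with quantities in ml on a 0–0.9 ml range (0.1-ml steps in the standard
designs). Level sets of `u` are the indifference curves (ICs); `a/b` is the
currency relation between the rewards (ml of A per ml of B at the margin) and
`c` bends the curves (c > 0 convex toward the origin when plotted as qA
against qB). Construction rejects parameterizations that are not strictly
increasing in both rewards anywhere on the quantity range, since revealed
preference arguments presuppose "more is better".

Stochastic choice is softmax in utility: an option set of two or three
bundles is chosen with probabilities `softmax(u_i / τ)`. The temperature τ is
the one free behavioral noise parameter; no generative choice rule is implied
by the indifference-curve formalism itself, and a logistic/softmax family was
chosen because the psychometric stage fits a different monotone sigmoid (a
cumulative Weibull) — recovery of the indifference point across the two
families is itself a test of robustness, exercised throughout the suite.

Simulated neurons emit per-epoch Poisson counts over five fixed epochs:
pretrial 1 s (always baseline), bundle stimulus 2 s, go 1 s, choice 1 s, and
reward 2 s (covering both liquid deliveries). Tuning classes: positive and
inverse revealed-preference coders (rate = baseline ± gain·u of the offered
bundle), single-reward coders (rate follows one quantity only), absolute and
relative chosen-value coders (rate follows u of the chosen bundle, or chosen
minus best-unchosen), and unmodulated cells. Rates are linear in their signal
by default (an optional monotone transform hook exists) and clipped at zero
before the Poisson draw.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| a, b, c | utility coefficients | 1.0, 1.25, 0.4 | non-diagonal currency (A ≈ 1.25× B per ml) with mild convexity, so slope and curvature estimation are both exercised |
| τ | choice temperature (utility units) | 0.05 | psychometric functions rise from ~0.1 to ~0.9 over the 5-point, 0.1-ml grids: sharp but clearly stochastic |
| IP block | 2 positions × 5 quantities × 8 reps | 80 trials | standard psychophysical design |
| choice block | 12 option pairs × 2 positions × ≥10 reps | 240 trials | standard neuronal test design |
| baseline rate | pretrial firing | 10 imp/s | typical cortical baseline |
| gain | imp/s per utility unit | 10–25; calibrated for benchmarks | see calibration below |
| bootstrap | resamples for CIs | 1000 (fits), smaller in orchestration | percentile CIs, seeded |
| decoding | 10 trials/class, 20-fold LOO, 150 iterations, linear SVM C = 1 | — | larger per-class counts did not change conclusions; C sensitivity is flat for these separations |

Signal calibration for the population benchmarks: the Poisson gain is
grid-searched so that the mean per-neuron Spearman correlation between
trial responses and IC rank is ≈ 0.6 at 10 trials per bundle — a deliberately
moderate single-cell signal at which the population-level claims (decoding,
out-of-sample curve validation) must still hold.

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: stochastic
choices driven by a fixed utility over the session, pseudorandomly
interleaved balanced designs (balanced-then-shuffled; left/right positions
counterbalanced exactly), independent Poisson spiking per neuron and epoch,
and trial tables with the same schema the fitting code reads. It does not
emulate: within-epoch spike timing (counts only), satiety or value drift
(except as an explicit planted manipulation in tests), serial choice
dependencies, attention or gaze effects, inter-neuron noise correlations
(neurons are simulated independently, as pseudo-populations assume), or
non-Poisson count dispersion. Passing tests therefore demonstrate that the
estimators recover the truth under their own assumptions at realistic trial
counts — not that real cortical data satisfy those assumptions.

## Numerical choices

- **Psychometric fit.** Two-parameter cumulative Weibull
  `P(x) = 1 − exp(−(x/α)^γ)` fit by binomial maximum likelihood
  (Nelder–Mead on log-parameters); optional guess/lapse rates default to 0.
  The IP solves P = 0.5 in closed form. CIs by parametric bootstrap
  (binomial resampling at the fitted probabilities, refit, percentile
  interval). Perfect separation (all-or-none frequencies) returns the
  midpoint between the last never-chosen and first always-chosen quantity,
  flagged; an all-same-choice block raises.
- **IC fit gauge.** The hyperbolic coefficients are identified only up to a
  common scale, so each curve is normalized to level d = 1 and fit by
  weighted least squares of `1 = a·x + b·y + c·x·y` (weights default to the
  inverse bootstrap variance of each IP). If the unrestricted fit produces a
  rising or singular branch on the quantity range, the interaction term is
  pinned to 0 and the linear curve refit. The interaction coefficient is
  weakly identified from few near-collinear IPs; its uncertainty is carried
  by the bootstrap and tests assert its CI coverage rather than its point
  value.
- **Scale-free curve comparison.** Neuronal curve slope is the coefficient
  ratio β2/β1, compared with behavioral a/b; curvature is compared as β3/β1
  against c/b. Both ratios are invariant to the arbitrary overall scale of
  each coefficient vector (response gain, curve-level normalization) and
  coincide exactly when the response is an affine function of the utility.
- **Iso-response curves.** The level form `k = β1·qA + β2·qB + β3·qA·qB` is
  inverted exactly as `qA(qB) = (k − β2·qB)/(β1 + β3·qB)`; points where the
  denominator vanishes are masked. Level grids are deciles of the fitted
  response range. The ±95% band is 1.96× the pooled regression's residual
  RMSE (the error that merges into the offset constant), converted to ml
  along the y-axis by dividing by |β1 + β3·qB|. Out-of-sample responses are
  matched to the nearest level ("matching color"), with responses outside
  the training level range matched to the end curve and flagged.
- **ANOVA.** The two-factor test (across-IC × within-IC position) uses Type
  II sums of squares on the generally unbalanced designs; within-IC levels
  order bundles by ascending qB. When every curve holds a single bundle
  (grid designs) the within factor is vacuous and a one-way across-IC test
  is used with the within and interaction p-values reported as 1.
- **Nested model comparison.** Whether the interaction/quadratic extensions
  beat the two-reward base model is decided by the nested-model F-test on
  residual sums of squares, with adjusted R² reported alongside.
- **Wilcoxon screening.** Paired signed-rank per epoch against pretrial at
  P < 0.01, exact method for small samples (scipy's automatic switch);
  all-tied samples cannot reject. The sliding-window confirmation groups
  50-ms bins into 150-ms windows and requires four consecutive significant
  windows (600 ms), which rejects brief transients.
- **Decoding.** Within-neuron label shuffling for the null. Note that
  20-fold leave-one-out on pure noise has a small below-chance expectation
  (~48%): removing one trial leaves its class in the training minority, and
  the decoder leans toward the majority. This is a property of the
  protocol, not of the data; the benchmark reports it as measured and
  averages over independently simulated populations only to reduce
  simulation variance.
- **Degenerate inputs.** Constant regressors are dropped and reported;
  perfect separation in logistic fits is flagged rather than fit;
  rank-deficient response designs raise naming the collinear dimension;
  CV/UCV correlation above 0.95 refuses value classification; a constant
  UCV reduces the value regression exactly to a CV-only fit.

## Open design choices made

- The single-reward rule (reduced regressions, each-but-not-both
  significance, nested F-tests) is only identifiable on designs where the
  two quantities are uncorrelated — rectangular grids and anchor trials. On
  bundles-on-IC designs the trade-off itself anticorrelates qA with qB, and
  a genuine single-reward cell then also loads on the other reward's reduced
  model; such responses surface as `mixed`. Tests and benchmarks therefore
  use grid designs for single-reward questions.
- During choice over a zero-reward bundle, the chosen value equals the
  offered bundle's value, so chosen-value cells legitimately classify as
  revealed-preference coders there; the two are dissociated only in choices
  between two nonzero bundles.
- Three-option unchosen value is the maximum over unchosen options
  (configurable).
- The choice-axiom thresholds (frequency > 1/3 in the triple, > 1/2 in the
  pair) are strict; empirical ties return an indeterminate verdict, as does
  a triple whose winner is absent from the tested pair (the axiom does not
  constrain that reduction).
- k1 is estimated from anchor psychophysics per session rather than read off
  fitted ICs, keeping the currency estimate independent of the curve model.

## Problem sizes

The default test-suite and reproduction-script scales — 12–25 neurons,
80-trial psychometric blocks, 4 curves × 3–4 bundles × 10 trials, 6×6 bundle
grids, 60–300 bootstrap resamples, 150 decoding iterations, 20 validation
seeds — were chosen so the full suite completes in a few minutes on one CPU
while keeping every statistical claim at its stated threshold.

## Known limitations

- The Weibull forces P(0) = 0, while the softmax generator does not; the
  slight mis-specification at the low tail is absorbed by the fit and does
  not bias the IP detectably at the study's noise level, but extreme
  temperatures would expose it.
- Curvature (interaction) coefficients are weakly identified on small
  on-curve designs; claims about curvature should come from grid designs or
  pooled populations.
- The pipeline estimates one utility per session; preference drift within a
  session is detected (satiety flag) but not modeled.
- Decoding assumes trial-exchangeable pseudo-populations; simultaneously
  recorded populations with noise correlations are out of scope.
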