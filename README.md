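# revpref

Revealed-preference analysis of two-component reward bundles: a tested,
reusable pipeline for studying how scalar signals (stochastic choices, single
neuron firing rates) represent vectorial choice options.

## The problem

A choice option composed of two rewards — quantity *qA* of reward A and *qB*
of reward B, both in milliliters — is a vector, but preferences and neuronal
firing rates are scalars. Revealed Preference Theory resolves the mismatch
with indifference curves (ICs): bundles chosen against each other with equal
probability (P = 0.5) are indifference points (IPs); IPs trace an IC; bundles
on higher ICs are revealed preferred. `revpref` implements that program end to
end on simulated data:

- **Stochastic choice simulation** from a hyperbolic utility
  `u(qA, qB) = a·qB + b·qA + c·qA·qB` with softmax choice at temperature τ,
  plus Poisson spiking neurons from revealed-preference, single-reward,
  chosen-value, and unmodulated tuning classes across five task epochs.
- **Behavioral estimation** — two-parameter cumulative-Weibull psychometric
  fits (`P(x) = 1 − exp(−(x/α)^γ)`, IP at P = 0.5, parametric-bootstrap CIs),
  weighted least-squares hyperbolic IC fits (`d = a·x + b·y + c·x·y`,
  normalized to d = 1), marginal rate of substitution `MRS = −dy/dx`, logistic
  choice-control regressions, and a satiety-drift detector.
- **Neuronal classification** — responses z-scored to the pretrial epoch are
  labelled by a three-test procedure: double linear regression on both rewards
  (both coefficients significant, same sign), Spearman rank correlation across
  ICs, and a two-factor ANOVA (significant across ICs, not within, no
  interaction); single-reward coding via reduced regressions with nested
  F-tests.
- **Neuronal indifference curves** — pooled interaction regression
  `z = β0 + β1·qA + β2·qB + β3·qA·qB`, iso-response curves
  `qA(qB) = (k − β2·qB)/(β1 + β3·qB)`, slope (β2/β1) and curvature comparison
  with behavior, and out-of-sample validation against a ±95% band in ml.
- **Chosen value** — common-currency weight k1 from anchor psychophysics
  (k1 = qA/qB at indifference between single-reward bundles), CV/UCV
  regressions, and value-coding categories.
- **Decoding** — pseudo-population leave-one-out linear SVM/LDA (10 trials
  per class, 20-fold LOO, 150 iterations) with a within-neuron shuffle null.
- **Choice axiom** — behavioral and neuronal tests of the weak axiom of
  revealed preference under three-to-two option-set reduction.

## Worked example

```bash
python examples/01_behavioral_indifference.py
```

```
qB=0.1 ml: IP at qA=0.373 ml (95% CI 0.345-0.403, truth 0.368), P(choose variable at IP)=0.50
qB=0.2 ml: IP at qA=0.310 ml (95% CI 0.279-0.344, truth 0.282), P(choose variable at IP)=0.50
qB=0.3 ml: IP at qA=0.200 ml (95% CI 0.195-0.204, truth 0.201), P(choose variable at IP)=0.50
qB=0.4 ml: IP at qA=0.120 ml (95% CI 0.089-0.149, truth 0.124), P(choose variable at IP)=0.50

hyperbolic curve (level=1): a=1.93 b=2.17 c=-0.24, adj R2=0.983
slope at origin -0.89 (ml of A per ml of B; steeper than -1 means B is the pricier reward)
MRS at qB=0.0: 0.84 (ml of A the agent trades for one more ml of B)
```

Each line is one 80-trial psychophysical block (2 stimulus positions × 5
quantities × 8 repeats): the fitted Weibull crosses P = 0.5 at the estimated
IP, whose bootstrap CI brackets the generator's analytic indifference point.
The hyperbolic fit through the IPs gives the curve's slope (the currency
relation between the rewards) and curvature; the MRS is how much reward A the
agent gives up per extra ml of reward B at constant preference.

The other scripts in `examples/` walk through neuronal classification,
iso-response curves with out-of-sample validation, common-currency chosen
value, population decoding, the choice axiom, and the end-to-end session
pipeline (`revpref.run_pipeline`), each printing the numbers it computes.

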