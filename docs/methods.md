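# Methods

## Task model

The generator emulates a change-point predictive-inference ("helicopter")
session: 280 trials in 4 runs of 70, a hidden mean on a 0–100 screen scale
that relocates with per-trial hazard H (default 0.125, exposed in
`TaskConfig`; the forced first trial of each run also counts as a change
point because runs restart the helicopter), outcomes drawn Gaussian around
the mean with run-wise SD alternating 2.3 / 4.6 screen units, binary reward
labels with probability 0.5, and a catch criterion |prediction − outcome| ≤ 5
screen units (the on-screen width of the bag).

Numerical choices:

- Outcomes falling off-scale are **redrawn** (rejection sampling), not
  clipped: clipping would put point masses at 0 and 100 and distort the
  cubic edge-term regressor.
- New means are drawn uniform with a 10-unit margin from the scale edges
  (configurable), mirroring the on-screen landscape and avoiding
  edge-saturated blocks.
- The hazard rate and the exact change-point spacing of the original fixed
  trajectory are not public; 0.125 gives the episodic structure of roughly
  2–3 change points per 20-trial stretch and is the conventional value for
  this task family. Any match to published summary magnitudes is therefore
  approximate by construction.

## Observer

The reduced-Bayesian observer approximates the exact run-length mixture
with one Gaussian of matched mean and variance. Per trial, with prediction
error δ, relative uncertainty τ (share of predictive variance due to the
mean), noise SD σₙ and scale width W = 100:

```
Ω  = (H/W) / (H/W + (1−H)·N(δ; 0, σₙ²/(1−τ)))          change-point probability
τ' = N/(N+σₙ²),  N = Ωσₙ² + (1−Ω)τσₙ² + Ω(1−Ω)(δ(1−τ))²  uncertainty update
α  = Ω + (1−Ω)τ                                          learning rate
B' = B + αδ                                              belief (self mode)
```

σₙ²/(1−τ) is the total predictive variance σₙ² + σ_belief² under no change;
1/W is the predictive density under a complete relocation. Useful fixed
points: Ω=0 gives τ′ = τ/(τ+1) (slow hyperbolic decay through stable
stretches, τₙ = τ₁/(1+(n−1)τ₁)); Ω=1 gives τ′ = 0.5 (one observation's
worth of information about a fresh mean).

Conventions and open choices, fixed as follows:

- **Conditioning modes.** `self` propagates the model belief (normative
  agent); `empirical` replaces the belief each trial by the participant's
  actual prediction, so Ω/τ trajectories are driven by the individually
  observed signed PEs. All behavioural analyses use empirical mode.
- **Timing.** `ru[t]` and `belief[t]` are pre-outcome state; `cpp[t]`,
  `lr[t]`, `pe[t]` refer to the outcome of trial t. Hence mean CPP peaks on
  the change trial and mean RU on the trial after — the double dissociation
  the dynamics checks assert.
- τ resets to 0.5 at run boundaries (runs restart the helicopter); the
  observer is assumed to know the true run-wise σₙ (instructed via
  practice).
- Missing trials freeze the observer state by default (`freeze`); the
  alternative of advancing on the outcome alone is config-switchable
  (`advance`).
- τ = 1 is a degenerate state (infinite predictive variance) and raises.

A grid filter (`full_bayes_oracle`, ≥201 points, uniform redraw on change,
exact Bayes) serves as validation oracle only. Self-mode beliefs agree with
its posterior mean to ~0.27 screen units on average (max ~0.64 across 40
70-trial schedules, both noise regimes), and reduced CPP rank-correlates
with the oracle change posterior at ρ ≥ 0.92 on every tested schedule; the
test tolerance (mean |ΔB| < 1 screen unit) was frozen from that first
oracle run.

## Agents

Agents mirror the analysis regression generatively. The intended update is

```
u = b₀ + w_PE·δ + w_CPP·δΩ + w_RU·δτ(1−Ω) + w_reward·δr
    + w_edge·((B−50)/50)³·50 + ε,   ε ~ N(0, σ_motor²)
```

with lapses (uniform prediction), perseveration (no update) and missing
responses as competing per-trial events; predictions clip to the scale; the
agent's Ω/τ are computed online from its *own* PEs, so generative and
analysis models share one set of recursions. The normative agent is the
special case w_CPP = w_RU = 1, all else 0 (update = αδ); it dominates
fixed-LR agents in performance error across seeds.

Cohort presets (the study conditions): the control-like agent uses
w = (0.75, 0.15, 0.15, 0.03) for (PE, CPP, RU, reward), motor noise SD 2,
lapse 0.01, perseveration 0.02, missing 0.04; the PSD-like agent
(0.65, 0.05, 0.20, 0.03), motor noise 3, lapse 0.03, perseveration 0.08,
missing 0.04 — i.e. CPP down-weighted and non-updates increased. Weights
jitter between subjects (SD 0.08/0.05/0.08/0.03); these values were chosen
to put the per-subject regression coefficients and group summary statistics
(mean LR ≈ 0.6–0.7, post-change-point LR ≈ 0.65–0.85, performance error
≈ 6.5–8 screen units per trial, ~4% missing) in the published cohort's
range, and the CPP group shift (0.15 vs 0.05 against 0.05 between-subject
SD) was calibrated once on a pilot so the group logistic detects it
reliably at n = 40 vs 19. Covariates (age, delusional-ideation score,
symptom scales, six cognitive domains) are drawn from the two groups'
published means/SDs; symptom scores optionally load on weight deviations
(default: delusional ideation −2·z(w_CPP) + 2·z(w_RU)) so that symptom
regressions have a recoverable signal. Setting all loadings to zero yields
null cohorts.

What the generator does **not** emulate: sequential response dynamics
(reaction-time/accuracy trade-offs), trackball motor kinematics, visual
attention, practice or fatigue effects, medication, and any correlation
structure among covariates beyond the configured loadings. Passing tests
therefore demonstrate correctness and calibration of the estimators under
the generative model, not fidelity of that model to human data.

## Behavioural statistics

- Empirical LR_t = update_t / δ_t, the update following the PE of trial t.
  Trials with |δ| < 1 screen unit are excluded (raw LR explodes near δ=0).
  For aggregation, LR > 1 → 1 and LR < 0 → 0; raw values are kept, trials
  with raw LR < −0.1 are counted as aberrant and can be excluded
  (switchable follow-up filter).
- Update categories default to the bounds non < 0.1 ≤ moderate < 0.9 ≤
  total; an alternative low bound of 0.01 is config-exposed because the two
  printed variants of the rule disagree.
- Performance error = |prediction − hidden mean| summed within blocks and
  across; default reported per trial (mean mode), total sum available.
- The update regression is OLS with intercept on centred regressors
  {δ, δΩ, δτ(1−Ω), δr, ((B−50)/50)³}. Reward enters as an interaction with
  the PE by default (updates scale after rewarded outcomes); a main-effect
  coding is config-exposed. Zero-variance columns are dropped with a logged
  warning; residuals keep session length (NaN where excluded) and feed the
  fMRI residual modulator.
- Recovery: at the recovery conditions (weights 0.5/0.3/0.2/0.1, motor
  noise 2, 280 trials) median recovered coefficients sit within ±0.05 of
  truth over 100 seeds. A small finite-sample bias of order 1/T (largest on
  the weakly identified RU interaction, ~0.03 at T=280, vanishing at
  T=1120) is inherent to OLS with predetermined regressors — the motor
  noise of trial t enters the regressors of later trials through the
  belief and τ recursions — and is not an implementation error.
- Group comparison reports Welch t and Wilcoxon rank-sum side by side;
  the sensitivity re-analysis removes values > 3 normalized MADs from the
  group median (the published analysis names no explicit outlier rule).
- The group logistic falls back to an L2-penalized fit (coefficients only,
  p = NaN, flagged) on separation. No multiple-testing correction is
  applied anywhere, matching the reporting convention of the analyses this
  package mirrors; this is deliberate and documented rather than silent.

## fMRI design and GLM

Microtime resolution is 16 bins per TR (TR default 0.8 s); the canonical
double-gamma HRF (peak ~5 s, undershoot ~15 s, 32 s support) is normalized
to its continuous peak so kernels at different TRs subsample one curve.
Modulator trial series are standardized within run (noise regime alternates
by run; session-level standardization is config-switchable), multiplied
into the 1-s bag-drop boxcar at microtime resolution, convolved and
sampled at scan onsets; they are **not** orthogonalized. Error trials get a
dedicated regressor spanning the full decision window; the column is
dropped if a session has no missing trials. Motion nuisance columns are
supplied or simulated as smooth AR(1) series. High-pass filtering is
omitted in simulation (drift can be injected via noise settings); the
timing template fixes fixation at 0.5 s and feedback at 1.5 s (package
choices), decision window ≤ 3 s, ITI uniform 1–3 s.

Estimation is ordinary least squares, optionally with single-pass AR(1)
prewhitening (rho estimated from pooled OLS residuals). On noiseless
simulated BOLD betas reproduce the generating values to numerical
precision; at the working SNR (noise SD 2 at unit CPP beta, one 70-trial
run) the CPP beta is unbiased with ~95% CI coverage over 200 seeds despite
the modulators' native collinearity (max pairwise |r| ≈ 0.3). VOI-level
analyses are a linear model beta ~ group + age and Spearman correlations
with symptom/cognition scores; voxelwise group maps, smoothing and
preprocessing are out of scope. Published cluster coordinates are treated
as metadata only.

## Pipeline

`run_study` chains schedule → cohort → empirical observer traces →
learning-rate/performance summaries → per-subject regressions → group and
symptom models → optional per-subject VOI fMRI simulation/recovery, with
all randomness spawned from one master seed (per-stage/per-subject
sub-seeds, so enlarging the cohort never perturbs existing subjects) and a
content-hashable report. Configs are schema-validated (unknown keys
rejected); an empty config file reproduces the default study. The numbered
scripts under `analysis/` are the command-line entry points; each is a thin
driver over these library calls and writes tidy CSVs under `results/`.

## Problem sizes

Default checks use: 40 oracle schedules of 70 trials (grid 401), 30
schedules (≥200 isolated change points) for dynamics, 100 recovery seeds,
200–400 null draws for calibration, 30–40 simulated cohorts of 59 subjects
for detection rates, and 200 BOLD noise seeds for GLM coverage — sizes at
which every check's sampling error is small relative to its assertion band.

## Known limitations

- The observer recursions follow the standard reduced-Bayesian formulation
  of this model family; the original study's exact supplementary formula
  sheet is not public, so minor parameterization differences are possible.
- Hazard and the fixed trajectory are reconstructed, not copied; published
  group magnitudes are targets of plausibility, not of numerical match.
- The logistic fallback reports no standard errors under separation.
- AR(1) whitening is single-pass (no iterated Cochrane–Orcutt, no
  spatially regularized autocorrelation).
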