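# Methods

This note documents the models, estimators, numerical choices, and the
synthetic-data conditions used throughout `latentcp`, and states what
the tests do and do not establish.

## Session geometry and conventions

A trial stores 1500 one-millisecond bins: 100 ms pre-stimulus, seven
150 ms motion pulses, 350 ms post-offset.  Time zero is **stimulus
onset**; stored arrays begin at t = −100 ms, and every window
specification in the package (epochs, time-course windows, pulse
onsets) is relative to stimulus onset.  Bins are half-open `[t, t+dt)`.
Choice is coded 1 for the saccade toward the positive-pulse direction,
so CP > 0.5 means activity predicts positive-direction choices.
Sessions round-trip bit-exactly through a fixed HDF5 layout
(`/session/{spikes,pulses,choice,correct,frozen}` plus timing
attributes, written without HDF5 timestamps so files are byte
deterministic).  The minimum-population threshold for analysing a
session is exposed as a parameter (≥ 10 neurons by convention).

## Latent model and variational inference

Each latent dimension carries an independent GP prior with
squared-exponential kernel (defaults: variance 1, timescale 100 ms,
jitter 1e−6 — the timescale matches the pulse duration, which is the
natural scale of stimulus-driven rate changes).  Spikes are a point
process through `y_t ~ Poisson(exp(A x_t + b))`; at 1 ms resolution the
counts are effectively binary.

**Parameterisation.**  The prior covariance over a trial is truncated
to its top-r eigenpairs, `K ≈ Φ Φᵀ` with `Φ = U_r S_r^{1/2}` (default
r = 50; for a 100 ms squared-exponential kernel on 1500 bins the
spectrum has decayed by many orders of magnitude well before rank 50).
Posteriors live in whitened coordinates `x_k = Φ z_k`,
`q(z_k) = N(m, C)` with a full r × r covariance.  This keeps memory
linear in trial length, makes every covariance PSD by construction, and
reduces the KL term to the exact Gaussian KL against `N(0, I_r)`.  The
expected Poisson likelihood uses `E[exp(aᵀx)] = exp(aᵀμ + aᵀΣa/2)`.

**Optimisation.**  Coordinate ascent alternates (i) per-trial,
per-dimension Newton steps on `m` and damped fixed-point updates on `C`
(the trial ELBO is concave in each), and (ii) per-neuron Newton updates
of the loading row and bias (penalised Poisson regression, ridge 1e−4
on loadings), every step gated by a backtracking line search on its
exact local ELBO component.  The ELBO trace is therefore non-decreasing
(asserted at 1e−6 relative tolerance).  Initialisation: loading
directions and latent means from PCA of square-root-transformed 100 ms
counts (means upsampled to 1 ms and projected onto Φ), bias at the log
mean rate.  Non-convergence within `max_iter` returns the best iterate
with `converged=False`.  Log intensities are capped at 30 before
exponentiation, applied identically in the ELBO and all gradients, so
the optimised surrogate stays consistent.  On exit each posterior-mean
dimension is rescaled to unit variance across the session with the
inverse scale absorbed into the loading column (identifiability
convention only; it changes no predicted rate).

**Dimensionality selection.**  Leave-one-neuron-out co-smoothing: for
each candidate dimensionality and each neuron, fit on the remaining
neurons, infer latents, and score a Poisson regression of the held-out
neuron's counts on those latents.  The regression is **cross-fitted
over trials** (weights from one half, log likelihood on the other,
both directions summed).  An in-sample score was rejected because
smooth latent trajectories and smoothly varying spike rates are
strongly autocorrelated: spurious regression between smooth series
rewards useless extra dimensions by tens of log-likelihood units, far
beyond the ~0.5 per degree of freedom expected under independence, and
the score then grows monotonically in the candidate dimension.
Ties are resolved by the one-standard-error rule (smallest
dimensionality within one paired standard error of the best score).

## Stimulus axis

The pulse design uses raised-cosine bumps
`b_j(t) = (1 − cos(2π(t − t_j)/100))/2` on `[t_j, t_j+100)` ms, onsets
0/50/100/150 ms after each pulse, scaled by the signed pulse strength —
28 columns for 7 pulses.  Weights are fit by ridge regression with the
penalty chosen by generalized cross-validation,
`GCV(γ) = ‖(I−H)y‖² / (n(1 − tr H/n)²)` summed over target columns, on
a fixed grid of 15 log-spaced values in [1e−6, 1e3].  Two numerically
equivalent routes exist: an SVD route (reference) and a Gram route that
accumulates `DᵀD` and `Dᵀy` from the shared per-trial basis template so
the concatenated design (≈ 10⁶ rows) is never materialised; they agree
to 1e−8 and the PTA uses the Gram route.  PTA curves are the
unit-pulse basis expansion of the weights, smoothed with a Gaussian
kernel of σ = 40 ms (truncated at ±3σ, unit mass; width 0 disables
smoothing).  The SVD `Wᵀ = USVᵀ` gives the rotation `Uᵀx`; per-factor
stimulus power fractions are `S_k²/ΣS_j²`.  Each rotated factor's sign
is flipped so its pulse-averaged unit-pulse response is positive at the
lag of largest magnitude, making the stimulus-axis direction
reproducible across seeds.

## Choice pipeline

*Weak trials*: coherence is `|Σ s_i|`; levels are added in ascending
order and a level is kept only while the pooled correct rate of the
included trials stays below 65% (level 0 always included; the rule
stops *before* crossing the threshold).  Sets below 100 trials are
flagged excluded.

*Residualization*: per 100 ms bin, an intercept-free GCV-ridge
regression of activity on the 7 pulse strengths; residuals
`r_t = x_t − Σ w_ti s_i`, whole-trial residual `r = Σ_t r_t`.

*Decoders and choice mapping*: L2-penalised logistic regression of
choice on `r`, with the bias penalised together with the weights
(implemented by appending a constant column).  The penalty is chosen by
3-fold stratified cross-validation maximising held-out log likelihood;
the same three folds provide the held-out mapped values
`c = σ(βᵀr + β₀)` (each trial's `c` comes from the decoder that did not
train on it), which is what makes high-dimensional axis sets unable to
inflate CP through overfitting.  Features are not standardised — the
CV over a 9-decade penalty grid adapts to their scale.

*CP*: the two-sample ROC area with tie correction (Mann–Whitney
statistic / n₁n₀) of the held-out `c` grouped by choice.  This is the
field-standard CP definition; it is verified exactly against
brute-force pair counting and against trapezoidal ROC integration.

*Nested tests*: unpenalised logistic models of choice on (c_stim),
(c_stim, c_nonstim), (c_stim, c_nonstim, c_pop); likelihood ratios of
successive models with χ²(1) p-values on −2 log LR.  Perfect separation
falls back to a weak ridge (1e−8) with a warning.

*Session pooling*: multi-session analyses concatenate held-out mapped
values.  `session_pooled_likelihood_ratio` quantifies what pooling
costs: the full logistic choice model fit to the pooled trials is
evaluated on each session and compared with that session's own fit;
ratios near 1 mean pooling keeps essentially all the choice
information.  Because the per-session fit enjoys an overfitting
advantage of roughly half its parameter count in log likelihood, the
ratio approaches 1 from below as per-session trial counts grow.

*Time course*: decoders fit to early (200–500 ms), middle (600–900 ms)
and late (1000–1300 ms) epoch residual sums, then applied to every
100 ms window's residual; CP per window per decoder.  Epoch-window CPs
are in-sample for the windows inside the training epoch, as in the
whole-period mapping this mirrors.

## Validation statistics

Noise correlations on frozen trials subtract the frozen-trial PSTH per
neuron and bin before correlating over (trial × bin) samples
(zero-variance channels are zeroed off-diagonal with a warning).  Model
correlations regenerate spikes from the plug-in intensity on the
inferred per-trial latents by the same Bernoulli thinning as the
generator, averaging the correlation matrix over 20 regenerations
(configurable).  `R² = 1 − ‖C_data − C_model‖²_F / ‖C_data‖²_F` is
computed on off-diagonal entries only: the diagonals are identically 1
in both matrices, so including them would add nothing to the numerator
while inflating the denominator and flattering every model.  The PCA
baseline reconstructs mean-centred (unscaled) 100 ms counts from the
top components fit on all trials; its R² is expected to be negative for
exponential-link data.

## Synthetic-data conditions

The generator emulates the task and the four choice mechanisms.  Fixed
structural choices: spiking is Bernoulli thinning of the Poisson
intensity at 1 ms (at most one spike per bin, matching the binary
point-process convention); the choice is generated from the
pre-feedback latents and feedback then modifies the latents used for
spiking ("the choice is fed back"); corrupting feedback is injected
along latent dim 1 only, non-corrupting feedback within dims 2..D only;
frozen trials share a single pulse vector; correctness on zero-sum
trials is a fair coin.

Parameters the task description leaves open were set once to values a
recording session of this kind would plausibly show, and are not
retuned per analysis:

- pulse strengths: `round(N(0, 2²))`, giving coherences mostly in 0–10;
- baseline rate: bias −4 (≈ 18 Hz); loading entries N(0, 0.25²), so
  log-rate fluctuations of order 0.5;
- pulse kernel: alpha function `gain·(t/τ)·e^{1−t/τ}` with τ = 60 ms,
  gain 1.2, length 300 ms — unit-pulse latent deflections comparable to
  the GP standard deviation;
- decision noise SD 1500 on the time-integrated dim-1 readout.  Jointly
  with the pulse kernel this puts overall accuracy near 70%, the 65%
  weak-trial threshold at moderate coherence (so weak-trial selection
  is non-trivial), and the stimulus-axis CP in the 0.6–0.7 range —
  choices informed by, but far from determined by, the stimulus axis;
- feedback gain 0.8 with a ramp that is zero until 400 ms after
  stimulus onset, rises linearly to 1 at stimulus offset (1050 ms) and
  decays linearly to 0.3 by the end of the trial.  The post-offset
  decay models commitment of the decision: it makes "CP peaks near
  stimulus offset" a well-defined property of the time course rather
  than a race among statistically tied post-offset windows.

What the generator does **not** emulate: realistic MT tuning curves and
their heterogeneity, spike-history effects (refractoriness, bursting),
non-stationary baselines, eye movements, and any nonlinear readout.
Passing tests therefore show that the pipeline recovers the structure
it assumes when that structure is present at realistic signal-to-noise,
and that its null behaviour is calibrated — not that cortical data
satisfy these assumptions.

## Problem sizes in the test suite

Tests run at the smallest sizes that make each property decidable:
latent recovery at 15 neurons × 150 trials × 500 ms (truncated trials;
the first two pulses' full basis support fits the window);
dimensionality selection at 8 neurons × 40 trials × 500 ms over five
seeds; mechanism discrimination and time courses at 600 trials on the
generator's ground-truth latents (latent recovery being established
separately); noise-correlation validation at 100 frozen trials.  The
whole suite runs in a few minutes on one CPU, as does
`scripts/acceptance.py`, which recomputes the same quantities from
scratch.

## Known limitations

- The rank-r spectral truncation makes the ELBO exact for the truncated
  prior, not the full-rank kernel; for the default kernel the truncated
  spectrum is negligible, but very short timescales need a larger rank.
- Kernel hyperparameters are fixed, not optimised; `select_dimension`
  refits the whole model per held-out neuron and is the most expensive
  operation in the package.
- The held-out choice-mapping protocol reuses the folds that selected
  the penalty (no nested CV), so penalty selection sees each test fold
  once; with a 15-point grid and log-likelihood selection the effect on
  CP is far below its sampling noise (the inflation check bounds it).
- Pooling across sessions is supported by concatenating held-out mapped
  values; per-session decoders are fit independently and no hierarchical
  shrinkage is attempted.
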