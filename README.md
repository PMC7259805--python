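# latentcp

Single-trial latent-factor analysis of population spike trains during a
motion-pulse discrimination task: variational latent Gaussian-process
(vLGP) inference, stimulus-axis identification by pulse-triggered
averaging, and decomposition of choice probability (CP) into
stimulus-aligned and stimulus-orthogonal components.

## The problem

When an animal discriminates the direction of a noisy motion stimulus,
the trial-to-trial variability of sensory neurons correlates with the
upcoming choice.  Such choice probabilities can arise in very different
ways: the downstream readout may use the stimulus-coding direction of
the population (optimally or suboptimally), or the forming decision may
be fed back into the sensory population — either *along* the stimulus
axis (corrupting its stimulus information) or *orthogonally* to it
(non-corrupting).  Distinguishing these mechanisms requires single-trial
access to the population's shared variability, not trial-averaged
tuning curves.

`latentcp` implements the full analysis chain for this question, for
sessions of simultaneously recorded neurons in a pulsed
direction-discrimination task (seven 150 ms motion pulses with signed
integer strengths, 100 ms pre-stimulus and 350 ms post-offset padding,
1500 one-millisecond bins per trial), together with a generator of
synthetic sessions in which the choice mechanism is known ground truth.

## The model

Shared variability is modelled by a low-dimensional latent Gaussian
process driving all neurons through a linear-exponential cascade:

    x_k ~ N(0, K),    K_ij = sigma^2 exp(-(t_i - t_j)^2 / 2 ell^2)
    y_t ~ Poisson(exp(A x_t + b))

with `y_t` the binary 1 ms spike indicators of the N neurons, `A` the
N x D loading matrix and `b` the per-neuron log baseline rate.  The
posterior over the latent factors is approximated per dimension by a
Gaussian `q(x_k) = N(mu_k, Sigma_k)` whose evidence lower bound is
maximised by coordinate ascent (`VLGP(...).fit()`); the posterior means
`mu_k` are the latent factors used by all downstream stages.  Latent
dimensionality is chosen by leave-one-neuron-out co-smoothing
(`select_dimension`); a four-dimensional latent space is the default.

Downstream, the pulse-triggered average `X = DW + E` is estimated by
GCV-ridge regression on a raised-cosine temporal basis (4 bumps per
pulse, 28 design columns), and the SVD `W' = USV'` rotates the factors
so that stimulus power concentrates in rotated factor 1 (the *stimulus
axis*).  On low-coherence ("weak") trials, pulses are regressed out of
100 ms-binned activity, cross-validated L2 logistic decoders map the
residuals to a scalar choice mapping `c = sigma(beta' r + beta_0)`, and
CP is the two-sample ROC area of the held-out `c` grouped by choice —
computed separately for the stimulus axis, the non-stimulus axes, all
latent dimensions, and the raw population counts, with nested
likelihood-ratio tests across these regressor sets.

## Worked example

```python
import latentcp as lc

cfg = lc.GeneratorConfig(n_neurons=15, n_trials=600,
                         feedback_mode="noncorrupting", seed=0)
session, truth = lc.generate_session(cfg)

pta = lc.estimate_pta(truth.latents, session.pulses)
rotation, rotated = lc.rotate_to_stimulus_axis(pta, truth.latents)
print(f"stimulus-axis power fraction: {rotation.power_fractions[0]:.3f}")

result = lc.run_choice_pipeline(session, rotated, seed=0)
print(result.summary())
```

prints

```
stimulus-axis power fraction: 0.996
Choice-probability decomposition
========================================
weak trials: 519 (levels [0, 1, 2, 3, 4, 5, 6, 7], correct rate 0.636)

axis set        CP      n
stimulus       0.624  519
non_stimulus   0.812  519
all_latent     0.821  519
population     0.789  519

LR1 (+non-stimulus) = 1.005e-34, p = 6.37e-36
LR2 (+population)   = 0.2568, p = 0.0991
```

Reading the output: the pulse-driven signal is almost entirely
concentrated in one rotated latent dimension (power fraction 0.996).
Because this session was generated with *non-corrupting feedback*, the
choice information on the orthogonal (non-stimulus) axes (CP 0.812)
exceeds that on the stimulus axis itself (CP 0.624), and adding the
non-stimulus mapping to a choice model already containing the stimulus
mapping improves it decisively (LR1 test, p ~ 1e-35) — exactly the
signature that separates non-corrupting feedback from optimal readout
or corrupting feedback.  To fit the latent model itself rather than use
the generator's ground-truth latents:

```python
model = lc.VLGP.from_session(session, latent_dim=4)
res = model.fit()            # VLGPResults: loading, bias, posterior, ELBO trace
print(res.summary())
latents = res.posterior.mean  # (n_trials, 1500, 4)
```

A thin CLI mirrors the stages:
`latentcp simulate | fit | align | choice | validate` (see `--help`).

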