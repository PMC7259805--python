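"""Synthetic sessions with known latent structure and choice mechanism.

The generator produces sessions with the statistical structure the
analysis pipeline assumes: low-dimensional shared latent trajectories
with squared-exponential temporal smoothness, a one-dimensional pulse
drive confined to latent dimension 1, conditionally independent
Bernoulli-thinned Poisson spiking through an exponential link, and a
behavioural choice produced by one of four mechanisms:

``optimal``
    read out of the stimulus axis (latent dim 1) only;
``suboptimal``
    read out along an arbitrary fixed direction in latent space;
corrupting feedback
    the committed choice is injected back *along* the stimulus axis;
non-corrupting feedback
    the committed choice is injected back *orthogonally* to the
    stimulus axis (within dims 2..d).

The choice is always generated from the pre-feedback latents; feedback
then modifies the latents used for spiking, following the causal story
"the choice is fed back".  Ground truth (latents, decision variable,
mechanism label) is returned alongside the session for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

from .session import SessionData
from .vlgp import GPKernelSpec, se_kernel_matrix, spectral_basis

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "default_pulse_kernel",
    "default_feedback_ramp",
    "generate_pulses",
    "generate_choice",
    "generate_session",
]

_ETA_MAX = 30.0  # cap on log intensity before exponentiation


def default_pulse_kernel(gain: float = 1.2, tau_ms: float = 60.0,
                         length_ms: int = 300) -> np.ndarray:
    """Alpha-shaped impulse response of latent dim 1 to a unit pulse.

    ``k(t) = gain * (t/tau) * exp(1 - t/tau)``, peaking at ``gain`` at
    ``t = tau``; length at most 300 ms.
    """
    t = np.arange(length_ms, dtype=float)
    return gain * (t / tau_ms) * np.exp(1.0 - t / tau_ms)


def default_feedback_ramp(T: int, t_pre_ms: int = 100, onset_ms: int = 400,
                          peak_ms: int = 1050, end_value: float = 0.3) -> np.ndarray:
    """Temporal gain of the choice-feedback injection.

    Zero before ``onset_ms`` (relative to stimulus onset), linear rise
    to 1 at ``peak_ms`` (default: stimulus offset), then linear decay to
    ``end_value`` at the end of the trial — the fed-back decision signal
    builds up during evidence accumulation and wanes after commitment.
    """
    t = np.arange(T, dtype=float) - t_pre_ms
    ramp = np.clip((t - onset_ms) / (peak_ms - onset_ms), 0.0, 1.0)
    post = t > peak_ms
    if post.any():
        t_end = T - 1 - t_pre_ms
        frac = (t[post] - peak_ms) / max(t_end - peak_ms, 1.0)
        ramp[post] = 1.0 + (end_value - 1.0) * frac
    return ramp


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic-session generator.

    Defaults define the study conditions: 1500 ms trials, four latent
    dimensions with 100 ms squared-exponential smoothness, pulse
    strengths rounded from N(0, 2**2), ~18 Hz baseline firing, and a
    pulse drive confined to latent dimension 1.
    """

    n_neurons: int = 20
    n_trials: int = 400
    n_frozen: int = 0
    latent_dim: int = 4
    pulse_sd: float = 2.0
    kernel: GPKernelSpec = field(default_factory=GPKernelSpec)
    true_loading: Optional[np.ndarray] = None   # defaults to N(0, 0.25^2) entries
    true_bias: Optional[np.ndarray] = None      # defaults to -4.0 (~18 Hz)
    pulse_kernel: Optional[np.ndarray] = None   # defaults to default_pulse_kernel()
    readout_mode: str = "optimal"               # or "suboptimal"
    readout_weights: Optional[np.ndarray] = None
    decision_noise_sd: float = 1500.0
    feedback_mode: str = "none"                 # "corrupting" | "noncorrupting"
    feedback_gain: float = 0.8
    feedback_ramp: Optional[Callable[[int], np.ndarray]] = None
    seed: int = 0
    # trial geometry (fixed by the task)
    t_pre_ms: int = 100
    pulse_ms: int = 150
    n_pulses: int = 7
    t_post_ms: int = 350
    loading_scale: float = 0.25
    basis_rank: int = 50

    @property
    def T_1ms(self) -> int:
        return self.t_pre_ms + self.n_pulses * self.pulse_ms + self.t_post_ms

    def validate(self) -> None:
        if self.readout_mode not in ("optimal", "suboptimal"):
            raise ValueError(f"unknown readout_mode {self.readout_mode!r}")
        if self.feedback_mode not in ("none", "corrupting", "noncorrupting"):
            raise ValueError(f"unknown feedback_mode {self.feedback_mode!r}")
        if self.pulse_sd < 0:
            raise ValueError("pulse_sd must be nonnegative")
        if self.readout_mode == "suboptimal" and self.readout_weights is None:
            raise ValueError("suboptimal readout requires readout_weights")
        if self.feedback_mode == "noncorrupting" and self.latent_dim < 2:
            raise ValueError("noncorrupting feedback needs latent_dim >= 2")
        if not 0 <= self.n_frozen <= self.n_trials:
            raise ValueError("n_frozen must be within [0, n_trials]")
        pk = self.pulse_kernel
        if pk is not None and len(pk) > 300:
            raise ValueError("pulse_kernel length must be <= 300 ms")


@dataclass
class GroundTruth:
    """Exactly the quantities used to generate the spikes."""

    latents: np.ndarray             # (n_trials, T, latent_dim), incl. feedback
    latents_prefeedback: np.ndarray
    decision_variable: np.ndarray   # (n_trials,)
    mechanism_label: str
    loading: np.ndarray
    bias: np.ndarray
    feedback_term: np.ndarray       # (n_trials, T, latent_dim)


def generate_pulses(n_trials: int, pulse_sd: float, seed: int,
                    n_pulses: int = 7) -> np.ndarray:
    """Signed integer pulse strengths, round(N(0, pulse_sd^2)) per pulse."""
    if pulse_sd < 0:
        raise ValueError("pulse_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    return np.rint(rng.normal(0.0, pulse_sd, size=(n_trials, n_pulses))).astype(np.int16)


def generate_choice(latents: np.ndarray, config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None):
    """Choice from pre-feedback latents.

    The decision variable is ``d = sum_t w . x_t + eps`` with
    ``eps ~ N(0, decision_noise_sd^2)``; ``w`` is the first unit vector
    (optimal readout of the stimulus axis) or ``readout_weights``.
    Returns ``(choices, decision_variable)`` with ``choice = 1{d > 0}``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if config.readout_mode == "optimal":
        w = np.zeros(config.latent_dim)
        w[0] = 1.0
    else:
        w = np.asarray(config.readout_weights, dtype=float)
    d = latents @ w
    d = d.sum(axis=1)
    d = d + rng.normal(0.0, config.decision_noise_sd, size=d.shape[0])
    return (d > 0).astype(np.uint8), d


def _feedback_direction(config: GeneratorConfig) -> np.ndarray:
    e = np.zeros(config.latent_dim)
    if config.feedback_mode == "corrupting":
        e[0] = 1.0
    else:  # noncorrupting: orthogonal to the stimulus axis
        e[1] = 1.0
    return e


def generate_session(config: GeneratorConfig):
    """Generate one synthetic session and its ground truth.

    Latents are GP draws (rank-limited spectral construction of the
    squared-exponential prior) plus the pulse train convolved with
    ``pulse_kernel`` on dim 1, plus — after the choice is committed —
    the choice-feedback term prescribed by ``feedback_mode``.  Spikes
    are Bernoulli thinnings of the Poisson intensity per 1 ms bin:
    ``P(spike) = 1 - exp(-exp(A x_t + b))``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T, D, N = config.T_1ms, config.latent_dim, config.n_neurons

    loading = config.true_loading
    if loading is None:
        loading = rng.normal(0.0, config.loading_scale, size=(N, D))
    loading = np.asarray(loading, dtype=float)
    if loading.shape != (N, D):
        raise ValueError(f"true_loading shape {loading.shape} != ({N}, {D})")
    bias = config.true_bias
    if bias is None:
        bias = np.full(N, -4.0)
    bias = np.broadcast_to(np.asarray(bias, dtype=float), (N,)).copy()

    # pulses; frozen trials share one pulse vector
    pulses = generate_pulses(config.n_trials, config.pulse_sd,
                             rng.integers(2**31), config.n_pulses)
    frozen = np.zeros(config.n_trials, dtype=np.uint8)
    if config.n_frozen > 0:
        idx = rng.choice(config.n_trials, size=config.n_frozen, replace=False)
        frozen[idx] = 1
        shared = generate_pulses(1, config.pulse_sd, rng.integers(2**31),
                                 config.n_pulses)[0]
        pulses[idx.astype(int)] = shared

    # shared GP latents through the rank-r spectral factor of K
    Phi = spectral_basis(config.kernel, T, bin_ms=1, rank=config.basis_rank)
    z = rng.standard_normal((config.n_trials, D, Phi.shape[1]))
    latents = np.einsum("tr,ndr->ntd", Phi, z)

    # pulse drive on dim 1
    kern = config.pulse_kernel
    if kern is None:
        kern = default_pulse_kernel()
    kern = np.asarray(kern, dtype=float)
    drive = _pulse_drive(pulses, kern, T, config.t_pre_ms, config.pulse_ms)
    latents[:, :, 0] += drive

    pre = latents.copy()
    choices, dvar = generate_choice(pre, config, rng)

    # feedback injection (after the choice is committed)
    feedback = np.zeros_like(latents)
    if config.feedback_mode != "none" and config.feedback_gain != 0.0:
        ramp_fn = config.feedback_ramp or default_feedback_ramp
        ramp = np.asarray(ramp_fn(T), dtype=float)
        direction = _feedback_direction(config)
        signed = (2.0 * choices - 1.0)
        feedback = (signed[:, None, None] * ramp[None, :, None]
                    * direction[None, None, :]) * config.feedback_gain
        latents = latents + feedback

    # Bernoulli-thinned Poisson spiking
    eta = latents @ loading.T + bias
    if np.max(eta) > _ETA_MAX:
        raise FloatingPointError(
            "log intensity exceeds the overflow guard; rescale true_loading, "
            "true_bias or the latent amplitude")
    p_spike = 1.0 - np.exp(-np.exp(eta))
    spikes = (rng.random(size=p_spike.shape) < p_spike).astype(np.uint8)

    # correct flag: sign of pulse sum vs choice; coin flip on zero-sum trials
    s = pulses.sum(axis=1)
    correct = (np.sign(s) == (2.0 * choices - 1.0)).astype(np.uint8)
    zero = s == 0
    correct[zero] = (rng.random(zero.sum()) < 0.5).astype(np.uint8)

    sess = SessionData(
        session_id=f"synthetic-seed{config.seed}",
        spikes=spikes, pulses=pulses, choice=choices,
        correct=correct, frozen=frozen,
        t_pre_ms=config.t_pre_ms, pulse_ms=config.pulse_ms,
        n_pulses=config.n_pulses, t_post_ms=config.t_post_ms,
    )
    truth = GroundTruth(
        latents=latents, latents_prefeedback=pre, decision_variable=dvar,
        mechanism_label=_mechanism_label(config), loading=loading, bias=bias,
        feedback_term=feedback,
    )
    return sess, truth


def _mechanism_label(config: GeneratorConfig) -> str:
    if config.feedback_mode != "none":
        return config.feedback_mode
    return config.readout_mode


def _pulse_drive(pulses: np.ndarray, kernel: np.ndarray, T: int,
                 t_pre_ms: int, pulse_ms: int) -> np.ndarray:
    """Convolve the per-trial pulse impulse train with the pulse kernel."""
    n_trials, n_pulses = pulses.shape
    train = np.zeros((n_trials, T))
    onsets = t_pre_ms + pulse_ms * np.arange(n_pulses)
    train[:, onsets] = pulses
    L = len(kernel)
    drive = np.zeros((n_trials, T))
    for i, onset in enumerate(onsets):
        end = min(onset + L, T)
        drive[:, onset:end] += pulses[:, [i]] * kernel[: end - onset]
    return drive
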