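"""Pulse-triggered averages and the stimulus-axis rotation.

The pulse-triggered average (PTA) is the estimated change in the latent
factors caused by a unit-strength motion pulse, as a function of time
lag.  It is estimated by ridge regression of the concatenated 1 ms
latent trajectories ``X`` (T_total x D) on a temporal-basis design
``D``: each of the 7 pulses contributes 4 raised-cosine bumps starting
0/50/100/150 ms after its onset, each lasting 100 ms and scaled by the
signed pulse strength, for 28 design columns in total.  The ridge
penalty is chosen by generalized cross-validation (GCV).

An SVD of the weight matrix, ``W^T = U S V^T``, yields the rotation
``U`` that concentrates stimulus power in the leading rotated factor:
factor 1 of ``U^T x`` is the *stimulus axis*, factors 2..D the
*non-stimulus axes*.  Per-factor stimulus power fractions are
``S_k^2 / sum_j S_j^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "PulseBasis",
    "PTAWeights",
    "FactorRotation",
    "DEFAULT_GAMMA_GRID",
    "build_design",
    "ridge_gcv",
    "estimate_pta",
    "rotate_to_stimulus_axis",
]

DEFAULT_GAMMA_GRID = np.logspace(-6, 3, 15)


def _latent_array(latents) -> np.ndarray:
    """Accept a (trials, T, D) array or an object with a ``.mean`` array."""
    if not isinstance(latents, np.ndarray):
        mean = getattr(latents, "mean", None)
        if isinstance(mean, np.ndarray):
            latents = mean
    return np.asarray(latents, dtype=float)


@dataclass
class PulseBasis:
    """Raised-cosine temporal basis for one pulse.

    Four bumps ``b_j(t) = (1 - cos(2 pi (t - t_j) / 100)) / 2`` on
    ``[t_j, t_j + 100)`` ms with onsets ``t_j`` in {0, 50, 100, 150}
    relative to the pulse onset.
    """

    onsets_ms: Sequence[int] = (0, 50, 100, 150)
    duration_ms: int = 100

    @property
    def n_bases_per_pulse(self) -> int:
        return len(self.onsets_ms)

    @property
    def support_ms(self) -> int:
        """Length of the full response window of one pulse."""
        return max(self.onsets_ms) + self.duration_ms

    def evaluate(self, length_ms: Optional[int] = None) -> np.ndarray:
        """Basis functions on a lag axis, shape (length, n_bases)."""
        L = length_ms or self.support_ms
        t = np.arange(L, dtype=float)
        out = np.zeros((L, self.n_bases_per_pulse))
        for j, t0 in enumerate(self.onsets_ms):
            mask = (t >= t0) & (t < t0 + self.duration_ms)
            out[mask, j] = 0.5 * (1.0 - np.cos(
                2.0 * np.pi * (t[mask] - t0) / self.duration_ms))
        return out


def _trial_template(basis: PulseBasis, T_1ms: int, t_pre_ms: int = 100,
                    pulse_ms: int = 150, n_pulses: int = 7) -> np.ndarray:
    """Unit-pulse design of one trial, shape (T, n_pulses*n_bases)."""
    nb = basis.n_bases_per_pulse
    last_end = t_pre_ms + (n_pulses - 1) * pulse_ms + basis.support_ms
    if T_1ms < last_end:
        raise ValueError(
            f"T_1ms={T_1ms} shorter than the last basis support end {last_end}")
    bumps = basis.evaluate()
    template = np.zeros((T_1ms, n_pulses * nb))
    for i in range(n_pulses):
        onset = t_pre_ms + i * pulse_ms
        L = bumps.shape[0]
        template[onset:onset + L, i * nb:(i + 1) * nb] = bumps
    return template


def build_design(pulses: np.ndarray, basis: Optional[PulseBasis] = None,
                 T_1ms: int = 1500, t_pre_ms: int = 100, pulse_ms: int = 150
                 ) -> np.ndarray:
    """Concatenated-trials design matrix, shape (n_trials*T, 28).

    Column ``4*(i-1)+j`` holds ``s_i * basis_j(t - onset_i)`` where
    pulse ``i`` starts at ``(i-1)*150`` ms after stimulus onset.
    """
    basis = basis or PulseBasis()
    pulses = np.asarray(pulses)
    n_trials, n_pulses = pulses.shape
    template = _trial_template(basis, T_1ms, t_pre_ms, pulse_ms, n_pulses)
    scale = np.repeat(pulses.astype(float), basis.n_bases_per_pulse, axis=1)
    # (n_trials, T, p) = template broadcast scaled per trial, then stacked
    out = template[None, :, :] * scale[:, None, :]
    return out.reshape(n_trials * T_1ms, -1)


# ---------------------------------------------------------------------------
# GCV ridge
# ---------------------------------------------------------------------------

def _gcv_from_svd(U, s, Vt, targets, gamma_grid):
    """GCV curve and per-gamma weights from an economy SVD of the design."""
    n = U.shape[0]
    Uy = U.T @ targets
    ynorm2 = float(np.sum(targets**2))
    proj2 = np.sum(Uy**2, axis=1)
    gcv = np.empty(len(gamma_grid))
    for gi, g in enumerate(gamma_grid):
        f = s**2 / (s**2 + g)
        rss = ynorm2 - float(np.sum(proj2)) + float(np.sum((1 - f)**2 * proj2))
        tr_h = float(np.sum(f))
        gcv[gi] = rss / (n * (1.0 - tr_h / n) ** 2)
    g = gamma_grid[int(np.argmin(gcv))]
    coef = Vt.T @ (Uy * (s / (s**2 + g))[:, None])
    return coef, float(g), gcv


def ridge_gcv(targets: np.ndarray, design: np.ndarray,
              gamma_grid: Optional[np.ndarray] = None, return_curve: bool = False):
    """Ridge regression with the penalty chosen by generalized cross-validation.

    ``weights = (D^T D + gamma I)^-1 D^T targets`` at the gamma on the grid
    minimizing ``GCV(gamma) = ||(I-H) y||^2 / (n (1 - tr(H)/n)^2)`` summed
    over target columns, with the hat trace computed from the singular
    values of the design.  Returns ``(weights, gamma)`` (plus the GCV
    curve if requested).
    """
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    gamma_grid = np.asarray(gamma_grid, dtype=float)
    if gamma_grid.size == 0:
        raise ValueError("gamma grid is empty")
    if (gamma_grid <= 0).any():
        raise ValueError("gamma grid must be positive")
    design = np.asarray(design, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    U, s, Vt = np.linalg.svd(design, full_matrices=False)
    coef, g, gcv = _gcv_from_svd(U, s, Vt, targets, gamma_grid)
    if return_curve:
        return coef, g, gcv
    return coef, g


def _gcv_from_gram(G, c, yty, n_rows, gamma_grid):
    """Gram-matrix route: needs only D^T D, D^T y and ||y||^2 per column."""
    lam, Q = np.linalg.eigh(G)
    lam = np.clip(lam, 0.0, None)
    Qc = Q.T @ c
    gcv = np.empty(len(gamma_grid))
    for gi, g in enumerate(gamma_grid):
        denom = lam + g
        beta_t = Qc / denom[:, None]
        # ||(I-H)y||^2 = ||y||^2 - 2 c' beta + beta' G beta, summed over cols
        rss = yty - 2.0 * float(np.sum(Qc * beta_t)) \
            + float(np.sum(lam[:, None] * beta_t**2))
        tr_h = float(np.sum(lam / denom))
        gcv[gi] = rss / (n_rows * (1.0 - tr_h / n_rows) ** 2)
    g = gamma_grid[int(np.argmin(gcv))]
    coef = Q @ (Qc / (lam + g)[:, None])
    return coef, float(g), gcv


@dataclass
class PTAWeights:
    """Ridge weights from the pulse design to the latents, and PTA curves.

    ``weights`` is 28 x D; ``pta_curves[i, tau, k]`` is the response of
    factor ``k`` to a unit pulse ``i`` at lag ``tau`` ms (Gaussian
    smoothed unless the width is zero); ``residual_sse`` is the sum of
    squared regression residuals.
    """

    weights: np.ndarray
    ridge_gamma: float
    pta_curves: np.ndarray
    residual_sse: float
    basis: PulseBasis = field(default_factory=PulseBasis)
    smooth_sd_ms: float = 40.0

    @property
    def latent_dim(self) -> int:
        return self.weights.shape[1]


def _curves_from_weights(weights, basis, n_pulses, smooth_sd_ms):
    nb = basis.n_bases_per_pulse
    bumps = basis.evaluate()                       # (L, nb)
    D = weights.shape[1]
    curves = np.empty((n_pulses, bumps.shape[0], D))
    for i in range(n_pulses):
        curves[i] = bumps @ weights[i * nb:(i + 1) * nb]
    if smooth_sd_ms and smooth_sd_ms > 0:
        curves = gaussian_filter1d(curves, sigma=smooth_sd_ms, axis=1,
                                   mode="constant", truncate=3.0)
    return curves


def estimate_pta(latents, pulses: np.ndarray, basis: Optional[PulseBasis] = None,
                 gamma_grid: Optional[np.ndarray] = None,
                 smooth_sd_ms: float = 40.0, t_pre_ms: int = 100,
                 pulse_ms: int = 150) -> PTAWeights:
    """Fit the PTA weights by GCV ridge on concatenated trials.

    ``latents`` is an (n_trials, T, D) array of latent trajectories (or
    an object exposing one as ``.mean``).  The design is never
    materialised: the Gram matrix is accumulated from the shared
    unit-pulse trial template, which is exact because every trial shares
    the basis layout and differs only in the pulse strengths.
    """
    X = _latent_array(latents)
    if X.ndim != 3:
        raise ValueError("latents must be (n_trials, T, latent_dim)")
    pulses = np.asarray(pulses)
    if np.all(pulses == 0):
        raise ValueError("all pulses are zero: the pulse design is degenerate")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    basis = basis or PulseBasis()
    n_trials, T, D = X.shape
    n_pulses = pulses.shape[1]
    nb = basis.n_bases_per_pulse
    template = _trial_template(basis, T, t_pre_ms, pulse_ms, n_pulses)
    BtB = template.T @ template
    scale = np.repeat(pulses.astype(float), nb, axis=1)     # (n_trials, p)
    G = BtB * (scale.T @ scale)                             # Gram of the design
    # D^T X accumulated per trial: diag(scale) B^T X_trial
    BtX = np.einsum("tp,ntd->npd", template, X)             # (n_trials, p, D)
    c = np.einsum("np,npd->pd", scale, BtX)
    yty = float(np.sum(X**2))
    W, g, _ = _gcv_from_gram(G, c, yty, n_trials * T, np.asarray(gamma_grid))
    sse = yty - 2.0 * float(np.sum(c * W)) + float(np.sum(W * (G @ W)))
    curves = _curves_from_weights(W, basis, n_pulses, smooth_sd_ms)
    return PTAWeights(weights=W, ridge_gamma=g, pta_curves=curves,
                      residual_sse=max(sse, 0.0), basis=basis,
                      smooth_sd_ms=smooth_sd_ms)


@dataclass
class FactorRotation:
    """Orthogonal rotation concentrating stimulus power in factor 1."""

    rotation: np.ndarray          # U, (D, D); rotated latents are x @ U
    singular_values: np.ndarray
    right_vectors: np.ndarray
    power_fractions: np.ndarray


def rotate_to_stimulus_axis(pta: PTAWeights, latents):
    """SVD rotation ``W^T = U S V^T``; rotated latents are ``U^T x``.

    Each rotated factor's sign is flipped so that its pulse-averaged
    unit-pulse PTA is positive at the lag of largest magnitude, making
    the stimulus-axis direction reproducible across seeds.  Returns
    ``(FactorRotation, rotated_means)``.
    """
    X = _latent_array(latents)
    U, S, Vt = np.linalg.svd(pta.weights.T, full_matrices=False)
    W_rot = pta.weights @ U
    curves = _curves_from_weights(W_rot, pta.basis, pta.pta_curves.shape[0],
                                  pta.smooth_sd_ms)
    mean_curve = curves.mean(axis=0)              # (L, D)
    for k in range(U.shape[1]):
        peak = mean_curve[np.argmax(np.abs(mean_curve[:, k])), k]
        if peak < 0:
            U[:, k] *= -1.0
    power = S**2
    total = power.sum()
    fractions = np.full(U.shape[0], 0.0)
    if total > 0:
        fractions[: len(S)] = power / total
    rot = FactorRotation(rotation=U, singular_values=S, right_vectors=Vt,
                         power_fractions=fractions)
    return rot, X @ U
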