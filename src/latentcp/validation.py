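"""Model-validation statistics.

Frozen trials (repeats of one identical pulse sequence) allow the
pairwise *noise correlation* — correlation of trial-to-trial response
fluctuations after removing the stimulus-locked mean time course
(PSTH) — to be measured from data and compared with the correlations of
spike trains regenerated from the fitted latent-factor model.  Fit
quality is summarised by

    R^2 = 1 - ||C_data - C_model||_F^2 / ||C_data||_F^2,

computed on the off-diagonal entries (the diagonals are identically 1
and carry no information; including them in the denominator would only
dilute the statistic).  A PCA reconstruction of the raw 100 ms counts
serves as the linear baseline; its R^2 may be negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA

from .choice import choice_probability, fit_choice_decoder
from .session import BinnedCounts, rebin
from .vlgp import LatentPosterior, VLGPModel, _ETA_MAX

__all__ = [
    "NoiseCorrelationReport",
    "noise_correlation",
    "model_noise_correlation",
    "r2_frobenius",
    "pca_baseline",
    "cp_inflation_check",
]


@dataclass
class NoiseCorrelationReport:
    c_data: np.ndarray
    c_model: np.ndarray
    r2: float
    bin_ms: int = 100
    n_frozen_trials: int = 0


def _corr_with_guard(samples: np.ndarray) -> np.ndarray:
    """Pearson correlation across rows; zero-variance columns zeroed off-diag."""
    n = samples.shape[1]
    centered = samples - samples.mean(axis=0)
    cov = centered.T @ centered / max(samples.shape[0] - 1, 1)
    sd = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    dead = sd == 0
    if dead.any():
        warnings.warn(f"{int(dead.sum())} zero-variance channel(s) in "
                      "noise-correlation estimate; rows/columns set to 0")
    denom = np.outer(sd, sd)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    corr[dead, :] = 0.0
    corr[:, dead] = 0.0
    corr[np.diag_indices(n)] = 1.0
    return corr


def noise_correlation(counts, trial_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise noise correlations on frozen trials.

    ``counts`` is a :class:`BinnedCounts` at 100 ms (or a plain
    (n_trials, n_bins, n) array); ``trial_mask`` selects the frozen
    trials.  The across-trial mean time course is subtracted per neuron
    before correlating over (trial x bin) samples.
    """
    arr = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if trial_mask is not None:
        arr = arr[np.asarray(trial_mask).astype(bool)]
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frozen trials")
    resid = arr - arr.mean(axis=0, keepdims=True)   # PSTH subtraction
    samples = resid.reshape(-1, arr.shape[2])
    return _corr_with_guard(samples)


def model_noise_correlation(model: VLGPModel, posterior: LatentPosterior,
                            trial_mask: Optional[np.ndarray] = None,
                            sim_seed: int = 0, n_regen: int = 20,
                            bin_ms: int = 100) -> np.ndarray:
    """Noise correlations of spike trains regenerated from the model.

    Spikes are re-drawn by Bernoulli thinning of the plug-in intensity
    ``exp(A mu_t + b)`` on the inferred per-trial latents (identically
    to the generator) for the frozen trials; the correlation matrix is
    averaged over ``n_regen`` regenerations.
    """
    rng = np.random.default_rng(sim_seed)
    mean = posterior.mean
    if trial_mask is not None:
        mean = mean[np.asarray(trial_mask).astype(bool)]
    if mean.shape[0] < 2:
        raise ValueError("need at least 2 frozen trials")
    eta = mean @ model.loading.T + model.bias
    p = 1.0 - np.exp(-np.exp(np.minimum(eta, _ETA_MAX)))
    acc = None
    for _ in range(n_regen):
        spikes = (rng.random(size=p.shape) < p).astype(float)
        c = noise_correlation(rebin(spikes, bin_ms))
        acc = c if acc is None else acc + c
    return acc / n_regen


def r2_frobenius(c_data: np.ndarray, c_model: np.ndarray) -> float:
    """1 - ||C_data - C_model||_F^2 / ||C_data||_F^2 on off-diagonals."""
    c_data = np.asarray(c_data, dtype=float)
    c_model = np.asarray(c_model, dtype=float)
    if c_data.shape != c_model.shape:
        raise ValueError("correlation matrices must share a shape")
    off = ~np.eye(c_data.shape[0], dtype=bool)
    denom = float(np.sum(c_data[off] ** 2))
    if denom == 0:
        raise ValueError("data correlation matrix has no off-diagonal power")
    return 1.0 - float(np.sum((c_data[off] - c_model[off]) ** 2)) / denom


def pca_baseline(counts, n_components: int = 4,
                 trial_mask: Optional[np.ndarray] = None,
                 bin_ms: int = 100) -> NoiseCorrelationReport:
    """Linear baseline: reconstruct 100 ms counts from the top PCs.

    The PCA is fit on mean-centered counts of *all* trials; the
    rank-``n_components`` reconstruction's noise correlations on the
    frozen trials are compared with the data's via :func:`r2_frobenius`.
    """
    arr = np.asarray(getattr(counts, "counts", counts), dtype=float)
    n_trials, n_bins, n = arr.shape
    if n_components > n:
        raise ValueError("n_components exceeds the number of neurons")
    flat = arr.reshape(-1, n)
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(flat)
    recon = (scores @ pca.components_ + pca.mean_).reshape(arr.shape)
    mask = (np.asarray(trial_mask).astype(bool) if trial_mask is not None
            else np.ones(n_trials, dtype=bool))
    c_data = noise_correlation(arr[mask])
    c_model = noise_correlation(recon[mask])
    return NoiseCorrelationReport(
        c_data=c_data, c_model=c_model, r2=r2_frobenius(c_data, c_model),
        bin_ms=bin_ms, n_frozen_trials=int(mask.sum()))


def cp_inflation_check(base_dims: int = 1, extra_noise_dims: int = 10,
                       n_trials: int = 500, seed: int = 0,
                       signal: float = 0.5):
    """Held-out CP with and without appended choice-irrelevant dimensions.

    Synthetic residuals carry a choice signal of strength ``signal`` in
    the first ``base_dims`` dimensions only; ``extra_noise_dims`` pure
    N(0, 1) dimensions are appended and the full decoder + held-out
    choice-mapping + CP pipeline is run on both versions.  Returns
    ``(cp_base, cp_augmented)``.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_trials)
    choices = (z > 0).astype(int)
    base = signal * z[:, None] + rng.standard_normal((n_trials, base_dims))
    noise = rng.standard_normal((n_trials, extra_noise_dims))
    _, m_base = fit_choice_decoder(base, choices, seed=seed)
    cp_base = choice_probability(m_base, choices).cp
    if extra_noise_dims == 0:
        return cp_base, cp_base
    _, m_aug = fit_choice_decoder(np.column_stack([base, noise]), choices,
                                  seed=seed)
    cp_aug = choice_probability(m_aug, choices).cp
    return cp_base, cp_aug
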