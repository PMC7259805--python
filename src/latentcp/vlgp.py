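"""Variational latent Gaussian-process inference for population spike trains.

Model
-----
Each latent dimension k carries an independent Gaussian-process prior
with squared-exponential covariance, ``x_k ~ N(0, K)``.  The binary
1 ms spike indicators of the N simultaneously recorded neurons are a
point process driven through a linear-exponential cascade,

    y_t ~ Poisson(exp(A x_t + b)),

with loading matrix ``A`` (N x D) and per-neuron bias ``b``.  The
posterior over latents is intractable, so each dimension gets a
Gaussian variational posterior ``q(x_k) = N(mu_k, Sigma_k)`` and the
evidence lower bound (ELBO) is maximised by coordinate ascent over
per-trial posteriors and the loading/bias.

Numerics
--------
The prior covariance over a 1500-bin trial is approximated by its
rank-r spectral truncation ``K ~= Phi Phi^T`` (``Phi = U_r S_r^{1/2}``)
and the posterior is parameterised in the whitened coordinates
``x_k = Phi z_k``, ``q(z_k) = N(m, C)`` with a full r x r covariance.
This keeps memory linear in trial length, makes every covariance PSD by
construction, and reduces the KL term to the exact Gaussian KL against
``N(0, I_r)``.  The expected Poisson likelihood uses
``E[exp(a^T x)] = exp(a^T mu + a^T Sigma a / 2)``.  Every update step
(Newton on m, damped fixed point on C, Newton on each neuron's
loading row) is accepted only if its exact local ELBO component
improves, so the ELBO trace is non-decreasing.

Usage follows the statsmodels convention::

    model = VLGP(counts, latent_dim=4)
    res = model.fit()
    res.summary()
    res.posterior.mean  # (n_trials, T, latent_dim)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, eigh
from scipy.special import gammaln

__all__ = [
    "GPKernelSpec",
    "VLGPModel",
    "LatentPosterior",
    "VLGP",
    "VLGPResults",
    "se_kernel_matrix",
    "spectral_basis",
    "elbo",
    "fit_vlgp",
    "select_dimension",
    "reconstruct_rates",
]

_ETA_MAX = 30.0  # cap on log intensity inside exp() — overflow guard


@dataclass
class GPKernelSpec:
    """Squared-exponential GP kernel: variance, timescale (ms), jitter."""

    variance: float = 1.0
    timescale_ms: float = 100.0
    jitter: float = 1e-6

    def validate(self) -> None:
        if self.variance <= 0 or self.timescale_ms <= 0:
            raise ValueError("variance and timescale_ms must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be nonnegative")


def se_kernel_matrix(spec: GPKernelSpec, n_bins: int, bin_ms: int = 1) -> np.ndarray:
    """K[i, j] = variance * exp(-dt_ij^2 / (2 timescale^2)) + jitter * I."""
    spec.validate()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    t = np.arange(n_bins, dtype=float) * bin_ms
    dt = t[:, None] - t[None, :]
    K = spec.variance * np.exp(-(dt**2) / (2.0 * spec.timescale_ms**2))
    K[np.diag_indices(n_bins)] += spec.jitter
    return K


def spectral_basis(spec: GPKernelSpec, n_bins: int, bin_ms: int = 1,
                   rank: Optional[int] = None) -> np.ndarray:
    """Rank-r factor ``Phi`` with ``K ~= Phi Phi^T`` (top eigenpairs of K)."""
    K = se_kernel_matrix(spec, n_bins, bin_ms)
    if rank is None:
        rank = min(n_bins, 50)
    rank = min(rank, n_bins)
    w, U = eigh(K, subset_by_index=(n_bins - rank, n_bins - 1))
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    w = np.clip(w, 1e-12, None)
    return U * np.sqrt(w)


@dataclass
class VLGPModel:
    """Fitted observation-model parameters (A and b) plus kernel metadata."""

    loading: np.ndarray           # (n_neurons, latent_dim)
    bias: np.ndarray              # (n_neurons,)
    kernels: Sequence[GPKernelSpec]
    latent_dim: int


@dataclass
class LatentPosterior:
    """Per-trial Gaussian variational posterior of the latent factors.

    ``mean[n, t, k]`` is the posterior mean trajectory (the latent
    factor used by all downstream analyses).  The covariance is stored
    in whitened low-rank form: ``Sigma_k = Phi C_k Phi^T`` with the
    shared basis ``Phi`` (T x r) and per-trial, per-dimension ``C_k``.
    """

    mean: np.ndarray      # (n_trials, T, D)
    z_mean: np.ndarray    # (n_trials, D, r)
    z_cov: np.ndarray     # (n_trials, D, r, r)
    basis: np.ndarray     # (T, r)

    @property
    def n_trials(self) -> int:
        return self.mean.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.mean.shape[2]

    def cov_diag(self) -> np.ndarray:
        """diag(Sigma_k) per trial and dimension, shape (n_trials, T, D)."""
        Phi = self.basis
        n, D = self.z_mean.shape[:2]
        out = np.empty_like(self.mean)
        for i in range(n):
            for k in range(D):
                out[i, :, k] = np.einsum(
                    "tr,rs,ts->t", Phi, self.z_cov[i, k], Phi)
        return np.clip(out, 0.0, None)

    def cov_factor(self, trial: int, dim: int) -> np.ndarray:
        """B with Sigma = B B^T for one trial/dimension (T x r)."""
        C = self.z_cov[trial, dim]
        w, U = np.linalg.eigh(C)
        w = np.clip(w, 0.0, None)
        return self.basis @ (U * np.sqrt(w))


def _expected_loglik(y, mu, vdiag, loading, bias):
    """Expected Poisson log likelihood of one trial under q (gammaln term incl.)."""
    eta = mu @ loading.T + bias
    vterm = vdiag @ (loading**2).T
    z = np.minimum(eta + 0.5 * vterm, _ETA_MAX)
    return float(np.sum(y * eta - np.exp(z)) - np.sum(gammaln(y + 1.0)))


def _kl_whitened(m: np.ndarray, C: np.ndarray) -> float:
    """KL( N(m, C) || N(0, I_r) ) in the whitened coordinates."""
    r = m.shape[0]
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "variational covariance not positive definite") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return 0.5 * (np.trace(C) + m @ m - r - logdet)


def elbo(model: VLGPModel, posterior: LatentPosterior, counts: np.ndarray) -> float:
    """Evidence lower bound of ``counts`` (n_trials, T, n_neurons)."""
    counts = np.asarray(counts, dtype=float)
    vdiag = posterior.cov_diag()
    total = 0.0
    for i in range(posterior.n_trials):
        total += _expected_loglik(counts[i], posterior.mean[i], vdiag[i],
                                  model.loading, model.bias)
        for k in range(posterior.latent_dim):
            total -= _kl_whitened(posterior.z_mean[i, k], posterior.z_cov[i, k])
    return total


class VLGP:
    """Variational latent GP model of binned spike counts at 1 ms.

    Parameters
    ----------
    counts : ndarray, shape (n_trials, T, n_neurons)
        Spike counts at 1 ms resolution (binary under the point-process
        convention, but any nonnegative integer counts are accepted).
    latent_dim : int
        Number of shared latent dimensions (the study default is 4).
    kernel : GPKernelSpec
        Prior smoothness; one spec shared by all dimensions.
    rank : int
        Rank of the spectral truncation of the prior covariance.
    loading_ridge : float
        L2 penalty on loading rows in the M step.
    """

    def __init__(self, counts, latent_dim: int = 4,
                 kernel: Optional[GPKernelSpec] = None, rank: Optional[int] = None,
                 loading_ridge: float = 1e-4, seed: int = 0):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 3:
            raise ValueError("counts must be (n_trials, T, n_neurons)")
        if counts.shape[2] < latent_dim:
            raise ValueError("need n_neurons >= latent_dim")
        self.counts = counts
        self.n_trials, self.T, self.n_neurons = counts.shape
        self.latent_dim = latent_dim
        self.kernel = kernel or GPKernelSpec()
        self.rank = min(rank or min(self.T, 50), self.T)
        self.loading_ridge = loading_ridge
        self.seed = seed
        self.Phi = spectral_basis(self.kernel, self.T, 1, self.rank)

    @classmethod
    def from_session(cls, session, latent_dim: int = 4, **kwargs) -> "VLGP":
        return cls(session.spikes.astype(float), latent_dim=latent_dim, **kwargs)

    # ------------------------------------------------------------------
    def _initialize(self):
        """PCA of square-root-transformed coarse counts; means upsampled to 1 ms."""
        D, T = self.latent_dim, self.T
        bin_ms = next(d for d in range(min(100, T), 0, -1) if T % d == 0)
        nb = T // bin_ms
        coarse = self.counts.reshape(self.n_trials, nb, bin_ms, self.n_neurons).sum(2)
        X = np.sqrt(coarse.reshape(-1, self.n_neurons))
        Xc = X - X.mean(0)
        # top-D principal directions of the coarse counts
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        scores = Xc @ Vt[:D].T
        sd = scores.std(0)
        sd[sd == 0] = 1.0
        scores = scores / sd
        mu0 = np.repeat(scores.reshape(self.n_trials, nb, D), bin_ms, axis=1)
        # whitened coordinates: least-squares projection onto the basis
        pinv = np.linalg.pinv(self.Phi)
        z_mean = np.einsum("rt,ntd->ndr", pinv, mu0)
        z_cov = np.broadcast_to(np.eye(self.rank),
                                (self.n_trials, D, self.rank, self.rank)).copy()
        mean = np.einsum("tr,ndr->ntd", self.Phi, z_mean)
        post = LatentPosterior(mean=mean, z_mean=z_mean, z_cov=z_cov, basis=self.Phi)
        rate = self.counts.mean(axis=(0, 1))
        bias = np.log(np.clip(rate, 1e-8, None))
        loading = 0.1 * Vt[:D].T
        return loading, bias, post

    # ------------------------------------------------------------------
    def _trial_objective(self, y, mu, vdiag, m, C, loading, bias):
        ll = _expected_loglik(y, mu, vdiag, loading, bias)
        kl = sum(_kl_whitened(m[k], C[k]) for k in range(self.latent_dim))
        return ll - kl

    def _update_trial(self, y, m, C, loading, bias):
        """Coordinate ascent over dims of one trial; returns new (m, C, mu, v)."""
        Phi = self.Phi
        D = self.latent_dim
        mu = np.einsum("tr,dr->td", Phi, m)
        vdiag = np.empty((self.T, D))
        for k in range(D):
            vdiag[:, k] = np.einsum("tr,rs,ts->t", Phi, C[k], Phi)
        obj = self._trial_objective(y, mu, vdiag, m, C, loading, bias)
        A2 = loading**2
        I_r = np.eye(self.rank)
        for k in range(D):
            # --- Newton step on the mean ---------------------------------
            eta = mu @ loading.T + bias
            z = np.minimum(eta + 0.5 * (vdiag @ A2.T), _ETA_MAX)
            rho = np.exp(z)
            grad = Phi.T @ ((y - rho) @ loading[:, k]) - m[k]
            w = rho @ A2[:, k]
            H = Phi.T @ (Phi * w[:, None]) + I_r
            try:
                delta = cho_solve(cho_factor(H), grad)
            except np.linalg.LinAlgError:
                delta = np.linalg.solve(H + 1e-8 * I_r, grad)
            for step in (1.0, 0.5, 0.25, 0.125):
                m_new = m[k] + step * delta
                mu_new = mu.copy()
                mu_new[:, k] = Phi @ m_new
                cand = self._trial_objective(y, mu_new, vdiag,
                                             _row_replace(m, k, m_new), C,
                                             loading, bias)
                if cand >= obj - 1e-12 * abs(obj):
                    m = _row_replace(m, k, m_new)
                    mu, obj = mu_new, cand
                    break
            # --- damped fixed point on the covariance --------------------
            eta = mu @ loading.T + bias
            z = np.minimum(eta + 0.5 * (vdiag @ A2.T), _ETA_MAX)
            rho = np.exp(z)
            w = rho @ A2[:, k]
            H = Phi.T @ (Phi * w[:, None]) + I_r
            try:
                C_prop = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                C_prop = np.linalg.inv(H + 1e-8 * I_r)
            C_prop = 0.5 * (C_prop + C_prop.T)
            for alpha in (1.0, 0.5, 0.25):
                C_new = (1 - alpha) * C[k] + alpha * C_prop
                v_new = vdiag.copy()
                v_new[:, k] = np.einsum("tr,rs,ts->t", Phi, C_new, Phi)
                cand = self._trial_objective(y, mu, v_new,
                                             m, _mat_replace(C, k, C_new),
                                             loading, bias)
                if cand >= obj - 1e-12 * abs(obj):
                    C = _mat_replace(C, k, C_new)
                    vdiag, obj = v_new, cand
                    break
        return m, C, mu, vdiag, obj

    def _update_loading(self, loading, bias, mu_all, v_all, y_all):
        """Penalized Poisson regression per neuron given posterior moments."""
        D = self.latent_dim
        ridge = self.loading_ridge
        for n in range(self.n_neurons):
            y = y_all[:, n]
            a, b = loading[n].copy(), float(bias[n])

            def obj(a, b):
                lin = mu_all @ a + b
                z = np.minimum(lin + 0.5 * (v_all @ (a**2)), _ETA_MAX)
                return float(y @ lin - np.sum(np.exp(z)) - ridge * (a @ a))

            f = obj(a, b)
            for _ in range(4):
                lin = mu_all @ a + b
                z = np.minimum(lin + 0.5 * (v_all @ (a**2)), _ETA_MAX)
                rho = np.exp(z)
                J = np.empty((mu_all.shape[0], D + 1))
                J[:, :D] = mu_all + v_all * a
                J[:, D] = 1.0
                grad = np.empty(D + 1)
                grad[:D] = y @ mu_all - rho @ J[:, :D] - 2.0 * ridge * a
                grad[D] = y.sum() - rho.sum()
                H = J.T @ (J * rho[:, None])
                H[:D, :D] += np.diag(rho @ v_all) + 2.0 * ridge * np.eye(D)
                try:
                    step = cho_solve(cho_factor(H), grad)
                except np.linalg.LinAlgError:
                    step = np.linalg.solve(H + 1e-8 * np.eye(D + 1), grad)
                improved = False
                for t in (1.0, 0.5, 0.25, 0.125, 0.0625):
                    a_new = a + t * step[:D]
                    b_new = b + t * step[D]
                    f_new = obj(a_new, b_new)
                    if f_new >= f - 1e-12 * abs(f):
                        if f_new > f:
                            improved = True
                        a, b, f = a_new, b_new, f_new
                        break
                if not improved:
                    break
            loading[n], bias[n] = a, b
        return loading, bias

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 30, tol: float = 1e-5,
            update_loading: bool = True,
            loading: Optional[np.ndarray] = None,
            bias: Optional[np.ndarray] = None,
            normalize: bool = True, verbose: bool = False) -> "VLGPResults":
        """Coordinate-ascent fit; returns a :class:`VLGPResults`.

        Non-convergence within ``max_iter`` returns the best iterate
        with ``converged=False`` (no exception).
        """
        loading0, bias0, post = self._initialize()
        if loading is None:
            loading = loading0
        else:
            loading = np.array(loading, dtype=float)
        if bias is None:
            bias = bias0
        else:
            bias = np.array(bias, dtype=float)

        trace = []
        converged = False
        mu_flat = post.mean.reshape(-1, self.latent_dim)
        v_flat = post.cov_diag().reshape(-1, self.latent_dim)
        y_flat = self.counts.reshape(-1, self.n_neurons)
        for it in range(max_iter):
            if update_loading:
                loading, bias = self._update_loading(
                    loading, bias, mu_flat, v_flat, y_flat)
            total = 0.0
            v_full = np.empty_like(post.mean)
            for i in range(self.n_trials):
                m, C, mu, vdiag, obj = self._update_trial(
                    self.counts[i], post.z_mean[i], post.z_cov[i], loading, bias)
                post.z_mean[i], post.z_cov[i] = m, C
                post.mean[i] = mu
                v_full[i] = vdiag
                total += obj
            mu_flat = post.mean.reshape(-1, self.latent_dim)
            v_flat = v_full.reshape(-1, self.latent_dim)
            trace.append(total)
            if verbose:
                print(f"iter {it:3d}  elbo {total:.4f}")
            if it > 0 and trace[-1] - trace[-2] < tol * abs(trace[-2]):
                converged = True
                break

        model = VLGPModel(loading=loading, bias=bias,
                          kernels=[self.kernel] * self.latent_dim,
                          latent_dim=self.latent_dim)
        if normalize:
            _normalize_scale(model, post)
        return VLGPResults(model=model, posterior=post,
                           elbo_trace=np.asarray(trace), converged=converged,
                           n_iter=len(trace), counts_shape=self.counts.shape)


def _row_replace(m, k, row):
    out = m.copy()
    out[k] = row
    return out


def _mat_replace(C, k, mat):
    out = C.copy()
    out[k] = mat
    return out


def _normalize_scale(model: VLGPModel, post: LatentPosterior) -> None:
    """Unit posterior-mean variance per dimension; scale absorbed into loading."""
    flat = post.mean.reshape(-1, post.latent_dim)
    sd = flat.std(axis=0)
    sd[sd == 0] = 1.0
    post.mean /= sd
    post.z_mean /= sd[None, :, None]
    post.z_cov /= (sd**2)[None, :, None, None]
    model.loading *= sd


@dataclass
class VLGPResults:
    """Fit results: parameters, posterior, ELBO trace and diagnostics."""

    model: VLGPModel
    posterior: LatentPosterior
    elbo_trace: np.ndarray
    converged: bool
    n_iter: int
    counts_shape: tuple

    @property
    def loading(self) -> np.ndarray:
        return self.model.loading

    @property
    def bias(self) -> np.ndarray:
        return self.model.bias

    def reconstruct_rates(self) -> np.ndarray:
        return reconstruct_rates(self.model, self.posterior)

    def summary(self) -> str:
        n_trials, T, n_neurons = self.counts_shape
        k = self.model.kernels[0]
        lines = [
            "Variational latent Gaussian process fit",
            "=" * 45,
            f"trials: {n_trials}    bins/trial: {T} (1 ms)    neurons: {n_neurons}",
            f"latent dim: {self.model.latent_dim}    "
            f"kernel: SE(var={k.variance:g}, ell={k.timescale_ms:g} ms)",
            f"iterations: {self.n_iter}    converged: {self.converged}",
            f"final ELBO: {self.elbo_trace[-1]:.2f}",
            "",
            "neuron   bias    " + "  ".join(f"a[{j}]" for j in range(self.model.latent_dim)),
        ]
        for n in range(n_neurons):
            row = "  ".join(f"{v: .3f}" for v in self.model.loading[n])
            lines.append(f"{n:5d}  {self.model.bias[n]: .3f}   {row}")
        return "\n".join(lines)

    def plot_factors(self, trial: int = 0, ax=None):
        """Plot the posterior-mean latent trajectories of one trial."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(self.posterior.mean.shape[1])
        for k in range(self.model.latent_dim):
            ax.plot(t, self.posterior.mean[trial, :, k], label=f"factor {k + 1}")
        ax.set_xlabel("time (ms, stored)")
        ax.set_ylabel("posterior mean")
        ax.legend(frameon=False)
        return ax


def fit_vlgp(counts, latent_dim: int, init_seed: int = 0, max_iter: int = 30,
             tol: float = 1e-5, **kwargs):
    """Functional wrapper: fit and return ``(VLGPModel, LatentPosterior)``."""
    res = VLGP(counts, latent_dim=latent_dim, seed=init_seed, **kwargs).fit(
        max_iter=max_iter, tol=tol)
    return res.model, res.posterior


def reconstruct_rates(model: VLGPModel, posterior: LatentPosterior) -> np.ndarray:
    """Plug-in intensity exp(A mu_t + b), shape (n_trials, T, n_neurons)."""
    eta = posterior.mean @ model.loading.T + model.bias
    return np.exp(np.minimum(eta, _ETA_MAX))


def _poisson_regression(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                        max_iter: int = 50):
    """Poisson GLM with log link and small L2 penalty; returns (coef, loglik)."""
    Xd = np.column_stack([X, np.ones(len(X))])
    p = Xd.shape[1]
    beta = np.zeros(p)
    beta[-1] = np.log(np.clip(y.mean(), 1e-8, None))

    def loglik(b):
        eta = np.minimum(Xd @ b, _ETA_MAX)
        return float(y @ eta - np.sum(np.exp(eta)) - np.sum(gammaln(y + 1.0))
                     - ridge * (b[:-1] @ b[:-1]))

    f = loglik(beta)
    for _ in range(max_iter):
        eta = np.minimum(Xd @ beta, _ETA_MAX)
        rho = np.exp(eta)
        grad = Xd.T @ (y - rho)
        grad[:-1] -= 2 * ridge * beta[:-1]
        H = Xd.T @ (Xd * rho[:, None])
        H[:-1, :-1] += 2 * ridge * np.eye(p - 1)
        try:
            step = cho_solve(cho_factor(H), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        accepted = False
        for t in (1.0, 0.5, 0.25, 0.125):
            b_new = beta + t * step
            f_new = loglik(b_new)
            if f_new >= f:
                accepted = f_new > f + 1e-10 * abs(f)
                beta, f = b_new, f_new
                break
        if not accepted:
            break
    return beta, f


def select_dimension(counts, candidate_dims: Sequence[int], seed: int = 0,
                     max_iter: int = 8, kernel: Optional[GPKernelSpec] = None,
                     rank: Optional[int] = None, return_scores: bool = False):
    """Latent dimensionality by leave-one-neuron-out co-smoothing.

    For each candidate dimensionality and each neuron, the model is fit
    on the remaining neurons, latents are inferred, and the held-out
    neuron's 1 ms counts are scored by the predictive log likelihood of
    a Poisson regression on those latents.  The regression is cross-
    fitted over trials (weights from one half of the trials, likelihood
    evaluated on the other half, and vice versa): latent trajectories
    and spike trains are strongly autocorrelated, so an in-sample score
    would reward useless extra dimensions through spurious regression
    between smooth time series.  The smallest dimensionality within one
    standard error of the best summed score is returned.
    """
    counts = np.asarray(counts, dtype=float)
    n_neurons = counts.shape[2]
    if n_neurons < 3:
        raise ValueError("leave-one-neuron-out selection needs >= 3 neurons")
    candidate_dims = sorted(set(int(d) for d in candidate_dims))
    if any(d < 1 for d in candidate_dims):
        raise ValueError("candidate dims must be >= 1")
    if len(candidate_dims) == 1:
        return candidate_dims[0]
    n_trials = counts.shape[0]
    rng = np.random.default_rng(seed)
    half = rng.permutation(n_trials) < n_trials // 2
    scores = np.zeros((len(candidate_dims), n_neurons))
    for di, d in enumerate(candidate_dims):
        if d > n_neurons - 1:
            scores[di] = -np.inf
            continue
        for n in range(n_neurons):
            keep = [j for j in range(n_neurons) if j != n]
            model, post = fit_vlgp(counts[:, :, keep], latent_dim=d,
                                   init_seed=seed, max_iter=max_iter,
                                   kernel=kernel, rank=rank)
            ll = 0.0
            for train in (half, ~half):
                Xtr = post.mean[train].reshape(-1, d)
                ytr = counts[train][:, :, n].reshape(-1)
                beta, _ = _poisson_regression(Xtr, ytr)
                Xte = post.mean[~train].reshape(-1, d)
                yte = counts[~train][:, :, n].reshape(-1)
                eta = np.minimum(
                    np.column_stack([Xte, np.ones(len(Xte))]) @ beta, _ETA_MAX)
                ll += float(yte @ eta - np.sum(np.exp(eta))
                            - np.sum(gammaln(yte + 1.0)))
            scores[di, n] = ll
    totals = scores.sum(axis=1)
    best = int(np.argmax(totals))
    se = np.std(scores[best] - scores, axis=1, ddof=1) * np.sqrt(n_neurons)
    within = [d for di, d in enumerate(candidate_dims)
              if totals[di] >= totals[best] - max(se[di], 0.0) or di == best]
    choice = min(within)
    if return_scores:
        return choice, dict(zip(candidate_dims, totals))
    return choice
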