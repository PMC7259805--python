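"""Choice decoding: weak trials, residualization, choice mapping, CP.

The pipeline, applied after the stimulus-axis rotation:

1. *Weak trials* — restrict to coherence levels low enough that the
   behavioural correct rate of the included trials stays below 65%, so
   choice variability is not dominated by the stimulus.
2. *Residualization* — per 100 ms bin, regress the activity on the 7
   signed pulse strengths (GCV ridge) and keep the residuals ``r_t``;
   whole-trial analyses use the summed residual ``r = sum_t r_t``.
3. *Choice decoders* — L2-penalized logistic regression of choice on
   ``r``, the penalty chosen by 3-fold stratified cross-validation, and
   the *choice mapping* ``c = sigma(beta' r + beta0)`` evaluated on
   held-out folds only so decoder overfitting cannot inflate CP.
4. *Choice probability* — the two-sample ROC area (Mann-Whitney
   statistic with tie correction) of the held-out ``c`` grouped by
   choice, per axis set: stimulus axis, non-stimulus axes, all latent
   dimensions, or the raw population counts.
5. *Nested likelihood-ratio tests* — sequential unpenalized logistic
   models of choice on the mapped values (stimulus; + non-stimulus;
   + population) with chi-square p-values on one degree of freedom.
6. *CP time course* — epoch decoders (early 200-500, middle 600-900,
   late 1000-1300 ms after stimulus onset) applied to every 100 ms
   window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .session import BinnedCounts, SessionData
from .stimulus import DEFAULT_GAMMA_GRID, ridge_gcv

__all__ = [
    "WeakTrialSet",
    "ResidualActivity",
    "ChoiceDecoder",
    "ChoiceMapping",
    "CPResult",
    "NestedLRResult",
    "TimeCourseResult",
    "DEFAULT_EPOCHS",
    "select_weak_trials",
    "regress_out_pulses",
    "fit_choice_decoder",
    "choice_probability",
    "nested_lr_tests",
    "session_pooled_likelihood_ratio",
    "cp_time_course",
    "mapping_frame",
]

DEFAULT_EPOCHS: Dict[str, Tuple[int, int]] = {
    "early": (200, 500),
    "middle": (600, 900),
    "late": (1000, 1300),
}


@dataclass
class WeakTrialSet:
    """Trials of coherence levels with pooled correct rate below threshold."""

    trial_indices: np.ndarray
    coherence_levels_included: list
    achieved_correct_rate: float
    threshold: float = 0.65
    min_trials: int = 100
    excluded: bool = False

    @property
    def n_trials(self) -> int:
        return len(self.trial_indices)


def select_weak_trials(session: SessionData, threshold: float = 0.65,
                       min_trials: int = 100) -> WeakTrialSet:
    """Cumulative coherence-level inclusion below the correct-rate threshold.

    Levels of |pulse sum| are sorted ascending and added one by one; a
    level is kept only if the pooled correct rate of all included trials
    stays below ``threshold`` (level 0 is always kept).  Sets with fewer
    than ``min_trials`` trials are flagged ``excluded``.
    """
    coh = session.coherence
    levels = np.unique(coh)
    included_levels: list = []
    n_inc = 0
    n_correct = 0
    for lv in levels:
        mask = coh == lv
        n_new = n_inc + int(mask.sum())
        c_new = n_correct + int(session.correct[mask].sum())
        if included_levels and n_new > 0 and c_new / n_new >= threshold:
            break
        included_levels.append(int(lv))
        n_inc, n_correct = n_new, c_new
    idx = np.flatnonzero(np.isin(coh, included_levels))
    rate = n_correct / n_inc if n_inc else float("nan")
    return WeakTrialSet(
        trial_indices=idx, coherence_levels_included=included_levels,
        achieved_correct_rate=rate, threshold=threshold, min_trials=min_trials,
        excluded=len(idx) < min_trials)


@dataclass
class ResidualActivity:
    """Pulse-residualized 100 ms activity of the weak trials.

    ``residual_bins`` is (n_trials, n_bins, q); ``weights`` holds the
    per-bin pulse regression coefficients (n_bins, 7, q);
    ``residual_sum`` is the whole-trial sum over bins.
    """

    residual_bins: np.ndarray
    weights: np.ndarray
    bin_ms: int = 100
    trial_indices: Optional[np.ndarray] = None

    @property
    def residual_sum(self) -> np.ndarray:
        return self.residual_bins.sum(axis=1)

    def subset(self, channels) -> "ResidualActivity":
        channels = np.atleast_1d(channels)
        return ResidualActivity(
            residual_bins=self.residual_bins[:, :, channels],
            weights=self.weights[:, :, channels],
            bin_ms=self.bin_ms, trial_indices=self.trial_indices)


def regress_out_pulses(activity, pulses: np.ndarray,
                       gamma_grid: Optional[np.ndarray] = None,
                       trial_indices: Optional[np.ndarray] = None
                       ) -> ResidualActivity:
    """Remove the pulse-driven component per 100 ms bin by GCV ridge.

    ``activity`` is a :class:`BinnedCounts` or an (n_trials, n_bins, q)
    array already restricted to the analysis trials; ``pulses`` are the
    matching (n_trials, 7) signed strengths.  Each bin gets its own
    intercept-free ridge fit of the activity on the pulses; residuals
    are activity minus prediction.
    """
    if isinstance(activity, BinnedCounts):
        arr = np.asarray(activity.counts, dtype=float)
        bin_ms = activity.bin_ms
    else:
        arr = np.asarray(activity, dtype=float)
        bin_ms = 100
    n_trials, n_bins, q = arr.shape
    pulses = np.asarray(pulses, dtype=float)
    if pulses.shape[0] != n_trials:
        raise ValueError("pulses and activity disagree on n_trials")
    if n_trials < 8:
        raise ValueError("fewer than 8 trials: pulse regression underdetermined")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    n_pulses = pulses.shape[1]
    weights = np.zeros((n_bins, n_pulses, q))
    resid = np.empty_like(arr)
    all_zero = np.all(pulses == 0)
    for t in range(n_bins):
        y = arr[:, t, :]
        if all_zero:
            resid[:, t, :] = y
            continue
        w, _ = ridge_gcv(y, pulses, gamma_grid)
        weights[t] = w
        resid[:, t, :] = y - pulses @ w
    return ResidualActivity(residual_bins=resid, weights=weights, bin_ms=bin_ms,
                            trial_indices=trial_indices)


@dataclass
class ChoiceDecoder:
    """L2-penalized logistic choice decoder (bias penalized as well)."""

    weights: np.ndarray
    bias: float
    ridge_gamma: float
    fold_assignment: np.ndarray

    def map(self, r: np.ndarray) -> np.ndarray:
        """Choice mapping ``c = sigma(beta' r + beta0)``."""
        r = np.atleast_2d(r)
        return expit(r @ self.weights + self.bias)


@dataclass
class ChoiceMapping:
    """Per-trial held-out choice-mapped scalars for one axis set."""

    c: np.ndarray
    axis_set: str = "all_latent"
    session_id: str = ""
    held_out: bool = True
    trial_indices: Optional[np.ndarray] = None


@dataclass
class CPResult:
    cp: float
    n_trials: int
    axis_set: str = ""
    grouping: str = "pooled"
    se: Optional[float] = None


@dataclass
class NestedLRResult:
    loglik_stim: float
    loglik_stim_nonstim: float
    loglik_full: float
    lr1: float
    lr2: float
    p1: float
    p2: float


def _fit_l2_logistic(X: np.ndarray, y: np.ndarray, gamma: float):
    """Logistic fit maximizing loglik - gamma*||beta, beta0||^2."""
    Xa = np.column_stack([X, np.ones(len(X))])
    clf = LogisticRegression(C=1.0 / (2.0 * gamma), fit_intercept=False,
                             solver="lbfgs", max_iter=2000)
    clf.fit(Xa, y)
    coef = clf.coef_.ravel()
    return coef[:-1], float(coef[-1])


def _loglik(c_pred: np.ndarray, y: np.ndarray) -> float:
    eps = 1e-12
    c_pred = np.clip(c_pred, eps, 1 - eps)
    return float(np.sum(y * np.log(c_pred) + (1 - y) * np.log(1 - c_pred)))


def fit_choice_decoder(residuals, choices: np.ndarray,
                       gamma_grid: Optional[np.ndarray] = None, seed: int = 0,
                       n_folds: int = 3, axis_set: str = "all_latent",
                       session_id: str = ""):
    """Cross-validated choice decoder and held-out choice mapping.

    ``residuals`` is a :class:`ResidualActivity` (its whole-trial summed
    residual is used) or an (n_trials, q) array.  The ridge penalty is
    chosen by ``n_folds``-fold stratified CV maximizing held-out log
    likelihood; the held-out ``c`` of each trial comes from the decoder
    of the fold that held it out, and the returned decoder is refit on
    all trials at the chosen penalty.
    """
    if isinstance(residuals, ResidualActivity):
        X = residuals.residual_sum
        trial_indices = residuals.trial_indices
    else:
        X = np.asarray(residuals, dtype=float)
        trial_indices = None
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(choices).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both choice classes must be present")
    if gamma_grid is None:
        gamma_grid = DEFAULT_GAMMA_GRID
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    fold_assignment = np.empty(len(y), dtype=int)
    for fi, (_, test) in enumerate(folds):
        fold_assignment[test] = fi

    best_gamma, best_ll = None, -np.inf
    for g in gamma_grid:
        ll = 0.0
        for train, test in folds:
            beta, b0 = _fit_l2_logistic(X[train], y[train], g)
            ll += _loglik(expit(X[test] @ beta + b0), y[test])
        if ll > best_ll:
            best_ll, best_gamma = ll, float(g)

    c_heldout = np.empty(len(y))
    for train, test in folds:
        beta, b0 = _fit_l2_logistic(X[train], y[train], best_gamma)
        c_heldout[test] = expit(X[test] @ beta + b0)
    beta, b0 = _fit_l2_logistic(X, y, best_gamma)
    decoder = ChoiceDecoder(weights=beta, bias=b0, ridge_gamma=best_gamma,
                            fold_assignment=fold_assignment)
    mapping = ChoiceMapping(c=c_heldout, axis_set=axis_set, held_out=True,
                            session_id=session_id, trial_indices=trial_indices)
    return decoder, mapping


def choice_probability(mapping, choices: np.ndarray, axis_set: str = "",
                       grouping: str = "pooled", n_boot: int = 0,
                       seed: int = 0) -> CPResult:
    """Two-sample ROC area of the mapped values grouped by choice.

    ``CP = P(c_1 > c_0) + P(c_1 = c_0)/2`` over all pairs of a choice-1
    and a choice-0 trial, computed through the Mann-Whitney U statistic.
    """
    c = np.asarray(getattr(mapping, "c", mapping), dtype=float)
    y = np.asarray(choices).astype(int)
    c1, c0 = c[y == 1], c[y == 0]
    if len(c1) == 0 or len(c0) == 0:
        raise ValueError("choice probability undefined: one class is empty")
    u = stats.mannwhitneyu(c1, c0, alternative="two-sided").statistic
    cp = float(u) / (len(c1) * len(c0))
    se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            i1 = rng.integers(0, len(c1), len(c1))
            i0 = rng.integers(0, len(c0), len(c0))
            ub = stats.mannwhitneyu(c1[i1], c0[i0],
                                    alternative="two-sided").statistic
            boots[b] = ub / (len(c1) * len(c0))
        se = float(boots.std(ddof=1))
    if not axis_set:
        axis_set = getattr(mapping, "axis_set", "")
    return CPResult(cp=cp, n_trials=len(c), axis_set=axis_set,
                    grouping=grouping, se=se)


def _logit_loglik(X: np.ndarray, y: np.ndarray) -> float:
    """Max log likelihood of an unpenalized logistic model (ridge fallback)."""
    Xc = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.isfinite(res.llf):
                return float(res.llf)
        except Exception:
            pass
    warnings.warn("separation in nested logistic fit; falling back to weak ridge")
    beta, b0 = _fit_l2_logistic(X, y, 1e-8)
    c = expit(X @ beta + b0)
    return _loglik(c, y)


def nested_lr_tests(c_stim, c_nonstim, c_pop, choices) -> NestedLRResult:
    """Sequential likelihood-ratio tests of the choice-mapped values.

    Three nested unpenalized logistic models of choice on (c_stim),
    (c_stim, c_nonstim), (c_stim, c_nonstim, c_pop); LR values are
    ratios of maximized likelihoods (<= 1) and p-values come from the
    chi-square distribution of -2 log LR with one degree of freedom.
    """
    arrs = [np.asarray(getattr(a, "c", a), dtype=float)
            for a in (c_stim, c_nonstim, c_pop)]
    y = np.asarray(choices).astype(int)
    if not all(len(a) == len(y) for a in arrs):
        raise ValueError("mapped vectors must align with choices")
    ll1 = _logit_loglik(arrs[0][:, None], y)
    ll2 = _logit_loglik(np.column_stack(arrs[:2]), y)
    ll3 = _logit_loglik(np.column_stack(arrs), y)
    ll2 = max(ll2, ll1)   # guard against optimizer slack breaking nesting
    ll3 = max(ll3, ll2)
    lr1 = float(np.exp(min(ll1 - ll2, 0.0)))
    lr2 = float(np.exp(min(ll2 - ll3, 0.0)))
    p1 = float(stats.chi2.sf(2.0 * (ll2 - ll1), 1))
    p2 = float(stats.chi2.sf(2.0 * (ll3 - ll2), 1))
    return NestedLRResult(loglik_stim=ll1, loglik_stim_nonstim=ll2,
                          loglik_full=ll3, lr1=lr1, lr2=lr2, p1=p1, p2=p2)


def session_pooled_likelihood_ratio(c_by_session, choices_by_session):
    """Per-session diagnostic of how much pooling costs.

    For each session, a full logistic choice model (stimulus,
    non-stimulus and population mapped values) is fit to that session
    alone, and the model fit to the pooled trials of all sessions is
    evaluated on the same session.  The returned ratios
    ``L_pooled / L_session`` lie in (0, 1]; values near 1 mean pooling
    across sessions keeps essentially all the choice information.

    ``c_by_session`` is a list of (n_s, 3) arrays of mapped values,
    ``choices_by_session`` the matching choice vectors.
    """
    Xs = [np.column_stack([np.ones(len(c)), np.asarray(c, dtype=float)])
          for c in c_by_session]
    ys = [np.asarray(y).astype(int) for y in choices_by_session]

    def fit(X, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
                if np.all(np.isfinite(res.params)):
                    return np.asarray(res.params)
            except Exception:
                pass
        beta, b0 = _fit_l2_logistic(X[:, 1:], y, 1e-8)
        return np.concatenate([[b0], beta])

    pooled = fit(np.vstack(Xs), np.concatenate(ys))
    ratios = []
    for X, y in zip(Xs, ys):
        own = fit(X, y)
        ll_own = _loglik(expit(X @ own), y)
        ll_pooled = _loglik(expit(X @ pooled), y)
        ratios.append(float(np.exp(min(ll_pooled - ll_own, 0.0))))
    return np.asarray(ratios)


@dataclass
class TimeCourseResult:
    """CP per 100 ms window for each epoch-trained decoder."""

    window_centers_ms: np.ndarray            # relative to stimulus onset
    cp: Dict[str, np.ndarray]
    decoders: Dict[str, ChoiceDecoder]
    epochs: Dict[str, Tuple[int, int]]


def cp_time_course(residuals: ResidualActivity, choices: np.ndarray,
                   epochs: Optional[Dict[str, Tuple[int, int]]] = None,
                   t_pre_ms: int = 100, seed: int = 0,
                   gamma_grid: Optional[np.ndarray] = None) -> TimeCourseResult:
    """Epoch decoders applied across 100 ms windows.

    One decoder is fit per epoch on the summed residual of that epoch's
    bins (same CV protocol as :func:`fit_choice_decoder`); its weights
    are then applied to every window's single-bin residual and the CP of
    the resulting mapped values is computed per window.  Epochs and the
    returned window centers are relative to stimulus onset.
    """
    epochs = epochs or DEFAULT_EPOCHS
    y = np.asarray(choices).astype(int)
    r = residuals.residual_bins
    bin_ms = residuals.bin_ms
    n_bins = r.shape[1]
    centers = np.arange(n_bins) * bin_ms + bin_ms / 2.0 - t_pre_ms
    cp_curves: Dict[str, np.ndarray] = {}
    decoders: Dict[str, ChoiceDecoder] = {}
    for name, (lo, hi) in epochs.items():
        b0 = (lo + t_pre_ms) // bin_ms
        b1 = (hi + t_pre_ms) // bin_ms
        if b0 < 0 or b1 > n_bins:
            raise ValueError(f"epoch {name} {lo}-{hi} ms outside the trial")
        epoch_sum = r[:, b0:b1, :].sum(axis=1)
        dec, _ = fit_choice_decoder(epoch_sum, y, gamma_grid=gamma_grid,
                                    seed=seed, axis_set=name)
        decoders[name] = dec
        curve = np.empty(n_bins)
        for t in range(n_bins):
            c = dec.map(r[:, t, :])
            curve[t] = choice_probability(c, y).cp
        cp_curves[name] = curve
    return TimeCourseResult(window_centers_ms=centers, cp=cp_curves,
                            decoders=decoders, epochs=dict(epochs))


def mapping_frame(mappings: Sequence[ChoiceMapping], choices: np.ndarray):
    """Tidy export of mapped values: session_id, trial, axis_set, c_value, choice."""
    import pandas as pd

    y = np.asarray(choices).astype(int)
    rows = []
    for m in mappings:
        idx = (m.trial_indices if m.trial_indices is not None
               else np.arange(len(m.c)))
        for pos, (t, c) in enumerate(zip(idx, m.c)):
            rows.append((m.session_id, int(t), m.axis_set, float(c), int(y[pos])))
    return pd.DataFrame(rows, columns=["session_id", "trial", "axis_set",
                                       "c_value", "choice"])
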