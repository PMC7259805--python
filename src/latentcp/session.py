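"""Epoched-session container, HDF5 I/O and binning utilities.

A *session* is one simultaneously recorded population during a
motion-pulse discrimination task.  Trials are epoched to a fixed layout:
100 ms of pre-stimulus baseline, seven 150 ms motion pulses, and 350 ms
after stimulus offset, giving 1500 one-millisecond bins per trial.
Stored time starts at t = -100 ms relative to stimulus onset; every
window specification elsewhere in the package is relative to stimulus
onset.  Bins are half-open ``[t, t + dt)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "SessionData",
    "BinnedCounts",
    "FormatError",
    "ValidationError",
    "read_session",
    "write_session",
    "bin_counts",
    "meets_population_threshold",
    "rebin",
]


class FormatError(Exception):
    """The on-disk file does not follow the session layout."""


class ValidationError(ValueError):
    """A container violates a session invariant."""


@dataclass
class SessionData:
    """One recording session.

    Parameters
    ----------
    session_id : str
        Free-form identifier, stored as an HDF5 attribute.
    spikes : ndarray of uint8, shape (n_trials, T, n_neurons)
        Binary spike indicator at 1 ms resolution (at most one spike
        per bin per neuron).
    pulses : ndarray of int, shape (n_trials, 7)
        Signed pulse strengths; the sign encodes motion direction and
        the magnitude the number of coherently drifting patches.
    choice : ndarray of uint8, shape (n_trials,)
        1 = saccade toward the positive-pulse direction.
    correct : ndarray of uint8, shape (n_trials,)
    frozen : ndarray of uint8, shape (n_trials,)
        1 on interleaved trials that share a single repeated pulse
        sequence.
    """

    session_id: str
    spikes: np.ndarray
    pulses: np.ndarray
    choice: np.ndarray
    correct: np.ndarray
    frozen: np.ndarray
    t_pre_ms: int = 100
    pulse_ms: int = 150
    n_pulses: int = 7
    t_post_ms: int = 350

    def __post_init__(self) -> None:
        self.spikes = np.asarray(self.spikes, dtype=np.uint8)
        self.pulses = np.asarray(self.pulses)
        for name in ("choice", "correct", "frozen"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.uint8))
        self.validate()

    # -- derived geometry ------------------------------------------------
    @property
    def T_1ms(self) -> int:
        return self.t_pre_ms + self.n_pulses * self.pulse_ms + self.t_post_ms

    @property
    def n_trials(self) -> int:
        return self.spikes.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.spikes.shape[2]

    @property
    def coherence(self) -> np.ndarray:
        """Per-trial coherence, the absolute pulse sum |sum_i s_i|."""
        return np.abs(self.pulses.sum(axis=1))

    def validate(self) -> None:
        if self.spikes.ndim != 3:
            raise ValidationError("spikes must be (n_trials, T, n_neurons)")
        n_trials, T, n_neurons = self.spikes.shape
        if T != self.T_1ms:
            raise ValidationError(
                f"spikes time axis {T} != t_pre + n_pulses*pulse + t_post = {self.T_1ms}"
            )
        if n_neurons < 1:
            raise ValidationError("need at least one neuron")
        if self.pulses.shape != (n_trials, self.n_pulses):
            raise ValidationError(
                f"pulses shape {self.pulses.shape} != ({n_trials}, {self.n_pulses})"
            )
        if not np.issubdtype(self.pulses.dtype, np.integer):
            raise ValidationError("pulses must be integers")
        for name in ("choice", "correct", "frozen"):
            arr = getattr(self, name)
            if arr.shape != (n_trials,):
                raise ValidationError(f"{name} shape {arr.shape} != ({n_trials},)")
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"{name} must be binary")
        if not np.isin(self.spikes, (0, 1)).all():
            raise ValidationError("spikes must be binary at 1 ms resolution")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionData):
            return NotImplemented
        if self.session_id != other.session_id:
            return False
        for f in dataclasses.fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, np.ndarray):
                if not (a.shape == b.shape and (a == b).all()):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class BinnedCounts:
    """Activity re-binned by summation.

    ``counts`` has shape (n_trials, n_bins, n_channels); channels are
    either neurons (nonnegative integer counts) or latent factors
    (real-valued posterior-mean sums).
    """

    counts: np.ndarray
    bin_ms: int
    channel_kind: str = "neurons"  # or "latent_factors"

    def __post_init__(self) -> None:
        if self.channel_kind not in ("neurons", "latent_factors"):
            raise ValidationError(f"unknown channel_kind {self.channel_kind!r}")
        self.counts = np.asarray(self.counts)
        if self.channel_kind == "neurons" and (self.counts < 0).any():
            raise ValidationError("neuron counts must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def n_channels(self) -> int:
        return self.counts.shape[2]


_DATASETS = ("spikes", "pulses", "choice", "correct", "frozen")
_ATTRS = ("t_pre_ms", "pulse_ms", "n_pulses", "t_post_ms")
_DTYPES = {
    "spikes": np.uint8,
    "pulses": np.int16,
    "choice": np.uint8,
    "correct": np.uint8,
    "frozen": np.uint8,
}


def write_session(session: SessionData, path) -> None:
    """Write a session to HDF5 (deterministic layout, bit-exact round trip)."""
    with h5py.File(path, "w", track_order=False) as f:
        g = f.create_group("session")
        for name in _DATASETS:
            g.create_dataset(
                name,
                data=np.asarray(getattr(session, name), dtype=_DTYPES[name]),
                track_times=False,
            )
        g.attrs["session_id"] = session.session_id
        for name in _ATTRS:
            g.attrs[name] = int(getattr(session, name))


def read_session(path) -> SessionData:
    """Read a session written by :func:`write_session`.

    Raises
    ------
    FormatError
        If a required dataset or attribute is missing.
    ValidationError
        If shapes or values violate the session invariants.
    """
    with h5py.File(path, "r") as f:
        if "session" not in f:
            raise FormatError("missing group 'session'")
        g = f["session"]
        data = {}
        for name in _DATASETS:
            if name not in g:
                raise FormatError(f"missing dataset 'session/{name}'")
            data[name] = g[name][...]
        attrs = {}
        for name in ("session_id",) + _ATTRS:
            if name not in g.attrs:
                raise FormatError(f"missing attribute 'session/{name}'")
            attrs[name] = g.attrs[name]
    sid = attrs.pop("session_id")
    if isinstance(sid, bytes):
        sid = sid.decode()
    return SessionData(session_id=str(sid), **data,
                       **{k: int(v) for k, v in attrs.items()})


def meets_population_threshold(session: SessionData, min_neurons: int = 10) -> bool:
    """Session-inclusion rule: at least ``min_neurons`` simultaneous units."""
    return session.n_neurons >= min_neurons


def rebin(array: np.ndarray, bin_ms: int) -> np.ndarray:
    """Sum an (n_trials, T, n_channels) array into bins of ``bin_ms`` samples."""
    n_trials, T, n_channels = array.shape
    if bin_ms < 1 or T % bin_ms:
        raise ValidationError(f"bin_ms={bin_ms} does not divide T={T}")
    n_bins = T // bin_ms
    return array.reshape(n_trials, n_bins, bin_ms, n_channels).sum(axis=2)


def bin_counts(session: SessionData, bin_ms: int, source="spikes") -> BinnedCounts:
    """Re-bin a session's spikes, or a latent posterior's means, by summation.

    ``source`` is either the string ``"spikes"`` or an object with a
    ``mean`` array of shape (n_trials, T, latent_dim) (a fitted latent
    posterior, or a plain array of latent trajectories).
    """
    if isinstance(source, str):
        if source != "spikes":
            raise ValidationError(f"unknown source {source!r}")
        arr = session.spikes.astype(np.int64)
        kind = "neurons"
    else:
        if not isinstance(source, np.ndarray):
            mean = getattr(source, "mean", None)
            if isinstance(mean, np.ndarray):
                source = mean
        arr = np.asarray(source, dtype=float)
        kind = "latent_factors"
    return BinnedCounts(counts=rebin(arr, bin_ms), bin_ms=bin_ms, channel_kind=kind)
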