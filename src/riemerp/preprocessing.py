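"""From continuous EEG to super-trial covariance features.

The decoding pipeline is: band-pass filter the continuous multichannel
recording (0.1–40 Hz, zero phase), cut 0–1000 ms epochs at each stimulus
onset, and turn every single-trial epoch ``X`` (N channels x M samples)
into a *super-trial*

    S = [ X ; P_target ; P_nontarget ]  in R^{3N x M},

where the prototypes ``P`` are the class-average target and non-target
epochs estimated on training data only.  Each row of ``S`` is centered to
zero mean and the feature is the sample covariance

    C = S S.T / (M - 1)  in R^{3N x 3N},

regularized into the SPD cone.  Stacking the fixed class prototypes under
the trial compensates for the weak spatial variability of ERP responses:
the cross-covariance between the trial and each prototype encodes how
target-like the trial is, which is what the Riemannian classifier exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import ensure_spd

logger = logging.getLogger(__name__)

__all__ = [
    "ContinuousRecording",
    "EpochSet",
    "TARGET",
    "NONTARGET",
    "bandpass_filter",
    "extract_epochs",
    "class_prototypes",
    "build_super_trial",
    "supertrial_covariance",
    "SuperTrialCovariance",
]

#: class labels: 1 = rare target (carries the P300), 2 = frequent non-target
TARGET = 1
NONTARGET = 2

EVENT_COLUMNS = ("onset", "code", "is_target", "block")


def _validate_events(events: pd.DataFrame) -> pd.DataFrame:
    events = pd.DataFrame(events).reset_index(drop=True)
    for col in ("onset", "code", "is_target"):
        if col not in events.columns:
            raise ValueError(f"event table is missing required column '{col}'")
    if "block" not in events.columns:
        events["block"] = 0
    onsets = events["onset"].to_numpy()
    if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
        bad = int(np.flatnonzero(np.diff(onsets) <= 0)[0]) + 1
        raise ValueError(f"event onsets must be strictly increasing (violated at row {bad})")
    if (events["code"] < 1).any():
        raise ValueError("stimulus codes must be in 1..K (found code < 1)")
    return events[list(EVENT_COLUMNS)].astype(
        {"onset": int, "code": int, "is_target": bool, "block": int}
    )


@dataclass
class ContinuousRecording:
    """Continuous multichannel EEG (µV) plus its stimulus event table.

    ``events`` columns: ``onset`` (sample index, 0-based), ``code``
    (stimulus code 1..K), ``is_target`` (attended?), ``block`` (selection
    block index).  Onsets must be strictly increasing.
    """

    samples: np.ndarray  # (n_channels, n_samples), µV
    fs: float
    channel_names: list[str]
    events: pd.DataFrame

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("channel_names length must match the channel axis")
        self.events = _validate_events(self.events)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EpochSet:
    """Labeled single-trial ERP epochs cut 0–1000 ms from stimulus onset."""

    epochs: np.ndarray  # (n_trials, n_channels, n_times)
    fs: float
    labels: np.ndarray  # 1 = target, 2 = non-target
    codes: np.ndarray  # stimulus code 1..K per trial
    blocks: np.ndarray  # selection-block index per trial
    channel_names: list[str] = field(default_factory=list)
    window_ms: tuple[float, float] = (0.0, 1000.0)

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be a 3-D (trials x channels x times) array")
        self.labels = np.asarray(self.labels, dtype=int)
        self.codes = np.asarray(self.codes, dtype=int)
        self.blocks = np.asarray(self.blocks, dtype=int)
        n = len(self.epochs)
        for name, arr in (("labels", self.labels), ("codes", self.codes), ("blocks", self.blocks)):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != number of trials {n}")
        if n and not np.isin(self.labels, [TARGET, NONTARGET]).all():
            raise ValueError("labels must be 1 (target) or 2 (non-target)")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.epochs.shape[1])]

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_times(self) -> int:
        return self.epochs.shape[2]

    def subset(self, mask: np.ndarray) -> "EpochSet":
        """Epochs selected by a boolean mask or index array."""
        mask = np.asarray(mask)
        return EpochSet(
            epochs=self.epochs[mask],
            fs=self.fs,
            labels=self.labels[mask],
            codes=self.codes[mask],
            blocks=self.blocks[mask],
            channel_names=list(self.channel_names),
            window_ms=self.window_ms,
        )


def bandpass_filter(
    rec: ContinuousRecording, low: float = 0.1, high: float = 40.0, order: int = 4
) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass per channel; events untouched.

    Defaults are the conventional ERP band 0.1–40 Hz.  The filter is
    applied forward-backward (``sosfiltfilt``) so that P300 latency is not
    shifted by phase distortion.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= rec.fs / 2:
        raise ValueError(f"high cut-off {high} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return ContinuousRecording(
        samples=filtered,
        fs=rec.fs,
        channel_names=list(rec.channel_names),
        events=rec.events.copy(),
    )


def extract_epochs(rec: ContinuousRecording, window_s: float = 1.0) -> EpochSet:
    """Cut one epoch per event over the half-open window [onset, onset + M).

    M = round(fs * window_s) samples.  Events whose epoch would run past
    the end of the recording are dropped with a logged warning so that
    extracted + dropped = number of events.
    """
    m = int(round(rec.fs * window_s))
    epochs, labels, codes, blocks = [], [], [], []
    n_dropped = 0
    for row in rec.events.itertuples(index=False):
        start = int(row.onset)
        stop = start + m
        if start < 0 or stop > rec.n_samples:
            n_dropped += 1
            continue
        epochs.append(rec.samples[:, start:stop])
        labels.append(TARGET if row.is_target else NONTARGET)
        codes.append(row.code)
        blocks.append(row.block)
    if n_dropped:
        logger.warning("dropped %d truncated epoch(s) at the recording edge", n_dropped)
    epochs_arr = (
        np.stack(epochs) if epochs else np.empty((0, rec.n_channels, m))
    )
    return EpochSet(
        epochs=epochs_arr,
        fs=rec.fs,
        labels=np.array(labels, dtype=int),
        codes=np.array(codes, dtype=int),
        blocks=np.array(blocks, dtype=int),
        channel_names=list(rec.channel_names),
        window_ms=(0.0, 1000.0 * window_s),
    )


def class_prototypes(train: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-class arithmetic-mean epochs (target, non-target) from training data.

    Prototypes must come from training folds only; the API returns plain
    arrays that are passed explicitly downstream, so a test trial can never
    leak into its own prototype.
    """
    tgt = train.epochs[train.labels == TARGET]
    non = train.epochs[train.labels == NONTARGET]
    if len(tgt) == 0 or len(non) == 0:
        raise ValueError(
            "both classes must be present to form prototypes "
            f"(targets: {len(tgt)}, non-targets: {len(non)})"
        )
    return tgt.mean(axis=0), non.mean(axis=0)


def build_super_trial(
    epoch: np.ndarray, prototypes: tuple[np.ndarray, np.ndarray]
) -> np.ndarray:
    """Stack [epoch; target prototype; non-target prototype] and center rows.

    Output is 3N x M with every row's mean over the epoch window removed
    (the zero-mean assumption under which the covariance is the feature).
    """
    epoch = np.asarray(epoch, dtype=float)
    p_t, p_nt = (np.asarray(p, dtype=float) for p in prototypes)
    if epoch.shape != p_t.shape or epoch.shape != p_nt.shape:
        raise ValueError(
            f"epoch and prototypes must share N x M shape: "
            f"{epoch.shape}, {p_t.shape}, {p_nt.shape}"
        )
    st = np.vstack([epoch, p_t, p_nt])
    return st - st.mean(axis=1, keepdims=True)


def supertrial_covariance(st: np.ndarray, loading: float = 1e-10):
    """Sample covariance C = S S.T / (M-1) of a centered super-trial.

    Passed through :func:`riemerp.geometry.ensure_spd` so rank-deficient
    cases (M < 3N, or identical rows) come back positive definite.
    Returns the :class:`~riemerp.geometry.EnsureSPDResult`.
    """
    st = np.asarray(st, dtype=float)
    if st.ndim != 2:
        raise ValueError("super-trial must be 2-D")
    m = st.shape[1]
    if m < 2:
        raise ValueError(f"need at least 2 samples per row to form a covariance, got {m}")
    c = st @ st.T / (m - 1)
    return ensure_spd(c, loading=loading)


class SuperTrialCovariance(TransformerMixin, BaseEstimator):
    """Transformer: single-trial epochs -> prototype-augmented SPD covariances.

    ``fit`` learns the target / non-target prototype epochs from the
    training trials; ``transform`` stacks each trial with both prototypes,
    centers the rows, and returns the 3N x 3N sample covariances.  The
    feature construction is label-agnostic: the prototypes are fixed rows
    of every super-trial regardless of the trial's (hypothesized) class.

    Parameters
    ----------
    loading : relative diagonal-loading floor forwarded to ``ensure_spd``.

    Attributes
    ----------
    target_prototype_, nontarget_prototype_ : (N, M) mean class epochs.
    n_channels_, n_times_ : training epoch geometry.
    """

    def __init__(self, loading: float = 1e-10):
        self.loading = loading

    def fit(self, X, y):
        """Learn class prototypes from epochs ``X`` (n, N, M) and labels ``y``."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be 3-D (trials x channels x times)")
        if len(y) != len(X):
            raise ValueError("X and y length mismatch")
        train = EpochSet(
            epochs=X,
            fs=1.0,
            labels=y,
            codes=np.ones(len(X), dtype=int),
            blocks=np.zeros(len(X), dtype=int),
        )
        self.target_prototype_, self.nontarget_prototype_ = class_prototypes(train)
        self.n_channels_, self.n_times_ = X.shape[1], X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        """Map epochs (n, N, M) to super-trial covariances (n, 3N, 3N)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1:] != (self.n_channels_, self.n_times_):
            raise ValueError(
                f"X must have shape (n, {self.n_channels_}, {self.n_times_}), got {X.shape}"
            )
        protos = (self.target_prototype_, self.nontarget_prototype_)
        covs = [
            supertrial_covariance(build_super_trial(ep, protos), loading=self.loading).matrix
            for ep in X
        ]
        return np.stack(covs) if covs else np.empty((0, 3 * self.n_channels_, 3 * self.n_channels_))
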