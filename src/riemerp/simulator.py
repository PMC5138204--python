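"""Synthetic spatial-oddball EEG sessions with controllable P300 structure.

A K-command oddball session consists of selection blocks; within a block
one command is attended and every code 1..K is presented once per
sub-round in block-randomized order, for ``reps_per_command`` sub-rounds.
Rare attended ("target") stimuli evoke a P300: a positive Gaussian bump
peaking inside the 300–600 ms window, scaled across channels by a smooth
centro-parietal topography.  Non-targets evoke nothing.  The background is
white plus 1/f ("pink") Gaussian noise, independent per channel.

The generator exists so that the whole decoding chain — filtering,
epoching, super-trial covariances, MDM and SWLDA, accuracy-vs-averaging —
is testable end-to-end without any recorded EEG.  Defaults are one fixed
choice of realistic study conditions (documented in the methods note), not
tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .preprocessing import NONTARGET, TARGET, ContinuousRecording, EpochSet

__all__ = [
    "ParadigmConfig",
    "ERPModel",
    "PRESETS",
    "get_preset",
    "simulate_session",
    "simulate_epochs",
    "default_topography",
]

#: 10/10 montages used by the emulated rigs (8 or 16 active electrodes)
CHANNELS_8 = ["Cz", "Pz", "P3", "P4", "C3", "C4", "CP5", "CP6"]
CHANNELS_16 = CHANNELS_8 + ["P1", "P2", "POz", "C1", "C2", "FC1", "FC2", "FCz"]


@dataclass
class ParadigmConfig:
    """Stimulation-schedule parameters of one oddball paradigm."""

    K: int = 5  # command count
    isi_ms: float = 400.0  # inter-stimulus interval
    stim_ms: float = 100.0  # stimulus duration (schedule metadata)
    fs: float = 512.0
    n_channels: int = 8
    reps_per_command: int = 10  # sub-rounds per selection block
    n_blocks: int = 10  # selection blocks per session
    attended_sequence: tuple[int, ...] | None = None  # target command per block

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.reps_per_command < 1:
            raise ValueError("reps_per_command must be at least 1")
        for name in ("isi_ms", "stim_ms", "fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.attended_sequence is None:
            # cycle through the K commands across blocks
            self.attended_sequence = tuple(
                (b % self.K) + 1 for b in range(self.n_blocks)
            )
        if len(self.attended_sequence) != self.n_blocks:
            raise ValueError("attended_sequence must have one entry per block")
        if any(not 1 <= a <= self.K for a in self.attended_sequence):
            raise ValueError("attended commands must lie in 1..K")

    @property
    def channel_names(self) -> list[str]:
        if self.n_channels == 8:
            return list(CHANNELS_8)
        if self.n_channels == 16:
            return list(CHANNELS_16)
        return [f"ch{i}" for i in range(self.n_channels)]

    @property
    def n_events(self) -> int:
        return self.K * self.reps_per_command * self.n_blocks


def default_topography(n_channels: int, channel_names: list[str] | None = None) -> np.ndarray:
    """Smooth per-channel P300 gain, maximal at the Pz-like channel.

    A Gaussian profile over electrode index centered on Pz (fallback:
    second channel), width n_channels/3, normalized to peak gain 1.
    """
    names = channel_names or (
        CHANNELS_8 if n_channels == 8 else CHANNELS_16 if n_channels == 16 else []
    )
    center = names.index("Pz") if "Pz" in names else min(1, n_channels - 1)
    idx = np.arange(n_channels)
    gain = np.exp(-0.5 * ((idx - center) / (n_channels / 3.0)) ** 2)
    return gain / gain.max()


@dataclass
class ERPModel:
    """Additive P300 component and background-noise model.

    Amplitude is the peak deflection (µV) at the best channel; latency and
    width (the Gaussian standard deviation) are in ms.  ``noise_sigma`` is
    the white-noise standard deviation per channel and sample;
    ``pink_noise_scale`` the standard deviation of the 1/f component.
    """

    p300_amplitude: float = 5.0
    p300_latency_ms: float = 450.0
    p300_width_ms: float = 80.0
    channel_topography: np.ndarray | None = None
    noise_sigma: float = 10.0
    pink_noise_scale: float = 10.0
    seed: int | None = None

    def __post_init__(self):
        if self.p300_amplitude < 0:
            raise ValueError("p300_amplitude must be nonnegative")
        if self.noise_sigma < 0 or self.pink_noise_scale < 0:
            raise ValueError("noise scales must be nonnegative")

    def topography(self, n_channels: int, channel_names=None) -> np.ndarray:
        if self.channel_topography is not None:
            topo = np.asarray(self.channel_topography, dtype=float)
            if len(topo) != n_channels:
                raise ValueError("channel_topography length must equal n_channels")
            return topo
        return default_topography(n_channels, channel_names)

    def bump(self, fs: float, n_times: int) -> np.ndarray:
        """P300 time course sampled on an epoch-length grid (µV)."""
        t_ms = np.arange(n_times) / fs * 1000.0
        return self.p300_amplitude * np.exp(
            -0.5 * ((t_ms - self.p300_latency_ms) / self.p300_width_ms) ** 2
        )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_times: int) -> np.ndarray:
    """Unit-variance 1/f-power noise, independent per channel."""
    white = rng.standard_normal((n_channels, n_times))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_times)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^(-1/2) => power ~ 1/f
    pink = np.fft.irfft(spec * scale, n=n_times, axis=1)
    sd = pink.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pink / sd


def _event_schedule(cfg: ParadigmConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Block-randomized stimulus order: each code once per sub-round."""
    codes, targets, blocks = [], [], []
    for b in range(cfg.n_blocks):
        attended = cfg.attended_sequence[b]
        for _ in range(cfg.reps_per_command):
            order = rng.permutation(cfg.K) + 1
            codes.extend(order.tolist())
            targets.extend((order == attended).tolist())
            blocks.extend([b] * cfg.K)
    return pd.DataFrame({"code": codes, "is_target": targets, "block": blocks})


def simulate_session(
    cfg: ParadigmConfig, erp: ERPModel, seed: int | None = None
) -> ContinuousRecording:
    """Synthesize one continuous oddball EEG session with its event table.

    Stimulus onsets are spaced ``isi_ms`` apart with a 1 s lead-in and a
    1.5 s inter-block gap; the recording is padded so the last 1000 ms
    epoch fits.  With short ISIs (150 ms) consecutive epochs overlap;
    that is a property of the paradigm, and the event bookkeeping stays
    exact.  Identical seeds give bit-identical output.
    """
    rng = np.random.default_rng(seed if seed is not None else erp.seed)
    sched = _event_schedule(cfg, rng)

    isi = int(round(cfg.isi_ms / 1000.0 * cfg.fs))
    lead_in = int(round(1.0 * cfg.fs))
    block_gap = int(round(1.5 * cfg.fs))
    per_block = cfg.K * cfg.reps_per_command

    onsets = np.empty(len(sched), dtype=int)
    cursor = lead_in
    for i, row in enumerate(sched.itertuples(index=False)):
        within = i % per_block
        if i > 0 and within == 0:
            cursor += block_gap
        onsets[i] = cursor
        cursor += isi
    n_total = cursor + int(round(1.5 * cfg.fs))  # room for the final epoch

    names = cfg.channel_names
    samples = erp.noise_sigma * rng.standard_normal((cfg.n_channels, n_total))
    if erp.pink_noise_scale > 0:
        samples += erp.pink_noise_scale * _pink_noise(rng, cfg.n_channels, n_total)

    n_epoch = int(round(cfg.fs))
    bump = erp.bump(cfg.fs, n_epoch)
    topo = erp.topography(cfg.n_channels, names)
    component = np.outer(topo, bump)
    for onset, is_tgt in zip(onsets, sched["is_target"]):
        if is_tgt:
            samples[:, onset : onset + n_epoch] += component

    events = sched.assign(onset=onsets)[["onset", "code", "is_target", "block"]]
    return ContinuousRecording(samples=samples, fs=cfg.fs, channel_names=names, events=events)


def simulate_epochs(
    cfg: ParadigmConfig, erp: ERPModel, seed: int | None = None
) -> EpochSet:
    """Directly emit labeled epochs under the same ERP + noise model.

    Bypasses continuous synthesis (no filtering, no epoch overlap) for
    fast statistically-matched unit tests: each epoch is white + pink
    noise, plus the topography-scaled P300 bump when the trial's code is
    the attended one.
    """
    rng = np.random.default_rng(seed if seed is not None else erp.seed)
    sched = _event_schedule(cfg, rng)
    n = len(sched)
    n_epoch = int(round(cfg.fs))
    names = cfg.channel_names

    epochs = erp.noise_sigma * rng.standard_normal((n, cfg.n_channels, n_epoch))
    if erp.pink_noise_scale > 0:
        for i in range(n):
            epochs[i] += erp.pink_noise_scale * _pink_noise(rng, cfg.n_channels, n_epoch)
    component = np.outer(erp.topography(cfg.n_channels, names), erp.bump(cfg.fs, n_epoch))
    is_tgt = sched["is_target"].to_numpy()
    epochs[is_tgt] += component

    return EpochSet(
        epochs=epochs,
        fs=cfg.fs,
        labels=np.where(is_tgt, TARGET, NONTARGET),
        codes=sched["code"].to_numpy(),
        blocks=sched["block"].to_numpy(),
        channel_names=names,
    )


#: Named paradigm presets for the nine emulated rigs (command count, ISI,
#: stimulus duration, montage size, sampling rate).  Where a rig's schedule
#: parameter is not fixed by its description, the package uses ISI 400 ms
#: and fs 512 Hz as the typical values of this hardware family.
PRESETS: dict[str, ParadigmConfig] = {
    "vrtba": ParadigmConfig(K=5, isi_ms=150, stim_ms=100, fs=512, n_channels=8),
    "vrtpp": ParadigmConfig(K=5, isi_ms=150, stim_ms=100, fs=512, n_channels=8),
    "rtc": ParadigmConfig(K=5, isi_ms=400, stim_ms=100, fs=512, n_channels=16),
    "rbt": ParadigmConfig(K=6, isi_ms=400, stim_ms=100, fs=512, n_channels=16),
    "rautd": ParadigmConfig(K=6, isi_ms=400, stim_ms=100, fs=512, n_channels=16),
    "rtpp": ParadigmConfig(K=6, isi_ms=400, stim_ms=100, fs=256, n_channels=8),
    "rsa": ParadigmConfig(K=5, isi_ms=150, stim_ms=150, fs=512, n_channels=16),
    "rtg": ParadigmConfig(K=5, isi_ms=400, stim_ms=100, fs=512, n_channels=8),
    "rfbt": ParadigmConfig(K=6, isi_ms=400, stim_ms=100, fs=512, n_channels=8),
}


def get_preset(name: str, **overrides) -> ParadigmConfig:
    """A copy of a named paradigm preset, optionally with fields overridden."""
    try:
        base = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset '{name}'; available: {sorted(PRESETS)}") from None
    if ("K" in overrides or "n_blocks" in overrides) and "attended_sequence" not in overrides:
        overrides["attended_sequence"] = None  # re-derive for the new geometry
    return replace(base, **overrides) if overrides else replace(base)
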