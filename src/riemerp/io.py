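"""File I/O: EDF recordings, delimited event tables, epoch archives, results.

Continuous sessions travel as European Data Format (EDF) files plus a
tab-separated event table (``onset_sample``, ``code``, ``is_target``,
optional ``block``; onsets are 0-based sample indices).  Reading goes
through :func:`mne.io.read_raw_edf`.  Writing uses a minimal EDF writer
implemented here (ASCII header + 16-bit data records, 1 s records): the
format is simple enough that round-tripping through mne's reader verifies
it to within the 16-bit amplitude quantization.

Epoch sets use a compact archive: a ``.npz`` array container plus a
human-readable JSON sidecar with the schema (fs, channels, window).
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import AccuracyTable, GrandAverage
from .preprocessing import ContinuousRecording, EpochSet

__all__ = [
    "read_edf",
    "write_edf",
    "read_events",
    "write_events",
    "save_epochs",
    "load_epochs",
    "write_results",
    "RunConfig",
]

EVENT_REQUIRED = ("onset_sample", "code", "is_target")


def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: ContinuousRecording, path, event_path=None) -> None:
    """Write a recording as EDF (16-bit) plus an optional event TSV.

    Uses 1 s data records, so the sampling rate must be a positive
    integer; the final record is zero-padded.  Per-channel physical
    min/max are taken from the data (as the truncated header strings, so
    the scaling is exactly what a reader will reconstruct).
    """
    fs = rec.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n_ch = rec.n_channels
    n_records = int(np.ceil(rec.n_samples / fs))
    padded = np.zeros((n_ch, n_records * fs))
    padded[:, : rec.n_samples] = rec.samples

    # physical range per channel, reparsed from the 8-char header strings
    # so writer and reader agree exactly
    phys_min_s, phys_max_s = [], []
    phys_min, phys_max = [], []
    for ch in range(n_ch):
        lo, hi = float(padded[ch].min()), float(padded[ch].max())
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        lo_s, hi_s = f"{lo:.6g}"[:8], f"{hi:.6g}"[:8]
        phys_min_s.append(lo_s)
        phys_max_s.append(hi_s)
        phys_min.append(float(lo_s))
        phys_max.append(float(hi_s))

    dig_min, dig_max = -32768, 32767
    header = b"".join(
        [
            _ascii_field("0", 8),  # version
            _ascii_field("X X X X", 80),  # patient
            _ascii_field("Startdate 01-JAN-2020 X X X", 80),  # recording
            _ascii_field("01.01.20", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),  # record duration, s
            _ascii_field(n_ch, 4),
        ]
    )
    sig = b"".join(_ascii_field(name, 16) for name in rec.channel_names)
    sig += b"".join(_ascii_field("AgAgCl electrode", 80) for _ in range(n_ch))
    sig += b"".join(_ascii_field("uV", 8) for _ in range(n_ch))
    sig += b"".join(_ascii_field(s, 8) for s in phys_min_s)
    sig += b"".join(_ascii_field(s, 8) for s in phys_max_s)
    sig += b"".join(_ascii_field(dig_min, 8) for _ in range(n_ch))
    sig += b"".join(_ascii_field(dig_max, 8) for _ in range(n_ch))
    sig += b"".join(_ascii_field("", 80) for _ in range(n_ch))
    sig += b"".join(_ascii_field(fs, 8) for _ in range(n_ch))
    sig += b"".join(_ascii_field("", 32) for _ in range(n_ch))

    gain = np.array(
        [(phys_max[c] - phys_min[c]) / (dig_max - dig_min) for c in range(n_ch)]
    )
    offset = np.array(phys_min) - gain * dig_min
    digital = np.clip(
        np.round((padded - offset[:, None]) / gain[:, None]), dig_min, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_records):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())

    if event_path is not None:
        write_events(rec.events, event_path)


def write_events(events: pd.DataFrame, path) -> None:
    """Event table as TSV: onset_sample, code, is_target, block."""
    out = events.rename(columns={"onset": "onset_sample"})
    out = out[["onset_sample", "code", "is_target", "block"]].copy()
    out["is_target"] = out["is_target"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read and validate a TSV event table; errors name the offending line."""
    df = pd.read_csv(path, sep="\t")
    for col in EVENT_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if "block" not in df.columns:
        df["block"] = 0
    onsets = df["onset_sample"].to_numpy()
    bad = np.flatnonzero(np.diff(onsets) <= 0)
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: onsets must be strictly increasing "
            f"(violated at line {int(bad[0]) + 3})"
        )
    if (df["code"] < 1).any():
        line = int(np.flatnonzero(df["code"] < 1)[0]) + 2
        raise ValueError(f"{path}: stimulus code < 1 at line {line}")
    return pd.DataFrame(
        {
            "onset": df["onset_sample"].astype(int),
            "code": df["code"].astype(int),
            "is_target": df["is_target"].astype(bool),
            "block": df["block"].astype(int),
        }
    )


def read_edf(path, event_path) -> ContinuousRecording:
    """Load an EDF recording and its event TSV as a validated recording."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    samples = raw.get_data() * 1e6  # mne returns Volts for uV channels
    events = read_events(event_path)
    last = events["onset"].max() if len(events) else 0
    if last >= samples.shape[1]:
        raise ValueError(
            f"event onset {last} beyond recording length {samples.shape[1]}"
        )
    return ContinuousRecording(
        samples=samples,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
    )


def save_epochs(es: EpochSet, path) -> None:
    """Epoch archive: arrays in ``.npz``, schema in a JSON sidecar."""
    path = Path(path)
    np.savez(
        path,
        epochs=es.epochs,
        labels=es.labels,
        codes=es.codes,
        blocks=es.blocks,
    )
    schema = {
        "fs": es.fs,
        "channel_names": list(es.channel_names),
        "window_ms": list(es.window_ms),
        "n_trials": len(es),
    }
    path.with_suffix(".json").write_text(json.dumps(schema, indent=2))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        arrays = {k: data[k] for k in ("epochs", "labels", "codes", "blocks")}
    schema = json.loads(path.with_suffix(".json").read_text())
    return EpochSet(
        fs=schema["fs"],
        channel_names=schema["channel_names"],
        window_ms=tuple(schema["window_ms"]),
        **arrays,
    )


@dataclass
class RunConfig:
    """One evaluation run: input source, paradigm, model, protocol, seed.

    Exactly one of ``preset`` or (``edf_path`` + ``event_path``) or
    ``epochs_path`` selects the input source.
    """

    preset: str | None = None
    edf_path: str | None = None
    event_path: str | None = None
    epochs_path: str | None = None
    K: int | None = None
    seed: int = 0
    n_folds: int = 5
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    p300_amplitude: float = 5.0
    noise_sigma: float = 10.0
    pink_noise_scale: float = 10.0
    reps_per_command: int | None = None
    n_blocks: int | None = None
    out_dir: str = "results"

    def __post_init__(self):
        sources = [
            self.preset is not None,
            self.edf_path is not None,
            self.epochs_path is not None,
        ]
        if sum(sources) != 1:
            raise ValueError(
                "exactly one input source required: preset, edf_path, or epochs_path"
            )
        if self.edf_path is not None and self.event_path is None:
            raise ValueError("edf_path requires event_path")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        if "k_range" in raw:
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_results(
    table: AccuracyTable,
    ga: GrandAverage | None,
    outdir,
    config: RunConfig | dict | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the accuracy table, grand-average waveforms, and run metadata.

    ``accuracy.tsv``: classifier, k, mean, sd, p (rank-sum MDM vs SWLDA).
    ``grand_average.tsv``: long-format per-channel/class waveforms with SE.
    ``run_metadata.json``: config, seed, config hash, package versions.
    Content is deterministic for a fixed config + seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    acc = table.table.copy()
    acc["p_ranksum"] = [table.p_values.get(k, np.nan) for k in acc["k"]]
    acc_path = outdir / "accuracy.tsv"
    acc.to_csv(acc_path, sep="\t", index=False, float_format="%.6g")
    written["accuracy"] = acc_path

    if ga is not None:
        t_ms = np.arange(ga.target_mean.shape[1]) / ga.fs * 1000.0
        frames = []
        for cls, mean, se in (
            ("target", ga.target_mean, ga.target_se),
            ("nontarget", ga.nontarget_mean, ga.nontarget_se),
        ):
            for ci, name in enumerate(ga.channel_names):
                frames.append(
                    pd.DataFrame(
                        {
                            "class": cls,
                            "channel": name,
                            "time_ms": t_ms,
                            "mean_uV": mean[ci],
                            "se_uV": se[ci],
                        }
                    )
                )
        ga_path = outdir / "grand_average.tsv"
        pd.concat(frames, ignore_index=True).to_csv(
            ga_path, sep="\t", index=False, float_format="%.6g"
        )
        written["grand_average"] = ga_path

    import riemerp

    cfg_dict = (
        asdict(config) if isinstance(config, RunConfig) else (config or {})
    )
    meta = {
        "seed": seed if seed is not None else cfg_dict.get("seed"),
        "config": cfg_dict,
        "config_hash": (
            config.digest()
            if isinstance(config, RunConfig)
            else hashlib.sha256(
                json.dumps(cfg_dict, sort_keys=True, default=str).encode()
            ).hexdigest()[:16]
        ),
        "chance_percent": table.chance_percent,
        "protocol": table.metadata,
        "versions": {
            "riemerp": riemerp.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    written["metadata"] = meta_path
    return written
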