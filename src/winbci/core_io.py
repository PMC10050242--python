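"""Domain types and file plumbing for the window-size BCI study.

The on-disk format emulates a wireless-headset export: one CSV per
recording (one column per channel, one row per sample, values in
microvolts) plus a JSON sidecar holding the sampling rate, subject id and
the eyes-open / rest / eyes-closed protocol annotations.

Conventions used throughout the package: time is seconds from recording
start, sample index ``i`` maps to time ``i / fs`` (0-based).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "STATES",
    "STANDARD_REQUIRED_CHANNELS",
    "EEG_CHANNELS_14",
    "EEGRecording",
    "ProtocolSpec",
    "RunConfig",
    "read_recording",
    "write_recording",
    "load_config",
    "save_config",
]

#: Valid annotation states. Classification uses EO vs EC only.
STATES = ("EO", "EC", "REST")

#: Channels the analysis pipeline cannot run without (blink reference +
#: lateral frontal + occipital).
STANDARD_REQUIRED_CHANNELS = ("AF3", "AF4", "F7", "F8", "O1", "O2")

#: The 14-channel 10-20 montage of the emulated wireless headset.
EEG_CHANNELS_14 = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


@dataclass
class EEGRecording:
    """Multichannel EEG recording with state annotations.

    samples
        ``(n_channels, n_samples)`` float array, microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered 10-20 electrode labels, one per row of ``samples``.
    annotations
        ``(start_s, end_s, state)`` triples; non-overlapping, inside the
        recording, ``state`` in :data:`STATES`.
    """

    samples: np.ndarray
    fs: float
    channels: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channels = list(self.channels)
        self.annotations = [(float(a), float(b), str(s)) for a, b, s in self.annotations]
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time matrix")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.samples.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        dur = self.duration
        prev_end = None
        for start, end, state in sorted(self.annotations):
            if state not in STATES:
                raise ValueError(f"unknown state {state!r}")
            if not (0.0 <= start < end <= dur + 1e-9):
                raise ValueError(
                    f"annotation ({start}, {end}) outside recording [0, {dur:.3f}]"
                )
            if prev_end is not None and start < prev_end - 1e-9:
                raise ValueError("annotations overlap")
            prev_end = end

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        """Return one channel's signal by 10-20 label."""
        try:
            return self.samples[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def state_labels(self) -> np.ndarray:
        """Per-sample state array ('EO'/'EC'/'REST'); unannotated gaps are REST."""
        labels = np.full(self.n_samples, "REST", dtype="<U6")
        for start, end, state in self.annotations:
            i0 = int(np.ceil(start * self.fs - 1e-9))
            i1 = int(np.floor(end * self.fs - 1e-9)) + 1
            labels[i0:min(i1, self.n_samples)] = state
        return labels

    def copy(self) -> "EEGRecording":
        return EEGRecording(
            self.samples.copy(), self.fs, list(self.channels),
            list(self.annotations), self.subject_id,
        )


@dataclass
class ProtocolSpec:
    """Trial structure: eyes-open fixation, rest (black screen), eyes closed."""

    eo_duration_s: float = 20.0
    rest_duration_s: float = 10.0
    ec_duration_s: float = 20.0
    n_trials: int = 10

    def __post_init__(self) -> None:
        for name in ("eo_duration_s", "rest_duration_s", "ec_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    @property
    def trial_duration_s(self) -> float:
        return self.eo_duration_s + self.rest_duration_s + self.ec_duration_s

    def annotations(self) -> list[tuple[float, float, str]]:
        """EO/REST/EC intervals for ``n_trials`` back-to-back trials."""
        out: list[tuple[float, float, str]] = []
        t = 0.0
        for _ in range(self.n_trials):
            out.append((t, t + self.eo_duration_s, "EO"))
            t += self.eo_duration_s
            out.append((t, t + self.rest_duration_s, "REST"))
            t += self.rest_duration_s
            out.append((t, t + self.ec_duration_s, "EC"))
            t += self.ec_duration_s
        return out


@dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with study defaults.

    Filtering / blink removal
        ``blink_band`` (Hz) and ``blink_order`` define the regression
        component; ``blink_k`` thresholds the detection signal at
        ``k * median``; ``blink_ma_s`` is the moving-average length;
        ``blink_pad_s`` pads detected intervals; ``weight_scope`` selects
        the samples over which per-channel blink weights are estimated.
    Artifact rejection
        ``reject_pad_s`` dilates rejected regions around threshold
        crossings of the combined standardized signal.
    Wavelet power
        ``cycles`` Morlet cycles, ``freq_lo/hi/step`` the alpha grid,
        ``power_decim`` the decimation factor of the power series.
    Datasets / training
        ``windows_s`` window lengths, ``hop`` in decimated samples,
        ``split_fraction`` train share, ``repetitions`` J random splits,
        LSTM hyperparameters, and caps on the number of training /
        validation items drawn per class (keeps repeated studies tractable;
        windows overlap heavily so the caps discard little information).
    """

    # blink denoising
    blink_band: tuple[float, float] = (1.0, 7.0)
    blink_order: int = 5
    blink_k: float = 5.0
    blink_ma_s: float = 0.125
    blink_pad_s: float = 0.1
    weight_scope: str = "blinks"        # "blinks" | "all"
    # band-pass
    band: tuple[float, float] = (5.0, 40.0)
    band_order: int = 5
    # rejection
    reject_pad_s: float = 0.1
    # wavelet power
    cycles: float = 7.0
    freq_lo: float = 8.0
    freq_hi: float = 12.0
    freq_step: float = 0.5
    power_decim: int = 8
    # datasets
    windows_s: tuple[float, ...] = tuple(float(w) for w in range(1, 11))
    hop: int = 1
    split_fraction: float = 0.75
    repetitions: int = 20
    max_train_per_class: int = 120
    max_val_per_class: int = 200
    max_points_per_class: int = 1000
    seed: int = 0
    # classifier roster (Table-style option names)
    classifiers: tuple[str, ...] = (
        "DTL:fine", "DTL:medium", "DTL:coarse",
        "DA:linear", "DA:quadratic",
        "SVM:linear", "SVM:quadratic", "SVM:cubic",
        "SVM:fine_gaussian", "SVM:medium_gaussian", "SVM:coarse_gaussian",
        "KNN:fine", "KNN:medium", "KNN:coarse",
        "KNN:cubic", "KNN:weighted", "KNN:cosine",
    )
    # LSTM
    lstm_layers: int = 1
    lstm_cells: int = 8
    lstm_epochs: int = 60
    lstm_lr: float = 0.012
    lstm_batch: int = 64

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError(
                f"split_fraction must be in (0, 1), got {self.split_fraction}"
            )
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(w <= 0 for w in self.windows_s):
            raise ValueError("window lengths must be positive")
        if self.hop < 1:
            raise ValueError("hop must be >= 1")
        if self.weight_scope not in ("blinks", "all"):
            raise ValueError("weight_scope must be 'blinks' or 'all'")
        if self.power_decim < 1:
            raise ValueError("power_decim must be >= 1")
        self.blink_band = tuple(float(v) for v in self.blink_band)  # type: ignore[assignment]
        self.band = tuple(float(v) for v in self.band)  # type: ignore[assignment]
        self.windows_s = tuple(float(v) for v in self.windows_s)  # type: ignore[assignment]
        self.classifiers = tuple(self.classifiers)  # type: ignore[assignment]

    @property
    def freqs(self) -> np.ndarray:
        """Alpha-band frequency grid for the wavelet transform."""
        n = int(round((self.freq_hi - self.freq_lo) / self.freq_step)) + 1
        return self.freq_lo + self.freq_step * np.arange(n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("blink_band", "band", "windows_s", "classifiers"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("blink_band", "band", "windows_s", "classifiers"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def read_recording(
    path: str | Path,
    fs_hint: float | None = None,
    required_channels: Sequence[str] | None = None,
) -> EEGRecording:
    """Read a recording from a headset-style CSV (+ optional JSON sidecar).

    The CSV header names the channels; the sidecar (same stem, ``.json``)
    supplies ``fs``, ``subject_id`` and annotations. Without a sidecar,
    ``fs_hint`` is required and annotations are empty. If
    ``required_channels`` is given, their absence is a hard error naming
    the missing labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    channels = [str(c) for c in df.columns]
    if required_channels:
        missing = [c for c in required_channels if c not in channels]
        if missing:
            raise ValueError(f"recording {path} is missing required channels: {missing}")
    cols = []
    for c in channels:
        try:
            # numpy's parser round-trips float64 exactly
            col = df[c].to_numpy(dtype=np.float64)
        except (ValueError, TypeError):
            coerced = pd.to_numeric(df[c], errors="coerce")
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(
                f"non-numeric value {df[c].iloc[row]!r} in column {c!r} "
                f"at data row {row}"
            ) from None
        if np.isnan(col).any():
            row = int(np.flatnonzero(np.isnan(col))[0])
            raise ValueError(f"missing value in column {c!r} at data row {row}")
        cols.append(col)
    samples = np.vstack(cols) if cols else np.empty((0, 0))

    sidecar = _sidecar_path(path)
    fs = fs_hint
    annotations: list[tuple[float, float, str]] = []
    subject_id = path.stem
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = float(meta.get("fs", fs_hint or 0.0))
        subject_id = meta.get("subject_id", subject_id)
        annotations = [(float(a), float(b), str(s)) for a, b, s in meta.get("annotations", [])]
    if fs is None:
        raise ValueError(f"no sidecar {sidecar} and no fs_hint given")
    return EEGRecording(samples, float(fs), channels, annotations, subject_id)


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write CSV (one column per channel) + JSON sidecar with annotations."""
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channels)
    # float_format chosen so the round trip is bit-identical for float64
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {
        "fs": rec.fs,
        "subject_id": rec.subject_id,
        "annotations": [[a, b, s] for a, b, s in rec.annotations],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML/JSON run configuration; absent keys take defaults,
    unknown keys are rejected."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
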