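"""Time-frequency power via complex Morlet wavelets; alpha series at O1/O2.

The transform convolves the signal with complex Morlet wavelets
(Gaussian-windowed complex exponentials, ``cycles`` cycles inside the
Gaussian). Normalization is chosen so that a pure sinusoid of amplitude
``A`` at a grid frequency yields power ``~A**2`` away from the edges.
Samples closer to an edge than half the wavelet support are flagged and
treated as masked downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .core_io import EEGRecording, RunConfig
from .preprocess import RejectionMask

__all__ = ["PowerSeries", "morlet_power", "alpha_power_series"]


@dataclass
class PowerSeries:
    """Alpha-band power at O1/O2, time-aligned with per-sample state labels.

    ``labels`` take values EO / EC / REST / MASKED; MASKED marks samples
    rejected by preprocessing or inside wavelet edge regions.
    """

    times: np.ndarray
    p_o1: np.ndarray          # microvolts squared
    p_o2: np.ndarray
    labels: np.ndarray        # '<U6'
    fs_power: float

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.p_o1) == len(self.p_o2) == len(self.labels) == n):
            raise ValueError("PowerSeries fields must have equal length")
        if (self.p_o1 < 0).any() or (self.p_o2 < 0).any():
            raise ValueError("power must be non-negative")


def _morlet(fs: float, freq: float, cycles: float) -> np.ndarray:
    sd_t = cycles / (2.0 * np.pi * freq)
    half = int(np.ceil(4.0 * sd_t * fs))
    t = np.arange(-half, half + 1) / fs
    gauss = np.exp(-0.5 * (t / sd_t) ** 2)
    wavelet = gauss * np.exp(2j * np.pi * freq * t)
    # scale so |conv| ~ amplitude of a tone at `freq`
    return wavelet * (2.0 / gauss.sum())


def morlet_power(
    x: np.ndarray, fs: float, freqs: np.ndarray, cycles: float = 7.0
) -> tuple[np.ndarray, np.ndarray]:
    """Squared magnitude of the complex Morlet transform.

    Returns ``(power, edge)`` where ``power`` is ``(n_freqs, n_times)``
    and ``edge`` is a boolean time mask flagging samples within half a
    wavelet support of either end (computed at the lowest frequency,
    whose wavelet is the longest).
    """
    x = np.asarray(x, float)
    freqs = np.atleast_1d(np.asarray(freqs, float))
    if cycles < 3:
        raise ValueError("need at least 3 cycles for a well-formed wavelet")
    if (freqs <= 0).any() or (freqs >= fs / 2).any():
        raise ValueError(f"frequencies must lie in (0, {fs / 2}) Hz")
    power = np.empty((len(freqs), len(x)))
    max_half = 0
    for i, f in enumerate(freqs):
        w = _morlet(fs, f, cycles)
        half = (len(w) - 1) // 2
        max_half = max(max_half, half)
        coef = fftconvolve(x, w, mode="same")
        power[i] = np.abs(coef) ** 2
    edge = np.zeros(len(x), dtype=bool)
    edge[:max_half] = True
    if max_half > 0:
        edge[-max_half:] = True
    return power, edge


def _block_reduce(x: np.ndarray, d: int, how: str) -> np.ndarray:
    """Reduce ``x`` over non-overlapping blocks of ``d`` samples; the last
    partial block is kept, so output length is ceil(len(x)/d)."""
    n = len(x)
    n_full = n // d
    out_len = int(np.ceil(n / d))
    out = np.empty(out_len, dtype=x.dtype if how != "mean" else float)
    if n_full:
        blocks = x[: n_full * d].reshape(n_full, d)
        out[:n_full] = blocks.mean(axis=1) if how == "mean" else blocks[:, 0]
    if out_len > n_full:
        tail = x[n_full * d:]
        out[n_full] = tail.mean() if how == "mean" else tail[0]
    return out


def alpha_power_series(
    rec: EEGRecording,
    mask: RejectionMask | np.ndarray | None = None,
    cfg: RunConfig | None = None,
) -> PowerSeries:
    """Alpha-band (default 8-12 Hz) Morlet power at O1 and O2.

    Per channel, the mean over the frequency grid of the wavelet power,
    block-averaged by ``cfg.power_decim``. Labels come from the
    recording's annotations; decimated samples touching rejected or
    edge-flagged raw samples are MASKED.
    """
    cfg = cfg or RunConfig()
    for need in ("O1", "O2"):
        if need not in rec.channels:
            raise ValueError(f"alpha power needs channel {need}")
    freqs = cfg.freqs
    p1, edge = morlet_power(rec.channel("O1"), rec.fs, freqs, cfg.cycles)
    p2, _ = morlet_power(rec.channel("O2"), rec.fs, freqs, cfg.cycles)
    a1 = p1.mean(axis=0)
    a2 = p2.mean(axis=0)

    bad = edge.copy()
    if mask is not None:
        kept = mask.kept if isinstance(mask, RejectionMask) else np.asarray(mask, bool)
        bad |= ~kept
    labels = rec.state_labels()

    d = cfg.power_decim
    out_a1 = _block_reduce(a1, d, "mean")
    out_a2 = _block_reduce(a2, d, "mean")
    # a decimated sample is MASKED if any raw sample in its block is bad
    bad_dec = _block_reduce(bad.astype(float), d, "mean") > 0
    lab_dec = _block_reduce(labels, d, "first")
    lab_dec = np.where(bad_dec, "MASKED", lab_dec).astype("<U6")
    times = _block_reduce(rec.times, d, "first")
    return PowerSeries(times=times, p_o1=out_a1, p_o2=out_a2,
                       labels=lab_dec, fs_power=rec.fs / d)
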