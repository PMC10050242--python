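"""Pre-processing: blink denoising, band-pass filtering, artifact rejection.

Three steps, applied in this order:

1. **Blink denoising** (regression-based, REBLINCA-style). A reference
   AFZ = mean(AF3, AF4) is band-passed 1-7 Hz (5th-order Butterworth) to
   form the regression component. Its derivative, standardized, squared
   and moving-averaged, is the detection signal; maximal runs above
   ``k * median`` locate blinks. Inside each blink interval every channel
   is corrected as ``x_ch(t) - w_ch * regr_afz(t)`` with
   ``w_ch = mean(|x_ch|) / mean(|AFZ|)``.
2. **Band-pass** 5-40 Hz Butterworth on every channel.
3. **Automatic rejection**: each channel standardized with population
   (1/N) statistics, combined as ``z_sum = sum_ch(z_ch) / sqrt(c)``, and
   samples where ``z_sum`` exceeds ``mu_sum + 3 sigma_sum`` are masked
   (with padding), not deleted.

Filters are zero-phase (forward-backward) in this offline path.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.ndimage import binary_dilation, uniform_filter1d
from scipy.signal import butter, sosfiltfilt

from .core_io import EEGRecording, RunConfig

__all__ = [
    "BlinkCorrection",
    "RejectionMask",
    "regression_component",
    "blink_threshold_signal",
    "detect_blinks",
    "channel_weight",
    "remove_blinks",
    "bandpass_5_40",
    "standardize_channel",
    "z_sum",
    "rejection_mask",
    "preprocess_recording",
]


@dataclass
class BlinkCorrection:
    """Diagnostics of the blink-removal step."""

    afz: np.ndarray                    # reference signal, microvolts
    regr_afz: np.ndarray               # 1-7 Hz regression component, microvolts
    thres_afz: np.ndarray              # detection signal, unitless
    blink_intervals: list[tuple[float, float]]
    weights: dict                      # channel label -> w_ch


@dataclass
class RejectionMask:
    """Outcome of the z-sum threshold rejection."""

    z_sum: np.ndarray
    mu_sum: float
    sigma_sum: float
    th_rej: float
    kept: np.ndarray                   # bool per sample

    @property
    def kept_fraction(self) -> float:
        return float(self.kept.mean()) if self.kept.size else 1.0


def _bandpass_sos(lo: float, hi: float, fs: float, order: int):
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def regression_component(
    x: np.ndarray, fs: float, band: tuple[float, float] = (1.0, 7.0), order: int = 5
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 1-7 Hz, order 5) of ``x``."""
    if fs <= 2 * band[1]:
        raise ValueError(f"fs={fs} Hz cannot support the {band} Hz band")
    return sosfiltfilt(_bandpass_sos(band[0], band[1], fs, order), np.asarray(x, float))


def blink_threshold_signal(
    regr: np.ndarray, fs: float, ma_s: float = 0.125
) -> np.ndarray:
    """Detection signal: derivative of the regression component (so both the
    rising and falling flanks of a blink light up), standardized, squared,
    then moving-averaged over ``ma_s`` seconds."""
    regr = np.asarray(regr, float)
    d = np.gradient(regr) * fs
    sd = d.std()
    if sd == 0:
        raise ValueError("constant regression component: no blink signal")
    z = (d - d.mean()) / sd
    win = max(int(round(ma_s * fs)), 1)
    return uniform_filter1d(z * z, size=win, mode="nearest")


def detect_blinks(
    thres: np.ndarray, fs: float, k: float = 5.0, pad_s: float = 0.1
) -> list[tuple[float, float]]:
    """Maximal runs where ``thres > k * median(thres)``, padded by ``pad_s``
    on both sides and merged when overlapping. Returns (start_s, end_s)."""
    thres = np.asarray(thres, float)
    if thres.size == 0:
        return []
    level = k * float(np.median(thres))
    above = thres > level
    if not above.any():
        return []
    # run boundaries from the diff of the boolean mask
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = ([0] if above[0] else []) + list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1) + ([thres.size] if above[-1] else [])
    merged: list[tuple[float, float]] = []
    for i0, i1 in zip(starts, ends):
        s = max(i0 / fs - pad_s, 0.0)
        e = min(i1 / fs + pad_s, thres.size / fs)
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def channel_weight(x_ch: np.ndarray, afz: np.ndarray) -> float:
    """Proportion of the AFZ reference present in a channel:
    ``mean(|x_ch|) / mean(|AFZ|)``."""
    x_ch = np.asarray(x_ch, float)
    afz = np.asarray(afz, float)
    if x_ch.shape != afz.shape:
        raise ValueError("channel and reference must have equal length")
    denom = np.abs(afz).mean()
    if denom == 0:
        raise ValueError("AFZ reference is identically zero")
    return float(np.abs(x_ch).mean() / denom)


def _interval_indices(
    intervals: list[tuple[float, float]], fs: float, n: int
) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for s, e in intervals:
        mask[int(np.floor(s * fs)):min(int(np.ceil(e * fs)), n)] = True
    return mask


def remove_blinks(
    rec: EEGRecording, cfg: RunConfig | None = None
) -> tuple[EEGRecording, BlinkCorrection]:
    """Regression-based blink removal.

    Inside each detected blink interval every channel becomes
    ``x_ch(t) - w_ch * regr_afz(t)``; samples outside the intervals are
    untouched. ``w_ch`` is estimated over the detected blink intervals
    (``cfg.weight_scope == 'blinks'``, the default) or the whole
    recording (``'all'``).
    """
    cfg = cfg or RunConfig()
    for need in ("AF3", "AF4"):
        if need not in rec.channels:
            raise ValueError(f"blink removal needs channel {need}")
    afz = 0.5 * (rec.channel("AF3") + rec.channel("AF4"))
    regr = regression_component(afz, rec.fs, cfg.blink_band, cfg.blink_order)
    thres = blink_threshold_signal(regr, rec.fs, cfg.blink_ma_s)
    intervals = detect_blinks(thres, rec.fs, cfg.blink_k, cfg.blink_pad_s)

    out = rec.copy()
    in_blink = _interval_indices(intervals, rec.fs, rec.n_samples)
    weights: dict[str, float] = {}
    if intervals:
        scope = in_blink if cfg.weight_scope == "blinks" else np.ones_like(in_blink)
        for i, ch in enumerate(rec.channels):
            w = channel_weight(rec.samples[i][scope], afz[scope])
            weights[ch] = w
            out.samples[i][in_blink] -= w * regr[in_blink]
    corr = BlinkCorrection(afz=afz, regr_afz=regr, thres_afz=thres,
                           blink_intervals=intervals, weights=weights)
    return out, corr


def bandpass_5_40(rec: EEGRecording, cfg: RunConfig | None = None) -> EEGRecording:
    """Zero-phase Butterworth band-pass (default 5-40 Hz, order 5) on every
    channel."""
    cfg = cfg or RunConfig()
    lo, hi = cfg.band
    if rec.fs <= 10:
        raise ValueError(f"fs={rec.fs} Hz is too low for the {cfg.band} Hz band")
    if rec.fs <= 2 * hi:
        warnings.warn(
            f"fs={rec.fs} Hz puts the {hi} Hz band edge at or above Nyquist/1",
            stacklevel=2,
        )
        hi = min(hi, rec.fs / 2 * 0.95)
    out = rec.copy()
    sos = _bandpass_sos(lo, hi, rec.fs, cfg.band_order)
    out.samples = sosfiltfilt(sos, out.samples, axis=1)
    return out


def standardize_channel(x: np.ndarray, name: str = "channel") -> np.ndarray:
    """Zero-mean, unit-variance standardization with population (1/N)
    normalization."""
    x = np.asarray(x, float)
    sd = x.std()                     # numpy default ddof=0 = population
    if sd == 0:
        raise ValueError(f"{name} is constant; cannot standardize")
    return (x - x.mean()) / sd


def z_sum(z_channels: np.ndarray) -> np.ndarray:
    """Combined standardized signal: per-sample sum over the ``c`` channels
    divided by ``sqrt(c)`` (as printed; the prose calls it an average)."""
    z = np.atleast_2d(np.asarray(z_channels, float))
    c = z.shape[0]
    if c < 1:
        raise ValueError("need at least one channel")
    return z.sum(axis=0) / np.sqrt(c)


def rejection_mask(
    zs: np.ndarray, fs: float = 1.0, pad_s: float = 0.0
) -> RejectionMask:
    """Threshold rejection: samples with ``z_sum > mu_sum + 3 sigma_sum``
    (population sigma) are rejected, then dilated by ``pad_s`` per side."""
    zs = np.asarray(zs, float)
    mu = float(zs.mean())
    sigma = float(zs.std())
    if sigma == 0:
        raise ValueError("constant z_sum; cannot build a rejection threshold")
    th = mu + 3.0 * sigma
    rejected = zs > th
    pad = int(round(pad_s * fs))
    if pad > 0 and rejected.any():
        rejected = binary_dilation(rejected, iterations=pad)
    return RejectionMask(z_sum=zs, mu_sum=mu, sigma_sum=sigma, th_rej=th,
                         kept=~rejected)


def preprocess_recording(
    rec: EEGRecording, cfg: RunConfig | None = None
) -> tuple[EEGRecording, RejectionMask, BlinkCorrection]:
    """Full pre-processing chain: blink removal, then 5-40 Hz band-pass,
    then z-sum rejection. Returns the band-passed recording, the sample
    mask and the blink diagnostics."""
    cfg = cfg or RunConfig()
    deblinked, corr = remove_blinks(rec, cfg)
    filtered = bandpass_5_40(deblinked, cfg)
    z = np.vstack([
        standardize_channel(filtered.samples[i], filtered.channels[i])
        for i in range(len(filtered.channels))
    ])
    mask = rejection_mask(z_sum(z), rec.fs, cfg.reject_pad_s)
    return filtered, mask, corr
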