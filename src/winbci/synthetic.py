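"""Protocol-shaped synthetic EEG with ground truth.

Emulates a 14-channel, 128 Hz wireless-headset recording of the
eyes-open (EO) / rest / eyes-closed (EC) protocol, with the statistical
structure the downstream analysis assumes:

* an 8-12 Hz alpha rhythm at O1/O2 whose *envelope* is a positive,
  slowly varying stochastic process. Its log-amplitude is the sum of a
  state-dependent level (EC median well above EO), a fast
  Ornstein-Uhlenbeck component (sub-second timescale, clipped at 2 sd),
  a quasi-periodic infra-slow waxing/waning (period ~4-5 s, fresh phase
  each protocol segment) and a per-trial random effect. Short windows
  therefore see heavily overlapping EO/EC power distributions; windows
  of several seconds average the fast and infra-slow components away,
  and the per-trial effect sets the floor that no within-trial
  averaging removes. This is the mechanism behind the
  accuracy-vs-window-length effect and its plateau near the infra-slow
  period.
* eye-blink transients (smooth biphasic difference-of-Gaussians pulse,
  ~400 ms, spectrum concentrated below ~5 Hz) mixed into the frontal
  channels with known weights, only while the eyes are open;
* broadband background (pink + white) noise on every channel;
* occasional high-amplitude broadband artifact bursts;
* per-subject variability (alpha frequency, amplitude levels, envelope
  timescale) across the default 13-subject cohort.

Everything injected is reported in :class:`GroundTruth`, which serves as
the oracle for the preprocessing tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core_io import EEG_CHANNELS_14, EEGRecording, ProtocolSpec

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_subject",
    "generate_cohort",
    "generate_stream",
    "blink_pulse",
]

#: Relative blink coupling of the frontal channels (AFZ reference ~ 1).
DEFAULT_BLINK_WEIGHTS = {
    "AF3": 1.0, "AF4": 0.95, "F7": 0.5, "F8": 0.5, "F3": 0.3, "F4": 0.3,
}


@dataclass
class SynthConfig:
    """Generator parameters; the defaults define the study cohort.

    Alpha envelope: median amplitude ``alpha_eo_uv`` in EO/REST and
    ``alpha_eo_uv * ec_eo_ratio`` in EC; log-amplitude fluctuates with an
    OU component (sd ``env_sigma``, timescale ``env_tau_s``, clipped at
    ``env_clip_sigma`` sd), an infra-slow quasi-periodic modulation
    (sd ``slow_mod_sigma``, period ``slow_mod_period_s``) and a
    per-trial-segment effect (sd ``trial_sigma``). Subject-level jitter
    scales the EO level, the EC/EO ratio, the OU timescale and the
    infra-slow period.
    """

    n_subjects: int = 13
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    fs: float = 128.0
    # alpha rhythm at O1/O2
    alpha_eo_uv: float = 7.0
    ec_eo_ratio: float = 2.0
    env_sigma: float = 0.35
    env_tau_s: float = 0.4
    env_clip_sigma: float = 2.0
    slow_mod_sigma: float = 0.40
    slow_mod_period_s: float = 4.5
    trial_sigma: float = 0.28
    channel_gain_sigma: float = 0.05
    channel_env_sigma: float = 0.15
    # subject-level jitter (log scale)
    subject_level_sigma: float = 0.25
    subject_ratio_sigma: float = 0.30
    subject_tau_sigma: float = 0.30
    # blinks
    blink_rate_per_min: float = 10.0
    blink_amp_uv: float = 150.0
    blink_duration_ms: float = 400.0
    blink_weights: dict = field(default_factory=lambda: dict(DEFAULT_BLINK_WEIGHTS))
    # background noise
    pink_uv: float = 8.0
    white_uv: float = 4.0
    # broadband artifact bursts
    burst_rate_per_min: float = 0.5
    burst_amp_uv: float = 80.0
    burst_duration_s: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ec_eo_ratio <= 1.0:
            raise ValueError("EC alpha amplitude mean must exceed the EO mean")
        for name in ("blink_rate_per_min", "burst_rate_per_min", "pink_uv",
                     "white_uv", "alpha_eo_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass
class GroundTruth:
    """What was injected where; the oracle for preprocessing tests."""

    state_labels: np.ndarray                     # per raw sample, '<U6'
    blink_intervals: list[tuple[float, float]]
    artifact_intervals: list[tuple[float, float]]
    blink_weights: dict                          # channel -> true mixing weight
    alpha_envelope: np.ndarray                   # O1 envelope, microvolts


def blink_pulse(fs: float, duration_ms: float, amp_uv: float) -> np.ndarray:
    """Smooth biphasic eye-blink waveform (difference of Gaussians).

    Main positive lobe with a shallow negative rebound; the spectrum is
    concentrated below ~7 Hz so the 1-7 Hz regression component captures
    essentially all of it.
    """
    n = max(int(round(duration_ms / 1000.0 * fs)), 5)
    t = np.linspace(-1.0, 1.0, n)
    s1, s2 = 0.32, 0.60
    p = np.exp(-0.5 * (t / s1) ** 2) - 0.5 * np.exp(-0.5 * (t / s2) ** 2)
    # taper to exactly zero at the interval edges
    p *= np.hanning(n) ** 0.25
    return amp_uv * p / p.max()


def _ou(rng: np.random.Generator, n: int, tau_s: float, sigma: float, fs: float) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path, mean 0, sd ``sigma``."""
    dt = 1.0 / fs
    a = np.exp(-dt / tau_s)
    b = sigma * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = sigma * eps[0]
    for i in range(1, n):
        x[i] = a * x[i - 1] + b * eps[i]
    return x


def _ou_fast(rng: np.random.Generator, n: int, tau_s: float, sigma: float, fs: float) -> np.ndarray:
    """OU path via lfilter (identical law to :func:`_ou`, vectorized)."""
    from scipy.signal import lfilter

    dt = 1.0 / fs
    a = np.exp(-dt / tau_s)
    b = sigma * np.sqrt(1.0 - a * a)
    eps = rng.standard_normal(n)
    x0 = sigma * eps[0]
    driven = np.concatenate(([x0], b * eps[1:]))
    return lfilter([1.0], [1.0, -a], driven)


def _pink_noise(rng: np.random.Generator, n: int, rms: float) -> np.ndarray:
    """1/f-power noise with the requested RMS (flat below 0.5 Hz-ish)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)          # cycles/sample; shape only
    scale = 1.0 / np.sqrt(np.maximum(f, f[1] if n > 1 else 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


@dataclass
class _SubjectParams:
    alpha_freq: float
    a_eo: float
    a_ec: float
    env_tau_s: float
    env_sigma: float
    slow_period_s: float


def _draw_subject(cfg: SynthConfig, rng: np.random.Generator) -> _SubjectParams:
    a_eo = cfg.alpha_eo_uv * np.exp(rng.normal(0.0, cfg.subject_level_sigma))
    ratio = cfg.ec_eo_ratio * np.exp(rng.normal(0.0, cfg.subject_ratio_sigma))
    ratio = max(ratio, 1.05)
    return _SubjectParams(
        alpha_freq=rng.uniform(9.0, 11.0),
        a_eo=a_eo,
        a_ec=a_eo * ratio,
        env_tau_s=cfg.env_tau_s * np.exp(rng.normal(0.0, cfg.subject_tau_sigma)),
        env_sigma=cfg.env_sigma,
        slow_period_s=cfg.slow_mod_period_s * rng.uniform(0.9, 1.1),
    )


def _synthesize(
    cfg: SynthConfig,
    annotations: list[tuple[float, float, str]],
    sp: _SubjectParams,
    rng: np.random.Generator,
    subject_id: str,
) -> tuple[EEGRecording, GroundTruth]:
    fs = cfg.fs
    duration = max(end for _, end, _ in annotations)
    n = int(round(duration * fs))
    channels = list(EEG_CHANNELS_14)
    samples = np.zeros((len(channels), n))

    # --- background noise on every channel
    for ch in range(len(channels)):
        samples[ch] += _pink_noise(rng, n, cfg.pink_uv)
        samples[ch] += rng.normal(0.0, cfg.white_uv, n)

    # --- state timeline
    labels = np.full(n, "REST", dtype="<U6")
    for start, end, state in annotations:
        labels[int(round(start * fs)):int(round(end * fs))] = state

    # --- alpha envelope: state level + per-segment effect + fast OU
    with np.errstate(divide="ignore"):
        log_env = np.where(labels == "EC", np.log(sp.a_ec), np.log(sp.a_eo))
    seg_starts = [int(round(s * fs)) for s, _, _ in annotations]
    seg_ends = [int(round(e * fs)) for _, e, _ in annotations]
    for i0, i1 in zip(seg_starts, seg_ends):
        log_env[i0:i1] += rng.normal(0.0, cfg.trial_sigma)
    fast = _ou_fast(rng, n, sp.env_tau_s, sp.env_sigma, fs)
    clip = cfg.env_clip_sigma * sp.env_sigma
    log_env = log_env + np.clip(fast, -clip, clip)   # amplitude saturates
    # infra-slow waxing/waning of the alpha envelope: a quasi-periodic
    # modulation (~0.2 Hz) with a fresh phase in every protocol segment
    if cfg.slow_mod_sigma > 0:
        t_all = np.arange(n) / fs
        slow = np.empty(n)
        for i0, i1 in zip(seg_starts, seg_ends):
            phase = rng.uniform(0.0, 2 * np.pi)
            slow[i0:i1] = np.sin(
                2 * np.pi * t_all[i0:i1] / sp.slow_period_s + phase)
        log_env = log_env + np.sqrt(2.0) * cfg.slow_mod_sigma * slow

    t = np.arange(n) / fs
    envelope_o1 = np.exp(log_env + _ou_fast(rng, n, 0.3, cfg.channel_env_sigma, fs))
    envelope_o2 = np.exp(log_env + _ou_fast(rng, n, 0.3, cfg.channel_env_sigma, fs))
    gain_o1 = np.exp(rng.normal(0.0, cfg.channel_gain_sigma))
    gain_o2 = np.exp(rng.normal(0.0, cfg.channel_gain_sigma))
    phase = rng.uniform(0.0, 2 * np.pi)
    carrier = np.sin(2 * np.pi * sp.alpha_freq * t + phase)
    samples[channels.index("O1")] += gain_o1 * envelope_o1 * carrier
    samples[channels.index("O2")] += gain_o2 * envelope_o2 * carrier

    # --- blinks while the eyes are open (EO and REST)
    blink_intervals: list[tuple[float, float]] = []
    if cfg.blink_rate_per_min > 0:
        pulse = blink_pulse(fs, cfg.blink_duration_ms, 1.0)
        np_pulse = len(pulse)
        rate_hz = cfg.blink_rate_per_min / 60.0
        t_next = rng.exponential(1.0 / rate_hz)
        while t_next < duration - np_pulse / fs:
            i0 = int(round(t_next * fs))
            if "EC" not in (labels[i0], labels[min(i0 + np_pulse, n - 1)]):
                # whole pulse outside closed-eyes periods
                amp = cfg.blink_amp_uv * np.exp(rng.normal(0.0, 0.15))
                for ch_name, w in cfg.blink_weights.items():
                    idx = channels.index(ch_name)
                    samples[idx, i0:i0 + np_pulse] += w * amp * pulse
                pad = 0.05
                blink_intervals.append(
                    (max(t_next - pad, 0.0),
                     min(t_next + np_pulse / fs + pad, duration))
                )
            t_next += rng.exponential(1.0 / rate_hz)

    # --- broadband artifact bursts
    artifact_intervals: list[tuple[float, float]] = []
    if cfg.burst_rate_per_min > 0:
        rate_hz = cfg.burst_rate_per_min / 60.0
        nb = int(round(cfg.burst_duration_s * fs))
        win = np.hanning(nb)
        t_next = rng.exponential(1.0 / rate_hz)
        while t_next < duration - cfg.burst_duration_s:
            i0 = int(round(t_next * fs))
            burst = win * rng.normal(0.0, cfg.burst_amp_uv, nb)
            gains = rng.uniform(0.5, 1.5, len(channels))
            samples[:, i0:i0 + nb] += gains[:, None] * burst[None, :]
            artifact_intervals.append((t_next, t_next + cfg.burst_duration_s))
            t_next += rng.exponential(1.0 / rate_hz)

    rec = EEGRecording(samples, fs, channels, list(annotations), subject_id)
    gt = GroundTruth(
        state_labels=labels,
        blink_intervals=blink_intervals,
        artifact_intervals=artifact_intervals,
        blink_weights=dict(cfg.blink_weights),
        alpha_envelope=gain_o1 * envelope_o1,
    )
    return rec, gt


def generate_subject(
    cfg: SynthConfig, subject_index: int
) -> tuple[EEGRecording, GroundTruth]:
    """Generate one subject's protocol recording; deterministic under
    ``(cfg.seed, subject_index)``."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))
    sp = _draw_subject(cfg, rng)
    annotations = cfg.protocol.annotations()
    return _synthesize(cfg, annotations, sp, rng, f"S{subject_index:02d}")


def generate_cohort(cfg: SynthConfig) -> list[tuple[EEGRecording, GroundTruth]]:
    """All ``cfg.n_subjects`` subjects, each with its own parameter draws."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]


def generate_stream(
    cfg: SynthConfig,
    subject_index: int,
    ec_durations_s: tuple[float, ...] = (7.0, 15.0, 20.0),
    eo_duration_s: float = 10.0,
) -> tuple[EEGRecording, GroundTruth]:
    """A continuous test stream: EO segments with EC periods of the given
    lengths in between (the online-evaluation paradigm). Same subject
    parameters as :func:`generate_subject` for the same index, fresh noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, subject_index)))
    sp = _draw_subject(cfg, rng)                 # same draws as the protocol run
    stream_rng = np.random.default_rng(
        np.random.SeedSequence((cfg.seed, subject_index, 7741))
    )
    annotations: list[tuple[float, float, str]] = []
    t = 0.0
    for ec in ec_durations_s:
        annotations.append((t, t + eo_duration_s, "EO"))
        t += eo_duration_s
        annotations.append((t, t + ec, "EC"))
        t += ec
    annotations.append((t, t + eo_duration_s, "EO"))
    no_burst = replace(cfg, burst_rate_per_min=0.0)
    return _synthesize(no_burst, annotations, sp, stream_rng,
                       f"S{subject_index:02d}-stream")
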