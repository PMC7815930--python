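"""Seeded synthetic fNIRS generator.

Emulates the generative structure the decoding pipeline assumes: each video
trial drives active channels with a boxcar convolved with a canonical
(double-gamma) hemodynamic response, scaled to a class-dependent peak dHbO
amplitude; physiological noise is added as fixed-frequency sinusoids with
random phase (very-low-frequency oscillations at 0.03 Hz, respiration at
0.2 Hz, cardiac at 0.8 Hz), white noise and a linear drift.  dHbR mirrors the
activation with negative proportionality (neurovascular coupling).

All randomness flows from the single ``SimConfig.seed``; identical configs
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemodynamics import (ConfigError, DataError, DEFAULT_FS, ExtinctionMatrix,
                           GeometryConfig, HemoSeries, N_CHANNELS, OpticalRecording,
                           forward_mbll)
from .paradigm import Event, PREFERENCES

__all__ = [
    "HRFParams",
    "SimConfig",
    "canonical_hrf",
    "simulate_hemo",
    "simulate_optical",
    "simulate_session",
]


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameterization (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 32.0  # kernel support

    def __post_init__(self) -> None:
        if min(self.peak_delay_s, self.undershoot_delay_s,
               self.peak_dispersion_s, self.undershoot_dispersion_s) <= 0:
            raise ConfigError("HRF delays and dispersions must be positive")
        if self.peak_undershoot_ratio <= 0:
            raise ConfigError("peak/undershoot ratio must be positive")


def canonical_hrf(t: np.ndarray, params: HRFParams = HRFParams()) -> np.ndarray:
    """Unit-peak double-gamma HRF sampled on the grid ``t`` (seconds).

    Difference of two gamma densities (shape = delay/dispersion, scale =
    dispersion), the second down-weighted by the peak/undershoot ratio; zero
    for t <= 0 and rescaled so max = 1.
    """
    import scipy.stats

    t = np.asarray(t, dtype=float)
    p = params

    def g(delay: float, disp: float) -> np.ndarray:
        return scipy.stats.gamma.pdf(t, a=delay / disp, scale=disp)

    h = g(p.peak_delay_s, p.peak_dispersion_s) \
        - g(p.undershoot_delay_s, p.undershoot_dispersion_s) / p.peak_undershoot_ratio
    h = np.where(t > 0, h, 0.0)
    peak = h.max()
    if peak <= 0:
        raise ConfigError("HRF grid does not cover the response peak")
    return h / peak


@dataclass
class SimConfig:
    """Generator settings.

    Class peak-dHbO amplitudes default to 1.0 / 0.5 / 0.1 uM for like / so-so /
    dislike (high-, mid- and low-activation); the left-hemisphere channels 1-6
    respond for every class.  Noise amplitudes are uM.
    """

    class_amplitudes: dict = field(
        default_factory=lambda: {"like": 1.0, "so-so": 0.5, "dislike": 0.1})
    active_channels_per_class: dict = field(
        default_factory=lambda: {c: tuple(range(1, 7)) for c in PREFERENCES})
    sine_noise: dict = field(
        default_factory=lambda: {0.03: 0.05, 0.2: 0.05, 0.8: 0.05})  # Hz -> uM amplitude
    white_sd: float = 0.05          # uM
    drift_slope: float = 2e-4       # uM per second
    hbr_coupling: float = 1.0 / 3.0  # dHbR = -r * activation
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def validate(self, fs: float) -> None:
        if any(a < 0 for a in self.class_amplitudes.values()):
            raise ConfigError("class amplitudes must be >= 0")
        if any(f >= fs / 2 for f in self.sine_noise):
            raise ConfigError("noise frequency at or above Nyquist")
        if self.white_sd < 0 or any(a < 0 for a in self.sine_noise.values()):
            raise ConfigError("noise amplitudes must be >= 0")


def _trial_regressors(schedule: list[Event], n_samples: int, fs: float,
                      hrf_params: HRFParams) -> dict[int, np.ndarray]:
    """Per-trial unit-peak boxcar (x) HRF regressor over the full session."""
    kernel = canonical_hrf(np.arange(0, hrf_params.duration_s, 1 / fs), hrf_params)
    out: dict[int, np.ndarray] = {}
    for ev in schedule:
        if ev.kind != "video":
            continue
        box = np.zeros(n_samples)
        start = int(np.floor(ev.onset_s * fs))
        stop = min(start + int(np.floor(ev.duration_s * fs)), n_samples)
        box[start:stop] = 1.0
        resp = np.convolve(box, kernel)[:n_samples]
        peak = resp.max()
        if peak > 0:
            resp /= peak
        assert ev.trial_index is not None
        out[ev.trial_index] = resp
    return out


def simulate_hemo(schedule: list[Event], labels: list[str], cfg: SimConfig,
                  fs: float = DEFAULT_FS,
                  n_channels: int = N_CHANNELS) -> tuple[HemoSeries, pd.DataFrame]:
    """Generate a HemoSeries for a schedule plus its per-trial label table.

    ``labels`` gives one preference label per video event, in trial order.
    """
    cfg.validate(fs)
    video_events = [ev for ev in schedule if ev.kind == "video"]
    if len(labels) != len(video_events):
        raise DataError(f"got {len(labels)} labels for {len(video_events)} video events")
    unknown = set(labels) - set(cfg.class_amplitudes)
    if unknown:
        raise DataError(f"labels without configured amplitude: {sorted(unknown)}")

    total_s = max(ev.onset_s + ev.duration_s for ev in schedule)
    n = int(np.floor(total_s * fs))
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(n) / fs

    regs = _trial_regressors(schedule, n, fs, cfg.hrf)
    label_of = dict(zip((ev.trial_index for ev in video_events), labels))

    signal = np.zeros((n, n_channels))
    channel_pos = {ch: i for i, ch in enumerate(range(1, n_channels + 1))}
    for trial_idx, resp in regs.items():
        lab = label_of[trial_idx]
        amp = cfg.class_amplitudes[lab]
        for ch in cfg.active_channels_per_class.get(lab, ()):
            if ch in channel_pos:
                signal[:, channel_pos[ch]] += amp * resp

    def noise_block(scale: float) -> np.ndarray:
        out = np.zeros((n, n_channels))
        for f, amp in sorted(cfg.sine_noise.items()):
            phases = rng.uniform(0, 2 * np.pi, size=n_channels)
            out += scale * amp * np.sin(2 * np.pi * f * t[:, None] + phases[None, :])
        out += rng.normal(0.0, scale * cfg.white_sd, size=(n, n_channels)) \
            if cfg.white_sd > 0 else 0.0
        out += scale * cfg.drift_slope * t[:, None]
        return out

    dhbo = signal + noise_block(1.0)
    # HbR: anticorrelated activation, independent noise at coupling scale
    dhbr = -cfg.hbr_coupling * signal + noise_block(cfg.hbr_coupling)

    hemo = HemoSeries(dhbo, dhbr, fs=fs, channel_ids=tuple(range(1, n_channels + 1)))
    table = pd.DataFrame({
        "trial_index": [ev.trial_index for ev in video_events],
        "label": labels,
        "onset_s": [ev.onset_s for ev in video_events],
    })
    return hemo, table


def simulate_optical(hemo: HemoSeries,
                     geom: GeometryConfig = GeometryConfig(),
                     eps: ExtinctionMatrix = ExtinctionMatrix(),
                     baseline_intensity: float | np.ndarray = 1.0) -> OpticalRecording:
    """Forward-model a HemoSeries into raw intensities (inverse of the MBLL stage).

    I(t) = I0 * 10^(-dOD(t)); converting the output back through
    ``optical_density`` (whole-series baseline on a zero-mean series) and
    ``mbll`` recovers ``hemo`` up to numerical round-off.
    """
    od = forward_mbll(hemo, geom, eps)
    i0 = np.broadcast_to(np.asarray(baseline_intensity, dtype=float), od.shape)
    if not np.all(i0 > 0):
        raise DataError("baseline intensities must be positive")
    intensity = i0 * np.power(10.0, -od)
    if np.any(intensity <= 0) or np.any(~np.isfinite(intensity)):
        raise DataError("optical-density excursion too large: intensity underflow")
    return OpticalRecording(intensity, fs=hemo.fs, channel_ids=hemo.channel_ids)


def default_labels(n_trials: int) -> list[str]:
    """Balanced label assignment, rotated per 3-trial block so that no class
    is confounded with a single video duration."""
    order = ("like", "so-so", "dislike")
    return [order[(i + i // 3) % 3] for i in range(n_trials)]


def simulate_session(cfg: SimConfig, fs: float = DEFAULT_FS,
                     labels: list[str] | None = None):
    """Convenience: paper-style 12-trial session with balanced labels.

    Returns (schedule, hemo, label_table).  Default labels repeat
    (like, so-so, dislike) over the 12 trials — balanced 4/4/4.
    """
    from .paradigm import build_schedule, paper_session

    session = paper_session()
    n_trials = sum(len(s.trials) for s in session.sections)
    if labels is None:
        labels = default_labels(n_trials)
    schedule = build_schedule(session, labels=labels)
    hemo, table = simulate_hemo(schedule, labels, cfg, fs=fs)
    return schedule, hemo, table
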