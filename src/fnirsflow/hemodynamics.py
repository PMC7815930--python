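"""Optical intensity -> hemoglobin concentration changes, plus preprocessing.

The chain is the standard continuous-wave fNIRS one: optical-density change
relative to a baseline window, the modified Beer-Lambert law (MBLL) to unmix
oxy-/deoxy-hemoglobin (uM), then a zero-phase Butterworth low-pass and linear
detrending to suppress cardiac (~0.8 Hz), respiratory (~0.2 Hz) and drift
components.

MBLL per channel and sample::

    dOD(lambda) / (d * DPF(lambda)) = eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR

with ``d`` the source-detector distance (cm), DPF the differential path
factor, and ``eps`` molar extinction coefficients (uM^-1 cm^-1).  The 2x2
system over the two wavelengths is solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

__all__ = [
    "DataError",
    "ConfigError",
    "OpticalRecording",
    "ExtinctionMatrix",
    "GeometryConfig",
    "HemoSeries",
    "optical_density",
    "mbll",
    "forward_mbll",
    "lowpass",
    "butter_sos",
    "detrend",
    "preprocess",
]

DEFAULT_FS = 15.625  # Hz
DEFAULT_WAVELENGTHS = (690, 830)  # nm
N_CHANNELS = 12


class DataError(ValueError):
    """Input data violates a precondition (e.g. non-positive intensity)."""


class ConfigError(ValueError):
    """A processing parameter is invalid (e.g. cutoff above Nyquist)."""


@dataclass
class OpticalRecording:
    """Raw dual-wavelength intensities, shape (time, channel, wavelength)."""

    intensity: np.ndarray
    fs: float = DEFAULT_FS
    wavelengths_nm: tuple[int, int] = DEFAULT_WAVELENGTHS
    channel_ids: tuple[int, ...] = tuple(range(1, N_CHANNELS + 1))

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[2] != 2:
            raise DataError(
                f"intensity must be (time, channel, 2 wavelengths), got {self.intensity.shape}")
        if self.intensity.shape[1] != len(self.channel_ids):
            raise DataError("channel_ids length does not match intensity shape")
        if self.fs <= 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if not np.all(self.intensity > 0):
            raise DataError("optical intensities must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]


@dataclass(frozen=True)
class ExtinctionMatrix:
    """Molar extinction coefficients, uM^-1 cm^-1.

    The four defaults are the printed study values, assigned to chromophores
    by the hemoglobin spectra: at 690 nm HbR absorbs far more than HbO, at
    830 nm the ordering flips.
    """

    eps_hbo_690: float = 0.95
    eps_hbr_690: float = 4.93
    eps_hbo_830: float = 2.135
    eps_hbr_830: float = 1.791

    def matrix(self) -> np.ndarray:
        """Rows: wavelength (690, 830); columns: chromophore (HbO, HbR)."""
        return np.array([[self.eps_hbo_690, self.eps_hbr_690],
                         [self.eps_hbo_830, self.eps_hbr_830]])

    def __post_init__(self) -> None:
        m = self.matrix()
        if not np.all(m > 0):
            raise ConfigError("extinction coefficients must be positive")
        if abs(np.linalg.det(m)) <= 1e-6:
            raise ConfigError("extinction matrix is (near-)singular")


@dataclass(frozen=True)
class GeometryConfig:
    """Probe geometry: source-detector distance (cm) and DPF per wavelength."""

    source_detector_distance_cm: float = 2.828
    dpf: tuple[float, float] = (6.0, 6.0)  # (690 nm, 830 nm)

    def __post_init__(self) -> None:
        if self.source_detector_distance_cm <= 0:
            raise ConfigError("source-detector distance must be positive")
        if any(d <= 0 for d in self.dpf):
            raise ConfigError("DPF must be positive")


@dataclass
class HemoSeries:
    """Concentration changes dHbO / dHbR in uM, shape (time, channel)."""

    dhbo: np.ndarray
    dhbr: np.ndarray
    fs: float = DEFAULT_FS
    channel_ids: tuple[int, ...] = tuple(range(1, N_CHANNELS + 1))

    def __post_init__(self) -> None:
        self.dhbo = np.asarray(self.dhbo, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if self.dhbo.shape != self.dhbr.shape or self.dhbo.ndim != 2:
            raise DataError("dHbO and dHbR must share a (time, channel) shape")
        if self.dhbo.shape[1] != len(self.channel_ids):
            raise DataError("channel_ids length does not match series shape")
        if not (np.all(np.isfinite(self.dhbo)) and np.all(np.isfinite(self.dhbr))):
            raise DataError("hemodynamic series must be finite")

    @property
    def n_samples(self) -> int:
        return self.dhbo.shape[0]

    def copy(self) -> "HemoSeries":
        return HemoSeries(self.dhbo.copy(), self.dhbr.copy(), self.fs, self.channel_ids)


def optical_density(rec: OpticalRecording,
                    baseline_window: slice | tuple[int, int] | None = None) -> np.ndarray:
    """Optical-density change relative to the baseline-window mean intensity.

    dOD(t) = -log10(I(t) / mean(I over baseline)).  The default baseline is
    the whole recording; in practice pass the section's initial rest.
    """
    if baseline_window is None:
        sl = slice(None)
    elif isinstance(baseline_window, tuple):
        sl = slice(*baseline_window)
    else:
        sl = baseline_window
    base = rec.intensity[sl]
    if base.shape[0] == 0:
        raise ConfigError("empty baseline window")
    i0 = base.mean(axis=0, keepdims=True)
    return -np.log10(rec.intensity / i0)


def _pathlength_cm(geom: GeometryConfig) -> np.ndarray:
    """Effective pathlength d * DPF per wavelength, cm."""
    return geom.source_detector_distance_cm * np.asarray(geom.dpf, dtype=float)


def mbll(od: np.ndarray,
         geom: GeometryConfig = GeometryConfig(),
         eps: ExtinctionMatrix = ExtinctionMatrix(),
         fs: float = DEFAULT_FS,
         channel_ids: tuple[int, ...] | None = None) -> HemoSeries:
    """Invert the MBLL: optical-density changes -> (dHbO, dHbR) in uM."""
    od = np.asarray(od, dtype=float)
    if od.ndim != 3 or od.shape[2] != 2:
        raise DataError(f"OD must be (time, channel, 2 wavelengths), got {od.shape}")
    if not np.all(np.isfinite(od)):
        raise DataError("OD series must be finite")
    scaled = od / _pathlength_cm(geom)  # uM^-1 cm^-1 * uM gives cm^-1; units check out
    inv = np.linalg.inv(eps.matrix())
    conc = scaled @ inv.T  # (T, C, 2): columns HbO, HbR
    if channel_ids is None:
        channel_ids = tuple(range(1, od.shape[1] + 1))
    return HemoSeries(conc[:, :, 0], conc[:, :, 1], fs=fs, channel_ids=channel_ids)


def forward_mbll(hemo: HemoSeries,
                 geom: GeometryConfig = GeometryConfig(),
                 eps: ExtinctionMatrix = ExtinctionMatrix()) -> np.ndarray:
    """Forward MBLL: concentrations -> optical-density changes (time, channel, 2)."""
    conc = np.stack([hemo.dhbo, hemo.dhbr], axis=2)
    return (conc @ eps.matrix().T) * _pathlength_cm(geom)


def butter_sos(order: int, fc_hz: float, fs: float) -> np.ndarray:
    """Design the low-pass Butterworth (second-order sections)."""
    if fc_hz >= fs / 2:
        raise ConfigError(f"cutoff {fc_hz} Hz is not below Nyquist ({fs / 2} Hz)")
    if fc_hz <= 0 or order < 1:
        raise ConfigError("need fc > 0 and order >= 1")
    return scipy.signal.butter(order, fc_hz, btype="low", fs=fs, output="sos")


def _lowpass_array(x: np.ndarray, fs: float, order: int, fc_hz: float) -> np.ndarray:
    sos = butter_sos(order, fc_hz, fs)
    # zero-phase: forward-backward pass, DC gain 1, no onset lag
    return scipy.signal.sosfiltfilt(sos, x, axis=0)


def lowpass(series: "HemoSeries | np.ndarray", order: int = 4, fc_hz: float = 0.15,
            fs: float | None = None) -> "HemoSeries | np.ndarray":
    """4th-order Butterworth low-pass (0.15 Hz default), zero-phase, per channel.

    Accepts a HemoSeries (fs taken from it) or a bare array with ``fs`` given
    (e.g. an OD series to filter before conversion).
    """
    if isinstance(series, HemoSeries):
        return HemoSeries(_lowpass_array(series.dhbo, series.fs, order, fc_hz),
                          _lowpass_array(series.dhbr, series.fs, order, fc_hz),
                          fs=series.fs, channel_ids=series.channel_ids)
    if fs is None:
        raise ConfigError("fs is required when filtering a bare array")
    return _lowpass_array(np.asarray(series, dtype=float), fs, order, fc_hz)


def _detrend_linear(x: np.ndarray) -> np.ndarray:
    if x.shape[0] < 2:
        raise DataError("detrending needs at least 2 samples")
    return scipy.signal.detrend(x, axis=0, type="linear")


def _detrend_dct(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    """Remove drift by projecting out low-frequency DCT basis vectors."""
    n = x.shape[0]
    if n < 2:
        raise DataError("detrending needs at least 2 samples")
    # DCT-II basis; component k has frequency k * fs / (2n)
    k_max = int(np.floor(2 * n * cutoff_hz / fs))
    k_max = max(k_max, 1)
    t = (np.arange(n) + 0.5) / n
    basis = np.cos(np.pi * np.outer(t, np.arange(k_max + 1)))  # incl. DC
    q, _ = np.linalg.qr(basis)
    return x - q @ (q.T @ x)


def detrend(series: "HemoSeries | np.ndarray", method: str = "linear",
            fs: float | None = None, cutoff_hz: float = 1 / 128) -> "HemoSeries | np.ndarray":
    """Remove slow drift per channel.

    ``linear`` (default): least-squares line removal, leaving zero mean and
    zero best-fit slope.  ``dct``: project out a discrete-cosine drift basis
    below ``cutoff_hz``.
    """
    if isinstance(series, HemoSeries):
        if method == "linear":
            return HemoSeries(_detrend_linear(series.dhbo), _detrend_linear(series.dhbr),
                              fs=series.fs, channel_ids=series.channel_ids)
        if method == "dct":
            return HemoSeries(_detrend_dct(series.dhbo, series.fs, cutoff_hz),
                              _detrend_dct(series.dhbr, series.fs, cutoff_hz),
                              fs=series.fs, channel_ids=series.channel_ids)
        raise ConfigError(f"unknown detrend method {method!r}")
    x = np.asarray(series, dtype=float)
    if method == "linear":
        return _detrend_linear(x)
    if method == "dct":
        if fs is None:
            raise ConfigError("fs is required for DCT detrending of a bare array")
        return _detrend_dct(x, fs, cutoff_hz)
    raise ConfigError(f"unknown detrend method {method!r}")


def preprocess(hemo: HemoSeries, order: int = 4, fc_hz: float = 0.15,
               detrend_method: str = "linear") -> HemoSeries:
    """Low-pass then detrend — the standard preprocessing applied before epoching."""
    return detrend(lowpass(hemo, order=order, fc_hz=fc_hz), method=detrend_method)
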