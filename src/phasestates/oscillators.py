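"""Band-limited oscillatory source generation.

Sources emulate alpha-band (10 +/- 2 Hz) cortical parcel activity: each
source is a dense sum of sinusoids spanning the target band, with
independent random amplitudes and phases per sinusoid, passed through a
fifth-order all-pole (AR) filter to impose temporal smoothness.  Sources
are mutually independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = ["BandLimitedConfig", "SourceSignals", "ar_smooth", "generate_uncoupled_sources"]


@dataclass(frozen=True)
class BandLimitedConfig:
    """Parameters of the band-limited source model.

    Defaults follow the study conditions: 78 alpha-band sources at
    125 Hz for five-minute sessions, sinusoids every 0.01 Hz across
    10 +/- 2 Hz, order-5 AR smoothing.
    """

    n_sources: int = 78
    f_center: float = 10.0
    half_bandwidth: float = 2.0
    freq_step: float = 0.01
    fs: float = 125.0
    duration: float = 300.0
    ar_order: int = 5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_sources < 1:
            raise ValueError("n_sources must be >= 1")
        if self.f_center - self.half_bandwidth <= 0:
            raise ValueError("band must lie strictly above 0 Hz")
        if self.half_bandwidth > 0 and self.freq_step <= 0:
            raise ValueError("freq_step must be positive")
        if self.fs <= 2 * (self.f_center + self.half_bandwidth):
            raise ValueError("fs violates the Nyquist bound for the band")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        T = self.duration * self.fs
        if not np.isclose(T, round(T)) or round(T) < 1:
            raise ValueError("duration*fs must be an integer sample count >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    @property
    def frequencies(self) -> np.ndarray:
        """Sinusoid grid across the band (a single line if bandwidth is 0)."""
        if self.half_bandwidth == 0:
            return np.array([self.f_center])
        n = int(round(2 * self.half_bandwidth / self.freq_step)) + 1
        return self.f_center - self.half_bandwidth + self.freq_step * np.arange(n)


@dataclass
class SourceSignals:
    """Matrix of simulated neural activity, one row per source."""

    data: np.ndarray  # (n_sources, T)
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (sources x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")
        if np.any(self.data.var(axis=1) == 0):
            raise ValueError("every source must have nonzero variance")
        if not self.labels:
            self.labels = [f"src{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_sources(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


def design_ar_filter(order: int, f_center: float, fs: float,
                     peak_radius: float = 0.95, real_radius: float = 0.1) -> np.ndarray:
    """Denominator coefficients of the all-pole smoothing filter.

    A conjugate pole pair sits at `peak_radius` at the band-center digital
    frequency; the remaining `order - 2` poles are real and near the
    origin, completing the requested order without shaping the passband.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    omega = 2 * np.pi * f_center / fs
    poles: list[complex] = []
    if order >= 2:
        poles += [peak_radius * np.exp(1j * omega), peak_radius * np.exp(-1j * omega)]
        poles += [real_radius] * (order - 2)
    else:
        poles += [peak_radius]
    a = np.real(np.poly(poles))
    if np.any(np.abs(np.roots(a)) >= 1.0):
        raise ValueError("unstable pole configuration")
    return a


def ar_smooth(x: np.ndarray, order: int, passband: tuple[float, float], fs: float) -> np.ndarray:
    """Apply the stable all-pole smoothing filter forward along time.

    Parameters
    ----------
    x : array, shape (..., T)
        Input series; filtering runs along the last axis.
    order : int
        Filter order (number of poles).
    passband : (low, high) in Hz
        Must lie inside (0, fs/2); the pole pair is placed at its center.
    fs : float
        Sampling rate in Hz.
    """
    lo, hi = passband
    if not (0 < lo <= hi < fs / 2):
        raise ValueError("passband must lie inside (0, fs/2)")
    a = design_ar_filter(order, 0.5 * (lo + hi), fs)
    return sps.lfilter([1.0], a, np.asarray(x, dtype=float), axis=-1)


def generate_uncoupled_sources(config: BandLimitedConfig,
                               rng: np.random.Generator) -> SourceSignals:
    """Generate mutually independent band-limited sources.

    Each source is  sum_k a_k sin(2 pi f_k t + phi_k)  over the band's
    frequency grid with a_k ~ U(0,1) and phi_k ~ U(0, 2 pi) drawn
    independently per sinusoid and per source, then AR-smoothed and
    rescaled to unit variance.  No warm-up samples are discarded; the
    filter transient is negligible at session length.
    """
    if rng is None:
        raise ValueError("an explicit seeded numpy Generator is required")
    freqs = config.frequencies
    T = config.n_samples
    t = np.arange(T) / config.fs
    band = (config.f_center - config.half_bandwidth, config.f_center + config.half_bandwidth)
    # pure-tone degenerate band: keep the passband well-posed for the filter
    if band[0] == band[1]:
        band = (config.f_center, config.f_center)
        lo = hi = config.f_center
        if not (0 < lo < config.fs / 2):
            raise ValueError("f_center outside (0, fs/2)")
    data = np.empty((config.n_sources, T))
    phase_arg = 2 * np.pi * np.outer(freqs, t)  # (F, T)
    for i in range(config.n_sources):
        amps = rng.uniform(0.0, 1.0, size=freqs.size)
        phis = rng.uniform(0.0, 2 * np.pi, size=freqs.size)
        x = amps @ np.sin(phase_arg + phis[:, None])
        data[i] = x
    lo = max(band[0], 1e-6)
    hi = min(band[1], config.fs / 2 - 1e-6)
    data = ar_smooth(data, config.ar_order, (lo, max(lo, hi)), config.fs)
    data /= data.std(axis=1, ddof=0)[:, None]
    return SourceSignals(data=data, fs=config.fs)


def band_power_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of periodogram power inside `band` (zero-frequency excluded)."""
    f, p = sps.periodogram(np.asarray(x, dtype=float), fs=fs)
    mask = f > 0
    inband = mask & (f >= band[0]) & (f <= band[1])
    return float(p[inband].sum() / p[mask].sum())
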