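"""Rendering state paths into realistic sampled current traces.

The signal chain mirrors a FET recording front end: the piecewise-constant
conductance level function is integrated onto a fine internal grid (default
4x the sampling rate), Gaussian white and 1/f noise are added, the sum is
passed through a causal low-pass Bessel filter (default 4-pole, 10 kHz) and
decimated to the acquisition rate.  Traces are in relative conductance with
baseline 1.0; more folded / bound states sit at lower levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .schemes import KineticScheme
from .simulate import StatePath

logger = logging.getLogger(__name__)


@dataclass
class NoiseSpec:
    """Additive noise model: white Gaussian + 1/f^exponent pink noise.

    Amplitudes are in relative-conductance units (standard deviations on the
    fine internal grid, before low-pass filtering).
    """

    white_sd: float = 0.0
    pink_amplitude: float = 0.0
    pink_exponent: float = 1.0

    def __post_init__(self):
        if self.white_sd < 0 or self.pink_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")
        if not 0.5 <= self.pink_exponent <= 1.5:
            raise ValueError("pink_exponent must lie in [0.5, 1.5]")


@dataclass
class AcquisitionSpec:
    """Sampling and anti-alias filtering of the recording chain.

    filter_cutoff=None disables filtering (useful for noiseless ground-truth
    renders).
    """

    sampling_rate: float = 57600.0
    filter_cutoff: float | None = 10000.0
    filter_order: int = 4
    duration: float = 1.0

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.filter_cutoff is not None and not self.filter_cutoff < self.sampling_rate / 2:
            raise ValueError("filter_cutoff must be below the Nyquist frequency")


@dataclass
class CurrentTrace:
    """Uniformly sampled current time series with acquisition metadata."""

    samples: np.ndarray
    sampling_rate: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


def pink_noise(n: int, amplitude: float, exponent: float = 1.0, seed=None) -> np.ndarray:
    """Zero-mean noise with power spectral density proportional to 1/f^exponent.

    Synthesized in the Fourier domain: independent complex Gaussian rfft
    coefficients shaped by ``f**(-exponent/2)`` (zero DC), inverse
    transformed, and rescaled so the sample standard deviation equals
    ``amplitude``.  Reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if amplitude == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_freq = n // 2 + 1
    re = rng.standard_normal(n_freq)
    im = rng.standard_normal(n_freq)
    k = np.arange(n_freq, dtype=float)
    shape = np.zeros(n_freq)
    shape[1:] = k[1:] ** (-exponent / 2.0)
    spec = (re + 1j * im) * shape
    spec[0] = 0.0
    if n % 2 == 0:
        spec[-1] = re[-1] * shape[-1]  # Nyquist bin must be real
    x = np.fft.irfft(spec, n)
    x -= x.mean()
    sd = x.std()
    if sd > 0:
        x *= amplitude / sd
    return x


def default_noise(scheme: KineticScheme, snr: float = 5.0) -> NoiseSpec:
    """Default noise for a scheme: white SD = (smallest level separation)/snr,
    pink amplitude = white SD / 2."""
    levels = np.unique(scheme.levels)
    if len(levels) < 2:
        sep = 0.03
    else:
        sep = np.diff(levels).min()
    white = sep / snr
    return NoiseSpec(white_sd=white, pink_amplitude=white / 2.0)


def _integrated_levels(path: StatePath, levels: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Mean level over each interval [edges[k], edges[k+1]] by exact integration."""
    bnd = path.boundaries
    lev = levels[path.states]
    cum = np.concatenate([[0.0], np.cumsum(lev * path.durations)])

    def integral(t):
        idx = np.clip(np.searchsorted(bnd, t, side="right") - 1, 0, path.n_events - 1)
        return cum[idx] + lev[idx] * (t - bnd[idx])

    vals = integral(edges)
    return np.diff(vals) / np.diff(edges)


def render_trace(
    path: StatePath,
    scheme: KineticScheme,
    noise: NoiseSpec | None = None,
    acq: AcquisitionSpec | None = None,
    seed=None,
    oversample: int = 4,
    metadata: dict | None = None,
) -> CurrentTrace:
    """Render a state path into a sampled, noisy, filtered current trace.

    The level function is averaged onto an internal grid at
    ``oversample * sampling_rate`` (dwells shorter than one grid step are
    time-weighted into their sample, with a logged warning), noise is added
    on the fine grid, the causal Bessel low-pass is applied, and the result
    is decimated to the acquisition rate.
    """
    noise = noise or NoiseSpec()
    acq = acq or AcquisitionSpec(duration=path.total_duration)
    if path.total_duration < acq.duration - 1e-12:
        raise ValueError(
            f"path covers {path.total_duration} s but acquisition needs {acq.duration} s"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fine_rate = oversample * acq.sampling_rate
    n_out = round(acq.duration * acq.sampling_rate)
    n_fine = n_out * oversample
    if np.any(path.durations < 1.0 / fine_rate):
        logger.warning(
            "%d dwells shorter than the internal grid step (%.3g s) were "
            "time-averaged into their samples",
            int(np.sum(path.durations < 1.0 / fine_rate)),
            1.0 / fine_rate,
        )
    edges = np.arange(n_fine + 1) / fine_rate
    y = _integrated_levels(path, scheme.levels, edges)
    if noise.white_sd > 0:
        y = y + rng.normal(0.0, noise.white_sd, n_fine)
    if noise.pink_amplitude > 0:
        y = y + pink_noise(n_fine, noise.pink_amplitude, noise.pink_exponent, rng)
    if acq.filter_cutoff is not None:
        b, a = _sig.bessel(acq.filter_order, acq.filter_cutoff, fs=fine_rate, norm="mag")
        y = _sig.lfilter(b, a, y)
    samples = y[::oversample]
    meta = dict(metadata or {})
    meta.setdefault("scheme_id", scheme.scheme_id)
    return CurrentTrace(samples=samples, sampling_rate=acq.sampling_rate, metadata=meta)
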