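"""Synthetic resting-state time series with planted network covariance.

Each network n gets one latent AR(1) series g_n(t) with unit innovation
variance; a vertex with label n observes ``a_n * g_n(t) + sigma * noise``.
Under this model the population correlation of two same-network vertices is
``a_n^2 / (a_n^2 + sigma^2)`` and cross-network correlations are zero, which
is exactly the structure the downstream connectivity analysis assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .surface import ParcellationMap

__all__ = [
    "TimeSeriesMatrix",
    "NetworkSignalModel",
    "simulate_rfmri",
    "band_pass",
    "amplitude_for_correlation",
]

#: Run-length defaults: the human-like value matches a 15-minute run at
#: TR = 0.72 s; the macaque-like run is emulated at reduced length with an
#: assumed TR of 2.0 s.
HUMAN_DEFAULT_T = 1200
HUMAN_DEFAULT_TR = 0.72
MACAQUE_DEFAULT_T = 1600
MACAQUE_DEFAULT_TR = 2.0


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """Vertex x timepoint BOLD-like matrix with its repetition time (s)."""

    data: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 2:
            raise InputError("time-series data must be 2-D (vertices x time)")
        if not np.all(np.isfinite(d)):
            raise InputError("time-series data contains non-finite values")
        if self.tr <= 0:
            raise ParameterError("TR must be > 0")
        object.__setattr__(self, "data", d)

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr


@dataclass(frozen=True)
class NetworkSignalModel:
    """Generative parameters: per-network latent amplitudes ``a_n`` (index
    1..7), noise sd ``sigma``, latent AR(1) coefficient ``rho``, and an
    optional band-pass applied after generation."""

    amplitudes: dict[int, float] = field(
        default_factory=lambda: {n: 1.0 for n in range(1, 8)}
    )
    sigma: float = 1.0
    rho: float = 0.3
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        amps = {int(k): float(v) for k, v in self.amplitudes.items()}
        if any(k < 1 or k > 7 for k in amps):
            raise ParameterError("amplitude keys must be network ids 1..7")
        if any(a < 0 for a in amps.values()):
            raise ParameterError("amplitudes must be >= 0")
        # All-zero amplitudes are allowed: a degenerate pure-noise generator.
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if not 0 <= self.rho < 1:
            raise ParameterError("rho must lie in [0, 1)")
        object.__setattr__(self, "amplitudes", amps)

    def amplitude_vector(self) -> np.ndarray:
        """Amplitudes indexed by label 0..7 (label 0 is pure noise)."""
        a = np.zeros(8)
        for k, v in self.amplitudes.items():
            a[k] = v
        return a


def amplitude_for_correlation(target_r: float, sigma: float) -> float:
    """Latent amplitude giving within-network population correlation
    ``target_r`` at noise level ``sigma`` (inverts a^2/(a^2+sigma^2) = r)."""
    if not 0 < target_r < 1:
        raise ParameterError("target correlation must lie in (0, 1)")
    return sigma * np.sqrt(target_r / (1.0 - target_r))


def simulate_rfmri(
    parcellation: ParcellationMap,
    model: NetworkSignalModel,
    n_timepoints: int,
    tr: float,
    seed: int,
) -> TimeSeriesMatrix:
    """Draw one synthetic run; a pure function of its arguments.

    Latents are stationary AR(1) (variance ``1/(1 - rho^2)`` at t=0), vertex
    noise is i.i.d. standard normal scaled by sigma, label-0 vertices get
    pure noise.
    """
    if n_timepoints < 10:
        raise ParameterError("need at least 10 timepoints")
    if tr <= 0:
        raise ParameterError("TR must be > 0")
    rng = np.random.default_rng(seed)
    rho = model.rho

    innovations = rng.standard_normal((7, n_timepoints))
    latents = np.empty_like(innovations)
    latents[:, 0] = innovations[:, 0] / np.sqrt(1.0 - rho**2)
    for t in range(1, n_timepoints):
        latents[:, t] = rho * latents[:, t - 1] + innovations[:, t]

    amp = model.amplitude_vector()
    labels = parcellation.labels
    data = np.zeros((labels.shape[0], n_timepoints))
    signal_mask = labels > 0
    data[signal_mask] = (
        amp[labels[signal_mask], None] * latents[labels[signal_mask] - 1]
    )
    if model.sigma > 0:
        data += model.sigma * rng.standard_normal(data.shape)

    ts = TimeSeriesMatrix(data, tr)
    if model.band is not None:
        ts = band_pass(ts, *model.band)
    return ts


def band_pass(ts: TimeSeriesMatrix, low_hz: float, high_hz: float) -> TimeSeriesMatrix:
    """Hard spectral band-pass per vertex via forward/inverse real FFT.

    Keeps Fourier bins with ``low <= f <= high`` (the DC bin is always
    removed, so the output is zero-mean per vertex).
    """
    if low_hz < 0 or low_hz >= high_hz:
        raise ParameterError("need 0 <= low < high")
    if high_hz >= ts.nyquist_hz:
        raise ParameterError(
            f"high cutoff {high_hz} Hz must be below Nyquist {ts.nyquist_hz:.4g} Hz"
        )
    t = ts.n_timepoints
    spec = np.fft.rfft(ts.data, axis=1)
    freqs = np.fft.rfftfreq(t, d=ts.tr)
    keep = (freqs >= low_hz) & (freqs <= high_hz) & (freqs > 0)
    spec[:, ~keep] = 0.0
    return TimeSeriesMatrix(np.fft.irfft(spec, n=t, axis=1), ts.tr)
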