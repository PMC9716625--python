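"""Between-musician coordination via cross-wavelet analysis.

Coordination strength is operationalised as the modulus of the cross-wavelet
transform of the two musicians' body-part acceleration (norm of the 3-D
Savitzky-Golay second derivative), evaluated on a logarithmic period grid
spanning 0.3-7 s and extracted at the dominant common period — the grid
period with the highest time-averaged cross power.  The continuous wavelet
transform uses the complex Morlet mother wavelet (centre frequency
``omega0 = 6`` by default) computed in the Fourier domain with zero padding
to the next power of two (Torrence & Compo normalisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import COORDINATION_PARTS, DuoRecording
from .kinematics import KinematicSeries, block_average, smooth_and_differentiate

__all__ = [
    "PeriodGrid",
    "CoordinationSeries",
    "morlet_cwt",
    "cross_wavelet",
    "smooth_cross",
    "dominant_period",
    "coordination_series",
    "coordination_all_pairs",
]


@dataclass
class PeriodGrid:
    """Ascending grid of wavelet periods (s)."""

    periods: np.ndarray
    per_octave: int = 20

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        if len(self.periods) == 0:
            raise ValueError("empty period grid")
        if np.any(np.diff(self.periods) <= 0):
            raise ValueError("periods must be strictly increasing")
        if self.periods[0] <= 0:
            raise ValueError("periods must be positive")

    @classmethod
    def from_range(
        cls, min_period: float = 0.3, max_period: float = 7.0, per_octave: int = 20
    ) -> "PeriodGrid":
        """Suboctave grid: ``min_period * 2**(k/per_octave)`` up to ``max_period``."""
        if not 0 < min_period < max_period:
            raise ValueError("need 0 < min_period < max_period")
        n = int(np.floor(per_octave * np.log2(max_period / min_period))) + 1
        periods = min_period * 2.0 ** (np.arange(n) / per_octave)
        return cls(periods, per_octave)

    def __len__(self) -> int:
        return len(self.periods)


@dataclass
class CoordinationSeries:
    """Cross-wavelet power of one body-part pair at its dominant period."""

    pair: str  # body part name (head, chest, l/r shoulder, l/r arm)
    dominant_period: float  # s
    power: KinematicSeries  # non-negative, 10 Hz
    grid: PeriodGrid

    def __post_init__(self) -> None:
        if np.any(self.power.values < 0):
            raise ValueError("cross power must be non-negative")


def _morlet_scale(period: np.ndarray | float, omega0: float) -> np.ndarray | float:
    """Wavelet scale for a Fourier period (Morlet relation
    ``period = 4*pi*s / (omega0 + sqrt(2 + omega0^2))``)."""
    return np.asarray(period) * (omega0 + np.sqrt(2.0 + omega0**2)) / (4.0 * np.pi)


def morlet_cwt(
    series: KinematicSeries | np.ndarray,
    grid: PeriodGrid,
    omega0: float = 6.0,
    rate: float | None = None,
) -> np.ndarray:
    """Continuous Morlet wavelet transform on a period grid.

    Returns a complex coefficient matrix of shape ``(len(grid), n)``.  The
    input is zero-padded to the next power of two before the FFT and the
    padding is removed from the result.  ``omega0`` must be >= 5 so that the
    Morlet wavelet is admissible in practice.
    """
    if isinstance(series, KinematicSeries):
        values, rate = series.values, series.rate
    else:
        values = np.asarray(series, dtype=float)
        if rate is None:
            raise ValueError("rate required for a bare array")
    if values.ndim != 1:
        raise ValueError("CWT input must be a scalar series")
    if omega0 < 5:
        raise ValueError("omega0 must be >= 5 (admissibility)")
    n = len(values)
    dt = 1.0 / rate
    scales = _morlet_scale(grid.periods, omega0)
    if 2.0 * scales.max() > n * dt:
        raise ValueError(
            f"series of {n * dt:.2f}s too short for largest wavelet period "
            f"{grid.periods.max():.2f}s"
        )
    n_pad = 1 << int(np.ceil(np.log2(n)))
    x = np.zeros(n_pad)
    x[:n] = values - values.mean()
    fx = np.fft.fft(x)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=dt)
    coeffs = np.empty((len(scales), n), dtype=complex)
    norm_const = np.pi**-0.25
    for i, s in enumerate(scales):
        # Fourier transform of the (analytic) Morlet daughter wavelet
        psi_hat = np.zeros(n_pad)
        pos = omega > 0
        psi_hat[pos] = (
            norm_const
            * np.sqrt(2.0 * np.pi * s / dt)
            * np.exp(-0.5 * (s * omega[pos] - omega0) ** 2)
        )
        coeffs[i] = np.fft.ifft(fx * psi_hat)[:n]
    return coeffs


def cross_wavelet(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise cross-wavelet matrix ``a * conj(b)``.

    The modulus is the cross power; the phase is the local lead/lag of ``a``
    relative to ``b`` at each period.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"coefficient grids differ: {a.shape} vs {b.shape}")
    return a * np.conj(b)


def smooth_cross(
    cross: np.ndarray,
    grid: PeriodGrid,
    rate: float,
    sigma_periods: float = 1.0,
) -> np.ndarray:
    """Phase-coherent time smoothing of a complex cross matrix.

    Each period row is convolved (real and imaginary parts jointly) with a
    Gaussian of ``sigma_periods`` x period seconds.  Pairs that hold a stable
    relative phase keep their cross power; pairs whose relative phase drifts
    within the window cancel, so the smoothed modulus rewards genuinely
    common, phase-locked oscillation rather than the mere co-occurrence of
    energy at a period.  (No coherence normalisation is applied.)
    """
    cross = np.asarray(cross, dtype=complex)
    n = cross.shape[1]
    n_pad = 1 << int(np.ceil(np.log2(2 * n)))
    freq = np.fft.fftfreq(n_pad, d=1.0 / rate)
    out = np.empty_like(cross)
    for i, period in enumerate(grid.periods):
        sigma = sigma_periods * period  # seconds
        kernel_hat = np.exp(-2.0 * (np.pi * freq * sigma) ** 2)
        padded = np.zeros(n_pad, dtype=complex)
        padded[:n] = cross[i]
        out[i] = np.fft.ifft(np.fft.fft(padded) * kernel_hat)[:n]
    return out


def dominant_period(cross: np.ndarray, grid: PeriodGrid) -> float:
    """Grid period maximising the time-averaged cross power.

    Exact ties are broken toward the shorter period (grid is ascending, the
    first argmax wins).
    """
    cross = np.asarray(cross)
    if cross.size == 0:
        raise ValueError("empty cross matrix")
    if cross.shape[0] != len(grid):
        raise ValueError("cross matrix and grid disagree")
    mean_power = np.abs(cross).mean(axis=1)
    if np.all(mean_power == 0):
        raise ValueError("all-zero cross matrix: no dominant period")
    return float(grid.periods[int(np.argmax(mean_power))])


def coordination_series(
    rec: DuoRecording,
    pair: str,
    out_rate: float = 10.0,
    grid: PeriodGrid | None = None,
    omega0: float = 6.0,
    window: int = 25,
    polyorder: int = 2,
    smooth_sigma_periods: float | None = 3.0,
) -> CoordinationSeries:
    """Cross-wavelet coordination of one paired body part of a duo.

    Pipeline per musician: Savitzky-Golay acceleration (2nd derivative of
    position) -> Euclidean norm -> Morlet CWT; then the element-wise cross
    matrix of the two musicians, phase-coherent time smoothing (see
    :func:`smooth_cross`; disable with ``smooth_sigma_periods=None``), the
    dominant common period over the grid, and the cross-power row at that
    period block-averaged down to ``out_rate`` (10 Hz, the rating grid).
    """
    if grid is None:
        grid = PeriodGrid.from_range()
    coeffs = {}
    for role in ("P", "S"):
        mid = f"{role}_{pair}"
        if mid not in rec.trajectories:
            raise ValueError(f"marker {mid!r} missing from recording")
        acc = smooth_and_differentiate(
            rec.trajectories[mid], window=window, polyorder=polyorder, order=2
        )
        acc_norm = KinematicSeries(
            "speed", np.linalg.norm(acc.values, axis=1), acc.rate, "mm/s^2"
        )
        coeffs[role] = morlet_cwt(acc_norm, grid, omega0=omega0)
    cross = cross_wavelet(coeffs["P"], coeffs["S"])
    if smooth_sigma_periods is not None:
        cross = smooth_cross(cross, grid, rec.rate, smooth_sigma_periods)
    period = dominant_period(cross, grid)
    row = np.abs(cross[int(np.argmin(np.abs(grid.periods - period)))])
    power = block_average(row, rec.rate, out_rate)
    return CoordinationSeries(
        pair=pair,
        dominant_period=period,
        power=KinematicSeries("qom", power, out_rate, "a.u."),
        grid=grid,
    )


def coordination_all_pairs(
    rec: DuoRecording, out_rate: float = 10.0, **kwargs
) -> dict[str, CoordinationSeries]:
    """Coordination series for the six paired body parts (hands excluded)."""
    return {
        pair: coordination_series(rec, pair, out_rate=out_rate, **kwargs)
        for pair in COORDINATION_PARTS
    }
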