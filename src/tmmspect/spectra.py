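"""Low-level spectral quantification shared by cell, slab, and EPSI analyses.

An NMR spectrum is held as a complex vector on a uniform, descending ppm
axis. All downstream readouts (build-up curves, ratio maps, SNR) reduce to
three primitives defined here: window integration (Riemann sum times bin
spacing), noise estimation (sample standard deviation of the real part of a
signal-free region), and peak SNR (max magnitude in a window over sigma).

Design notes
------------
* Integration is a plain Riemann sum, not a trapezoid or a line fit: it is
  exactly oracle-checkable and matches discrete peak-integral practice.
* A bin belongs to a window when its center lies in the closed interval
  [center - half_width, center + half_width]; boundary ties are included.
* SNR uses the maximum magnitude in the window (conventional MR definition),
  not the integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np

__all__ = [
    "PpmAxis",
    "MetaboliteWindow",
    "DynamicSpectrumSeries",
    "ppm_axis",
    "integrate_window",
    "estimate_noise",
    "snr",
    "sum_spectra",
]


@dataclass(frozen=True)
class PpmAxis:
    """Uniform chemical-shift axis, descending ppm (NMR plotting convention)."""

    n_points: int
    bandwidth_ppm: float
    center_ppm: float
    values: np.ndarray = field(repr=False)

    @property
    def spacing(self) -> float:
        return self.bandwidth_ppm / self.n_points

    @property
    def ppm_min(self) -> float:
        return self.center_ppm - self.bandwidth_ppm / 2.0

    @property
    def ppm_max(self) -> float:
        return self.center_ppm + self.bandwidth_ppm / 2.0

    def contains(self, lo: float, hi: float) -> bool:
        """True when [lo, hi] lies inside the axis span."""
        return lo >= self.ppm_min and hi <= self.ppm_max


@dataclass(frozen=True)
class MetaboliteWindow:
    """Closed ppm interval used to integrate one metabolite peak."""

    name: str
    center_ppm: float
    half_width_ppm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center_ppm) or not np.isfinite(self.half_width_ppm):
            raise ValueError(f"window {self.name!r}: non-finite bounds")
        if self.half_width_ppm <= 0:
            raise ValueError(
                f"window {self.name!r}: half_width_ppm must be > 0, "
                f"got {self.half_width_ppm}"
            )

    @property
    def lo(self) -> float:
        return self.center_ppm - self.half_width_ppm

    @property
    def hi(self) -> float:
        return self.center_ppm + self.half_width_ppm


@dataclass
class DynamicSpectrumSeries:
    """Time series of complex spectra on a shared ppm axis.

    ``spectra`` has shape (n_time, n_freq); ``times`` are the excitation
    times in seconds, strictly increasing. ``schedule`` (when present) is
    the :class:`tmmspect.synthkit.AcquisitionSchedule` that produced the
    series, and ``cell_count`` the number of cells in the tube for
    per-cell normalization.
    """

    times: np.ndarray
    spectra: np.ndarray
    axis: PpmAxis
    schedule: Optional[object] = None
    cell_count: Optional[int] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.spectra = np.asarray(self.spectra, dtype=complex)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (n_time, n_freq)")
        if self.spectra.shape[0] != self.times.size:
            raise ValueError(
                f"{self.spectra.shape[0]} spectra for {self.times.size} times"
            )
        if self.spectra.shape[1] != self.axis.n_points:
            raise ValueError("spectral width does not match axis")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(
            np.isfinite(self.spectra.view(float))
        ):
            raise ValueError("non-finite values in series")

    @property
    def n_time(self) -> int:
        return int(self.times.size)


def ppm_axis(n_points: int, bandwidth_ppm: float, center_ppm: float) -> PpmAxis:
    """Build a uniform descending ppm axis of bin centers.

    Bin *i* (i = 0 the most downfield) is centered at
    ``center + bandwidth/2 - (i + 1/2) * spacing``, so the axis spans
    exactly ``bandwidth_ppm`` and its mean is ``center_ppm``.
    """
    if n_points < 2:
        raise ValueError(f"n_points must be >= 2, got {n_points}")
    if not bandwidth_ppm > 0:
        raise ValueError(f"bandwidth_ppm must be > 0, got {bandwidth_ppm}")
    spacing = bandwidth_ppm / n_points
    values = center_ppm + bandwidth_ppm / 2.0 - (np.arange(n_points) + 0.5) * spacing
    return PpmAxis(int(n_points), float(bandwidth_ppm), float(center_ppm), values)


def window_mask(axis: PpmAxis, window: MetaboliteWindow) -> np.ndarray:
    """Boolean mask of bins whose center lies in the closed window interval."""
    if not axis.contains(window.lo, window.hi):
        raise ValueError(
            f"window {window.name!r} [{window.lo}, {window.hi}] outside axis "
            f"[{axis.ppm_min}, {axis.ppm_max}]"
        )
    return (axis.values >= window.lo) & (axis.values <= window.hi)


def integrate_window(
    spectrum: np.ndarray,
    axis: PpmAxis,
    window: MetaboliteWindow,
    mode: Literal["real", "magnitude"] = "real",
) -> float:
    """Riemann-sum peak integral over a metabolite window.

    ``mode="real"`` sums the real part (signed; phased absorption spectra);
    ``mode="magnitude"`` sums |value| per bin. Either sum is multiplied by
    the bin spacing so the result approximates the continuous peak area.
    """
    spectrum = np.asarray(spectrum)
    if spectrum.shape != (axis.n_points,):
        raise ValueError("spectrum length does not match axis")
    mask = window_mask(axis, window)
    n_bins = int(mask.sum())
    if n_bins == 0:
        raise ValueError(
            f"window {window.name!r} covers 0 bins on this axis "
            f"(spacing {axis.spacing} ppm)"
        )
    if mode == "real":
        vals = spectrum.real[mask]
    elif mode == "magnitude":
        vals = np.abs(spectrum[mask])
    else:
        raise ValueError(f"mode must be 'real' or 'magnitude', got {mode!r}")
    return float(vals.sum() * axis.spacing)


def estimate_noise(values: Sequence[complex] | np.ndarray) -> float:
    """Noise sigma: sample standard deviation (ddof=1) of the real part.

    ``values`` are samples from a designated signal-free region — in vivo,
    a voxel outside the brain across frequency and time.
    """
    values = np.asarray(values).ravel()
    if values.size < 2:
        raise ValueError(f"need >= 2 samples to estimate noise, got {values.size}")
    real = np.real(values).astype(float)
    if not np.all(np.isfinite(real)):
        raise ValueError("non-finite samples in noise region")
    return float(np.std(real, ddof=1))


def snr(
    spectrum: np.ndarray,
    axis: PpmAxis,
    window: MetaboliteWindow,
    sigma: float,
) -> float:
    """Peak SNR: maximum magnitude within the window divided by sigma."""
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    spectrum = np.asarray(spectrum)
    mask = window_mask(axis, window)
    if not mask.any():
        raise ValueError(f"window {window.name!r} covers 0 bins")
    return float(np.abs(spectrum[mask]).max() / sigma)


def sum_spectra(series: DynamicSpectrumSeries) -> np.ndarray:
    """Elementwise complex sum of the spectral array over time.

    The summed spectrum is the basis for the pyruvate/alanine and
    lactate/alanine ratios of the live-cell analysis.
    """
    if series.n_time == 0:
        raise ValueError("empty series")
    return series.spectra.sum(axis=0)
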