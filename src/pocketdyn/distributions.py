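"""Normalized fixed-resolution distributions of structural descriptors.

Equilibrium structure is summarised by unit-area histograms at fixed,
kind-specific resolutions — 0.02 Å for proton-wire O–O distances, 2.00°
for angles/torsions, 1 Å³ for the cavity volume — optionally smoothed with
a centered moving average, followed by peak location to read off the
preferred arrangements (e.g., the bimodal Tyr66–water distance of the
anionic chromophore forms).

"Normalized" means unit area (∫ρ = 1), the standard probability-density
convention, so curves at different bin widths are directly comparable.
Bin edges are anchored at 0.0 by default so reported bin centers do not
depend on the sampled range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trajectory import TimeSeries

__all__ = [
    "Histogram",
    "PeakList",
    "DistributionError",
    "DEFAULT_RESOLUTIONS",
    "histogram",
    "smooth",
    "find_peaks",
    "histogram_peaks",
]

#: Default bin widths per descriptor kind / unit.
DEFAULT_RESOLUTIONS = {"A": 0.02, "deg": 2.00, "A^3": 1.0}


class DistributionError(ValueError):
    """Invalid histogram/smoothing/peak parameters."""


@dataclass(frozen=True)
class Histogram:
    """Left-closed right-open bins (last bin closed) of constant width."""

    bin_edges: np.ndarray
    density: np.ndarray
    resolution: float
    n_samples: int
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if np.any(widths <= 0):
            raise DistributionError("bin edges must be strictly increasing")
        if np.max(np.abs(widths - self.resolution)) > 1e-12:
            raise DistributionError("bins must have constant width = resolution")
        area = float(np.sum(self.density * widths))
        if abs(area - 1.0) > 1e-9:
            raise DistributionError(f"density area {area} != 1")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.density)


@dataclass(frozen=True)
class PeakList:
    """Peaks of a density curve, ordered by height descending."""

    locations: np.ndarray  # bin centers (series units)
    heights: np.ndarray    # density at the peak

    def __len__(self) -> int:
        return len(self.locations)


def histogram(ts: TimeSeries | np.ndarray, resolution: float,
              anchor: float = 0.0, name: str = "",
              units: str = "") -> Histogram:
    """Unit-area histogram with bin edges at anchor + k·resolution.

    The edge grid is the integer lattice of the resolution, covering
    [min, max] of the data; bins are left-closed, right-open, with the last
    bin closed (so the maximum sample is always counted).
    """
    if isinstance(ts, TimeSeries):
        values = ts.values
        name = name or ts.name
        units = units or ts.units
    else:
        values = np.asarray(ts, dtype=float)
    if values.size == 0:
        raise DistributionError("cannot histogram an empty series")
    if not resolution > 0:
        raise DistributionError(f"resolution must be positive, got {resolution}")
    k0 = int(np.floor((values.min() - anchor) / resolution))
    k1 = int(np.floor((values.max() - anchor) / resolution)) + 1
    edges = anchor + np.arange(k0, k1 + 1) * resolution
    counts, _ = np.histogram(values, bins=edges)
    density = counts / (values.size * resolution)
    return Histogram(bin_edges=edges, density=density, resolution=resolution,
                     n_samples=values.size, name=name, units=units)


def smooth(hist: Histogram | np.ndarray, window: int = 15) -> np.ndarray:
    """Centered moving average of the density curve over ``window`` bins.

    Edge bins average over the truncated window that fits inside the curve;
    the output has the same length as the input.  ``window`` must be odd,
    positive, and no larger than the number of bins.
    """
    density = hist.density if isinstance(hist, Histogram) else np.asarray(hist, float)
    n = density.size
    if window < 1 or window % 2 == 0:
        raise DistributionError(f"window must be odd and positive, got {window}")
    if window > n:
        raise DistributionError(f"window {window} exceeds bin count {n}")
    kernel = np.ones(window)
    sums = np.convolve(density, kernel, mode="same")
    norm = np.convolve(np.ones(n), kernel, mode="same")
    return sums / norm


def find_peaks(density: np.ndarray, bin_centers: np.ndarray | None = None,
               min_separation: int = 5,
               min_height_fraction: float = 0.1) -> PeakList:
    """Strict local maxima of a density curve, filtered and ordered.

    Peaks below ``min_height_fraction`` × (global max) are dropped; of any
    pair closer than ``min_separation`` bins, the higher wins.  Endpoints
    of monotone curves are never peaks (the list may be empty).
    """
    density = np.asarray(density, dtype=float)
    if density.size == 0:
        raise DistributionError("empty density curve")
    floor = min_height_fraction * density.max() if density.max() > 0 else None
    idx, _ = signal.find_peaks(density, height=floor,
                               distance=max(int(min_separation), 1))
    order = np.argsort(density[idx])[::-1]
    idx = idx[order]
    loc = bin_centers[idx] if bin_centers is not None else idx.astype(float)
    return PeakList(locations=np.asarray(loc, dtype=float),
                    heights=density[idx])


def histogram_peaks(hist: Histogram, smooth_window: int | None = None,
                    min_separation: int = 5,
                    min_height_fraction: float = 0.1) -> PeakList:
    """Peaks of a histogram, optionally after moving-average smoothing."""
    curve = smooth(hist, smooth_window) if smooth_window else hist.density
    return find_peaks(curve, bin_centers=hist.bin_centers,
                      min_separation=min_separation,
                      min_height_fraction=min_height_fraction)
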