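"""Circular torsion-angle distributions: 5-degree histograms, wrapped-Gaussian
KDE smoothing, and Pearson r^2 comparison between density profiles.

The KDE is circular: each observation contributes a Gaussian kernel plus its
periodic images at +-360k degrees (truncated at 3 images), so densities are
seam-correct at 0/360.  Profiles are normalized so the periodic trapezoidal
integral over [0, 360) equals one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TorsionHistogram",
    "DensityProfile",
    "build_histogram",
    "kde_profile",
    "kde_r2",
    "summarize_correlations",
]

N_WRAP = 3  # periodic images summed on each side


@dataclass(frozen=True)
class TorsionHistogram:
    """Binned circular torsion counts with half-open bins [b*step, (b+1)*step)."""

    counts: np.ndarray
    step: float = 5.0
    pattern_id: int = -1

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def edges(self) -> np.ndarray:
        return np.arange(0.0, 360.0 + self.step, self.step)

    @property
    def centers(self) -> np.ndarray:
        return np.arange(self.step / 2.0, 360.0, self.step)

    @property
    def probabilities(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("empty histogram has no probabilities")
        return self.counts / self.n


@dataclass(frozen=True)
class DensityProfile:
    """Continuous circular density on a regular grid over [0, 360)."""

    grid: np.ndarray
    density: np.ndarray

    def __post_init__(self):
        if self.grid.shape != self.density.shape:
            raise ValueError("grid/density length mismatch")

    @property
    def step(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def integral(self) -> float:
        # periodic trapezoid == rectangle rule on a wrap-around grid
        return float(self.density.sum() * self.step)

    def at(self, angles) -> np.ndarray:
        """Density linearly interpolated at arbitrary angles (periodic)."""
        angles = np.asarray(angles, dtype=float) % 360.0
        gx = np.append(self.grid, 360.0)
        gy = np.append(self.density, self.density[0])
        return np.interp(angles, gx, gy)


def build_histogram(angles, step: float = 5.0, pattern_id: int = -1) -> TorsionHistogram:
    """Bin angles (degrees, [0, 360)) into 360/step half-open bins."""
    if step <= 0 or abs(360.0 / step - round(360.0 / step)) > 1e-12:
        raise ValueError("step must divide 360")
    angles = np.asarray(angles, dtype=float)
    if angles.size and (angles.min() < 0.0 or angles.max() >= 360.0):
        raise ValueError("angles must lie in [0, 360)")
    nbins = int(round(360.0 / step))
    counts, _ = np.histogram(angles, bins=nbins, range=(0.0, 360.0))
    return TorsionHistogram(counts=counts, step=step, pattern_id=pattern_id)


def kde_profile(angles, bandwidth: float = 5.0, grid_step: float = 1.0) -> DensityProfile:
    """Wrapped-Gaussian kernel density estimate on a regular grid.

    Each angle contributes a Gaussian of width ``bandwidth`` (degrees) summed
    over periodic images at +-360k, k <= 3.  The result is normalized to unit
    periodic integral.
    """
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if angles.size == 0:
        raise ValueError("KDE requires at least one observation")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.arange(0.0, 360.0, grid_step)
    dens = np.zeros_like(grid)
    # chunk over observations to bound memory at large n
    chunk = max(1, int(2e6 // grid.size))
    for lo in range(0, angles.size, chunk):
        d = grid[None, :] - angles[lo:lo + chunk, None] % 360.0
        acc = np.zeros_like(d)
        for k in range(-N_WRAP, N_WRAP + 1):
            acc += np.exp(-0.5 * ((d + 360.0 * k) / bandwidth) ** 2)
        dens += acc.sum(axis=0)
    dens /= angles.size * bandwidth * np.sqrt(2.0 * np.pi)
    dens /= dens.sum() * grid_step  # enforce unit periodic integral
    return DensityProfile(grid=grid, density=dens)


def kde_r2(profile_a: DensityProfile, profile_b: DensityProfile) -> float:
    """Squared Pearson correlation between two densities on a shared grid."""
    if profile_a.grid.shape != profile_b.grid.shape or not np.allclose(
        profile_a.grid, profile_b.grid
    ):
        raise ValueError("profiles must share a grid")
    a, b = profile_a.density, profile_b.density
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        raise ValueError("constant density: correlation undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def summarize_correlations(pairs, high: float = 0.8, low: float = 0.2) -> dict:
    """Summarise per-pattern (pattern_id, r2, support) correlation triples.

    Returns the median r2, the number of patterns above ``high``, and the
    median support (observation count) of the patterns below ``low`` —
    the diagnostics used to judge whether poorly correlated patterns are
    simply data-starved.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no correlation records")
    r2 = np.array([p[1] for p in pairs], dtype=float)
    support = np.array([p[2] for p in pairs], dtype=float)
    low_support = support[r2 < low]
    return {
        "median_r2": float(np.median(r2)),
        "n_above_high": int((r2 > high).sum()),
        "median_support_low_r2": float(np.median(low_support)) if low_support.size else float("nan"),
    }
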