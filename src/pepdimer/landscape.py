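"""Ensemble-level descriptive statistics.

Ring-orientation histograms (41 bin centers spanning 0–180° in 4.5° steps)
with the same-side (<90°) fraction, the end-to-end-distance vs
radius-of-gyration landscape in nm, basin detection on the gridded density,
and placement of cluster representatives on the landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .clustering import ClusterResult
from .geometry import (
    end_to_end_distance,
    radius_of_gyration,
    ring_orientation_angle,
)
from .trajectory import DimerSpec, Trajectory, chain_indices

__all__ = [
    "AngleHistogram",
    "LandscapeGrid",
    "Basin",
    "ring_angle_series",
    "angle_histogram",
    "fraction_same_side",
    "shape_series",
    "density_grid",
    "find_basins",
    "place_representatives",
]


@dataclass
class AngleHistogram:
    bin_centers: np.ndarray  # degrees, 0, 4.5, ..., 180
    percent: np.ndarray  # % of frames per bin, sums to 100
    n_frames: int


@dataclass
class LandscapeGrid:
    x_edges: np.ndarray  # D_N-C, nm
    y_edges: np.ndarray  # R_g, nm
    density: np.ndarray  # counts per cell, shape (nx, ny)

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class Basin:
    center: tuple[float, float]  # (D_N-C nm, R_g nm) of the peak cell
    population: float  # % of frames assigned to this basin
    peak_density: float  # raw counts in the peak cell


def ring_angle_series(
    traj: Trajectory, spec: DimerSpec, chain: str
) -> np.ndarray:
    """Ring-orientation angle (degrees) for every frame."""
    return np.array(
        [
            ring_orientation_angle(traj.coords[f], traj.topology, spec, chain)
            for f in range(traj.n_frames)
        ]
    )


def angle_histogram(series: np.ndarray, n_bins: int = 41) -> AngleHistogram:
    """Histogram over ``n_bins`` bin centers spanning [0°, 180°].

    With 41 centers the spacing is 4.5°; a value is assigned to its nearest
    center, exact midpoints deterministically to the lower center.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty angle series")
    if np.any((series < 0) | (series > 180)):
        raise ValueError("angles must lie in [0, 180] degrees")
    width = 180.0 / (n_bins - 1)
    centers = np.arange(n_bins) * width
    idx = np.ceil(series / width - 0.5).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    return AngleHistogram(
        bin_centers=centers,
        percent=100.0 * counts / series.size,
        n_frames=series.size,
    )


def fraction_same_side(series: np.ndarray) -> float:
    """Percent of frames with ring angle strictly below 90° (both aromatic
    rings on the same side of the peptide); 90° itself counts as opposite."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty angle series")
    return float(100.0 * np.mean(series < 90.0))


def shape_series(
    traj: Trajectory, spec: DimerSpec, chain: str
) -> np.ndarray:
    """(D_N-C, R_g) pairs in nm, one row per frame."""
    idx = chain_indices(traj.topology, chain)
    masses = traj.masses()[idx]
    out = np.empty((traj.n_frames, 2))
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        out[f, 0] = end_to_end_distance(coords, traj.topology, spec, chain) / 10.0
        out[f, 1] = radius_of_gyration(coords[idx], masses) / 10.0
    return out


def density_grid(
    series: np.ndarray, x_bin: float = 0.05, y_bin: float = 0.025
) -> LandscapeGrid:
    """2D count histogram over the data range padded one bin on each side,
    with half-open cells [lo, hi)."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty shape series")
    x, y = series[:, 0], series[:, 1]

    def _edges(v: np.ndarray, width: float) -> np.ndarray:
        lo = np.floor(v.min() / width) - 1
        hi = np.floor(v.max() / width) + 2
        return np.arange(lo, hi + 1) * width

    xe = _edges(x, x_bin)
    ye = _edges(y, y_bin)
    ix = np.floor(x / x_bin).astype(int) - int(np.floor(x.min() / x_bin) - 1)
    iy = np.floor(y / y_bin).astype(int) - int(np.floor(y.min() / y_bin) - 1)
    density = np.zeros((len(xe) - 1, len(ye) - 1))
    np.add.at(density, (ix, iy), 1.0)
    return LandscapeGrid(x_edges=xe, y_edges=ye, density=density)


def find_basins(
    grid: LandscapeGrid, min_separation: int = 2, min_population: float = 5.0
) -> list[Basin]:
    """Local maxima of the 3×3-mean-smoothed density, merged when closer
    than ``min_separation`` cells, with population from nearest-peak
    assignment of all grid mass; basins below ``min_population`` % dropped.
    """
    dens = grid.density
    total = dens.sum()
    if total <= 0:
        return []
    smooth = ndimage.uniform_filter(dens, size=3, mode="constant")
    local_max = (
        (smooth == ndimage.maximum_filter(smooth, size=3, mode="constant"))
        & (smooth > 0)
    )
    peaks = np.argwhere(local_max)
    # merge peaks closer than min_separation (Chebyshev) into the higher one
    order = np.argsort(-smooth[tuple(peaks.T)], kind="stable")
    kept: list[np.ndarray] = []
    for k in order:
        p = peaks[k]
        if all(np.max(np.abs(p - q)) >= min_separation for q in kept):
            kept.append(p)
    if not kept:
        return []
    kept_arr = np.array(kept)
    # assign every occupied cell to its nearest kept peak (Euclidean, cells)
    occ = np.argwhere(dens > 0)
    d2 = np.sum(
        (occ[:, None, :].astype(float) - kept_arr[None, :, :]) ** 2, axis=2
    )
    nearest = np.argmin(d2, axis=1)
    basins = []
    for b, p in enumerate(kept_arr):
        mass = dens[tuple(occ[nearest == b].T)].sum() if occ.size else 0.0
        pop = 100.0 * mass / total
        if pop >= min_population:
            basins.append(
                Basin(
                    center=(
                        float(grid.x_centers[p[0]]),
                        float(grid.y_centers[p[1]]),
                    ),
                    population=float(pop),
                    peak_density=float(dens[p[0], p[1]]),
                )
            )
    basins.sort(key=lambda b: -b.population)
    return basins


def place_representatives(
    series: np.ndarray, cluster_result: ClusterResult
) -> np.ndarray:
    """(D_N-C, R_g) pair of each cluster's representative frame."""
    reps = cluster_result.representatives
    if np.any(reps < 0) or np.any(reps >= len(series)):
        raise IndexError("representative frame index outside the series")
    return np.asarray(series)[reps]
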