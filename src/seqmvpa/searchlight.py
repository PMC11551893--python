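"""ROI-constrained volumetric searchlight mapping.

A searchlight is built for every in-mask voxel: its members are the in-mask
voxels sorted by physical (mm) distance from the center — ties broken by
lexicographic coordinate offset — truncated at whichever binds first of the
member-count cap (default 160 voxels) and the maximum radius (default 6 mm in
native space).  At 2 mm isotropic resolution the 6 mm radius admits at most
123 lattice voxels, so there the radius cap binds; both parameters are
configurable.  An analysis statistic computed on each searchlight's voxels is
assigned to the center voxel, yielding a volumetric map; per-subject maps are
combined by a voxelwise one-sample t-test with 26-connected suprathreshold
cluster extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .datasets import PatternDataset, VolumeMask

logger = logging.getLogger(__name__)

#: default suprathreshold cut: t(23) upper 0.001 quantile, as used for n=24
DEFAULT_T_THRESHOLD = 3.48


@dataclass(frozen=True)
class SearchlightSpec:
    """One searchlight: center voxel, member voxels, realized radius."""

    center: tuple[int, int, int]
    members: np.ndarray  # (n_members, 3) int
    radius_used_mm: float

    @property
    def n_members(self) -> int:
        return len(self.members)


def _sorted_offsets(
    voxel_size_mm: Sequence[float], max_radius_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel offsets within the radius, sorted by (distance, lexicographic)."""
    vs = np.asarray(voxel_size_mm, dtype=float)
    reach = np.floor(max_radius_mm / vs).astype(int)
    axes = [np.arange(-r, r + 1) for r in reach]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.sqrt(((grid * vs) ** 2).sum(axis=1))
    keep = dist <= max_radius_mm + 1e-9
    grid, dist = grid[keep], dist[keep]
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], dist))
    return grid[order], dist[order]


def define_searchlights(
    mask: VolumeMask,
    target_size: int = 160,
    max_radius_mm: float = 6.0,
) -> list[SearchlightSpec]:
    """One searchlight per in-mask voxel under size and radius caps."""
    if target_size < 1:
        raise ValueError("target_size must be a positive integer")
    if max_radius_mm <= 0:
        raise ValueError("max_radius_mm must be strictly positive")
    offsets, dists = _sorted_offsets(mask.voxel_size_mm, max_radius_mm)
    shape = np.asarray(mask.grid.shape)
    specs = []
    for center in mask.coordinates():
        cand = center + offsets
        inside = np.all((cand >= 0) & (cand < shape), axis=1)
        cand, d = cand[inside], dists[inside]
        in_mask = mask.grid[cand[:, 0], cand[:, 1], cand[:, 2]]
        members, d = cand[in_mask], d[in_mask]
        members, d = members[:target_size], d[:target_size]
        specs.append(
            SearchlightSpec(
                center=tuple(int(c) for c in center),
                members=members,
                radius_used_mm=float(d[-1]) if len(d) else 0.0,
            )
        )
    return specs


def run_searchlight(
    ds: PatternDataset,
    mask: VolumeMask,
    searchlights: Sequence[SearchlightSpec],
    analysis_fn: Callable[[PatternDataset], float],
) -> np.ndarray:
    """Map ``analysis_fn`` over searchlights; values land at center voxels.

    ``ds`` must be volumetric (``voxel_coordinates`` set) and cover the mask.
    Voxels outside the mask — and searchlights whose analysis fails — carry
    NaN.
    """
    if ds.voxel_coordinates is None:
        raise ValueError("dataset must carry voxel_coordinates")
    col_grid = np.full(mask.grid.shape, -1, dtype=int)
    col_grid[tuple(ds.voxel_coordinates.T)] = np.arange(ds.n_voxels)
    out = np.full(mask.grid.shape, np.nan)
    for spec in searchlights:
        cols = col_grid[tuple(spec.members.T)]
        if np.any(cols < 0):
            logger.warning("searchlight at %s has voxels without data", spec.center)
            continue
        try:
            out[spec.center] = float(analysis_fn(ds.restrict_voxels(cols)))
        except Exception:  # noqa: BLE001 - record and continue
            logger.warning(
                "analysis failed for searchlight at %s", spec.center, exc_info=True
            )
    return out


@dataclass(frozen=True)
class Cluster:
    size: int
    peak_t: float
    peak_voxel: tuple[int, int, int]


def group_t_map(
    maps: Sequence[np.ndarray],
    mu: float = 0.0,
    t_threshold: float = DEFAULT_T_THRESHOLD,
) -> tuple[np.ndarray, list[Cluster]]:
    """Voxelwise one-sample t against ``mu`` with suprathreshold clusters.

    Suprathreshold voxels (t > threshold, one-tailed) are grouped into
    26-connected clusters; cluster extents and peaks are returned sorted by
    extent.  Cluster-level corrected p values are deliberately not computed.
    """
    if len(maps) < 2:
        raise ValueError("need at least two subject maps")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError("subject maps are not aligned on the same grid")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    valid = np.all(np.isfinite(stack), axis=0)
    n = stack.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0, ddof=1)
        t = (mean - mu) / (sd / np.sqrt(n))
    t[~valid] = np.nan
    t[valid & (sd == 0)] = np.nan

    supra = np.zeros_like(t, dtype=bool)
    finite = np.isfinite(t)
    supra[finite] = t[finite] > t_threshold
    labels, n_clusters = ndimage.label(supra, structure=np.ones((3, 3, 3)))
    clusters = []
    for c in range(1, n_clusters + 1):
        voxels = np.argwhere(labels == c)
        ts = t[tuple(voxels.T)]
        peak = voxels[int(np.argmax(ts))]
        clusters.append(
            Cluster(
                size=len(voxels),
                peak_t=float(ts.max()),
                peak_voxel=tuple(int(v) for v in peak),
            )
        )
    clusters.sort(key=lambda cl: cl.size, reverse=True)
    return t, clusters
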