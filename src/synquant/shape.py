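"""Cell-shape standardization onto a canonical half spheroid.

Each T cell is rigidly reoriented so the T cell:APC interface faces "up"
(single-landmark alignment of the interface center plus alignment of the
interface normal with the depth axis), then morphed onto a fixed
half-spheroid voxel grid: every cell voxel is addressed by its relative
depth behind the interface, its relative radial position within the cell
cross-section at that depth, and its azimuth.  The standardized sensor
distribution is normalized to sum 1, which makes voxel-by-voxel averaging
and ratio statistics comparable across all cell couples of a cohort.

Two enrichment statistics are computed on the template grid: the ratio of
the mean probability inside the *interface enrichment region* (the 10%
most fluorescent voxels of the cohort-average distribution) to the mean
over the whole cell, and the same ratio for a *central core* cylinder of
relative radius and depth 0.5 anchored at the interface center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import ShapeParams
from .tracking import InterfaceGeometry, _plane_basis


@dataclass
class ReorientedCell:
    """A cell resampled on an isotropic grid with the interface on top.

    ``origin`` is the (z, y, x) index of the interface center; axis 0
    points into the cell (increasing depth).
    """

    mask: np.ndarray
    volume: np.ndarray
    spacing: float
    origin: np.ndarray


@dataclass
class StandardizedMap:
    """Sensor probability distribution on the half-spheroid template.

    ``values`` sum to 1 over the ``support`` voxels and are zero outside.
    """

    values: np.ndarray
    support: np.ndarray

    def __post_init__(self) -> None:
        total = float(self.values[self.support].sum())
        if total <= 0:
            raise ValueError("standardized map has no mass")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("standardized map must sum to 1")


@dataclass
class EnrichmentRegion:
    """Boolean template mask marking the top decile of the average map."""

    mask: np.ndarray
    fraction: float


def template_support(grid: tuple[int, int, int]) -> np.ndarray:
    """Half-spheroid support on the (depth, y, x) template grid."""
    d, h, w = grid
    radius = (min(h, w) - 1) / 2.0
    c = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    k = np.arange(d)[:, None, None]
    rho = (k + 0.5) / d
    r_t = radius * np.sqrt(np.clip(1.0 - rho**2, 0.0, None))
    jj = np.arange(h)[None, :, None]
    ii = np.arange(w)[None, None, :]
    rr = np.hypot(jj - c[0], ii - c[1])
    return rr <= r_t


def reorient_interface_up(
    tcell_mask: np.ndarray,
    volume: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: ShapeParams | None = None,
) -> ReorientedCell:
    """Rigidly rotate/resample the cell so the interface normal is "up".

    The interface center maps to a fixed reference point near the top of
    an isotropic output grid and the normal to the depth axis; intensities
    are resampled by trilinear interpolation.  When the input is already
    upright on a matching isotropic grid the identity fast path returns
    the input voxel-for-voxel.

    Raises
    ------
    ValueError
        For a degenerate (zero) interface normal.
    """
    params = params or ShapeParams()
    n = np.asarray(interface.normal, float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("degenerate interface normal")
    n = n / norm
    s = params.iso_spacing_um
    sp = np.asarray(spacing, float)

    upright = np.allclose(n, [1.0, 0.0, 0.0], atol=1e-6)
    if upright and np.allclose(sp, s, atol=1e-9):
        return ReorientedCell(
            mask=tcell_mask,
            volume=volume,
            spacing=s,
            origin=interface.center / s,
        )

    # physical extent of the cell around the interface center
    vox = np.argwhere(tcell_mask)
    if len(vox) == 0:
        raise ValueError("empty mask")
    rel = vox * sp - interface.center
    reach = float(np.sqrt((rel**2).sum(axis=1)).max()) + 2 * s
    pad = 2  # voxels of margin above the interface
    n_depth = int(np.ceil(reach / s)) + pad + 1
    n_lat = 2 * int(np.ceil(reach / s)) + 3
    c_lat = (n_lat - 1) // 2
    origin = np.array([float(pad), float(c_lat), float(c_lat)])

    u, v = _plane_basis(n)
    dz = (np.arange(n_depth) - origin[0])[:, None, None] * s
    dy = (np.arange(n_lat) - origin[1])[None, :, None] * s
    dx = (np.arange(n_lat) - origin[2])[None, None, :] * s
    # physical point = center + depth*n + a*u + b*v
    p = (
        interface.center[None, None, None, :]
        + dz[..., None] * n
        + dy[..., None] * u
        + dx[..., None] * v
    )
    idx = np.moveaxis(p / sp, -1, 0)
    vol_out = ndi.map_coordinates(
        np.asarray(volume, float), idx, order=1, cval=0.0
    )
    mask_out = (
        ndi.map_coordinates(tcell_mask.astype(float), idx, order=1, cval=0.0)
        > 0.5
    )
    return ReorientedCell(mask=mask_out, volume=vol_out, spacing=s,
                          origin=origin)


def _slice_boundary_table(mask, n_bins=72):
    """Per z-plane centroid and per-azimuth boundary radius (index units)."""
    nz = mask.shape[0]
    centroids = np.full((nz, 2), np.nan)
    rmax = np.zeros((nz, n_bins))
    valid = np.zeros(nz, bool)
    for iz in range(nz):
        pts = np.argwhere(mask[iz])
        if len(pts) == 0:
            continue
        c = pts.mean(axis=0)
        d = pts - c
        r = np.hypot(d[:, 0], d[:, 1])
        theta = np.arctan2(d[:, 0], d[:, 1])
        bins = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
        table = np.zeros(n_bins)
        np.maximum.at(table, bins, r)
        empty = table == 0
        if empty.all():
            table[:] = 0.5
        elif empty.any():
            # circular nearest-fill for azimuth bins with no boundary voxel
            filled = np.flatnonzero(~empty)
            for b in np.flatnonzero(empty):
                gap = np.minimum(
                    np.abs(filled - b), n_bins - np.abs(filled - b)
                )
                table[b] = table[filled[np.argmin(gap)]]
        centroids[iz] = c
        rmax[iz] = table
        valid[iz] = True
    return centroids, rmax, valid


def standardize_half_spheroid(
    cell: ReorientedCell,
    params: ShapeParams | None = None,
) -> StandardizedMap:
    """Morph a reoriented cell onto the half-spheroid template.

    Template voxel (relative depth, relative radius, azimuth) is sampled
    from the matching relative coordinate of the cell: depth scaled by the
    cell's depth extent, radius by the cross-section boundary at that
    depth and azimuth.  Outside-mask voxels are filled with their nearest
    in-mask intensity before sampling so that boundary voxels do not dilute
    the map; the result is normalized to sum 1.

    Raises
    ------
    ValueError
        For an empty mask.
    """
    params = params or ShapeParams()
    mask, vol = cell.mask, np.clip(np.asarray(cell.volume, float), 0, None)
    if not mask.any():
        raise ValueError("empty mask")
    oz = cell.origin[0]

    # nearest-inside fill
    idx = ndi.distance_transform_edt(~mask, return_indices=True)[1]
    vol_filled = vol[tuple(idx)]

    n_bins = 72
    centroids, rtable, valid = _slice_boundary_table(mask, n_bins)
    vz = np.flatnonzero(valid)
    zmin, zmax = vz.min(), vz.max()
    dmax = max(zmax - oz, 1.0)  # depth extent in voxels

    grid = params.grid
    support = template_support(grid)
    d, h, w = grid
    radius = (min(h, w) - 1) / 2.0
    cj, ci = (h - 1) / 2.0, (w - 1) / 2.0

    kk, jj, ii = np.nonzero(support)
    rho = (kk + 0.5) / d
    r_t = radius * np.sqrt(np.clip(1.0 - rho**2, 1e-12, None))
    dj = jj - cj
    di = ii - ci
    rr = np.hypot(dj, di)
    rel_r = np.clip(rr / r_t, 0.0, 1.0)
    theta = np.arctan2(dj, di)

    zf = oz + rho * dmax
    iz_n = np.clip(np.round(zf).astype(int), zmin, zmax)
    # snap to the nearest valid plane
    if not valid[iz_n].all():
        lut = vz[np.argmin(np.abs(vz[None, :] -
                                  np.arange(mask.shape[0])[:, None]), axis=1)]
        iz_n = lut[iz_n]
    tb = ((theta + np.pi) / (2 * np.pi) * n_bins).astype(int) % n_bins
    r_src = rel_r * np.maximum(rtable[iz_n, tb] - 0.5, 0.25)
    safe_rr = np.where(rr == 0, 1.0, rr)
    yf = centroids[iz_n, 0] + r_src * dj / safe_rr
    xf = centroids[iz_n, 1] + r_src * di / safe_rr

    samples = ndi.map_coordinates(
        vol_filled, np.stack([zf, yf, xf]), order=1, mode="nearest"
    )
    values = np.zeros(grid, float)
    values[kk, jj, ii] = np.clip(samples, 0.0, None)
    total = values.sum()
    if total <= 0:
        raise ValueError("standardized map has no mass")
    values /= total
    return StandardizedMap(values=values, support=support)


def standardize_couple(
    volume: np.ndarray,
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: ShapeParams | None = None,
) -> StandardizedMap:
    """Reorient and standardize one frame in a single call."""
    params = params or ShapeParams()
    cell = reorient_interface_up(tcell_mask, volume, interface, spacing,
                                 params)
    return standardize_half_spheroid(cell, params)


def build_enrichment_region(
    maps: list[StandardizedMap],
    params: ShapeParams | None = None,
) -> EnrichmentRegion:
    """Top-decile voxels of the cohort-average standardized distribution.

    Ties at the cutoff are broken by fixed grid order, so the region size
    is exactly ``round(fraction * support size)``.

    Raises
    ------
    ValueError
        For an empty cohort.
    """
    params = params or ShapeParams()
    if not maps:
        raise ValueError("empty cohort")
    support = maps[0].support
    for m in maps[1:]:
        if m.support.shape != support.shape:
            raise ValueError("maps must share one template grid")
    avg = np.mean([m.values for m in maps], axis=0)
    flat = avg[support]
    n_region = int(round(params.region_fraction * flat.size))
    order = np.argsort(-flat, kind="stable")[:n_region]
    mask = np.zeros_like(support)
    sup_idx = np.argwhere(support)
    chosen = sup_idx[order]
    mask[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = True
    return EnrichmentRegion(mask=mask, fraction=params.region_fraction)


def enrichment_ratio(smap: StandardizedMap, region: EnrichmentRegion) -> float:
    """Mean probability in the enrichment region over the whole-cell mean."""
    return float(
        smap.values[region.mask].mean() / smap.values[smap.support].mean()
    )


def core_cylinder_mask(
    grid: tuple[int, int, int],
    params: ShapeParams | None = None,
) -> np.ndarray:
    """Central-core cylinder (relative radius and depth 0.5) on the grid."""
    params = params or ShapeParams()
    d, h, w = grid
    radius = (min(h, w) - 1) / 2.0
    cj, ci = (h - 1) / 2.0, (w - 1) / 2.0
    k = np.arange(d)[:, None, None]
    jj = np.arange(h)[None, :, None]
    ii = np.arange(w)[None, None, :]
    rr = np.hypot(jj - cj, ii - ci)
    core = (rr <= params.core_rel_radius * radius) & (
        (k + 0.5) / d <= params.core_rel_depth
    )
    return core & template_support(grid)


def central_core_ratio(
    smap: StandardizedMap,
    params: ShapeParams | None = None,
) -> float:
    """Mean probability in the central core over the whole-cell mean."""
    params = params or ShapeParams()
    core = core_cylinder_mask(smap.values.shape, params)
    return float(
        smap.values[core].mean() / smap.values[smap.support].mean()
    )
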