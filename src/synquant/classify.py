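"""Interface enrichment measurement and six-pattern classification.

A frame's interface enrichment is the mean sensor intensity in the
interface shell (the contact set dilated one voxel into the T cell)
relative to the cellular background (T cell voxels excluding the shell and
the invagination search region, so a deep accumulation cannot mask
itself).  Interface enrichment below 35% of the background classifies the
frame as no accumulation; above it, geometric rules assign exactly one of
the six mutually exclusive patterns in fixed precedence

    invagination > central > peripheral > asymmetric > lamellal > diffuse

so depth-based structures, the key discriminator between a central
supramolecular cluster and the degradative invagination, are tested
first.  The quantitative geometric thresholds are re-derived defaults
(see :class:`synquant.config.ClassifierParams`), each a named parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .config import ClassifierParams, StatsParams
from .labels import PATTERNS
from .tracking import CoupleTrack, InterfaceGeometry, _plane_basis

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class EnrichmentMeasure:
    """Scalar interface enrichment of a frame.

    ``enrichment_fraction = interface_mean / background_mean - 1``; the
    35% rule compares this value against 0.35.
    """

    interface_mean: float
    background_mean: float

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be positive")

    @property
    def enrichment_fraction(self) -> float:
        return self.interface_mean / self.background_mean - 1.0


def interface_shell(
    tcell_mask: np.ndarray, interface: InterfaceGeometry
) -> np.ndarray:
    """Contact set dilated one voxel into the T cell."""
    contact = np.zeros(tcell_mask.shape, bool)
    vox = interface.voxels
    contact[vox[:, 0], vox[:, 1], vox[:, 2]] = True
    return ndi.binary_dilation(contact, structure=_STRUCT26) & tcell_mask


def _interface_coords(shape, spacing, interface):
    """Per-voxel depth behind the interface, in-plane radius and basis
    coordinates (all µm), for the whole volume."""
    sp = np.asarray(spacing, float)
    z = (np.arange(shape[0]) * sp[0])[:, None, None]
    y = (np.arange(shape[1]) * sp[1])[None, :, None]
    x = (np.arange(shape[2]) * sp[2])[None, None, :]
    n = interface.normal
    c = interface.center
    dz, dy, dx = z - c[0], y - c[1], x - c[2]
    depth = dz * n[0] + dy * n[1] + dx * n[2]
    # u, v are orthogonal to n, so in-plane components project directly
    u, v = _plane_basis(n)
    cu = dz * u[0] + dy * u[1] + dx * u[2]
    cv = dz * v[0] + dy * v[1] + dx * v[2]
    cu = np.broadcast_to(cu, shape).astype(float, copy=True)
    cv = np.broadcast_to(cv, shape).astype(float, copy=True)
    depth = np.broadcast_to(depth, shape).astype(float, copy=True)
    r = np.hypot(cu, cv)
    return depth, r, cu, cv


def measure_enrichment(
    volume: np.ndarray,
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: ClassifierParams | None = None,
) -> EnrichmentMeasure:
    """Mean shell intensity relative to the cellular background.

    The background excludes the shell and a cylindrical invagination
    search region under the interface center, so accumulations deep in the
    cell do not inflate their own reference.

    Raises
    ------
    ValueError
        If the interface is empty or the background region vanishes.
    """
    params = params or ClassifierParams()
    if interface is None or len(interface.voxels) == 0:
        raise ValueError("interface is empty")
    shell = interface_shell(tcell_mask, interface)
    depth, r, _, _ = _interface_coords(volume.shape, spacing, interface)
    search = (
        (r <= params.background_exclusion_radius_um)
        & (depth >= -1e-9)
        & (depth <= params.background_exclusion_depth_um)
    )
    background = tcell_mask & ~shell & ~search
    if not background.any():
        raise ValueError("empty background region")
    if not shell.any():
        raise ValueError("empty interface shell")
    return EnrichmentMeasure(
        interface_mean=float(volume[shell].mean()),
        background_mean=float(volume[background].mean()),
    )


def _angular_coverage_deg(theta_deg, mass, n_bins):
    """Angular span covered by the mass: 360 minus the largest empty gap."""
    bins = ((theta_deg + 180.0) / 360.0 * n_bins).astype(int) % n_bins
    per_bin = np.bincount(bins, weights=mass, minlength=n_bins)
    occupied = per_bin >= max(0.01 * mass.sum(), 1e-12)
    if not occupied.any():
        return 0.0
    if occupied.all():
        return 360.0
    # largest run of empty bins, circularly
    empty = ~occupied
    doubled = np.concatenate([empty, empty])
    best = run = 0
    for e in doubled:
        run = run + 1 if e else 0
        best = max(best, run)
    best = min(best, n_bins - 1)
    return 360.0 * (1.0 - best / n_bins)


def _robust_depth(depths: np.ndarray, params: ClassifierParams) -> float:
    """Depth of the k-th deepest voxel: a structure only "extends" to a
    depth where non-negligible volume lies, so a stray noise voxel cannot
    drag the depth statistic."""
    k = min(params.depth_min_voxels, depths.size)
    return float(np.sort(depths)[-k])


def _footprint_cells(cu, cv, cell_um):
    """Hash in-plane positions into 2D cells of roughly one pixel."""
    iu = np.round(cu / cell_um).astype(np.int64)
    iv = np.round(cv / cell_um).astype(np.int64)
    return iu * (1 << 21) + iv


def classify_frame(
    volume: np.ndarray,
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    enrichment: EnrichmentMeasure,
    spacing: tuple[float, float, float],
    params: ClassifierParams | None = None,
) -> str:
    """Assign one of the seven pattern labels to a frame.

    Below the 35% rule the frame is ``none``.  Otherwise the enriched
    voxel set (intensity >= 1.35 x background inside the T cell, small
    components removed) is tested in fixed precedence:

    * invagination -- the enriched component seeded at the interface
      center reaches more than 1.5 µm behind the interface plane;
    * central -- the mass-weighted mean relative radius of the enriched
      shell mass lies inside the central disc (< 0.5);
    * peripheral -- at least 75% of the enriched shell mass sits in the
      annulus, spanning at least 180 degrees, with the central disc mostly
      spared;
    * asymmetric -- the enriched shell mass spans less than 180 degrees;
    * lamellal -- a slab covering at least half the interface area and
      reaching 0.5-2.5 µm behind it;
    * diffuse -- at least 75% projected coverage of both the central disc
      and the annulus.
    """
    params = params or ClassifierParams()
    if enrichment.enrichment_fraction < params.enrichment_threshold:
        return "none"

    bg = enrichment.background_mean
    cutoff = (1.0 + params.enrichment_threshold) * bg
    enriched = tcell_mask & (volume >= cutoff)
    lab, n = ndi.label(enriched, structure=_STRUCT26)
    if n:
        sizes = ndi.sum_labels(
            np.ones_like(lab), lab, index=np.arange(1, n + 1)
        )
        keep = np.flatnonzero(sizes >= params.min_component_voxels) + 1
        enriched = np.isin(lab, keep)
    if not enriched.any():
        return "diffuse"

    depth, r, cu, cv = _interface_coords(volume.shape, spacing, interface)
    r_if = max(interface.diameter / 2.0, 1e-6)
    rel_r = r / r_if
    shell = interface_shell(tcell_mask, interface)

    # invagination: component(s) seeded under the interface center
    seed = (
        enriched
        & (r <= params.invagination_seed_radius_um)
        & (depth >= -1e-9)
        & (depth <= params.invagination_seed_depth_um)
    )
    if seed.any():
        seed_labels = np.unique(lab[seed])
        seeded = np.isin(lab, seed_labels[seed_labels > 0])
        if _robust_depth(depth[seeded], params) > params.invagination_depth_um:
            return "invagination"

    a_shell = enriched & shell
    if not a_shell.any():
        return "diffuse"
    mass = np.clip(volume - bg, 0.0, None)

    m_shell = mass[a_shell]
    mean_rel_r = float((m_shell * rel_r[a_shell]).sum() / m_shell.sum())
    if mean_rel_r < params.central_rel_radius:
        return "central"

    # projected footprints on the interface plane (2D cells of ~pixel size)
    cell_um = float(min(spacing[1], spacing[2]))
    shell_cells = _footprint_cells(cu[shell], cv[shell], cell_um)
    shell_rel_r = rel_r[shell]
    enr_cells = _footprint_cells(cu[a_shell], cv[a_shell], cell_um)
    central_ref = np.unique(shell_cells[shell_rel_r < params.central_rel_radius])
    annulus_ref = np.unique(shell_cells[shell_rel_r >= params.central_rel_radius])
    enr_unique = np.unique(enr_cells)
    cov_central = (
        np.isin(central_ref, enr_unique).mean() if len(central_ref) else 0.0
    )
    cov_annulus = (
        np.isin(annulus_ref, enr_unique).mean() if len(annulus_ref) else 0.0
    )

    theta = np.degrees(np.arctan2(cv[a_shell], cu[a_shell]))
    angle = _angular_coverage_deg(theta, m_shell, params.angular_bins)
    annulus_mass_frac = float(
        m_shell[rel_r[a_shell] >= params.central_rel_radius].sum()
        / m_shell.sum()
    )

    if (
        annulus_mass_frac >= params.peripheral_mass_fraction
        and angle >= params.peripheral_min_angle_deg
        and cov_central <= params.peripheral_central_coverage_max
    ):
        return "peripheral"

    if angle < params.asymmetric_max_angle_deg:
        return "asymmetric"

    # lamellal: slab behind the interface
    under = enriched & (rel_r <= 1.0) & (depth >= -1e-9)
    if under.any():
        depth_max = _robust_depth(depth[under], params)
        slab_cells = np.unique(
            _footprint_cells(
                cu[under & (depth <= params.lamella_depth_max_um)],
                cv[under & (depth <= params.lamella_depth_max_um)],
                cell_um,
            )
        )
        disc_ref = np.unique(shell_cells[shell_rel_r <= 1.0])
        area_cov = (
            np.isin(disc_ref, slab_cells).mean() if len(disc_ref) else 0.0
        )
        if (
            area_cov >= params.lamella_area_fraction
            and params.lamella_depth_min_um
            < depth_max
            <= params.lamella_depth_max_um
        ):
            return "lamellal"

    if (
        cov_central >= params.diffuse_coverage
        and cov_annulus >= params.diffuse_coverage
    ):
        return "diffuse"
    return "diffuse"


def classify_timeline(
    track: CoupleTrack,
    volumes: np.ndarray,
    spacing: tuple[float, float, float],
    params: ClassifierParams | None = None,
    stats: StatsParams | None = None,
) -> dict[float, str]:
    """Classify a tracked couple on the aligned time grid.

    Returns ``{time_rel_s: label}`` on the −40 s … +420 s grid (or the
    configured one).  Aligned times mapping outside the movie are missing
    from the result; flagged frames are excluded; frames before contact
    are ``none``.

    ``volumes`` is the (t, z, y, x) sensor channel.
    """
    if track.t0 is None:
        raise ValueError("t0 undefined: couple was never tightly coupled")
    params = params or ClassifierParams()
    stats = stats or StatsParams()
    if track.n_frames > 1:
        dt = float(track.timestamps[1] - track.timestamps[0])
    else:
        dt = stats.grid_step_s
    out: dict[float, str] = {}
    for t_rel in stats.grid():
        f = track.t0 + int(round(t_rel / dt))
        if not 0 <= f < track.n_frames:
            continue
        if track.flagged is not None and track.flagged[f]:
            continue
        iface = track.interfaces[f]
        if iface is None:
            out[float(t_rel)] = "none"
            continue
        enr = measure_enrichment(
            volumes[f], track.tcell_masks[f], iface, spacing, params
        )
        out[float(t_rel)] = classify_frame(
            volumes[f], track.tcell_masks[f], iface, enr, spacing, params
        )
    assert all(v in PATTERNS for v in out.values())
    return out
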