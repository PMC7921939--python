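"""Cell-couple segmentation, interface geometry and tight-coupling detection.

A couple consists of a GFP-expressing T cell and a non-fluorescent APC.
Per frame the two cells are segmented, their contact voxels identified
(26-connectivity after one voxel of dilation, tolerant to single-voxel
segmentation gaps), and the interface summarized by its center, inward
normal and diameter.  The reference frame t0 of tight cell coupling is the
first frame where either the interface has reached its full width or the
cells have been in contact for 40 s, whichever comes first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .config import TrackingParams
from .volumes import APC_CHANNEL, GFP_CHANNEL, VolumeSeries

_STRUCT26 = np.ones((3, 3, 3), bool)


class SegmentationError(ValueError):
    """Raised when a frame cannot be segmented into a T cell/APC pair."""


@dataclass
class InterfaceGeometry:
    """Geometry of the T cell:APC contact region.

    Attributes
    ----------
    voxels : ndarray, shape (n, 3)
        Integer (z, y, x) indices of T cell contact voxels.
    center : ndarray, shape (3,)
        Contact centroid in µm (z, y, x).
    normal : ndarray, shape (3,)
        Unit vector perpendicular to the interface, pointing into the
        T cell (the direction of increasing depth).
    diameter : float
        Maximum in-plane extent of the contact region in µm; the line
        connecting the two outmost points at the edges of the interface.
    """

    voxels: np.ndarray
    center: np.ndarray
    normal: np.ndarray
    diameter: float


@dataclass
class CoupleTrack:
    """Per-frame masks and coupling state for one cell couple."""

    tcell_masks: np.ndarray  # (t, z, y, x) bool
    apc_masks: np.ndarray
    timestamps: np.ndarray
    interfaces: list = field(default_factory=list)  # InterfaceGeometry | None
    contact_start: int | None = None
    t0: int | None = None
    flagged: np.ndarray | None = None  # frames excluded from statistics

    @property
    def n_frames(self) -> int:
        return self.tcell_masks.shape[0]


def _largest_component(mask: np.ndarray, min_voxels: int) -> np.ndarray | None:
    lab, n = ndi.label(mask, structure=_STRUCT26)
    if n == 0:
        return None
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_voxels:
        return None
    return lab == best


def segment_couple(
    gfp: np.ndarray,
    label_channel: np.ndarray | None = None,
    params: TrackingParams | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Segment the T cell (GFP channel) and APC (label channel).

    The T cell is the largest GFP-positive connected component above an
    Otsu (or configured) threshold, hole-filled.  The APC is segmented the
    same way from the label channel when provided; without one the APC
    cannot be identified (the study used transmitted-light images, which
    are not modelled here) and ``None`` is returned for its mask.

    Raises
    ------
    SegmentationError
        If no sufficiently large T cell component exists ("no cells").
    """
    params = params or TrackingParams()
    gfp = np.asarray(gfp, dtype=float)
    if gfp.size == 0:
        raise SegmentationError("no cells: empty volume")
    thr = params.tcell_threshold
    if thr is None:
        if np.ptp(gfp) == 0:
            raise SegmentationError("no cells: constant volume")
        thr = threshold_otsu(gfp)
    tcell = _largest_component(gfp > thr, params.min_component_voxels)
    if tcell is None:
        raise SegmentationError("no cells: no T cell component above threshold")
    tcell = ndi.binary_fill_holes(tcell)

    apc = None
    if label_channel is not None:
        lc = np.asarray(label_channel, dtype=float)
        athr = params.apc_threshold
        if athr is None:
            athr = threshold_otsu(lc) if np.ptp(lc) > 0 else np.inf
        apc = _largest_component(lc > athr, params.min_component_voxels)
        if apc is not None:
            apc = ndi.binary_fill_holes(apc)
            apc &= ~tcell  # masks must be disjoint
            if not apc.any():
                apc = None
    return tcell, apc


def contact_voxels(tcell: np.ndarray, apc: np.ndarray) -> np.ndarray:
    """T cell boundary voxels within one voxel step of the APC.

    Contact is evaluated with 26-connectivity after one voxel of dilation
    of the APC mask, tolerating single-voxel segmentation gaps.
    Returns an (n, 3) integer index array (possibly empty).
    """
    boundary = tcell & ~ndi.binary_erosion(tcell, structure=_STRUCT26)
    near_apc = ndi.binary_dilation(apc, structure=_STRUCT26)
    return np.argwhere(boundary & near_apc)


def interface_geometry(
    tcell: np.ndarray,
    apc: np.ndarray,
    spacing: tuple[float, float, float],
) -> InterfaceGeometry | None:
    """Compute contact set, center, inward normal and diameter.

    Returns ``None`` when the cells share no contact voxels.
    """
    vox = contact_voxels(tcell, apc)
    if len(vox) == 0:
        return None
    sp = np.asarray(spacing, float)
    pts = vox * sp  # µm
    center = pts.mean(axis=0)

    tc_centroid = np.argwhere(tcell).mean(axis=0) * sp
    if len(vox) >= 3:
        cov = np.cov((pts - center).T)
        w, v = np.linalg.eigh(cov)
        normal = v[:, 0]  # smallest-variance direction
    else:
        normal = tc_centroid - center
    if np.linalg.norm(normal) == 0:
        normal = np.array([1.0, 0.0, 0.0])
    normal = normal / np.linalg.norm(normal)
    # orient into the T cell
    if np.dot(tc_centroid - center, normal) < 0:
        normal = -normal

    # diameter: maximum pairwise distance projected onto the interface plane
    rel = pts - center
    inplane = rel - np.outer(rel @ normal, normal)
    if len(inplane) > 800:
        # thin out deterministically; the hull extremes survive coarsening
        from scipy.spatial import ConvexHull

        try:
            basis = _plane_basis(normal)
            uv = inplane @ basis.T
            hull = ConvexHull(uv)
            uv = uv[hull.vertices]
            diff = uv[:, None, :] - uv[None, :, :]
            diameter = float(np.sqrt((diff**2).sum(-1)).max())
        except Exception:
            diff = inplane[:, None, :] - inplane[None, :, :]
            diameter = float(np.sqrt((diff**2).sum(-1)).max())
    else:
        diff = inplane[:, None, :] - inplane[None, :, :]
        diameter = float(np.sqrt((diff**2).sum(-1)).max())

    return InterfaceGeometry(
        voxels=vox, center=center, normal=normal, diameter=diameter
    )


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane perpendicular to normal."""
    a = np.array([0.0, 1.0, 0.0]) if abs(normal[0]) > 0.9 else np.array(
        [1.0, 0.0, 0.0]
    )
    u = np.cross(normal, a)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    return np.stack([u, v])


def tight_coupling_frame(
    diameters: list[float | None],
    frame_interval: float,
    params: TrackingParams | None = None,
) -> int | None:
    """Tight-coupling frame t0 from a per-frame interface diameter record.

    ``diameters[i]`` is the interface diameter at frame i, or ``None``
    when the cells are not in contact.  t0 is the earlier of

    * the first contact frame whose diameter reaches
      ``full_width_fraction`` of the running maximum over the subsequent
      ``full_width_window_s`` window (the interface has its full width);
    * ``contact_start + ceil(contact_rule_s / frame_interval)`` (the cells
      have been in contact for 40 s).

    Returns ``None`` when no frame has contact.
    """
    params = params or TrackingParams()
    contact = [i for i, d in enumerate(diameters) if d is not None]
    if not contact:
        return None
    start = contact[0]
    n = len(diameters)

    window = int(math.ceil(params.full_width_window_s / frame_interval))
    full_width = None
    for i in contact:
        ds = [
            d
            for d in diameters[i : min(n, i + window + 1)]
            if d is not None
        ]
        if diameters[i] >= params.full_width_fraction * max(ds):
            full_width = i
            break

    rule = start + int(math.ceil(params.contact_rule_s / frame_interval))
    rule = min(rule, n - 1)
    t0 = rule if full_width is None else min(full_width, rule)
    return t0


def detect_tight_coupling(
    track: CoupleTrack,
    params: TrackingParams | None = None,
    frame_interval: float | None = None,
) -> int | None:
    """Apply the whichever-first rule to a tracked couple; sets ``track.t0``."""
    if frame_interval is None:
        if track.n_frames > 1:
            frame_interval = float(track.timestamps[1] - track.timestamps[0])
        else:
            frame_interval = 1.0
    diameters = [
        (g.diameter if g is not None else None) for g in track.interfaces
    ]
    t0 = tight_coupling_frame(diameters, frame_interval, params)
    track.t0 = t0
    contact = [i for i, d in enumerate(diameters) if d is not None]
    track.contact_start = contact[0] if contact else None
    return t0


def track_couple(
    series: VolumeSeries,
    params: TrackingParams | None = None,
) -> CoupleTrack:
    """Segment and track one couple through a volume series.

    Frames that fail segmentation are flagged (excluded from downstream
    statistics) and carried by the nearest valid masks so the track stays
    continuous.
    """
    params = params or TrackingParams()
    nt = series.n_frames
    shape = series.frame_shape
    tcell_masks = np.zeros((nt,) + shape, bool)
    apc_masks = np.zeros((nt,) + shape, bool)
    flagged = np.zeros(nt, bool)
    has_label = APC_CHANNEL in series.channels

    for t in range(nt):
        try:
            tc, apc = segment_couple(
                series.channel(GFP_CHANNEL, t),
                series.channel(APC_CHANNEL, t) if has_label else None,
                params,
            )
        except SegmentationError:
            flagged[t] = True
            continue
        tcell_masks[t] = tc
        if apc is None:
            flagged[t] = True
        else:
            apc_masks[t] = apc

    # interpolate flagged frames from the nearest valid neighbour
    valid = np.flatnonzero(~flagged)
    if len(valid) == 0:
        raise SegmentationError("no cells: no frame segmented")
    for t in np.flatnonzero(flagged):
        src = valid[np.argmin(np.abs(valid - t))]
        tcell_masks[t] = tcell_masks[src]
        apc_masks[t] = apc_masks[src]

    track = CoupleTrack(
        tcell_masks=tcell_masks,
        apc_masks=apc_masks,
        timestamps=series.timestamps.copy(),
        flagged=flagged,
    )
    track.interfaces = [
        interface_geometry(tcell_masks[t], apc_masks[t], series.spacing)
        for t in range(nt)
    ]
    detect_tight_coupling(track, params)
    return track
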