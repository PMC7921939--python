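"""Cell-shape morphometry: interface diameter, width, neck/lamella scoring.

The measurements mirror line drawings on transmitted-light images of T
cell/APC couples: the *interface diameter* connects the two outmost points
of the contact; the *cell length* runs from the interface to the posterior
pole along the (possibly bent) cell midline; the *cell width* is the
widest diameter perpendicular to that midline; a *lamella* is scorable
when a neck — a point between the interface and the widest part where the
cell is narrower than both — lies more than 1.3 µm behind the interface,
and then the *lamellal length* is the interface-to-neck distance.  The
*T cell shape factor* divides the lamellal length by the interface
diameter.  Off-interface lamellae (protrusions away from the synapse,
indicating impaired couple maintenance) are detected as residuals of a
morphological smoothing of the cell body.

The automatic path works on 3D masks; an annotation path accepts manual
line endpoints (CSV) and overrides the automatic measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull, QhullError
from skimage.graph import MCP_Geometric

from .config import MorphParams
from .tracking import InterfaceGeometry, _plane_basis

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class MorphFrame:
    """Morphometric measurements of one frame."""

    interface_diameter: float
    cell_width: float
    cell_length: float | None = None
    neck_distance: float | None = None
    lamellal_length: float | None = None
    shape_factor: float | None = None
    has_scorable_lamella: bool = False
    has_off_interface_lamella: bool = False
    flagged: bool = False


@dataclass
class MidlineProfile:
    """Arc positions (µm from the interface) and the cell diameter there."""

    arcs: np.ndarray
    diameters: np.ndarray
    length: float
    flagged: bool = False


def _ball_structure(radius_um: float, spacing) -> np.ndarray:
    sp = np.asarray(spacing, float)
    half = np.maximum(np.floor(radius_um / sp).astype(int), 0)
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, sp)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_um**2 + 1e-9


def _max_pairwise(points2d: np.ndarray) -> float:
    if len(points2d) < 2:
        return 0.0
    pts = points2d
    if len(pts) > 40:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff**2).sum(-1)).max())


def _smooth_path(path_um: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or len(path_um) <= window:
        return path_um
    pad = window // 2
    padded = np.pad(path_um, ((pad, pad), (0, 0)), mode="edge")
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, k], kernel, mode="valid") for k in range(3)]
    )[: len(path_um)]


def midline_profile(
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: MorphParams | None = None,
) -> MidlineProfile:
    """Midline from the interface center to the posterior pole, with the
    perpendicular diameter profile along it.

    The midline is a minimum-cost geodesic inside the mask whose cost
    favors the medial axis (low cost where the distance to the boundary is
    large), so it tracks the centerline even when the cell is bent.  The
    pole is the mask voxel of maximal in-mask geodesic distance from the
    interface center.
    """
    params = params or MorphParams()
    sp = np.asarray(spacing, float)
    mask = tcell_mask.astype(bool)
    if not mask.any():
        raise ValueError("empty mask")

    vox_all = np.argwhere(mask)
    start = tuple(
        vox_all[np.argmin(((vox_all * sp - interface.center) ** 2).sum(axis=1))]
    )
    # restrict to the connected component holding the interface
    lab, _ = ndi.label(mask, structure=_STRUCT26)
    mask = lab == lab[start]

    # geodesic distance (uniform cost) to find the posterior pole
    uniform = np.where(mask, 1.0, np.inf)
    mcp_dist = MCP_Geometric(uniform, sampling=tuple(sp))
    dist, _ = mcp_dist.find_costs([start])
    dist = np.where(mask & np.isfinite(dist), dist, -np.inf)
    end = tuple(np.unravel_index(np.argmax(dist), dist.shape))

    # medial-weighted geodesic for the midline itself
    edt = ndi.distance_transform_edt(mask, sampling=sp)
    cost = np.where(mask, 1.0 / (edt + 0.5), np.inf)
    mcp = MCP_Geometric(cost, sampling=tuple(sp))
    mcp.find_costs([start], [end])
    path = np.asarray(mcp.traceback(end), float) * sp  # µm

    step = params.profile_step_um
    window = max(1, int(round(params.midline_smooth_um / max(
        float(np.linalg.norm(np.diff(path, axis=0), axis=1).mean())
        if len(path) > 1 else step, 1e-6))))
    path = _smooth_path(path, window)
    path[0] = interface.center  # anchor at the interface center

    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(cum[-1])
    n_samples = max(int(np.floor(length / step)) + 1, 2)
    arcs = np.linspace(0.0, length, n_samples)
    samples = np.column_stack(
        [np.interp(arcs, cum, path[:, k]) for k in range(3)]
    )
    tangents = np.gradient(samples, arcs, axis=0)
    tangents /= np.maximum(
        np.linalg.norm(tangents, axis=1, keepdims=True), 1e-9
    )

    # assign every mask voxel to its nearest midline sample; each sample's
    # diameter is the in-plane extent of its own thin cross-section bin
    vox_um = np.argwhere(mask) * sp
    nearest = np.empty(len(vox_um), dtype=int)
    chunk = 100_000
    for lo in range(0, len(vox_um), chunk):
        d2 = (
            (vox_um[lo : lo + chunk, None, :] - samples[None, :, :]) ** 2
        ).sum(-1)
        nearest[lo : lo + chunk] = np.argmin(d2, axis=1)
    diameters = np.full(n_samples, np.nan)
    flagged = False
    for i, (p, t) in enumerate(zip(samples, tangents)):
        sel = nearest == i
        if sel.sum() < 2:
            flagged = True
            continue
        rel = vox_um[sel] - p
        u, v = _plane_basis(t)
        q = np.column_stack([rel @ u, rel @ v])
        diameters[i] = _max_pairwise(q)
    return MidlineProfile(
        arcs=arcs, diameters=diameters, length=length, flagged=flagged
    )


def measure_axes(
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: MorphParams | None = None,
) -> tuple[float, float, float, MidlineProfile]:
    """Interface diameter, cell width, cell length and diameter profile."""
    profile = midline_profile(tcell_mask, interface, spacing, params)
    cell_width = float(np.nanmax(profile.diameters))
    return interface.diameter, cell_width, profile.length, profile


def score_lamella(
    profile: MidlineProfile,
    interface_diameter: float,
    params: MorphParams | None = None,
) -> tuple[bool, float | None, float | None]:
    """Neck detection and the >1.3 µm scorable-lamella rule.

    A neck is the narrowest point strictly between the interface and the
    widest part of the cell, qualifying only when the cell diameter there
    is smaller than both the interface diameter and the cell width beyond
    it.  Returns ``(has_scorable_lamella, neck_distance, lamellal_length)``
    where the lamellal length (interface-to-neck distance) is set only for
    scorable lamellae.
    """
    params = params or MorphParams()
    d = np.nan_to_num(profile.diameters, nan=np.inf)
    n = len(d)
    if n < 3:
        return False, None, None
    rev = np.nan_to_num(profile.diameters[::-1], nan=0.0)
    later_max = np.concatenate(
        [np.maximum.accumulate(rev)[::-1][1:], [0.0]]
    )
    interior = np.arange(1, n - 1)
    ok = (d[interior] < interface_diameter) & (
        d[interior] < later_max[interior]
    )
    candidates = interior[ok]
    if len(candidates) == 0:
        return False, None, None
    neck = candidates[np.argmin(d[candidates])]
    neck_distance = float(profile.arcs[neck])
    scorable = neck_distance > params.neck_min_um
    return scorable, neck_distance, (neck_distance if scorable else None)


def shape_factor(lamellal_length: float, interface_diameter: float) -> float:
    """Lamellal length divided by the interface diameter."""
    if interface_diameter <= 0:
        raise ValueError("interface_diameter must be positive")
    if lamellal_length < 0:
        raise ValueError("lamellal_length must be >= 0")
    return lamellal_length / interface_diameter


def detect_off_interface_lamella(
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: MorphParams | None = None,
) -> bool:
    """True when a protrusion longer than 1.3 µm grows away from the synapse.

    Protrusions are residuals of a morphological opening of the cell (the
    smoothed convex body); a residual counts when its extent beyond the
    body exceeds the lamella length rule and its base lies farther than
    one interface radius from the interface center, so interface lamellae
    are not counted.
    """
    params = params or MorphParams()
    sp = np.asarray(spacing, float)
    struct = _ball_structure(params.opening_radius_um, sp)
    body = ndi.binary_opening(tcell_mask, structure=struct)
    if not body.any():
        return False
    residual = tcell_mask & ~body
    if not residual.any():
        return False
    dist_from_body = ndi.distance_transform_edt(~body, sampling=sp)
    lab, n = ndi.label(residual, structure=_STRUCT26)
    r_if = interface.diameter / 2.0
    for i in range(1, n + 1):
        comp = lab == i
        dists = dist_from_body[comp]
        if float(dists.max()) <= params.neck_min_um:
            continue
        base_vox = np.argwhere(comp)[np.argmin(dists)]
        base_um = base_vox * sp
        if np.linalg.norm(base_um - interface.center) > r_if:
            return True
    return False


def measure_morph_frame(
    tcell_mask: np.ndarray,
    interface: InterfaceGeometry,
    spacing: tuple[float, float, float],
    params: MorphParams | None = None,
) -> MorphFrame:
    """All morphometric measurements of one frame from its mask."""
    params = params or MorphParams()
    iface_d, cell_width, cell_length, profile = measure_axes(
        tcell_mask, interface, spacing, params
    )
    scorable, neck, lam = score_lamella(profile, iface_d, params)
    sf = shape_factor(lam, iface_d) if scorable else None
    off = detect_off_interface_lamella(tcell_mask, interface, spacing, params)
    return MorphFrame(
        interface_diameter=iface_d,
        cell_width=cell_width,
        cell_length=cell_length,
        neck_distance=neck,
        lamellal_length=lam,
        shape_factor=sf,
        has_scorable_lamella=scorable,
        has_off_interface_lamella=off,
        flagged=profile.flagged,
    )


LINE_TYPES = (
    "interface_diameter", "cell_width", "lamellal_length", "cell_length"
)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read manual line annotations (endpoints in µm).

    Expected columns: couple_id, time_rel_s, line_type (one of
    ``interface_diameter``, ``cell_width``, ``lamellal_length``,
    ``cell_length``), x1, y1, x2, y2.
    """
    df = pd.read_csv(path)
    required = {"couple_id", "time_rel_s", "line_type", "x1", "y1", "x2", "y2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns {sorted(missing)}")
    bad = set(df["line_type"]) - set(LINE_TYPES)
    if bad:
        raise ValueError(f"unknown line types {sorted(bad)}")
    df["length_um"] = np.hypot(df.x2 - df.x1, df.y2 - df.y1)
    return df


def morph_from_annotations(
    df: pd.DataFrame,
    params: MorphParams | None = None,
) -> dict[tuple, MorphFrame]:
    """Morph frames from manual lines; up to four lines per frame.

    The lamellal-length line is only drawn for scorable lamellae; its
    length doubles as the neck distance, and the >1.3 µm rule is enforced.
    """
    params = params or MorphParams()
    out: dict[tuple, MorphFrame] = {}
    for (cid, t), grp in df.groupby(["couple_id", "time_rel_s"]):
        lengths = dict(zip(grp.line_type, grp.length_um))
        iface_d = float(lengths.get("interface_diameter", np.nan))
        width = float(lengths.get("cell_width", np.nan))
        lam = lengths.get("lamellal_length")
        scorable = lam is not None and float(lam) > params.neck_min_um
        frame = MorphFrame(
            interface_diameter=iface_d,
            cell_width=width,
            cell_length=(
                float(lengths["cell_length"])
                if "cell_length" in lengths else None
            ),
            neck_distance=float(lam) if lam is not None else None,
            lamellal_length=float(lam) if scorable else None,
            has_scorable_lamella=bool(scorable),
            shape_factor=(
                shape_factor(float(lam), iface_d)
                if scorable and iface_d > 0 else None
            ),
        )
        out[(cid, float(t))] = frame
    return out


def morph_table(frames: dict[tuple, MorphFrame]) -> pd.DataFrame:
    """Tidy morphometry table, one row per (couple, aligned time)."""
    rows = []
    for (cid, t), f in sorted(frames.items()):
        rows.append(
            {
                "couple_id": cid,
                "time_rel_s": t,
                "interface_diameter_um": f.interface_diameter,
                "cell_width_um": f.cell_width,
                "cell_length_um": f.cell_length,
                "neck_distance_um": f.neck_distance,
                "lamellal_length_um": f.lamellal_length,
                "shape_factor": f.shape_factor,
                "has_scorable_lamella": f.has_scorable_lamella,
                "has_off_interface_lamella": f.has_off_interface_lamella,
                "flagged": f.flagged,
            }
        )
    return pd.DataFrame(rows)
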