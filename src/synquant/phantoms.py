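"""Closed-form geometric phantoms for validating the morphometry and
shape pipelines.

All phantoms are built on isotropic grids with known ground truth: a
sphere truncated by a flat contact disc, an hourglass cell with a neck at
a programmed distance behind the interface, and a bent tubular cell with a
known midline arc length.  Each constructor returns the binary mask and
the exact :class:`~synquant.tracking.InterfaceGeometry` of its contact
disc.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import cKDTree

from .tracking import InterfaceGeometry


def _grid(n: int, spacing: float):
    ax = np.arange(n) * spacing
    return np.meshgrid(ax, ax, ax, indexing="ij")


def _disc_interface(mask, z_if, center_yx, rc, spacing):
    n = mask.shape[0]
    z, y, x = _grid(n, spacing)
    r = np.hypot(y - center_yx[0], x - center_yx[1])
    sel = mask & (np.abs(z - z_if) < spacing / 2) & (r <= rc)
    vox = np.argwhere(sel)
    return InterfaceGeometry(
        voxels=vox,
        center=np.array([z_if, center_yx[0], center_yx[1]]),
        normal=np.array([1.0, 0.0, 0.0]),
        diameter=2.0 * rc,
    )


def sphere_with_disc(
    radius: float = 5.0,
    disc_radius: float = 3.0,
    spacing: float = 0.25,
    n: int = 96,
    z_if: float = 4.0,
) -> tuple[np.ndarray, InterfaceGeometry]:
    """Sphere of the given radius flattened by a contact disc.

    Ground truth: interface diameter ``2*disc_radius``, cell width
    ``2*radius``, cell length ``radius + sqrt(radius^2-disc_radius^2)``.
    """
    z, y, x = _grid(n, spacing)
    c_yx = ((n - 1) * spacing / 2,) * 2
    d0 = math.sqrt(radius**2 - disc_radius**2)
    cc = np.array([z_if + d0, c_yx[0], c_yx[1]])
    mask = ((z - cc[0]) ** 2 + (y - cc[1]) ** 2 + (x - cc[2]) ** 2
            <= radius**2) & (z >= z_if - 1e-9)
    return mask, _disc_interface(mask, z_if, c_yx, disc_radius, spacing)


def hourglass(
    neck_position: float,
    neck_width: float = 2.0,
    interface_radius: float = 2.5,
    body_radius: float = 4.0,
    spacing: float = 0.25,
    n: int = 96,
    z_if: float = 3.0,
) -> tuple[np.ndarray, InterfaceGeometry]:
    """Hourglass cell: cone from the interface disc to a neck, then a
    spherical body.

    The diameter profile decreases linearly from ``2*interface_radius``
    at the interface to ``neck_width`` at ``neck_position`` µm behind it,
    then widens into a sphere of ``body_radius`` — a unique neck at the
    programmed arc position.
    """
    if neck_width / 2 >= min(interface_radius, body_radius):
        raise ValueError("neck must be narrower than interface and body")
    z, y, x = _grid(n, spacing)
    c_yx = ((n - 1) * spacing / 2,) * 2
    d = z - z_if
    cone = np.where(
        (d >= -1e-9) & (d <= neck_position),
        interface_radius
        + (neck_width / 2 - interface_radius) * d / neck_position,
        0.0,
    )
    dc = neck_position + math.sqrt(body_radius**2 - (neck_width / 2) ** 2)
    body = np.where(
        d >= neck_position - 1e-9,
        np.sqrt(np.clip(body_radius**2 - (d - dc) ** 2, 0.0, None)),
        0.0,
    )
    rad = np.maximum(cone, body)
    mask = (np.hypot(y - c_yx[0], x - c_yx[1]) <= rad) & (d >= -1e-9)
    return mask, _disc_interface(mask, z_if, c_yx, interface_radius, spacing)


def bent_tube(
    tube_radius: float = 1.5,
    bend_radius: float = 8.0,
    bend_deg: float = 90.0,
    spacing: float = 0.25,
    n: int = 96,
) -> tuple[np.ndarray, InterfaceGeometry, float]:
    """Tubular cell bent along a circular arc of known length.

    The midline is a circular arc of ``bend_radius`` spanning
    ``bend_deg`` degrees starting at the interface plane; the returned
    length is the ground-truth cell length — the arc plus one tube radius,
    because the posterior pole sits on the rounded end cap.
    """
    margin = tube_radius + 3 * spacing
    start = np.array([margin, (n - 1) * spacing / 2, margin + bend_radius])
    angles = np.linspace(0.0, math.radians(bend_deg), 400)
    # arc in the z-x plane, starting along +z
    curve = np.stack(
        [
            start[0] + bend_radius * np.sin(angles),
            np.full_like(angles, start[1]),
            start[2] - bend_radius * (1 - np.cos(angles)) + 0.0,
        ],
        axis=1,
    )
    z, y, x = _grid(n, spacing)
    pts = np.column_stack([z.ravel(), y.ravel(), x.ravel()])
    dist, _ = cKDTree(curve).query(pts, k=1)
    mask = (dist.reshape(z.shape) <= tube_radius) & (z >= start[0] - 1e-9)
    rc = tube_radius * 0.98
    iface = _disc_interface(mask, start[0], (start[1], start[2]), rc, spacing)
    arc_length = bend_radius * math.radians(bend_deg) + tube_radius
    return mask, iface, arc_length
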