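"""Loft per-station superellipse rings into the main-body triangle mesh.

One superellipse ring is drawn per pixel station along the body axis, with
semi-axes half the transverse and dorsoventral diameters at that station and
the ring centered on the station's section center.  A tiny superelliptical
disk (radius 1e-4 px by default) is appended one station beyond each end;
after cleaning, its vertices merge into a single point that closes the mesh
without affecting volume or area.  Adjacent rings are stitched with two
triangles per quad, giving a consistent winding throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyProfile, InvalidExponent, NonPositiveDiameter
from .geometry_core import DEFAULT_RING_VERTICES
from .mesh_ops import TriMesh
from .outline_processing import AxialProfile


@dataclass
class TipConfig:
    """Radius of the terminal superelliptical disks (px)."""

    tip_radius_px: float = 1e-4

    def __post_init__(self) -> None:
        if self.tip_radius_px <= 0:
            raise ValueError("tip_radius_px must be positive")


def _ring_stack(a: np.ndarray, b: np.ndarray, n: float, m: int,
                cx: np.ndarray, cy: np.ndarray,
                z: np.ndarray) -> np.ndarray:
    """All rings at once: (S, m, 3) superellipse vertices."""
    theta = np.linspace(0.0, 2.0 * np.pi, m)
    c, s = np.cos(theta), np.sin(theta)
    e = 2.0 / n
    px = np.sign(c) * np.abs(c) ** e
    py = np.sign(s) * np.abs(s) ** e
    px[-1], py[-1] = px[0], py[0]
    x = cx[:, None] + a[:, None] * px[None, :]
    y = cy[:, None] + b[:, None] * py[None, :]
    zz = np.broadcast_to(z[:, None], x.shape)
    return np.stack([x, y, zz], axis=-1)


def loft_rings(rings: np.ndarray) -> TriMesh:
    """Stitch an (S, m, 3) ring stack into an open tube mesh.

    Vertex k of ring i is joined to vertices k and k+1 of ring i+1, two
    triangles per quad; the duplicate ring endpoint closes the loop and is
    merged away during cleaning.
    """
    n_rings, m, _ = rings.shape
    verts = rings.reshape(-1, 3)
    k = np.arange(m - 1)
    i = np.arange(n_rings - 1)[:, None]
    a = i * m + k          # ring i, vertex k
    b = (i + 1) * m + k    # ring i+1, vertex k
    c = (i + 1) * m + k + 1
    d = i * m + k + 1
    tri1 = np.stack([a, b, c], axis=-1).reshape(-1, 3)
    tri2 = np.stack([a, c, d], axis=-1).reshape(-1, 3)
    return TriMesh(verts, np.concatenate([tri1, tri2]))


def build_body_mesh(profile: AxialProfile, n: float,
                    m: int = DEFAULT_RING_VERTICES,
                    tips: TipConfig | None = None) -> TriMesh:
    """Build the (uncleaned) main-body mesh for one superelliptical exponent.

    Parameters
    ----------
    profile
        Per-station diameters and centers from the two body views.
    n
        Superelliptical exponent of every cross-section.
    m
        Vertices per ring, duplicate endpoint included (default 181, i.e.
        one vertex per 2 degrees).
    tips
        Terminal tip-disk configuration.
    """
    tips = tips or TipConfig()
    if n <= 0:
        raise InvalidExponent(f"superelliptical exponent must be > 0, got {n}")
    if profile.n_stations < 2:
        raise EmptyProfile("profile needs at least 2 stations")
    a = profile.tv_diameter_px / 2.0
    b = profile.dv_diameter_px / 2.0
    interior = slice(1, -1)
    if np.any(a[interior] <= 0) or np.any(b[interior] <= 0):
        raise NonPositiveDiameter(
            "zero diameter at an interior station; the silhouette must be a "
            "single connected shape")
    # end stations may rasterize to zero width; floor them at the tip radius
    r = tips.tip_radius_px
    a = np.maximum(a, r)
    b = np.maximum(b, r)
    z = profile.z_px.astype(float)
    cx = profile.x_center_px
    cy = profile.y_center_px
    # terminal tip disks one station beyond each end, at the local centers
    a_all = np.concatenate([[r], a, [r]])
    b_all = np.concatenate([[r], b, [r]])
    cx_all = np.concatenate([[cx[0]], cx, [cx[-1]]])
    cy_all = np.concatenate([[cy[0]], cy, [cy[-1]]])
    z_all = np.concatenate([[z[0] - 1.0], z, [z[-1] + 1.0]])
    rings = _ring_stack(a_all, b_all, n, m, cx_all, cy_all, z_all)
    return loft_rings(rings)
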