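"""Outline smoothing and conversion of two body views into an axial profile.

The two body silhouettes (lateral and ventral, fins removed) are reduced to
one pair of diameters per pixel station along the body axis: the lateral view
yields the dorsoventral diameter and section center, the ventral view the
transverse diameter and center.  Before that reduction the outline may be
smoothed with local regression so coordinates take non-integer values —
skipping the smoothing tends to leave step artifacts that later produce
non-manifold mesh elements.

Local regression here is a tricube-weighted local quadratic fit of each
boundary branch (dorsal/ventral or left/right edge) as a function of the
axial coordinate, with the window holding a fraction ``nn`` of the branch
points.  A quadratic local model reproduces affine data exactly and keeps
bias low where the boundary curves strongly (e.g. near the snout and tail of
a rounded body).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import TooFewPoints, ViewLengthMismatch
from .silhouette_io import OutlineTrace


@dataclass
class SmoothingConfig:
    """Local-regression settings.

    nn
        Nearest-neighbor parameter: fraction of branch points inside the
        local window.  Default 0.1 (0.05 suits small fin outlines).
    enabled
        Disable to pass raw marching-squares coordinates through.
    """

    nn: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.nn <= 1.0:
            raise ValueError("nn must lie in (0, 1]")


@dataclass
class AxialProfile:
    """Per-pixel-station diameters and section centers along the body axis.

    Station 0 is the anterior-most foreground pixel; indices increase
    posteriorly.  y is dorsoventral (dorsal positive), x transverse.
    """

    z_px: np.ndarray
    dv_diameter_px: np.ndarray
    tv_diameter_px: np.ndarray
    y_center_px: np.ndarray
    x_center_px: np.ndarray

    @property
    def n_stations(self) -> int:
        return len(self.z_px)


def local_regression(x: np.ndarray, y: np.ndarray, frac: float,
                     degree: int = 2) -> np.ndarray:
    """Tricube-weighted local polynomial fit evaluated at each ``x``.

    The window for point i holds the ``k = ceil(frac * n)`` nearest
    neighbors along x (taken as a contiguous block in sort order, the
    standard LOESS neighborhood).  Returns fitted y in the original order.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    k = max(int(np.ceil(frac * n)), degree + 2)
    if n < k:
        raise TooFewPoints(f"{n} points cannot support a window of {k}")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    fitted = np.empty(n)
    half = k // 2
    for i in range(n):
        lo = min(max(i - half, 0), n - k)
        xw = xs[lo:lo + k]
        yw = ys[lo:lo + k]
        t = xw - xs[i]
        h = np.max(np.abs(t))
        if h <= 0:
            fitted[i] = yw.mean()
            continue
        w = (1.0 - np.minimum(np.abs(t) / h, 1.0) ** 3) ** 3
        # weighted least squares on centered powers; beta0 = fit at xs[i]
        A = np.vander(t, degree + 1, increasing=True)
        Aw = A * w[:, None]
        ata = Aw.T @ A
        atb = Aw.T @ yw
        try:
            beta = np.linalg.solve(ata, atb)
        except np.linalg.LinAlgError:
            beta = np.linalg.lstsq(Aw, yw * np.sqrt(w), rcond=None)[0]
        fitted[i] = beta[0]
    out = np.empty(n)
    out[order] = fitted
    return out


def _split_branches(trace: OutlineTrace) -> tuple[np.ndarray, np.ndarray]:
    """Cyclic index runs for the two boundary branches between the
    extreme axial (u) points of a closed trace."""
    u = trace.u
    i_min = int(np.argmin(u))
    i_max = int(np.argmax(u))
    n = len(u)
    if i_min == i_max:
        raise TooFewPoints("trace has no axial extent")
    if i_min < i_max:
        a = np.arange(i_min, i_max + 1)
        b = np.concatenate([np.arange(i_max, n), np.arange(0, i_min + 1)])
    else:
        a = np.concatenate([np.arange(i_min, n), np.arange(0, i_max + 1)])
        b = np.arange(i_max, i_min + 1)
    return a, b


def smooth_outline(trace: OutlineTrace,
                   cfg: SmoothingConfig | None = None) -> OutlineTrace:
    """Smooth a closed outline with local regression.

    The trace is split at its extreme axial points into an upper and a lower
    branch; each branch's transverse coordinate is regressed on the axial
    coordinate and replaced by the fit, then the branches are re-joined.
    Point count is preserved.
    """
    cfg = cfg or SmoothingConfig()
    if not cfg.enabled:
        return trace
    if len(trace) < 10:
        raise TooFewPoints("need at least 10 points to smooth an outline")
    pts = trace.points.copy()
    branch_a, branch_b = _split_branches(trace)
    for idx in (branch_a, branch_b):
        pts[idx, 1] = local_regression(trace.u[idx], trace.v[idx], cfg.nn)
    return OutlineTrace(points=pts, closed=trace.closed)


def station_extents(trace: OutlineTrace
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-integer-station transverse extents of a closed trace.

    Returns (stations, lower, upper): integer axial pixel positions within
    the trace's axial span and the interpolated min/max transverse (v)
    coordinate of the boundary at each station.
    """
    branch_a, branch_b = _split_branches(trace)
    u, v = trace.u, trace.v
    z0 = int(np.ceil(u.min()))
    z1 = int(np.floor(u.max()))
    stations = np.arange(z0, z1 + 1)
    vals = []
    for idx in (branch_a, branch_b):
        ub, vb = u[idx], v[idx]
        order = np.argsort(ub, kind="stable")
        vals.append(np.interp(stations, ub[order], vb[order]))
    va, vb_ = vals
    lower = np.minimum(va, vb_)
    upper = np.maximum(va, vb_)
    return stations, lower, upper


def build_axial_profile(lateral: OutlineTrace,
                        ventral: OutlineTrace) -> AxialProfile:
    """Combine lateral and ventral outlines into per-station diameters.

    Both views must span the same number of axial pixel stations to within
    1% of the longer span; the two spans are aligned at their anterior-most
    points and cropped to the common station count.
    """
    z_lat, lo_lat, hi_lat = station_extents(lateral)
    z_ven, lo_ven, hi_ven = station_extents(ventral)
    n_lat, n_ven = len(z_lat), len(z_ven)
    if abs(n_lat - n_ven) > max(0.01 * max(n_lat, n_ven), 1.0):
        raise ViewLengthMismatch(
            f"axial spans differ: lateral {n_lat} px vs ventral {n_ven} px")
    n = min(n_lat, n_ven)
    dv = hi_lat[:n] - lo_lat[:n]
    tv = hi_ven[:n] - lo_ven[:n]
    # image rows increase downward; flip lateral midline to dorsal-positive y
    y_center = -(hi_lat[:n] + lo_lat[:n]) / 2.0
    x_center = (hi_ven[:n] + lo_ven[:n]) / 2.0
    return AxialProfile(
        z_px=np.arange(n),
        dv_diameter_px=np.maximum(dv, 0.0),
        tv_diameter_px=np.maximum(tv, 0.0),
        y_center_px=y_center,
        x_center_px=x_center,
    )
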