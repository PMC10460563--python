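"""Programmatically rendered test silhouettes with analytic ground truth.

Every validation shape is rendered as an anti-aliased grayscale silhouette
(dark foreground on white, 4x4 supersampled coverage per pixel), mimicking
raster exports from vector drawing software, so that binarization at the 0.5
level recovers the boundary to sub-pixel accuracy.  Ground-truth volumes and
areas come from closed forms where available (sphere, prolate spheroid) and
from documented high-resolution 1D quadrature otherwise (superellipse solids
and the synthetic fish).

The validation resolution sweep runs the long axis from 100 to 10,000 px:
increments of 100 up to 1,000 and of 1,000 beyond, i.e. 19 resolutions.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .geometry_core import naca_half_thickness, superellipse_area, \
    thickness_envelope

#: ground-truth quadrature station count for non-closed-form solids
ORACLE_STATIONS = 10_000

SHAPES = ("circle", "ellipse", "superellipse_profile", "rectangle",
          "synthetic_fish")


@dataclass
class FixtureSpec:
    """A renderable validation shape.

    ``long_axis_px`` is the foreground extent along the body axis (the image
    itself carries a small margin); ``aspect`` is long/short axis ratio;
    ``n_true`` the outline exponent for superellipse profiles.
    """

    shape: str
    long_axis_px: int
    aspect: float = 1.0
    n_true: float = 2.0
    fin_span_px: int = 0
    fin_chord_px: int = 0

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown fixture shape {self.shape!r}")
        if self.long_axis_px < 16:
            raise ValueError("long_axis_px must be at least 16")


def sweep_resolutions() -> list[int]:
    """Long-axis resolutions of the geometric validation sweep."""
    return list(range(100, 1000, 100)) + list(range(1000, 10_001, 1000))


def render_mask_image(inside_fn, width: int, height: int,
                      supersample: int = 4) -> np.ndarray:
    """Anti-aliased uint8 silhouette (0 = foreground) from an indicator.

    ``inside_fn(x, y)`` receives pixel-center-based coordinate arrays and
    returns a boolean array; coverage is estimated on a supersample x
    supersample subgrid per pixel.
    """
    acc = np.zeros((height, width), dtype=np.uint16)
    offsets = (np.arange(supersample) + 0.5) / supersample - 0.5
    ys = np.arange(height, dtype=float)[:, None]
    xs = np.arange(width, dtype=float)[None, :]
    for dy in offsets:
        for dx in offsets:
            acc += inside_fn(xs + dx, ys + dy)
    coverage = acc / float(supersample ** 2)
    return np.round(255.0 * (1.0 - coverage)).astype(np.uint8)


def _axis_center(extent_px: int, margin: int) -> float:
    # boundary at half-integers so exactly `extent_px` pixel centers fall
    # inside: first at `margin`, last at `margin + extent_px - 1`
    return margin - 0.5 + extent_px / 2.0


def ellipse_image(major_px: int, minor_px: int, margin: int = 8,
                  supersample: int = 4) -> np.ndarray:
    """Filled axis-aligned ellipse, major axis along image columns."""
    width = major_px + 2 * margin
    height = minor_px + 2 * margin
    cx = _axis_center(major_px, margin)
    cy = _axis_center(minor_px, margin)
    a, b = major_px / 2.0, minor_px / 2.0

    def inside(x, y):
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0

    return render_mask_image(inside, width, height, supersample)


def circle_image(diameter_px: int, margin: int = 8,
                 supersample: int = 4) -> np.ndarray:
    return ellipse_image(diameter_px, diameter_px, margin, supersample)


def rectangle_image(length_px: int, depth_px: int, margin: int = 8,
                    supersample: int = 4) -> np.ndarray:
    width = length_px + 2 * margin
    height = depth_px + 2 * margin
    cx = _axis_center(length_px, margin)
    cy = _axis_center(depth_px, margin)

    def inside(x, y):
        return (np.abs(x - cx) <= length_px / 2.0) \
            & (np.abs(y - cy) <= depth_px / 2.0)

    return render_mask_image(inside, width, height, supersample)


def superellipse_profile_image(length_px: int, depth_px: int, n_true: float,
                               margin: int = 8,
                               supersample: int = 4) -> np.ndarray:
    """Filled 2D superellipse outline (exponent ``n_true``), long axis along
    columns; used as a body silhouette with analytically known half-depth
    profile."""
    width = length_px + 2 * margin
    height = depth_px + 2 * margin
    cx = _axis_center(length_px, margin)
    cy = _axis_center(depth_px, margin)
    a, b = length_px / 2.0, depth_px / 2.0

    def inside(x, y):
        return (np.abs((x - cx) / a) ** n_true
                + np.abs((y - cy) / b) ** n_true) <= 1.0

    return render_mask_image(inside, width, height, supersample)


# ---------------------------------------------------------------------------
# ground truth


def sphere_truth(diameter_px: int) -> dict:
    r = diameter_px / 2.0
    return {"volume_px3": 4.0 / 3.0 * np.pi * r ** 3,
            "area_px2": 4.0 * np.pi * r ** 2}


def prolate_spheroid_truth(major_px: int, minor_px: int) -> dict:
    """Closed forms for a prolate spheroid: V = 4/3 pi a b^2 and
    S = 2 pi b^2 (1 + a / (b e) arcsin e), e the eccentricity."""
    a, b = major_px / 2.0, minor_px / 2.0
    e = np.sqrt(1.0 - (b / a) ** 2)
    area = 2.0 * np.pi * b ** 2 * (1.0 + a / (b * e) * np.arcsin(e))
    return {"volume_px3": 4.0 / 3.0 * np.pi * a * b ** 2,
            "area_px2": float(area)}


def superellipse_solid_truth(length_px: int, depth_px: int, n_true: float,
                             n_section: float,
                             stations: int = ORACLE_STATIONS) -> dict:
    """Quadrature volume of the solid whose lateral AND ventral silhouettes
    are the same superellipse profile and whose cross-sections are
    superellipses of exponent ``n_section``."""
    a_out, b_out = length_px / 2.0, depth_px / 2.0
    z = np.linspace(-a_out, a_out, stations)
    half = b_out * (1.0 - np.abs(z / a_out) ** n_true) ** (1.0 / n_true)
    areas = superellipse_area(1.0, 1.0, n_section) * half ** 2
    return {"volume_px3": float(np.trapezoid(areas, z))}


def naca_section_area(chord_px: float, t_pct: float) -> float:
    """Analytic area of a symmetric NACA section with a blunt trailing edge
    (the open -0.1015 polynomial closed by a straight base)."""
    x = np.linspace(0.0, 1.0, 20_001)
    y = naca_half_thickness(x, t_pct)
    return float(2.0 * np.trapezoid(y, x) * chord_px ** 2)


def fin_volume_oracle(span_px: float, chord_px: float, t_pct: float,
                      thickest_frac: float,
                      stations: int = ORACLE_STATIONS) -> float:
    """Quadrature oracle for a rectangular-planform fin: section area scales
    linearly with the envelope factor."""
    s = np.linspace(0.0, 1.0, stations)
    env = thickness_envelope(s, thickest_frac)
    a0 = naca_section_area(chord_px, t_pct)
    return float(a0 * np.trapezoid(env, s) * span_px)


# ---------------------------------------------------------------------------
# synthetic fish


@dataclass
class SyntheticFish:
    """A fully synthetic fish: elliptical body profiles plus one rectangular
    caudal fin, with a quadrature ground truth."""

    body_length_px: int = 1200
    body_depth_px: int = 400
    body_width_px: int = 240
    fin_span_px: int = 240
    fin_chord_px: int = 120
    fin_t_pct: float = 20.0
    fin_thickest_frac: float = 0.5

    def images(self) -> dict[str, np.ndarray]:
        return {
            "lateral": ellipse_image(self.body_length_px, self.body_depth_px),
            "ventral": ellipse_image(self.body_length_px, self.body_width_px),
            "caudal": rectangle_image(self.fin_span_px, self.fin_chord_px),
        }

    def ground_truth(self, n: float,
                     stations: int = ORACLE_STATIONS) -> dict:
        """Body solid (elliptical profiles, superelliptical sections of
        exponent n) by 1D quadrature, plus the fin oracle, summed with the
        same double-counting convention as the pipeline."""
        a = self.body_length_px / 2.0
        z = np.linspace(-a, a, stations)
        w = 1.0 - (z / a) ** 2
        w[w < 0] = 0.0
        half_dv = self.body_depth_px / 2.0 * np.sqrt(w)
        half_tv = self.body_width_px / 2.0 * np.sqrt(w)
        areas = superellipse_area(1.0, 1.0, n) * half_tv * half_dv
        body_v = float(np.trapezoid(areas, z))
        fin_v = fin_volume_oracle(self.fin_span_px, self.fin_chord_px,
                                  self.fin_t_pct, self.fin_thickest_frac)
        return {"body_volume_px3": body_v, "fin_volume_px3": fin_v,
                "total_volume_px3": body_v + fin_v}


def render_fixture(spec: FixtureSpec, outdir) -> dict:
    """Render a fixture to PNG files plus a ground-truth JSON.

    Returns a dict with image paths and the ground-truth values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    L = spec.long_axis_px
    short = max(int(round(L / spec.aspect)), 2)
    name = f"{spec.shape}_{L}"
    result: dict = {"spec": {"shape": spec.shape, "long_axis_px": L,
                             "aspect": spec.aspect, "n_true": spec.n_true}}
    if spec.shape == "circle":
        img = circle_image(L)
        result["images"] = {"lateral": str(outdir / f"{name}.png"),
                            "ventral": str(outdir / f"{name}.png")}
        iio.imwrite(outdir / f"{name}.png", img)
        result["truth"] = sphere_truth(L)
    elif spec.shape == "ellipse":
        img = ellipse_image(L, short)
        result["images"] = {"lateral": str(outdir / f"{name}.png"),
                            "ventral": str(outdir / f"{name}.png")}
        iio.imwrite(outdir / f"{name}.png", img)
        result["truth"] = prolate_spheroid_truth(L, short)
    elif spec.shape == "rectangle":
        img = rectangle_image(L, short)
        iio.imwrite(outdir / f"{name}.png", img)
        result["images"] = {"planar": str(outdir / f"{name}.png")}
        result["truth"] = {"area_px2_planform": float(L * short)}
    elif spec.shape == "superellipse_profile":
        img = superellipse_profile_image(L, short, spec.n_true)
        iio.imwrite(outdir / f"{name}.png", img)
        result["images"] = {"lateral": str(outdir / f"{name}.png"),
                            "ventral": str(outdir / f"{name}.png")}
        result["truth"] = superellipse_solid_truth(L, short, spec.n_true,
                                                   spec.n_true)
    else:  # synthetic_fish
        fish = SyntheticFish(body_length_px=L)
        paths = {}
        for tag, img in fish.images().items():
            p = outdir / f"{name}_{tag}.png"
            iio.imwrite(p, img)
            paths[tag] = str(p)
        result["images"] = paths
        result["truth"] = fish.ground_truth(n=2.0)
    with open(outdir / f"{name}_truth.json", "w") as fh:
        json.dump(result, fh, indent=2)
    return result
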