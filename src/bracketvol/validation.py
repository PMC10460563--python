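"""Geometric validation: run the pipeline on shapes with closed-form truth.

A rendered circle (or 5:1 ellipse) is fed in as both the lateral and the
ventral body view; the n = 2 model of a circle is a sphere (of an ellipse, a
prolate spheroid), so mesh volume and surface area can be compared to the
parametric closed forms.  Errors are reported in percent, signed as
(estimate - truth) / truth.
"""
from __future__ import annotations

import numpy as np

from .body_mesher import TipConfig, build_body_mesh
from .fixtures import (
    circle_image,
    ellipse_image,
    prolate_spheroid_truth,
    sphere_truth,
)
from .mesh_ops import CleanConfig, clean_mesh, mesh_area, mesh_volume
from .outline_processing import (
    SmoothingConfig,
    build_axial_profile,
    smooth_outline,
)
from .silhouette_io import SilhouetteImage, extract_outline

#: aspect ratio of the validation spheroid (major axis = 5 x minor)
SPHEROID_ASPECT = 5


def measure_revolution_model(image: np.ndarray, n: float = 2.0,
                             nn: float = 0.1, smoothing: bool = True,
                             m_vertices: int = 181) -> tuple[float, float]:
    """Volume (px^3) and area (px^2) of the model built from one silhouette
    image used as both body views."""
    sil = SilhouetteImage.from_array(image < 128)
    trace = extract_outline(sil)
    trace = smooth_outline(trace, SmoothingConfig(nn=nn, enabled=smoothing))
    profile = build_axial_profile(trace, trace)
    mesh = clean_mesh(build_body_mesh(profile, n=n, m=m_vertices,
                                      tips=TipConfig()),
                      CleanConfig())
    return mesh_volume(mesh), mesh_area(mesh)


def sphere_errors(diameter_px: int, **kwargs) -> dict:
    """Signed percent errors of the n=2 sphere model vs closed forms."""
    vol, area = measure_revolution_model(circle_image(diameter_px), **kwargs)
    truth = sphere_truth(diameter_px)
    return {
        "shape": "sphere",
        "long_axis_px": diameter_px,
        "volume_error_pct": 100.0 * (vol / truth["volume_px3"] - 1.0),
        "area_error_pct": 100.0 * (area / truth["area_px2"] - 1.0),
    }


def spheroid_errors(major_px: int, aspect: float = SPHEROID_ASPECT,
                    **kwargs) -> dict:
    """Signed percent errors of the n=2 prolate-spheroid model."""
    minor_px = int(round(major_px / aspect))
    vol, area = measure_revolution_model(ellipse_image(major_px, minor_px),
                                         **kwargs)
    truth = prolate_spheroid_truth(major_px, minor_px)
    return {
        "shape": "spheroid",
        "long_axis_px": major_px,
        "volume_error_pct": 100.0 * (vol / truth["volume_px3"] - 1.0),
        "area_error_pct": 100.0 * (area / truth["area_px2"] - 1.0),
    }


def geometric_error_sweep(resolutions, shapes=("sphere", "spheroid"),
                          **kwargs) -> list[dict]:
    """Run the error protocol over a list of long-axis resolutions."""
    rows = []
    for r in resolutions:
        if "sphere" in shapes:
            rows.append(sphere_errors(int(r), **kwargs))
        if "spheroid" in shapes:
            rows.append(spheroid_errors(int(r), **kwargs))
    return rows
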