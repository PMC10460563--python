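"""Build fin/flipper meshes from planar outlines with serial NACA sections.

At each pixel station along the fin span, the chord extent is read off the
planar outline and a symmetric NACA 4-digit section of that chord is drawn,
with thickness equal to the part's base thickness percentage scaled by the
span-wise thickness envelope (square-root profile peaking at the thickest
station).  Sections are lofted into a tube the same way as body rings; span
ends whose section is still open (nonzero thickness) are closed with a tiny
tip ring that merges to a point during cleaning, while ends driven to zero
thickness by the envelope fold shut on their own.

The cephalofoil (hammerhead "hammer") uses the same serial-section
construction with an inverted envelope: factor 1 at both span ends and a
configurable minimum at midspan.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegeneratePlanform
from .geometry_core import (
    cephalofoil_envelope,
    naca_half_thickness,
    thickness_envelope,
)
from .body_mesher import loft_rings
from .mesh_ops import TriMesh
from .outline_processing import station_extents
from .silhouette_io import OutlineTrace

PART_TYPES = ("pectoral", "pelvic", "caudal", "dorsal", "second_dorsal",
              "anal", "cephalofoil")

#: base NACA thickness (percent of chord) per part type
DEFAULT_T_PCT = {"anal": 10.0, "second_dorsal": 10.0}
#: span fraction of the thickest station per part type
DEFAULT_THICKEST_FRAC = {"caudal": 0.5}

#: chordwise sample count per surface (cosine-clustered toward the leading
#: edge); unstated by the construction itself, chosen for leading-edge
#: fidelity at fixed cost
DEFAULT_CHORD_SAMPLES = 60


@dataclass
class PartSpec:
    """Per-fin configuration: thickness, thickest point, and placement.

    ``base_t_pct`` defaults to 10 for anal and second dorsal fins and 20 for
    all other parts; ``thickest_frac`` defaults to 0.5 for the caudal fin
    (symmetric) and 0 (span root) otherwise.  Placement angles are degrees;
    roll (about z) is applied first, then pitch (about x), then yaw
    (about y), then translation.
    """

    part_type: str
    base_t_pct: float | None = None
    thickest_frac: float | None = None
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    cephalofoil_mid_factor: float = 0.6
    span_axis: str | None = None  # "u", "v", or None = longer extent

    def __post_init__(self) -> None:
        if self.part_type not in PART_TYPES:
            raise ValueError(f"unknown part type {self.part_type!r}")
        if self.base_t_pct is None:
            self.base_t_pct = DEFAULT_T_PCT.get(self.part_type, 20.0)
        if self.thickest_frac is None:
            self.thickest_frac = DEFAULT_THICKEST_FRAC.get(self.part_type,
                                                           0.0)
        if self.base_t_pct <= 0:
            raise ValueError("base_t_pct must be positive")
        if not 0.0 <= self.thickest_frac <= 1.0:
            raise ValueError("thickest_frac must lie in [0, 1]")


def _planform_stations(planar: OutlineTrace, spec: PartSpec):
    """Per-span-station chord intervals from the planar outline.

    Returns (span_positions, chord_lo, chord_hi).  The span axis is the
    planform's longer foreground axis unless overridden in the spec.
    """
    pts = planar.points
    extent_u = pts[:, 0].max() - pts[:, 0].min()
    extent_v = pts[:, 1].max() - pts[:, 1].min()
    axis = spec.span_axis or ("u" if extent_u >= extent_v else "v")
    if axis == "v":
        pts = pts[:, ::-1]
    trace = OutlineTrace(points=pts, closed=planar.closed)
    stations, lo, hi = station_extents(trace)
    if len(stations) < 2:
        raise DegeneratePlanform("planform spans < 2 px along the span axis")
    return stations.astype(float), lo, hi


def _section_rings(spans, lo, hi, factors, base_t_pct,
                   n_chord: int) -> np.ndarray:
    """(S, R, 3) NACA section rings in the fin's local frame.

    Local frame: x chordwise (leading edge at the lower chord extent),
    y thickness, z span.  Each ring runs over the upper surface from leading
    to trailing edge then back along the lower surface; the blunt trailing
    edge of the printed polynomial is closed by the ring's wrap-around edge.
    """
    beta = np.linspace(0.0, np.pi, n_chord)
    xf = 0.5 * (1.0 - np.cos(beta))  # cosine clustering at both chord ends
    chords = hi - lo
    t_eff = np.maximum(base_t_pct * np.asarray(factors), 1e-9)
    half = np.stack([naca_half_thickness(xf, t) for t in t_eff])  # (S, C)
    half *= chords[:, None]
    xloc = lo[:, None] + xf[None, :] * chords[:, None]
    # ring: upper LE->TE, then lower TE->LE excluding the shared LE vertex
    rx = np.concatenate([xloc, xloc[:, -1:0:-1]], axis=1)
    ry = np.concatenate([half, -half[:, -1:0:-1]], axis=1)
    rz = np.broadcast_to(spans[:, None], rx.shape)
    rings = np.stack([rx, ry, rz], axis=-1)
    # wrap-around: append the leading-edge vertex to close each ring loop
    return np.concatenate([rings, rings[:, :1, :]], axis=1)


def _tip_ring(ring: np.ndarray, dz: float, radius: float) -> np.ndarray:
    """Shrink a ring to an absolute size below the merge tolerance and push
    it one pixel beyond the span end."""
    centroid = ring.mean(axis=0)
    offsets = ring - centroid
    extent = np.abs(offsets).max()
    scale = radius / extent if extent > 0 else 0.0
    tip = centroid + offsets * min(scale, 1.0)
    tip[:, 2] += dz
    return tip


def _build_serial_sections(planar: OutlineTrace, spec: PartSpec,
                           factors_fn, n_chord: int,
                           tip_radius: float) -> TriMesh:
    spans, lo, hi = _planform_stations(planar, spec)
    chords = hi - lo
    if np.all(chords <= 0):
        raise DegeneratePlanform("all chords are zero")
    span_frac = (spans - spans[0]) / (spans[-1] - spans[0])
    factors = factors_fn(span_frac)
    rings = _section_rings(spans, lo, hi, factors, spec.base_t_pct, n_chord)
    stack = [rings]
    # cap only span ends whose section is an open ring (nonzero thickness);
    # zero-thickness ends already fold shut when upper/lower vertices merge
    first, last = rings[0], rings[-1]
    if np.abs(first[:, 1] - first[:, 1].mean()).max() > tip_radius:
        stack.insert(0, _tip_ring(first, -1.0, tip_radius)[None])
    if np.abs(last[:, 1] - last[:, 1].mean()).max() > tip_radius:
        stack.append(_tip_ring(last, 1.0, tip_radius)[None])
    return loft_rings(np.concatenate(stack, axis=0))


def build_fin_mesh(planar: OutlineTrace, spec: PartSpec,
                   n_chord: int = DEFAULT_CHORD_SAMPLES,
                   tip_radius_px: float = 1e-4) -> TriMesh:
    """Build the (uncleaned) mesh of a fin or flipper from its planar
    outline, using the standard tip-thinning thickness envelope."""
    return _build_serial_sections(
        planar, spec,
        lambda s: thickness_envelope(s, spec.thickest_frac),
        n_chord, tip_radius_px)


def build_cephalofoil_mesh(planar: OutlineTrace, spec: PartSpec,
                           n_chord: int = DEFAULT_CHORD_SAMPLES,
                           tip_radius_px: float = 1e-4) -> TriMesh:
    """Build the (uncleaned) cephalofoil mesh: thickest at both span ends
    (where the eye sockets sit), thinnest at midspan."""
    return _build_serial_sections(
        planar, spec,
        lambda s: cephalofoil_envelope(s, spec.cephalofoil_mid_factor),
        n_chord, tip_radius_px)
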