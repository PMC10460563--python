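"""Superellipse rings, NACA 4-digit foil sections, and thickness envelopes.

A superellipse generalizes the ellipse::

    |x / a|^n + |y / b|^n = 1,   n > 0

n = 2 is the ellipse; n -> larger approaches a rectangle, n -> 1 a diamond.
Body cross-sections of marine vertebrates are well bracketed by two
superellipses with different exponents, which is the basis of the volume
bracketing performed by this package.

Fins and flippers use symmetric (uncambered) NACA 4-digit foil sections,
whose half-thickness as a fraction of chord is the classical polynomial

    y_t = 5 (t/100) [0.2969 sqrt(x) - 0.1260 x - 0.3516 x^2
                     + 0.2843 x^3 - 0.1015 x^4]

with x the chord fraction in [0, 1] and t the thickness in percent of chord.
The printed -0.1015 trailing-edge coefficient (open trailing edge) is kept
verbatim; the mesher closes the trailing edge geometrically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma

from .exceptions import InvalidExponent, OutOfChord

#: default vertex count per section ring: one vertex per 2 degrees, with the
#: first and last coincident (merged later during cleaning -> 180 unique)
DEFAULT_RING_VERTICES = 181

_NACA_COEFFS = (0.2969, -0.1260, -0.3516, 0.2843, -0.1015)


@dataclass
class SuperellipseSection:
    """One superelliptical cross-section ring at axial station ``z``."""

    a: float
    b: float
    n: float
    center: tuple[float, float]
    z: float
    vertices: np.ndarray = field(repr=False)


@dataclass
class FoilSection:
    """A single sampled point of a symmetric NACA 4-digit section."""

    chord_px: float
    t_pct: float
    x_frac: float
    half_thickness: float = field(init=False)

    def __post_init__(self) -> None:
        self.half_thickness = float(
            naca_half_thickness(self.x_frac, self.t_pct) * self.chord_px)


def superellipse_vertices(a: float, b: float, n: float,
                          m: int = DEFAULT_RING_VERTICES,
                          center: tuple[float, float] = (0.0, 0.0),
                          z: float = 0.0) -> SuperellipseSection:
    """Sample a superellipse ring at uniform angular parameter spacing.

    Vertices sit at parameter angles theta = 0, 360/(m-1), ..., 360 degrees
    (default m = 181 -> one vertex per 2 degrees) using the signed-power
    parametrization

        x = cx + a sgn(cos t) |cos t|^(2/n)
        y = cy + b sgn(sin t) |sin t|^(2/n)

    so every vertex satisfies the superellipse equation exactly.  The first
    and last vertices coincide and are merged during mesh cleaning.
    """
    if n <= 0:
        raise InvalidExponent(f"superelliptical exponent must be > 0, got {n}")
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    if m < 8:
        raise ValueError("need at least 8 vertices per ring")
    theta = np.linspace(0.0, 2.0 * np.pi, m)
    c, s = np.cos(theta), np.sin(theta)
    e = 2.0 / n
    x = center[0] + a * np.sign(c) * np.abs(c) ** e
    y = center[1] + b * np.sign(s) * np.abs(s) ** e
    verts = np.column_stack([x, y, np.full(m, float(z))])
    verts[-1] = verts[0]  # exact closure of the duplicate endpoint
    return SuperellipseSection(a=a, b=b, n=n, center=tuple(center), z=z,
                               vertices=verts)


def superellipse_area(a: float, b: float, n: float) -> float:
    """Closed-form area enclosed by a superellipse: 4ab G(1+1/n)^2 / G(1+2/n).

    Strictly increasing in n at fixed a, b, which is what makes a pair of
    exponents bracket a body volume.
    """
    if n <= 0:
        raise InvalidExponent(f"superelliptical exponent must be > 0, got {n}")
    return 4.0 * a * b * gamma(1.0 + 1.0 / n) ** 2 / gamma(1.0 + 2.0 / n)


def naca_half_thickness(x_frac, t_pct: float):
    """Half thickness of a symmetric NACA 4-digit section, as chord fraction.

    ``x_frac`` may be a scalar or array of chord fractions in [0, 1];
    ``t_pct`` is the section thickness in percent of chord (e.g. 20 for a
    NACA 0020).
    """
    x = np.asarray(x_frac, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise OutOfChord("chord fraction outside [0, 1]")
    if t_pct <= 0:
        raise ValueError("t_pct must be positive")
    c1, c2, c3, c4, c5 = _NACA_COEFFS
    y = 5.0 * (t_pct / 100.0) * (
        c1 * np.sqrt(x) + c2 * x + c3 * x ** 2 + c4 * x ** 3 + c5 * x ** 4)
    return y if y.ndim else float(y)


def thickness_envelope(span_fracs, thickest_frac: float) -> np.ndarray:
    """Span-wise thickness scale factors for a fin.

    The span coordinate runs from 0 to 1.  A normalized coordinate u is
    assigned along each side of the thickest point: u = 1 at
    ``thickest_frac`` and u = 0 at the relevant fin end; the returned factor
    is sqrt(u).  E.g. halfway between the thickest point and a tip the raw
    thickness is multiplied by sqrt(0.5).

    Inputs outside [0, 1] are clamped with a warning.
    """
    s = np.atleast_1d(np.asarray(span_fracs, dtype=float))
    tf = float(thickest_frac)
    if tf < 0.0 or tf > 1.0:
        warnings.warn("thickest_frac clamped to [0, 1]", stacklevel=2)
        tf = min(max(tf, 0.0), 1.0)
    if np.any(s < 0.0) or np.any(s > 1.0):
        warnings.warn("span fractions clamped to [0, 1]", stacklevel=2)
        s = np.clip(s, 0.0, 1.0)
    u = np.empty_like(s)
    left = s <= tf
    if tf > 0.0:
        u[left] = s[left] / tf
    else:
        u[left] = 1.0  # thickest point at the very end
    if tf < 1.0:
        u[~left] = (1.0 - s[~left]) / (1.0 - tf)
    else:
        u[~left] = 1.0
    return np.sqrt(u)


def cephalofoil_envelope(span_fracs, mid_factor: float = 0.6) -> np.ndarray:
    """End-thickened envelope for a hammerhead cephalofoil.

    Unlike fins that thin toward the tip, the two span ends of a cephalofoil
    (where the eye sockets sit) are the thickest regions: the factor is 1 at
    both ends and dips to ``mid_factor`` at midspan, following the same
    square-root profile as the fin envelope.
    """
    if not 0.0 < mid_factor <= 1.0:
        raise ValueError("mid_factor must lie in (0, 1]")
    s = np.clip(np.atleast_1d(np.asarray(span_fracs, dtype=float)), 0.0, 1.0)
    return mid_factor + (1.0 - mid_factor) * np.sqrt(np.abs(2.0 * s - 1.0))
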