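# Methods

## Model

`bracketvol` estimates the volume, surface area, and mass of a marine
vertebrate with a straight body axis by lofting serial cross-sections along
that axis.

**Coordinate frame.** x is bilateral (right positive), y dorsoventral
(dorsal positive), z antero-posterior (snout at the origin, posterior
positive). Pixel scale is identical across all input images; the
user-supplied body-axis length in meters fixes meters-per-pixel.

**Main body.** The lateral and ventral silhouettes (fins removed) are
binarized (default threshold 0.5 of the luminance range, dark foreground),
reduced to their largest connected component, and traced at the 0.5
iso-level of the mask with marching squares, giving sub-pixel boundary
coordinates. For every pixel station along the body axis the lateral view
yields the dorsoventral diameter and section mid-height, the ventral view
the transverse diameter and mid-width; a 3,000-px body yields 3,000
stations. Each station carries a superellipse |x/a|ⁿ + |y/b|ⁿ = 1 with
semi-axes half the two diameters, sampled at one vertex per 2° of angular
parameter (181 vertices, the duplicated endpoint merged during cleaning to
180) using the signed-power parametrization, which satisfies the section
equation exactly at every vertex. Rings at adjacent stations are stitched
with two triangles per quad. A tiny superelliptical disk (radius 10⁻⁴ px)
is added one station beyond each body end; vertex merging collapses it to a
point that closes the mesh without measurable effect on volume or area.

Two body meshes are built, differing only in the exponent pair
(n_low, n_high). Superellipse area is 4ab·Γ(1+1/n)²/Γ(1+2/n), strictly
increasing in n, so the pair brackets any body whose true sections lie
between the two shapes. Preset pairs: tetrapod/cetacean 2.0–2.4 (narrower
2.0–2.3 also exposed), shark 1.8–2.0, typical bony fish 1.8–2.1, U-shaped
(flat-bellied) fish 2.2–2.4, strongly compressed V-shaped fish 1.6–1.7.
There is no automatic clade detection; the user picks or overrides.

**Fins.** Each fin/flipper is supplied as one planar silhouette. The span
axis is the planform's longer foreground axis (overridable); at each pixel
station along the span the chord interval is read off the outline and a
symmetric NACA 4-digit section is drawn with thickness t (percent of chord)
equal to the part's base value — 10 for anal and second dorsal fins, 20
otherwise — multiplied by the thickness envelope: with the thickest station
at span fraction f (0 for paired fins and dorsals, 0.5 for the caudal), a
normalized coordinate u runs from 1 at f to 0 at each fin end and the
envelope is √u, e.g. √0.5 midway between thickest point and tip. The NACA
polynomial is kept with its printed open-trailing-edge coefficient
(−0.1015); each section ring simply closes across the blunt trailing edge.
Sections use 60 chordwise samples per surface, cosine-clustered so the
curved leading edge is well resolved at fixed cost. In the t interpretation,
t = 20 means max thickness ≈ 20% of chord (the standard 00xx reading);
treating the "percent" value as a raw multiplier would produce foils 100×
too thick.

Span ends whose section still has thickness (e.g. the root of a pectoral
flipper, where the envelope is 1) are closed with the same tiny-tip trick
as the body; ends driven to zero thickness by the envelope fold shut on
their own when the coincident upper/lower vertices merge, and adding a cap
there would create duplicate faces, so capping is conditional on end-ring
thickness exceeding the tip radius.

**Cephalofoil.** The hammerhead "hammer" uses the same serial-section
construction with an inverted envelope: factor 1 at both span ends (eye
sockets), dipping to a configurable minimum (default 0.6) at midspan with
the same square-root profile. The magnitude of the end thickening is a
modeling choice exposed in configuration, not a measured constant.

**Cleaning and measurement.** Cleaning merges vertices within 10⁻⁴ px
(absolute, clusters found with a KD-tree and united to their mean), removes
degenerate, duplicate, and non-manifold faces, and flags the mesh
watertight only if every edge borders exactly two faces; remaining boundary
edges raise `NotCloseable`, the failure mode typical of unsmoothed or
low-resolution input. Volume is the absolute signed-tetrahedron sum over
faces (divergence theorem) after a global orientation pass; area is the sum
of triangle areas. Volume refuses to run on an uncleaned mesh. trimesh is
used for file export/import only and serves as an independent cross-check
of volume/area in the test suite, never as the measurement path.

**Mass.** Per exponent, total volume = body + Σ parts; overlap between body
and placed fins is counted twice (Boolean union is out of scope; the
overlap is ordinarily small against body volume). Mass = total volume ×
density for a fixed seawater density 1.027 g/cm³ and a user density
defaulting to 1.000 g/cm³. Fin placement (roll about z, then pitch about x,
then yaw about y, about the part's vertex centroid, then translation) only
affects the exported assembly; measurement uses unplaced parts, and rigid
motion preserves both measures regardless.

## Smoothing

Outlines may be smoothed ("interpolation with local regression") before
profile extraction; the default is on, with nearest-neighbor fraction
nn = 0.1 (0.05 suits small fin outlines). The outline is split at its
extreme axial points into two branches; each branch's transverse coordinate
is regressed on the axial coordinate with a tricube-weighted local
*quadratic* and replaced by the fit. Local quadratic is used because the
contract is that affine boundaries pass through unchanged while pixel noise
variance shrinks, and a locally linear fit biases strongly curved branches
(sphere poles) outward/inward; the quadratic keeps that bias below the
rendering noise at the recommended resolutions. Window ties are broken by
contiguous sort-order neighborhoods, the standard LOESS convention; a
window collapsing to zero axial width falls back to the weighted mean.

## Synthetic data

All test silhouettes are rendered in-package: an analytic indicator
function is supersampled 4×4 per pixel to an anti-aliased grayscale PNG
(dark on white), mimicking raster exports from vector-drawing software, so
thresholding at 0.5 recovers the boundary to sub-pixel accuracy. Shapes:
circle, ellipse, rectangle, filled superellipse profile, and a synthetic
fish (elliptical body profiles + rectangular caudal fin). Ground truth
uses closed forms where they exist (sphere V = 4/3πr³, A = 4πr²; prolate
spheroid V = 4/3πab², S = 2πb²(1 + a/(be)·arcsin e)) and otherwise a
10⁴-station 1D quadrature of the closed-form section area, documented as
the oracle. Shape boundaries are placed on half-integer pixel coordinates
so a nominal 3,000-px shape binarizes to exactly 3,000 foreground pixel
stations.

What this does *not* emulate: hand-traced outlines with correlated tracing
error, JPEG artifacts, uncertain fin/body separation, or curved body axes.
Passing the geometric suite therefore demonstrates the fidelity of the
reconstruction and measurement machinery, not the accuracy of any
particular animal's silhouette.

## Numerical choices

- Binarization threshold 0.5, dark = foreground; both configurable. Only
  the largest connected component is kept (discards compression specks).
- Station grids are the integer pixel positions inside each trace's axial
  span; the two body views are aligned at their anterior-most points and
  must agree in span to 1% (else `ViewLengthMismatch`).
- 181 ring vertices ≙ 2° parameter steps: polygon-vs-section area deficit
  ≈ 0.02%, well below the 0.5% accuracy target; the count is configurable.
- Merge tolerance 10⁻⁴ px and tip radius 10⁻⁴ px are coupled: the tip ring
  must collapse within the merge distance.
- Zero-area faces are dropped at 10⁻¹² px²; interior zero diameters raise
  an error instead of being bridged.
- Degenerate inputs: empty masks, sub-2-px components, all-zero chords,
  and n ≤ 0 exponents all raise typed exceptions early.

## Validation protocol and problem sizes

The geometric protocol feeds one rendered shape in as *both* body views:
a circle yields a sphere at n = 2, a 5:1 ellipse a prolate spheroid.
Signed percent errors against the closed forms at 3,000 px long axis are
≈ −0.02% (sphere volume), −0.01% (sphere area), −0.09% (spheroid volume),
−0.06% (spheroid area); all magnitudes stay below 0.5% from 800 px up and
shrink with resolution. The documented sweep grid is 100–1,000 px in steps
of 100 and 1,000–10,000 in steps of 1,000 (19 resolutions); the test suite
spot-checks 400, 800, and 3,000 px, which already exercises both the
sub-recommended and recommended regimes. Bracketing is property-tested on
an elliptical-section solid (exact at n = 2): its true volume must fall
strictly inside [V(1.9), V(2.1)].

## Known limitations

- Straight body axis only; no lateral concavities (a concave boundary
  branch is not single-valued in z) and no dorso-ventral fin concavities.
- Overlap double-counting biases totals slightly upward when fins are
  deeply embedded in the body.
- One exponent pair per run; dorsal and ventral body halves share the same
  exponent.
- The cephalofoil end-thickening profile is a configurable assumption.
- Accuracy on real animals is bounded by silhouette quality and exponent
  choice, not by the machinery validated here.
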