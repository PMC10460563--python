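"""Load raster silhouettes, binarize them, and trace sub-pixel outlines.

Silhouettes are conventionally drawn as dark shapes on a light background;
the loader converts to luminance, thresholds (default at half of the full
range), keeps the largest connected foreground component, and warns when the
long axis falls below the recommended 3,000 px.  Outlines are traced at the
0.5 iso-level of the binary mask (marching squares), so coordinates are
real-valued and ready for local-regression smoothing downstream.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import imageio.v3 as iio
from skimage import measure

from .exceptions import (
    DegenerateSilhouette,
    EmptySilhouette,
    LowResolutionWarning,
    UnreadableImage,
)

#: long-axis pixel count below which a low-resolution warning is emitted
RECOMMENDED_AXIS_PX = 3000

_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class SilhouetteImage:
    """A binarized single-component silhouette.

    ``grid`` is a 2D boolean mask (rows x cols, row index increasing
    downward); pixel scale is implicit and must be identical across all
    images of one model.
    """

    grid: np.ndarray
    source_path: str = ""
    view_tag: str = "lateral"

    @property
    def height_px(self) -> int:
        return int(self.grid.shape[0])

    @property
    def width_px(self) -> int:
        return int(self.grid.shape[1])

    @classmethod
    def from_array(cls, mask: np.ndarray, view_tag: str = "lateral",
                   source_path: str = "<array>") -> "SilhouetteImage":
        """Wrap an in-memory boolean mask (keeps largest component)."""
        return _finalize_mask(np.asarray(mask, dtype=bool), source_path,
                              view_tag, warn_resolution=False)


@dataclass
class OutlineTrace:
    """Closed boundary of a silhouette as ordered (u, v) pixel coordinates.

    ``u`` is the column coordinate, ``v`` the row coordinate.  Points are
    ordered counter-clockwise in the conventional y-up frame (clockwise in
    raster row-down coordinates) and the first point is not repeated at the
    end; ``closed`` marks the implicit wrap-around.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def u(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.points[:, 1]


def _to_luminance(arr: np.ndarray) -> np.ndarray:
    """Convert a decoded image array to luminance in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        a = a[..., :3] @ _LUMA if a.shape[-1] >= 3 else a[..., 0]
    a = a.astype(float)
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        a = a / np.iinfo(np.asarray(arr).dtype).max
    elif a.max() > 1.0:
        a = a / 255.0
    return np.clip(a, 0.0, 1.0)


def _finalize_mask(mask: np.ndarray, path: str, view_tag: str,
                   warn_resolution: bool = True) -> SilhouetteImage:
    if not mask.any():
        raise EmptySilhouette(f"no foreground pixels in {path!r}")
    labels = measure.label(mask, connectivity=2)
    if labels.max() > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        mask = labels == int(np.argmax(counts))
    rows, cols = np.nonzero(mask)
    long_axis = max(rows.max() - rows.min(), cols.max() - cols.min()) + 1
    if warn_resolution and long_axis < RECOMMENDED_AXIS_PX:
        warnings.warn(
            f"silhouette {path!r} long axis is {long_axis} px; at least "
            f"{RECOMMENDED_AXIS_PX} px along the body axis is recommended",
            LowResolutionWarning,
            stacklevel=3,
        )
    return SilhouetteImage(grid=mask, source_path=path, view_tag=view_tag)


def load_silhouette(path, threshold: float = 0.5, foreground: str = "dark",
                    view_tag: str = "lateral") -> SilhouetteImage:
    """Load and binarize a silhouette raster image (PNG/JPEG/TIFF).

    Parameters
    ----------
    path
        Image file path.
    threshold
        Luminance fraction in [0, 1] separating foreground from background.
    foreground
        ``"dark"`` keeps pixels below the threshold, ``"light"`` above.
    view_tag
        One of ``lateral``, ``ventral``, ``planar``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if foreground not in ("dark", "light"):
        raise ValueError("foreground must be 'dark' or 'light'")
    try:
        raw = iio.imread(path)
    except Exception as exc:  # decode failures vary by backend
        raise UnreadableImage(f"cannot decode {path!r}: {exc}") from exc
    lum = _to_luminance(raw)
    mask = lum < threshold if foreground == "dark" else lum > threshold
    return _finalize_mask(mask, str(path), view_tag)


def extract_outline(img: SilhouetteImage) -> OutlineTrace:
    """Trace the closed foreground boundary at sub-pixel precision.

    The boundary is the 0.5 iso-contour of the binary mask (marching
    squares), returned counter-clockwise with respect to the y-up frame.
    """
    rows, cols = np.nonzero(img.grid)
    if rows.max() - rows.min() < 1 or cols.max() - cols.min() < 1:
        raise DegenerateSilhouette(
            "foreground component is < 2 px in at least one dimension")
    padded = np.pad(img.grid.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) -> (u, v); undo padding offset
    pts = np.column_stack([contour[:, 1], contour[:, 0]]) - 1.0
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    # CCW in y-up frame <=> negative shoelace area in row-down coordinates
    area2 = np.sum(pts[:, 0] * np.roll(pts[:, 1], -1)
                   - np.roll(pts[:, 0], -1) * pts[:, 1])
    if area2 > 0:
        pts = pts[::-1]
    return OutlineTrace(points=pts, closed=True)
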