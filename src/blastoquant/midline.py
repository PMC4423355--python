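"""Midline spline and the 10%-of-embryo-height extraction strip.

The lateral midline of the aligned embryo is initialised from the
morphological skeleton of the mask, smoothed, and modelled as a natural
cubic spline through five knots equidistant in x across the mask's
horizontal span (manual knot overrides replace the automatic placement
verbatim).  The extraction strip is the band of height 10% of the mask
height centred on the spline.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from skimage.morphology import skeletonize

from .core import ValidationError, as_uint8, round_half_up
from .segmentation import EmbryoMask

DEFAULT_STRIP_FRACTION = 0.10
DEFAULT_KNOT_COUNT = 5
SKELETON_SMOOTH_PX = 15


class DegenerateSkeletonError(ValidationError):
    """Skeleton has no usable antero-posterior extent (e.g. circular mask)."""


class AmbiguousSkeletonError(ValidationError):
    """Skeleton branches with no dominant path."""


@dataclass
class MidlineSpline:
    """Natural cubic spline through equidistant knots, parameterised by x."""

    knots: np.ndarray  # (n, 2) array of (x, y)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[1] != 2:
            raise ValidationError("knots must be an (n, 2) array of (x, y)")
        if len(self.knots) < 3:
            raise ValidationError("at least three knots required")
        x = self.knots[:, 0]
        if np.any(np.diff(x) <= 0):
            raise ValidationError("knot x-values must be strictly increasing")
        steps = np.diff(x)
        if np.any(np.abs(steps - steps[0]) > 1e-6 * max(steps[0], 1.0)):
            raise ValidationError("knot x-values must be equidistant")
        self._spline = CubicSpline(x, self.knots[:, 1], bc_type="natural")

    @property
    def x_start(self) -> float:
        return float(self.knots[0, 0])

    @property
    def x_end(self) -> float:
        return float(self.knots[-1, 0])

    def __call__(self, x) -> np.ndarray:
        return self._spline(x)

    def derivative(self, x) -> np.ndarray:
        return self._spline(x, 1)

    def mirrored(self, width: int) -> "MidlineSpline":
        """Spline of the horizontally mirrored image of width ``width``."""
        flipped = self.knots[::-1].copy()
        flipped[:, 0] = (width - 1) - flipped[:, 0]
        return MidlineSpline(flipped)


@dataclass
class StripBand:
    """Extraction geometry: midline spline plus strip height in pixels."""

    spline: MidlineSpline
    height_px: int

    def __post_init__(self) -> None:
        if self.height_px < 1:
            raise ValidationError("strip height must be at least one pixel")


def skeleton_midline(mask: EmbryoMask) -> np.ndarray:
    """Longest path through the mask skeleton, ordered left-to-right.

    Returns an (n, 2) array of (x, y) pixel coordinates.  The skeleton of
    an elongated mask is a single arc (possibly with short spurs); the
    path between its two most distant endpoints is extracted by double
    breadth-first search.
    """
    skel = skeletonize(mask.mask)
    ys, xs = np.nonzero(skel)
    n = len(xs)
    if n < 10 or xs.max() - xs.min() < 0.2 * mask.width_px:
        raise DegenerateSkeletonError(
            "degenerate skeleton: no antero-posterior extent (circular mask?)"
        )
    pixels = set(zip(xs.tolist(), ys.tolist()))

    def neighbours(p):
        x, y = p
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if (dx or dy) and (x + dx, y + dy) in pixels:
                    yield (x + dx, y + dy)

    def bfs(start):
        prev = {start: None}
        queue = deque([start])
        last = start
        while queue:
            p = queue.popleft()
            last = p
            for q in neighbours(p):
                if q not in prev:
                    prev[q] = p
                    queue.append(q)
        return last, prev

    far, _ = bfs(next(iter(pixels)))
    end, prev = bfs(far)
    path = []
    p = end
    while p is not None:
        path.append(p)
        p = prev[p]
    if len(path) < 0.6 * n:
        raise AmbiguousSkeletonError(
            "branched skeleton: no dominant path covers the skeleton"
        )
    arr = np.asarray(path, dtype=float)
    if arr[0, 0] > arr[-1, 0]:
        arr = arr[::-1]
    return arr


def _smooth_path(path: np.ndarray, window: int = SKELETON_SMOOTH_PX):
    """Collapse the path to one y per x and moving-average smooth it."""
    xs = np.rint(path[:, 0]).astype(int)
    order = np.argsort(xs, kind="stable")
    xs, ys = xs[order], path[order, 1]
    ux, inverse = np.unique(xs, return_inverse=True)
    sums = np.bincount(inverse, weights=ys)
    counts = np.bincount(inverse)
    uy = sums / counts
    w = min(window, len(ux))
    if w > 1:
        kernel = np.ones(w) / w
        pad = w // 2
        padded = np.pad(uy, pad, mode="edge")
        uy = np.convolve(padded, kernel, mode="same")[pad : pad + len(ux)]
    return ux.astype(float), uy


def place_knots(
    path: np.ndarray,
    mask: EmbryoMask,
    n_knots: int = DEFAULT_KNOT_COUNT,
    override_knots=None,
) -> MidlineSpline:
    """Equidistant knots across the mask span, y read off the skeleton.

    ``override_knots`` (a list of (x, y)) replaces the computed knots
    verbatim, mirroring manual adjustment of the midline.
    """
    if override_knots is not None:
        override = np.asarray(override_knots, dtype=float)
        if override.shape != (n_knots, 2):
            raise ValidationError(f"override must supply exactly {n_knots} knots")
        return MidlineSpline(override)
    if path is None or len(path) < 2:
        raise DegenerateSkeletonError("non-degenerate skeleton path required")
    knot_x = np.linspace(mask.x_min, mask.x_max, n_knots)
    px, py = _smooth_path(path)
    knot_y = np.interp(knot_x, px, py)
    # Keep knots inside the mask even near the poles, where the skeleton
    # stops short and extrapolation could drift off the tapering body.
    for i, (kx, ky) in enumerate(zip(knot_x, knot_y)):
        extent = mask.column_extent(int(round(kx)))
        if extent is not None:
            knot_y[i] = float(np.clip(ky, extent[0], extent[1]))
    return MidlineSpline(np.column_stack([knot_x, knot_y]))


def fit_midline(mask: EmbryoMask, n_knots: int = DEFAULT_KNOT_COUNT,
                override_knots=None) -> MidlineSpline:
    """Convenience: skeleton extraction followed by knot placement."""
    path = None if override_knots is not None else skeleton_midline(mask)
    return place_knots(path, mask, n_knots=n_knots, override_knots=override_knots)


def make_strip(
    spline: MidlineSpline,
    mask: EmbryoMask,
    strip_fraction: float = DEFAULT_STRIP_FRACTION,
) -> StripBand:
    """Extraction strip of height = strip_fraction x mask height (rounded).

    Rounding is half-up to an integer pixel count.
    """
    if not 0 < strip_fraction <= 0.5:
        raise ValidationError("strip fraction must lie in (0, 0.5]")
    h = mask.height_px
    if h < 1:
        raise ValidationError("mask height must be positive")
    height_px = round_half_up(strip_fraction * h)
    if height_px < 1:
        raise ValidationError("strip height rounds to zero pixels")
    strip = StripBand(spline, height_px)
    rows, cols = strip_coords(strip, mask.mask.shape)
    if rows.size == 0:
        raise ValidationError("strip lies entirely outside the image")
    return strip


def strip_coords(strip: StripBand, shape: tuple[int, int]):
    """Integer (rows, cols) of every strip pixel inside ``shape``.

    Columns are perpendicular to the local spline tangent, of length
    ``height_px`` at unit spacing, centred on the spline point; pixels
    falling outside the image are clipped (with a warning if any are).
    """
    xs = np.arange(int(np.ceil(strip.spline.x_start)),
                   int(np.floor(strip.spline.x_end)) + 1)
    ys = strip.spline(xs)
    d = strip.spline.derivative(xs)
    norm = np.sqrt(1.0 + d * d)
    nx, ny = -d / norm, 1.0 / norm  # unit normal to the tangent (1, d)
    offsets = np.arange(strip.height_px) - (strip.height_px - 1) / 2.0
    px = xs[None, :] + offsets[:, None] * nx[None, :]
    py = ys[None, :] + offsets[:, None] * ny[None, :]
    cols = np.rint(px).astype(int).ravel()
    rows = np.rint(py).astype(int).ravel()
    inside = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    if not inside.all():
        warnings.warn("strip exceeds image bounds; clipped", stacklevel=2)
    return rows[inside], cols[inside]


def render_band(strip: StripBand, mask: EmbryoMask) -> np.ndarray:
    """`_band` overlay: strip highlighted on the binary mask."""
    base = np.repeat(mask.to_image()[:, :, None], 3, axis=2).astype(float)
    rows, cols = strip_coords(strip, mask.mask.shape)
    base[rows, cols] = [255, 0, 0]
    return as_uint8(base)


def render_stband(strip: StripBand, bright: np.ndarray) -> np.ndarray:
    """`_stband` overlay: strip outline blended onto the bright-field image."""
    img = np.asarray(bright, dtype=float).copy()
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    rows, cols = strip_coords(strip, img.shape[:2])
    img[rows, cols] = 0.55 * img[rows, cols] + 0.45 * np.array([255.0, 0.0, 0.0])
    return as_uint8(img)
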