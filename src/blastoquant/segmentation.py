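"""Whole-embryo masking from DIC images and canonical alignment.

The DIC image shows the embryo as a dark textured body on a bright
background.  Automatic thresholding plus morphological cleanup produces a
single filled mask; the mask's principal axis then defines the rotation
that brings the embryo into the canonical frame (anterior left, dorsal
up, major axis horizontal), and all registered images are cropped to the
mask bounding box plus a fixed margin.  Antero-posterior polarity cannot
be inferred from morphology alone and is supplied as metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology, transform

from .core import EmbryoRecord, ValidationError, as_uint8

DEFAULT_CROP_MARGIN_PX = 10


class NoEmbryoFoundError(ValidationError):
    """No sufficiently large foreground component in the DIC image."""


class MultipleEmbryosError(ValidationError):
    """Two comparable foreground components: scene is not single-embryo."""


class MaskQualityError(ValidationError):
    """Mask violates the ellipse-like sanity invariants."""


@dataclass
class EmbryoMask:
    """Binary whole-embryo mask plus derived geometry."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValidationError("empty mask")

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), max edges inclusive."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max())

    @property
    def height_px(self) -> int:
        r0, _, r1, _ = self.bbox
        return r1 - r0 + 1

    @property
    def width_px(self) -> int:
        _, c0, _, c1 = self.bbox
        return c1 - c0 + 1

    @property
    def x_min(self) -> int:
        return self.bbox[1]

    @property
    def x_max(self) -> int:
        return self.bbox[3]

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centroid in pixel coordinates."""
        rows, cols = np.nonzero(self.mask)
        return float(cols.mean()), float(rows.mean())

    @property
    def angle_deg(self) -> float:
        """Principal-axis angle, counter-clockwise from horizontal (y-up).

        Computed from the principal component of the foreground pixel
        coordinates; a circularly symmetric mask (degenerate tie) is
        declared horizontal.
        """
        rows, cols = np.nonzero(self.mask)
        x = cols - cols.mean()
        y = -(rows - rows.mean())  # flip to y-up
        cov = np.cov(np.stack([x, y]))
        evals, evecs = np.linalg.eigh(cov)
        if evals[1] - evals[0] < 1e-9 * max(evals[1], 1.0):
            return 0.0  # tie: declare the image x-axis the major axis
        vx, vy = evecs[:, 1]  # leading eigenvector
        angle = math.degrees(math.atan2(vy, vx))
        if angle <= -90:
            angle += 180
        elif angle > 90:
            angle -= 180
        return angle

    def column_extent(self, x: int) -> tuple[int, int] | None:
        """(min_row, max_row) of the mask in column x, or None if empty."""
        rows = np.nonzero(self.mask[:, x])[0]
        if rows.size == 0:
            return None
        return int(rows.min()), int(rows.max())

    def to_image(self) -> np.ndarray:
        return as_uint8(self.mask.astype(float) * 255.0)


def compute_mask(dic: np.ndarray) -> EmbryoMask:
    """Binary whole-embryo mask from a DIC image.

    Procedure: automatic (Otsu) intensity threshold with the embryo on
    the dark side, morphological closing, largest-connected-component
    selection, hole filling.  Deterministic.
    """
    img = np.asarray(dic, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.max() - img.min() < 10:
        raise NoEmbryoFoundError("no embryo found: image has no contrast")
    from skimage.filters import threshold_otsu

    fg = img < threshold_otsu(img)
    fg = morphology.closing(fg, morphology.disk(5))
    labels = measure.label(fg)
    if labels.max() == 0:
        raise NoEmbryoFoundError("no embryo found: empty foreground")
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(areas)[::-1]
    largest = areas[order[0]]
    if largest < 0.05 * img.size:
        raise NoEmbryoFoundError(
            "no embryo found: largest component covers <5% of the frame"
        )
    if len(order) > 1 and areas[order[1]] >= 0.5 * largest:
        raise MultipleEmbryosError("multiple embryos: two comparable components")
    mask = ndimage.binary_fill_holes(labels == order[0] + 1)
    em = EmbryoMask(mask)
    fill = em.area / (em.height_px * em.width_px)
    if not 0.5 <= fill <= 0.95:
        raise MaskQualityError(
            f"mask is not ellipse-like: bounding-box fill fraction {fill:.2f}"
        )
    return em


def _rotate(img: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    """Rotate about the image centre; border filled with the edge median."""
    img = np.asarray(img)
    border = np.concatenate([img[0].ravel(), img[-1].ravel(),
                             img[:, 0].ravel(), img[:, -1].ravel()])
    cval = float(np.median(border))
    out = transform.rotate(
        img.astype(float), angle_deg, resize=False, order=order,
        mode="constant", cval=cval, preserve_range=True,
    )
    return out


def align_record(
    record: EmbryoRecord,
    mask: EmbryoMask,
    anterior_on_left: bool = True,
    margin: int = DEFAULT_CROP_MARGIN_PX,
) -> tuple[EmbryoRecord, EmbryoMask]:
    """Rotate, crop and (if needed) mirror a record into the canonical frame.

    The principal axis is brought horizontal (within 0.5 degrees,
    iterating if interpolation shifts it), all 10X images are cropped to
    the mask bounding box plus ``margin`` pixels, and the scene is
    mirrored horizontally when the anterior pole is on the right.  The
    membrane image (40X, unregistered) passes through untouched.
    """
    for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00"):
        img = record.images.get(suffix)
        if img is not None and img.shape[:2] != mask.mask.shape:
            raise ValidationError(
                f"mask/image dimension mismatch for {suffix}: "
                f"{mask.mask.shape} vs {img.shape[:2]}"
            )

    images = {k: np.asarray(v, dtype=float) for k, v in record.images.items()}
    m = mask.mask
    total_angle = 0.0
    for _ in range(3):
        angle = EmbryoMask(m).angle_deg
        if abs(angle) <= 0.5:
            break
        # skimage's positive rotation adds to the y-up principal-axis
        # angle, so rotating by -angle brings the axis horizontal.
        m = _rotate(m.astype(float), -angle, order=0) > 0.5
        total_angle += -angle
    if abs(total_angle) > 0:
        for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00"):
            if suffix in images:
                images[suffix] = _rotate(images[suffix], total_angle, order=1)

    aligned = EmbryoMask(m)
    r0, c0, r1, c1 = aligned.bbox
    h, w = m.shape
    r0, c0 = max(0, r0 - margin), max(0, c0 - margin)
    r1, c1 = min(h - 1, r1 + margin), min(w - 1, c1 + margin)
    m = m[r0 : r1 + 1, c0 : c1 + 1]
    for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00"):
        if suffix in images:
            images[suffix] = images[suffix][r0 : r1 + 1, c0 : c1 + 1]

    if not anterior_on_left:
        m = m[:, ::-1]
        for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00"):
            if suffix in images:
                images[suffix] = images[suffix][:, ::-1]

    out_images = {k: as_uint8(v) for k, v in images.items()}
    if "_memb_ch00" in record.images:
        out_images["_memb_ch00"] = record.images["_memb_ch00"]
    out = record.with_images(out_images)
    out.metadata["aligned"] = True
    out.metadata["anterior_on_left"] = True
    return out, EmbryoMask(m)
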