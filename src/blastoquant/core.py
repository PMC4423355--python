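"""Shared primitives for the quantification pipeline.

Every embryo enters the pipeline as an :class:`EmbryoRecord`: four raster
images acquired from one stained embryo (bright-field stain image, DIC
morphology, DAPI nuclear counterstain, membrane-detail DIC) together with
identifiers and stain metadata.  The two colorimetric stains the pipeline
knows about are NBT/BCIP (purple) and FastRed (red).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

# Image suffixes of the on-disk naming scheme: raw/registered inputs ...
IMAGE_SUFFIXES = ("_ch00", "_dic_ch00", "_nuc_ch00", "_memb_ch00")
# ... and derived artifacts written by the pipeline.
DERIVED_SUFFIXES = ("_embmsk", "_band", "_stband", "_prof.dat")
ALL_SUFFIXES = IMAGE_SUFFIXES + DERIVED_SUFFIXES


class ValidationError(ValueError):
    """An input violates a documented contract of the pipeline."""


class Channel(str, Enum):
    """Colorimetric stain channel."""

    NBT_BCIP = "NBT_BCIP"
    FASTRED = "FASTRED"

    @property
    def csv_name(self) -> str:
        """Name used in the deposited CSV tables ('purple' / 'red')."""
        return "purple" if self is Channel.NBT_BCIP else "red"

    @classmethod
    def from_csv_name(cls, name: str) -> "Channel":
        try:
            return {"purple": cls.NBT_BCIP, "red": cls.FASTRED}[name]
        except KeyError:
            raise ValidationError(
                f"unknown channel {name!r}; expected 'purple' or 'red'"
            ) from None

    @classmethod
    def coerce(cls, value) -> "Channel":
        if isinstance(value, cls):
            return value
        if value in ("purple", "red"):
            return cls.from_csv_name(value)
        return cls(value)


@dataclass
class EmbryoRecord:
    """One embryo's image quadruplet plus identifiers and provenance.

    Parameters
    ----------
    embryo_id :
        Zero-padded three-digit identifier within its batch ("001", ...).
    batch_id :
        'species_stain_date' batch identifier, e.g. "ma_gt_260911".
    images :
        Map from suffix to raster.  ``_ch00`` (bright-field) and
        ``_dic_ch00`` (DIC) must share dimensions: both are acquired with
        the same 10X objective and are registered together.  The membrane
        image (40X) is exempt.
    genes, channels :
        Stained gene abbreviation(s) and the stain channel(s) used.
    metadata :
        Free-form provenance: ``anterior_on_left`` (bool), ``background``
        ('wt' or 'rnai'), curator staging overrides, etc.
    """

    embryo_id: str
    batch_id: str
    images: dict[str, np.ndarray]
    genes: tuple[str, ...] = ()
    channels: tuple[Channel, ...] = ()
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for suffix in self.images:
            if suffix not in IMAGE_SUFFIXES:
                raise ValidationError(f"unknown image suffix {suffix!r}")
        ch, dic = self.images.get("_ch00"), self.images.get("_dic_ch00")
        if ch is not None and dic is not None and ch.shape[:2] != dic.shape[:2]:
            raise ValidationError(
                "bright-field and DIC images must share dimensions "
                f"({ch.shape[:2]} vs {dic.shape[:2]})"
            )
        self.channels = tuple(Channel.coerce(c) for c in self.channels)

    @property
    def background(self) -> str:
        """'wt' or 'rnai' (default 'wt')."""
        return self.metadata.get("background", "wt")

    def with_images(self, images: dict[str, np.ndarray]) -> "EmbryoRecord":
        """Copy of this record with (some) images replaced."""
        merged = dict(self.images)
        merged.update(images)
        return EmbryoRecord(
            embryo_id=self.embryo_id,
            batch_id=self.batch_id,
            images=merged,
            genes=self.genes,
            channels=self.channels,
            metadata=dict(self.metadata),
        )


def as_uint8(img: np.ndarray) -> np.ndarray:
    """Clip a float raster into the 8-bit range and cast."""
    return np.clip(np.rint(np.asarray(img, dtype=float)), 0, 255).astype(np.uint8)


def round_half_up(value: float) -> int:
    """Round to the nearest integer, halves away from zero-upward."""
    return int(np.floor(value + 0.5))
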