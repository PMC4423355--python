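"""Embryo staging: cleavage cycles C1-C14A and C14A time classes T1-T8.

Early fly development proceeds through near-synchronous nuclear division
(cleavage) cycles; the nucleus number roughly doubles each cycle, so the
DAPI counterstain is a direct readout of the cycle.  Cleavage cycle 14A is
long (58 min) and is subdivided into eight equal time classes, which on
real data are distinguished visually from membrane morphology: cell
membranes invaginate progressively from the surface during C14A, so the
invagination depth acts as a clock.  Here the depth is read as a fraction
in [0, 1] -- from the rendered front on synthetic images, or supplied by a
curator on real images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .core import ValidationError

#: Minutes per blastoderm cleavage cycle; earlier cycles (<= C9) all last
#: roughly EARLY_CYCLE_DURATION_MIN.
BLASTODERM_CYCLE_DURATIONS_MIN = {10: 13.0, 11: 11.0, 12: 14.0, 13: 23.0, 14: 58.0}
EARLY_CYCLE_DURATION_MIN = 10.0
N_TIME_CLASSES = 8


class UncountableImageError(ValidationError):
    """Nuclear image is blank or saturated; no nucleus count possible."""


@dataclass(frozen=True)
class TimeClass:
    """A staging label: cleavage cycle plus, within C14A, a time class."""

    cycle: int
    subclass: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.cycle <= 14:
            raise ValidationError(f"cycle must be 1-14, got {self.cycle}")
        if (self.subclass is not None) != (self.cycle == 14):
            raise ValidationError("subclass present iff cycle = 14")
        if self.subclass is not None and not 1 <= self.subclass <= N_TIME_CLASSES:
            raise ValidationError(f"time class must be 1-8, got {self.subclass}")

    @property
    def label(self) -> str:
        if self.cycle == 14:
            return f"C14_T{self.subclass}"
        return f"C{self.cycle}"

    @classmethod
    def parse(cls, label: str) -> "TimeClass":
        if label.startswith("C14_T"):
            try:
                sub = int(label[5:])
            except ValueError:
                raise ValidationError(f"bad time class label {label!r}") from None
            return cls(14, sub)
        if label.startswith("C"):
            try:
                cycle = int(label[1:])
            except ValueError:
                raise ValidationError(f"bad time class label {label!r}") from None
            if cycle == 14:
                raise ValidationError("C14 requires a time class, e.g. 'C14_T3'")
            return cls(cycle)
        raise ValidationError(f"bad time class label {label!r}")

    @property
    def sort_key(self) -> tuple[int, int]:
        return (self.cycle, self.subclass or 0)


#: The 21 valid staging labels in temporal order: C1..C13, C14_T1..C14_T8.
ALL_TIME_CLASS_LABELS: tuple[str, ...] = tuple(
    [f"C{c}" for c in range(1, 14)]
    + [f"C14_T{t}" for t in range(1, N_TIME_CLASSES + 1)]
)


@dataclass(frozen=True)
class StagingTimetable:
    """Durations of the blastoderm stages and the C14A subdivision."""

    cycle_durations_min: dict[int, float] = field(
        default_factory=lambda: dict(BLASTODERM_CYCLE_DURATIONS_MIN)
    )
    early_cycle_duration_min: float = EARLY_CYCLE_DURATION_MIN
    n_time_classes: int = N_TIME_CLASSES

    @property
    def time_class_duration_min(self) -> float:
        """C14A split into equal classes: 58 / 8 = 7.25 min each."""
        return self.cycle_durations_min[14] / self.n_time_classes

    def duration_min(self, cycle: int) -> float:
        if cycle in self.cycle_durations_min:
            return self.cycle_durations_min[cycle]
        return self.early_cycle_duration_min

    @property
    def labels(self) -> tuple[str, ...]:
        return ALL_TIME_CLASS_LABELS


def expected_nucleus_count(cycle: int) -> int:
    """Nuclei double each cycle starting from one nucleus at C1."""
    return 2 ** (cycle - 1)


def count_nuclei(nuc: np.ndarray, mask: np.ndarray | None = None) -> int:
    """Count nuclei on a DAPI-like image by band-pass blob detection.

    A difference-of-Gaussians band-pass suppresses both pixel noise and
    slowly-varying background; nuclei are then counted as local maxima
    above a fraction of the dynamic range, restricted to the embryo mask.
    """
    img = np.asarray(nuc, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    inside = np.ones(img.shape, bool) if mask is None else np.asarray(mask, bool)
    vals = img[inside]
    if vals.size == 0 or vals.max() - vals.min() < 10:
        raise UncountableImageError("blank nuclear image: no dynamic range")
    if np.mean(vals >= 250) > 0.5:
        raise UncountableImageError("saturated nuclear image")
    # Narrow band-pass: nuclei are ~2 px wide and, at cycle 14, only
    # ~3 px apart, so the blob scale must stay close to a single pixel.
    dog = ndimage.gaussian_filter(img, 0.8) - ndimage.gaussian_filter(img, 2.5)
    peaks = peak_local_max(
        dog, min_distance=1, threshold_abs=0.25 * dog.max(), exclude_border=False
    )
    if peaks.size == 0:
        return 0
    keep = inside[peaks[:, 0], peaks[:, 1]]
    return int(keep.sum())


def assign_cycle(n_nuclei: int) -> int:
    """Cleavage cycle from a nucleus count under the doubling model.

    One nucleus at C1 and a doubling per cycle put cycle c at 2**(c-1)
    nuclei; class boundaries sit at the geometric midpoints between
    successive powers of two, which is exactly rounding log2(n).
    """
    if n_nuclei <= 0:
        raise ValidationError(f"nucleus count must be positive, got {n_nuclei}")
    return int(np.clip(round(np.log2(n_nuclei)) + 1, 1, 14))


def assign_time_class(invagination_depth: float) -> int:
    """C14A time class T1-T8 from membrane invagination depth in [0, 1]."""
    if not 0.0 <= invagination_depth <= 1.0:
        raise ValidationError(
            f"invagination depth must be in [0, 1], got {invagination_depth}"
        )
    return min(N_TIME_CLASSES, int(np.floor(invagination_depth * N_TIME_CLASSES)) + 1)


# Geometry of the synthetic membrane rendering shared with the generator:
# the invagination front is drawn as a dark region advancing from the top
# of a fixed vertical band.
MEMBRANE_BAND = {
    "row_lo_frac": 0.08,
    "row_hi_frac": 0.92,
    "col_lo_frac": 0.35,
    "col_hi_frac": 0.65,
    "dark": 60,
    "light": 220,
}


def measure_invagination_depth(memb: np.ndarray) -> float:
    """Read the invagination depth fraction from a rendered membrane image.

    Counts how far the dark membrane front has advanced down the fixed
    measurement band.  This is the synthetic-data inverse of the
    generator's rendering; on real images the depth is curator-supplied.
    """
    img = np.asarray(memb, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    h, w = img.shape
    r0 = int(round(MEMBRANE_BAND["row_lo_frac"] * h))
    r1 = int(round(MEMBRANE_BAND["row_hi_frac"] * h))
    c0 = int(round(MEMBRANE_BAND["col_lo_frac"] * w))
    c1 = int(round(MEMBRANE_BAND["col_hi_frac"] * w))
    band = img[r0:r1, c0:c1]
    if band.size == 0:
        raise ValidationError("membrane image too small to measure")
    row_means = band.mean(axis=1)
    threshold = (MEMBRANE_BAND["dark"] + MEMBRANE_BAND["light"]) / 2.0
    dark = row_means < threshold
    if not dark.any():
        return 0.0
    # Depth = extent of the contiguous dark front from the top of the band.
    front = int(np.flatnonzero(dark).max()) + 1
    return front / len(row_means)


def stage_record(
    nuc: np.ndarray,
    memb: np.ndarray | None,
    mask: np.ndarray | None = None,
    depth_override: float | None = None,
) -> TimeClass:
    """Full staging of one embryo: cycle from nuclei, time class from membrane.

    ``depth_override`` replaces the image-derived invagination depth,
    mirroring curator-supplied classification on real data.
    """
    cycle = assign_cycle(count_nuclei(nuc, mask))
    if cycle < 14:
        return TimeClass(cycle)
    if depth_override is not None:
        depth = depth_override
    elif memb is not None:
        depth = measure_invagination_depth(memb)
    else:
        raise ValidationError("C14 embryo needs a membrane image or depth override")
    return TimeClass(14, assign_time_class(depth))
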