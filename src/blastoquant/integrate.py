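"""Integration of boundary fits across embryos into the atlas.

Per gene x time class x boundary, the antero-posterior boundary position
(%EL) is summarised by its arithmetic mean, median, sample standard
deviation and unscaled median absolute deviation (MAD), together with
the number of contributing embryos.  RNAi-treated material is refused by
default: knock-down strength varies from embryo to embryo, so averaging
positions across an RNAi batch is not meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import ValidationError
from .staging import ALL_TIME_CLASS_LABELS

log = logging.getLogger(__name__)


class RNAiIntegrationError(ValidationError):
    """Aggregation of RNAi-background fits without an explicit force."""


@dataclass(frozen=True)
class BoundaryMeasurement:
    """One embryo's contribution: a boundary position in %EL."""

    gene: str
    timeclass: str
    boundary_id: int
    position_pct_el: float | None
    embryo: str = ""
    background: str = "wt"


@dataclass(frozen=True)
class IntegratedBoundary:
    """Summary of one boundary at one time class across embryos."""

    gene: str
    timeclass: str
    boundary_id: int
    mean: float
    median: float
    standard_deviation: float
    mad: float
    n: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("a group must contain at least one embryo")
        if self.standard_deviation < 0 or self.mad < 0:
            raise ValidationError("dispersion cannot be negative")


def check_not_rnai(measurements, force: bool = False) -> None:
    """Guard: refuse RNAi-tagged inputs unless explicitly forced.

    Gene knock-down strength varies between injected embryos, so median
    boundary positions are not evaluated for RNAi data sets by default.
    """
    if any(m.background == "rnai" for m in measurements):
        if not force:
            raise RNAiIntegrationError(
                "refusing to integrate RNAi-background fits: knock-down "
                "effects vary between embryos, so averaged boundary "
                "positions are not meaningful (pass force=True to override)"
            )
        log.warning(
            "FORCED integration of RNAi-background fits: averaged positions "
            "do not account for variable knock-down strength"
        )


def aggregate(measurements, force: bool = False) -> list[IntegratedBoundary]:
    """Group by (gene, timeclass, boundary_id) and summarise positions.

    mean = arithmetic mean; median = middle-order statistic; SD = sample
    standard deviation (n-1 denominator, 0 with a flag for n = 1); MAD =
    median(|x - median|), unscaled.  Fits without a position are excluded
    with a logged count.  Output ordered by gene, then time class
    (temporal order), then boundary ID.
    """
    measurements = list(measurements)
    check_not_rnai(measurements, force=force)
    missing = [m for m in measurements if m.position_pct_el is None
               or not np.isfinite(m.position_pct_el)]
    if missing:
        log.warning("excluding %d measurement(s) without a position", len(missing))
    usable = [m for m in measurements if m not in missing]

    groups: dict[tuple, list[float]] = {}
    for m in usable:
        if m.timeclass not in ALL_TIME_CLASS_LABELS:
            raise ValidationError(f"invalid timeclass label {m.timeclass!r}")
        groups.setdefault((m.gene, m.timeclass, m.boundary_id), []).append(
            float(m.position_pct_el)
        )

    tc_order = {label: i for i, label in enumerate(ALL_TIME_CLASS_LABELS)}
    out = []
    forced = ("rnai_forced",) if force and any(
        m.background == "rnai" for m in measurements) else ()
    for key in sorted(groups, key=lambda k: (k[0], tc_order[k[1]], k[2])):
        xs = np.asarray(groups[key], dtype=float)
        med = float(np.median(xs))
        flags = forced
        if len(xs) > 1:
            sd = float(np.std(xs, ddof=1))
        else:
            sd = 0.0
            flags = flags + ("single_embryo",)
        out.append(
            IntegratedBoundary(
                gene=key[0],
                timeclass=key[1],
                boundary_id=key[2],
                mean=float(np.mean(xs)),
                median=med,
                standard_deviation=sd,
                mad=float(np.median(np.abs(xs - med))),
                n=len(xs),
                flags=flags,
            )
        )
    return out
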