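"""Expression-boundary detection and clamped-spline fitting.

Each boundary of an expression domain is a sigmoid transition of the
intensity profile.  It is modelled by a clamped cubic spline through
three control points (x1,y1), (x2,y2), (x3,y3) with the first derivative
fixed to zero at both ends -- two cubic Hermite segments whose interior
slope is chosen for second-derivative continuity.  The boundary position
is the half-amplitude point x2 (the standard convention in the gap-gene
literature) and the width is x3 - x1, both convertible to % embryo
length.  Boundary identities (ID + facing) follow a per-gene catalogue;
for giant (gt) the measurable boundaries are numbered 2, 5, 6 and 7, IDs
3-4 being reserved for numbering consistency with homologous boundaries
in other species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import least_squares

from .core import Channel, ValidationError
from .segmentation import EmbryoMask

DEFAULT_MIN_AMPLITUDE = 20.0
DETECTION_SMOOTH_WINDOW = 5
#: Plateau edge = where the profile is within this fraction of the
#: amplitude from the plateau level.
PLATEAU_EDGE_FRACTION = 0.10


class AmbiguousBoundaryError(ValidationError):
    """Window is not a single monotone transition."""


class UnknownGeneError(ValidationError):
    pass


@dataclass(frozen=True)
class ClampedSpline:
    """Cubic through three control points with zero end slopes.

    Two Hermite segments [x1,x2], [x2,x3]; slopes are 0 at x1 and x3
    exactly (the clamp) and the interior slope at x2 makes the second
    derivative continuous.
    """

    x: tuple[float, float, float]
    y: tuple[float, float, float]

    def __post_init__(self) -> None:
        x1, x2, x3 = self.x
        if not x1 < x2 < x3:
            raise ValidationError("control points must satisfy x1 < x2 < x3")

    @property
    def mid_slope(self) -> float:
        x1, x2, x3 = self.x
        y1, y2, y3 = self.y
        h1, h2 = x2 - x1, x3 - x2
        return (6 * (y3 - y2) / h2**2 - 6 * (y1 - y2) / h1**2) / (4 / h1 + 4 / h2)

    def _segments(self):
        x1, x2, x3 = self.x
        y1, y2, y3 = self.y
        m2 = self.mid_slope
        return ((x1, x2, y1, y2, 0.0, m2), (x2, x3, y2, y3, m2, 0.0))

    def __call__(self, t):
        return self._eval(t, derivative=False)

    def derivative(self, t):
        return self._eval(t, derivative=True)

    def _eval(self, t, derivative: bool):
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        # Outside the control interval the spline continues flat at the
        # plateau values, consistent with its zero end slopes.
        t = np.clip(t, self.x[0], self.x[2])
        out = np.empty_like(t)
        (a1, b1, ya1, yb1, ma1, mb1), (a2, b2, ya2, yb2, ma2, mb2) = self._segments()
        left = t <= b1
        for seg_mask, (a, b, ya, yb, ma, mb) in (
            (left, (a1, b1, ya1, yb1, ma1, mb1)),
            (~left, (a2, b2, ya2, yb2, ma2, mb2)),
        ):
            if not np.any(seg_mask):
                continue
            h = b - a
            s = (t[seg_mask] - a) / h
            if derivative:
                d00 = (6 * s**2 - 6 * s) / h
                d10 = 3 * s**2 - 4 * s + 1
                d01 = (-6 * s**2 + 6 * s) / h
                d11 = 3 * s**2 - 2 * s
                out[seg_mask] = d00 * ya + d10 * ma + d01 * yb + d11 * mb
            else:
                h00 = 2 * s**3 - 3 * s**2 + 1
                h10 = s**3 - 2 * s**2 + s
                h01 = -2 * s**3 + 3 * s**2
                h11 = s**3 - s**2
                out[seg_mask] = (
                    h00 * ya + h10 * h * ma + h01 * yb + h11 * h * mb
                )
        return float(out[0]) if scalar else out


@dataclass
class BoundaryFit:
    """One fitted expression boundary (intensity-space y coordinates)."""

    spline: ClampedSpline
    direction: str  # 'rising' or 'falling'
    embryo: str = ""
    gene: str = ""
    channel: Channel | None = None
    boundary_id: int | None = None
    facing: str | None = None
    timeclass: str | None = None
    converged: bool = True
    flags: tuple[str, ...] = ()
    position_pct_el: float | None = None
    width_pct_el: float | None = None

    @property
    def control_points(self):
        return tuple(zip(self.spline.x, self.spline.y))

    @property
    def position_px(self) -> float:
        return self.spline.x[1]

    @property
    def width_px(self) -> float:
        return self.spline.x[2] - self.spline.x[0]


@dataclass(frozen=True)
class Window:
    """Candidate boundary window on the profile x axis."""

    x_lo: float
    x_hi: float
    direction: str


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    w = min(window, len(y))
    if w <= 1:
        return np.asarray(y, dtype=float)
    pad = w // 2
    padded = np.pad(np.asarray(y, dtype=float), pad, mode="edge")
    return np.convolve(padded, np.ones(w) / w, mode="same")[pad : pad + len(y)]


def detect_boundary_windows(
    profile, min_amplitude: float = DEFAULT_MIN_AMPLITUDE
) -> list[Window]:
    """Non-overlapping windows around monotone rises/falls >= min_amplitude.

    The lightly smoothed intensity profile is reduced to its sequence of
    turning points; adjacent wiggles smaller than the amplitude threshold
    are pruned (smallest first) so that one boundary yields one window,
    running from plateau extremum to plateau extremum.
    """
    if profile.intensity is None:
        raise ValidationError("profile intensity must be populated before detection")
    y = _moving_average(profile.intensity, DETECTION_SMOOTH_WINDOW)
    x = profile.x_px
    n = len(y)
    if n < 3 or np.ptp(y) < min_amplitude:
        return []
    d = np.diff(y)
    sign = np.sign(d)
    # carry the previous sign through flat stretches
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turning = [0] + [i for i in range(1, n - 1) if sign[i] != sign[i - 1] and sign[i - 1] != 0] + [n - 1]
    turning = sorted(set(turning))
    # prune sub-threshold oscillations, smallest amplitude first
    while len(turning) > 2:
        amps = [abs(y[b] - y[a]) for a, b in zip(turning, turning[1:])]
        k = int(np.argmin(amps))
        if amps[k] >= min_amplitude:
            break
        if k == 0:
            del turning[1]
        elif k == len(amps) - 1:
            del turning[-2]
        else:
            # drop both endpoints of the wiggle, merging three segments
            del turning[k : k + 2]
    windows = []
    for a, b in zip(turning, turning[1:]):
        amp = y[b] - y[a]
        if abs(amp) >= min_amplitude:
            windows.append(
                Window(float(x[a]), float(x[b]), "rising" if amp > 0 else "falling")
            )
    return windows


def fit_clamped_boundary(
    profile,
    window: Window,
    overrides=None,
    max_iter: int = 100,
) -> BoundaryFit:
    """Fit a zero-end-slope cubic to one boundary window.

    Initialisation: y1/y3 are robust shoulder means at the window edges,
    x2 the half-amplitude crossing, x1/x3 the plateau edges, and
    y2 = (y1+y3)/2.  The x positions are then refined by least squares
    against the raw profile; ``overrides`` (three (x, y) control points)
    bypass fitting entirely, mirroring manual curation.
    """
    if overrides is not None:
        pts = np.asarray(overrides, dtype=float)
        if pts.shape != (3, 2):
            raise ValidationError("overrides must supply three (x, y) points")
        spline = ClampedSpline(tuple(pts[:, 0]), tuple(pts[:, 1]))
        direction = "rising" if pts[2, 1] > pts[0, 1] else "falling"
        return BoundaryFit(spline=spline, direction=direction, flags=("override",))

    if profile.intensity is None:
        raise ValidationError("profile intensity must be populated before fitting")
    sel = (profile.x_px >= window.x_lo) & (profile.x_px <= window.x_hi)
    x = profile.x_px[sel]
    y_raw = profile.intensity[sel]
    if len(x) < 5:
        raise ValidationError("window too narrow to fit")
    y = _moving_average(y_raw, DETECTION_SMOOTH_WINDOW)

    net = y[-1] - y[0]
    # A true boundary moves essentially one way; a window whose largest
    # adverse excursion (drawdown against the net direction) rivals its
    # range contains a sign flip and cannot be fitted unambiguously.
    if net >= 0:
        drawdown = float(np.max(np.maximum.accumulate(y) - y))
    else:
        drawdown = float(np.max(y - np.minimum.accumulate(y)))
    if net == 0 or drawdown > 0.5 * np.ptp(y):
        raise AmbiguousBoundaryError(
            "ambiguous boundary: window amplitude changes sign"
        )
    shoulder = max(3, len(x) // 20)
    y1 = float(np.mean(y[:shoulder]))
    y3 = float(np.mean(y[-shoulder:]))
    amp = y3 - y1
    half = (y1 + y3) / 2.0

    rel = y - half
    if net < 0:
        rel = -rel
    crossing = np.flatnonzero((rel[:-1] < 0) & (rel[1:] >= 0))
    if crossing.size:
        i = crossing[0]
        frac = -rel[i] / (rel[i + 1] - rel[i]) if rel[i + 1] != rel[i] else 0.0
        x2 = float(x[i] + frac * (x[i + 1] - x[i]))
    else:
        x2 = float(x[len(x) // 2])

    edge = PLATEAU_EDGE_FRACTION * abs(amp)
    before = np.flatnonzero((x < x2) & (np.abs(y - y1) <= edge))
    after = np.flatnonzero((x > x2) & (np.abs(y - y3) <= edge))
    x1 = float(x[before[-1]]) if before.size else float(x[0])
    x3 = float(x[after[0]]) if after.size else float(x[-1])
    if not x1 < x2 < x3:
        x1, x3 = float(x[0]), float(x[-1])
        x2 = min(max(x2, x1 + 0.5), x3 - 0.5)

    y2 = (y1 + y3) / 2.0
    initial = ClampedSpline((x1, x2, x3), (y1, y2, y3))

    span = x[-1] - x[0]

    def residuals(params):
        p1, g1, g2 = params
        spline = ClampedSpline((p1, p1 + g1, p1 + g1 + g2), (y1, y2, y3))
        return spline(x) - y_raw

    try:
        result = least_squares(
            residuals,
            x0=[x1, x2 - x1, x3 - x2],
            bounds=([x[0] - span, 1.0, 1.0], [x[-1], span, span]),
            max_nfev=max_iter,
        )
        converged = bool(result.status > 0)
        if converged:
            p1, g1, g2 = result.x
            spline = ClampedSpline((p1, p1 + g1, p1 + g1 + g2), (y1, y2, y3))
        else:
            spline = initial
    except Exception:
        spline, converged = initial, False

    return BoundaryFit(
        spline=spline,
        direction="rising" if net > 0 else "falling",
        converged=converged,
        flags=() if converged else ("refinement_not_converged",),
    )


def position_and_width(fit: BoundaryFit, mask: EmbryoMask) -> tuple[float, float]:
    """(position, width) in %EL: position = %EL(x2), width = %EL(x3)-%EL(x1)."""
    from .profiles import pct_el_of

    x1, x2, x3 = fit.spline.x
    return float(pct_el_of(x2, mask)), float(pct_el_of(x3, mask) - pct_el_of(x1, mask))


def add_percent_positions(fits, mask: EmbryoMask):
    """Return fits with position_pct_el / width_pct_el filled in."""
    out = []
    for f in fits:
        pos, width = position_and_width(f, mask)
        out.append(replace(f, position_pct_el=pos, width_pct_el=width))
    return out


# ---------------------------------------------------------------------------
# Boundary catalogue


@dataclass
class BoundaryCatalogue:
    """Per-gene ordered boundary identities: gene -> [(id, facing), ...].

    The complete ID map is configuration: defaults below cover the
    maternal and gap genes with invented facings consistent with their
    qualitative patterns, and gt carries the documented ID set
    {2, 5, 6, 7} (3-4 reserved).  Editable via YAML.
    """

    entries: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, items in self.entries.items():
            ids = [i for i, _ in items]
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate boundary IDs for gene {gene!r}")
            for _, facing in items:
                if facing not in ("anterior", "posterior"):
                    raise ValidationError(f"bad facing {facing!r} for gene {gene!r}")

    def for_gene(self, gene: str) -> list[tuple[int, str]]:
        if gene not in self.entries:
            raise UnknownGeneError(
                f"unknown gene {gene!r}; known genes: {sorted(self.entries)}"
            )
        return self.entries[gene]

    @classmethod
    def default(cls) -> "BoundaryCatalogue":
        return cls(
            {
                "bcd": [(1, "posterior")],
                "cad": [(1, "anterior")],
                "hb": [(1, "posterior"), (2, "anterior"), (3, "posterior")],
                "Kr": [(1, "anterior"), (2, "posterior")],
                "kni": [(1, "anterior"), (2, "posterior")],
                # gt IDs 3-4 reserved for cross-species numbering consistency
                "gt": [(2, "posterior"), (5, "anterior"),
                       (6, "posterior"), (7, "anterior")],
                "tll": [(1, "posterior"), (2, "anterior")],
                "hkb": [(1, "posterior"), (2, "anterior")],
            }
        )

    @classmethod
    def from_yaml(cls, path) -> "BoundaryCatalogue":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            {g: [(int(i), f) for i, f in items] for g, items in raw.items()}
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {g: [[i, f] for i, f in items] for g, items in self.entries.items()},
                fh,
                sort_keys=True,
            )


#: Direction a boundary's intensity takes along +x given its facing: an
#: anterior-facing boundary sits on the anterior edge of its domain, so
#: intensity rises towards the posterior.
FACING_DIRECTION = {"anterior": "rising", "posterior": "falling"}


def assign_boundary_ids(fits, catalogue: BoundaryCatalogue, gene: str):
    """Attach catalogue IDs/facings to fits by antero-posterior rank.

    With matching counts the assignment is positional; otherwise an
    order-preserving alignment maximising facing/direction agreement
    decides which catalogue entries apply, and surplus fits are flagged
    'unassigned' rather than dropped.
    """
    entries = catalogue.for_gene(gene)
    fits = sorted(fits, key=lambda f: f.spline.x[1])
    if not fits:
        return []
    directions_match = len(fits) == len(entries) and all(
        FACING_DIRECTION[facing] == f.direction
        for f, (_, facing) in zip(fits, entries)
    )
    if directions_match:
        return [
            replace(f, boundary_id=bid, facing=facing, gene=gene)
            for f, (bid, facing) in zip(fits, entries)
        ]

    # Order-preserving alignment (LCS-style DP on facing/direction match).
    n, m = len(fits), len(entries)
    score = np.zeros((n + 1, m + 1))
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            match = 1.0 if FACING_DIRECTION[entries[j][1]] == fits[i].direction else 0.1
            score[i, j] = max(match + score[i + 1, j + 1], score[i, j + 1],
                              score[i + 1, j])
    out = []
    i = j = 0
    while i < n and j < m:
        match = 1.0 if FACING_DIRECTION[entries[j][1]] == fits[i].direction else 0.1
        if score[i, j] == match + score[i + 1, j + 1]:
            bid, facing = entries[j]
            flags = fits[i].flags + (("count_mismatch",) if n != m else ())
            out.append(replace(fits[i], boundary_id=bid, facing=facing,
                               gene=gene, flags=flags))
            i += 1
            j += 1
        elif score[i, j] == score[i + 1, j]:
            # tie-break: flag the fit as unassigned rather than shifting
            # it onto a later catalogue ID
            out.append(replace(fits[i], gene=gene,
                               flags=fits[i].flags + ("unassigned",)))
            i += 1
        else:
            j += 1
    for f in fits[i:]:
        out.append(replace(f, gene=gene, flags=f.flags + ("unassigned",)))
    return out


def intensity_to_graph_y(intensity):
    """Intensity -> stored graph y (origin upper-left: y grows downward)."""
    return 255.0 - np.asarray(intensity, dtype=float)


def graph_y_to_intensity(y):
    return 255.0 - np.asarray(y, dtype=float)
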