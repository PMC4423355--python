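"""Synthetic embryo-image generator with ground truth.

Renders four-image quadruplets of an idealised blastoderm embryo so that
every downstream stage of the quantification pipeline can be tested
against known truth:

* bright-field: the stain rendered as linear RGB interpolation between an
  unstained-embryo background colour and a full-stain colour, weighted by
  a logistic ramp at each expression boundary;
* DIC-like: dark embryo interior on a bright background with texture and
  a strong edge, sufficient for automatic masking;
* nuclear: a Poisson-disc-like point pattern of exactly 2**(cycle-1)
  Gaussian nuclei inside the embryo ellipse;
* membrane: a dark invagination front advancing down a fixed band,
  encoding the C14A time class as depth t/8.

The geometry is an ellipse of ~2:1 aspect rendered analytically at an
arbitrary rotation; the ground-truth manifest records everything needed
to score a recovery (geometry, boundary positions, stage, nucleus count,
noise level, seed) and round-trips losslessly through CSV.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import dataio, staging
from .core import Channel, EmbryoRecord, ValidationError, as_uint8
from .staging import MEMBRANE_BAND, TimeClass

DEFAULT_CANVAS = (350, 700)  # rows, cols
#: Colour outside the embryo on bright-field images.
OUTSIDE_RGB = (246, 244, 240)


@dataclass(frozen=True)
class EmbryoGeometry:
    """Elliptical embryo geometry in pixel coordinates (origin upper-left)."""

    semi_major_px: float
    semi_minor_px: float
    center_xy: tuple[float, float]
    rotation_deg: float = 0.0
    anterior_on_left_after_derotation: bool = True

    def __post_init__(self) -> None:
        if not self.semi_major_px > self.semi_minor_px > 0:
            raise ValidationError(
                "need semi_major_px > semi_minor_px > 0, got "
                f"{self.semi_major_px}, {self.semi_minor_px}"
            )
        if not -90 < self.rotation_deg <= 90:
            raise ValidationError("rotation_deg must lie in (-90, 90]")

    def axis_coords(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Major/minor-axis coordinates (u, v) of every pixel of a canvas.

        The rotation angle is counter-clockwise from horizontal in the
        conventional (y-up) sense, i.e. a positive angle tilts the
        anterior-posterior axis visually upwards to the right.
        """
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        dx = xx - self.center_xy[0]
        dy = yy - self.center_xy[1]
        th = math.radians(self.rotation_deg)
        # y-down pixel coordinates: flip the sign of dy for a y-up angle.
        u = dx * math.cos(th) - dy * math.sin(th)
        v = dx * math.sin(th) + dy * math.cos(th)
        return u, v

    def ellipse_mask(self, shape: tuple[int, int]) -> np.ndarray:
        u, v = self.axis_coords(shape)
        return (u / self.semi_major_px) ** 2 + (v / self.semi_minor_px) ** 2 <= 1.0

    def pct_el(self, u: np.ndarray) -> np.ndarray:
        """%% embryo length of major-axis coordinate u (0 = anterior pole)."""
        a = self.semi_major_px
        pct = 100.0 * (u + a) / (2.0 * a)
        if not self.anterior_on_left_after_derotation:
            pct = 100.0 - pct
        return pct

    def fits_in(self, shape: tuple[int, int]) -> bool:
        th = math.radians(self.rotation_deg)
        a, b = self.semi_major_px, self.semi_minor_px
        half_w = math.hypot(a * math.cos(th), b * math.sin(th))
        half_h = math.hypot(a * math.sin(th), b * math.cos(th))
        cx, cy = self.center_xy
        return (
            cx - half_w >= 0
            and cx + half_w < shape[1]
            and cy - half_h >= 0
            and cy + half_h < shape[0]
        )


@dataclass(frozen=True)
class BoundarySpec:
    """One expression boundary of a synthetic domain."""

    boundary_id: int
    facing: str  # 'anterior' or 'posterior'
    position_pct_el: float
    width_pct_el: float
    plateau_intensity: float = 0.9

    def __post_init__(self) -> None:
        if self.facing not in ("anterior", "posterior"):
            raise ValidationError(f"facing must be anterior/posterior, got {self.facing!r}")
        if not 0.0 <= self.position_pct_el <= 100.0:
            raise ValidationError("boundary position must lie in [0, 100] %EL")
        if not self.width_pct_el > 0:
            raise ValidationError("boundary width must be positive")
        if not 0.0 <= self.plateau_intensity <= 1.0:
            raise ValidationError("plateau intensity must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionDomainSpec:
    """Ordered boundary list of one gene's expression pattern."""

    gene: str
    boundaries: tuple[BoundarySpec, ...]
    stain: Channel = Channel.NBT_BCIP

    def __post_init__(self) -> None:
        object.__setattr__(self, "stain", Channel.coerce(self.stain))
        object.__setattr__(self, "boundaries", tuple(self.boundaries))
        bs = self.boundaries
        pos = [b.position_pct_el for b in bs]
        if any(q <= p for p, q in zip(pos, pos[1:])):
            raise ValidationError("boundary positions must be strictly increasing")
        for p, q in zip(bs, bs[1:]):
            if p.facing == q.facing:
                raise ValidationError("boundary facings must alternate along the axis")
            gap = q.position_pct_el - p.position_pct_el
            if gap < (p.width_pct_el + q.width_pct_el) / 2.0:
                raise ValidationError(
                    "overlapping boundary ramps: boundaries "
                    f"{p.boundary_id} and {q.boundary_id} are closer than their widths"
                )


@dataclass(frozen=True)
class StainColorModel:
    """Linear colour model: pixel = lerp(background, full_stain, strength)."""

    background_rgb: tuple[int, int, int]
    full_stain_rgb: tuple[int, int, int]

    def __post_init__(self) -> None:
        for rgb in (self.background_rgb, self.full_stain_rgb):
            if any(not 0 <= c <= 255 for c in rgb):
                raise ValidationError("RGB components must lie in [0, 255]")


#: Default colours.  NBT/BCIP (purple) absorbs red strongly, so the
#: full-stain red channel is far below background red; FastRed depresses
#: green relative to red.  Both chosen so the pipeline's channel
#: arithmetic (255-R, R-G) is an exact inverse of the rendering.
DEFAULT_STAIN_COLORS = {
    Channel.NBT_BCIP: StainColorModel((210, 200, 172), (64, 48, 122)),
    Channel.FASTRED: StainColorModel((210, 200, 172), (205, 48, 66)),
}

#: Logistic scale = width / RAMP_WIDTH_FACTOR.  The nominal boundary
#: width is defined as the span of the zero-end-slope cubic that best
#: fits the ramp in least squares; for a logistic of scale k that span
#: is ~7.05 k, so this convention makes the generator's width the
#: quantity the boundary-fitting stage measures.
RAMP_WIDTH_FACTOR = 7.05


def stain_strength(pct_el: np.ndarray, domains) -> np.ndarray:
    """Local stain strength in [0, 1] at each %EL position.

    Each anterior-facing boundary contributes a rising logistic ramp, each
    posterior-facing one a falling ramp; consecutive rising/falling pairs
    multiply into a domain lobe scaled by its plateau intensity, and lobes
    from separate domains add (clipped to 1).
    """
    x = np.asarray(pct_el, dtype=float)
    total = np.zeros_like(x)
    for dom in domains:
        pending = None  # (ramp array, plateau) awaiting its posterior partner
        lobes = []
        for b in dom.boundaries:
            k = b.width_pct_el / RAMP_WIDTH_FACTOR
            z = np.clip((x - b.position_pct_el) / k, -60, 60)
            if b.facing == "anterior":
                pending = (1.0 / (1.0 + np.exp(-z)), b.plateau_intensity)
            else:
                fall = 1.0 / (1.0 + np.exp(z))
                if pending is None:
                    # Domain runs from the anterior pole to this boundary.
                    lobes.append(b.plateau_intensity * fall)
                else:
                    rise, plateau = pending
                    lobes.append(plateau * rise * fall)
                    pending = None
        if pending is not None:
            rise, plateau = pending  # domain runs to the posterior pole
            lobes.append(plateau * rise)
        for lobe in lobes:
            total += lobe
    return np.clip(total, 0.0, 1.0)


def _nucleus_points(
    geometry: EmbryoGeometry, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Poisson-disc-like (jittered grid) sample of n points in the ellipse.

    A jittered grid keeps a guaranteed minimum spacing of ~0.7 cell sizes
    between nuclei -- enough for blob counting to resolve every nucleus --
    while remaining fast for the 8192 nuclei of cycle 14.
    """
    a, b = geometry.semi_major_px, geometry.semi_minor_px
    area = math.pi * a * b
    cell = math.sqrt(area / n) * 0.97
    while True:
        # Candidate cell centres inside a slightly shrunk ellipse.
        us = np.arange(-a + cell / 2, a, cell)
        vs = np.arange(-b + cell / 2, b, cell)
        uu, vv = np.meshgrid(us, vs)
        inside = (uu / (a - 1.5)) ** 2 + (vv / (b - 1.5)) ** 2 <= 0.96
        cand = np.column_stack([uu[inside], vv[inside]])
        if len(cand) >= n:
            break
        cell *= 0.95
    idx = rng.choice(len(cand), size=n, replace=False)
    pts = cand[idx] + rng.uniform(-0.15 * cell, 0.15 * cell, size=(n, 2))
    # Map axis coordinates (u, v) back to pixel (x, y).
    th = math.radians(geometry.rotation_deg)
    x = geometry.center_xy[0] + pts[:, 0] * math.cos(th) + pts[:, 1] * math.sin(th)
    y = geometry.center_xy[1] - pts[:, 0] * math.sin(th) + pts[:, 1] * math.cos(th)
    return np.column_stack([x, y])


def render_membrane(depth: float, shape: tuple[int, int]) -> np.ndarray:
    """Membrane-morphology stand-in: dark front at `depth` of a fixed band."""
    if not 0.0 <= depth <= 1.0:
        raise ValidationError("invagination depth must lie in [0, 1]")
    img = np.full(shape, MEMBRANE_BAND["light"], dtype=float)
    h, w = shape
    r0 = int(round(MEMBRANE_BAND["row_lo_frac"] * h))
    r1 = int(round(MEMBRANE_BAND["row_hi_frac"] * h))
    c0 = int(round(MEMBRANE_BAND["col_lo_frac"] * w))
    c1 = int(round(MEMBRANE_BAND["col_hi_frac"] * w))
    front = r0 + int(round(depth * (r1 - r0)))
    img[r0:front, c0:c1] = MEMBRANE_BAND["dark"]
    return np.repeat(as_uint8(img)[:, :, None], 3, axis=2)


def true_depth_for(stage: TimeClass) -> float:
    """Mid-class invagination depth rendered for a stage: (2t-1)/16."""
    if stage.cycle < 14:
        return 0.0
    return (2 * stage.subclass - 1) / (2 * staging.N_TIME_CLASSES)


def generate_embryo(
    geometry: EmbryoGeometry,
    domains,
    stage: TimeClass,
    noise_sd: float = 2.0,
    seed: int = 0,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    colors: dict | None = None,
    embryo_id: str = "001",
    batch_id: str = "ma_syn_010101",
    background: str = "wt",
) -> tuple[EmbryoRecord, dict]:
    """Render one synthetic embryo quadruplet plus its ground-truth entry.

    Deterministic given ``seed``.  All four rasters share the canvas
    dimensions and are 8-bit RGB.
    """
    domains = tuple(domains)
    if len({d.stain for d in domains}) > 1:
        raise ValidationError("a synthetic embryo carries a single stain")
    if not geometry.fits_in(canvas):
        raise ValidationError(f"geometry does not fit inside canvas {canvas}")
    colors = colors or DEFAULT_STAIN_COLORS
    rng = np.random.default_rng(seed)

    u, v = geometry.axis_coords(canvas)
    r2 = (u / geometry.semi_major_px) ** 2 + (v / geometry.semi_minor_px) ** 2
    inside = r2 <= 1.0

    # Bright-field: stain colorimetry.
    stain = domains[0].stain if domains else Channel.NBT_BCIP
    cm = colors[stain]
    bright = np.empty(canvas + (3,), dtype=float)
    bright[:] = OUTSIDE_RGB
    s = stain_strength(geometry.pct_el(u[inside]), domains)
    bg = np.asarray(cm.background_rgb, float)
    full = np.asarray(cm.full_stain_rgb, float)
    bright[inside] = bg + s[:, None] * (full - bg)

    # DIC: dark textured interior, strong edge ring, bright background.
    dic = np.full(canvas, 235.0)
    dic[inside] = 140.0 + rng.normal(0.0, 8.0, size=int(inside.sum()))
    ring = inside & (r2 > 0.94)
    dic[ring] = 90.0
    dic3 = np.repeat(dic[:, :, None], 3, axis=2)

    # Nuclear: exactly 2**(cycle-1) Gaussian spots inside the ellipse.
    n_nuclei = staging.expected_nucleus_count(stage.cycle)
    pts = _nucleus_points(geometry, n_nuclei, rng)
    impulses = np.zeros(canvas)
    px = np.clip(np.rint(pts[:, 0]).astype(int), 0, canvas[1] - 1)
    py = np.clip(np.rint(pts[:, 1]).astype(int), 0, canvas[0] - 1)
    np.add.at(impulses, (py, px), 1.0)
    spots = ndimage.gaussian_filter(impulses, 1.0)
    peak = 1.0 / (2.0 * math.pi)  # isolated unit impulse after sigma=1 blur
    nuc = np.clip(spots / peak, 0.0, 1.0) * 255.0
    nuc3 = np.repeat(nuc[:, :, None], 3, axis=2)

    # Membrane: time-class front (same canvas; all rasters share dims).
    depth = true_depth_for(stage)
    memb = render_membrane(depth, canvas).astype(float)

    if noise_sd > 0:
        for img in (bright, dic3, nuc3, memb):
            img += rng.normal(0.0, noise_sd, size=img.shape)

    record = EmbryoRecord(
        embryo_id=embryo_id,
        batch_id=batch_id,
        images={
            "_ch00": as_uint8(bright),
            "_dic_ch00": as_uint8(dic3),
            "_nuc_ch00": as_uint8(nuc3),
            "_memb_ch00": as_uint8(memb),
        },
        genes=tuple(sorted({d.gene for d in domains})),
        channels=(stain,),
        metadata={
            "anterior_on_left": geometry.anterior_on_left_after_derotation,
            "background": background,
            "synthetic": True,
        },
    )
    entry = {
        "embryo_id": embryo_id,
        "batch_id": batch_id,
        "semi_major_px": geometry.semi_major_px,
        "semi_minor_px": geometry.semi_minor_px,
        "center_x": geometry.center_xy[0],
        "center_y": geometry.center_xy[1],
        "rotation_deg": geometry.rotation_deg,
        "anterior_on_left": geometry.anterior_on_left_after_derotation,
        "gene": ";".join(sorted({d.gene for d in domains})),
        "stain": stain.value,
        "boundaries": encode_boundaries(domains),
        "timeclass": stage.label,
        "n_nuclei": n_nuclei,
        "invagination_depth": depth,
        "noise_sd": float(noise_sd),
        "seed": int(seed),
        "background": background,
    }
    return record, entry


def encode_boundaries(domains) -> str:
    """Compact one-field encoding of all boundary truths."""
    parts = []
    for dom in domains:
        for b in dom.boundaries:
            parts.append(
                f"{b.boundary_id}:{b.facing}:{b.position_pct_el!r}:"
                f"{b.width_pct_el!r}:{b.plateau_intensity!r}"
            )
    return "|".join(parts)


def decode_boundaries(encoded: str, gene: str, stain: str) -> ExpressionDomainSpec:
    bs = []
    for part in encoded.split("|"):
        if not part:
            continue
        bid, facing, pos, width, plateau = part.split(":")
        bs.append(
            BoundarySpec(int(bid), facing, float(pos), float(width), float(plateau))
        )
    return ExpressionDomainSpec(gene=gene, boundaries=tuple(bs), stain=Channel(stain))


MANIFEST_COLUMNS = [
    "embryo_id", "batch_id", "semi_major_px", "semi_minor_px", "center_x",
    "center_y", "rotation_deg", "anterior_on_left", "gene", "stain",
    "boundaries", "timeclass", "n_nuclei", "invagination_depth", "noise_sd",
    "seed", "background",
]

_MANIFEST_TYPES = {
    "semi_major_px": float, "semi_minor_px": float, "center_x": float,
    "center_y": float, "rotation_deg": float, "invagination_depth": float,
    "noise_sd": float, "n_nuclei": int, "seed": int,
    "anterior_on_left": lambda s: s == "True",
}


@dataclass
class GroundTruthManifest:
    """Per-embryo ground truth of a synthetic batch; CSV round-trip safe."""

    entries: list[dict] = field(default_factory=list)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=MANIFEST_COLUMNS, lineterminator="\n")
            w.writeheader()
            for e in self.entries:
                row = dict(e)
                for key in ("semi_major_px", "semi_minor_px", "center_x",
                            "center_y", "rotation_deg", "invagination_depth",
                            "noise_sd"):
                    row[key] = repr(float(row[key]))
                w.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "GroundTruthManifest":
        entries = []
        with open(path, newline="") as fh:
            for raw in csv.DictReader(fh):
                entry = {
                    k: _MANIFEST_TYPES.get(k, str)(v) for k, v in raw.items()
                }
                entries.append(entry)
        return cls(entries)

    def entry_for(self, embryo_id: str) -> dict:
        for e in self.entries:
            if e["embryo_id"] == embryo_id:
                return e
        raise KeyError(embryo_id)

    def __eq__(self, other) -> bool:
        return isinstance(other, GroundTruthManifest) and self.entries == other.entries


@dataclass(frozen=True)
class BatchSpec:
    """Description of a synthetic batch to generate."""

    n_embryos: int
    gene: str = "gt"
    stain: Channel = Channel.NBT_BCIP
    stages: tuple[str, ...] = ("C14_T4",)
    domains: tuple[ExpressionDomainSpec, ...] | None = None
    noise_sd: float = 2.0
    species: str = "ma"
    date: str = "010115"
    background: str = "wt"
    canvas: tuple[int, int] = DEFAULT_CANVAS

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValidationError("a batch must contain at least one embryo")
        object.__setattr__(self, "stain", Channel.coerce(self.stain))

    @property
    def batch_id(self) -> str:
        return f"{self.species}_{self.gene}_{self.date}"


def default_domains(gene: str, stain: Channel) -> tuple[ExpressionDomainSpec, ...]:
    """A gt-like two-lobe pattern used when a batch spec gives no domains."""
    return (
        ExpressionDomainSpec(
            gene=gene,
            stain=stain,
            boundaries=(
                BoundarySpec(2, "posterior", 30.0, 5.0),
                BoundarySpec(5, "anterior", 55.0, 5.0),
                BoundarySpec(6, "posterior", 75.0, 5.0),
            ),
        ),
    )


def sample_geometry(rng: np.random.Generator, canvas=DEFAULT_CANVAS) -> EmbryoGeometry:
    """Realistic per-embryo geometry jitter around a 300 x 120 px ellipse."""
    a = 300.0 * rng.uniform(0.92, 1.0)
    b = 120.0 * rng.uniform(0.92, 1.04)
    rot = rng.uniform(-20.0, 20.0)
    cx = canvas[1] / 2 + rng.uniform(-8, 8)
    cy = canvas[0] / 2 + rng.uniform(-8, 8)
    return EmbryoGeometry(a, b, (cx, cy), rot)


def generate_batch(
    spec: BatchSpec, out_dir, seed: int = 0, overwrite: bool = False
) -> GroundTruthManifest:
    """Write a synthetic batch in the standard directory layout.

    Files land in ``<out_dir>/<root>/megaselia/<batch_id>/proc/`` with the
    standard suffixes; the ground-truth manifest is written alongside
    ``proc`` as ``manifest.csv``.  Deterministic given ``seed``.
    """
    out_dir = Path(out_dir)
    batch_dir = out_dir / dataio.batch_root(spec.background) / "megaselia" / spec.batch_id
    if batch_dir.exists() and any(batch_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"output batch directory {batch_dir} is not empty (use overwrite)"
        )
    (batch_dir / "proc").mkdir(parents=True, exist_ok=True)

    domains = spec.domains or default_domains(spec.gene, spec.stain)
    master = np.random.SeedSequence(seed)
    geom_rng = np.random.default_rng(master.spawn(1)[0])
    manifest = GroundTruthManifest()
    for i in range(spec.n_embryos):
        embryo_id = f"{i + 1:03d}"
        stage = TimeClass.parse(spec.stages[i % len(spec.stages)])
        geometry = sample_geometry(geom_rng, spec.canvas)
        embryo_seed = int(np.random.SeedSequence([seed, i + 1]).generate_state(1)[0] % (2**31))
        record, entry = generate_embryo(
            geometry, domains, stage,
            noise_sd=spec.noise_sd, seed=embryo_seed, canvas=spec.canvas,
            embryo_id=embryo_id, batch_id=spec.batch_id, background=spec.background,
        )
        for suffix, img in record.images.items():
            rel = dataio.layout_path(spec.batch_id, embryo_id, suffix, spec.background)
            dataio.write_png(out_dir / rel, img)
        manifest.entries.append(entry)
    manifest.to_csv(batch_dir / "manifest.csv")
    return manifest
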