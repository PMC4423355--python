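"""Expression-profile extraction and stain unmixing.

For each integer x along the midline spline, the mean RGB over the
perpendicular strip column is recorded; stain intensity is then obtained
by channel arithmetic: NBT/BCIP (purple) absorbs red, so intensity is the
inverse red channel (255 - R, blue ignored); FastRed depresses green
relative to red, so intensity is derived from R - G, which simultaneously
removes the yellow-like background of unstained embryo regions.
Positions are reported both in pixels and in % embryo length (%EL,
0 = anterior pole) via the mask's horizontal extremes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Channel, ValidationError
from .midline import StripBand
from .segmentation import EmbryoMask


@dataclass
class ExpressionProfile:
    """Per-position averaged RGB and unmixed stain intensity along A-P."""

    x_px: np.ndarray
    rgb: np.ndarray  # (n, 3) means in [0, 255]
    channel: Channel | None = None
    gene: str = ""
    intensity: np.ndarray | None = None
    pct_el: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.rgb = np.asarray(self.rgb, dtype=float)
        if self.rgb.shape != (len(self.x_px), 3):
            raise ValidationError("rgb must be an (n, 3) array matching x_px")
        if np.any(np.diff(self.x_px) <= 0):
            raise ValidationError("profile positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x_px)


def extract_rgb_profile(bright: np.ndarray, strip: StripBand) -> ExpressionProfile:
    """Average RGB across the perpendicular strip column at each spline x.

    The column at each integer x is perpendicular to the local spline
    tangent, ``height_px`` samples long at unit spacing and centred on
    the spline point; samples are read with nearest-pixel lookup and
    out-of-image samples are dropped from the mean.
    """
    img = np.asarray(bright, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    h, w = img.shape[:2]
    xs = np.arange(int(np.ceil(strip.spline.x_start)),
                   int(np.floor(strip.spline.x_end)) + 1)
    if xs.size == 0:
        raise ValidationError("strip has no integer sample positions")
    ys = strip.spline(xs)
    d = strip.spline.derivative(xs)
    norm = np.sqrt(1.0 + d * d)
    nx, ny = -d / norm, 1.0 / norm
    offsets = np.arange(strip.height_px) - (strip.height_px - 1) / 2.0
    cols = np.rint(xs[None, :] + offsets[:, None] * nx[None, :]).astype(int)
    rows = np.rint(ys[None, :] + offsets[:, None] * ny[None, :]).astype(int)
    inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    if not inside.any():
        raise ValidationError("strip lies entirely outside the image")
    rgb = np.zeros((len(xs), 3))
    counts = inside.sum(axis=0)
    safe_rows = np.clip(rows, 0, h - 1)
    safe_cols = np.clip(cols, 0, w - 1)
    samples = img[safe_rows, safe_cols]  # (height, n, 3)
    samples = samples * inside[:, :, None]
    keep = counts > 0
    rgb[keep] = samples.sum(axis=0)[keep] / counts[keep, None]
    return ExpressionProfile(x_px=xs[keep].astype(float), rgb=rgb[keep])


def trim_to_mask(
    profile: ExpressionProfile,
    strip: StripBand,
    mask: EmbryoMask,
    min_coverage: float = 0.95,
) -> ExpressionProfile:
    """Drop profile samples whose strip column lies mostly outside the mask.

    Near the embryo poles the tapering body covers only part of the
    perpendicular column, so the mean RGB mixes in non-embryo background
    and produces spurious intensity ramps.  Samples where less than
    ``min_coverage`` of the column falls inside the mask are removed.
    """
    m = mask.mask
    h, w = m.shape
    xs = profile.x_px
    ys = strip.spline(xs)
    d = strip.spline.derivative(xs)
    norm = np.sqrt(1.0 + d * d)
    nx, ny = -d / norm, 1.0 / norm
    offsets = np.arange(strip.height_px) - (strip.height_px - 1) / 2.0
    cols = np.rint(xs[None, :] + offsets[:, None] * nx[None, :]).astype(int)
    rows = np.rint(ys[None, :] + offsets[:, None] * ny[None, :]).astype(int)
    inside_img = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    covered = np.zeros(len(xs))
    safe_rows = np.clip(rows, 0, h - 1)
    safe_cols = np.clip(cols, 0, w - 1)
    covered = (m[safe_rows, safe_cols] & inside_img).mean(axis=0)
    keep = covered >= min_coverage
    if not keep.any():
        raise ValidationError("no strip column sufficiently inside the mask")
    return replace(
        profile,
        x_px=profile.x_px[keep],
        rgb=profile.rgb[keep],
        intensity=None if profile.intensity is None else profile.intensity[keep],
        pct_el=None if profile.pct_el is None else profile.pct_el[keep],
    )


def unmix_nbt_bcip(profile: ExpressionProfile) -> ExpressionProfile:
    """Purple-stain intensity: inverse red channel (blue ignored)."""
    intensity = 255.0 - profile.rgb[:, 0]
    return replace(profile, intensity=intensity, channel=Channel.NBT_BCIP)


def unmix_fastred(
    profile: ExpressionProfile, mode: str = "subtract"
) -> ExpressionProfile:
    """Red-stain intensity from the red-minus-green channel difference.

    ``subtract`` (default): intensity = clamp(R - G, 0, 255); the
    subtraction itself yields a stain-positive signal on the bright
    background.  ``literal_invert``: 255 - (R - G), the word-for-word
    reading of "inverting the outcome".
    """
    diff = profile.rgb[:, 0] - profile.rgb[:, 1]
    if mode == "subtract":
        intensity = np.clip(diff, 0.0, 255.0)
    elif mode == "literal_invert":
        intensity = np.clip(255.0 - diff, 0.0, 255.0)
    else:
        raise ValidationError(f"unknown FastRed mode {mode!r}")
    return replace(profile, intensity=intensity, channel=Channel.FASTRED)


def unmix(profile: ExpressionProfile, channel: Channel,
          fastred_mode: str = "subtract") -> ExpressionProfile:
    channel = Channel.coerce(channel)
    if channel is Channel.NBT_BCIP:
        return unmix_nbt_bcip(profile)
    return unmix_fastred(profile, mode=fastred_mode)


def to_percent_el(profile: ExpressionProfile, mask: EmbryoMask) -> ExpressionProfile:
    """Attach %EL positions: affine map of x between the mask extremes."""
    span = mask.x_max - mask.x_min
    if span <= 0:
        raise ValidationError("mask has zero horizontal extent")
    pct = 100.0 * (profile.x_px - mask.x_min) / span
    return replace(profile, pct_el=pct)


def pct_el_of(x, mask: EmbryoMask):
    span = mask.x_max - mask.x_min
    if span <= 0:
        raise ValidationError("mask has zero horizontal extent")
    return 100.0 * (np.asarray(x, dtype=float) - mask.x_min) / span


def write_prof_dat(profile: ExpressionProfile, path) -> None:
    """`_prof.dat`: one line per sample, whitespace-separated x R G B [I]."""
    with open(path, "w") as fh:
        for i in range(len(profile)):
            fields = [f"{profile.x_px[i]:.0f}"] + [
                f"{v:.3f}" for v in profile.rgb[i]
            ]
            if profile.intensity is not None:
                fields.append(f"{profile.intensity[i]:.3f}")
            fh.write(" ".join(fields) + "\n")


def read_prof_dat(path) -> ExpressionProfile:
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] not in (4, 5):
        raise ValidationError("profile file must have 4 or 5 columns")
    intensity = data[:, 4] if data.shape[1] == 5 else None
    return ExpressionProfile(x_px=data[:, 0], rgb=data[:, 1:4], intensity=intensity)


def plot_profile(profile: ExpressionProfile, path=None):
    """Intensity profile plot (magenta trace), optionally saved to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    x = profile.pct_el if profile.pct_el is not None else profile.x_px
    y = profile.intensity if profile.intensity is not None else 255 - profile.rgb[:, 0]
    ax.plot(x, y, color="magenta", lw=1.5)
    ax.set_xlabel("A-P position (%EL)" if profile.pct_el is not None else "x (px)")
    ax.set_ylabel("stain intensity")
    ax.set_ylim(0, 260)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
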