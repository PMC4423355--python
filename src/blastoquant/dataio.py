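"""Readers/writers for the deposited directory layout and CSV schemas.

The on-disk conventions mirror the public data records byte-for-byte:

* image batches under ``ish/megaselia/<species_stain_date>/proc/`` (or
  ``RNAi/...`` for knock-down batches), embryo files named
  ``<NNN><suffix>.png`` with the fixed suffix vocabulary;
* ``*_timeclasses_bands.csv`` -- 13 columns: embryo, timeclass,
  spline_height, spline_x1..x5, spline_y1..y5;
* ``*_boundary_data.csv`` -- 11 columns: embryo, boundary_id, facing,
  gene, channel, boundary_x1..x3, boundary_y1..y3 (graph coordinates,
  origin upper-left);
* ``wt_integrated_boundaries.csv`` -- 7 columns: gene, timeclass,
  "boundary id" (with a space, as deposited), mean, median,
  "standard deviation", MAD.

Writers are deterministic (same rows -> same bytes): comma separator, LF
line endings, floats rendered with three decimals.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

import imageio.v3 as iio
import numpy as np

from .core import ValidationError
from .staging import ALL_TIME_CLASS_LABELS

FACINGS = ("anterior", "posterior")
CSV_CHANNELS = ("purple", "red")

TIMECLASSES_HEADER = (
    ["embryo", "timeclass", "spline_height"]
    + [f"spline_x{i}" for i in range(1, 6)]
    + [f"spline_y{i}" for i in range(1, 6)]
)
BOUNDARY_HEADER = (
    ["embryo", "boundary_id", "facing", "gene", "channel"]
    + [f"boundary_x{i}" for i in range(1, 4)]
    + [f"boundary_y{i}" for i in range(1, 4)]
)
INTEGRATED_HEADER = [
    "gene", "timeclass", "boundary id", "mean", "median",
    "standard deviation", "MAD",
]


class SchemaError(ValidationError):
    """A CSV file violates its deposited schema."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# ---------------------------------------------------------------------------
# Batch IDs and directory layout


@dataclass(frozen=True)
class BatchID:
    """'species_stain_date' batch identifier, e.g. ma_gt_260911."""

    species: str
    stain: str
    date: str

    def __post_init__(self) -> None:
        for token in (self.species, self.stain):
            if not token or "_" in token:
                raise ValidationError(f"bad batch token {token!r}")
        if not re.fullmatch(r"\d{6}", self.date):
            raise ValidationError(f"batch date must be DDMMYY, got {self.date!r}")

    def __str__(self) -> str:
        return f"{self.species}_{self.stain}_{self.date}"

    @classmethod
    def parse(cls, batch_id: str) -> "BatchID":
        parts = batch_id.split("_")
        if len(parts) != 3:
            raise ValidationError(
                f"batch ID must be 'species_stain_date', got {batch_id!r}"
            )
        return cls(*parts)


def batch_root(background: str = "wt") -> str:
    """Top directory: 'ish' for wild-type batches, 'RNAi' for knock-down."""
    if background not in ("wt", "rnai"):
        raise ValidationError(f"background must be 'wt' or 'rnai', got {background!r}")
    return "ish" if background == "wt" else "RNAi"


def layout_path(
    batch_id, embryo_id: str, suffix: str, background: str = "wt"
) -> str:
    """Relative path of one embryo artifact, forward slashes always.

    >>> layout_path("ma_gt_260911", "001", "_ch00")
    'ish/megaselia/ma_gt_260911/proc/001_ch00.png'
    """
    from .core import ALL_SUFFIXES

    if suffix not in ALL_SUFFIXES:
        raise ValidationError(f"unknown suffix {suffix!r}; known: {ALL_SUFFIXES}")
    batch = BatchID.parse(str(batch_id))
    name = f"{embryo_id}{suffix}" + ("" if suffix.endswith(".dat") else ".png")
    return str(PurePosixPath(batch_root(background)) / "megaselia" / str(batch) / "proc" / name)


def parse_layout_path(path) -> tuple[BatchID, str, str, str]:
    """Inverse of :func:`layout_path`: (batch, embryo_id, suffix, background)."""
    from .core import ALL_SUFFIXES

    parts = PurePosixPath(str(path).replace("\\", "/")).parts
    if len(parts) < 5 or parts[-2] != "proc" or parts[-4] != "megaselia":
        raise ValidationError(f"path {path!r} does not match the batch layout")
    background = {"ish": "wt", "RNAi": "rnai"}.get(parts[-5])
    if background is None:
        raise ValidationError(f"unknown layout root {parts[-5]!r}")
    batch = BatchID.parse(parts[-3])
    name = parts[-1]
    for suffix in sorted(ALL_SUFFIXES, key=len, reverse=True):
        tail = suffix + ("" if suffix.endswith(".dat") else ".png")
        # Fig-legend variant 001_ch00_prof.dat is accepted on parse.
        candidates = [tail]
        if suffix == "_prof.dat":
            candidates.insert(0, "_ch00" + tail)
        for candidate in candidates:
            if name.endswith(candidate):
                return batch, name[: -len(candidate)], suffix, background
    raise ValidationError(f"file name {name!r} has no recognised suffix")


def write_png(path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(img))


def read_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path))


# ---------------------------------------------------------------------------
# Row types


def _fmt(value) -> str:
    if isinstance(value, str):
        return value
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return f"{float(value):.3f}"


@dataclass(frozen=True)
class TimeclassBandRow:
    embryo: str
    timeclass: str
    spline_height: int
    spline_x: tuple[float, ...]
    spline_y: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.timeclass not in ALL_TIME_CLASS_LABELS:
            raise ValidationError(f"invalid timeclass label {self.timeclass!r}")
        if len(self.spline_x) != 5 or len(self.spline_y) != 5:
            raise ValidationError("exactly five spline knots required")
        if any(q <= p for p, q in zip(self.spline_x, self.spline_x[1:])):
            raise ValidationError("spline knot x-values must be strictly increasing")

    def to_fields(self) -> list[str]:
        return (
            [self.embryo, self.timeclass, _fmt(self.spline_height)]
            + [_fmt(v) for v in self.spline_x]
            + [_fmt(v) for v in self.spline_y]
        )


@dataclass(frozen=True)
class BoundaryRow:
    embryo: str
    boundary_id: int
    facing: str
    gene: str
    channel: str
    boundary_x: tuple[float, float, float]
    boundary_y: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.facing not in FACINGS:
            raise ValidationError(
                f"facing must be one of {FACINGS}, got {self.facing!r}"
            )
        if self.channel not in CSV_CHANNELS:
            raise ValidationError(
                f"channel must be one of {CSV_CHANNELS}, got {self.channel!r}"
            )
        x1, x2, x3 = self.boundary_x
        if not x1 < x2 < x3:
            raise ValidationError("boundary control points must satisfy x1 < x2 < x3")

    def to_fields(self) -> list[str]:
        return (
            [self.embryo, _fmt(self.boundary_id), self.facing, self.gene, self.channel]
            + [_fmt(v) for v in self.boundary_x]
            + [_fmt(v) for v in self.boundary_y]
        )


@dataclass(frozen=True)
class IntegratedRow:
    gene: str
    timeclass: str
    boundary_id: int
    mean: float
    median: float
    standard_deviation: float
    mad: float

    def __post_init__(self) -> None:
        if self.timeclass not in ALL_TIME_CLASS_LABELS:
            raise ValidationError(f"invalid timeclass label {self.timeclass!r}")
        if self.standard_deviation < 0 or self.mad < 0:
            raise ValidationError("dispersion measures cannot be negative")

    def to_fields(self) -> list[str]:
        return [
            self.gene, self.timeclass, _fmt(self.boundary_id), _fmt(self.mean),
            _fmt(self.median), _fmt(self.standard_deviation), _fmt(self.mad),
        ]


# ---------------------------------------------------------------------------
# CSV reading/writing


def _write_csv(path_or_buf, header: list[str], rows) -> None:
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf, "w", newline="") if own else path_or_buf
    try:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row.to_fields())
    finally:
        if own:
            fh.close()


def _read_csv(path_or_buf, header: list[str]):
    own = isinstance(path_or_buf, (str, Path))
    fh = open(path_or_buf, newline="") if own else path_or_buf
    try:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise SchemaError("empty file: missing header", line=1) from None
        if got != header:
            raise SchemaError(f"bad header {got!r}; expected {header!r}", line=1)
        out = []
        for lineno, fields in enumerate(reader, start=2):
            if not fields:
                continue
            if len(fields) != len(header):
                raise SchemaError(
                    f"expected {len(header)} columns, got {len(fields)}", line=lineno
                )
            out.append((lineno, fields))
        return out
    finally:
        if own:
            fh.close()


def _num(value: str, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise SchemaError(f"non-numeric {what}: {value!r}", line=lineno) from None


def write_timeclasses_bands(path, rows) -> None:
    _write_csv(path, TIMECLASSES_HEADER, rows)


def read_timeclasses_bands(path) -> list[TimeclassBandRow]:
    out = []
    for lineno, f in _read_csv(path, TIMECLASSES_HEADER):
        try:
            out.append(
                TimeclassBandRow(
                    embryo=f[0],
                    timeclass=f[1],
                    spline_height=int(_num(f[2], lineno, "spline_height")),
                    spline_x=tuple(_num(v, lineno, "spline_x") for v in f[3:8]),
                    spline_y=tuple(_num(v, lineno, "spline_y") for v in f[8:13]),
                )
            )
        except SchemaError:
            raise
        except ValidationError as exc:
            raise SchemaError(str(exc), line=lineno) from None
    return out


def write_boundary_data(path, rows) -> None:
    _write_csv(path, BOUNDARY_HEADER, rows)


def read_boundary_data(path) -> list[BoundaryRow]:
    out = []
    for lineno, f in _read_csv(path, BOUNDARY_HEADER):
        try:
            out.append(
                BoundaryRow(
                    embryo=f[0],
                    boundary_id=int(_num(f[1], lineno, "boundary_id")),
                    facing=f[2],
                    gene=f[3],
                    channel=f[4],
                    boundary_x=tuple(_num(v, lineno, "boundary_x") for v in f[5:8]),
                    boundary_y=tuple(_num(v, lineno, "boundary_y") for v in f[8:11]),
                )
            )
        except SchemaError:
            raise
        except ValidationError as exc:
            raise SchemaError(str(exc), line=lineno) from None
    return out


def write_integrated(path, rows) -> None:
    _write_csv(path, INTEGRATED_HEADER, rows)


def read_integrated(path) -> list[IntegratedRow]:
    out = []
    for lineno, f in _read_csv(path, INTEGRATED_HEADER):
        try:
            out.append(
                IntegratedRow(
                    gene=f[0],
                    timeclass=f[1],
                    boundary_id=int(_num(f[2], lineno, "boundary id")),
                    mean=_num(f[3], lineno, "mean"),
                    median=_num(f[4], lineno, "median"),
                    standard_deviation=_num(f[5], lineno, "standard deviation"),
                    mad=_num(f[6], lineno, "MAD"),
                )
            )
        except SchemaError:
            raise
        except ValidationError as exc:
            raise SchemaError(str(exc), line=lineno) from None
    return out


# ---------------------------------------------------------------------------
# Tree validation


@dataclass
class QCReport:
    """Structured summary of a batch-tree validation pass."""

    n_batches: int = 0
    n_embryos: int = 0
    n_complete: int = 0
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems


def validate_tree(root) -> QCReport:
    """Walk a data tree and check layout, file naming and CSV schemas."""
    root = Path(root)
    report = QCReport()
    for top, background in (("ish", "wt"), ("RNAi", "rnai")):
        species_dir = root / top / "megaselia"
        if not species_dir.is_dir():
            continue
        for batch_dir in sorted(p for p in species_dir.iterdir() if p.is_dir()):
            report.n_batches += 1
            try:
                BatchID.parse(batch_dir.name)
            except ValidationError as exc:
                report.problems.append(f"{batch_dir}: {exc}")
                continue
            proc = batch_dir / "proc"
            if not proc.is_dir():
                report.problems.append(f"{batch_dir}: missing proc/ directory")
                continue
            embryos: dict[str, set[str]] = {}
            for f in sorted(proc.iterdir()):
                try:
                    _, embryo_id, suffix, _ = parse_layout_path(
                        f"{top}/megaselia/{batch_dir.name}/proc/{f.name}"
                    )
                except ValidationError as exc:
                    report.problems.append(f"{f}: {exc}")
                    continue
                embryos.setdefault(embryo_id, set()).add(suffix)
            report.n_embryos += len(embryos)
            from .core import IMAGE_SUFFIXES

            for embryo_id, suffixes in sorted(embryos.items()):
                missing = set(IMAGE_SUFFIXES) - suffixes
                if missing:
                    report.problems.append(
                        f"{proc}/{embryo_id}: missing images {sorted(missing)}"
                    )
                else:
                    report.n_complete += 1
            for name, reader in (
                (f"{'wt' if background == 'wt' else 'RNAi'}_timeclasses_bands.csv",
                 read_timeclasses_bands),
                (f"{'wt' if background == 'wt' else 'RNAi'}_boundary_data.csv",
                 read_boundary_data),
            ):
                csv_path = batch_dir / name
                if csv_path.exists():
                    try:
                        reader(csv_path)
                    except ValidationError as exc:
                        report.problems.append(f"{csv_path}: {exc}")
    return report


def roundtrip_bytes(read, write, path) -> bytes:
    """write(read(path)) into memory; used to assert byte fidelity."""
    rows = read(path)
    buf = io.StringIO()
    write(buf, rows)
    return buf.getvalue().encode()
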