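"""End-to-end orchestration: image tree in, CSV tables and overlays out.

For every embryo quadruplet found in a batch tree the pipeline masks,
aligns, strips, extracts, unmixes, stages and fits boundaries, writing
the per-embryo intermediate images (`_embmsk`, `_band`, `_stband`,
`_prof.dat`) and per-batch CSV tables.  Per-embryo failures are logged
and skipped; a batch where more than half of the embryos fail aborts the
run.  Deterministic given a fixed configuration.
"""

from __future__ import annotations

import csv
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import boundaries, dataio, midline, profiles, segmentation, staging
from .config import PipelineConfig
from .core import Channel, EmbryoRecord, ValidationError
from .synthgen import GroundTruthManifest

log = logging.getLogger(__name__)

POSITIONS_HEADER = [
    "embryo", "gene", "timeclass", "boundary_id", "facing", "channel",
    "position_pct_el", "width_pct_el", "background",
]


class PipelineError(RuntimeError):
    pass


@dataclass
class EmbryoResult:
    """Everything computed for one embryo."""

    record: EmbryoRecord
    mask: "segmentation.EmbryoMask"
    strip: "midline.StripBand"
    profile: "profiles.ExpressionProfile"
    timeclass: staging.TimeClass
    fits: list
    embryo_path: str


@dataclass
class RunReport:
    n_processed: int = 0
    n_failed: int = 0
    failures: list[tuple[str, str]] = field(default_factory=list)
    timings_s: dict[str, float] = field(default_factory=dict)

    def add_timing(self, stage: str, dt: float) -> None:
        self.timings_s[stage] = self.timings_s.get(stage, 0.0) + dt


def process_embryo(
    record: EmbryoRecord,
    config: PipelineConfig | None = None,
    catalogue: "boundaries.BoundaryCatalogue | None" = None,
    report: RunReport | None = None,
) -> EmbryoResult:
    """Run the full quantification chain on one (unaligned) record."""
    config = config or PipelineConfig()
    catalogue = catalogue or config.catalogue()
    report = report or RunReport()

    def timed(stage, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        report.add_timing(stage, time.perf_counter() - t0)
        return out

    mask = timed("mask", segmentation.compute_mask, record.images["_dic_ch00"])
    # Stage before alignment: interpolation during rotation blurs densely
    # packed nuclei together and biases the count low at late cycles.
    timeclass = timed(
        "staging", staging.stage_record,
        record.images["_nuc_ch00"], record.images.get("_memb_ch00"),
        mask.mask, record.metadata.get("invagination_depth"),
    )
    aligned, mask = timed(
        "align", segmentation.align_record, record, mask,
        anterior_on_left=record.metadata.get("anterior_on_left", True),
        margin=config.crop_margin_px,
    )
    spline = timed("midline", midline.fit_midline, mask, n_knots=config.knot_count)
    strip = timed("strip", midline.make_strip, spline, mask,
                  strip_fraction=config.strip_fraction)
    profile = timed("profile", profiles.extract_rgb_profile,
                    aligned.images["_ch00"], strip)
    profile = profiles.trim_to_mask(profile, strip, mask)
    channel = aligned.channels[0] if aligned.channels else Channel.NBT_BCIP
    profile = profiles.unmix(profile, channel, fastred_mode=config.fastred_mode)
    profile = profiles.to_percent_el(profile, mask)
    profile.gene = aligned.genes[0] if aligned.genes else ""

    if "timeclass" in record.metadata:  # curator override
        timeclass = staging.TimeClass.parse(record.metadata["timeclass"])

    windows = timed("detect", boundaries.detect_boundary_windows,
                    profile, config.min_amplitude)
    fits = []
    for win in windows:
        try:
            fits.append(timed("fit", boundaries.fit_clamped_boundary,
                              profile, win))
        except boundaries.AmbiguousBoundaryError as exc:
            log.warning("%s/%s: skipping window %s: %s", record.batch_id,
                        record.embryo_id, win, exc)
    gene = profile.gene
    if gene:
        try:
            fits = boundaries.assign_boundary_ids(fits, catalogue, gene)
        except boundaries.UnknownGeneError:
            log.warning("gene %r not in catalogue; boundary IDs unassigned", gene)
    fits = boundaries.add_percent_positions(fits, mask)
    from dataclasses import replace

    fits = [
        replace(f, embryo=record.embryo_id, channel=channel,
                timeclass=timeclass.label)
        for f in fits
    ]
    embryo_path = str(Path(dataio.layout_path(
        record.batch_id, record.embryo_id, "_ch00", record.background
    )).parent / record.embryo_id).replace("\\", "/")
    return EmbryoResult(
        record=aligned, mask=mask, strip=strip, profile=profile,
        timeclass=timeclass, fits=fits, embryo_path=embryo_path,
    )


def _load_record(proc: Path, embryo_id: str, batch_id: str,
                 background: str, manifest: GroundTruthManifest | None) -> EmbryoRecord:
    images = {}
    for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00", "_memb_ch00"):
        path = proc / f"{embryo_id}{suffix}.png"
        if not path.exists():
            raise ValidationError(f"missing image {path.name}")
        images[suffix] = dataio.read_png(path)
    genes: tuple[str, ...] = (dataio.BatchID.parse(batch_id).stain,)
    channels: tuple = (Channel.NBT_BCIP,)
    metadata: dict = {"background": background}
    if manifest is not None:
        try:
            entry = manifest.entry_for(embryo_id)
        except KeyError:
            entry = None
        if entry:
            channels = (Channel(entry["stain"]),)
            genes = tuple(entry["gene"].split(";"))
            metadata["anterior_on_left"] = entry["anterior_on_left"]
    return EmbryoRecord(
        embryo_id=embryo_id, batch_id=batch_id, images=images,
        genes=genes, channels=channels, metadata=metadata,
    )


def run_pipeline(input_root, config: PipelineConfig | None = None) -> RunReport:
    """Quantify every batch under ``input_root``; write artifacts in place."""
    config = config or PipelineConfig()
    catalogue = config.catalogue()
    root = Path(input_root)
    report = RunReport()
    found_any = False
    for top, background in (("ish", "wt"), ("RNAi", "rnai")):
        species_dir = root / top / "megaselia"
        if not species_dir.is_dir():
            continue
        for batch_dir in sorted(p for p in species_dir.iterdir() if p.is_dir()):
            found_any = True
            _run_batch(batch_dir, background, config, catalogue, report)
    if not found_any:
        raise PipelineError(f"no batches found under {input_root}")
    _write_run_log(root / "run_log.txt", report)
    return report


def _write_run_log(path: Path, report: RunReport) -> None:
    lines = [f"processed {report.n_processed} embryos, {report.n_failed} failed"]
    lines += [f"stage {stage}: {dt:.3f} s"
              for stage, dt in sorted(report.timings_s.items())]
    lines += [f"FAILED {embryo}: {msg}" for embryo, msg in report.failures]
    path.write_text("\n".join(lines) + "\n")


def _run_batch(batch_dir: Path, background: str, config: PipelineConfig,
               catalogue, report: RunReport) -> None:
    batch_id = batch_dir.name
    proc = batch_dir / "proc"
    if not proc.is_dir():
        raise PipelineError(f"batch {batch_id} has no proc/ directory")
    manifest = None
    manifest_path = batch_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = GroundTruthManifest.from_csv(manifest_path)
    embryo_ids = sorted(
        {p.name[: -len("_ch00.png")] for p in proc.glob("*_ch00.png")
         if not p.name.endswith(("_dic_ch00.png", "_nuc_ch00.png",
                                 "_memb_ch00.png"))}
    )
    band_rows, boundary_rows, position_rows = [], [], []
    n_failed = 0
    for embryo_id in embryo_ids:
        try:
            record = _load_record(proc, embryo_id, batch_id, background, manifest)
            result = process_embryo(record, config, catalogue, report)
        except Exception as exc:  # per-embryo fault isolation
            n_failed += 1
            report.n_failed += 1
            report.failures.append((f"{batch_id}/{embryo_id}", str(exc)))
            log.error("embryo %s/%s failed: %s", batch_id, embryo_id, exc)
            continue
        report.n_processed += 1
        _write_embryo_outputs(proc, embryo_id, result)
        band_rows.append(_band_row(result))
        boundary_rows.extend(_boundary_rows(result))
        position_rows.extend(_position_rows(result, background))
    prefix = "wt" if background == "wt" else "RNAi"
    dataio.write_timeclasses_bands(batch_dir / f"{prefix}_timeclasses_bands.csv",
                                   band_rows)
    dataio.write_boundary_data(batch_dir / f"{prefix}_boundary_data.csv",
                               boundary_rows)
    _write_positions(batch_dir / f"{prefix}_boundary_positions.csv", position_rows)
    if embryo_ids and n_failed > 0.5 * len(embryo_ids):
        raise PipelineError(
            f"batch {batch_id}: {n_failed}/{len(embryo_ids)} embryos failed"
        )


def _write_embryo_outputs(proc: Path, embryo_id: str, result: EmbryoResult) -> None:
    dataio.write_png(proc / f"{embryo_id}_embmsk.png", result.mask.to_image())
    dataio.write_png(proc / f"{embryo_id}_band.png",
                     midline.render_band(result.strip, result.mask))
    dataio.write_png(proc / f"{embryo_id}_stband.png",
                     midline.render_stband(result.strip,
                                           result.record.images["_ch00"]))
    profiles.write_prof_dat(result.profile, proc / f"{embryo_id}_prof.dat")


def _band_row(result: EmbryoResult) -> dataio.TimeclassBandRow:
    knots = result.strip.spline.knots
    return dataio.TimeclassBandRow(
        embryo=result.embryo_path,
        timeclass=result.timeclass.label,
        spline_height=result.strip.height_px,
        spline_x=tuple(knots[:, 0]),
        spline_y=tuple(knots[:, 1]),
    )


def _boundary_rows(result: EmbryoResult) -> list[dataio.BoundaryRow]:
    rows = []
    for f in result.fits:
        if f.boundary_id is None:
            continue
        rows.append(
            dataio.BoundaryRow(
                embryo=result.embryo_path,
                boundary_id=f.boundary_id,
                facing=f.facing,
                gene=f.gene,
                channel=f.channel.csv_name,
                boundary_x=f.spline.x,
                boundary_y=tuple(
                    boundaries.intensity_to_graph_y(list(f.spline.y))
                ),
            )
        )
    return rows


def _position_rows(result: EmbryoResult, background: str) -> list[list]:
    rows = []
    for f in result.fits:
        if f.boundary_id is None:
            continue
        rows.append([
            result.embryo_path, f.gene, result.timeclass.label, f.boundary_id,
            f.facing, f.channel.csv_name, f"{f.position_pct_el:.3f}",
            f"{f.width_pct_el:.3f}", background,
        ])
    return rows


def _write_positions(path, rows) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(POSITIONS_HEADER)
        w.writerows(rows)


def read_positions(path) -> list:
    """Read a *_boundary_positions.csv into BoundaryMeasurement objects."""
    from .integrate import BoundaryMeasurement

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                BoundaryMeasurement(
                    gene=row["gene"],
                    timeclass=row["timeclass"],
                    boundary_id=int(row["boundary_id"]),
                    position_pct_el=float(row["position_pct_el"]),
                    embryo=row["embryo"],
                    background=row["background"],
                )
            )
    return out
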