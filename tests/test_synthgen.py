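"""Generator contracts: determinism, ground truth, forward/inverse consistency."""

import numpy as np
import pytest

from blastoquant import midline, profiles, segmentation
from blastoquant import synthgen as sg
from blastoquant.core import Channel, ValidationError
from blastoquant.staging import TimeClass, count_nuclei


def test_same_seed_gives_bit_identical_rasters(geometry, gt_domains):
    a, _ = sg.generate_embryo(geometry, gt_domains, TimeClass(14, 4),
                              noise_sd=3.0, seed=9)
    b, _ = sg.generate_embryo(geometry, gt_domains, TimeClass(14, 4),
                              noise_sd=3.0, seed=9)
    for suffix in a.images:
        assert np.array_equal(a.images[suffix], b.images[suffix])


def test_rasters_share_dimensions_and_8bit_range(clean_embryo):
    record, _ = clean_embryo
    shapes = {img.shape[:2] for img in record.images.values()}
    assert len(shapes) == 1
    for img in record.images.values():
        assert img.dtype == np.uint8


def test_zero_stain_gives_uniform_background_interior(geometry):
    domains = (
        sg.ExpressionDomainSpec(
            "gt",
            (sg.BoundarySpec(1, "anterior", 40.0, 5.0, plateau_intensity=0.0),),
        ),
    )
    record, _ = sg.generate_embryo(geometry, domains, TimeClass(13),
                                   noise_sd=0.0, seed=0)
    inside = geometry.ellipse_mask(record.images["_ch00"].shape[:2])
    bg = sg.DEFAULT_STAIN_COLORS[Channel.NBT_BCIP].background_rgb
    assert np.array_equal(
        np.unique(record.images["_ch00"][inside].reshape(-1, 3), axis=0),
        np.array([bg]),
    )


def test_c10_nuclear_image_contains_exactly_512_nuclei(geometry):
    record, entry = sg.generate_embryo(geometry, (), TimeClass(10),
                                       noise_sd=0.0, seed=3)
    assert entry["n_nuclei"] == 512
    counted = count_nuclei(record.images["_nuc_ch00"],
                           geometry.ellipse_mask((350, 700)))
    assert abs(counted - 512) <= 0.05 * 512


@pytest.mark.parametrize("cycle", [1, 5, 10, 14])
def test_nucleus_count_doubles_per_cycle(cycle):
    from blastoquant.staging import expected_nucleus_count

    assert expected_nucleus_count(cycle) == 2 ** (cycle - 1)


def test_overlapping_ramps_rejected():
    with pytest.raises(ValidationError, match="overlapping"):
        sg.ExpressionDomainSpec(
            "gt",
            (
                sg.BoundarySpec(1, "anterior", 40.0, 10.0),
                sg.BoundarySpec(2, "posterior", 44.0, 10.0),
            ),
        )


def test_facings_must_alternate_and_positions_increase():
    with pytest.raises(ValidationError, match="alternate"):
        sg.ExpressionDomainSpec(
            "gt",
            (
                sg.BoundarySpec(1, "anterior", 30.0, 4.0),
                sg.BoundarySpec(2, "anterior", 60.0, 4.0),
            ),
        )
    with pytest.raises(ValidationError, match="increasing"):
        sg.ExpressionDomainSpec(
            "gt",
            (
                sg.BoundarySpec(1, "anterior", 60.0, 4.0),
                sg.BoundarySpec(2, "posterior", 30.0, 4.0),
            ),
        )


def test_geometry_invariants():
    with pytest.raises(ValidationError):
        sg.EmbryoGeometry(100.0, 120.0, (0, 0))  # minor > major
    with pytest.raises(ValidationError):
        sg.EmbryoGeometry(300.0, 120.0, (0, 0), rotation_deg=135.0)


def test_stain_color_invariants():
    purple = sg.DEFAULT_STAIN_COLORS[Channel.NBT_BCIP]
    red = sg.DEFAULT_STAIN_COLORS[Channel.FASTRED]
    assert purple.full_stain_rgb[0] < purple.background_rgb[0] - 50
    assert red.full_stain_rgb[1] < red.full_stain_rgb[0] - 50


def test_forward_inverse_half_max_crossings_within_half_percent(gt_domains):
    """Unmixing a noise-free image recovers every boundary to <0.5 %EL.

    The half-maximum crossings of the extracted intensity profile are
    located numerically, independently of the boundary-fitting stage.
    """
    geometry = sg.EmbryoGeometry(300.0, 120.0, (350.0, 175.0), rotation_deg=0.0)
    record, _ = sg.generate_embryo(geometry, gt_domains, TimeClass(14, 1),
                                   noise_sd=0.0, seed=11)
    mask = segmentation.compute_mask(record.images["_dic_ch00"])
    aligned, mask = segmentation.align_record(record, mask)
    spline = midline.fit_midline(mask)
    strip = midline.make_strip(spline, mask)
    prof = profiles.extract_rgb_profile(aligned.images["_ch00"], strip)
    prof = profiles.trim_to_mask(prof, strip, mask)
    prof = profiles.unmix_nbt_bcip(prof)
    prof = profiles.to_percent_el(prof, mask)

    lo, hi = 45.0, 45.0 + 0.9 * (191.0 - 45.0)  # plateau intensities
    half = (lo + hi) / 2.0
    y, x = prof.intensity, prof.pct_el
    for b in gt_domains[0].boundaries:
        near = (x > b.position_pct_el - 5) & (x < b.position_pct_el + 5)
        rel = y[near] - half
        idx = np.flatnonzero(np.diff(np.sign(rel)) != 0)
        assert idx.size >= 1
        i = idx[0]
        frac = abs(rel[i]) / abs(rel[i + 1] - rel[i])
        crossing = x[near][i] + frac * (x[near][i + 1] - x[near][i])
        assert abs(crossing - b.position_pct_el) < 0.5


class TestGenerateBatch:
    def test_layout_and_suffixes(self, tmp_path):
        spec = sg.BatchSpec(n_embryos=3, gene="gt", date="260911")
        sg.generate_batch(spec, tmp_path, seed=5)
        proc = tmp_path / "ish" / "megaselia" / "ma_gt_260911" / "proc"
        for i in (1, 2, 3):
            for suffix in ("_ch00", "_dic_ch00", "_nuc_ch00", "_memb_ch00"):
                assert (proc / f"{i:03d}{suffix}.png").exists()

    def test_empty_spec_rejected(self):
        with pytest.raises(ValidationError):
            sg.BatchSpec(n_embryos=0)

    def test_identical_seed_identical_manifest(self, tmp_path):
        spec = sg.BatchSpec(n_embryos=2)
        m1 = sg.generate_batch(spec, tmp_path / "a", seed=3)
        m2 = sg.generate_batch(spec, tmp_path / "b", seed=3)
        assert m1 == m2

    def test_refuses_nonempty_output_without_overwrite(self, tmp_path):
        spec = sg.BatchSpec(n_embryos=1)
        sg.generate_batch(spec, tmp_path, seed=1)
        with pytest.raises(FileExistsError):
            sg.generate_batch(spec, tmp_path, seed=1)
        sg.generate_batch(spec, tmp_path, seed=1, overwrite=True)

    def test_manifest_roundtrips_losslessly(self, tmp_path):
        spec = sg.BatchSpec(n_embryos=2, noise_sd=1.5)
        manifest = sg.generate_batch(spec, tmp_path, seed=8)
        path = tmp_path / "ish" / "megaselia" / spec.batch_id / "manifest.csv"
        assert sg.GroundTruthManifest.from_csv(path) == manifest
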