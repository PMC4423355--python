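"""Clamped-spline boundary fitting, detection, and ID assignment."""

import numpy as np
import pytest

from blastoquant import synthgen as sg
from blastoquant.boundaries import (
    AmbiguousBoundaryError,
    BoundaryCatalogue,
    ClampedSpline,
    UnknownGeneError,
    assign_boundary_ids,
    detect_boundary_windows,
    fit_clamped_boundary,
    position_and_width,
)
from blastoquant.core import ValidationError
from blastoquant.profiles import ExpressionProfile


def _intensity_profile(y, x=None):
    y = np.asarray(y, dtype=float)
    x = np.arange(len(y), dtype=float) if x is None else np.asarray(x, float)
    return ExpressionProfile(
        x_px=x, rgb=np.stack([255 - y] * 3, axis=1), intensity=y
    )


def _logistic_profile(boundaries, length=600, lo=45.0, hi=191.0,
                      noise_sd=0.0, seed=0):
    """Profile over x in [0, length): %EL = x / (length/100)."""
    x = np.arange(length, dtype=float)
    pct = 100.0 * x / (length - 1)
    s = sg.stain_strength(
        pct,
        (sg.ExpressionDomainSpec("gt", tuple(boundaries)),),
    )
    y = lo + s * (hi - lo)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, size=len(y))
    return _intensity_profile(np.clip(y, 0, 255), x)


class TestClampedSpline:
    def test_end_slopes_zero_and_interpolation(self):
        sp = ClampedSpline((10.0, 20.0, 30.0), (200.0, 100.0, 0.0))
        assert abs(sp.derivative(10.0)) < 1e-9
        assert abs(sp.derivative(30.0)) < 1e-9
        for x, y in zip(sp.x, sp.y):
            assert sp(x) == pytest.approx(y, abs=1e-12)

    def test_flat_outside_control_interval(self):
        sp = ClampedSpline((10.0, 20.0, 30.0), (200.0, 100.0, 0.0))
        assert sp(0.0) == 200.0
        assert sp(99.0) == 0.0
        assert sp.derivative(0.0) == 0.0

    def test_requires_ordered_x(self):
        with pytest.raises(ValidationError):
            ClampedSpline((10.0, 10.0, 30.0), (0.0, 0.0, 0.0))


class TestDetection:
    def test_single_domain_gives_exactly_two_windows(self):
        prof = _logistic_profile([
            sg.BoundarySpec(1, "anterior", 35.0, 6.0),
            sg.BoundarySpec(2, "posterior", 65.0, 6.0),
        ])
        wins = detect_boundary_windows(prof, 20.0)
        assert [w.direction for w in wins] == ["rising", "falling"]

    def test_flat_profile_gives_no_windows(self):
        assert detect_boundary_windows(_intensity_profile(np.zeros(100)), 20) == []

    def test_threshold_above_range_gives_no_windows(self):
        prof = _logistic_profile([sg.BoundarySpec(1, "anterior", 50.0, 6.0)])
        assert detect_boundary_windows(prof, 300.0) == []

    def test_noise_wiggles_do_not_split_a_boundary(self):
        prof = _logistic_profile(
            [sg.BoundarySpec(1, "anterior", 50.0, 6.0)], noise_sd=4.0, seed=5
        )
        wins = detect_boundary_windows(prof, 20.0)
        assert len(wins) == 1 and wins[0].direction == "rising"


class TestFitting:
    def test_noise_free_boundary_position_and_width_recovered(self):
        prof = _logistic_profile([sg.BoundarySpec(1, "anterior", 45.0, 6.0)])
        win = detect_boundary_windows(prof, 20.0)[0]
        fit = fit_clamped_boundary(prof, win)
        px_per_el = (len(prof) - 1) / 100.0
        assert fit.position_px / px_per_el == pytest.approx(45.0, abs=0.5)
        assert fit.width_px / px_per_el == pytest.approx(6.0, abs=1.0)

    def test_override_control_points_used_verbatim(self):
        prof = _logistic_profile([sg.BoundarySpec(1, "anterior", 45.0, 6.0)])
        fit = fit_clamped_boundary(prof, None,
                                   overrides=[(100, 40), (150, 120), (200, 200)])
        assert fit.spline.x == (100, 150, 200)
        assert "override" in fit.flags

    def test_non_monotone_window_is_ambiguous(self):
        y = np.concatenate([np.zeros(30), np.linspace(0, 120, 30),
                            np.linspace(120, 0, 30), np.zeros(30)])
        prof = _intensity_profile(y)
        from blastoquant.boundaries import Window

        with pytest.raises(AmbiguousBoundaryError):
            fit_clamped_boundary(prof, Window(0.0, 119.0, "rising"))

    def test_noisy_replicates_mean_position_error_below_one_percent(self):
        errs = []
        for rep in range(50):
            prof = _logistic_profile(
                [sg.BoundarySpec(1, "anterior", 45.0, 6.0)],
                noise_sd=8.0, seed=100 + rep,
            )
            px_per_el = (len(prof) - 1) / 100.0
            # evaluate the rising window containing the true boundary;
            # per-sample noise can add spurious low-amplitude windows
            win = next(
                w for w in detect_boundary_windows(prof, 20.0)
                if w.direction == "rising" and w.x_lo <= 45 * px_per_el <= w.x_hi
            )
            fit = fit_clamped_boundary(prof, win)
            errs.append(abs(fit.position_px / px_per_el - 45.0))
        assert np.mean(errs) <= 1.0

    def test_fit_sweep_end_slopes_and_bounded_overshoot(self):
        """Across a seeded grid the clamp and monotonicity contracts hold."""
        rng = np.random.default_rng(7)
        for _ in range(40):
            pos = rng.uniform(20, 80)
            width = rng.uniform(3, 10)
            sigma = rng.choice([0.0, 4.0, 8.0])
            facing = rng.choice(["anterior", "posterior"])
            prof = _logistic_profile(
                [sg.BoundarySpec(1, facing, pos, width)],
                noise_sd=sigma, seed=int(rng.integers(1 << 30)),
            )
            px_per_el = (len(prof) - 1) / 100.0
            win = next(
                w for w in detect_boundary_windows(prof, 20.0)
                if w.x_lo <= pos * px_per_el <= w.x_hi
            )
            fit = fit_clamped_boundary(prof, win)
            sp = fit.spline
            assert abs(sp.derivative(sp.x[0])) < 1e-9
            assert abs(sp.derivative(sp.x[2])) < 1e-9
            dense = sp(np.linspace(sp.x[0], sp.x[2], 500))
            lo, hi = min(sp.y[0], sp.y[2]), max(sp.y[0], sp.y[2])
            assert dense.min() >= lo - 1.0 and dense.max() <= hi + 1.0


class TestPositionAndWidth:
    def test_pole_to_pole_fit_has_position_fifty_width_hundred(self, rect_mask):
        mask = rect_mask(100, width=601, left=10)  # x in [10, 610]
        from blastoquant.boundaries import BoundaryFit

        fit = BoundaryFit(
            spline=ClampedSpline((10.0, 310.0, 610.0), (0.0, 50.0, 100.0)),
            direction="rising",
        )
        pos, width = position_and_width(fit, mask)
        assert pos == pytest.approx(50.0)
        assert width == pytest.approx(100.0)

    def test_symmetric_window_shrink_keeps_position(self, rect_mask):
        mask = rect_mask(100, width=601, left=10)
        from blastoquant.boundaries import BoundaryFit

        for half in (300.0, 150.0, 50.0):
            fit = BoundaryFit(
                spline=ClampedSpline((310 - half, 310.0, 310 + half),
                                     (0.0, 50.0, 100.0)),
                direction="rising",
            )
            assert position_and_width(fit, mask)[0] == pytest.approx(50.0)


class TestAssignment:
    def _fits(self, directions, positions):
        from blastoquant.boundaries import BoundaryFit

        out = []
        for d, p in zip(directions, positions):
            lo, hi = (0.0, 100.0) if d == "rising" else (100.0, 0.0)
            out.append(
                BoundaryFit(
                    spline=ClampedSpline((p - 10, p, p + 10), (lo, 50.0, hi)),
                    direction=d,
                )
            )
        return out

    def test_four_gt_boundaries_get_ids_2_5_6_7(self):
        fits = self._fits(["falling", "rising", "falling", "rising"],
                          [150, 300, 420, 520])
        out = assign_boundary_ids(fits, BoundaryCatalogue.default(), "gt")
        assert [f.boundary_id for f in out] == [2, 5, 6, 7]
        assert [f.facing for f in out] == ["posterior", "anterior",
                                           "posterior", "anterior"]

    def test_empty_fits_give_empty_output(self):
        assert assign_boundary_ids([], BoundaryCatalogue.default(), "gt") == []

    def test_three_fits_for_four_boundary_gene_flagged(self):
        fits = self._fits(["falling", "rising", "falling"], [150, 300, 420])
        out = assign_boundary_ids(fits, BoundaryCatalogue.default(), "gt")
        assigned = [f for f in out if f.boundary_id is not None]
        assert [f.boundary_id for f in assigned] == [2, 5, 6]
        assert all("count_mismatch" in f.flags for f in assigned)

    def test_artifact_fit_left_unassigned_when_directions_disagree(self):
        fits = self._fits(["rising", "falling", "rising", "falling"],
                          [20, 150, 300, 420])
        out = assign_boundary_ids(fits, BoundaryCatalogue.default(), "gt")
        by_pos = sorted(out, key=lambda f: f.spline.x[1])
        assert by_pos[0].boundary_id is None
        assert "unassigned" in by_pos[0].flags
        assert [f.boundary_id for f in by_pos[1:]] == [2, 5, 6]

    def test_unknown_gene_lists_known_genes(self):
        with pytest.raises(UnknownGeneError, match="gt"):
            assign_boundary_ids([], BoundaryCatalogue.default(), "nope")

    def test_catalogue_yaml_roundtrip(self, tmp_path):
        cat = BoundaryCatalogue.default()
        cat.to_yaml(tmp_path / "cat.yaml")
        back = BoundaryCatalogue.from_yaml(tmp_path / "cat.yaml")
        assert back.entries == cat.entries

    def test_packaged_catalogue_matches_default(self):
        from importlib.resources import files

        path = files("blastoquant.data") / "boundary_catalogue.yaml"
        cat = BoundaryCatalogue.from_yaml(str(path))
        assert cat.entries == BoundaryCatalogue.default().entries

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            BoundaryCatalogue({"gt": [(2, "anterior"), (2, "posterior")]})
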