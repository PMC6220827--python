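import numpy as np
import pytest

from valvemorph.io import Unit, ValveOutline
from valvemorph.outline import (
    align_outline,
    basic_measures,
    calibrate_harmonic_power,
    compute_efd,
    convexity_indices,
    eccentricity_broadest,
    extract_outline_features,
    heteropolarity_index,
    heuristic_descriptors,
    reconstruct_efd,
)
from valvemorph.synthetic import SyntheticValveParams, generate_outline

from conftest import ellipse_outline


def rigid_motion(outline, angle_deg, shift):
    th = np.deg2rad(angle_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return ValveOutline(outline.specimen_id, outline.points @ R.T + shift, unit=Unit.micrometer)


class TestAlignment:
    def test_axis_aligned_ellipse_unchanged(self, ellipse):
        al = align_outline(ellipse)
        assert not al.flipped
        assert abs(al.regression_slope) < 1e-9
        # identical up to start-index normalization
        i = np.argmin(np.linalg.norm(ellipse.points - al.points[0], axis=1))
        np.testing.assert_allclose(np.roll(ellipse.points, -i, axis=0), al.points, atol=1e-9)

    def test_rigid_motion_invariance(self, ellipse):
        al0 = align_outline(ellipse)
        al1 = align_outline(rigid_motion(ellipse, 30, [12.0, -7.0]))
        # principal axis back on x
        cov = np.cov((al1.points - al1.points.mean(0)).T)
        _, evecs = np.linalg.eigh(cov)
        angle = np.arctan2(evecs[1, -1], evecs[0, -1]) % np.pi
        assert min(angle, np.pi - angle) < 1e-6
        np.testing.assert_allclose(al0.points, al1.points, atol=1e-6)

    def test_mirrored_heteropolar_flipped_back(self, heteropolar_valve):
        _, outline, _ = heteropolar_valve
        mirrored = outline.points.copy()
        mirrored[:, 0] = -mirrored[:, 0]
        al = align_outline(ValveOutline("m", mirrored, unit=Unit.micrometer))
        assert al.flipped
        # recompute OLS slope of |y| on x on the output: must be >= 0
        x, ay = al.points[:, 0], np.abs(al.points[:, 1])
        slope = np.sum((x - x.mean()) * (ay - ay.mean())) / np.sum((x - x.mean()) ** 2)
        assert slope >= 0
        assert al.regression_slope == pytest.approx(slope)
        # agrees with the direct alignment of the unmirrored outline
        np.testing.assert_allclose(al.points, align_outline(outline).points, atol=1e-9)

    def test_idempotence(self, heteropolar_valve):
        _, outline, _ = heteropolar_valve
        once = align_outline(outline)
        twice = align_outline(ValveOutline("x", once.points, unit=Unit.micrometer))
        np.testing.assert_allclose(once.points, twice.points, atol=1e-9)

    def test_collinear_raises(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0)])
        with pytest.raises(ValueError):
            align_outline(ValveOutline("bad", pts, unit=Unit.micrometer))


class TestEFD:
    def test_ellipse_first_harmonic_closed_form(self, ellipse):
        efd = compute_efd(align_outline(ellipse), 5)
        a1, b1, c1, d1 = efd.harmonics[0]
        assert a1 == pytest.approx(30, rel=0.01)
        assert d1 == pytest.approx(4, rel=0.01)
        assert abs(b1) < 0.03 and abs(c1) < 0.03
        power = efd.power()
        assert power[1:].sum() / power.sum() < 1e-3

    def test_circle_harmonic_power(self):
        circle = ellipse_outline(a=10, b=10, n=90)
        efd = compute_efd(circle.points, 5)
        power = efd.power()
        assert power[0] == pytest.approx(100, rel=0.01)
        assert power[1:].sum() < 0.01 * power[0]

    @pytest.mark.parametrize("h,bulge", [(0.0, 0.0), (0.4, 0.05), (0.7, 0.1)])
    def test_reconstruction_error_monotone_and_small(self, h, bulge):
        params = SyntheticValveParams(length=60, width=8, h=h, bulge=bulge)
        outline, _ = generate_outline(params)
        al = align_outline(outline)
        errs = []
        for n in (2, 5, 10, 20):
            rec = reconstruct_efd(compute_efd(al, n), len(al.points))
            errs.append(np.abs(rec - al.points).max())
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 0.01 * 60

    def test_aliasing_guard(self, ellipse):
        with pytest.raises(ValueError, match="aliasing"):
            compute_efd(align_outline(ellipse), 31)


class TestHarmonicCalibration:
    def test_pure_ellipses_need_one_harmonic(self):
        outlines = [
            align_outline(ellipse_outline(a=20 + i, b=4 + 0.2 * i)) for i in range(5)
        ]
        assert calibrate_harmonic_power(outlines, 0.999) == 1

    def test_matches_brute_force_oracle(self, small_cohort):
        aligned = [align_outline(o) for o in small_cohort["outlines"][:15]]
        n_max = min(len(o.points) // 2 for o in aligned)
        spectra = np.array([compute_efd(o, n_max).power() for o in aligned])
        mean_cum = spectra.mean(axis=0).cumsum()
        for threshold in (0.95, 0.99, 0.999):
            brute = 1 + int(np.argmax(mean_cum >= threshold * mean_cum[-1]))
            assert calibrate_harmonic_power(aligned, threshold) == brute

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            calibrate_harmonic_power([], 0.999)


class TestBasicMeasures:
    def test_ellipse_closed_form(self, ellipse):
        m = basic_measures(ellipse)
        assert m["length"] == pytest.approx(60, rel=1e-6)
        assert m["width"] == pytest.approx(8, rel=0.01)
        assert m["aspect_ratio"] == pytest.approx(7.5, rel=0.01)
        assert m["area"] == pytest.approx(np.pi * 30 * 4, rel=0.005)

    def test_rectangle(self):
        pts = np.array([[2.0, -0.5], [2, 0.5], [-2, 0.5], [-2, -0.5]])
        m = basic_measures(ValveOutline("rect", pts, unit=Unit.micrometer))
        assert m["area"] == pytest.approx(4.0, rel=1e-9)
        assert m["perimeter"] == pytest.approx(10.0, rel=1e-9)
        assert m["aspect_ratio"] == pytest.approx(4.0, rel=1e-9)

    def test_generated_valve_area_matches_integration(self):
        params = SyntheticValveParams(length=60, width=8, h=0.4, bulge=0.08)
        outline, _ = generate_outline(params)
        t = np.linspace(-1, 1, 200001)
        oracle = np.trapezoid(2 * params.half_width(t), t) * 30  # dx = (L/2) dt
        assert basic_measures(outline)["area"] == pytest.approx(oracle, rel=0.005)

    def test_scale_equivariance(self, heteropolar_valve):
        _, outline, _ = heteropolar_valve
        m1 = basic_measures(outline)
        scaled = ValveOutline("s", outline.points * 3.0, unit=Unit.micrometer)
        m2 = basic_measures(scaled)
        assert m2["length"] == pytest.approx(3 * m1["length"], rel=1e-9)
        assert m2["area"] == pytest.approx(9 * m1["area"], rel=1e-9)
        assert m2["aspect_ratio"] == pytest.approx(m1["aspect_ratio"], rel=1e-9)


class TestHeteropolarityIndex:
    def test_symmetric_shapes_are_isopolar(self, ellipse):
        assert heteropolarity_index(ellipse) < 1e-9
        rect = ValveOutline(
            "rect",
            np.array([[3.0, -1.0], [3, 1], [-3, 1], [-3, -1]]),
            unit=Unit.micrometer,
        )
        assert heteropolarity_index(rect) < 1e-9

    @pytest.mark.parametrize("h", [0.0, 0.2, 0.4, 0.6, 0.8])
    def test_matches_integration_oracle(self, h):
        params = SyntheticValveParams(length=60, width=8, h=h)
        outline, truth = generate_outline(params)
        assert heteropolarity_index(outline) == pytest.approx(
            truth["heteropolarity_index"], abs=1e-3
        )

    def test_rigid_motion_invariance(self, heteropolar_valve):
        _, outline, _ = heteropolar_valve
        hi0 = heteropolarity_index(outline)
        hi1 = heteropolarity_index(rigid_motion(outline, 73, [5.0, 9.0]))
        assert hi1 == pytest.approx(hi0, rel=1e-6)


class TestEccentricityBroadest:
    def test_ellipse_centered(self, ellipse):
        assert eccentricity_broadest(align_outline(ellipse)) == pytest.approx(0.5, abs=1 / 256)

    def test_centered_bulge(self):
        params = SyntheticValveParams(length=60, width=8, h=0, bulge=0.1)
        outline, _ = generate_outline(params)
        assert eccentricity_broadest(align_outline(outline)) == pytest.approx(0.5, abs=0.01)

    def test_constructed_profile_peak_at_40_percent(self):
        # tent-shaped width profile: maximum width exactly 24 um from the
        # +x apex of a 60 um valve, i.e. at 40% of L from the broad apex
        x = np.linspace(-30, 30, 121)
        w = np.where(x <= 6, (x + 30) / 36.0, (30 - x) / 24.0) * 4.0
        upper = np.column_stack([x[::-1][1:], w[::-1][1:] / 2])
        lower = np.column_stack([x[1:], -w[1:] / 2])
        pts = np.vstack([[30.0, 0.0], upper[:-1], [[-30.0, 0.0]], lower[:-1]])
        al = align_outline(ValveOutline("tent", pts, unit=Unit.micrometer))
        assert al.regression_slope >= 0 and not al.flipped
        assert eccentricity_broadest(al) == pytest.approx(0.40, abs=0.01)


def notched_rectangle(depth):
    """6x2 rectangle with a triangular notch of given depth on the top edge."""
    return np.array(
        [
            [3.0, -1.0],
            [3.0, 1.0],
            [1.0, 1.0],
            [0.0, 1.0 - depth],
            [-1.0, 1.0],
            [-3.0, 1.0],
            [-3.0, -1.0],
        ]
    )[::-1]


class TestConvexity:
    def test_convex_polygon_extremes(self, ellipse):
        c = convexity_indices(ellipse)
        assert c["convexity_by_perimeter"] == pytest.approx(1.0, abs=1e-9)
        assert c["convexity_by_area"] == pytest.approx(1.0, abs=1e-9)
        assert c["PCAF"] == pytest.approx(0.0, abs=1e-7)
        assert c["CDF"] == pytest.approx(0.0, abs=1e-9)
        assert c["CHMDF"] == pytest.approx(0.0, abs=1e-9)

    def test_notched_rectangle_hand_values(self):
        depth = 0.5
        pts = notched_rectangle(depth)
        outline = ValveOutline("notch", pts, unit=Unit.micrometer)
        c = convexity_indices(outline)
        hull_area, hull_perim = 12.0, 16.0
        notch_area = 0.5 * 2.0 * depth
        notch_perim = 16.0 - 2.0 + 2 * np.hypot(1.0, depth)
        assert c["convexity_by_area"] == pytest.approx((hull_area - notch_area) / hull_area, rel=1e-9)
        assert c["PCAF"] == pytest.approx(100 * notch_area / hull_area, rel=1e-9)
        assert c["convexity_by_perimeter"] == pytest.approx(hull_perim / notch_perim, rel=1e-9)
        assert c["CHMDF"] == pytest.approx(depth / 6.0, rel=1e-9)
        assert c["CDF"] == pytest.approx(depth / (7 * 6.0), rel=1e-9)  # one of 7 vertices inside

    def test_deeper_notch_monotone(self):
        by_area, pcaf, chmdf = [], [], []
        for depth in (0.2, 0.4, 0.6, 0.8):
            c = convexity_indices(
                ValveOutline("n", notched_rectangle(depth), unit=Unit.micrometer)
            )
            by_area.append(c["convexity_by_area"])
            pcaf.append(c["PCAF"])
            chmdf.append(c["CHMDF"])
        assert np.all(np.diff(by_area) < 0)
        assert np.all(np.diff(pcaf) > 0)
        assert np.all(np.diff(chmdf) > 0)


class TestHeuristicDescriptors:
    def test_circle_anchors(self):
        circle = ellipse_outline(a=10, b=10.0001, n=120)
        d = heuristic_descriptors(circle)
        assert d["form_factor"] == pytest.approx(1.0, rel=0.01)
        assert d["compactness"] == pytest.approx(1.0, rel=0.01)
        assert d["roundness"] == pytest.approx(1.0, rel=0.01)

    def test_rectangle_rectangularity(self):
        pts = np.array([[3.0, -1.0], [3, 1], [-3, 1], [-3, -1]])
        d = heuristic_descriptors(ValveOutline("r", pts, unit=Unit.micrometer))
        assert d["rectangularity"] == pytest.approx(1.0, abs=1e-6)

    def test_ellipse_and_triangle_moment_anchors(self, ellipse):
        assert heuristic_descriptors(ellipse)["ellipticity"] == pytest.approx(1.0, rel=0.01)
        tri = np.array([[3.0, -1.0], [0.0, 2.0], [-3.0, -1.0]])
        d = heuristic_descriptors(ValveOutline("t", tri, unit=Unit.micrometer))
        assert d["triangularity"] == pytest.approx(1.0, rel=0.01)

    def test_dimensionless_scale_invariance(self, heteropolar_valve):
        _, outline, _ = heteropolar_valve
        d1 = heuristic_descriptors(outline)
        d2 = heuristic_descriptors(
            ValveOutline("s", outline.points * 2.5, unit=Unit.micrometer)
        )
        for key in d1:
            assert d2[key] == pytest.approx(d1[key], rel=1e-9)


class TestBatchExtraction:
    def test_clean_cohort_no_missing(self, small_cohort):
        feats = extract_outline_features(small_cohort["outlines"][:10], n_harmonics=5)
        assert len(feats) == 10
        assert not feats.isna().any().any()
        assert "A1" in feats.columns and "D5" in feats.columns

    def test_degenerate_row_degrades_to_missing(self, small_cohort):
        bad = ValveOutline(
            "bad", np.column_stack([np.arange(5.0), np.arange(5.0)]), unit=Unit.micrometer
        )
        with pytest.warns(UserWarning, match="bad"):
            feats = extract_outline_features(small_cohort["outlines"][:3] + [bad], n_harmonics=5)
        assert len(feats) == 4
        assert feats.set_index("specimen_id").loc["bad"].isna().all()

    def test_batch_equals_single(self, small_cohort):
        outlines = small_cohort["outlines"][:4]
        batch = extract_outline_features(outlines, n_harmonics=5)
        singles = [extract_outline_features([o], n_harmonics=5) for o in outlines]
        for i, s in enumerate(singles):
            for col in batch.columns:
                a, b = batch.iloc[i][col], s.iloc[0][col]
                assert a == b or (a != a and b != b)
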