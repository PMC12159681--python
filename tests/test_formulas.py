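"""Clinical formula toolkit: geometry, stiffness, relaxometry, grading, FD."""

import math

import numpy as np
import pytest

from cmrnorms import formulas as f
from cmrnorms.synth import gen_flow_pair, gen_fractal_image

LN4_LN3 = math.log(4) / math.log(3)


class TestBodySize:
    def test_mosteller_exact_case(self):
        assert f.bsa(180, 80, "mosteller") == pytest.approx(2.0)

    def test_dubois_closed_form(self):
        want = 0.007184 * 180 ** 0.725 * 80 ** 0.425
        assert f.bsa(180, 80, "dubois") == pytest.approx(want, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            f.bsa(0, 80)
        with pytest.raises(ValueError):
            f.index_value(147, 0)

    @pytest.mark.parametrize("value, bsa, want", [(147, 2.0, 73.5), (5, 1, 5), (0, 1.8, 0)])
    def test_indexing(self, value, bsa, want):
        assert f.index_value(value, bsa) == want


class TestAtrialVolumes:
    def test_monoplane_arithmetic(self):
        assert f.atrial_volume_monoplane(20, 5) == pytest.approx(
            8 * 400 / (3 * math.pi * 5))

    def test_biplane_equals_monoplane_for_equal_areas(self):
        g = f.BiplaneGeometry(20, 20, 5, 5)
        assert f.atrial_volume_biplane_ellipsoid(g) == pytest.approx(
            f.atrial_volume_monoplane(20, 5))

    def test_calibrated_variant(self):
        g = f.BiplaneGeometry(20, 20, 5, 5)
        assert f.atrial_volume_biplane_calibrated(g) == pytest.approx(67.84)
        ratio = f.atrial_volume_biplane_calibrated(g) / \
            f.atrial_volume_biplane_ellipsoid(g, length_rule="mean")
        assert ratio == pytest.approx(0.848 / (8 / (3 * math.pi)), rel=1e-12)

    def test_shortest_length_rule(self):
        g = f.BiplaneGeometry(20, 18, 6, 5)
        assert f.atrial_volume_biplane_ellipsoid(g, "shortest") == pytest.approx(
            8 * 20 * 18 / (3 * math.pi * 5))

    def test_volume_vanishes_with_area(self):
        g = f.BiplaneGeometry(0, 20, 5, 5)
        assert f.atrial_volume_biplane_ellipsoid(g) == 0.0

    def test_volume_decreases_with_length(self):
        vols = [f.atrial_volume_monoplane(20, L) for L in (4, 8, 16, 64)]
        assert vols == sorted(vols, reverse=True)


class TestSphericity:
    def test_sphere_scores_one(self):
        r = 3.0
        edv = 4 / 3 * math.pi * r ** 3
        assert f.sphericity_index(edv, 2 * r) == pytest.approx(1.0)

    def test_linear_in_volume(self):
        assert f.sphericity_index(75, 9) == pytest.approx(
            0.5 * f.sphericity_index(150, 9))

    def test_worked_example(self):
        assert f.sphericity_index(150, 9) == pytest.approx(150 / 381.70, abs=1e-4)


class TestDistensibility:
    def test_no_area_change_is_zero(self):
        assert f.distensibility(4.0, 4.0, 120, 80) == 0.0

    def test_ten_percent_over_40mmHg(self):
        assert f.distensibility(1.1, 1.0, 120, 80) == pytest.approx(2.5)

    def test_area_unit_invariance(self):
        a = f.distensibility(550, 500, 130, 75)      # mm^2
        b = f.distensibility(5.5, 5.0, 130, 75)      # cm^2
        assert a == pytest.approx(b)

    def test_nonpositive_pulse_pressure_rejected(self):
        with pytest.raises(ValueError):
            f.distensibility(1.1, 1.0, 80, 80)


class TestTransitTimeAndPwv:
    def test_known_shift_recovered(self):
        pair = gen_flow_pair(true_pwv=6.0, delta_x=0.3, dt=5.0)  # 50 ms truth
        for method in ("upslope_intersect", "upslope_midpoint"):
            assert f.transit_time(pair, method) == pytest.approx(50.0, abs=5.0)

    def test_identical_curves_have_zero_delay(self):
        pair = gen_flow_pair(true_pwv=6.0, delta_x=0.3, dt=5.0)
        same = f.AortaPathPair(proximal=pair.proximal, distal=pair.proximal,
                               delta_x=0.3)
        assert f.transit_time(same) == pytest.approx(0.0, abs=1e-9)

    def test_translation_equivariance(self):
        pair = gen_flow_pair(true_pwv=6.0, delta_x=0.3, dt=5.0)
        shift = 40.0  # whole samples
        moved = f.FlowCurve(times=pair.distal.times + shift,
                            velocities=pair.distal.velocities)
        both = f.AortaPathPair(
            proximal=f.FlowCurve(times=pair.proximal.times + shift,
                                 velocities=pair.proximal.velocities),
            distal=moved, delta_x=0.3)
        assert f.transit_time(both) == pytest.approx(f.transit_time(pair), abs=1e-6)
        one = f.AortaPathPair(proximal=pair.proximal, distal=moved, delta_x=0.3)
        assert f.transit_time(one) == pytest.approx(
            f.transit_time(pair) + shift, abs=1e-6)

    def test_pwv_arithmetic_and_scaling(self):
        pair = gen_flow_pair(true_pwv=10.0, delta_x=0.3, dt=2.0)  # 30 ms
        assert f.pwv(pair) == pytest.approx(10.0, rel=0.05)
        double = gen_flow_pair(true_pwv=20.0, delta_x=0.6, dt=2.0)  # same 30 ms
        assert f.pwv(double) == pytest.approx(2 * f.pwv(pair), rel=0.05)

    def test_noisy_recovery_within_ten_percent(self):
        pair = gen_flow_pair(true_pwv=6.0, delta_x=0.3, dt=5.0,
                             noise_sd=0.05, seed=3)
        assert f.transit_time(pair) == pytest.approx(50.0, rel=0.10)

    def test_flat_curve_rejected(self):
        t = np.arange(0, 500, 5.0)
        flat = f.FlowCurve(times=t, velocities=np.zeros_like(t))
        pair = gen_flow_pair(true_pwv=6.0, delta_x=0.3, dt=5.0)
        bad = f.AortaPathPair(proximal=flat, distal=pair.distal, delta_x=0.3)
        with pytest.raises(ValueError):
            f.transit_time(bad)


class TestRelaxometry:
    def test_equal_delta_r1_gives_one_minus_hct(self):
        r = f.RelaxometryInput(t1_myo_native=1000, t1_myo_post=500,
                               t1_blood_native=1000, t1_blood_post=500,
                               hematocrit=0.42)
        assert f.ecv(r) == pytest.approx(0.58)

    def test_half_ratio_example(self):
        # myocardial delta-R1 half of blood's: ECV = 0.6 * 0.5 = 0.30
        r = f.RelaxometryInput(t1_myo_native=1000, t1_myo_post=800,
                               t1_blood_native=1000, t1_blood_post=2000 / 3,
                               hematocrit=0.40)
        assert f.ecv(r) == pytest.approx(0.30, abs=1e-12)

    def test_hct_to_one_drives_ecv_to_zero(self):
        r = f.RelaxometryInput(1000, 500, 1000, 500, hematocrit=1 - 1e-9)
        assert f.ecv(r) == pytest.approx(0.0, abs=1e-6)

    def test_synthetic_hct_constant_calibration(self):
        assert f.synthetic_hct(1600, (0.0, 0.4)) == 0.4

    def test_synthetic_hct_requires_calibration_and_positive_t1(self):
        with pytest.raises(ValueError):
            f.synthetic_hct(1600, None)
        with pytest.raises(ValueError):
            f.synthetic_hct(-5, (0.1, 0.1))

    def test_synthetic_hct_round_trip(self):
        slope, intercept = 0.9, -0.25
        t1 = 1550.0
        hct = slope * (1000 / t1) + intercept
        assert f.synthetic_hct(t1, (slope, intercept)) == pytest.approx(hct)

    def test_r2star_reciprocal(self):
        assert f.r2star(25) == pytest.approx(40.0)
        assert f.r2star(1000) == pytest.approx(1.0)
        assert 1000 / f.r2star(17.3) == pytest.approx(17.3)

    def test_iron_concentration(self):
        assert f.iron_concentration(20) == pytest.approx(45 / 20 ** 1.22, rel=1e-12)
        fe = [f.iron_concentration(t) for t in (5, 10, 20, 40)]
        assert fe == sorted(fe, reverse=True)


class TestIronGrading:
    @pytest.mark.parametrize("t2s, field, want", [
        (25, "1.5", "normal"), (15, "1.5", "overload"), (9, "1.5", "severe"),
        (13, "3", "normal"), (6, "3", "overload"), (4, "3", "severe"),
        (20, "1.5", "overload"), (10, "1.5", "overload"),
        (12, "3", "overload"), (5.5, "3", "overload"),
    ])
    def test_grades(self, t2s, field, want):
        assert f.grade_iron(t2s, field) == want

    def test_partition_no_gaps_or_overlaps(self):
        """Every positive T2* gets exactly one grade at either field strength."""
        grid = np.concatenate([np.linspace(0.1, 30, 2000),
                               [5.5, 10.0, 12.0, 20.0]])
        for field in ("1.5", "3"):
            grades = [f.grade_iron(t, field) for t in grid]
            assert set(grades) == {"normal", "overload", "severe"}
            order = {"severe": 0, "overload": 1, "normal": 2}
            ranked = [order[g] for g, _ in sorted(zip(grades, grid),
                                                  key=lambda p: p[1])]
            assert ranked == sorted(ranked)  # monotone in T2*: no overlap


class TestValveAndDiastole:
    @pytest.mark.parametrize("v, want", [(2.5, "mild"), (3.5, "moderate"),
                                         (4.2, "severe"), (5.2, "severe")])
    def test_stenosis_by_velocity(self, v, want):
        stage, quals = f.stage_aortic_stenosis(v_max=v)
        assert stage == want
        if v >= 5:
            assert any("very severe" in q for q in quals)

    def test_stenosis_by_area_alone(self):
        stage, quals = f.stage_aortic_stenosis(orifice_area=0.9)
        assert stage == "severe" and any("orifice" in q for q in quals)

    def test_stenosis_requires_some_input(self):
        with pytest.raises(ValueError):
            f.stage_aortic_stenosis()

    @pytest.mark.parametrize("mdt, ea, want", [
        (180, 1.5, {"normal", "type2"}),
        (300, 0.8, {"type1"}),
        (100, 2.5, {"type3"}),
        (180, 2.5, {"indeterminate"}),
    ])
    def test_diastolic_rule_table(self, mdt, ea, want):
        assert f.classify_diastolic(mdt, ea) == frozenset(want)


class TestFractalDimension:
    def test_line_is_one_dimensional(self):
        fd = f.box_counting_fd(gen_fractal_image("line", size_px=512))
        assert 0.95 <= fd <= 1.05

    def test_koch_curve(self):
        img = gen_fractal_image("koch", iterations=5, size_px=512)
        assert f.box_counting_fd(img) == pytest.approx(LN4_LN3, abs=0.05)

    def test_square_boundary_vs_interior(self):
        assert f.box_counting_fd(gen_fractal_image("square_boundary", size_px=512)) \
            == pytest.approx(1.0, abs=0.1)
        assert f.box_counting_fd(gen_fractal_image("filled_square", size_px=512)) \
            == pytest.approx(2.0, abs=0.1)

    def test_translation_by_whole_boxes_invariant(self):
        img = gen_fractal_image("koch", iterations=4, size_px=256)
        sizes = [4, 8, 16, 32]
        rolled = np.roll(img, (32, 32), axis=(0, 1))
        assert f.box_counting_fd(img, sizes) == pytest.approx(
            f.box_counting_fd(rolled, sizes), abs=1e-9)

    def test_region_mask_label_convention(self):
        img = gen_fractal_image("koch", iterations=4, size_px=256)
        region = np.ones_like(img, dtype=bool)
        assert f.box_counting_fd(img, region=region) == f.box_counting_fd(img)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            f.box_counting_fd(np.zeros((64, 64), dtype=bool))
        img = gen_fractal_image("line", size_px=128)
        with pytest.raises(ValueError):
            f.box_counting_fd(img, box_sizes=[2, 4])

    def test_stack_summaries(self):
        fds = [1.1, 1.2, 1.3, 1.25, 1.4, 1.35]
        out = f.summarize_fd_stack(fds)
        assert out["global_fd"] == pytest.approx(np.mean(fds))
        assert out["max_apical_fd"] == 1.4  # max over the apical half
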