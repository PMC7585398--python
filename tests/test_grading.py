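"""Rule-based defect/artifact grading against ground truth."""

import numpy as np
import pytest

from cprnfl import (
    ArtifactSpec,
    LesionSpec,
    attribute_factors,
    check_alignment,
    detect_clipping,
    detect_defects,
    estimate_scaling,
    grade_segmentation,
    make_normative_profile,
    simulate_pair,
)
from cprnfl.errors import UnsupportedInputError
from cprnfl.grading import circular_runs
from cprnfl.profiles import ThicknessProfile, VisitPair, canonical_angles


def _const_pair(level=80.0, n=768):
    a = ThicknessProfile(canonical_angles(n), np.full(n, float(level)),
                         vessel_markers=[(70.0, 3.0), (250.0, 3.0)])
    return VisitPair("e", a, a.copy())


class TestCircularRuns:
    def test_wrapping_run(self):
        mask = np.zeros(12, bool)
        mask[[10, 11, 0, 1]] = True
        assert circular_runs(mask) == [(10, 4)]

    def test_all_and_none(self):
        assert circular_runs(np.ones(5, bool)) == [(0, 5)]
        assert circular_runs(np.zeros(5, bool)) == []


class TestDetectDefects:
    def test_recovers_injected_local_lesion(self, tight_model, tight_bands):
        lesion = LesionSpec("local", 120.0, 30.0, 15.0, "boxcar")
        record = simulate_pair(tight_model.zero_noise(), [lesion], [], seed=0)
        defects = detect_defects(record.pair, tight_bands)
        assert len(defects) == 1
        defect = defects[0]
        assert defect.classification == "local"
        assert defect.width_deg == pytest.approx(30.0, abs=5.0)
        assert defect.mean_depth_um == pytest.approx(15.0, abs=1.0)

    def test_widespread_thinning_classified_widespread(self, tight_model, tight_bands):
        lesion = LesionSpec("widespread", 180.0, 270.0, 8.0, "boxcar")
        record = simulate_pair(tight_model.zero_noise(), [lesion], [], seed=1)
        defects = detect_defects(record.pair, tight_bands)
        assert len(defects) == 1
        assert defects[0].classification == "widespread"

    def test_identical_visits_give_no_defects(self, tight_model, tight_bands):
        record = simulate_pair(tight_model.zero_noise(), [], [], seed=2)
        assert detect_defects(record.pair, tight_bands) == []

    def test_width_recovery_over_many_lesions(self, tight_model, tight_bands):
        # ground-truth recovery: width within +/-2 grid steps, never widespread
        rng = np.random.default_rng(3)
        step = 360.0 / tight_model.grid_size
        for i in range(120):
            width = rng.uniform(10.0, 40.0)
            lesion = LesionSpec("local", rng.uniform(0, 360), width, 15.0, "boxcar")
            record = simulate_pair(tight_model.zero_noise(), [lesion], [], seed=[4, i])
            defects = detect_defects(record.pair, tight_bands)
            assert len(defects) == 1
            assert abs(defects[0].width_deg - width) <= 2 * step + step
            assert defects[0].classification == "local"


class TestGradeSegmentation:
    def test_recovers_injected_offset(self, quiet_model):
        art = ArtifactSpec("segmentation", "followup", (100.0, 136.0), -20.0)
        record = simulate_pair(quiet_model, [], [art], seed=0)
        findings = grade_segmentation(record, tol=5.0)
        assert len(findings) == 1
        f = findings[0]
        assert f.visit == "followup"
        assert f.width_deg == pytest.approx(36.0, abs=1.0)
        assert f.mean_error_um == pytest.approx(-20.0, abs=0.5)

    def test_narrow_offset_below_5deg_rule_ignored(self, quiet_model):
        art = ArtifactSpec("schisis", "followup", (100.0, 104.0), -20.0)
        record = simulate_pair(quiet_model, [], [art], seed=0)
        assert grade_segmentation(record, tol=5.0) == []

    def test_false_alarm_rate_on_clean_eyes(self, default_model):
        # tol at 5x the pointwise SD: graded segmentation on artifact-free
        # eyes should be (almost) never
        tol = 5.0 * default_model.within_eye_profile_sd
        alarms = sum(
            bool(grade_segmentation(simulate_pair(default_model, [], [], seed=[7, i]),
                                    tol=tol))
            for i in range(300))
        assert alarms / 300 <= 0.01

    def test_requires_latent_truth(self, quiet_model):
        record = simulate_pair(quiet_model, [], [], seed=0)
        record.latent_truth = None
        with pytest.raises(UnsupportedInputError):
            grade_segmentation(record)


class TestAlignment:
    def test_identical_markers_aligned(self):
        pair = _const_pair()
        assert check_alignment(pair) == (False, 0.0)

    @pytest.mark.parametrize("shift,expected_mis", [(5.0, True), (2.0, False)])
    def test_shift_vs_vessel_width_rule(self, shift, expected_mis):
        pair = _const_pair()
        pair.followup.vessel_markers = [((c + shift) % 360.0, w)
                                        for c, w in pair.followup.vessel_markers]
        mis, est = check_alignment(pair)
        assert mis is expected_mis
        assert est == pytest.approx(shift, abs=1e-9)

    def test_rotation_artifact_detected(self, quiet_model):
        art = ArtifactSpec("rotation", "followup", None, 6.0)
        record = simulate_pair(quiet_model, [], [art], seed=0)
        mis, est = check_alignment(record.pair)
        assert mis is True
        assert est == pytest.approx(6.0, abs=record.pair.baseline.step)

    def test_no_markers_unsupported(self):
        n = 768
        a = ThicknessProfile(canonical_angles(n), np.full(n, 80.0))
        with pytest.raises(UnsupportedInputError):
            check_alignment(VisitPair("e", a, a.copy()))


class TestScaling:
    def test_exact_ratio_on_proportional_pairs(self):
        pair = _const_pair(80.0)
        pair.followup.thickness = pair.baseline.thickness * 1.03
        s, flagged = estimate_scaling(pair)
        assert s == pytest.approx(0.03, abs=1e-12)
        assert flagged is True

    def test_identity_not_flagged(self):
        s, flagged = estimate_scaling(_const_pair())
        assert s == 0.0 and flagged is False

    def test_recovers_scaling_under_noise(self, default_model):
        rng = np.random.default_rng(0)
        pair = _const_pair(80.0)
        pair.followup.thickness = pair.baseline.thickness * 0.95 + rng.normal(0, 1, 768)
        s, flagged = estimate_scaling(pair)
        assert s == pytest.approx(-0.05, abs=0.005)
        assert flagged is True

    def test_insufficient_overlap_unsupported(self):
        pair = _const_pair()
        pair.followup.valid[: 500] = False
        with pytest.raises(UnsupportedInputError):
            estimate_scaling(pair)


class TestClipping:
    def test_masked_region_detected(self):
        pair = _const_pair()
        profile = pair.baseline
        mask = (profile.angles >= 30.0) & (profile.angles <= 90.0)
        profile.valid[mask] = False
        regions = detect_clipping(profile)
        assert len(regions) == 1
        start, end = regions[0]
        assert start == pytest.approx(30.0, abs=profile.step)
        assert end == pytest.approx(90.0, abs=2 * profile.step)

    def test_clean_profile_empty(self):
        assert detect_clipping(_const_pair().baseline) == []

    def test_clipped_followup_delta_g_magnitude(self, flat80):
        # 60° clipped to a 10 µm floor on an 80 µm eye: include_measured
        # ΔG = -(60/360)*70 ≈ -11.7 µm, same order as real clipping FPs
        art = ArtifactSpec("clipping", "followup", (100.0, 160.0), 10.0)
        record = simulate_pair(flat80, [], [art], seed=0)
        regions = detect_clipping(record.pair.followup)
        assert len(regions) == 1
        assert (regions[0][1] - regions[0][0]) == pytest.approx(60.0, abs=1.0)
        assert record.pair.delta_g == pytest.approx(-60.0 / 360.0 * 70.0, abs=0.1)


class TestAttributeFactors:
    def test_segmentation_primary_over_local(self, flat80):
        lesion = LesionSpec("local", 90.0, 30.0, 12.0, "boxcar")  # -1.0 µm
        seg = ArtifactSpec("segmentation", "followup", (200.0, 260.0), -15.6)  # -2.6 µm
        record = simulate_pair(flat80, [lesion], [seg], seed=0)
        report = attribute_factors(record)
        causes = [(f.cause, f.rank) for f in report.factor_ranking]
        assert causes == [("segmentation", 1), ("local", 2)]

    def test_scaling_only(self, flat80):
        record = simulate_pair(
            flat80, [], [ArtifactSpec("scaling", "followup", None, -0.04)], seed=0)
        report = attribute_factors(record)
        assert [f.cause for f in report.factor_ranking] == ["scaling"]
        assert report.scaling_flagged

    def test_artifact_free_progressor_ranks_local_only(self, quiet_model):
        record = simulate_pair(quiet_model, [LesionSpec("local", 90, 30, 12)], [], seed=0)
        report = attribute_factors(record)
        assert [f.cause for f in report.factor_ranking] == ["local"]

    def test_detector_false_alarm_rates_on_clean_cohort(self, default_model):
        # On artifact-free, lesion-free eyes every detector should stay
        # below a 2% flag rate at default thresholds.
        from cprnfl.grading import NormativeBands
        bands = NormativeBands.from_model(default_model, n_eyes=800, seed=77)
        n = 400
        alarms = {"defect": 0, "seg": 0, "clip": 0, "align": 0, "scale": 0}
        for i in range(n):
            record = simulate_pair(default_model, [], [], seed=[21, i])
            report = attribute_factors(record, bands)
            alarms["defect"] += bool(report.defects)
            alarms["seg"] += bool(report.segmentation_regions)
            alarms["clip"] += bool(report.clipped_regions)
            alarms["align"] += report.misaligned
            alarms["scale"] += report.scaling_flagged
        for name, count in alarms.items():
            assert count / n <= 0.02, name
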