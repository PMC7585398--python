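"""Generator contracts: shapes, lesions, artifacts, noise calibration."""

import numpy as np
import pytest

from cprnfl import (
    ArtifactSpec,
    CohortConfig,
    LesionSpec,
    NormativeModel,
    apply_artifact,
    apply_lesion,
    make_normative_profile,
    simulate_cohort,
    simulate_pair,
    simulate_testretest,
)
from cprnfl.errors import ParameterError
from cprnfl.profiles import canonical_angles, region_mask
from cprnfl.synthetic import (
    lesion_depth_profile,
    mean_g,
    mean_profile,
    sample_testretest_g,
    summarize_cohort,
)


class TestNormativeProfile:
    def test_degenerate_model_gives_constant_profile(self, flat80):
        profile = make_normative_profile(flat80, seed=0)
        assert np.all(profile.thickness == 80.0)
        assert profile.n == 768

    def test_default_mean_g_is_plausible_and_matches_configured_shape(self, default_model):
        # independent quadrature of the configured shape on the grid
        angles = canonical_angles(default_model.grid_size)
        expected = np.full_like(angles, default_model.base_level)
        for center, amp, sd in default_model.peak_params:
            d = (angles - center + 180.0) % 360.0 - 180.0
            expected += amp * np.exp(-0.5 * (d / sd) ** 2)
        for center, amp, width, _ in default_model.vessel_params:
            d = np.abs((angles - center + 180.0) % 360.0 - 180.0)
            inside = d < width / 2
            expected[inside] += amp * 0.5 * (1 + np.cos(2 * np.pi * d[inside] / width))
        assert mean_g(default_model) == pytest.approx(np.mean(expected), rel=1e-12)
        assert 70.0 <= mean_g(default_model) <= 120.0

    def test_between_eye_spread_matches_generator_sds(self, default_model):
        # |G_i - G_j| for independent eyes has SD driven by sqrt(2)*between_eye_sd
        # plus two visit-level G offsets; 3 sigma of that difference should
        # cover >= 99% of draws.
        gs = np.array([np.mean(make_normative_profile(default_model, [5, i]).thickness)
                       for i in range(1000)])
        diffs = np.abs(gs[:500] - gs[500:])
        sd_diff = np.sqrt(2 * default_model.between_eye_sd ** 2
                          + default_model.g_retest_sd ** 2)
        assert np.mean(diffs < 3 * sd_diff) >= 0.99

    def test_vessel_markers_at_configured_centers(self, default_model):
        profile = make_normative_profile(default_model, seed=0)
        centers = sorted(c for c, _ in profile.vessel_markers)
        expected = sorted(c for c, *_ in default_model.vessel_params)
        assert np.allclose(centers, expected, atol=profile.step)

    def test_negative_sd_rejected(self):
        model = NormativeModel(between_eye_sd=-1.0)
        with pytest.raises(ParameterError):
            make_normative_profile(model, seed=0)


class TestLesions:
    @pytest.mark.parametrize("kind,width,depth", [
        ("local", 30.0, 12.0),      # 30*12/360 = 1.0 µm off G
        ("widespread", 90.0, 4.0),  # 90*4/360 = 1.0 µm off G
        ("widespread", 270.0, 6.0),
    ])
    def test_boxcar_mean_drop_exact(self, flat80, kind, width, depth):
        # widths are whole multiples of the 768-grid step, so exact
        profile = make_normative_profile(flat80, 0)
        lesion = LesionSpec(kind, 180.0, width, depth, "boxcar")
        thinned = apply_lesion(profile, lesion)
        assert np.mean(profile.thickness) - np.mean(thinned.thickness) == pytest.approx(
            width * depth / 360.0, abs=1e-12)

    def test_raised_cosine_drop_matches_quadrature(self, flat80):
        profile = make_normative_profile(flat80, 0)
        lesion = LesionSpec("local", 123.0, 37.0, 9.0, "raised-cosine")
        thinned = apply_lesion(profile, lesion)
        # independent quadrature: grid mean of the analytic depth profile
        d = np.abs((profile.angles - 123.0 + 180.0) % 360.0 - 180.0)
        inside = d < 37.0 / 2
        depth = np.zeros_like(d)
        depth[inside] = 2.0 * 9.0 * 0.5 * (1 + np.cos(2 * np.pi * d[inside] / 37.0))
        expected = np.mean(depth)
        actual = np.mean(profile.thickness) - np.mean(thinned.thickness)
        assert actual == pytest.approx(expected, rel=1e-9)

    def test_lesion_only_thins_its_support_and_clamps_at_zero(self, flat80):
        profile = make_normative_profile(flat80, 0)
        lesion = LesionSpec("local", 10.0, 30.0, 200.0, "boxcar")  # wraps past 0
        thinned = apply_lesion(profile, lesion)
        mask = region_mask(profile.angles, lesion.region)
        assert np.all(thinned.thickness[mask] == 0.0)  # clamped
        assert np.all(thinned.thickness[~mask] == 80.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ParameterError):
            LesionSpec("local", 0, 50.0, 5.0).validate()  # local must be < 45
        with pytest.raises(ParameterError):
            LesionSpec("widespread", 0, 60.0, 5.0).validate()  # widespread >= 90
        with pytest.raises(ParameterError):
            LesionSpec("local", 0, 30.0, -1.0).validate()


class TestArtifacts:
    def test_five_percent_scaling_on_80_is_4_um(self, flat80):
        profile = make_normative_profile(flat80, 0)
        scaled = apply_artifact(profile, ArtifactSpec("scaling", "followup", None, -0.05))
        assert np.all(scaled.thickness == 76.0)

    def test_rotation_preserves_global_mean_exactly(self, default_model):
        profile = make_normative_profile(default_model, seed=2)
        rotated = apply_artifact(profile, ArtifactSpec("rotation", "followup", None, 33.75))
        assert np.mean(rotated.thickness) == np.mean(profile.thickness)
        # markers shifted by the same grid-snapped angle
        shift = (rotated.vessel_markers[0][0] - profile.vessel_markers[0][0]) % 360.0
        assert shift == pytest.approx(33.75, abs=profile.step)

    def test_segmentation_offset_shifts_mean_by_area(self, flat80):
        profile = make_normative_profile(flat80, 0)
        art = ArtifactSpec("segmentation", "baseline", (100.0, 145.0), -16.0)
        offset = apply_artifact(profile, art)
        assert np.mean(offset.thickness) == pytest.approx(78.0, abs=1e-12)  # 45*16/360

    def test_clipping_invalidates_and_collapses(self, flat80):
        profile = make_normative_profile(flat80, 0)
        art = ArtifactSpec("clipping", "followup", (30.0, 90.0), 10.0)
        clipped = apply_artifact(profile, art)
        mask = region_mask(profile.angles, (30.0, 90.0))
        assert np.all(~clipped.valid[mask])
        assert np.all(clipped.thickness[mask] == 10.0)
        assert np.all(clipped.valid[~mask])

    def test_artifact_validation(self):
        with pytest.raises(ParameterError):
            ArtifactSpec("segmentation", "baseline", (0.0, 4.0), -10.0).validate()
        with pytest.raises(ParameterError):
            ArtifactSpec("scaling", "baseline", None, 0.08).validate()
        with pytest.raises(ParameterError):
            ArtifactSpec("warp", "baseline", None, 0.0).validate()


class TestSimulatePair:
    def test_no_change_zero_noise_gives_zero_delta_g(self, quiet_model):
        record = simulate_pair(quiet_model, [], [], seed=0)
        assert record.pair.delta_g == 0.0
        assert record.truth_label == "NP"

    def test_boxcar_lesion_linearity(self, flat80):
        lesion = LesionSpec("local", 90.0, 30.0, 12.0, "boxcar")
        record = simulate_pair(flat80, [lesion], [], seed=0)
        assert record.pair.delta_g == pytest.approx(-1.0, abs=1e-12)
        assert record.truth_label == "P"

    def test_delta_g_sd_matches_configured_retest_sd(self, default_model):
        gb, gf = sample_testretest_g(default_model, 10000, seed=7)
        sd = np.std(gf - gb)
        assert sd == pytest.approx(default_model.g_retest_sd, rel=0.05)

    def test_latent_truth_stored_and_deterministic(self, default_model):
        lesion = LesionSpec("local", 90.0, 20.0, 10.0)
        a = simulate_pair(default_model, [lesion], [], seed=42)
        b = simulate_pair(default_model, [lesion], [], seed=42)
        assert np.array_equal(a.pair.baseline.thickness, b.pair.baseline.thickness)
        assert np.array_equal(a.latent_truth[1].thickness, b.latent_truth[1].thickness)
        # latent follow-up = latent baseline - lesion, no noise
        drop = a.latent_truth[0].thickness - a.latent_truth[1].thickness
        expected = lesion_depth_profile(lesion, a.latent_truth[0].angles)
        clamped = np.minimum(expected, a.latent_truth[0].thickness)
        assert np.allclose(drop, clamped)


class TestCohort:
    def test_linear_cohort_deltas(self, flat80):
        config = CohortConfig(
            n_p=5, n_np=8, model=flat80, lesion_shape="boxcar",
            local_fraction=0.0, widespread_width_range=(270.0, 270.0),
            widespread_depth_range=(6.0, 6.0),
            p_segmentation=0.0, p_clipping=0.0, p_scaling=0.0, p_rotation=0.0)
        records = simulate_cohort(config, seed=1)
        for record in records:
            if record.truth_label == "P":
                assert record.pair.delta_g == pytest.approx(-4.5, abs=1e-9)
            else:
                assert record.pair.delta_g == 0.0

    def test_segmentation_prevalence_binomial(self, default_model):
        config = CohortConfig(n_p=0, n_np=400, model=default_model,
                              p_segmentation=0.44, p_clipping=0.0,
                              p_scaling=0.0, p_rotation=0.0)
        summary = summarize_cohort(simulate_cohort(config, seed=2))
        n, p = 400, 0.44
        tol = 4 * np.sqrt(n * p * (1 - p))
        assert abs(summary["segmentation"] - n * p) <= tol

    def test_same_seed_bit_identical(self, default_model):
        config = CohortConfig(n_p=3, n_np=3, model=default_model)
        a = simulate_cohort(config, seed=9)
        b = simulate_cohort(config, seed=9)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.pair.followup.thickness, rb.pair.followup.thickness)
            assert ra.lesions == rb.lesions and ra.artifacts == rb.artifacts

    def test_negative_counts_rejected(self, default_model):
        with pytest.raises(ParameterError):
            simulate_cohort(CohortConfig(n_p=-1, model=default_model), seed=0)


class TestTestRetest:
    def test_zero_noise_all_deltas_zero(self, quiet_model):
        pairs = simulate_testretest(quiet_model, 5, seed=0)
        assert all(p.delta_g == 0.0 for p in pairs)

    def test_loss_tail_matches_normal_cdf(self, default_model):
        from scipy.stats import norm
        gb, gf = sample_testretest_g(default_model, 10000, seed=3)
        frac = np.mean(gf - gb <= -5.0)
        expected = norm.cdf(-5.0 / default_model.g_retest_sd)
        assert frac == pytest.approx(expected, abs=4 * np.sqrt(expected / 10000))

    def test_baseline_spread_covers_requested_range(self, default_model):
        pairs = simulate_testretest(default_model, 300, seed=4, baseline_range=(60, 110))
        gbs = np.array([p.g_baseline for p in pairs])
        assert (np.max(gbs) - np.min(gbs)) >= 0.8 * 50.0
        assert np.min(gbs) > 55 and np.max(gbs) < 115

    def test_too_few_pairs_rejected(self, default_model):
        with pytest.raises(ParameterError):
            simulate_testretest(default_model, 1, seed=0)

    def test_retest_limits_slightly_below_5um(self, default_model):
        gb, gf = sample_testretest_g(default_model, 20000, seed=6)
        limit = 1.96 * np.std(gf - gb)
        assert 4.2 <= limit <= 5.0
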