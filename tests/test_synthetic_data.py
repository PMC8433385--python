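import numpy as np
import pytest

from acoustocalib.deformability import fit_slope
from acoustocalib.errors import ValidationError
from acoustocalib.micropipette import fit_young_modulus
from acoustocalib.stats import viability_test
from acoustocalib.synthetic_data import (
    DeformationGroundTruth,
    SyntheticFrameSpec,
    generate_aspiration_trace,
    generate_deformation_series,
    generate_viability_samples,
    render_frames,
)

from conftest import RAMP


class TestDeformationGenerator:
    def test_noiseless_linear_model_exact(self):
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.209, true_slope_sd=0.0,
            area_noise_sd=0.0, baseline_radius_sd_um=0.0, n_samples=3,
        )
        expected = 1 + 0.209 * RAMP
        for s in generate_deformation_series(gt):
            norm = s.areas_um2 / s.areas_um2[0]
            assert np.allclose(norm, expected, atol=1e-12)
            assert np.allclose(
                norm, [1.000, 1.0489, 1.0901, 1.1310, 1.1722, 1.2090], atol=1e-3
            )

    def test_zero_slope_all_ones(self):
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.0, area_noise_sd=0.0,
        )
        for s in generate_deformation_series(gt):
            assert np.allclose(s.areas_um2 / s.areas_um2[0], 1.0)

    def test_baseline_anchor_exact_despite_noise(self):
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.1, area_noise_sd=0.02, seed=3
        )
        for s in generate_deformation_series(gt):
            assert s.areas_um2[0] == pytest.approx(
                s.metadata["true_baseline_area_um2"], rel=1e-12
            )

    def test_seed_determinism(self):
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.1, true_slope_sd=0.02,
            area_noise_sd=0.01, seed=42,
        )
        a = generate_deformation_series(gt)
        b = generate_deformation_series(gt)
        for x, y in zip(a, b):
            assert np.array_equal(x.areas_um2, y.areas_um2)

    def test_monte_carlo_slope_recovery_against_stored_truth(self):
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.168, true_slope_sd=0.02,
            area_noise_sd=0.005, n_samples=200, seed=21,
        )
        series = generate_deformation_series(gt)
        fitted = np.array([fit_slope(s).slope for s in series])
        stored = np.array([s.metadata["true_slope"] for s in series])
        assert fitted.mean() == pytest.approx(0.168, abs=0.01)
        # per-sample fits track the stored generative slopes closely
        assert np.max(np.abs(fitted - stored)) < 0.02

    def test_burst_truncation(self):
        gt = DeformationGroundTruth(
            group_label="soft", true_slope_mean=0.728, burst_pressure_mpa=0.431,
        )
        for s in generate_deformation_series(gt):
            assert s.n_steps == 3
            assert s.truncated

    def test_invalid_pressures_rejected(self):
        with pytest.raises(ValidationError):
            DeformationGroundTruth(
                group_label="g", true_slope_mean=0.1,
                pressures_mpa=(0.0, 0.5, 0.3),
            )


class TestRenderFrames:
    def test_circle_rasterization_area(self):
        spec = SyntheticFrameSpec(blur_sigma_px=0.0, noise_sd=0.0)
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.0, area_noise_sd=0.0,
            baseline_radius_sd_um=0.0, n_samples=1,
        )
        s = generate_deformation_series(gt)[0]
        frames = render_frames(s, spec, seed=0)
        mask = frames[0] < (spec.background_level + spec.object_level) / 2
        assert mask.sum() == pytest.approx(np.pi * 50**2, rel=0.01)

    def test_bit_identical_under_same_seed(self):
        spec = SyntheticFrameSpec()
        gt = DeformationGroundTruth(group_label="g", true_slope_mean=0.2, seed=1)
        s = generate_deformation_series(gt)[0]
        assert np.array_equal(render_frames(s, spec, 9), render_frames(s, spec, 9))

    def test_object_exceeding_frame_rejected(self):
        spec = SyntheticFrameSpec(image_size=(64, 64))
        gt = DeformationGroundTruth(
            group_label="g", true_slope_mean=0.0, baseline_radius_mean_um=10.0,
            baseline_radius_sd_um=0.0, n_samples=1,
        )
        s = generate_deformation_series(gt)[0]  # 50 px radius in a 64 px frame
        with pytest.raises(ValidationError, match="exceeds frame"):
            render_frames(s, spec, seed=0)

    def test_contrast_guard(self):
        with pytest.raises(ValidationError, match="contrast"):
            SyntheticFrameSpec(background_level=100.0, object_level=105.0, noise_sd=4.0)


class TestAspirationGenerator:
    def test_hand_evaluated_length(self):
        trace = generate_aspiration_trace(
            true_E_pa=1603.0, pressure_steps_pa=[500.0, 1000.0, 1500.0]
        )
        assert trace.aspirated_lengths_um[1] == pytest.approx(1.200, abs=0.001)

    def test_zero_pressure_zero_length(self):
        trace = generate_aspiration_trace(
            true_E_pa=1000.0, pressure_steps_pa=[0.0, 1000.0, 2000.0]
        )
        assert trace.aspirated_lengths_um[0] == 0.0

    def test_noisy_round_trip_recovery(self):
        recovered = []
        for i in range(10):
            trace = generate_aspiration_trace(
                true_E_pa=2995.0,
                pressure_steps_pa=np.linspace(500, 5000, 10),
                length_noise_sd_um=0.05,
                seed=50 + i,
            )
            recovered.append(fit_young_modulus(trace).E_pa)
        assert np.mean(recovered) == pytest.approx(2995.0, rel=0.05)

    def test_non_positive_modulus_rejected(self):
        with pytest.raises(ValidationError):
            generate_aspiration_trace(true_E_pa=0.0)


class TestViabilityGenerator:
    def test_zero_sd_exact_ratio(self):
        before, after = generate_viability_samples(1.0, 1.5, 0.0, 5)
        assert np.mean(after) / np.mean(before) == pytest.approx(1.5, rel=1e-12)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValidationError):
            generate_viability_samples(1.0, 1.0, 0.1, 1)

    def test_power_against_large_effect(self):
        rejections = 0
        for i in range(200):
            before, after = generate_viability_samples(1.0, 1.5, 0.04, 20, seed=i)
            if viability_test(before, after).p_value < 0.01:
                rejections += 1
        assert rejections / 200 > 0.99
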