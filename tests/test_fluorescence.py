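"""ROI detection, maximum-intensity quantification, and condition ratios."""

import numpy as np
import pytest

from roamdwell import (
    condition_ratio,
    detect_spot_rois,
    roi_max_intensity,
    simulate_fluorescence_image,
    simulate_fluorescence_table,
)
from roamdwell.errors import DetectionError, ValidationError
from roamdwell.fluorescence import subtract_rolling_minimum
from roamdwell.types import NeuronROI


class TestSpotDetection:
    def test_single_noiseless_spot_found_at_center(self):
        image, truth = simulate_fluorescence_image(
            (64, 64), [(30.0, 20.0)], [100.0], noise_sd=0.0
        )
        (roi,) = detect_spot_rois(image, 1, min_separation_px=5)
        cx, cy = roi.center_xy_px
        assert abs(cx - 30) <= 1 and abs(cy - 20) <= 1

    def test_two_separated_spots_both_found(self):
        centers = [(15.0, 32.0), (55.0, 32.0)]
        image, _ = simulate_fluorescence_image(
            (64, 72), centers, [100.0, 80.0], noise_sd=0.0
        )
        rois = detect_spot_rois(image, 2, min_separation_px=10)
        found = sorted(r.center_xy_px[0] for r in rois)
        assert abs(found[0] - 15) <= 1 and abs(found[1] - 55) <= 1
        # descending peak order: brighter spot first
        assert rois[0].center_xy_px[0] == pytest.approx(15, abs=1)

    def test_flat_image_yields_detection_error(self):
        with pytest.raises(DetectionError):
            detect_spot_rois(np.full((32, 32), 7.0), 1, min_separation_px=3)


class TestRoiMaxIntensity:
    def test_constant_image_returns_the_constant(self):
        roi = NeuronROI("ASJ", (10, 10), 5)
        assert roi_max_intensity(np.full((32, 32), 7.0), roi) == 7.0

    def test_noiseless_gaussian_peak_value_recovered(self):
        image, _ = simulate_fluorescence_image(
            (64, 64), [(32.0, 32.0)], [100.0], noise_sd=0.0, baseline=10.0
        )
        roi = NeuronROI("ASJ", (32, 32), 5)
        assert roi_max_intensity(image, roi) == pytest.approx(110.0, rel=1e-6)

    def test_matches_pixel_enumeration_oracle(self, rng):
        image = rng.uniform(0, 100, size=(48, 48))
        roi = NeuronROI("ASJ", (20, 25), 6)
        # brute force over every pixel in the disc
        best = max(
            image[y, x]
            for y in range(48)
            for x in range(48)
            if (x - 20) ** 2 + (y - 25) ** 2 <= 36
        )
        assert roi_max_intensity(image, roi) == best

    def test_roi_outside_image_rejected(self):
        with pytest.raises(ValidationError):
            roi_max_intensity(np.zeros((16, 16)), NeuronROI("ASJ", (40, 4), 3))

    def test_offset_invariance_and_linearity(self, rng):
        image = rng.uniform(0, 50, size=(32, 32))
        roi = NeuronROI("ASI", (16, 16), 4)
        base = roi_max_intensity(image, roi)
        assert roi_max_intensity(image + 20.0, roi) - 20.0 == pytest.approx(base)
        assert roi_max_intensity(image * 3.0, roi) == pytest.approx(3.0 * base)

    def test_rolling_minimum_flattens_constant_background(self):
        image, _ = simulate_fluorescence_image(
            (64, 64), [(32.0, 32.0)], [100.0], noise_sd=0.0, baseline=25.0
        )
        flattened = subtract_rolling_minimum(image, window_px=31)
        roi = NeuronROI("ASJ", (32, 32), 5)
        assert roi_max_intensity(flattened, roi) == pytest.approx(100.0, rel=0.01)


class TestConditionRatio:
    @staticmethod
    def _table(num_vals, den_vals):
        import pandas as pd

        rows = []
        for i, v in enumerate(num_vals):
            rows.append(("n%d" % i, "wild type", "Bottom", "ASJ", v))
        for i, v in enumerate(den_vals):
            rows.append(("d%d" % i, "wild type", "Fed", "ASJ", v))
        return pd.DataFrame(
            rows,
            columns=["animal_id", "genotype", "condition", "neuron", "max_intensity_au"],
        )

    def test_eightfold_example(self):
        res = condition_ratio(
            self._table([8.0, 8.0], [1.0, 1.0]), "wild type", "ASJ", "Bottom", "Fed"
        )
        assert res.ratio == 8.0
        assert (res.n_num, res.n_den) == (2, 2)

    def test_identical_groups_ratio_one(self):
        res = condition_ratio(
            self._table([5.0, 7.0], [5.0, 7.0]), "wild type", "ASJ", "Bottom", "Fed"
        )
        assert res.ratio == 1.0

    def test_reciprocal_ratios_multiply_to_one(self):
        t = self._table([12.0, 30.0, 18.0], [3.0, 5.0])
        fwd = condition_ratio(t, "wild type", "ASJ", "Bottom", "Fed").ratio
        rev = condition_ratio(t, "wild type", "ASJ", "Fed", "Bottom").ratio
        assert fwd * rev == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            condition_ratio(
                self._table([8.0, 8.0], [1.0, 1.0]), "wild type", "ASJ", "Lid", "Fed"
            )

    def test_zero_denominator_mean_rejected(self):
        with pytest.raises(ValidationError):
            condition_ratio(
                self._table([8.0, 8.0], [0.0, 0.0]), "wild type", "ASJ", "Bottom", "Fed"
            )

    def test_synthetic_fold_change_recovered_in_most_replicates(self):
        """With lognormal sigma 0.2 and n = 20/group, the estimated ratio
        lands within 15% of the generating fold change >= 95% of the time."""
        fold = 4.0
        hits = 0
        reps = 500
        for seed in range(reps):
            table, _ = simulate_fluorescence_table(
                20, {"Fed": 1.0, "Bottom": fold}, lognormal_sigma=0.2, seed=seed
            )
            r = condition_ratio(table, "wild type", "ASJ", "Bottom", "Fed").ratio
            hits += abs(r - fold) / fold <= 0.15
        assert hits / reps >= 0.95


class TestEndToEndImageRecovery:
    def test_detection_plus_quantification_recovers_amplitudes(self):
        centers = [(18.0, 40.0), (52.0, 22.0)]
        amps = [120.0, 90.0]
        noise_sd = 2.0
        image, truth = simulate_fluorescence_image(
            (64, 72), centers, amps, noise_sd=noise_sd, baseline=10.0, seed=3
        )
        rois = detect_spot_rois(image, 2, min_separation_px=10)
        got = sorted(
            roi_max_intensity(image, r) - truth["baseline"] for r in rois
        )
        for measured, true_amp in zip(got, sorted(amps)):
            assert abs(measured - true_amp) <= 3 * noise_sd


class TestTiffRoundTrip:
    def test_write_then_read_preserves_intensities(self, tmp_path):
        from roamdwell.fluorescence import read_intensity_image, write_intensity_image

        image, _ = simulate_fluorescence_image(
            (32, 32), [(16.0, 16.0)], [500.0], noise_sd=0.0, baseline=20.0
        )
        path = tmp_path / "spot.tif"
        write_intensity_image(image, path)
        back = read_intensity_image(path)
        assert back.shape == image.shape
        np.testing.assert_allclose(back, np.rint(image), atol=0.5)
        roi = NeuronROI("ASJ", (16, 16), 5)
        assert roi_max_intensity(back, roi) == pytest.approx(520.0, abs=1.0)
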