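import math

import numpy as np
import pytest

from granulequant.droplets import (
    CalibrationCurve,
    DropletRecord,
    droplet_concentration,
    droplet_metric,
    droplet_stoichiometry,
    fit_calibration,
    normalize_metric,
    segment_droplets,
    size_distribution,
)
from granulequant.errors import InputError
from granulequant.io import AnalysisConfig, DropletParams, ImageStack
from granulequant.simulate import NoiseSpec, generate_droplet_image

NO_NOISE = NoiseSpec(0.0, 0.0, False)


def record(area_px=50, mean=200.0, diameter=1.0, channel="mCherry"):
    rec = DropletRecord(1, area_px, area_px * 0.0324, diameter)
    rec.mean_intensity[channel] = mean
    rec.mean_intensity_raw[channel] = mean + 50.0
    return rec


class TestSegmentDroplets:
    def test_blank_field_yields_no_droplets(self, config):
        stack = ImageStack(np.full((64, 64), 50.0), ("mCherry",), 0.18)
        labels, records = segment_droplets(stack, config)
        assert records == [] and labels.max() == 0

    def test_planted_disc_areas_recovered(self, config):
        stack, truth = generate_droplet_image(
            n_droplets=12, radius_um=("uniform", 1.0, 2.0),
            concentrations=(2.0, 1.0), noise=NO_NOISE, psf_sigma_px=0.0, seed=1,
        )
        _, records = segment_droplets(stack, config)
        assert len(records) == 12
        planted = sorted(math.pi * d.radius_px**2 for d in truth.droplets)
        measured = sorted(r.area_px for r in records)
        for est, true in zip(measured, planted):
            assert abs(est / true - 1) < 0.10

    def test_small_components_filtered(self):
        frame = np.full((64, 64), 50.0)
        frame[10:14, 10:14] = 250.0      # 16 px, kept
        frame[40, 40] = 250.0            # 1 px, dropped
        stack = ImageStack(frame, ("mCherry",), 0.18)
        _, records = segment_droplets(stack, DropletParams(min_droplet_area_px=9))
        assert len(records) == 1
        assert records[0].area_px == 16

    def test_equivalent_diameter_definition(self, config):
        stack, _ = generate_droplet_image(
            n_droplets=5, noise=NO_NOISE, psf_sigma_px=0.0, seed=2
        )
        _, records = segment_droplets(stack, config)
        for rec in records:
            assert rec.equivalent_diameter_um == pytest.approx(
                2.0 * math.sqrt(rec.area_um2 / math.pi)
            )

    def test_threshold_increase_never_grows_areas(self):
        stack, _ = generate_droplet_image(
            n_droplets=8, noise=NoiseSpec(0.0, 5.0, False), seed=3
        )
        lo, _ = segment_droplets(stack, DropletParams(threshold_method="fixed:100"))
        hi, _ = segment_droplets(stack, DropletParams(threshold_method="fixed:150"))
        assert np.all((hi > 0) <= (lo > 0))


class TestDropletMetric:
    def test_forced_arithmetic(self):
        assert droplet_metric([record(area_px=50, mean=200.0)], "mCherry") == 10000.0

    def test_empty_field_scores_zero(self):
        assert droplet_metric([], "mCherry") == 0.0

    def test_linear_in_intensity(self):
        recs = [record(mean=100.0), record(mean=300.0)]
        doubled = [record(mean=200.0), record(mean=600.0)]
        assert droplet_metric(doubled, "mCherry") == pytest.approx(
            2 * droplet_metric(recs, "mCherry")
        )

    def test_additive_over_disjoint_fields(self, config):
        s1, _ = generate_droplet_image(n_droplets=10, noise=NO_NOISE, seed=4)
        s2, _ = generate_droplet_image(n_droplets=15, noise=NO_NOISE, seed=5)
        _, r1 = segment_droplets(s1, config)
        _, r2 = segment_droplets(s2, config)
        assert droplet_metric(r1 + r2, "mCherry") == pytest.approx(
            droplet_metric(r1, "mCherry") + droplet_metric(r2, "mCherry")
        )


class TestNormalizeMetric:
    def test_reference_maps_to_unity(self):
        assert normalize_metric([5.0, 10.0], 5.0) == [1.0, 2.0]

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InputError):
            normalize_metric([1.0], 0.0)


class TestCalibration:
    def test_exact_on_collinear_points(self):
        curve = fit_calibration([(0, 5.0), (1, 15.0), (2, 25.0)])
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(5.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_prediction_reproduces_line_at_range_endpoints(self):
        curve = fit_calibration([(0, 5.0), (2, 25.0)])
        assert curve.predict(0.0) == pytest.approx(5.0)
        assert curve.predict(2.0) == pytest.approx(25.0)

    def test_noisy_slope_recovered_within_three_percent(self):
        rng = np.random.default_rng(7)
        pairs = [(c, 100.0 * c + 50.0 + rng.normal(0, 1.0)) for c in range(8)]
        curve = fit_calibration(pairs)
        assert abs(curve.slope / 100.0 - 1) < 0.03

    def test_single_concentration_rejected(self):
        with pytest.raises(InputError):
            fit_calibration([(2.0, 10.0), (2.0, 12.0)])

    def test_concentration_inversion(self):
        curve = CalibrationCurve(2.0, 10.0, 1.0, 5, (0.0, 20.0))
        c, extrapolated = droplet_concentration(30.0, curve)
        assert c == pytest.approx(10.0) and not extrapolated
        c0, _ = droplet_concentration(10.0, curve)
        assert c0 == pytest.approx(0.0)
        _, flag = droplet_concentration(100.0, curve)
        assert flag

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(InputError):
            droplet_concentration(5.0, CalibrationCurve(-1.0, 0.0, 1.0, 2, (0, 1)))


class TestDropletStoichiometry:
    CURVE = CalibrationCurve(100.0, 50.0, 1.0, 6, (0.0, 6.0))

    def test_noiseless_planted_ratio_exact(self, config):
        stack, _ = generate_droplet_image(
            n_droplets=20, ratio_ab=2.7, concentrations=(2.0, 1.0),
            noise=NO_NOISE, psf_sigma_px=0.0, seed=8,
        )
        _, records = segment_droplets(stack, config)
        summary = droplet_stoichiometry(records, self.CURVE, self.CURVE,
                                        "mCherry", "GFP")
        assert summary.mean_ratio == pytest.approx(2.7, abs=1e-9)
        assert summary.sd == pytest.approx(0.0, abs=1e-9)

    def test_single_droplet(self):
        rec = DropletRecord(1, 50, 1.0, 1.0)
        rec.mean_intensity_raw = {"mCherry": 250.0, "GFP": 150.0}
        s = droplet_stoichiometry([rec], self.CURVE, self.CURVE, "mCherry", "GFP")
        assert s.mean_ratio == pytest.approx(2.0) and s.sd == 0.0 and s.n == 1

    def test_nonpositive_denominator_excluded_and_counted(self):
        good = DropletRecord(1, 50, 1.0, 1.0)
        good.mean_intensity_raw = {"mCherry": 250.0, "GFP": 150.0}
        bad = DropletRecord(2, 50, 1.0, 1.0)
        bad.mean_intensity_raw = {"mCherry": 250.0, "GFP": 40.0}
        s = droplet_stoichiometry([good, bad], self.CURVE, self.CURVE,
                                  "mCherry", "GFP")
        assert s.n == 1 and s.n_excluded == 1


class TestSizeDistribution:
    def test_half_open_binning(self):
        recs = [record(diameter=d) for d in (1.0, 1.4, 2.1)]
        assert size_distribution(recs, 1.0) == {1: 2, 2: 1}

    def test_empty_records(self):
        assert size_distribution([], 0.5) == {}

    def test_counts_sum_to_droplet_count(self, config):
        stack, _ = generate_droplet_image(n_droplets=30, noise=NO_NOISE, seed=9)
        _, records = segment_droplets(stack, config)
        hist = size_distribution(records, 0.5)
        assert sum(hist.values()) == len(records)

    def test_lognormal_sizes_recovered(self, config):
        # planted lognormal radii: histogram mean within 10% of planted mean
        diameters, planted = [], []
        for seed in range(4):
            stack, truth = generate_droplet_image(
                n_droplets=50, radius_um=("lognormal", 1.5, 0.25),
                noise=NO_NOISE, shape=(640, 640), seed=10 + seed,
            )
            _, records = segment_droplets(stack, config)
            diameters += [r.equivalent_diameter_um for r in records]
            planted += [2 * d.radius_px * 0.18 for d in truth.droplets]
        assert np.mean(diameters) == pytest.approx(np.mean(planted), rel=0.10)

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(InputError):
            size_distribution([], 0.0)
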