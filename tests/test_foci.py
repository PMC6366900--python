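import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import linear_sum_assignment

from granulequant.errors import InputError
from granulequant.foci import (
    Focus,
    assign_foci_to_cells,
    detect_foci,
    detect_local_maxima,
    filter_foci,
    foci_per_cell,
    match_foci_channels,
    measure_focus,
)
from granulequant.io import FocusParams
from granulequant.segmentation import CellLabelMap
from granulequant.simulate import NoiseSpec, generate_cell_field


def brute_force_maxima(image, radius):
    """Exhaustive all-pairs implementation of the local-maxima contract."""
    h, w = image.shape
    out = []
    lo = image.min()
    for r in range(h):
        for c in range(w):
            v = image[r, c]
            if v <= lo:
                continue
            ok = True
            for nr in range(h):
                for nc in range(w):
                    if (nr, nc) == (r, c):
                        continue
                    if (nr - r) ** 2 + (nc - c) ** 2 <= radius**2:
                        if image[nr, nc] > v:
                            ok = False
                        elif image[nr, nc] == v and (nr, nc) < (r, c):
                            ok = False
            if ok:
                out.append((r, c))
    out.sort(key=lambda rc: (-image[rc], rc))
    return out


def gaussian_spot(shape, centre, amplitude, sigma, background=100.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return background + amplitude * np.exp(
        -((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2) / (2 * sigma**2)
    )


class TestDetectLocalMaxima:
    def test_constant_image_has_no_maxima(self):
        assert detect_local_maxima(np.full((20, 20), 5.0), 3) == []

    def test_single_spot_found_at_centre(self):
        img = gaussian_spot((40, 40), (17, 23), 200.0, 1.5)
        maxima = detect_local_maxima(img, 3)
        assert len(maxima) == 1
        assert math.hypot(maxima[0][0] - 17, maxima[0][1] - 23) <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 30, size=(40, 40)).astype(float)  # forces ties
        assert detect_local_maxima(img, 3) == brute_force_maxima(img, 3)

    def test_invalid_radius_rejected(self):
        with pytest.raises(InputError):
            detect_local_maxima(np.zeros((5, 5)), 0.5)


class TestMeasureFocus:
    def test_uniform_image(self):
        f = measure_focus(np.full((30, 30), 100.0), (15, 15), 2.5, 4, 7)
        assert f.peak_intensity == 100.0
        assert f.background == 100.0
        assert f.contrast == 0.0
        assert f.integrated_intensity == 0.0

    def test_flat_disc_arithmetic(self):
        # 13-pixel disc at 105 over background 100: contrast 5%, integral 65
        img = np.full((30, 30), 100.0)
        dr, dc = np.mgrid[-2:3, -2:3]
        disc = dr**2 + dc**2 < 2.2**2
        img[15 + dr[disc], 15 + dc[disc]] = 105.0
        f = measure_focus(img, (15, 15), 2.2, 4, 7)
        assert disc.sum() == 13
        assert f.contrast == pytest.approx(0.05)
        assert f.integrated_intensity == pytest.approx(65.0)

    def test_gaussian_integral_recovered(self):
        # planted amplitude A, sigma s: integral 2*pi*A*s^2 within 2%
        A, s = 400.0, 1.0
        img = gaussian_spot((40, 40), (20, 20), A, s)
        f = measure_focus(img, (20, 20), 3, 4, 7)
        assert f.integrated_intensity == pytest.approx(2 * math.pi * A * s**2, rel=0.02)

    def test_subpixel_centroid(self):
        img = gaussian_spot((40, 40), (20.4, 19.7), 300.0, 1.3)
        f = measure_focus(img, (20, 20), 3, 4, 7)
        assert abs(f.row - 20.4) < 0.15 and abs(f.col - 19.7) < 0.15

    def test_border_clipped_focus_flagged(self):
        f = measure_focus(np.full((30, 30), 100.0), (2, 15), 2.5, 4, 7)
        assert not f.valid


class TestFilterFoci:
    def _image_with_contrast(self, contrast):
        img = np.full((30, 30), 100.0)
        dr, dc = np.mgrid[-2:3, -2:3]
        disc = dr**2 + dc**2 < 2.5**2
        img[15 + dr[disc], 15 + dc[disc]] = 100.0 * (1.0 + contrast)
        return img

    def test_contrast_boundary_is_inclusive_at_five_percent(self):
        params = FocusParams(r_int_px=2.5, intensity_min=0.0)
        kept = filter_foci([(15, 15)], self._image_with_contrast(0.05), params)
        assert len(kept) == 1
        rejected = filter_foci([(15, 15)], self._image_with_contrast(0.049), params)
        assert rejected == []

    def test_sorted_by_descending_integrated_intensity(self):
        img = np.full((60, 30), 100.0)
        img[15, 15] = 200.0
        img[45, 15] = 300.0
        params = FocusParams(intensity_min=0.0)
        kept = filter_foci([(15, 15), (45, 15)], img, params)
        assert [f.row for f in kept] == [45.0, 15.0]

    @given(
        st.integers(0, 2**31 - 1),
        st.floats(0.0, 0.3),
        st.floats(100.0, 400.0),
    )
    def test_threshold_monotonicity(self, seed, contrast_min, intensity_min):
        # raising either threshold can only shrink the retained set
        rng = np.random.default_rng(seed)
        img = rng.uniform(90, 110, size=(40, 40))
        img[20, 20] = 300.0
        cands = detect_local_maxima(img, 3)
        base = FocusParams(intensity_min=intensity_min, contrast_min=contrast_min)
        tighter = FocusParams(
            intensity_min=intensity_min + 50.0, contrast_min=contrast_min + 0.05
        )
        assert len(filter_foci(cands, img, tighter)) <= len(
            filter_foci(cands, img, base)
        )


class TestMatchFociChannels:
    @staticmethod
    def make_focus(row, col, channel=0):
        return Focus(row, col, 200.0, 100.0, 500.0, 1.0, channel=channel)

    def test_empty_input(self):
        assert match_foci_channels([], [self.make_focus(1, 1)], 0.25, 0.065) == []

    def test_coincident_singletons(self):
        m = match_foci_channels(
            [self.make_focus(10, 10)], [self.make_focus(10, 10, 1)], 0.25, 0.065
        )
        assert len(m) == 1 and m[0].distance_um == 0.0

    def test_distance_cutoff_enforced(self):
        # 10 px at 0.065 um/px = 0.65 um > d_max
        m = match_foci_channels(
            [self.make_focus(10, 10)], [self.make_focus(10, 20, 1)], 0.25, 0.065
        )
        assert m == []

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_optimal_assignment_oracle(self, seed):
        # 20 jittered pairs + 5 decoys per channel, well separated
        rng = np.random.default_rng(seed)
        d_max_um, px = 0.25, 0.065
        grid = [(20.0 + 12 * i, 20.0 + 12 * j) for i in range(5) for j in range(5)]
        pts = [grid[k] for k in rng.permutation(25)]
        set_a = [self.make_focus(r, c) for r, c in pts[:20]]
        set_b = [
            self.make_focus(r + rng.normal(0, 0.5), c + rng.normal(0, 0.5), 1)
            for r, c in pts[:20]
        ]
        set_a += [self.make_focus(r, c) for r, c in pts[20:25]]
        set_b += [self.make_focus(r + 5.0, c + 5.0, 1) for r, c in pts[20:25]]
        matches = match_foci_channels(set_a, set_b, d_max_um, px)
        # oracle: optimal assignment on the thresholded distance matrix
        cost = np.full((len(set_a), len(set_b)), 1e6)
        for i, fa in enumerate(set_a):
            for j, fb in enumerate(set_b):
                d = math.hypot(fa.row - fb.row, fa.col - fb.col) * px
                if d <= d_max_um:
                    cost[i, j] = d
        rows, cols = linear_sum_assignment(cost)
        oracle = {(i, j) for i, j in zip(rows, cols) if cost[i, j] < 1e6}
        ours = {
            (set_a.index(m.focus_a), set_b.index(m.focus_b)) for m in matches
        }
        assert len(ours) == 20
        assert ours == oracle

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(3)
        set_a = [self.make_focus(*rng.uniform(10, 90, 2)) for _ in range(8)]
        set_b = [self.make_focus(*rng.uniform(10, 90, 2), 1) for _ in range(8)]
        ab = match_foci_channels(set_a, set_b, 2.0, 0.065)
        ba = match_foci_channels(set_b, set_a, 2.0, 0.065)
        assert {(m.focus_a.row, m.focus_b.row) for m in ab} == {
            (m.focus_b.row, m.focus_a.row) for m in ba
        }

    def test_one_to_one(self):
        set_a = [self.make_focus(10, 10), self.make_focus(10, 11)]
        set_b = [self.make_focus(10, 10.4, 1)]
        m = match_foci_channels(set_a, set_b, 1.0, 0.065)
        assert len(m) == 1


class TestCellAssignment:
    def test_labels_at_centroid(self):
        labels = np.zeros((20, 20), int)
        labels[5:10, 5:10] = 3
        lm = CellLabelMap(labels)
        foci = [Focus(7.2, 7.8, 1, 1, 1, 1), Focus(15.0, 15.0, 1, 1, 1, 1)]
        out = assign_foci_to_cells(foci, lm)
        assert out[0].cell_label == 3
        assert out[1].cell_label is None


class TestFociPerCell:
    def test_forced_arithmetic(self):
        assert foci_per_cell(12, 6) == 2.0
        assert foci_per_cell(0, 10) == 0.0

    def test_zero_cells_guarded(self):
        with pytest.raises(InputError):
            foci_per_cell(3, 0)


class TestDetectionOnPlantedFields:
    def test_planted_foci_recovered(self, config):
        stack, truth = generate_cell_field(
            n_cells=6, foci_per_cell=3, n_channels=1, coloc_fraction=0.0,
            seed=5, focus_amplitude=300.0,
        )
        found = detect_foci(stack.frame(0), config)
        planted = [(f.row, f.col) for f in truth.foci]
        hits = 0
        for r, c in planted:
            if any(math.hypot(f.row - r, f.col - c) <= 2 for f in found):
                hits += 1
        assert hits == len(planted)
        assert len(found) <= len(planted) + 1

    def test_focus_free_field_stays_empty(self, config):
        stack, _ = generate_cell_field(
            n_cells=6, foci_per_cell=0, n_channels=1,
            noise=NoiseSpec(200.0, 4.0, False), seed=6,
        )
        assert detect_foci(stack.frame(0), config) == []
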