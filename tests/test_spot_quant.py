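"""Quantification pipeline: segmentation, spot detection, corrected intensity."""

import numpy as np
import pytest
from skimage.measure import label

from centrodyn.spot_quant import (
    CellMeasurement,
    PositivityPolicy,
    QuantConfig,
    classify_positive,
    detect_spots,
    max_project,
    measure_cell,
    measure_whole_cell,
    quantify_image,
    segment_nucleus,
    sum_cytokinesis_pair,
)
from centrodyn.synthetic_imaging import (
    ImagingParams,
    make_cytokinesis_pair,
    make_ground_truth,
    render_cell,
)


@pytest.fixture(scope="module")
def noise_only_measurements():
    """Corrected intensities of 100 amplitude-zero cells (the empirical null)."""
    params = ImagingParams()
    rng = np.random.default_rng(2024)
    out = []
    for i in range(100):
        truth = make_ground_truth(params, "G2", 0.0, rng, f"null{i}")
        cell = render_cell(params, truth, rng)
        out.append(quantify_image(cell.image, cell_id=f"null{i}")[0])
    return out


class TestMaxProject:
    def test_single_plane_identity(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(max_project(img[None]), img)

    def test_max_with_zero_plane_recovers_original(self):
        img = np.arange(12.0).reshape(3, 4)
        stack = np.stack([img, np.minimum(img, 0)])
        np.testing.assert_array_equal(max_project(stack), img)

    def test_idempotent(self):
        img = np.random.default_rng(0).random((5, 5))
        once = max_project(img[None])
        np.testing.assert_array_equal(max_project(once[None]), once)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            max_project(np.empty((0, 4, 4)))


class TestSegmentNucleus:
    def test_recovers_disk_area(self, noise_free_params, rng):
        truth = make_ground_truth(noise_free_params, "G2", 0.0, rng)
        cell = render_cell(noise_free_params, truth, rng)
        masks = segment_nucleus(cell.image[0].astype(float))
        assert len(masks) == 1
        true_area = np.pi * cell.nucleus_radius**2
        assert masks[0].sum() == pytest.approx(true_area, rel=0.05)

    def test_blank_image_yields_no_nuclei(self):
        assert segment_nucleus(np.full((64, 64), 7.0)) == []

    def test_noise_only_image_yields_no_nuclei(self):
        noisy = np.random.default_rng(1).poisson(50, (96, 96)).astype(float)
        assert segment_nucleus(noisy) == []

    def test_two_separated_nuclei(self):
        img = np.full((96, 160), 20.0)
        yy, xx = np.mgrid[0:96, 0:160]
        img[(yy - 48) ** 2 + (xx - 40) ** 2 <= 15**2] = 400.0
        img[(yy - 48) ** 2 + (xx - 120) ** 2 <= 15**2] = 400.0
        masks = segment_nucleus(img)
        assert len(masks) == 2
        assert not (masks[0] & masks[1]).any()


class TestDetectSpots:
    def test_false_positive_rate_on_noise_only_cells(self, noise_only_measurements):
        n_with_spots = sum(m.spot_area > 0 for m in noise_only_measurements)
        assert n_with_spots / len(noise_only_measurements) < 0.05

    def test_separated_bright_spots_found_exactly(self, rng):
        params = ImagingParams(
            poisson_noise=False, read_sigma=0.0, n_foci_mitotic=4,
            min_focus_separation=20.0,
        )
        truth = make_ground_truth(params, "metaphase", 40000.0, rng)
        cell = render_cell(params, truth, rng)
        masks = segment_nucleus(cell.image[0].astype(float))
        spots = detect_spots(cell.image[1].astype(float), masks[0])
        assert label(spots).max() == 4

    def test_spot_mask_contained_in_nucleus(self, default_params, rng):
        truth = make_ground_truth(default_params, "metaphase", 30000.0, rng)
        cell = render_cell(default_params, truth, rng)
        masks = segment_nucleus(cell.image[0].astype(float))
        spots = detect_spots(cell.image[1].astype(float), masks[0])
        assert not (spots & ~masks[0]).any()

    def test_empty_nucleus_mask_rejected(self):
        with pytest.raises(ValueError):
            detect_spots(np.zeros((8, 8)), np.zeros((8, 8), bool))


class TestMeasureCell:
    def test_flat_field_null_is_exactly_zero(self):
        img = np.full((40, 40), 7.5)
        nucleus = np.zeros((40, 40), bool)
        nucleus[5:35, 5:35] = True
        spots = np.zeros_like(nucleus)
        spots[10:14, 10:14] = True
        m = measure_cell(img, nucleus, spots)
        assert m.total_spot_intensity == pytest.approx(16 * 7.5)
        assert m.background_median == pytest.approx(7.5)
        assert m.corrected_intensity == pytest.approx(0.0)

    def test_contained_spot_measured_exactly(self):
        img = np.full((40, 40), 10.0)
        nucleus = np.zeros((40, 40), bool)
        nucleus[2:38, 2:38] = True
        spots = np.zeros_like(nucleus)
        spots[15:20, 15:20] = True
        img[16:19, 16:19] += 123.0  # signal wholly inside the spot mask
        m = measure_cell(img, nucleus, spots)
        assert m.corrected_intensity == pytest.approx(9 * 123.0)

    def test_negative_corrected_intensity_retained(self):
        img = np.full((30, 30), 50.0)
        nucleus = np.zeros((30, 30), bool)
        nucleus[2:28, 2:28] = True
        spots = np.zeros_like(nucleus)
        spots[5:8, 5:8] = True
        img[5:8, 5:8] = 40.0  # spot dimmer than background
        m = measure_cell(img, nucleus, spots)
        assert m.corrected_intensity < 0

    def test_spot_outside_nucleus_rejected(self):
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        spots = np.zeros_like(nucleus)
        spots[0:3, 0:3] = True
        with pytest.raises(ValueError, match="contained"):
            measure_cell(np.ones((20, 20)), nucleus, spots)

    def test_spots_covering_nucleus_rejected(self):
        nucleus = np.zeros((20, 20), bool)
        nucleus[5:15, 5:15] = True
        with pytest.raises(ValueError, match="background undefined"):
            measure_cell(np.ones((20, 20)), nucleus, nucleus.copy())

    def test_identity_c_equals_t_minus_am_enforced(self):
        with pytest.raises(ValueError, match="T - A\\*m"):
            CellMeasurement("x", "G1", 100.0, 10, 5.0, 99.0)

    def test_linearity_against_ground_truth(self):
        """Corrected intensity tracks true signal with unit slope (+/-5%)
        across a 10x amplitude range."""
        params = ImagingParams()
        rng = np.random.default_rng(77)
        xs, ys = [], []
        for total in np.linspace(4000, 40000, 30):
            truth = make_ground_truth(params, "G2", float(total), rng)
            cell = render_cell(params, truth, rng)
            m = quantify_image(cell.image)[0]
            xs.append(truth.true_total)
            ys.append(m.corrected_intensity)
        slope, intercept = np.polyfit(xs, ys, 1)
        assert abs(slope - 1.0) < 0.05
        assert abs(intercept) < 0.05 * np.mean(xs)

    def test_background_shift_invariance(self, noise_free_params, rng):
        truth = make_ground_truth(noise_free_params, "G2", 20000.0, rng)
        cell = render_cell(noise_free_params, truth, rng)
        tmr = cell.image[1].astype(float)
        masks = segment_nucleus(cell.image[0].astype(float))
        spots = detect_spots(tmr, masks[0])
        c0 = measure_cell(tmr, masks[0], spots).corrected_intensity
        c1 = measure_cell(tmr + 57.0, masks[0], spots).corrected_intensity
        assert abs(c1 - c0) < 0.01 * truth.true_total


class TestMeasureWholeCell:
    def test_blank_channel_near_zero(self):
        img = np.full((64, 64), 30.0)
        mask = np.zeros((64, 64), bool)
        mask[20:40, 20:40] = True
        assert measure_whole_cell(img, mask) == pytest.approx(0.0)

    def test_uniform_offset_invariance(self, rng):
        img = rng.poisson(40, (64, 64)).astype(float)
        mask = np.zeros((64, 64), bool)
        mask[20:44, 20:44] = True
        assert measure_whole_cell(img + 500.0, mask) == pytest.approx(
            measure_whole_cell(img, mask)
        )

    def test_doubling_amplitudes_doubles_w(self, noise_free_params, rng):
        t1 = make_ground_truth(noise_free_params, "G2", 15000.0, rng)
        c1 = render_cell(noise_free_params, t1, rng)
        w1 = measure_whole_cell(c1.image[1].astype(float), c1.nucleus_mask)
        base = (
            noise_free_params.nucleoplasm_background
            - noise_free_params.outside_background
        ) * c1.nucleus_mask.sum()
        # subtract the nucleoplasmic pedestal to isolate the spot signal
        assert (w1 - base) == pytest.approx(t1.true_total, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_whole_cell(np.ones((8, 8)), np.zeros((8, 8), bool))


class TestCytokinesisPairSum:
    def _measurement(self, c, t, pair):
        return measure_cell(
            c.image[1].astype(float),
            c.nucleus_mask,
            detect_spots(c.image[1].astype(float), c.nucleus_mask),
            cell_id=t.cell_id,
            stage="cytokinesis",
            pair_id=pair,
        )

    def test_commutative_and_truth_oracle(self, default_params, rng):
        a, b = make_cytokinesis_pair(default_params, (30000.0, 24000.0), rng, "pp")
        ma = self._measurement(a, a.truth, "pp")
        mb = self._measurement(b, b.truth, "pp")
        s1 = sum_cytokinesis_pair(ma, mb)
        s2 = sum_cytokinesis_pair(mb, ma)
        assert s1.corrected_intensity == pytest.approx(s2.corrected_intensity)
        assert s1.total_spot_intensity == pytest.approx(s2.total_spot_intensity)
        assert s1.stage == "cytokinesis"
        assert s1.corrected_intensity == pytest.approx(
            ma.corrected_intensity + mb.corrected_intensity
        )
        # crowded mitotic figures (13 foci per daughter) quantify with a few
        # percent downward bias from overlapping PSF tails
        assert s1.corrected_intensity == pytest.approx(
            a.truth.true_total + b.truth.true_total, rel=0.1
        )

    def test_zero_partner_is_identity_on_intensities(self):
        m1 = CellMeasurement("a", "cytokinesis", 50.0, 5, 2.0, 40.0, pair_id="p")
        m0 = CellMeasurement("b", "cytokinesis", 0.0, 0, 0.0, 0.0, pair_id="p")
        s = sum_cytokinesis_pair(m1, m0)
        assert s.corrected_intensity == m1.corrected_intensity
        assert s.total_spot_intensity == m1.total_spot_intensity
        assert s.spot_area == m1.spot_area

    def test_mismatched_pair_rejected(self):
        m1 = CellMeasurement("a", "cytokinesis", 1.0, 1, 0.5, 0.5, pair_id="p1")
        m2 = CellMeasurement("b", "cytokinesis", 1.0, 1, 0.5, 0.5, pair_id="p2")
        with pytest.raises(ValueError, match="pair"):
            sum_cytokinesis_pair(m1, m2)


class TestClassifyPositive:
    def test_below_cutoff_negative_and_monotone(self):
        policy = PositivityPolicy(absolute_cutoff=100.0)
        lo = CellMeasurement("a", "G1", 50.0, 10, 0.0, 50.0)
        hi = CellMeasurement("b", "G1", 500.0, 10, 0.0, 500.0)
        assert not classify_positive(lo, policy).positive
        assert classify_positive(hi, policy).positive

    def test_calibrated_cutoff_controls_false_positives(self, noise_only_measurements):
        """k=3 calibration on the empirical null: <=1% false positives."""
        cal = tuple(m.corrected_intensity for m in noise_only_measurements[:50])
        policy = PositivityPolicy(k_sigma=3.0, calibration=cal)
        flags = [
            classify_positive(m, policy).positive
            for m in noise_only_measurements[50:]
        ]
        assert np.mean(flags) <= 0.01

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError, match="calibration"):
            PositivityPolicy().cutoff()

    def test_flat_field_null_unbiased(self, noise_only_measurements):
        """Mean corrected intensity over noise-only cells is 0 within 3 SE."""
        c = np.array([m.corrected_intensity for m in noise_only_measurements])
        se = c.std(ddof=1) / np.sqrt(c.size)
        assert abs(c.mean()) < max(3 * se, 1e-9)
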