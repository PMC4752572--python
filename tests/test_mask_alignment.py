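"""Slice-shift estimation, quadratic smoothing, spline translation, and
projection of the artery mask to fractional PET partial-volume coefficients."""

import numpy as np
import pytest

from autoidif import mask_alignment as ma
from autoidif import phantom as ph
from autoidif.artery_segmentation import ArteryMask
from autoidif.core_io import Volume3D


def truth_artery_mask(subject):
    truth = subject["truth"]
    mra = subject["mra"]
    return ArteryMask(Volume3D(truth.mra_masks[truth.selected_artery].astype(float),
                               mra.spacing, mra.origin))


@pytest.fixture(scope="module")
def constant_shift_subject():
    cfg = ph.PhantomConfig(motion_x=(2.0, 0.0, 0.0), motion_y=(-1.0, 0.0, 0.0),
                           pet_noise_scale=0.0, mra_noise_sigma=0.0,
                           mra_bias_amplitude=0.0, catheter_activity=0.0)
    mra, series, blood, truth = ph.generate_subject(cfg, 21)
    return {"mra": mra, "series": series, "truth": truth, "config": cfg}


class TestEstimateSliceShifts:
    def test_zero_motion_gives_subvoxel_shifts(self, clean_static_subject):
        mask = truth_artery_mask(clean_static_subject)
        pet_ref = clean_static_subject["series"].max_over_time()
        shifts = ma.estimate_slice_shifts(mask, pet_ref)
        mags = np.hypot(shifts.dx[shifts.valid], shifts.dy[shifts.valid])
        assert np.all(mags < max(pet_ref.spacing[:2]))

    def test_constant_shift_recovered(self, constant_shift_subject):
        mask = truth_artery_mask(constant_shift_subject)
        pet_ref = constant_shift_subject["series"].max_over_time()
        shifts = ma.estimate_slice_shifts(mask, pet_ref)
        assert abs(np.median(shifts.dx[shifts.valid]) - 2.0) < 0.7
        assert abs(np.median(shifts.dy[shifts.valid]) - (-1.0)) < 0.7

    def test_zero_pet_slice_marked_invalid(self):
        mvals = np.zeros((20, 20, 6))
        mvals[8:12, 8:12, :] = 1.0
        mask = ArteryMask(Volume3D(mvals, (1, 1, 1), (-10, -10, -3)))
        pet = np.zeros((20, 20, 6))
        pet[9, 9, :] = 5.0
        pet[:, :, 2] = 0.0  # one dead slice
        pet_ref = Volume3D(pet, (1, 1, 1), (-10, -10, -3))
        shifts = ma.estimate_slice_shifts(mask, pet_ref, smooth_sigma_mm=0.0)
        assert not shifts.valid[2]
        assert shifts.valid.sum() == 5


class TestFitShiftPolynomial:
    def _series(self, z, dx, dy, valid=None):
        if valid is None:
            valid = np.ones(len(z), dtype=bool)
        return ma.SliceShiftSeries(np.arange(len(z)), np.asarray(z, float),
                                   np.asarray(dx, float), np.asarray(dy, float),
                                   np.asarray(valid))

    def test_exact_quadratic_recovered(self):
        z = np.linspace(-20, 20, 30)
        dx = 0.01 * z**2 - 0.2 * z + 1.0
        dy = -0.005 * z**2 + 0.1 * z - 0.5
        poly = ma.fit_shift_polynomial(self._series(z, dx, dy), edge_trim_mm=0.0)
        np.testing.assert_allclose(poly.coeff_x, [0.01, -0.2, 1.0], atol=1e-9)
        np.testing.assert_allclose(poly.coeff_y, [-0.005, 0.1, -0.5], atol=1e-9)

    def test_constant_shift_collapses_to_constant(self):
        z = np.linspace(-15, 15, 20)
        poly = ma.fit_shift_polynomial(self._series(z, np.full(20, 2.0),
                                                    np.full(20, -1.0)),
                                       edge_trim_mm=0.0)
        np.testing.assert_allclose(poly.coeff_x[:2], 0.0, atol=1e-10)
        assert poly.coeff_x[2] == pytest.approx(2.0)
        assert poly.coeff_y[2] == pytest.approx(-1.0)

    def test_noisy_quadratic_rmse_below_03mm(self, rng):
        z = np.linspace(-14, 14, 40)
        true_dx = 0.008 * z**2 + 0.05 * z + 1.5
        dx = true_dx + rng.normal(scale=0.5, size=40)
        dy = np.zeros(40) + rng.normal(scale=0.5, size=40)
        poly = ma.fit_shift_polynomial(self._series(z, dx, dy), edge_trim_mm=0.0)
        fit_dx, _ = poly(z)
        assert np.sqrt(np.mean((fit_dx - true_dx) ** 2)) < 0.3

    def test_fallback_to_mean_below_three_slices(self, caplog):
        series = self._series([0.0, 1.0], [2.0, 2.2], [0.5, 0.7])
        poly = ma.fit_shift_polynomial(series)
        assert poly.degree == 0
        assert poly(5.0)[0] == pytest.approx(2.1)


class TestApplyShift:
    def _mask(self):
        vals = np.zeros((20, 20, 8))
        vals[8:12, 9:13, :] = 1.0
        return ArteryMask(Volume3D(vals, (1, 1, 1), (-10, -10, -4)))

    def test_zero_polynomial_is_identity(self):
        mask = self._mask()
        out = ma.apply_shift(mask, ma.ShiftPolynomial.zero())
        np.testing.assert_array_equal(out.values, mask.mask.values)

    def test_integer_voxel_shift_is_exact(self):
        mask = self._mask()
        poly = ma.ShiftPolynomial(np.array([2.0]), np.array([-1.0]), degree=0)
        out = ma.apply_shift(mask, poly)
        expected = np.roll(mask.mask.values, (2, -1), axis=(0, 1))
        np.testing.assert_allclose(out.values, expected, atol=1e-9)

    def test_half_voxel_round_trip_nearly_inverse(self):
        mask = self._mask()
        fwd = ma.ShiftPolynomial(np.array([0.5]), np.array([0.0]), degree=0)
        bwd = ma.ShiftPolynomial(np.array([-0.5]), np.array([0.0]), degree=0)
        shifted = ma.apply_shift(mask, fwd)
        # wrap the fractional intermediate so it can be shifted back
        tmp = ArteryMask(Volume3D(np.ones(shifted.shape), shifted.spacing,
                                  shifted.origin))
        tmp.mask = shifted
        back = ma.apply_shift(tmp, bwd)
        mad = np.abs(back.values - mask.mask.values).mean()
        assert mad < 0.02

    def test_values_stay_in_unit_interval(self):
        mask = self._mask()
        poly = ma.ShiftPolynomial(np.array([0.37]), np.array([-0.61]), degree=0)
        out = ma.apply_shift(mask, poly)
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0


class TestProjectToPetGrid:
    def test_mask_filling_one_pet_voxel_exactly(self):
        # MRA 0.5 mm grid aligned so that 2x2x2 MRA voxels tile one 1 mm PET voxel
        mra = Volume3D(np.zeros((8, 8, 8)), (0.5, 0.5, 0.5), (0.25, 0.25, 0.25))
        pet = Volume3D(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5))
        mra.values[2:4, 2:4, 2:4] = 1.0  # exactly PET voxel (1,1,1)
        pv = ma.project_to_pet_grid(mra, pet)
        assert pv.values[1, 1, 1] == pytest.approx(1.0)
        assert pv.values.sum() == pytest.approx(1.0)

    def test_half_filled_pet_voxel(self):
        mra = Volume3D(np.zeros((8, 8, 8)), (0.5, 0.5, 0.5), (0.25, 0.25, 0.25))
        pet = Volume3D(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0), (0.5, 0.5, 0.5))
        mra.values[2:3, 2:4, 2:4] = 1.0  # half of PET voxel (1,1,1) in x
        pv = ma.project_to_pet_grid(mra, pet)
        assert pv.values[1, 1, 1] == pytest.approx(0.5, abs=0.02)

    def test_mass_conservation_on_phantom(self, clean_static_subject):
        mask = truth_artery_mask(clean_static_subject)
        pet_grid = clean_static_subject["series"].frame(0)
        pv = ma.project_to_pet_grid(mask.mask, pet_grid)
        mask_volume = mask.mask.values.sum() * mask.mask.voxel_volume
        pv_volume = pv.values.sum() * pet_grid.voxel_volume
        assert pv_volume == pytest.approx(mask_volume, rel=0.02)

    def test_disjoint_grids_rejected(self):
        mra = Volume3D(np.ones((4, 4, 4)), (0.5, 0.5, 0.5), (0, 0, 0))
        pet = Volume3D(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0), (100, 100, 100))
        with pytest.raises(ValueError, match="overlap"):
            ma.project_to_pet_grid(mra, pet)


class TestAlignEndToEnd:
    def test_idempotence_on_aligned_data(self, clean_static_subject):
        # zero true motion: running the alignment barely changes the PV map
        mask = truth_artery_mask(clean_static_subject)
        series = clean_static_subject["series"]
        pet_ref = series.max_over_time()
        pv_aligned, _, _ = ma.align_mask(mask, pet_ref, series.frame(0))
        pv_raw, _, _ = ma.align_mask(mask, pet_ref, series.frame(0), align=False)
        rel_change = (np.abs(pv_aligned.values - pv_raw.values).sum()
                      / pv_raw.values.sum())
        assert rel_change < 0.05
        assert pv_aligned.values.sum() == pytest.approx(pv_raw.values.sum(), rel=0.01)

    def test_constant_motion_alignment_improves_overlap(self, constant_shift_subject):
        subject = constant_shift_subject
        mask = truth_artery_mask(subject)
        series = subject["series"]
        pet_ref = series.max_over_time()
        truth = subject["truth"]
        target = truth.pet_artery_frac[truth.selected_artery]
        pv_aligned, _, _ = ma.align_mask(mask, pet_ref, series.frame(0))
        pv_raw, _, _ = ma.align_mask(mask, pet_ref, series.frame(0), align=False)
        assert ma.soft_dice(pv_aligned.values, target) > ma.soft_dice(pv_raw.values, target)
        assert ma.soft_dice(pv_aligned.values, target) > 0.9
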