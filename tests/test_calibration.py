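import dataclasses
import math

import numpy as np
import pytest

from spectqc.calibration import (collimator_geometry, compute_cf, compute_icf,
                                 compute_icf_expanded, crystal_interaction_ratio,
                                 estimate_total_activity,
                                 phantom_activity_from_samples,
                                 place_cylinder_voi)
from spectqc.images import VoxelImage
from spectqc.phantoms import GridSpec, PhantomSpec, voxelize
from spectqc.simulate import ReconstructionModel, simulate_phantom


def uniform_counts_image(counts_per_mL=1000.0, spacing=4.0, duration=100.0,
                         shape=(40, 40, 40), rr_scale=1.0):
    vox_mL = spacing**3 / 1000.0
    vals = np.full(shape, counts_per_mL * vox_mL)
    return VoxelImage(values=vals, spacing=(spacing,) * 3, units="counts",
                      duration=duration, rr_scale=rr_scale)


class TestCylinderVOI:
    def test_mask_volume_matches_geometry(self, cyl_spec):
        model = ReconstructionModel(psf_fwhm=0.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        img = simulate_phantom(cyl_spec, model, spacing=2.0)
        voi = place_cylinder_voi(img, cyl_spec)
        vol_L = voi.sum() * img.voxel_volume_mL / 1000.0
        assert vol_L == pytest.approx(math.pi * 6.0**2 * 15.0 / 1000.0, rel=0.02)

    def test_centroid_tracking_under_translation(self, cyl_spec):
        """A phantom off-centre in the grid yields the same VOI volume."""
        model = ReconstructionModel(psf_fwhm=0.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        grid0 = GridSpec.for_phantom(cyl_spec, 4.0)
        grid1 = GridSpec(shape=grid0.shape, spacing=grid0.spacing,
                         origin=(8.0, -4.0, 12.0))
        img0 = simulate_phantom(cyl_spec, model, spacing=4.0)
        from spectqc.simulate import simulate_reconstruction
        img1 = simulate_reconstruction(voxelize(cyl_spec, grid1), model, grid1)
        v0 = place_cylinder_voi(img0, cyl_spec)
        v1 = place_cylinder_voi(img1, cyl_spec)
        assert v0.sum() == v1.sum()

    def test_voi_larger_than_phantom_rejected(self, cyl_spec):
        img = uniform_counts_image()
        with pytest.raises(ValueError, match="inside"):
            place_cylinder_voi(img, cyl_spec, voi_diameter=200.0)


class TestICF:
    def test_closed_form(self):
        """1000 counts/mL over 100 s at 0.5 MBq/mL gives 20 cps/MBq."""
        img = uniform_counts_image(1000.0, duration=100.0)
        voi = np.zeros(img.values.shape, dtype=bool)
        voi[10:30, 10:30, 10:30] = True
        res = compute_icf(img, voi, ref_concentration=0.5)
        assert res.icf == pytest.approx(20.0, rel=1e-12)
        assert res.counts_concentration == pytest.approx(1000.0)

    def test_linearity_in_counts(self):
        img = uniform_counts_image(1000.0)
        voi = np.ones(img.values.shape, dtype=bool)
        base = compute_icf(img, voi, 0.5).icf
        scaled = compute_icf(img.with_values(3.0 * img.values), voi, 0.5).icf
        assert scaled == pytest.approx(3.0 * base, rel=1e-12)

    def test_parameter_recovery_at_7mcts(self, cyl_spec, cyl_poisson_4mm):
        voi = place_cylinder_voi(cyl_poisson_4mm, cyl_spec)
        res = compute_icf(cyl_poisson_4mm, voi,
                          cyl_spec.cylinder_concentration)
        assert res.icf == pytest.approx(20.0, rel=0.005)

    def test_declared_rr_scale_divides_icf_exactly(self, cyl_spec,
                                                   cyl_poisson_4mm):
        voi = place_cylinder_voi(cyl_poisson_4mm, cyl_spec)
        ref = cyl_spec.cylinder_concentration
        base = compute_icf(cyl_poisson_4mm, voi, ref).icf
        declared = dataclasses.replace(cyl_poisson_4mm, rr_scale=4.0)
        assert compute_icf(declared, voi, ref).icf == base / 4.0

    def test_icf_stable_under_voi_size_change(self, cyl_spec):
        """Noiseless uniform region: growing the VOI by 20 mm moves the
        ICF by less than 0.2%."""
        model = ReconstructionModel(psf_fwhm=8.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        ref = cyl_spec.cylinder_concentration
        a = compute_icf(img, place_cylinder_voi(img, cyl_spec, 120, 150), ref)
        b = compute_icf(img, place_cylinder_voi(img, cyl_spec, 140, 170), ref)
        assert b.icf == pytest.approx(a.icf, rel=0.002)


class TestExpandedICF:
    def test_agrees_with_central_voi_when_blur_contained(self, cyl_spec):
        model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        grid = img.grid
        deposited = voxelize(cyl_spec, grid).sum() * grid.voxel_volume_mL
        central = compute_icf(img, place_cylinder_voi(img, cyl_spec),
                              cyl_spec.cylinder_concentration)
        expanded = compute_icf_expanded(img, cyl_spec,
                                        total_activity=deposited)
        assert expanded.icf == pytest.approx(central.icf, rel=0.01)

    def test_background_inflates_expanded_but_not_central(self, cyl_spec):
        """Stray counts outside the phantom (scatter / septal
        penetration tails) inflate the expanded estimate while the
        central VOI is untouched."""
        model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        grid = img.grid
        truth = voxelize(cyl_spec, grid)
        deposited = truth.sum() * grid.voxel_volume_mL
        stray = np.where(truth == 0, 0.05 * img.values.max(), 0.0)
        bg = img.with_values(img.values + stray)
        ref = cyl_spec.cylinder_concentration
        voi = place_cylinder_voi(img, cyl_spec)
        assert compute_icf(bg, voi, ref).icf == pytest.approx(
            compute_icf(img, voi, ref).icf, rel=1e-12)
        exp0 = compute_icf_expanded(img, cyl_spec, total_activity=deposited).icf
        exp1 = compute_icf_expanded(bg, cyl_spec, total_activity=deposited).icf
        assert exp1 > 1.01 * exp0


class TestCF:
    def test_quant_bias_recovered(self, cyl_spec):
        model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                    count_target=7e6, noise="poisson", seed=3,
                                    units_out="Bq/mL", quant_bias=1.1)
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        voi = place_cylinder_voi(img, cyl_spec)
        res = compute_cf(img, voi, cyl_spec.cylinder_concentration)
        assert res.cf == pytest.approx(1.100, abs=0.005)

    def test_unbiased_noiseless_cf_is_one(self, cyl_spec):
        model = ReconstructionModel(psf_fwhm=0.0, icf_true=20.0,
                                    count_target=7e6, noise="none",
                                    units_out="Bq/mL")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        voi = place_cylinder_voi(img, cyl_spec)
        assert compute_cf(img, voi, cyl_spec.cylinder_concentration).cf \
            == pytest.approx(1.0, rel=1e-9)

    def test_linearity(self, cyl_spec):
        model = ReconstructionModel(psf_fwhm=0.0, icf_true=20.0,
                                    count_target=7e6, noise="none",
                                    units_out="Bq/mL")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        voi = place_cylinder_voi(img, cyl_spec)
        ref = cyl_spec.cylinder_concentration
        base = compute_cf(img, voi, ref).cf
        scaled = compute_cf(img.with_values(2.5 * img.values), voi, ref).cf
        assert scaled == pytest.approx(2.5 * base, rel=1e-12)


class TestPhantomActivity:
    def test_nema_printed_value(self):
        # 3.75 MBq/mL stock concentration x 161 mL total sphere volume
        assert phantom_activity_from_samples([3.75, 3.75, 3.75], 161.0) \
            == pytest.approx(603.75)

    def test_single_sample(self):
        assert phantom_activity_from_samples([2.0], 10.0) == 20.0
        assert phantom_activity_from_samples([1.0, 2.0, 3.0], 10.0) == 20.0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            phantom_activity_from_samples([-1.0], 10.0)


class TestTotalActivity:
    def test_expanded_recovers_truth_noiseless(self, cyl_spec, true_icf):
        model = ReconstructionModel(psf_fwhm=12.0, icf_true=20.0,
                                    count_target=7e6, noise="none")
        img = simulate_phantom(cyl_spec, model, spacing=4.0)
        truth = voxelize(cyl_spec, img.grid).sum() * img.voxel_volume_mL
        est = estimate_total_activity(img, true_icf(img), cyl_spec,
                                      method="expanded")
        assert est == pytest.approx(truth, rel=0.01)

    def test_simple_voi_underestimates_blurred_spheres(self, nema_spec,
                                                       nema_noiseless_4mm,
                                                       true_icf):
        img = nema_noiseless_4mm
        truth = voxelize(nema_spec, img.grid).sum() * img.voxel_volume_mL
        simple = estimate_total_activity(img, true_icf(img), nema_spec, "voi")
        expanded = estimate_total_activity(img, true_icf(img), nema_spec,
                                           "expanded")
        assert simple < truth
        assert expanded >= simple

    def test_zero_image_gives_zero(self, cyl_spec, true_icf):
        img = VoxelImage(values=np.zeros((30, 30, 30)), spacing=(10,) * 3,
                         units="counts", duration=100.0)
        assert estimate_total_activity(img, true_icf(img), cyl_spec) == 0.0


class TestSystemCharacterization:
    @pytest.mark.parametrize("params, g_lo, g_hi, res_expected", [
        # medium-energy general-purpose collimator, long holes
        (dict(hole_diameter=3.0, septal_thickness=1.05, hole_length=58.0),
         0.0104, 0.0115, 8.5),
        # medium-energy low-penetration collimator, shorter holes
        (dict(hole_diameter=2.94, septal_thickness=1.14, hole_length=40.64),
         0.0195, 0.0215, 10.7),
    ])
    def test_geometric_sensitivity_and_resolution(self, params, g_lo, g_hi,
                                                  res_expected):
        g, _ = collimator_geometry(**params)
        assert g_lo <= g <= g_hi
        # resolution at 10 cm matches the vendor figure with a small
        # collimator-to-detector gap
        _, r = collimator_geometry(**params, detector_gap=3.0)
        assert r == pytest.approx(res_expected, abs=0.25)

    def test_sensitivity_vanishes_with_thick_septa(self):
        g, _ = collimator_geometry(3.0, 1e6, 58.0)
        assert g < 1e-9

    def test_nonphysical_hole_length_rejected(self):
        with pytest.raises(ValueError, match="effective hole length"):
            collimator_geometry(3.0, 1.0, 1.0, mu_lead=1.13)

    def test_crystal_interaction_ratio(self):
        # 3/8" -> 5/8" NaI at 208 keV: ~27% more interactions
        assert crystal_interaction_ratio(9.525, 15.875, 0.111) \
            == pytest.approx(1.27, abs=0.01)
        assert crystal_interaction_ratio(10.0, 10.0, 0.111) == 1.0
        assert crystal_interaction_ratio(9.525, 15.875, 1e3) \
            == pytest.approx(1.0)
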