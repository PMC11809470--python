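"""Forward-simulator properties: exact chord OPD, index-matching nulls,
linearity in RI, determinism, and the GFP stack construction."""

import numpy as np
import pytest

from qpidense import (
    OpticalConstants,
    SyntheticCell,
    SyntheticChamberTruth,
    generate_gfp_stack,
    generate_pressure_series,
    render_chamber_scene,
    render_plate_scene,
    sample_plate_population,
)


def one_cell(ri, b=1.97, a=2.5, center=(6.0, 6.0), orientation=0.0):
    return SyntheticCell(center_xy=center, semi_axes=(a, b), ri=ri, orientation=orientation)


class TestPlateScene:
    def test_index_matched_cell_is_invisible(self, constants):
        scene = render_plate_scene([one_cell(constants.n_media)], constants, 0.05, (240, 240))
        assert np.all(scene.image == 0)

    def test_peak_opd_matches_closed_form_chord(self, constants):
        # RI 1.384 against medium 1.336 over a 3.94 μm minor axis: 0.048 * 3940 nm
        scene = render_plate_scene([one_cell(1.384, b=1.97)], constants, 0.02, (600, 600))
        assert scene.image.max() == pytest.approx(189.12, abs=0.2)
        assert scene.truth.peak_opd_nm.iloc[0] == pytest.approx(189.12, abs=1e-9)

    def test_background_is_exactly_zero_noiseless(self, constants):
        scene = render_plate_scene([one_cell(1.384)], constants, 0.05, (240, 240))
        border = np.concatenate([scene.image[0], scene.image[-1]])
        assert np.all(border == 0)

    def test_same_seed_same_image(self, constants):
        kw = dict(pixel_size_um=0.05, image_shape=(240, 240), noise_sd=5.0, seed=3)
        a = render_plate_scene([one_cell(1.384)], constants, **kw)
        b = render_plate_scene([one_cell(1.384)], constants, **kw)
        np.testing.assert_array_equal(a.image, b.image)

    def test_noise_requires_seed(self, constants):
        with pytest.raises(ValueError, match="seed"):
            render_plate_scene([one_cell(1.384)], constants, 0.05, (240, 240), noise_sd=5.0)

    def test_opd_affine_in_ri(self, constants):
        """For fixed geometry the image is (ri − n_media) times the chord map."""
        n = constants.n_media
        im1 = render_plate_scene([one_cell(n + 0.02)], constants, 0.05, (240, 240)).image
        im2 = render_plate_scene([one_cell(n + 0.06)], constants, 0.05, (240, 240)).image
        np.testing.assert_allclose(im2, 3.0 * im1, atol=1e-3)

    def test_overlapping_cells_rejected_or_summed(self, constants):
        cells = [one_cell(1.384, center=(6.0, 6.0)), one_cell(1.384, center=(7.0, 6.0))]
        with pytest.raises(ValueError, match="overlap"):
            render_plate_scene(cells, constants, 0.05, (240, 240))
        summed = render_plate_scene(cells, constants, 0.05, (240, 240), on_overlap="sum")
        singles = [render_plate_scene([c], constants, 0.05, (240, 240)).image for c in cells]
        np.testing.assert_allclose(summed.image, singles[0] + singles[1], atol=1e-4)

    def test_cell_outside_field_rejected(self, constants):
        with pytest.raises(ValueError, match="field"):
            render_plate_scene([one_cell(1.384, center=(1.0, 6.0))], constants, 0.05, (240, 240))

    def test_zero_size_image_rejected(self, constants):
        with pytest.raises(ValueError):
            render_plate_scene([one_cell(1.384)], constants, 0.05, (0, 240))

    def test_population_sampler_is_reproducible_and_in_field(self, constants):
        kw = dict(n_cells=20, ri_mean=1.384, ri_sd=0.004, height_mean_um=3.94,
                  height_sd_um=0.5, field_um=(60.0, 60.0), seed=11, constants=constants)
        pop1 = sample_plate_population(**kw)
        pop2 = sample_plate_population(**kw)
        assert [c.center_xy for c in pop1] == [c.center_xy for c in pop2]
        render_plate_scene(pop1, constants, 0.1, (600, 600))  # no overlap, all in field


class TestChamberScene:
    def test_index_matched_interior_is_zero(self, constants):
        truth = SyntheticChamberTruth.from_anchor(
            pi_c0_true=(constants.n_pdms - constants.n_water) / 0.0335,
            ri_at_zero=constants.n_pdms, n_water=constants.n_water,
            chamber_height0=9.2, height_slope=0.0,
        )
        scene = render_chamber_scene(truth, 0.0, constants, 0.1)
        assert np.all(scene.image == 0)

    def test_interior_opd_closed_form(self, constants):
        # φ=1, RI 1.386, n_PDMS 1.405, height 10 μm → (1.386 − 1.405)·10 μm = −190 nm
        truth = SyntheticChamberTruth.from_anchor(
            pi_c0_true=(1.386 - constants.n_water) / 0.0335, ri_at_zero=1.386,
            n_water=constants.n_water, chamber_height0=10.0, height_slope=0.0,
        )
        scene = render_chamber_scene(truth, 0.0, constants, 0.1)
        interior = scene.image[scene.interior_mask]
        assert interior.mean() == pytest.approx(-190.0, abs=1e-3)
        assert np.all(scene.image[~scene.interior_mask] == 0)

    def test_empty_chamber_reads_medium_opd(self, constants, chamber_truth):
        # φ=0: the medium-filled chamber is the height-calibration signal
        scene = render_chamber_scene(chamber_truth, 0.0, constants, 0.1, packing_fraction=0.0)
        expected = (constants.n_media - constants.n_pdms) * 9.2 * 1000.0
        assert scene.image[scene.interior_mask].mean() == pytest.approx(expected, rel=1e-6)

    def test_negative_pressure_rejected(self, constants, chamber_truth):
        with pytest.raises(ValueError, match="pressure"):
            render_chamber_scene(chamber_truth, -0.1, constants, 0.1)

    def test_inconsistent_truth_rejected(self, constants):
        truth = SyntheticChamberTruth(
            pi_c0_true=2.0, ri_slope=0.0335, ri_at_zero=1.384,
            chamber_height0=9.2, height_slope=0.5,
        )
        with pytest.raises(ValueError, match="inconsistent"):
            render_chamber_scene(truth, 0.1, constants, 0.1)

    def test_pressure_series_records_and_determinism(self, constants, chamber_truth):
        import dataclasses

        truth = dataclasses.replace(chamber_truth, noise_sd=5.0, seed=21)
        gips = [0.0, 0.2, 0.4]
        scenes1, table1 = generate_pressure_series(truth, gips, constants, 0.1,
                                                   packing_fraction_gip0=0.8)
        scenes2, table2 = generate_pressure_series(truth, gips, constants, 0.1,
                                                   packing_fraction_gip0=0.8)
        assert list(table1.gip_mpa) == gips
        assert table1.underestimated.tolist() == [True, False, False]
        np.testing.assert_allclose(table1.ri_true, [truth.ri_at(g) for g in gips])
        for s1, s2 in zip(scenes1, scenes2):
            np.testing.assert_array_equal(s1.image, s2.image)

    def test_pressure_series_empty_rejected(self, constants, chamber_truth):
        with pytest.raises(ValueError, match="non-empty"):
            generate_pressure_series(chamber_truth, [], constants, 0.1)


class TestGfpStack:
    def cells(self):
        return [SyntheticCell(center_xy=(4.0, 4.0), semi_axes=(2.0, 1.5), ri=1.384),
                SyntheticCell(center_xy=(10.0, 9.0), semi_axes=(2.2, 1.8), ri=1.384)]

    def test_zero_brightness_equals_baseline(self):
        labeled, blank = generate_gfp_stack(self.cells(), [0.0, 0.0], 20.0, 50.0,
                                            image_shape=(64, 64), pixel_size_um=0.25)
        np.testing.assert_array_equal(labeled, blank)
        assert np.all(blank == 70.0)

    def test_corrected_sum_recovers_brightness_exactly(self):
        labeled, blank = generate_gfp_stack(self.cells(), [1000.0, 2500.0], 20.0, 50.0,
                                            image_shape=(64, 64), pixel_size_um=0.25)
        corrected = labeled.sum() - blank.sum()
        assert corrected == pytest.approx(3500.0, rel=1e-9)

    def test_linearity_in_brightness(self):
        l1, b1 = generate_gfp_stack(self.cells(), [1000.0, 500.0], 20.0, 50.0,
                                    image_shape=(64, 64), pixel_size_um=0.25)
        l2, _ = generate_gfp_stack(self.cells(), [2000.0, 1000.0], 20.0, 50.0,
                                   image_shape=(64, 64), pixel_size_um=0.25)
        assert (l2 - b1).sum() == pytest.approx(2 * (l1 - b1).sum(), rel=1e-9)

    def test_negative_brightness_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            generate_gfp_stack(self.cells(), [-1.0, 1.0], 20.0, 50.0,
                               image_shape=(64, 64), pixel_size_um=0.25)
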