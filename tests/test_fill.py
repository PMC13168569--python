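import numpy as np
import pytest

from foramct import (
    PhantomSpec,
    close_fill,
    dice,
    edt,
    edt_seal,
    generate_phantom,
    is_filled,
)
from conftest import as_mask
from oracles import brute_edt, digitized_ball, hollow_ball


class TestEDT:
    def test_single_voxel_distance_is_one(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        d = edt(as_mask(mask), "foreground")
        assert d.data[2, 2, 2] == pytest.approx(1.0)
        assert d.data[0, 0, 0] == 0.0  # background is zero on the fg domain

    def test_anisotropic_slab_matches_brute_force(self):
        spacing = (1.0, 1.0, 2.0)
        mask = np.zeros((11, 23, 23), dtype=bool)
        mask[1:10] = True  # slab 9 voxels thick along z, wide laterally
        d = edt(as_mask(mask, spacing=spacing), "foreground")
        np.testing.assert_allclose(d.data, brute_edt(mask, spacing, "foreground"))
        assert d.data[5, 11, 11] == pytest.approx(10.0)  # 5 voxels x dz to the z face

    @pytest.mark.parametrize("domain", ["foreground", "background"])
    @pytest.mark.parametrize("spacing", [(1, 1, 1), (1.5, 1.0, 2.0)])
    def test_random_masks_match_exhaustive_oracle(self, rng, domain, spacing):
        mask = rng.random((9, 8, 10)) < 0.5
        d = edt(as_mask(mask, spacing=spacing), domain)
        np.testing.assert_allclose(d.data, brute_edt(mask, spacing, domain), atol=1e-9)

    def test_all_foreground_measured_against_virtual_border(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        d = edt(as_mask(mask), "foreground")
        assert d.data.min() == pytest.approx(1.0)  # border voxels see the pad
        assert d.data.max() == pytest.approx(2.0)


class TestCloseFill:
    def test_sealed_hollow_cube_becomes_solid(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[2:10, 2:10, 2:10] = True
        mask[3:9, 3:9, 3:9] = False  # sealed internal cavity
        out = close_fill(as_mask(mask), radius_vox=1)
        expected = np.zeros_like(mask)
        expected[2:10, 2:10, 2:10] = True
        np.testing.assert_array_equal(out.data, expected)

    def test_solid_ball_unchanged_by_closing(self):
        ball = digitized_ball(5, pad=4)
        out = close_fill(as_mask(ball), radius_vox=2)
        np.testing.assert_array_equal(out.data, ball)

    def test_radius_zero_is_pure_hole_fill(self):
        shell = hollow_ball(8, 2, pad=3)
        out = close_fill(as_mask(shell), radius_vox=0)
        np.testing.assert_array_equal(out.data, digitized_ball(8, pad=3))

    def test_pinhole_sealed_by_dilation(self):
        shell = hollow_ball(8, 2, pad=4)
        centre = shell.shape[0] // 2
        shell[centre, centre, 16:] = False  # 1-voxel pinhole through the wall
        out = close_fill(as_mask(shell), radius_vox=2)
        solid = digitized_ball(8, pad=4)
        assert dice(out.data, solid) > 0.99
        assert (out.data & solid).sum() >= 0.99 * solid.sum()

    def test_result_always_contains_input(self, rng):
        mask = rng.random((10, 10, 10)) < 0.2
        out = close_fill(as_mask(mask), radius_vox=2)
        assert not (mask & ~out.data).any()


class TestIsFilled:
    def test_solid_ball_is_filled(self):
        solid = as_mask(digitized_ball(7, pad=4))
        assert is_filled(solid, solid).is_filled

    def test_filled_equal_to_skeleton_is_trivially_filled(self):
        cube = np.zeros((10, 10, 10), dtype=bool)
        cube[2:8, 2:8, 2:8] = True  # solid: no cavities at all
        solid = as_mask(cube)
        assert is_filled(solid, solid).is_filled

    def test_open_aperture_detected(self):
        shell = hollow_ball(9, 2, pad=5)
        centre = shell.shape[0] // 2
        shell[centre - 1 : centre + 2, centre - 1 : centre + 2, 18:] = False  # aperture
        unfilled = close_fill(as_mask(shell), radius_vox=1)  # radius too small to seal
        report = is_filled(unfilled, as_mask(shell))
        assert not report.is_filled
        assert report.unfilled_aperture_count >= 1

    def test_multichamber_phantom_closed_test_is_filled(self, small_products):
        report = small_products.filled_report
        assert report.is_filled  # sealed phantom: surface creases must not count


class TestEDTSeal:
    def test_zero_thresholds_degenerate_to_hole_fill(self):
        shell = as_mask(hollow_ball(8, 2, pad=3))
        out = edt_seal(shell, 0.0, 0.0)
        np.testing.assert_array_equal(out.data, digitized_ball(8, pad=3))

    def test_aperture_sealed_and_cavity_recovered(self):
        spec = PhantomSpec(n_chambers=1, r0_um=10, wall_um=3, rng_seed=0)
        _, truth = generate_phantom(spec)
        shell = truth.wall_mask.data.copy()
        centre = np.array(shell.shape) // 2
        shell[centre[0] - 2 : centre[0] + 3, centre[1] - 2 : centre[1] + 3, : centre[2]] = (
            shell[centre[0] - 2 : centre[0] + 3, centre[1] - 2 : centre[1] + 3, : centre[2]]
            & False
        )  # punch an aperture of radius ~2 through one side
        t = 4.0  # > aperture radius
        sealed = edt_seal(as_mask(shell), t, t)
        solid = truth.wall_mask.data | (truth.chamber_labels.data > 0)
        assert dice(sealed.data, solid) > 0.99
        # the cavity itself must be fully recovered
        cavity = truth.chamber_labels.data > 0
        assert (sealed.data & cavity).sum() >= 0.99 * cavity.sum()

    def test_output_contains_skeleton_for_random_inputs(self, rng):
        mask = rng.random((10, 10, 10)) < 0.15
        out = edt_seal(as_mask(mask), 2.0, 1.0)
        assert not (mask & ~out.data).any()

    def test_sealed_and_closed_agree_on_closed_phantom(self, small_spec, small_products):
        """On a sealed test, both filling routes land on the same solid."""
        skeleton = small_products.skeleton
        closed = small_products.filled
        t = small_spec.wall_um / 2.0
        sealed = edt_seal(skeleton, t, t)
        assert dice(sealed.data, closed.data) >= 0.99
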