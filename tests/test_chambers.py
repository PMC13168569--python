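import numpy as np
import pytest

from foramct import (
    ChamberRecord,
    LabelMap,
    chamber_stats,
    inner_chambers,
    label_components,
    make_seeds,
    order_chambers,
    watershed_chambers,
)
from conftest import as_grid, as_mask
from oracles import brute_label_stats, digitized_ball, flood_fill_label


def two_sphere_cavity(r=7, neck=2, pad=3):
    """Two equal spherical cavities joined by a thin cylindrical neck."""
    gap = 2 * r + 4
    nz = 2 * (r + pad) + 1
    ny = nz
    nx = gap + 2 * (r + pad) + 1
    zz, yy, xx = np.indices((nz, ny, nx))
    c = r + pad
    left = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
    right = (zz - c) ** 2 + (yy - c) ** 2 + (xx - (c + gap)) ** 2 <= r**2
    tube = (
        ((zz - c) ** 2 + (yy - c) ** 2 <= neck**2)
        & (xx >= c)
        & (xx <= c + gap)
    )
    return left | right | tube, left, right


class TestInnerChambers:
    def test_filled_equals_skeleton_gives_empty(self):
        mask = as_mask(digitized_ball(5))
        out = inner_chambers(mask, mask)
        assert out.count == 0

    def test_hollow_sphere_cavity_voxel_count(self):
        solid = digitized_ball(10, pad=2)
        cavity = digitized_ball(7, pad=5)  # same shape, inner ball radius 7
        shell = solid & ~cavity
        out = inner_chambers(as_mask(solid), as_mask(shell))
        assert out.count == int(cavity.sum())

    def test_disjoint_from_skeleton(self, small_products):
        assert not (small_products.inner_chambers.data & small_products.skeleton.data).any()

    def test_skeleton_must_be_subset(self):
        with pytest.raises(ValueError):
            inner_chambers(as_mask(np.zeros((3, 3, 3))), as_mask(np.ones((3, 3, 3))))


class TestMakeSeeds:
    def test_single_cavity_single_seed(self):
        cavity = as_mask(digitized_ball(7, pad=3))
        seeds, _, _ = make_seeds(cavity, sigma_um=1.0, seed_t_um=3.0)
        labels = label_components(seeds)
        assert labels.n_labels == 1

    def test_threshold_above_radius_errors(self):
        cavity = as_mask(digitized_ball(5, pad=3))
        with pytest.raises(ValueError, match="too high"):
            make_seeds(cavity, sigma_um=1.0, seed_t_um=50.0)

    def test_neck_split_into_two_seeds(self):
        mask, _, _ = two_sphere_cavity(r=7, neck=2)
        seeds, _, _ = make_seeds(as_mask(mask), sigma_um=1.0, seed_t_um=4.0)
        assert label_components(seeds).n_labels == 2

    def test_auto_threshold_resolves_to_half_max_distance(self):
        cavity = as_mask(digitized_ball(7, pad=3))
        _, dist, resolved = make_seeds(cavity, sigma_um=1.0, seed_t_um="auto")
        assert resolved == pytest.approx(0.5 * dist.data.max())


class TestLabelComponents:
    def test_three_disjoint_cubes(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        for k, off in enumerate((1, 5, 9)):
            mask[off : off + 2, 1:3, 1:3] = True
        assert label_components(as_mask(mask)).n_labels == 3

    def test_single_voxel(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        labels = label_components(as_mask(mask))
        assert labels.n_labels == 1 and labels.data[1, 1, 1] == 1

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        mask = rng.random((9, 9, 9)) < 0.3
        labels = label_components(as_mask(mask), connectivity)
        oracle = flood_fill_label(mask, connectivity)
        np.testing.assert_array_equal(labels.data, oracle)


class TestWatershed:
    def test_single_seed_floods_everything(self):
        cavity = as_mask(digitized_ball(6, pad=3))
        seeds, dist, _ = make_seeds(cavity, 1.0, 3.0)
        labels = watershed_chambers(cavity, label_components(seeds), dist)
        assert labels.n_labels == 1
        assert (labels.data > 0).sum() == cavity.count

    def test_neck_split_volumes_within_5pct(self):
        mask, left, right = two_sphere_cavity(r=7, neck=2)
        cavity = as_mask(mask)
        seeds, dist, _ = make_seeds(cavity, 1.0, 4.0)
        labels = watershed_chambers(cavity, label_components(seeds), dist)
        assert labels.n_labels == 2
        sizes = np.bincount(labels.data.ravel())[1:]
        for size in sizes:
            assert size == pytest.approx(left.sum(), rel=0.05)

    def test_total_coverage(self, small_products):
        ws = small_products.watershed_labels
        inner = small_products.inner_chambers
        assert int((ws.data > 0).sum()) == inner.count
        assert ws.n_labels == small_products.labeled_seeds.n_labels

    def test_deterministic(self):
        mask, _, _ = two_sphere_cavity(r=6, neck=2)
        cavity = as_mask(mask)
        seeds, dist, _ = make_seeds(cavity, 1.0, 3.0)
        a = watershed_chambers(cavity, label_components(seeds), dist)
        b = watershed_chambers(cavity, label_components(seeds), dist)
        np.testing.assert_array_equal(a.data, b.data)

    def test_no_seeds_rejected(self):
        cavity = as_mask(digitized_ball(5, pad=2))
        empty = LabelMap(
            data=np.zeros(cavity.data.shape, dtype=np.int32), spacing=(1, 1, 1)
        )
        from foramct import edt

        with pytest.raises(ValueError, match="no seeds"):
            watershed_chambers(cavity, empty, edt(cavity))


class TestChamberStats:
    def test_cube_closed_form(self):
        labels = np.zeros((12, 12, 12), dtype=np.int32)
        labels[0:10, 0:10, 0:10] = 1
        raw = as_grid(np.full((12, 12, 12), 100.0))
        (rec,) = chamber_stats(LabelMap(data=labels, spacing=(1, 1, 1)), raw)
        assert rec.volume_um3 == pytest.approx(1000.0)
        assert rec.centroid_um == pytest.approx((4.5, 4.5, 4.5))
        assert rec.mean_intensity == pytest.approx(100.0)

    def test_typical_uct_voxel_volume(self):
        labels = np.zeros((10, 10, 10), dtype=np.int32)
        labels.ravel()[:1000] = 1
        spacing = (1.75, 1.75, 1.75)
        raw = as_grid(np.zeros((10, 10, 10)), spacing=spacing)
        (rec,) = chamber_stats(LabelMap(data=labels, spacing=spacing), raw)
        assert rec.volume_um3 == pytest.approx(5359.375)

    def test_matches_per_label_accumulation_oracle(self, rng):
        labels = rng.integers(0, 5, size=(8, 8, 8)).astype(np.int32)
        raw_data = rng.integers(0, 1000, size=(8, 8, 8)).astype(np.uint16)
        spacing = (1.5, 1.0, 2.0)
        recs = chamber_stats(
            LabelMap(data=labels, spacing=spacing), as_grid(raw_data, spacing=spacing)
        )
        oracle = brute_label_stats(labels, raw_data, spacing)
        assert {r.label for r in recs} == set(oracle)
        for r in recs:
            ref = oracle[r.label]
            assert r.voxels == ref["voxels"]
            assert r.volume_um3 == pytest.approx(ref["volume_um3"])
            assert r.centroid_um == pytest.approx(ref["centroid_um"])
            assert r.mean_intensity == pytest.approx(ref["mean_intensity"])

    def test_label_as_signal_variant(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0] = 1
        labels[2] = 2
        raw = as_grid(np.full((4, 4, 4), 99.0))
        recs = chamber_stats(LabelMap(data=labels, spacing=(1, 1, 1)), raw, signal="labels")
        assert [r.mean_intensity for r in recs] == [1.0, 2.0]


class TestOrderChambers:
    def _rec(self, label, vol):
        return ChamberRecord(
            label=label, volume_um3=vol, voxels=int(vol),
            centroid_um=(0, 0, 0), mean_intensity=0.0,
        )

    def test_sorted_with_cumulative_prefix_sum(self):
        ordered = order_chambers([self._rec(1, 5), self._rec(2, 1), self._rec(3, 3)])
        assert [o.record.volume_um3 for o in ordered] == [1, 3, 5]
        assert [o.chamber_number for o in ordered] == [1, 2, 3]
        assert [o.cumulative_volume_um3 for o in ordered] == [1, 4, 9]

    def test_single_chamber(self):
        (only,) = order_chambers([self._rec(1, 42.0)])
        assert only.chamber_number == 1
        assert only.cumulative_volume_um3 == 42.0

    def test_geometric_growth_slope_recovered(self):
        g = 1.8  # per-chamber volume growth ratio
        records = [self._rec(k + 1, 100.0 * g**k) for k in range(8)]
        ordered = order_chambers(records)
        logv = np.log([o.record.volume_um3 for o in ordered])
        slope = np.polyfit([o.chamber_number for o in ordered], logv, 1)[0]
        assert slope == pytest.approx(np.log(g), rel=0.10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_chambers([])
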