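"""Microtissue detection, adequacy rule, segmentation and skeleton graph."""

import numpy as np
import pytest

import fibroquant as fq
from fibroquant.detect import (
    CollagenMask,
    MicrotissueRegion,
    build_fiber_graph,
    scaled_min_object_px,
)
from fibroquant.stain import ODImage, default_stain_profile

from conftest import bar_mask


def _blank_image(side=128, color=(247, 245, 243)):
    pixels = np.tile(np.array(color, np.uint8), (side, side, 1))
    return fq.RGBImage(pixels=pixels, pixel_size_um=1.0)


class TestFindMicrotissues:
    def test_blank_image_no_regions(self):
        assert fq.find_microtissues(_blank_image()) == []

    def test_disc_area_within_two_percent(self, mash_sample):
        regions = fq.find_microtissues(mash_sample.image)
        assert len(regions) == 1
        expected = np.pi * 150.0**2
        assert abs(regions[0].area_um2 - expected) / expected < 0.02

    def test_two_discs_two_regions(self):
        a = fq.render_sample(fq.LEAN_PRESET, 1)
        side = a.image.pixels.shape[0]
        canvas = np.tile(np.array(a.preset.background_rgb, np.uint8), (side, 2 * side + 40, 1))
        canvas[:, :side] = a.image.pixels
        canvas[:, side + 40 :] = a.image.pixels
        regions = fq.find_microtissues(fq.RGBImage(canvas, 1.0))
        assert len(regions) == 2


class TestAdequacyFilter:
    @staticmethod
    def _regions(areas):
        return [
            MicrotissueRegion(i, np.ones((1, 1), bool), float(a))
            for i, a in enumerate(areas)
        ]

    def test_half_mean_rule_arithmetic(self):
        """Areas [100,100,100,40]: mean 85, cutoff 42.5, only the 40 excluded."""
        regions = fq.adequacy_filter(self._regions([100, 100, 100, 40]))
        assert [r.included for r in regions] == [True, True, True, False]
        assert "50%" in regions[3].exclusion_reason

    def test_single_region_always_included(self):
        assert fq.adequacy_filter(self._regions([17]))[0].included

    def test_all_equal_all_included(self):
        assert all(r.included for r in fq.adequacy_filter(self._regions([50] * 5)))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            fq.adequacy_filter([])

    def test_boundary_is_strict(self):
        # area exactly at 50% of the mean is kept (rule is strictly below).
        regions = fq.adequacy_filter(self._regions([150, 50]))  # mean 100, cutoff 50
        assert [r.included for r in regions] == [True, True]


class TestSegmentCollagen:
    def test_flat_channel_empty_mask(self):
        od = ODImage(
            od=np.zeros((32, 32, 3)), pixel_size_um=1.0,
            saturated_mask=np.zeros((32, 32), bool), collagen=np.zeros((32, 32)),
        )
        region = MicrotissueRegion(0, np.ones((32, 32), bool), 1024.0)
        assert not fq.segment_collagen(od, region).mask.any()

    def test_small_components_removed(self):
        collagen = np.zeros((32, 32))
        collagen[4, 4:7] = 1.0  # 3-px speck
        collagen[20:26, 10:12] = 1.0  # 12-px object
        od = ODImage(
            od=np.zeros((32, 32, 3)), pixel_size_um=1.0,
            saturated_mask=np.zeros((32, 32), bool), collagen=collagen,
        )
        region = MicrotissueRegion(0, np.ones((32, 32), bool), 1024.0)
        mask = fq.segment_collagen(od, region, min_object_px=5).mask
        assert not mask[4, 4:7].any()
        assert mask[20:26, 10:12].all()

    def test_empty_tissue_mask_rejected(self):
        od = ODImage(
            od=np.zeros((8, 8, 3)), pixel_size_um=1.0,
            saturated_mask=np.zeros((8, 8), bool), collagen=np.zeros((8, 8)),
        )
        with pytest.raises(ValueError, match="tissue"):
            fq.segment_collagen(od, MicrotissueRegion(0, np.zeros((8, 8), bool), 0.0))

    def test_dice_against_truth(self, mash_sample, synth_config):
        """Segmentation recovers the generator truth mask at Dice >= 0.80."""
        profile = default_stain_profile()
        od = fq.separate_collagen(fq.rgb_to_od(mash_sample.image, profile), profile)
        region = fq.find_microtissues(mash_sample.image)[0]
        mask = fq.segment_collagen(od, region).mask
        truth = mash_sample.collagen_mask_truth
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.80

    def test_min_object_px_scaling(self):
        assert scaled_min_object_px(1.0) == 5
        assert scaled_min_object_px(0.5) == 20
        assert scaled_min_object_px(2.0) == 1


class TestFiberGraph:
    def test_bar_single_branch(self):
        g = build_fiber_graph(CollagenMask(bar_mask(), 1.0, 5))
        assert g.n_branches == 1
        assert g.n_nodes == 0
        assert g.endpoints == 2
        assert abs(g.total_length_um - 50) <= 5  # end erosion ~ half-width

    def test_plus_sign_one_junction_four_branches(self):
        mask = np.zeros((61, 61), bool)
        mask[28:33, 5:56] = True
        mask[5:56, 28:33] = True
        g = build_fiber_graph(CollagenMask(mask, 1.0, 5))
        assert g.n_nodes == 1
        assert g.n_branches == 4
        assert g.endpoints == 4

    def test_empty_mask_empty_graph(self):
        g = build_fiber_graph(CollagenMask(np.zeros((10, 10), bool), 1.0, 5))
        assert (g.n_nodes, g.n_branches, g.endpoints) == (0, 0, 0)

    def test_branch_lengths_sum_to_total(self, mash_sample, synth_config):
        profile = default_stain_profile()
        od = fq.separate_collagen(fq.rgb_to_od(mash_sample.image, profile), profile)
        region = fq.find_microtissues(mash_sample.image)[0]
        mask = fq.segment_collagen(od, region)
        g = build_fiber_graph(mask)
        assert g.total_length_um == pytest.approx(sum(b.length_um for b in g.branches))

    def test_scale_equivariance(self):
        """Doubling the pixel size doubles lengths on identical pixel data."""
        g1 = build_fiber_graph(CollagenMask(bar_mask(), 1.0, 5))
        g2 = build_fiber_graph(CollagenMask(bar_mask(), 2.0, 5))
        assert g2.total_length_um == pytest.approx(2 * g1.total_length_um)


class TestExtractFibers:
    def test_two_disjoint_bars_two_components(self):
        mask = np.zeros((40, 70), bool)
        mask[5:10, 5:60] = True
        mask[25:30, 5:60] = True
        cm = CollagenMask(mask, 1.0, 5)
        comps = fq.extract_fibers(cm, build_fiber_graph(cm))
        assert len(comps) == 2

    def test_components_partition_mask(self, mash_sample):
        profile = default_stain_profile()
        od = fq.separate_collagen(fq.rgb_to_od(mash_sample.image, profile), profile)
        region = fq.find_microtissues(mash_sample.image)[0]
        cm = fq.segment_collagen(od, region)
        comps = fq.extract_fibers(cm, build_fiber_graph(cm))
        total = sum(c.n_pixels for c in comps)
        assert total == cm.mask.sum()
        seen = set()
        for c in comps:
            pix = set(zip(c.pixel_set[0].tolist(), c.pixel_set[1].tolist()))
            assert not (pix & seen)
            seen |= pix

    def test_separated_truth_fibers_recovered(self):
        """k non-touching rendered fibers produce k components."""
        polys = [
            [np.array([[10.0, 5.0], [10.0, 45.0]])],
            [np.array([[30.0, 5.0], [30.0, 45.0]])],
            [np.array([[50.0, 5.0], [50.0, 45.0]])],
        ]
        mask = np.zeros((60, 50), bool)
        for p in polys:
            mask |= fq.rasterize_polylines(p, 3.0, (60, 50), 1.0)
        cm = CollagenMask(mask, 1.0, 5)
        comps = fq.extract_fibers(cm, build_fiber_graph(cm))
        assert len(comps) == 3
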