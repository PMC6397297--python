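"""Segmentation and descriptor fidelity against rendered ground truth."""

import math

import numpy as np
import pytest
from scipy.stats import spearmanr
from skimage.draw import disk as draw_disk

import cytodose as cd
from cytodose.morphometrics import (EmptyFieldError, FibreMaps,
                                    compute_descriptors, segment_cell,
                                    segment_fibres, total_gfp)
from conftest import make_fibre_field


def _solid_mask(shape, rows, cols):
    m = np.zeros(shape, dtype=bool)
    m[rows, cols] = True
    return m


class TestSegmentCell:
    def test_blank_field_raises(self):
        z = np.zeros((64, 64))
        images = cd.CellImageSet(gfp=z, stain=z, dapi=z, pixel_size=1.0)
        with pytest.raises(EmptyFieldError):
            segment_cell(images)

    def test_mask_matches_truth(self, small_population):
        _, image_sets, truth = small_population
        for images, masks in zip(image_sets, truth.masks):
            cell_mask, nucleus_mask = segment_cell(images)
            inter = (cell_mask & masks["cell"]).sum()
            union = (cell_mask | masks["cell"]).sum()
            assert inter / union > 0.95
            assert not np.any(nucleus_mask & ~cell_mask)

    def test_channel_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            cd.CellImageSet(gfp=np.zeros((4, 4)), stain=np.zeros((4, 5)),
                            dapi=np.zeros((4, 4)), pixel_size=1.0)


class TestTotalGfp:
    def test_uniform_mask(self):
        img = np.full((5, 5), 50.0)
        mask = np.zeros((5, 5), dtype=bool)
        mask.flat[:10] = True
        assert total_gfp(img, mask, background=10.0) == 400.0

    def test_background_equals_signal(self):
        img = np.full((5, 5), 7.0)
        mask = np.ones((5, 5), dtype=bool)
        assert total_gfp(img, mask, background=7.0) == 0.0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            total_gfp(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))

    def test_recovers_expression_on_noiseless_cells(self, small_population):
        # proportionality constant is 1 count per expression unit
        _, image_sets, truth = small_population
        for images, expr in zip(image_sets, truth.cells["expression"]):
            cell_mask, _ = segment_cell(images)
            assert total_gfp(images.gfp, cell_mask) == pytest.approx(
                expr, rel=0.01)


class TestSegmentFibres:
    def test_uniform_cell_has_no_fibres(self):
        cell = np.zeros((64, 64), dtype=bool)
        cell[8:56, 8:56] = True
        stain = 40.0 * cell
        maps = segment_fibres(stain, cell)
        assert not maps.fibre_mask.any()
        assert maps.fibre_brightness.sum() == 0.0

    def test_single_fibre_geometry(self, single_fibre_field):
        cell, stain, _ = single_fibre_field
        maps = segment_fibres(stain, cell)
        from scipy import ndimage
        _, n = ndimage.label(maps.fibre_mask)
        assert n == 1
        w = maps.fibre_brightness[maps.fibre_mask]
        theta = maps.orientation[maps.fibre_mask]
        mean_angle = math.degrees(
            np.angle(np.sum(w * np.exp(2j * theta))) / 2) % 180
        assert abs(mean_angle - 30.0) < 3.0

    def test_crossing_fibres_two_modes(self):
        cell, stain, truth = make_fibre_field(
            [20.0, 110.0], [(64.0, 54.0), (64.0, 74.0)], length=70.0)
        maps = segment_fibres(stain, cell)
        assert (maps.fibre_mask & truth).sum() / truth.sum() > 0.9
        theta = np.degrees(maps.orientation[maps.fibre_mask])
        w = maps.fibre_brightness[maps.fibre_mask]
        hist, edges = np.histogram(theta, bins=36, range=(0, 180), weights=w)
        modes = np.sort(np.argsort(hist)[-2:])
        centers = edges[modes] + 2.5
        assert abs(centers[0] - 20.0) <= 5.0
        assert abs(centers[1] - 110.0) <= 5.0

    def test_maps_invariants(self, single_fibre_field):
        cell, stain, _ = single_fibre_field
        maps = segment_fibres(stain, cell)
        assert not np.any(maps.fibre_mask & ~maps.cell_mask)
        assert np.all(maps.fibre_brightness[~maps.fibre_mask] == 0)
        assert np.all((maps.orientation >= 0) & (maps.orientation < np.pi))


class TestDescriptors:
    def test_rectangle_aspect_ratio(self):
        mask = _solid_mask((160, 160), slice(30, 130), slice(55, 105))
        maps = FibreMaps(np.zeros_like(mask), np.zeros(mask.shape),
                         np.zeros(mask.shape), mask)
        rec = compute_descriptors(maps, pixel_size=1.0)
        assert rec.aspect_ratio == pytest.approx(2.0, rel=0.05)

    def test_disk_is_round_and_smooth(self):
        mask = np.zeros((128, 128), dtype=bool)
        rr, cc = draw_disk((64, 64), 40)
        mask[rr, cc] = True
        maps = FibreMaps(np.zeros_like(mask), np.zeros(mask.shape),
                         np.zeros(mask.shape), mask)
        rec = compute_descriptors(maps, pixel_size=1.0)
        assert rec.aspect_ratio == pytest.approx(1.0, rel=0.05)
        assert rec.stellate_factor < 0.05

    def test_single_fibre_thickness_and_coherence(self, single_fibre_field):
        cell, stain, _ = single_fibre_field
        maps = segment_fibres(stain, cell)
        rec = compute_descriptors(maps, pixel_size=1.0)
        assert 3.5 <= rec.fibre_thickness <= 4.5
        assert rec.orientation_coherence > 0.95

    def test_empty_cell_mask_raises(self):
        empty = np.zeros((8, 8), dtype=bool)
        maps = FibreMaps(empty, np.zeros((8, 8)), np.zeros((8, 8)), empty)
        with pytest.raises(ValueError):
            compute_descriptors(maps, pixel_size=1.0)

    def test_fibreless_cell_flagged(self):
        cell = np.zeros((64, 64), dtype=bool)
        cell[8:56, 8:56] = True
        maps = FibreMaps(np.zeros_like(cell), np.zeros(cell.shape),
                         np.zeros(cell.shape), cell)
        rec = compute_descriptors(maps, pixel_size=1.0)
        assert not rec.has_fibres
        assert rec.fibre_amount == 0.0

    def test_rotation_equivariance(self, single_fibre_field):
        cell, stain, _ = single_fibre_field
        rec1 = compute_descriptors(segment_fibres(stain, cell), 1.0)
        stain90 = np.rot90(stain).copy()
        cell90 = np.rot90(cell).copy()
        maps90 = segment_fibres(stain90, cell90)
        rec2 = compute_descriptors(maps90, 1.0)
        for name in ("area", "aspect_ratio", "stellate_factor",
                     "fibre_amount", "fibre_thickness"):
            a, b = getattr(rec1, name), getattr(rec2, name)
            assert a == pytest.approx(b, rel=0.02, abs=1e-6), name
        maps1 = segment_fibres(stain, cell)
        def mean_angle(maps):
            w = maps.fibre_brightness[maps.fibre_mask]
            t = maps.orientation[maps.fibre_mask]
            return np.angle(np.sum(w * np.exp(2j * t))) / 2 % np.pi
        shift = abs(mean_angle(maps90) - mean_angle(maps1)) % np.pi
        assert min(shift, np.pi - shift) == pytest.approx(
            np.pi / 2, abs=math.radians(3))

    def test_pixel_size_scale_law(self, single_fibre_field):
        cell, stain, _ = single_fibre_field
        maps = segment_fibres(stain, cell)
        r1 = compute_descriptors(maps, pixel_size=1.0)
        r2 = compute_descriptors(maps, pixel_size=2.0)
        assert r2.area == pytest.approx(4 * r1.area)
        assert r2.fibre_thickness == pytest.approx(2 * r1.fibre_thickness)
        assert r2.fibre_length == pytest.approx(2 * r1.fibre_length)
        assert r2.fibre_amount == pytest.approx(r1.fibre_amount)

    def test_fibre_amount_conservation(self, single_fibre_field):
        cell, stain, truth_mask = single_fibre_field
        maps = segment_fibres(stain, cell)
        rec = compute_descriptors(maps, 1.0)
        total_stain_in_cell = stain[cell].sum()
        assert rec.fibre_amount <= total_stain_in_cell
        # >= 90% of the rendered signal inside the half-max footprint
        rendered = (stain - 30.0)[truth_mask].sum()
        assert rec.fibre_amount >= 0.9 * rendered

    def test_area_rank_correlation_with_truth(self, small_population):
        _, image_sets, truth = small_population
        measured = []
        for images in image_sets:
            cell_mask, _ = segment_cell(images)
            measured.append(cell_mask.sum() * images.pixel_size ** 2)
        rho = spearmanr(measured, truth.cells["area_um2"]).statistic
        assert rho > 0.99
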