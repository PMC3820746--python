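"""Six-step segmentation: smoothing, thresholds, thinning, compartments."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.signal import convolve2d
from skimage.measure import euler_number

from furrowseg import (
    DegenerateImageError,
    IntensityImage,
    NoNetworkError,
    SegmentationParams,
    segment,
    skeletonize_network,
)
from furrowseg.segmentation import (
    compartment_mask,
    nuclei_link_mask,
    preliminary_network_mask,
    prune_spurs,
    remove_boundary_artifacts,
    smooth_coarse,
)
from furrowseg.simulate import SimulationConfig, rasterize_edges, simulate_embryo

PARAMS = SegmentationParams()


def _img(pixels, px=0.104):
    return IntensityImage(np.asarray(pixels, dtype=float), px)


# --------------------------------------------------------------------------
# step 1: smoothing
# --------------------------------------------------------------------------


class TestSmoothCoarse:
    def test_constant_image_unchanged(self):
        img = _img(np.full((64, 64), 7.0))
        out = smooth_coarse(img, PARAMS)
        np.testing.assert_allclose(out.pixels, 7.0)

    def test_mean_preserved_within_one_percent(self, wt_noiseless):
        pixels, _, _, cfg = wt_noiseless
        out = smooth_coarse(_img(pixels), PARAMS)
        assert out.pixels.mean() == pytest.approx(pixels.mean(), rel=0.01)

    def test_impulse_response_matches_direct_convolution(self):
        sigma = 2.0
        img = np.zeros((65, 65))
        img[32, 32] = 100.0
        out = smooth_coarse(
            _img(img), SegmentationParams(sigma_coarse_px=sigma, sigma_fine_px=1.0)
        )
        # independent oracle: direct convolution with a truncated kernel
        rad = int(4 * sigma)
        x = np.arange(-rad, rad + 1)
        k1 = np.exp(-(x**2) / (2 * sigma**2))
        k1 /= k1.sum()
        kernel = np.outer(k1, k1)
        expected = convolve2d(img, kernel, mode="same", boundary="symm")
        np.testing.assert_allclose(out.pixels, expected, atol=1e-8)

    def test_ridge_centerlines_stay_local_maxima(self, wt_noiseless):
        pixels, lattice, gt, cfg = wt_noiseless
        sm = smooth_coarse(_img(pixels), PARAMS).pixels
        # sample intact-edge points away from junctions and compare each
        # against the two ends of its perpendicular profile
        n_ok = n_tot = 0
        for e in lattice.edges:
            if e.length < 14:
                continue
            d = np.array([e.p1[0] - e.p0[0], e.p1[1] - e.p0[1]]) / e.length
            perp = np.array([-d[1], d[0]])
            for f in np.linspace(0.3, 0.7, 5):
                p = np.array(e.p0) + f * e.length * d
                pts = np.array([p, p + 2.5 * perp, p - 2.5 * perp]).T
                here, side_a, side_b = ndi.map_coordinates(sm, pts, order=1)
                n_tot += 1
                n_ok += bool(here >= side_a and here >= side_b)
        assert n_tot > 100
        assert n_ok / n_tot >= 0.95

    def test_rejects_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            SegmentationParams(sigma_coarse_px=0.0)


# --------------------------------------------------------------------------
# step 2: preliminary mask
# --------------------------------------------------------------------------


class TestPreliminaryNetworkMask:
    def test_otsu_separates_two_level_image(self):
        img = np.zeros((32, 32))
        img[:, 16:] = 100.0
        mask = preliminary_network_mask(_img(img), PARAMS)
        np.testing.assert_array_equal(mask, img == 100.0)

    def test_otsu_on_constant_image_raises(self):
        with pytest.raises(DegenerateImageError):
            preliminary_network_mask(_img(np.full((32, 32), 5.0)), PARAMS)

    def test_fixed_threshold_above_max_gives_empty_mask(self):
        params = SegmentationParams(
            threshold_strategy="fixed",
            low_threshold=10, mid_threshold=1000, high_threshold=2000,
        )
        img = np.random.default_rng(0).uniform(0, 100, (32, 32))
        assert not preliminary_network_mask(_img(img), params).any()

    def test_covers_centerlines_not_interiors(self, wt_noiseless):
        pixels, lattice, gt, cfg = wt_noiseless
        sm = smooth_coarse(_img(pixels), PARAMS)
        mask = preliminary_network_mask(sm, PARAMS)
        centers = rasterize_edges(lattice, range(len(lattice.edges)))
        assert (mask & centers).sum() / centers.sum() >= 0.99
        ridge_zone = ndi.binary_dilation(centers, np.ones((13, 13)))
        interior = ~ridge_zone
        assert (mask & interior).sum() / interior.sum() <= 0.05

    def test_raising_mid_threshold_shrinks_foreground(self, wt_noiseless):
        pixels, _, _, _ = wt_noiseless
        sm = smooth_coarse(_img(pixels), PARAMS)
        lo = preliminary_network_mask(sm, PARAMS, threshold=10.0)
        hi = preliminary_network_mask(sm, PARAMS, threshold=20.0)
        assert not (hi & ~lo).any()
        assert hi.sum() <= lo.sum()


# --------------------------------------------------------------------------
# step 3: thinning
# --------------------------------------------------------------------------


def _no_2x2_block(mask):
    return not (mask[:-1, :-1] & mask[:-1, 1:] & mask[1:, :-1] & mask[1:, 1:]).any()


class TestSkeletonizeNetwork:
    def test_wide_bar_thins_to_line(self):
        mask = np.zeros((32, 64), dtype=bool)
        mask[14:19, 8:56] = True
        skel = skeletonize_network(mask).mask
        assert _no_2x2_block(skel)
        rows, cols = np.nonzero(skel)
        assert len(np.unique(rows)) == 1  # a single horizontal line
        assert cols.min() <= 10 and cols.max() >= 53  # endpoints preserved

    def test_filled_disk_degenerates_to_few_pixels(self):
        yy, xx = np.mgrid[:64, :64]
        disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 15**2
        skel = skeletonize_network(disk).mask
        assert skel.sum() <= 5

    def test_skeleton_subset_and_topology_preserved(self, wt_noiseless):
        pixels, _, _, _ = wt_noiseless
        sm = smooth_coarse(_img(pixels), PARAMS)
        mask = preliminary_network_mask(sm, PARAMS)
        skel = skeletonize_network(mask).mask
        assert not (skel & ~mask).any()
        assert euler_number(skel, connectivity=2) == euler_number(mask, connectivity=2)
        n_in = ndi.label(mask, structure=np.ones((3, 3)))[1]
        n_out = ndi.label(skel, structure=np.ones((3, 3)))[1]
        assert n_in == n_out

    def test_idempotent(self, wt_noiseless):
        pixels, _, _, _ = wt_noiseless
        sm = smooth_coarse(_img(pixels), PARAMS)
        skel = skeletonize_network(preliminary_network_mask(sm, PARAMS)).mask
        again = skeletonize_network(skel).mask
        np.testing.assert_array_equal(skel, again)

    def test_empty_mask_rejected(self):
        with pytest.raises(NoNetworkError):
            skeletonize_network(np.zeros((32, 32), dtype=bool))


# --------------------------------------------------------------------------
# step 4: weak links
# --------------------------------------------------------------------------


class TestNucleiLinkMask:
    def test_without_weak_links_matches_strong_skeleton(self):
        cfg = SimulationConfig(
            image_size_px=(512, 512), n_nuclei=100, noise_sd=0.0,
            weak_link_contrast=0.0, seed=1,
        )
        pixels, _, _ = simulate_embryo(cfg)
        image = _img(pixels)
        sm = smooth_coarse(image, PARAMS)
        skel = skeletonize_network(preliminary_network_mask(sm, PARAMS)).mask
        link = nuclei_link_mask(image, PARAMS)
        near_skel = ndi.binary_dilation(skel, np.ones((3, 3)))
        # no spurious separations away from the true network
        assert (link & ~near_skel).sum() / link.sum() <= 0.01

    def test_failed_edge_centerline_covered(self, mutant_noiseless):
        pixels, lattice, gt, cfg = mutant_noiseless
        link = nuclei_link_mask(_img(pixels), PARAMS)
        fail_raster = rasterize_edges(lattice, sorted(gt.failed_edges))
        near_link = ndi.binary_dilation(link, np.ones((3, 3)))
        coverage = (fail_raster & near_link).sum() / fail_raster.sum()
        assert coverage >= 0.8

    def test_salt_noise_fully_pruned(self, wt_noiseless):
        pixels, _, _, cfg = wt_noiseless
        rng = np.random.default_rng(0)
        salted = pixels.copy()
        rr = rng.integers(0, 512, 40)
        cc = rng.integers(0, 512, 40)
        salted[rr, cc] = np.maximum(salted[rr, cc], 60.0)
        base = nuclei_link_mask(_img(pixels), PARAMS)
        with_salt = nuclei_link_mask(_img(salted), PARAMS)
        near_base = ndi.binary_dilation(base, np.ones((5, 5)))
        extra = (with_salt & ~near_base).sum()
        assert extra / with_salt.sum() <= 0.005

    def test_prune_spurs_removes_short_free_branches(self):
        skel = np.zeros((32, 64), dtype=bool)
        skel[16, 5:60] = True  # backbone
        skel[10:16, 30] = True  # 6-px spur
        pruned = prune_spurs(skel, max_length_px=8)
        # the free branch is peeled away; at most its 1-px base (which has
        # three backbone neighbours, hence is never an endpoint) survives
        assert not pruned[10:15, 30].any()
        assert pruned[16, 14:50].all()  # interior of the backbone survives


# --------------------------------------------------------------------------
# steps 5-6: compartments
# --------------------------------------------------------------------------


class TestCompartmentMask:
    def test_closed_network_encloses_one_region_per_tile(self, wt_noiseless):
        pixels, lattice, _, _ = wt_noiseless
        image = _img(pixels)
        sm = smooth_coarse(image, PARAMS)
        m2 = preliminary_network_mask(sm, PARAMS)
        comp = compartment_mask(m2, np.zeros_like(m2), PARAMS)
        comp = remove_boundary_artifacts(comp, sm, PARAMS, high_threshold=1e9)
        n_regions = ndi.label(comp)[1]
        n_interior = int((~lattice.boundary_tile).sum())
        # every surviving region corresponds to a tile (some boundary tiles
        # are dropped by the border clearing)
        assert n_regions >= n_interior
        assert n_regions <= lattice.n_tiles

    @staticmethod
    def _n_enclosed(mask):
        lbl, _ = ndi.label(mask)
        border = set(np.unique(np.concatenate(
            [lbl[0, :], lbl[-1, :], lbl[:, 0], lbl[:, -1]]))) - {0}
        return len(set(np.unique(lbl)) - {0} - border)

    def test_missing_edge_merges_adjacent_tiles(self):
        # a figure-eight network: removing the shared wall merges the loops
        m = np.zeros((40, 70), dtype=bool)
        m[5, 5:65] = m[34, 5:65] = True
        m[5:35, 5] = m[5:35, 64] = m[5:35, 35] = True
        full = compartment_mask(m, np.zeros_like(m), PARAMS)
        assert self._n_enclosed(full) == 2
        m_broken = m.copy()
        m_broken[5:35, 35] = False
        merged = compartment_mask(m_broken, np.zeros_like(m), PARAMS)
        assert self._n_enclosed(merged) == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compartment_mask(
                np.zeros((10, 10), dtype=bool), np.zeros((12, 10), dtype=bool), PARAMS
            )

    def test_high_threshold_removes_overlap(self, wt_noiseless):
        pixels, _, _, _ = wt_noiseless
        image = _img(pixels)
        sm = smooth_coarse(image, PARAMS)
        m2 = preliminary_network_mask(sm, PARAMS)
        comp = compartment_mask(m2, np.zeros_like(m2), PARAMS)
        cleaned = remove_boundary_artifacts(comp, sm, PARAMS, high_threshold=20.0)
        assert not (cleaned & (sm.pixels >= 20.0)).any()

    def test_no_surviving_compartment_touches_border(self, wt_noiseless_seg):
        labels = wt_noiseless_seg.compartments.labels
        border = np.concatenate(
            [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
        )
        assert (border == 0).all()


# --------------------------------------------------------------------------
# full pipeline
# --------------------------------------------------------------------------


class TestSegment:
    def test_intact_embryo_one_compartment_per_cell(self, wt_noiseless_seg):
        seg = wt_noiseless_seg
        assert seg.n_cells == seg.n_compartments > 0
        assert set(seg.nuclei_per_cell.values()) == {1}

    def test_single_failed_edge_gives_one_binucleate_cell(self):
        # find a seed planting exactly one (non-trivial) interior failure
        base = SimulationConfig(
            image_size_px=(512, 512), n_nuclei=100, noise_sd=0.0,
            failure_fraction=0.006,
        )
        for seed in range(50):
            cfg = base.with_(seed=seed)
            pixels, lattice, gt = simulate_embryo(cfg)
            if len(gt.failed_edges) != 1:
                continue
            (edge_id,) = gt.failed_edges
            if lattice.edges[edge_id].length < 12:
                continue  # sub-resolution sliver, covered by the sweep stats
            seg = segment(_img(pixels))
            counts = sorted(seg.nuclei_per_cell.values())
            assert counts[-1] == 2 and counts[:-1] == [1] * (len(counts) - 1)
            return
        pytest.fail("no suitable single-failure seed found")

    def test_skeleton_is_one_pixel_wide(self, wt_noiseless_seg):
        assert wt_noiseless_seg.network.is_one_pixel_wide()

    def test_label_conservation(self, wt_noiseless_seg):
        seg = wt_noiseless_seg
        assert sum(seg.nuclei_per_cell.values()) == seg.n_compartments

    def test_every_compartment_inside_its_cell(self, mutant_noiseless):
        pixels, _, _, cfg = mutant_noiseless
        seg = segment(_img(pixels))
        comp, cells = seg.compartments.labels, seg.cells.labels
        for comp_id, cell_id in seg.cell_of_compartment.items():
            assert (cells[comp == comp_id] == cell_id).all()

    def test_blank_image_raises_no_network(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(50, 10, (256, 256)).clip(min=0)
        with pytest.raises(NoNetworkError):
            segment(_img(noise))

    def test_provenance_records_thresholds(self, wt_noiseless_seg):
        thr = wt_noiseless_seg.provenance["thresholds"]
        assert thr["low"] < thr["mid"] < thr["high"]
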