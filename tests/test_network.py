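"""Skeletonization, thickness, node/element topology and curation."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi

from octava import (
    apply_curation,
    classify_elements,
    detect_nodes,
    exclude_nodes_from_diametry,
    local_thickness,
    measure_vessels,
    skeletonize_mask,
)
from octava.network import SkeletonMask
from octava.phantoms import _rasterize_centerline
from octava.segmentation import BinaryMask

PX = 10.0


def build_network(skel_bool, px=PX, twig=0, mask_bool=None):
    mask = BinaryMask(skel_bool if mask_bool is None else mask_bool, px)
    skel = SkeletonMask(np.asarray(skel_bool, bool), px)
    th = local_thickness(mask)
    net = classify_elements(skel, detect_nodes(skel), th, twig_size_px=twig)
    return exclude_nodes_from_diametry(net, th)


def cross(n=101):
    sk = np.zeros((n, n), bool)
    sk[n // 2, :] = True
    sk[:, n // 2] = True
    return sk


def theta():
    sk = np.zeros((60, 60), bool)
    sk[10, 10:51] = True
    sk[50, 10:51] = True
    sk[10:51, 10] = True
    sk[10:51, 50] = True
    sk[30, 10:51] = True
    return sk


class TestSkeletonize:
    def test_ribbon_thins_to_single_pixel_line(self):
        m = np.zeros((40, 120), bool)
        m[18:23, :] = True
        skel = skeletonize_mask(BinaryMask(m, PX))
        colcounts = skel.pixels.sum(axis=0)
        assert (colcounts[5:-5] == 1).all()
        # no 2x2 block is fully foreground
        blocks = skel.pixels[:-1, :-1] & skel.pixels[1:, :-1] & \
            skel.pixels[:-1, 1:] & skel.pixels[1:, 1:]
        assert not blocks.any()

    def test_annulus_topology_preserved(self):
        rr, cc = np.mgrid[:80, :80]
        d2 = (rr - 40) ** 2 + (cc - 40) ** 2
        m = (d2 <= 30**2) & (d2 >= 18**2)
        skel = skeletonize_mask(BinaryMask(m, PX))
        assert skel.pixels.sum() > 0
        # one component, one hole, both before and after thinning
        for raster in (m, skel.pixels):
            _, ncomp = ndi.label(raster, structure=np.ones((3, 3)))
            filled = ndi.binary_fill_holes(raster)
            _, nhole = ndi.label(filled & ~raster)
            assert (ncomp, nhole) == (1, 1)

    def test_component_count_matches_mask(self, grid_phantom):
        _, gt = grid_phantom
        skel = skeletonize_mask(gt.mask)
        _, n_mask = ndi.label(gt.mask.pixels, structure=np.ones((3, 3)))
        _, n_skel = ndi.label(skel.pixels, structure=np.ones((3, 3)))
        assert n_skel == n_mask

    def test_empty_mask_warns(self):
        with pytest.warns(UserWarning):
            skel = skeletonize_mask(BinaryMask(np.zeros((20, 20), bool), PX))
        assert not skel.pixels.any()


class TestLocalThickness:
    def test_filled_disk(self):
        rr, cc = np.mgrid[:60, :60]
        m = (rr - 30) ** 2 + (cc - 30) ** 2 <= 10.5**2
        th = local_thickness(BinaryMask(m, PX))
        assert th.values_um.max() == pytest.approx(21 * PX, abs=PX)

    def test_ribbon_centerline(self):
        m = np.zeros((40, 120), bool)
        m[15:25, :] = True  # 10 px wide
        th = local_thickness(BinaryMask(m, PX))
        assert th.values_um[20, 60] == pytest.approx(10 * PX, abs=PX)

    def test_lower_bound_from_distance_transform(self, grid_phantom):
        _, gt = grid_phantom
        th = local_thickness(gt.mask)
        edt = ndi.distance_transform_edt(gt.mask.pixels)
        px = gt.mask.pixel_size_um
        fg = gt.mask.pixels
        assert (th.values_um[fg] >= 2 * edt[fg] * px - 2 * px - 1e-9).all()

    def test_empty_mask_all_zero(self):
        th = local_thickness(BinaryMask(np.zeros((20, 20), bool), PX))
        assert not th.values_um.any()


class TestNodes:
    def test_straight_line_no_nodes(self):
        sk = np.zeros((30, 30), bool)
        sk[15, 5:25] = True
        assert detect_nodes(SkeletonMask(sk, PX)) == []

    def test_cross_single_node(self):
        nodes = detect_nodes(SkeletonMask(cross(), PX))
        assert len(nodes) == 1
        assert nodes[0].centroid == (50.0, 50.0)

    def test_theta_two_nodes(self):
        nodes = detect_nodes(SkeletonMask(theta(), PX))
        assert len(nodes) == 2


class TestClassify:
    def test_cross_four_branches(self):
        net = build_network(cross())
        kinds = sorted(e.kind for e in net.elements)
        assert kinds == ["branch"] * 4
        assert len(net.nodes) == 1

    def test_theta_three_segments_two_meshes(self):
        net = build_network(theta())
        assert sorted(e.kind for e in net.elements) == ["segment"] * 3
        assert len(net.nodes) == 2
        assert len(net.mesh_regions) == 2

    def test_small_speck_audited_as_twig(self):
        sk = np.zeros((30, 30), bool)
        sk[15, 5:25] = True
        sk[5, 5:7] = True  # 2-px speck
        mask = sk.copy()
        mask[13:18, 5:25] = True  # the real vessel is 5 px thick
        net = build_network(sk, twig=3, mask_bool=mask)
        assert len(net.elements) == 1
        assert len(net.excluded_twigs) == 1
        assert net.excluded_twigs[0]["n_pixels"] == 2

    def test_element_counts_partition_arcs(self, netfree_run):
        """Segments + branches + isolated = traced arcs, and arcs are
        pixel-disjoint except at shared node pixels."""
        _, inter = netfree_run
        net = inter["network"]
        seen = {}
        node_px = {p for n in net.nodes for p in n.pixels}
        for e in net.elements:
            for p in map(tuple, e.path):
                if p in seen and p not in node_px:
                    pytest.fail(f"pixel {p} appears in two elements")
                seen[p] = e.element_id


class TestDiametryExclusion:
    def test_junction_bulge_excluded_from_thin_ribbon(self):
        m = np.zeros((80, 80), bool)
        m[38:42, :] = True    # 4 px wide
        m[:, 34:46] = True    # 12 px wide
        mask = BinaryMask(m, PX)
        skel = skeletonize_mask(mask)
        th = local_thickness(mask)
        net = classify_elements(skel, detect_nodes(skel), th)
        net = exclude_nodes_from_diametry(net, th)
        tab = measure_vessels(net)
        thin = tab[tab.mean_diameter_um <= 8 * PX]
        assert len(thin) >= 1
        assert (thin.mean_diameter_um <= (4 + 1) * PX).all()

    def test_node_free_ribbon_unchanged(self):
        m = np.zeros((30, 100), bool)
        m[13:18, :] = True
        mask = BinaryMask(m, PX)
        skel = skeletonize_mask(mask)
        th = local_thickness(mask)
        net = classify_elements(skel, detect_nodes(skel), th)
        before = measure_vessels(net).mean_diameter_um.to_numpy()
        net = exclude_nodes_from_diametry(net, th)
        after = measure_vessels(net).mean_diameter_um.to_numpy()
        assert np.array_equal(before, after)

    def test_small_channel_diameter_improves(self, grid_phantom):
        """Paired comparison: node-region exclusion moves the small
        channel mean diameter toward the true 50 μm."""
        image, gt = grid_phantom
        mask = gt.mask
        skel = skeletonize_mask(mask)
        th = local_thickness(mask)
        net = classify_elements(skel, detect_nodes(skel), th)
        without = measure_vessels(net)
        net = exclude_nodes_from_diametry(net, th)
        with_ex = measure_vessels(net)

        def small_mean(tab):
            d = tab.mean_diameter_um.dropna()
            return d[d < 150].mean()

        true_small = 48.0  # 12 px at 4 um
        assert abs(small_mean(with_ex) - true_small) <= abs(small_mean(without) - true_small)


class TestMeasure:
    def test_horizontal_path_lengths(self):
        sk = np.zeros((20, 20), bool)
        sk[10, 5:16] = True  # 11 pixels
        tab = measure_vessels(build_network(sk))
        assert tab.arc_length_mm.iloc[0] == pytest.approx(0.100)
        assert tab.chord_length_mm.iloc[0] == pytest.approx(0.100)
        assert tab.tortuosity.iloc[0] == pytest.approx(0.0)

    def test_diagonal_step_convention(self):
        sk = np.zeros((20, 20), bool)
        idx = np.arange(5, 16)
        sk[idx, idx] = True  # 11 pixels, pure diagonal
        tab = measure_vessels(build_network(sk))
        assert tab.arc_length_mm.iloc[0] == pytest.approx(10 * np.sqrt(2) * PX / 1000.0)

    def test_semicircle_tortuosity(self):
        t = np.linspace(0, np.pi, 5000)
        xy = np.stack([150 - 120 * np.sin(t), 150 + 120 * np.cos(t)], axis=1)
        rc = _rasterize_centerline(xy, (300, 300))
        sk = np.zeros((300, 300), bool)
        sk[rc[:, 0], rc[:, 1]] = True
        tab = measure_vessels(build_network(sk))
        assert len(tab) == 1
        target = np.pi / 2 - 1
        assert abs(tab.tortuosity.iloc[0] - target) / target < 0.05

    def test_single_pixel_element(self):
        sk = np.zeros((20, 20), bool)
        sk[4, 4] = True
        tab = measure_vessels(build_network(sk))
        assert tab.arc_length_mm.iloc[0] == 0.0
        assert np.isnan(tab.tortuosity.iloc[0])

    def test_arc_never_shorter_than_chord(self, netfree_run):
        _, inter = netfree_run
        tab = inter["table"]
        assert (tab.arc_length_mm >= tab.chord_length_mm - 1e-12).all()

    def test_determinism_bit_identical(self, grid_phantom):
        image, gt = grid_phantom
        tabs = []
        for _ in range(2):
            net = build_network(skeletonize_mask(gt.mask).pixels, px=gt.mask.pixel_size_um,
                                mask_bool=gt.mask.pixels, twig=3)
            tabs.append(measure_vessels(net))
        pd.testing.assert_frame_equal(tabs[0], tabs[1])

    def test_rotation_consistency(self):
        """Rotating the skeleton raster by 90° leaves element count,
        kinds and every arc length unchanged."""
        sk = theta()
        a = measure_vessels(build_network(sk))
        b = measure_vessels(build_network(np.rot90(sk).copy()))
        assert sorted(a.kind) == sorted(b.kind)
        assert np.allclose(sorted(a.arc_length_mm), sorted(b.arc_length_mm))


class TestCuration:
    def test_empty_exclusions_identity(self):
        net = build_network(cross())
        out = apply_curation(net, {})
        assert len(out.elements) == len(net.elements)
        assert len(out.nodes) == len(net.nodes)

    def test_remove_one_arm_keeps_node(self):
        net = build_network(cross())
        first = min(e.element_id for e in net.elements)
        out = apply_curation(net, {"element_ids": [first]})
        assert sorted(e.kind for e in out.elements) == ["branch"] * 3
        assert len(out.nodes) == 1

    def test_remove_two_arms_merges_remainder(self):
        net = build_network(cross())
        ids = sorted(e.element_id for e in net.elements)[:2]
        out = apply_curation(net, {"element_ids": ids})
        assert len(out.elements) == 1
        assert out.elements[0].kind == "isolated"
        assert len(out.nodes) == 0
        assert out.curation_removed == ids

    def test_unknown_id_warns_and_skips(self):
        net = build_network(cross())
        with pytest.warns(UserWarning, match="unknown element id"):
            out = apply_curation(net, {"element_ids": [9999]})
        assert len(out.elements) == 4

    def test_polygon_removes_majority_covered_element(self):
        sk = np.zeros((40, 100), bool)
        sk[10, :] = True
        sk[30, :] = True
        net = build_network(sk)
        poly = [[5, -1], [5, 100], [15, 100], [15, -1]]  # covers the row-10 line
        out = apply_curation(net, {"polygons": [poly]})
        assert len(out.elements) == 1
        assert out.elements[0].path[0, 0] == 30

    def test_curation_file_roundtrip(self, tmp_path):
        net = build_network(cross())
        first = min(e.element_id for e in net.elements)
        f = tmp_path / "cur.yaml"
        f.write_text(f"element_ids: [{first}]\n")
        out = apply_curation(net, f)
        assert len(out.elements) == 3
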