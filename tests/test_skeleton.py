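"""Centerline extraction and the 3D remodeling indices."""

import numpy as np
import pytest

from pulmovasc.density import binarize_volume
from pulmovasc.skeleton import (
    angiogenesis_index,
    compute_remodeling_indices,
    elongation_index,
    measure_lung_circumference,
    neovessel_length,
    skeletonize_mask,
)
from pulmovasc.synthdata import (
    SynthParams,
    generate_vessel_tree,
    make_cylinder_volume,
    rasterize_tree,
)
from pulmovasc.types import EllipsoidBoundary, VesselTree

from conftest import NOISE_FREE, make_zero_noise


def _zero_noise_pair(seed: int, n_sprouts: int, sprout_len=45.0):
    """(post volume, baseline mask, tree with ground truth)."""
    post_p = make_zero_noise("hx", seed, n_sprouts=n_sprouts,
                             sprout_length_mean=sprout_len, sprout_length_sd=0.0)
    tree = generate_vessel_tree(post_p)
    post = rasterize_tree(tree, post_p, "EC")
    base_p = make_zero_noise("hx", seed, n_sprouts=0)
    base = rasterize_tree(generate_vessel_tree(base_p), base_p, "EC")
    return post, base.voxels > 1, tree


class TestSkeletonize:
    def test_straight_tube_length_recovered(self, clean_tube_params):
        """Oracle: the generated tube's 200 um length, within 2 voxel
        diagonals."""
        p = clean_tube_params
        diag = 2 * np.linalg.norm(p.spacing)
        for r in (5.0, 10.0):
            vol = make_cylinder_volume(r, 200.0, p.spacing, p.volume_shape, axis=0)
            skel = skeletonize_mask(vol.voxels > 1, p.spacing)
            assert skel.total_length() == pytest.approx(200.0, abs=diag)

    def test_tube_length_recovered_at_anisotropic_spacing(self):
        spacing = (2.2, 1.13, 1.13)
        diag = 2 * np.linalg.norm(spacing)
        vol = make_cylinder_volume(8.0, 200.0, spacing, (120, 61, 61), axis=0)
        skel = skeletonize_mask(vol.voxels > 1, spacing)
        assert skel.total_length() == pytest.approx(200.0, abs=diag)

    def test_y_tree_topology(self):
        """A Y-shaped union of three tubes: one bifurcation, three tips."""
        params = SynthParams(seed=0, volume_shape=(80, 100, 100), spacing=(2, 2, 2), **NOISE_FREE)
        y = VesselTree()
        y.add_node(0, (41, 101, 101), 6)
        y.add_node(1, (81, 101, 101), 6)
        y.add_node(2, (121, 61, 101), 5)
        y.add_node(3, (121, 141, 101), 5)
        y.add_edge(0, 1)
        y.add_edge(1, 2)
        y.add_edge(1, 3)
        skel = skeletonize_mask(rasterize_tree(y, params, "EC").voxels > 1, (2, 2, 2))
        degrees = sorted(d for _, d in skel.graph.degree())
        assert degrees == [1, 1, 1, 3]
        assert skel.n_edges == 3

    def test_branches_have_no_interior_degree_two_nodes(self, hx_scene):
        params, _, vol = hx_scene
        mask, _ = binarize_volume(vol, "otsu")
        skel = skeletonize_mask(mask, params.spacing)
        assert all(d != 2 for _, d in skel.graph.degree())

    def test_total_length_near_generator_ground_truth(self):
        """Oracle: the generator's recorded baseline + neovessel totals."""
        p = make_zero_noise("hx", 7)
        tree = generate_vessel_tree(p)
        vol = rasterize_tree(tree, p, "EC")
        skel = skeletonize_mask(vol.voxels > 1, p.spacing)
        truth = tree.total_baseline_length + tree.total_neovessel_length
        assert skel.total_length() == pytest.approx(truth, rel=0.15)

    def test_length_stable_under_resolution_doubling(self):
        """Skeleton length is a physical quantity: halving the voxel size of
        the same tree changes it by < 15%."""
        import dataclasses

        p = make_zero_noise("normoxia", 5)
        tree = generate_vessel_tree(p)
        fine = dataclasses.replace(
            p,
            spacing=tuple(s / 2 for s in p.spacing),
            volume_shape=tuple(2 * n for n in p.volume_shape),
        )
        len_normal = skeletonize_mask(
            rasterize_tree(tree, p, "EC").voxels > 1, p.spacing
        ).total_length()
        len_fine = skeletonize_mask(
            rasterize_tree(tree, fine, "EC").voxels > 1, fine.spacing
        ).total_length()
        assert len_fine == pytest.approx(len_normal, rel=0.15)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize_mask(np.zeros((5, 5, 5), bool), (1, 1, 1))


class TestNeovesselLength:
    def test_post_identical_to_baseline_yields_zero(self):
        post, base_mask, _ = _zero_noise_pair(2, 0)
        skel = skeletonize_mask(post.voxels > 1, post.spacing)
        assert neovessel_length(skel, post.voxels > 1) == pytest.approx(0.0, abs=1e-9)

    def test_empty_baseline_classifies_everything_as_new(self):
        post, _, _ = _zero_noise_pair(2, 5)
        skel = skeletonize_mask(post.voxels > 1, post.spacing)
        total = skel.total_length()
        assert neovessel_length(skel, np.zeros(post.shape, bool)) == pytest.approx(total)

    def test_ten_sprouts_of_100um_recovered_within_15_percent(self):
        # lung large enough that 100 um sprouts fit its periphery
        big = dict(volume_shape=(112, 224, 224))
        post_p = make_zero_noise("hx", 2, n_sprouts=10, sprout_length_mean=100.0,
                                 sprout_length_sd=0.0, **big)
        tree = generate_vessel_tree(post_p)
        post = rasterize_tree(tree, post_p, "EC")
        base_p = make_zero_noise("hx", 2, n_sprouts=0, **big)
        base_mask = rasterize_tree(generate_vessel_tree(base_p), base_p, "EC").voxels > 1
        skel = skeletonize_mask(post.voxels > 1, post.spacing)
        est = neovessel_length(skel, base_mask)
        assert tree.total_neovessel_length == pytest.approx(1000.0)
        assert est == pytest.approx(1000.0, rel=0.15)

    def test_partition_into_new_and_preexisting_is_exact(self):
        post, base_mask, _ = _zero_noise_pair(3, 10)
        skel = skeletonize_mask(post.voxels > 1, post.spacing)
        neovessel_length(skel, base_mask)
        for _, _, d in skel.graph.edges(data=True):
            assert d["neovessel_length"] + d["baseline_length"] == pytest.approx(
                d["length"], abs=1e-9
            )

    def test_shape_mismatch_rejected(self):
        post, _, _ = _zero_noise_pair(2, 0)
        skel = skeletonize_mask(post.voxels > 1, post.spacing)
        with pytest.raises(ValueError, match="shape"):
            neovessel_length(skel, np.zeros((3, 3, 3), bool))

    def test_recovery_monotone_in_sprout_count(self):
        ests, truths = [], []
        for n in (0, 5, 10, 20):
            post, base_mask, tree = _zero_noise_pair(4, n)
            skel = skeletonize_mask(post.voxels > 1, post.spacing)
            ests.append(neovessel_length(skel, base_mask))
            truths.append(tree.total_neovessel_length)
        assert all(a < b for a, b in zip(ests, ests[1:]))
        for est, truth in zip(ests[1:], truths[1:]):
            assert est == pytest.approx(truth, rel=0.20)


class TestCircumference:
    def test_circle_mask_matches_analytic_perimeter(self):
        yy, xx = np.mgrid[:520, :520]
        disk = (yy - 260.0) ** 2 + (xx - 260.0) ** 2 <= 250.0**2
        # radius 250 px at 2 um/px = 500 um
        assert measure_lung_circumference(disk, 2.0) == pytest.approx(
            2 * np.pi * 500.0, rel=0.02
        )

    def test_square_mask_perimeter(self):
        sq = np.zeros((120, 120), bool)
        sq[10:110, 10:110] = True
        assert measure_lung_circumference(sq, 1.0) == pytest.approx(400.0, rel=0.02)

    def test_ellipse_matches_arc_length_quadrature(self):
        """Oracle: numerical integration of the ellipse arc length."""
        boundary = EllipsoidBoundary((50, 300, 500), (40, 300, 500))
        theta = np.linspace(0, 2 * np.pi, 200001)
        ref = np.trapezoid(np.hypot(300 * np.sin(theta), 500 * np.cos(theta)), theta)
        assert measure_lung_circumference(boundary) == pytest.approx(ref, rel=1e-4)
        # and the rasterized route agrees with the analytic one
        mask = boundary.mid_axial_mask(2.0)
        assert measure_lung_circumference(mask, 2.0) == pytest.approx(ref, rel=0.02)

    def test_open_contour_rejected(self):
        half = np.zeros((50, 50), bool)
        half[:, :30] = True  # region touches the image edge: no closed outline
        with pytest.raises(ValueError):
            measure_lung_circumference(half, 1.0)


class TestIndices:
    def test_angiogenesis_index_is_the_plain_ratio(self):
        assert angiogenesis_index(0.0, 4000.0) == 0.0
        assert angiogenesis_index(1000.0, 5000.0) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            angiogenesis_index(10.0, 0.0)

    def test_angiogenesis_index_scale_invariant(self):
        for s in (0.5, 3.0, 17.0):
            assert angiogenesis_index(s * 1000.0, s * 5000.0) == pytest.approx(0.2)

    def test_elongation_zero_when_all_termini_at_hilum(self):
        b = EllipsoidBoundary((0, 0, 0), (100, 100, 100))
        t = VesselTree(boundary=b, hilum=b.hilum)
        t.add_node(0, b.hilum, 5)
        t.add_node(1, b.hilum, 5)
        t.add_edge(0, 1, length=0.0)
        assert elongation_index(t) == 0.0

    def test_single_branch_reaching_boundary_scores_one(self):
        b = EllipsoidBoundary((0, 0, 0), (100, 100, 100))
        t = VesselTree(boundary=b, hilum=b.hilum, roots=[0])
        t.add_node(0, b.hilum, 5)
        t.add_node(1, (0.0, 100.0, 0.0), 3)  # +y surface: diametrally opposite
        t.add_edge(0, 1)
        assert elongation_index(t) == pytest.approx(1.0, abs=1e-6)

    def test_elongation_index_tracks_elongation_factor(self):
        lo = generate_vessel_tree(make_zero_noise("normoxia", 3, elongation_factor=1.0))
        hi = generate_vessel_tree(make_zero_noise("normoxia", 3, elongation_factor=1.5))
        assert elongation_index(hi) > elongation_index(lo)

    def test_hilum_outside_boundary_rejected(self):
        b = EllipsoidBoundary((0, 0, 0), (10, 10, 10))
        t = VesselTree(boundary=b, hilum=(0, 50, 0))
        t.add_node(0, (0, 5, 0), 1)
        t.add_node(1, (0, 6, 0), 1)
        t.add_edge(0, 1)
        with pytest.raises(ValueError, match="hilum"):
            elongation_index(t)

    def test_pipeline_indices_ordered_across_presets(self):
        """Hypoxia shows the strongest angiogenic response, Sugen+hypoxia a
        blunted one, normoxia none."""
        results = {}
        for name in ("normoxia", "suhx", "hx"):
            post_p = make_zero_noise(name, 8)
            tree = generate_vessel_tree(post_p)
            post = rasterize_tree(tree, post_p, "EC")
            base_p = make_zero_noise(name, 8, n_sprouts=0)
            base = rasterize_tree(generate_vessel_tree(base_p), base_p, "EC")
            results[name] = compute_remodeling_indices(
                post, base, tree.boundary, method="fixed", fixed_threshold=1
            )
        assert results["normoxia"].angiogenesis_index == pytest.approx(0.0, abs=1e-6)
        assert (
            results["hx"].angiogenesis_index
            > results["suhx"].angiogenesis_index
            > results["normoxia"].angiogenesis_index
        )
        assert results["hx"].elongation_index > results["normoxia"].elongation_index
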