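"""Morphometry: binarization, thinning, node detection, length, lacunarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from angionet.synthgrowth import GrowthParams, VascularImage, grow_network, make_fixture
from angionet.vesselquant import (
    Skeleton,
    binarize,
    default_box_sizes,
    detect_nodes,
    lacunarity,
    quantify,
    skeleton_length,
    skeletonize,
    vessel_percentage,
)

STRUCT8 = np.ones((3, 3), dtype=bool)


def thin_mask(mask: np.ndarray) -> Skeleton:
    """Wrap an already-thin boolean mask as its own skeleton."""
    img = VascularImage(mask)
    return Skeleton(mask, img)


class TestBinarize:
    def test_boolean_passthrough(self):
        img = make_fixture("cross", 21)
        assert binarize(img.mask) .mask is not None
        assert np.array_equal(binarize(img).mask, img.mask)

    def test_otsu_separates_bimodal(self):
        gray = np.full((16, 16), 10.0)
        gray[:, 8:] = 200.0
        out = binarize(gray, method="otsu")
        assert np.array_equal(out.mask, gray == 200.0)

    def test_fixed_threshold_matches_direct_count(self):
        gray = np.linspace(0, 255, 16 * 16).reshape(16, 16)
        out = binarize(gray, method="fixed", threshold=128)
        assert out.mask.sum() == (gray >= 128).sum()

    def test_constant_image_otsu_rejected(self):
        with pytest.raises(ValueError, match="[Cc]onstant"):
            binarize(np.full((16, 16), 7.0), method="otsu")

    def test_fixed_requires_threshold(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((16, 16)), method="fixed")


class TestSkeletonize:
    def test_thick_bar_thins_to_line(self):
        m = np.zeros((16, 16), dtype=bool)
        m[7:10, 2:14] = True                      # 3-px-thick horizontal bar
        sk = skeletonize(VascularImage(m))
        _, endpoints = detect_nodes(sk)
        labels, n = ndimage.label(sk.mask, structure=STRUCT8)
        assert n == 1
        assert len(endpoints) == 2
        # single-pixel wide: no pixel has more than 2 skeleton neighbours
        from angionet.vesselquant import _neighbor_counts
        nb = _neighbor_counts(sk.mask)
        assert nb[sk.mask].max() <= 2

    def test_thin_line_unchanged(self):
        img = make_fixture("line", 32)
        sk = skeletonize(img)
        assert np.array_equal(sk.mask, img.mask)

    def test_component_count_preserved_on_simulations(self):
        for s in range(25):
            img, _ = grow_network(
                GrowthParams(n_seeds=3, branch_prob=0.1, max_steps=25,
                             width=192, height=192, rng_seed=s)
            )
            sk = skeletonize(img)
            _, n_before = ndimage.label(img.mask, structure=STRUCT8)
            _, n_after = ndimage.label(sk.mask, structure=STRUCT8)
            assert n_before == n_after
            assert not (sk.mask & ~img.mask).any()


class TestVesselPercentage:
    @pytest.mark.parametrize(
        "name,expected", [("empty", 0.0), ("filled", 100.0), ("half", 50.0)]
    )
    def test_reference_fixtures(self, name, expected):
        assert vessel_percentage(make_fixture(name, 32)) == expected


class TestDetectNodes:
    @pytest.mark.parametrize(
        "name,n_junc,n_ends",
        [("line", 0, 2), ("cross", 1, 4), ("hbar", 2, 4), ("ystem", 1, 3)],
    )
    def test_fixture_hand_counts(self, name, n_junc, n_ends):
        sk = skeletonize(make_fixture(name, 21))
        junctions, endpoints = detect_nodes(sk)
        assert len(junctions) == n_junc
        assert len(endpoints) == n_ends

    def test_cross_junction_at_center(self):
        junctions, _ = detect_nodes(skeletonize(make_fixture("cross", 21)))
        assert junctions == [(10, 10)]


class TestSkeletonLength:
    def test_horizontal_line(self):
        m = np.zeros((16, 16), dtype=bool)
        m[8, 3:13] = True                       # 10 pixels
        assert skeleton_length(thin_mask(m)) == pytest.approx(9.0)

    def test_diagonal_line(self):
        m = np.zeros((16, 16), dtype=bool)
        idx = np.arange(3, 13)
        m[idx, idx] = True
        assert skeleton_length(thin_mask(m)) == pytest.approx(9 * math.sqrt(2))

    def test_cross_with_five_pixel_arms(self):
        m = np.zeros((16, 16), dtype=bool)
        m[8, 3:14] = True
        m[3:14, 8] = True                       # arms of 5 px from center
        assert skeleton_length(thin_mask(m)) == pytest.approx(20.0)

    def test_scale_multiplies(self):
        m = np.zeros((16, 16), dtype=bool)
        m[8, 3:13] = True
        img = VascularImage(m, scale=2.5)
        assert skeleton_length(Skeleton(m, img)) == pytest.approx(9.0 * 2.5)

    def test_length_bounds_euclidean_span(self):
        """Arc length >= straight-line distance between the two endpoints
        of any single-component skeleton."""
        for s in range(5):
            img, _ = grow_network(
                GrowthParams(n_seeds=1, branch_prob=0.0, max_steps=30,
                             width=192, height=192, rng_seed=s)
            )
            sk = skeletonize(img)
            _, endpoints = detect_nodes(sk)
            if len(endpoints) < 2:
                continue
            (r1, c1), (r2, c2) = endpoints[0], endpoints[-1]
            assert skeleton_length(sk) >= math.hypot(r1 - r2, c1 - c2) - 1e-9


class TestLacunarity:
    def test_filled_is_one_everywhere(self):
        curve = lacunarity(make_fixture("filled", 64), [2, 4, 8, 16], stride=1)
        assert all(lam == pytest.approx(1.0) for lam in curve.lam)

    def test_checkerboard_closed_form(self):
        # box masses at r=1 are Bernoulli(1/2): E[M^2]/E[M]^2 = 2
        curve = lacunarity(make_fixture("checkerboard", 32), [1], stride=1)
        assert curve.lam[0] == pytest.approx(2.0)

    def test_full_canvas_box_is_one(self):
        img, _ = grow_network(GrowthParams(rng_seed=2, width=128, height=128))
        curve = lacunarity(img, [128], stride=1)
        assert curve.lam[0] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lacunarity(make_fixture("empty", 32), [2])

    def test_oversized_box_rejected(self):
        with pytest.raises(ValueError):
            lacunarity(make_fixture("cross", 21), [22])

    def test_default_box_sizes_dyadic(self):
        assert default_box_sizes((64, 64)) == [2, 4, 8, 16]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_lacunarity_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < rng.uniform(0.05, 0.9)
        if not mask.any():
            mask[16, 16] = True
        curve = lacunarity(VascularImage(mask), [2, 4, 8], stride=1)
        assert all(lam >= 1.0 - 1e-12 for lam in curve.lam)


class TestQuantify:
    def test_cross_record(self):
        rec = quantify(make_fixture("cross", 33))
        assert rec.vessel_pct > 0
        assert rec.n_junctions == 1
        assert rec.n_endpoints == 4
        assert rec.avg_length == pytest.approx(rec.total_length / 4)
        assert rec.junction_density == pytest.approx(100.0 / rec.total_length)

    def test_empty_record(self):
        rec = quantify(make_fixture("empty", 32))
        assert rec.vessel_pct == 0
        assert rec.n_junctions == rec.n_endpoints == 0
        assert rec.total_length == rec.avg_length == 0
        assert math.isnan(rec.mean_lacunarity)

    def test_junction_count_tracks_ground_truth(self):
        """Detected junctions within +-10% of ground-truth branch events,
        averaged over replicates of the validation condition."""
        from dataclasses import replace
        from angionet.synthgrowth import EXTRACTION_VALIDATION

        det, gt_n = [], []
        for s in range(15):
            img, gt = grow_network(replace(EXTRACTION_VALIDATION, rng_seed=s))
            junctions, _ = detect_nodes(skeletonize(img))
            det.append(len(junctions))
            gt_n.append(len(gt.branch_points))
        ratio = np.mean(det) / np.mean(gt_n)
        assert 0.9 <= ratio <= 1.1
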