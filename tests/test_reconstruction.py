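import numpy as np
import pytest
from scipy.ndimage import binary_dilation, binary_erosion
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from ribsep.edge_lists import BonePair, EdgeList
from ribsep.metrics import bsr
from ribsep.phantom import PhantomConfig, generate_phantom
from ribsep.profile_geometry import reverse_sample, sample_profiles
from ribsep.reconstruction import (
    SuppressionConfig,
    assemble_preliminary_bone,
    edge_reprocess,
    make_bone_region_mask,
    poisson_correct,
    suppress_bones_traditional,
)


def parallel_pair(r_up=10.0, r_lo=20.0, c0=5, c1=45, cat="anterior"):
    up = EdgeList(np.array([[r_up, float(c)] for c in range(c0, c1)]), cat, "upper")
    lo = EdgeList(np.array([[r_lo, float(c)] for c in range(c0, c1)]), cat, "lower")
    return BonePair(up, lo)


class TestAssemble:
    def test_single_bone_identity(self, rng):
        img = rng.random((64, 64))
        profile, smap = sample_profiles(img, parallel_pair())
        single = reverse_sample(profile, smap, img.shape)
        total = assemble_preliminary_bone([(profile, smap)], img.shape)
        np.testing.assert_array_equal(single, total)

    def test_disjoint_bones_sum_is_union(self, rng):
        img = rng.random((64, 64))
        pa = parallel_pair(10.0, 20.0)
        pb = parallel_pair(40.0, 50.0)
        parts = []
        for pair in (pa, pb):
            profile, smap = sample_profiles(img, pair)
            parts.append((profile, smap))
        total = assemble_preliminary_bone(parts, img.shape)
        individual = [reverse_sample(p, m, img.shape) for p, m in parts]
        np.testing.assert_array_equal(total, individual[0] + individual[1])
        assert not ((individual[0] != 0) & (individual[1] != 0)).any()

    def test_overlapping_bones_add(self, rng):
        # [DERIVED] overlap pixels equal the sum of individual contributions
        img = rng.random((64, 64))
        pa = parallel_pair(10.0, 20.0)
        pb = parallel_pair(15.0, 25.0)  # overlaps pa
        parts = [sample_profiles(img, p) for p in (pa, pb)]
        total = assemble_preliminary_bone(parts, img.shape)
        individual = [reverse_sample(p, m, img.shape) for p, m in parts]
        np.testing.assert_allclose(total, individual[0] + individual[1], atol=1e-12)
        assert ((individual[0] != 0) & (individual[1] != 0)).any()


class TestRegionMask:
    def test_parallel_band(self):
        pair = parallel_pair(10.0, 20.0, 5, 45)
        mask = make_bone_region_mask([pair], (64, 64))
        raw = np.zeros((64, 64), dtype=bool)
        rr, cc = draw_polygon(
            [10.0, 10.0, 20.0, 20.0], [5.0, 44.0, 44.0, 5.0], shape=(64, 64)
        )
        raw[rr, cc] = True
        expected = binary_dilation(raw, structure=np.ones((3, 3), dtype=bool))
        np.testing.assert_array_equal(mask, expected)

    def test_empty(self):
        assert not make_bone_region_mask([], (32, 32)).any()

    def test_dilation_monotone(self, default_scene):
        mask = make_bone_region_mask(default_scene.pairs, default_scene.cxr.shape)
        raw = np.zeros_like(mask)
        for p in default_scene.pairs:
            poly = np.vstack([p.upper.points, p.lower.points[::-1]])
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=raw.shape)
            raw[rr, cc] = True
        assert mask.sum() >= raw.sum()
        assert (mask | raw == mask).all()


def dense_poisson_oracle(i_b0, region):
    """Independent dense solve of the masked-gradient Poisson system."""
    i_b0 = np.pad(np.asarray(i_b0, dtype=float), 1)
    region = np.pad(np.asarray(region, dtype=bool), 1)
    rows, cols = i_b0.shape
    pts = [tuple(p) for p in np.argwhere(region)]
    index = {p: k for k, p in enumerate(pts)}
    n = len(pts)
    A = np.zeros((n, n))
    b = np.zeros(n)
    for (r, c), k in index.items():
        A[k, k] = -4.0
        rhs = 0.0
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            q = (r + dr, c + dc)
            if q in index:
                A[k, index[q]] = 1.0
                rhs += i_b0[q] - i_b0[r, c]
        b[k] = rhs
    x = np.linalg.solve(A, b)
    out = np.zeros(i_b0.shape)
    for p, k in index.items():
        out[p] = x[k]
    return out[1:-1, 1:-1]


class TestPoisson:
    def test_recovers_field_up_to_constant(self):
        # [DERIVED] I_B0 = B + c with B strictly inside the region -> B
        rng = np.random.default_rng(0)
        shape = (32, 32)
        region = np.zeros(shape, dtype=bool)
        region[8:24, 6:26] = True
        b_field = np.zeros(shape)
        rr, cc = np.mgrid[0:32, 0:32]
        bump = np.exp(-(((rr - 16) / 3.0) ** 2 + ((cc - 16) / 5.0) ** 2))
        bump[bump < 1e-10] = 0.0
        b_field[10:22, 8:24] = bump[10:22, 8:24]
        i_b0 = b_field + 0.37
        out = poisson_correct(i_b0, region)
        np.testing.assert_allclose(out, b_field, atol=1e-6)

    def test_zero_gradient_gives_zero(self):
        region = np.zeros((16, 16), dtype=bool)
        region[4:12, 4:12] = True
        out = poisson_correct(np.full((16, 16), 0.5), region)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_nonbone_exactly_zero(self, rng):
        region = np.zeros((24, 24), dtype=bool)
        region[6:18, 4:20] = True
        out = poisson_correct(rng.random((24, 24)), region)
        assert np.all(out[~region] == 0.0)

    def test_empty_region(self):
        out = poisson_correct(np.ones((8, 8)), np.zeros((8, 8), dtype=bool))
        assert not out.any()

    def test_region_touching_border_is_padded(self, rng):
        region = np.zeros((16, 16), dtype=bool)
        region[0:8, 0:8] = True  # touches two borders
        out = poisson_correct(rng.random((16, 16)), region)
        assert out.shape == (16, 16)
        assert np.all(out[~region] == 0.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_dense_oracle_equivalence(self, seed):
        rng = np.random.default_rng(seed)
        size = int(rng.integers(8, 33))
        region = np.zeros((size, size), dtype=bool)
        r0, c0 = rng.integers(1, size // 2, size=2)
        region[r0 : r0 + size // 2, c0 : c0 + size // 2] = True
        region &= rng.random((size, size)) < 0.9  # ragged region
        img = rng.random((size, size))
        np.testing.assert_allclose(
            poisson_correct(img, region), dense_poisson_oracle(img, region), atol=1e-8
        )


class TestEdgeReprocess:
    def test_perfect_ib1_near_zero_residual(self):
        # [DERIVED] feeding the ground-truth bone as I_B1 leaves ~no residual
        s = generate_phantom(PhantomConfig(seed=4))
        cfg = SuppressionConfig.for_phantom()
        residual, bone_final = edge_reprocess(s.cxr, s.bone, s.pairs, cfg)
        assert np.abs(residual).max() < 1e-3
        np.testing.assert_array_equal(bone_final, s.bone + residual)

    def test_residual_support_near_edges(self, default_scene):
        s = default_scene
        cfg = SuppressionConfig.for_phantom()
        residual, _ = edge_reprocess(s.cxr, s.bone, s.pairs, cfg)
        pts = np.vstack([p.points for pair in s.pairs for p in (pair.upper, pair.lower)])
        tree = cKDTree(pts)
        nz = np.argwhere(residual != 0)
        if len(nz):
            d, _ = tree.query(nz)
            assert d.max() <= cfg.edge_each_side + 2

    def test_additivity_bitwise(self, default_scene):
        s = default_scene
        cfg = SuppressionConfig.for_phantom()
        residual, bone_final = edge_reprocess(s.cxr, s.bone, s.pairs, cfg)
        np.testing.assert_array_equal(bone_final, s.bone + residual)


class TestSuppress:
    def test_no_bones_identity(self):
        img = np.random.default_rng(0).random((64, 64))
        res = suppress_bones_traditional(img, [], SuppressionConfig())
        np.testing.assert_array_equal(res.soft_final, img)
        assert not res.bone_final.any()

    def test_end_to_end_quality(self):
        # noise-free phantom with exact edges: near-complete suppression
        s = generate_phantom(PhantomConfig(seed=3))
        res = suppress_bones_traditional(s.cxr, s.pairs, SuppressionConfig.for_phantom())
        ob = binary_erosion(s.bone > 1e-9, structure=np.ones((3, 3), dtype=bool))
        assert bsr(s.soft, res.soft_final, s.bone, ob) >= 0.95

    def test_invariants(self, default_scene):
        s = default_scene
        res = suppress_bones_traditional(s.cxr, s.pairs, SuppressionConfig.for_phantom())
        # conservation, bitwise
        np.testing.assert_array_equal(res.soft_final, s.cxr - res.bone_final)
        # zero nonbone background of I_B1
        assert np.all(res.bone_corrected[~res.bone_region_mask] == 0.0)
        # bone_final = bone_corrected + residual_edges
        np.testing.assert_array_equal(
            res.bone_final, res.bone_corrected + res.residual_edges
        )

    def test_pca_d_mode_from_masks(self, default_scene):
        s = default_scene
        res = suppress_bones_traditional(
            s.cxr, s.edge_masks, SuppressionConfig.for_phantom()
        )
        assert len(res.per_bone) == len(s.pairs)
        ob = binary_erosion(s.bone > 1e-9, structure=np.ones((3, 3), dtype=bool))
        assert bsr(s.soft, res.soft_final, s.bone, ob) >= 0.85
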