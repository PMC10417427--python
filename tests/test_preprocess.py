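"""Resampling, normalisation, patch planning/assembly, augmentation, slabs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csrseg import preprocess as pp
from csrseg.grids import LabelVolume, VolumeGrid

from conftest import make_labels, make_volume


class TestResampleInplane:
    def test_identity_resample(self, rng):
        v = make_volume(rng.random((32, 32, 4)))
        out = pp.resample_inplane(v, (32, 32), "linear")
        assert np.array_equal(out.values, v.values)
        assert out.spacing == v.spacing

    def test_constant_invariance(self):
        v = make_volume(np.full((16, 16, 3), 0.37), spacing=(2, 2, 5))
        out = pp.resample_inplane(v, (32, 32), "linear")
        assert out.values.shape == (32, 32, 3)
        assert np.allclose(out.values, 0.37, atol=1e-6)
        assert out.spacing == (1.0, 1.0, 5.0)

    def test_nearest_introduces_no_new_labels(self, rng):
        lab = make_labels(rng.choice([0, 1, 3], size=(20, 20, 2)))
        out = pp.resample_inplane(lab, (31, 17), "nearest")
        assert set(np.unique(out.values)) <= {0, 1, 3}

    def test_linear_on_labels_rejected(self):
        lab = make_labels(np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            pp.resample_inplane(lab, (8, 8), "linear")


class TestClipNormalize:
    def test_range_contract(self, rng):
        v = make_volume(rng.random((12, 12, 6)))
        out = pp.clip_normalize(v)
        assert out.values.min() == 0.0
        assert out.values.max() == 1.0

    def test_constant_volume_returns_zeros(self):
        v = make_volume(np.full((6, 6, 2), 0.4))
        out = pp.clip_normalize(v)
        assert np.all(out.values == 0.0)

    def test_percentile_cuts_match_sort_oracle(self):
        vals = np.arange(1, 1001, dtype=np.float32).reshape(10, 10, 10)
        v = make_volume(vals)
        out = pp.clip_normalize(v, 0.5, 99.5)
        ranked = np.sort(vals.ravel())
        lo_oracle, hi_oracle = ranked[4], ranked[994]  # ~0.5% / 99.5% ranks
        # voxels at/below the low cut map to 0, at/above the high cut to 1
        assert np.all(out.values[vals <= lo_oracle] == 0.0)
        assert np.all(out.values[vals >= hi_oracle + 1] == 1.0)
        # affine in between: spot-check the midpoint
        mid = out.values[vals == 500][0]
        assert mid == pytest.approx(0.5, abs=0.01)

    def test_monotone_on_unclipped_voxels(self, rng):
        v = make_volume(rng.random((10, 10, 4)))
        out = pp.clip_normalize(v, 5, 95)
        a, b = v.values.ravel(), out.values.ravel()
        order = np.argsort(a)
        assert np.all(np.diff(b[order]) >= -1e-7)

    def test_masked_percentiles(self):
        vals = np.zeros((10, 10, 2), np.float32)
        vals[5:, :, :] = np.linspace(0.2, 0.8, 100).reshape(5, 10, 2)
        mask = np.zeros_like(vals, dtype=np.int16)
        mask[5:] = 1
        out = pp.clip_normalize(make_volume(vals), mask=make_labels(mask))
        # outside-mask zeros clamp to the low cut -> 0
        assert np.all(out.values[:5] == 0.0)


class TestPlanPatches:
    def test_snapped_grid_positions(self):
        specs = pp.plan_patches((512, 192, 192), (192, 192, 192), 0.5)
        xs = sorted({s.start[0] for s in specs})
        assert xs == [0, 96, 192, 288, 320]

    def test_single_patch_when_equal(self):
        specs = pp.plan_patches((64, 64, 8), (64, 64, 8))
        assert len(specs) == 1 and specs[0].start == (0, 0, 0)

    def test_nonpositive_patch_rejected(self):
        with pytest.raises(ValueError):
            pp.plan_patches((64, 64, 8), (0, 64, 8))

    @given(st.integers(10, 120), st.integers(3, 60), st.floats(0, 0.75))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_full_coverage(self, n, p, overlap):
        """Every voxel is covered by at least one patch (brute force)."""
        specs = pp.plan_patches((n, 4, 4), (min(p, n), 4, 4), overlap)
        covered = np.zeros(n, bool)
        for s in specs:
            covered[s.start[0]:s.start[0] + s.size[0]] = True
        assert covered.all()


class TestAssemble:
    def test_identity_reconstruction_both_weightings(self, rng):
        vol = rng.random((50, 40, 12)).astype(np.float32)
        for weighting in ("uniform", "gaussian"):
            specs = pp.plan_patches(vol.shape, (24, 16, 8), 0.5)
            outs = [(s, pp.extract_patch(vol, s)) for s in specs]
            rec = pp.assemble(outs, vol.shape, weighting)
            assert np.allclose(rec, vol, atol=1e-6)

    def test_single_full_patch(self, rng):
        vol = rng.random((8, 8, 4)).astype(np.float32)
        spec = pp.PatchSpec((0, 0, 0), vol.shape)
        assert np.allclose(pp.assemble([(spec, vol)], vol.shape), vol)

    def test_overlap_uniform_average(self):
        """Two overlapping constant patches 0 and 1: the overlap averages 0.5."""
        a = pp.PatchSpec((0, 0, 0), (6, 4, 1))
        b = pp.PatchSpec((4, 0, 0), (6, 4, 1))
        rec = pp.assemble([(a, np.zeros((6, 4, 1))), (b, np.ones((6, 4, 1)))],
                          (10, 4, 1), "uniform")
        assert np.allclose(rec[:4], 0.0)
        assert np.allclose(rec[4:6], 0.5)
        assert np.allclose(rec[6:], 1.0)

    def test_shape_mismatch_rejected(self):
        spec = pp.PatchSpec((0, 0, 0), (4, 4, 2))
        with pytest.raises(ValueError):
            pp.assemble([(spec, np.zeros((3, 4, 2)))], (4, 4, 2))


class TestAugment:
    def _pair(self, rng, shape=(16, 16, 6)):
        img = make_volume(rng.random(shape))
        lab = np.zeros(shape, np.int16)
        lab[4:9, 4:9, 2:4] = 1
        return img, make_labels(lab)

    def test_identity_params(self, rng):
        img, lab = self._pair(rng)
        params = pp.AugmentParams(flip_prob_per_axis=0.0, max_rotation_deg=0.0,
                                  intensity_scale_range=(1.0, 1.0))
        oi, ol = pp.augment(img, lab, params)
        assert np.array_equal(oi.values, img.values)
        assert np.array_equal(ol.values, lab.values)

    def test_label_set_preserved(self, rng):
        img, lab = self._pair(rng)
        for seed in range(5):
            _, ol = pp.augment(img, lab, pp.AugmentParams(seed=seed))
            assert set(np.unique(ol.values)) <= set(np.unique(lab.values))

    def test_flip_involution(self, rng):
        img, lab = self._pair(rng)
        params = pp.AugmentParams(flip_prob_per_axis=1.0, max_rotation_deg=0.0,
                                  intensity_scale_range=(1.0, 1.0))
        oi, _ = pp.augment(*pp.augment(img, lab, params), params)
        assert np.allclose(oi.values, img.values)

    def test_deterministic_under_seed(self, rng):
        img, lab = self._pair(rng)
        p = pp.AugmentParams(seed=3)
        a, _ = pp.augment(img, lab, p)
        b, _ = pp.augment(img, lab, p)
        assert np.array_equal(a.values, b.values)

    def test_flips_preserve_foreground_count(self, rng):
        img, lab = self._pair(rng)
        params = pp.AugmentParams(max_rotation_deg=0.0, seed=1)
        _, ol = pp.augment(img, lab, params)
        assert (ol.values > 0).sum() == (lab.values > 0).sum()


class TestSlabs:
    def test_edge_replication(self, rng):
        v = make_volume(rng.random((6, 6, 10)))
        slabs = pp.make_2p5d_slabs(v, k=5)
        assert len(slabs) == 10
        slab0, c0 = slabs[0]
        assert c0 == 0
        for ch, z in zip(range(5), (0, 0, 0, 1, 2)):
            assert np.array_equal(slab0[ch], v.values[:, :, z])

    def test_middle_slab_exact(self, rng):
        v = make_volume(rng.random((4, 4, 9)))
        slab, c = pp.make_2p5d_slabs(v, k=5)[4]
        for ch, z in zip(range(5), range(2, 7)):
            assert np.array_equal(slab[ch], v.values[:, :, z])

    def test_center_channels_reconstruct_volume(self, rng):
        v = make_volume(rng.random((5, 5, 7)))
        rec = np.stack([s[2] for s, _ in pp.make_2p5d_slabs(v, k=5)], axis=2)
        assert np.array_equal(rec, v.values)

    def test_even_k_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.make_2p5d_slabs(make_volume(np.zeros((4, 4, 4))), k=4)
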