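"""Sliding-window planning, Gaussian blending, and mask restriction."""

import numpy as np
import pytest

from stagedseg.caseio import CaseRecord, LabelMap, Volume3D
from stagedseg.infer import (
    enumerate_patches,
    gaussian_kernel,
    plan_windows,
    sliding_window_predict,
)
from stagedseg.model import NetConfig, build_network
from stagedseg.sampling import RECIPE_IMAGE_ONLY
from tests.conftest import make_labelmap


def _enumerate_axis_bruteforce(n, p, overlap):
    """Oracle: all start positions spaced by ceil(p*(1-overlap)), clipped final."""
    import math

    step = max(1, math.ceil(p * (1 - overlap)))
    starts = sorted({min(s, n - p) for s in range(0, n, step) if s <= n - p} | {n - p})
    return starts


class TestEnumeratePatches:
    @pytest.mark.parametrize(
        "n,p,overlap", [(64, 32, 0.5), (64, 32, 0.0), (48, 32, 0.5), (100, 32, 0.25), (33, 32, 0.5)]
    )
    def test_axis_starts_match_bruteforce(self, n, p, overlap):
        specs = enumerate_patches((n, n, n), (p, p, p), overlap)
        want = _enumerate_axis_bruteforce(n, p, overlap)
        got = sorted({s.origin[0] for s in specs})
        assert got == want

    def test_64_grid_32_patch_half_overlap_is_27_patches(self):
        specs = enumerate_patches((64, 64, 64), (32, 32, 32), 0.5)
        assert len(specs) == 27
        assert sorted({s.origin[0] for s in specs}) == [0, 16, 32]

    def test_zero_overlap_tiling(self):
        specs = enumerate_patches((64, 64, 64), (32, 32, 32), 0.0)
        assert sorted({s.origin[0] for s in specs}) == [0, 32]
        assert len(specs) == 8

    def test_full_coverage_unmasked(self):
        cov = np.zeros((48, 40, 36), dtype=int)
        for s in enumerate_patches((48, 40, 36), (16, 16, 16), 0.5):
            cov[s.slices()] += 1
        assert (cov > 0).all()

    def test_corner_roi_keeps_only_corner_patches(self):
        roi = np.zeros((64, 64, 64), dtype=np.int16)
        roi[0, 0, 0] = 1
        specs = enumerate_patches((64, 64, 64), (32, 32, 32), 0.5, roi=make_labelmap(roi))
        assert len(specs) == 1
        assert specs[0].origin == (0, 0, 0)

    def test_roi_patches_cover_all_roi_voxels(self, mid_case):
        roi = mid_case.prior_mask
        specs = enumerate_patches(mid_case.image.shape, (32, 32, 32), 0.5, roi=roi)
        cov = np.zeros(mid_case.image.shape, dtype=bool)
        for s in specs:
            cov[s.slices()] = True
        assert cov[roi.labels > 0].all()

    def test_empty_roi_raises(self):
        with pytest.raises(ValueError, match="empty"):
            enumerate_patches((32, 32, 32), (16, 16, 16), 0.5, roi=np.zeros((32, 32, 32)))

    def test_oversized_patch_rejected(self):
        with pytest.raises(ValueError, match="pad upstream"):
            enumerate_patches((16, 16, 16), (32, 32, 32), 0.5)


class TestGaussianKernel:
    def test_center_is_one_and_positive(self):
        k = gaussian_kernel((16, 16, 16))
        assert k.max() == 1.0
        assert (k > 0).all()
        c = (np.array(k.shape) - 1) // 2
        assert k[c[0], c[1], c[2]] == pytest.approx(1.0, abs=0.05)

    def test_mirror_symmetry(self):
        k = gaussian_kernel((8, 12, 6))
        np.testing.assert_allclose(k, k[::-1, ::-1, ::-1], atol=1e-6)

    def test_large_sigma_uniform_limit(self):
        k = gaussian_kernel((16, 16, 16), sigma_scale=100.0)
        assert k.min() > 0.999


class _ConstantNet:
    """Predicts fixed logits everywhere, any input."""

    def __init__(self, logits):
        self.logits = np.asarray(logits, dtype=np.float32)
        self.cfg = NetConfig(in_channels=1)

    def predict_proba(self, x):
        n, _, d, h, w = x.shape
        e = np.exp(self.logits - self.logits.max())
        p = e / e.sum()
        return np.broadcast_to(p.reshape(1, -1, 1, 1, 1), (n, 3, d, h, w)).copy()


def _phantom_case_and_net(mid_case, seed=0):
    net = build_network(NetConfig(in_channels=1), seed=seed)
    return mid_case, net


class TestSlidingWindowPredict:
    def test_constant_predictor_uniform_labels(self, mid_case):
        net = _ConstantNet([0.0, 3.0, 0.0])
        out = sliding_window_predict(net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32))
        assert (out.labels == 1).all()

    def test_constant_predictor_masked_background_elsewhere(self, mid_case):
        net = _ConstantNet([0.0, 3.0, 0.0])
        roi = mid_case.prior_mask
        out, proba, covered = sliding_window_predict(
            net, mid_case, RECIPE_IMAGE_ONLY, patch=(16, 16, 16), roi=roi, return_proba=True
        )
        assert (out.labels[covered] == 1).all()
        assert (out.labels[~covered] == 0).all()
        assert not covered.all()  # restriction is real for a small ROI

    def test_blended_probabilities_sum_to_one(self, mid_case):
        net = build_network(NetConfig(in_channels=1), seed=3)
        _, proba, covered = sliding_window_predict(
            net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32), return_proba=True
        )
        assert covered.all()
        np.testing.assert_allclose(proba.sum(axis=0), 1.0, atol=1e-6)

    def test_masked_equals_unmasked_on_roi_voxels(self, mid_case):
        """Every window containing an ROI voxel is kept, so blending there is identical."""
        net = build_network(NetConfig(in_channels=1), seed=5)
        roi = mid_case.prior_mask
        full, p_full, _ = sliding_window_predict(
            net, mid_case, RECIPE_IMAGE_ONLY, patch=(16, 16, 16), return_proba=True
        )
        masked, p_masked, covered = sliding_window_predict(
            net, mid_case, RECIPE_IMAGE_ONLY, patch=(16, 16, 16), roi=roi, return_proba=True
        )
        m = roi.labels > 0
        np.testing.assert_allclose(p_masked[:, m], p_full[:, m], atol=1e-6)
        np.testing.assert_array_equal(masked.labels[m], full.labels[m])

    def test_whole_grid_roi_equals_unmasked_exactly(self, mid_case):
        net = build_network(NetConfig(in_channels=1), seed=5)
        roi = make_labelmap(
            np.ones(mid_case.image.shape, dtype=np.int16), mid_case.image.spacing
        )
        full = sliding_window_predict(net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32))
        masked = sliding_window_predict(
            net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32), roi=roi
        )
        np.testing.assert_array_equal(masked.labels, full.labels)

    def test_empty_roi_falls_back_with_warning(self, mid_case, caplog):
        net = _ConstantNet([3.0, 0.0, 0.0])
        empty = make_labelmap(
            np.zeros(mid_case.image.shape, dtype=np.int16), mid_case.image.spacing
        )
        with caplog.at_level("WARNING"):
            out = sliding_window_predict(
                net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32), roi=empty
            )
        assert any("unmasked" in r.message for r in caplog.records)
        assert out.labels.shape == mid_case.image.shape

    def test_flip_equivariance_with_equivariant_predictor(self, mid_case):
        """Flipping the volume and un-flipping the output is an identity for a
        voxel-wise (hence trivially flip-equivariant) predictor."""

        class VoxelwiseNet:
            cfg = NetConfig(in_channels=1)

            def predict_proba(self, x):
                img = x[:, 0]
                logits = np.stack([-img, img, np.zeros_like(img)], axis=1)
                e = np.exp(logits - logits.max(axis=1, keepdims=True))
                return e / e.sum(axis=1, keepdims=True)

        net = VoxelwiseNet()
        out = sliding_window_predict(net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32))
        flipped_case = CaseRecord(
            "flip",
            Volume3D(mid_case.image.data[::-1].copy(), mid_case.image.spacing),
            LabelMap(mid_case.reference.labels[::-1].copy(), mid_case.image.spacing),
        )
        out_f = sliding_window_predict(net, flipped_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32))
        np.testing.assert_array_equal(out_f.labels[::-1], out.labels)

    def test_channel_mismatch_rejected(self, mid_case):
        net = build_network(NetConfig(in_channels=3), seed=0)
        with pytest.raises(ValueError, match="channels"):
            sliding_window_predict(net, mid_case, RECIPE_IMAGE_ONLY, patch=(32, 32, 32))
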