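"""Network construction, composite loss, gradients, and backend agreement."""

import numpy as np
import pytest

import stagedseg._tensor as T
from stagedseg.model import (
    LossWeights,
    NetConfig,
    build_network,
    composite_loss,
    one_hot,
    soft_dice_per_class,
    softmax,
)


def _loss_bruteforce(logits, target, dice_w=1.0, ce_w=1.0, eps=1e-5):
    """Direct evaluation of the stated compound formula on one level."""
    z = np.asarray(logits, dtype=np.float64)
    e = np.exp(z - z.max(axis=1, keepdims=True))
    p = e / e.sum(axis=1, keepdims=True)
    k = z.shape[1]
    g = np.stack([(target == c).astype(np.float64) for c in range(k)], axis=1)
    ce = -np.log(np.maximum((p * g).sum(axis=1), 1e-12)).mean()
    dices = []
    for c in range(1, k):
        num = (p[:, c] * g[:, c]).sum()
        den = p[:, c].sum() + g[:, c].sum()
        dices.append(2 * num / (den + eps))
    return dice_w * (1 - np.mean(dices)) + ce_w * ce


class TestBuildNetwork:
    def test_shape_contract(self):
        cfg = NetConfig(n_stages=3, base_channels=4, in_channels=1, ds_levels=2)
        net = build_network(cfg, seed=0)
        outs = net.forward(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
        assert outs[0].data.shape == (1, 3, 16, 16, 16)
        assert outs[1].data.shape == (1, 3, 8, 8, 8)

    def test_three_channel_input_accepted(self):
        cfg = NetConfig(in_channels=3)
        net = build_network(cfg, seed=0)
        out = net.forward(np.zeros((1, 3, 8, 8, 8), dtype=np.float32))
        assert out[0].data.shape == (1, 3, 8, 8, 8)

    def test_parameter_count_closed_form(self):
        """Layer-by-layer enumeration of the documented two-stage architecture.

        channels (4, 8), kernel 3^3, in=1, classes=3:
          encoder block 0 (1->4): unit1 conv 1*4*27+4 + IN 4+4, conv2 4*4*27+4
            + IN 4+4, 1x1 projection 1*4+4
          downsample unit (4->8): conv 4*8*27+8 + IN 8+8
          encoder block 1 (8->8): two convs 8*8*27+8 each + 2 IN, no projection
          upsample (8->4): transposed conv 8*4*8+4
          decoder block (8->4): unit1 8*4*27+4 + IN, conv2 4*4*27+4 + IN,
            projection 8*4+4
          head: 4*3+3
        """
        enc0 = (1 * 4 * 27 + 4 + 8) + (4 * 4 * 27 + 4 + 8) + (1 * 4 + 4)
        down = 4 * 8 * 27 + 8 + 16
        enc1 = 2 * (8 * 8 * 27 + 8 + 16)
        up = 8 * 4 * 8 + 4
        dec0 = (8 * 4 * 27 + 4 + 8) + (4 * 4 * 27 + 4 + 8) + (8 * 4 + 4)
        head = 4 * 3 + 3
        expected = enc0 + down + enc1 + up + dec0 + head
        cfg = NetConfig(n_stages=2, base_channels=4, in_channels=1, n_classes=3, ds_levels=1)
        assert build_network(cfg).n_parameters() == expected

    def test_indivisible_patch_rejected(self):
        cfg = NetConfig(n_stages=3)
        net = build_network(cfg)
        with pytest.raises(ValueError, match="axis"):
            net.forward(np.zeros((1, 1, 18, 16, 16), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(n_stages=3, ds_levels=3)


class TestCompositeLoss:
    def test_matches_bruteforce_formula_on_small_patch(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
        target = rng.integers(0, 3, size=(2, 4, 4, 4))
        tape = []
        t = T.Tensor(logits, tape=tape)
        w = LossWeights(ds_weights=(1.0,))
        got = float(composite_loss([t], target, w).data)
        want = _loss_bruteforce(logits, target)
        assert got == pytest.approx(want, rel=1e-4)

    def test_uniform_logits(self):
        target = np.zeros((1, 4, 4, 4), dtype=np.int64)
        target[0, :2] = 1
        logits = np.zeros((1, 3, 4, 4, 4), dtype=np.float32)
        tape = []
        got = float(composite_loss([T.Tensor(logits, tape=tape)], target, LossWeights(ds_weights=(1.0,))).data)
        assert got == pytest.approx(_loss_bruteforce(logits, target), rel=1e-4)

    def test_confident_correct_approaches_minimum(self):
        rng = np.random.default_rng(1)
        target = rng.integers(0, 3, size=(1, 8, 8, 8))
        logits = 50.0 * one_hot(target, 3) - 25.0
        tape = []
        val = float(composite_loss([T.Tensor(logits, tape=tape)], target, LossWeights(ds_weights=(1.0,))).data)
        # cross-entropy -> 0 and soft Dice -> 1, so the loss approaches 0
        assert val < 1e-3

    def test_single_level_reduction(self):
        rng = np.random.default_rng(2)
        logits = rng.normal(size=(1, 3, 8, 8, 8)).astype(np.float32)
        target = rng.integers(0, 3, size=(1, 8, 8, 8))
        tape = []
        single = composite_loss([T.Tensor(logits, tape=tape)], target, LossWeights(ds_weights=(1.0,)))
        assert float(single.data) == pytest.approx(_loss_bruteforce(logits, target), rel=1e-4)

    def test_foreground_relabeling_equivariance(self):
        """Swapping the two foreground classes consistently leaves the loss unchanged."""
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(1, 3, 8, 8, 8)).astype(np.float32)
        target = rng.integers(0, 3, size=(1, 8, 8, 8))
        perm = logits[:, [0, 2, 1]]
        t_perm = np.where(target == 1, 2, np.where(target == 2, 1, 0))
        w = LossWeights(ds_weights=(1.0,))
        a = float(composite_loss([T.Tensor(logits, tape=[])], target, w).data)
        b = float(composite_loss([T.Tensor(perm, tape=[])], t_perm, w).data)
        assert a == pytest.approx(b, rel=1e-5)

    def test_ds_weight_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ds_weights"):
            composite_loss(
                [T.Tensor(np.zeros((1, 3, 4, 4, 4)), tape=[])],
                np.zeros((1, 4, 4, 4), dtype=np.int64),
                LossWeights(ds_weights=(0.5, 0.5)),
            )


class TestGradients:
    def test_gradient_flows_to_every_parameter(self):
        cfg = NetConfig(n_stages=3, base_channels=2, in_channels=2, ds_levels=2)
        net = build_network(cfg, seed=0)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 2, 8, 8, 8)).astype(np.float32)
        y = rng.integers(0, 3, size=(2, 8, 8, 8))
        loss = composite_loss(net.forward(x), y, LossWeights.default_for(2))
        loss.backward()
        # biases of convs feeding instance norm have analytically zero gradient;
        # every other parameter group must receive signal
        n_nonzero = sum(1 for p in net.parameters() if p.grad is not None and np.abs(p.grad).max() > 1e-12)
        assert all(p.grad is not None for p in net.parameters())
        assert n_nonzero >= 0.7 * len(net.parameters())

    def test_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float64)
        target = rng.integers(0, 3, size=(1, 4, 4, 4))
        tape = []
        t = T.Tensor(logits.astype(np.float32), tape=tape)
        loss = composite_loss([t], target, LossWeights(ds_weights=(1.0,)))
        loss.backward()
        eps = 1e-3
        for idx in [(0, 0, 0, 0, 0), (0, 1, 2, 3, 1), (0, 2, 1, 1, 2)]:
            up = logits.copy()
            up[idx] += eps
            down = logits.copy()
            down[idx] -= eps
            fd = (_loss_bruteforce(up, target) - _loss_bruteforce(down, target)) / (2 * eps)
            assert t.grad[idx] == pytest.approx(fd, rel=5e-2, abs=1e-5)


class TestBackendAgreement:
    def test_numba_and_numpy_paths_agree(self):
        """The JIT conv/norm kernels match the im2col reference implementation."""
        if not T.USE_NUMBA:
            pytest.skip("numba backend not active")
        cfg = NetConfig(n_stages=3, base_channels=2, in_channels=3, ds_levels=2)
        rng = np.random.default_rng(3)
        x = rng.normal(size=(2, 3, 16, 16, 16)).astype(np.float32)
        y = rng.integers(0, 3, size=(2, 16, 16, 16))

        def run():
            T.clear_buffers()
            net = build_network(cfg, seed=7)
            loss = composite_loss(net.forward(x), y, LossWeights.default_for(2))
            loss.backward()
            return float(loss.data), [p.grad.copy() for p in net.parameters()]

        try:
            l1, g1 = run()
            T.USE_NUMBA = False
            l2, g2 = run()
        finally:
            T.USE_NUMBA = True
            T.clear_buffers()
        assert l1 == pytest.approx(l2, rel=1e-5)
        for a, b in zip(g1, g2):
            scale = max(np.abs(b).max(), 1e-3)
            assert np.abs(a - b).max() / scale < 1e-3


class TestCheckpoints:
    def test_roundtrip_and_recipe_guard(self, tmp_path):
        from stagedseg.model import load_checkpoint, save_checkpoint
        from stagedseg.sampling import RECIPE_FULL_PRIOR, RECIPE_IMAGE_ONLY

        net = build_network(NetConfig(in_channels=1), seed=0)
        save_checkpoint(tmp_path / "ck.npz", net, recipe=RECIPE_IMAGE_ONLY)
        back, meta = load_checkpoint(tmp_path / "ck.npz", expected_recipe=RECIPE_IMAGE_ONLY)
        x = np.random.default_rng(0).normal(size=(1, 1, 8, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(back.predict_proba(x), net.predict_proba(x), atol=1e-6)
        with pytest.raises(ValueError, match="recipe"):
            load_checkpoint(tmp_path / "ck.npz", expected_recipe=RECIPE_FULL_PRIOR)
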