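"""Desk-scale 3D residual encoder-decoder with deep supervision.

The architecture family follows the residual-encoder U-Net convention:
encoder stages of residual blocks (identity skip around two
conv-instancenorm-leakyReLU units), strided-convolution downsampling,
transposed-convolution upsampling with encoder skip concatenation, and
auxiliary segmentation heads on the finest ``ds_levels`` decoder outputs
for deep supervision.  Defaults are sized for CPU-minutes training on
phantom data rather than the seven-stage, 141M-parameter configuration
used on full-resolution clinical MRI; depth and width are configurable.

The training objective is the standard compound of soft Dice loss (batch-
pooled per foreground class) and voxel-wise cross-entropy, evaluated at
every supervision level against nearest-neighbor-downsampled targets and
combined with normalized level weights.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _tensor as T

DICE_EPS = 1e-5


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters.

    ``n_stages`` counts encoder resolutions (each after the first halves the
    grid); ``ds_levels`` is the number of decoder outputs that receive
    supervision, finest first.
    """

    n_stages: int = 3
    base_channels: int = 3
    channel_growth: int = 2
    in_channels: int = 1
    n_classes: int = 3
    kernel: tuple[int, int, int] = (3, 3, 3)
    ds_levels: int = 2

    def __post_init__(self) -> None:
        if self.n_stages < 2:
            raise ValueError("n_stages must be >= 2")
        if self.ds_levels > self.n_stages - 1:
            raise ValueError(
                f"ds_levels={self.ds_levels} must be <= n_stages-1={self.n_stages - 1}"
            )
        if min(self.base_channels, self.channel_growth, self.in_channels, self.n_classes) < 1:
            raise ValueError("all dimensions must be positive")
        if self.ds_levels < 1:
            raise ValueError("ds_levels must be >= 1")

    def stage_channels(self) -> list[int]:
        return [self.base_channels * self.channel_growth**s for s in range(self.n_stages)]

    def check_patch_size(self, patch_size) -> None:
        div = 2 ** (self.n_stages - 1)
        for ax, p in enumerate(patch_size):
            if p % div != 0:
                raise ValueError(
                    f"patch axis {ax} has size {p}, not divisible by 2^(n_stages-1)={div}"
                )


@dataclass(frozen=True)
class LossWeights:
    """Weights of the compound objective; ds_weights are normalized to sum 1."""

    dice_weight: float = 1.0
    ce_weight: float = 1.0
    ds_weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if self.dice_weight < 0 or self.ce_weight < 0 or any(w < 0 for w in self.ds_weights):
            raise ValueError("loss weights must be >= 0")
        s = sum(self.ds_weights)
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"ds_weights must sum to 1, got {s}")

    @staticmethod
    def default_for(ds_levels: int, dice_weight=1.0, ce_weight=1.0) -> "LossWeights":
        """Halve the weight per coarser level, then normalize."""
        raw = [0.5**i for i in range(ds_levels)]
        s = sum(raw)
        return LossWeights(dice_weight, ce_weight, tuple(w / s for w in raw))


def _he_init(rng: np.random.Generator, shape, fan_in) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class _ConvUnit:
    """conv(k, pad k//2) -> instance norm -> leaky ReLU."""

    def __init__(self, rng, cin, cout, kernel, stride=1):
        k = tuple(kernel)
        fan_in = cin * int(np.prod(k))
        self.w = T.Parameter(_he_init(rng, (cout, cin) + k, fan_in))
        self.b = T.Parameter(np.zeros(cout, dtype=np.float32))
        self.gamma = T.Parameter(np.ones(cout, dtype=np.float32))
        self.beta = T.Parameter(np.zeros(cout, dtype=np.float32))
        self.stride = stride
        self.pad = tuple(kk // 2 for kk in k)

    def __call__(self, x, tape):
        h = T.conv3d(x, self.w, self.b, stride=self.stride, pad=self.pad, tape=tape)
        h = T.instance_norm(h, self.gamma, self.beta, tape=tape)
        return T.leaky_relu(h, tape=tape)

    def params(self):
        return [self.w, self.b, self.gamma, self.beta]


class _ResBlock:
    """Two conv units with an identity (or 1x1-projected) skip."""

    def __init__(self, rng, cin, cout, kernel):
        k = tuple(kernel)
        self.unit1 = _ConvUnit(rng, cin, cout, k)
        # second unit: norm before the residual add, nonlinearity after
        fan_in = cout * int(np.prod(k))
        self.w2 = T.Parameter(_he_init(rng, (cout, cout) + k, fan_in))
        self.b2 = T.Parameter(np.zeros(cout, dtype=np.float32))
        self.gamma2 = T.Parameter(np.ones(cout, dtype=np.float32))
        self.beta2 = T.Parameter(np.zeros(cout, dtype=np.float32))
        self.pad = tuple(kk // 2 for kk in k)
        if cin != cout:
            self.wp = T.Parameter(_he_init(rng, (cout, cin, 1, 1, 1), cin))
            self.bp = T.Parameter(np.zeros(cout, dtype=np.float32))
        else:
            self.wp = self.bp = None

    def __call__(self, x, tape):
        h = self.unit1(x, tape)
        h = T.conv3d(h, self.w2, self.b2, stride=1, pad=self.pad, tape=tape)
        h = T.instance_norm(h, self.gamma2, self.beta2, tape=tape)
        skip = x if self.wp is None else T.conv3d(x, self.wp, self.bp, stride=1, pad=0, tape=tape)
        return T.leaky_relu(T.add(h, skip, tape=tape), tape=tape)

    def params(self):
        ps = self.unit1.params() + [self.w2, self.b2, self.gamma2, self.beta2]
        if self.wp is not None:
            ps += [self.wp, self.bp]
        return ps


class Network:
    """Residual encoder-decoder; forward returns deep-supervision logits, finest first."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.stage_channels()
        k = cfg.kernel

        self.enc_blocks = [_ResBlock(rng, cfg.in_channels, ch[0], k)]
        self.down = []
        for s in range(1, cfg.n_stages):
            self.down.append(_ConvUnit(rng, ch[s - 1], ch[s], k, stride=2))
            self.enc_blocks.append(_ResBlock(rng, ch[s], ch[s], k))

        self.up = []
        self.dec_blocks = []
        for s in range(cfg.n_stages - 2, -1, -1):
            cin, cout = ch[s + 1], ch[s]
            w = T.Parameter(_he_init(rng, (cin, cout, 2, 2, 2), cin * 8))
            b = T.Parameter(np.zeros(cout, dtype=np.float32))
            self.up.append((w, b))
            self.dec_blocks.append(_ResBlock(rng, 2 * cout, cout, k))

        self.heads = []
        for lvl in range(cfg.ds_levels):
            c = ch[lvl]
            w = T.Parameter(_he_init(rng, (cfg.n_classes, c, 1, 1, 1), c))
            b = T.Parameter(np.zeros(cfg.n_classes, dtype=np.float32))
            self.heads.append((w, b))

    def parameters(self) -> list[T.Parameter]:
        ps: list[T.Parameter] = []
        for blk in self.enc_blocks:
            ps += blk.params()
        for unit in self.down:
            ps += unit.params()
        for w, b in self.up:
            ps += [w, b]
        for blk in self.dec_blocks:
            ps += blk.params()
        for w, b in self.heads:
            ps += [w, b]
        return ps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(self, x: np.ndarray) -> list[T.Tensor]:
        """x: (N, C, D, H, W) -> list of logit tensors, finest resolution first."""
        if x.ndim != 5 or x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected input (N, {self.cfg.in_channels}, D, H, W), got {x.shape}"
            )
        self.cfg.check_patch_size(x.shape[2:])
        tape: list[T.Tensor] = []
        h = T.Tensor(x)
        skips = []
        h = self.enc_blocks[0](h, tape)
        skips.append(h)
        for s in range(1, self.cfg.n_stages):
            h = self.down[s - 1](h, tape)
            h = self.enc_blocks[s](h, tape)
            if s < self.cfg.n_stages - 1:
                skips.append(h)

        dec_feats: dict[int, T.Tensor] = {}
        for i, s in enumerate(range(self.cfg.n_stages - 2, -1, -1)):
            w, b = self.up[i]
            h = T.upconv2(h, w, b, tape=tape)
            h = T.concat([h, skips[s]], axis=1, tape=tape)
            h = self.dec_blocks[i](h, tape)
            dec_feats[s] = h

        outputs = []
        for lvl in range(self.cfg.ds_levels):
            w, b = self.heads[lvl]
            outputs.append(T.conv3d(dec_feats[lvl], w, b, stride=1, pad=0, tape=tape))
        return outputs

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities at full resolution, shape (N, K, D, H, W)."""
        outputs = self.forward(x)
        proba = softmax(outputs[0].data, axis=1)
        outputs[0].release_tape()
        return proba

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint parameter count mismatch")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"checkpoint shape mismatch at parameter {i}")
            p.data = arr


def build_network(cfg: NetConfig, seed: int = 0) -> Network:
    """Construct a seeded network from its configuration."""
    return Network(cfg, seed=seed)


def softmax(z: np.ndarray, axis=1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    """(N, D, H, W) int labels -> (N, K, D, H, W) float32."""
    g = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float32)
    for k in range(n_classes):
        g[:, k] = target == k
    return g


def downsample_target(target: np.ndarray, level: int) -> np.ndarray:
    """Nearest-neighbor downsampling by 2**level along each spatial axis."""
    f = 2**level
    return target[:, ::f, ::f, ::f]


def soft_dice_per_class(p: np.ndarray, g: np.ndarray, eps=DICE_EPS) -> np.ndarray:
    """Batch-pooled soft Dice per class; p, g: (N, K, ...)."""
    axes = (0,) + tuple(range(2, p.ndim))
    num = (p * g).sum(axis=axes)
    den = p.sum(axis=axes) + g.sum(axis=axes)
    return 2.0 * num / (den + eps)


def _dice_ce_level(logits: T.Tensor, target: np.ndarray, w: LossWeights, tape) -> T.Tensor:
    """Compound loss at one level, with an analytic gradient into the logits."""
    n_classes = logits.data.shape[1]
    p = softmax(logits.data, axis=1)
    g = one_hot(target, n_classes)
    nvox = float(np.prod(target.shape))

    ce = -np.log(np.maximum((p * g).sum(axis=1), 1e-12)).mean()

    axes = (0,) + tuple(range(2, p.ndim))
    fg = slice(1, n_classes)
    num = (p[:, fg] * g[:, fg]).sum(axis=axes)
    den = p[:, fg].sum(axis=axes) + g[:, fg].sum(axis=axes) + DICE_EPS
    dice_loss = 1.0 - float(np.mean(2.0 * num / den))

    value = w.dice_weight * dice_loss + w.ce_weight * ce
    out = T.Tensor(np.float32(value), parents=(logits,), tape=tape)

    def _backward():
        dce = (p - g) / nvox
        # d(dice)/dp on foreground classes: (2 g den - 2 num) / den^2, averaged
        n_fg = n_classes - 1
        dl_dp = np.zeros_like(p)
        coef = 2.0 / (den**2) / n_fg
        expand = (1, -1) + (1,) * (p.ndim - 2)
        dl_dp[:, fg] = -(
            g[:, fg] * (den * coef).reshape(expand) - (num * coef).reshape(expand)
        )
        inner = (dl_dp * p).sum(axis=1, keepdims=True)
        ddice = p * (dl_dp - inner)
        logits.accumulate(out.grad * (w.ce_weight * dce + w.dice_weight * ddice))

    out._backward = _backward
    return out


def composite_loss(
    preds: list[T.Tensor], target: np.ndarray, w: LossWeights
) -> T.Tensor:
    """Deep-supervision compound loss.

    ``preds`` are logit tensors finest-first (as returned by
    ``Network.forward``); ``target`` is the full-resolution label batch
    (N, D, H, W), downsampled internally per level by nearest neighbor.
    """
    if len(w.ds_weights) != len(preds):
        raise ValueError(
            f"got {len(preds)} supervision levels but {len(w.ds_weights)} ds_weights"
        )
    tape = preds[0]._tape
    terms = []
    for lvl, (logits, lw) in enumerate(zip(preds, w.ds_weights)):
        tgt = downsample_target(target, lvl)
        if logits.data.shape[2:] != tgt.shape[1:]:
            raise ValueError(
                f"level {lvl}: logits spatial shape {logits.data.shape[2:]} does not "
                f"match downsampled target {tgt.shape[1:]}"
            )
        terms.append((float(lw), _dice_ce_level(logits, tgt, w, tape)))
    return T.scale_add(terms, tape=tape)


def recipe_hash(recipe) -> str:
    payload = json.dumps(asdict(recipe), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path, net: Network, recipe=None, extra: dict | None = None) -> None:
    """Weights + NetConfig + channel-recipe hash in one .npz."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "net_config": asdict(net.cfg),
        "recipe": asdict(recipe) if recipe is not None else None,
        "recipe_hash": recipe_hash(recipe) if recipe is not None else None,
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())


def load_checkpoint(path, expected_recipe=None) -> tuple[Network, dict]:
    """Rebuild the network from a checkpoint; refuses a mismatched channel recipe."""
    with np.load(Path(path)) as f:
        meta = json.loads(bytes(f["__meta__"]).decode())
        state = {k: f[k] for k in f.files if k != "__meta__"}
    cfg_dict = dict(meta["net_config"])
    cfg_dict["kernel"] = tuple(cfg_dict["kernel"])
    cfg = NetConfig(**cfg_dict)
    if expected_recipe is not None and meta["recipe_hash"] is not None:
        if recipe_hash(expected_recipe) != meta["recipe_hash"]:
            raise ValueError(
                "checkpoint was trained with a different channel recipe "
                f"({meta['recipe']}); refusing to run inference with a mismatched recipe"
            )
    net = Network(cfg)
    net.load_state_dict(state)
    return net, meta
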