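"""Single-stage training and the staged pre-/mid-treatment pipelines.

The schedule contract follows the nnU-Net convention the backbone family
inherits: SGD with Nesterov momentum, polynomial learning-rate decay
``lr0 · (1 − step/total)^exponent``, a fixed number of steps per epoch, and
a light geometric/intensity augmentation set (flips, in-plane 90° rotations,
global intensity scaling, additive Gaussian noise).  Full-scale values
(1000 epochs × 250 steps, batch 2, patch 320×256×64) are representable in
the same config; desk-scale defaults train in CPU-minutes on phantoms.

Pipelines:

* pre-treatment — stage 1 trains with default foreground oversampling; for
  the staged variants its predictions on the cohort become priors for a
  refinement stage trained with mask-guided sampling (c1: priors steer
  sampling only; c2: the prior mask is also an input channel).  Final
  inference is deliberately *unrestricted*, which is what lets a c1-style
  model hallucinate islands outside the stage-1 region.
* mid-treatment — the registered pre-treatment mask plays the role of the
  first stage, so only one network is trained (c1 ablation: image only;
  c3: image + prior image + prior mask channels; staged_c3: c3 channels
  plus mask-guided sampling and mask-restricted inference).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd

from . import _tensor
from . import infer as infer_mod
from .caseio import CaseRecord, LabelMap
from .model import (
    LossWeights,
    NetConfig,
    Network,
    build_network,
    composite_loss,
    one_hot,
    save_checkpoint,
    soft_dice_per_class,
    softmax,
)
from .sampling import (
    RECIPE_FULL_PRIOR,
    RECIPE_IMAGE_ONLY,
    RECIPE_PRIOR_MASK,
    ChannelRecipe,
    extract_patch,
    sample_default,
    sample_masked,
)

logger = logging.getLogger(__name__)

Sampler = Literal["default", "masked"]
PriorSource = Literal["none", "stage1_output", "provided_prior"]

DEFAULT_AUGMENTATIONS = frozenset({"flip", "rot90", "intensity_scale", "gaussian_noise"})


@dataclass(frozen=True)
class StageConfig:
    """Everything defining one training stage."""

    recipe: ChannelRecipe = RECIPE_IMAGE_ONLY
    sampler: Sampler = "default"
    fg_fraction: float = 0.33
    prior_source: PriorSource = "none"
    patch_size: tuple[int, int, int] = (32, 32, 32)
    batch_size: int = 2
    epochs: int = 12
    steps_per_epoch: int = 50
    lr0: float = 0.01
    poly_exponent: float = 0.9
    # 0.99 is the full-scale framework convention; desk-scale schedules run
    # hundreds rather than hundreds of thousands of steps, where that much
    # momentum is unstable with multi-channel inputs
    momentum: float = 0.9
    seed: int = 0
    augmentations: frozenset[str] = DEFAULT_AUGMENTATIONS
    net: Optional[NetConfig] = None

    def __post_init__(self) -> None:
        if self.sampler == "masked" and self.prior_source == "none":
            raise ValueError("masked sampling requires a prior_source")
        if min(self.epochs, self.steps_per_epoch, self.batch_size) < 1:
            raise ValueError("epochs, steps_per_epoch and batch_size must be >= 1")
        unknown = set(self.augmentations) - DEFAULT_AUGMENTATIONS
        if unknown:
            raise ValueError(f"unknown augmentations: {sorted(unknown)}")

    def net_config(self) -> NetConfig:
        cfg = self.net if self.net is not None else NetConfig()
        if cfg.in_channels != self.recipe.n_channels:
            cfg = replace(cfg, in_channels=self.recipe.n_channels)
        return cfg


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(len(self.loss)),
                "loss": self.loss,
                "val_pseudo_dice": self.val_dice,
                "lr": self.lr,
            }
        )


def lr_schedule(step: int, total_steps: int, lr0: float, exponent: float) -> float:
    """Polynomial decay: lr0 · (1 − step/total_steps)^exponent."""
    if not (0 <= step <= total_steps):
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    return lr0 * (1.0 - step / total_steps) ** exponent


class SGDNesterov:
    def __init__(self, params, momentum: float):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        mu = self.momentum
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= mu
            v += p.grad
            p.data -= lr * (p.grad + mu * v)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def _image_channel_indices(recipe: ChannelRecipe) -> list[int]:
    """Channels that hold intensities (prior-mask channel excluded)."""
    idx = [0]
    if recipe.use_prior_image:
        idx.append(1)
    return idx


def augment(
    stack: np.ndarray,
    target: np.ndarray,
    recipe: ChannelRecipe,
    augmentations,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint geometric augmentation of all channels + target; intensity ops on image channels only."""
    if "flip" in augmentations:
        for ax in range(3):
            if rng.random() < 0.5:
                stack = np.flip(stack, axis=ax + 1)
                target = np.flip(target, axis=ax)
    if "rot90" in augmentations and stack.shape[1] == stack.shape[2]:
        k = int(rng.integers(0, 4))
        if k:
            stack = np.rot90(stack, k, axes=(1, 2))
            target = np.rot90(target, k, axes=(0, 1))
    stack = np.ascontiguousarray(stack).copy()
    target = np.ascontiguousarray(target)
    img_idx = _image_channel_indices(recipe)
    if "intensity_scale" in augmentations and rng.random() < 0.3:
        stack[img_idx] *= rng.uniform(0.75, 1.25)
    if "gaussian_noise" in augmentations and rng.random() < 0.3:
        stack[img_idx] += rng.normal(0.0, 0.1, size=stack[img_idx].shape).astype(np.float32)
    return stack, target


def _resolve_prior(
    case: CaseRecord, cfg: StageConfig, stage1_masks: dict[str, LabelMap] | None
) -> Optional[LabelMap]:
    if cfg.prior_source == "none":
        return None
    if cfg.prior_source == "provided_prior":
        if case.prior_mask is None:
            raise ValueError(f"case {case.case_id}: prior_source=provided_prior but no prior_mask")
        return case.prior_mask
    if stage1_masks is None or case.case_id not in stage1_masks:
        raise ValueError(
            f"case {case.case_id}: prior_source=stage1_output but no stage-1 mask supplied"
        )
    return stage1_masks[case.case_id]


def _with_prior_mask(case: CaseRecord, prior: Optional[LabelMap]) -> CaseRecord:
    if prior is None or prior is case.prior_mask:
        return case
    return CaseRecord(case.case_id, case.image, case.reference, case.prior_image, prior)


def _draw_patch(
    case: CaseRecord,
    prior: Optional[LabelMap],
    cfg: StageConfig,
    rng: np.random.Generator,
):
    if cfg.sampler == "masked" and prior is not None:
        if (prior.labels > 0).any():
            return sample_masked(case, prior, cfg.patch_size, rng)
        logger.warning(
            "case %s: empty prior mask, falling back to default sampling", case.case_id
        )
    return sample_default(case, cfg.patch_size, cfg.fg_fraction, rng)


def _validation_batch(val_cases, cfg: StageConfig, stage1_masks):
    """One fixed foreground-centered patch per validation case."""
    rng = np.random.default_rng(cfg.seed + 987654321)
    stacks, targets = [], []
    for case in val_cases:
        prior = _resolve_prior(case, cfg, stage1_masks) if cfg.prior_source != "none" else None
        spec = sample_default(case, cfg.patch_size, 1.0, rng)
        s, t = extract_patch(_with_prior_mask(case, prior), spec, cfg.recipe)
        stacks.append(s)
        targets.append(t)
    return np.stack(stacks), np.stack(targets)


def _pseudo_dice(net: Network, stacks: np.ndarray, targets: np.ndarray) -> float:
    """Foreground soft Dice of the softmax output on held-out patches."""
    proba = net.predict_proba(stacks)
    g = one_hot(targets, net.cfg.n_classes)
    d = soft_dice_per_class(proba, g)
    present = [k for k in range(1, net.cfg.n_classes) if g[:, k].any()]
    if not present:
        return float("nan")
    return float(np.mean([d[k] for k in present]))


def train_stage(
    cfg: StageConfig,
    train_cases: list[CaseRecord],
    val_cases: list[CaseRecord],
    stage1_masks: dict[str, LabelMap] | None = None,
    out_dir: str | Path | None = None,
) -> tuple[Network, TrainHistory]:
    """Run one training stage; returns the final network and its history.

    The best-validation weights (by foreground pseudo-Dice on fixed held-out
    patches) are kept alongside the final ones; with ``out_dir`` both are
    written as checkpoints together with a per-epoch metrics CSV.
    """
    if cfg.prior_source == "stage1_output" and stage1_masks is None:
        raise ValueError("prior_source=stage1_output requires stage1_masks")
    _tensor.clear_buffers()  # drop workspaces owned by previous runs' layers
    rng = np.random.default_rng(cfg.seed)
    net = build_network(cfg.net_config(), seed=cfg.seed)
    net.cfg.check_patch_size(cfg.patch_size)
    loss_w = LossWeights.default_for(net.cfg.ds_levels)
    opt = SGDNesterov(net.parameters(), cfg.momentum)

    priors = {
        c.case_id: (_resolve_prior(c, cfg, stage1_masks) if cfg.prior_source != "none" else None)
        for c in train_cases
    }
    val_stacks, val_targets = (
        _validation_batch(val_cases, cfg, stage1_masks) if val_cases else (None, None)
    )

    history = TrainHistory()
    total_steps = cfg.epochs * cfg.steps_per_epoch
    best_dice, best_state = -np.inf, None
    step = 0
    for epoch in range(cfg.epochs):
        epoch_losses = []
        for _ in range(cfg.steps_per_epoch):
            lr = lr_schedule(step, total_steps, cfg.lr0, cfg.poly_exponent)
            stacks, targets = [], []
            for _ in range(cfg.batch_size):
                case = train_cases[int(rng.integers(len(train_cases)))]
                prior = priors[case.case_id]
                spec = _draw_patch(case, prior, cfg, rng)
                s, t = extract_patch(_with_prior_mask(case, prior), spec, cfg.recipe)
                s, t = augment(s, t, cfg.recipe, cfg.augmentations, rng)
                stacks.append(s)
                targets.append(t)
            x = np.stack(stacks)
            y = np.stack(targets)
            opt.zero_grad()
            preds = net.forward(x)
            loss = composite_loss(preds, y, loss_w)
            loss.backward()
            opt.step(lr)
            epoch_losses.append(float(loss.data))
            step += 1
        history.loss.append(float(np.mean(epoch_losses)))
        history.lr.append(lr)
        vd = _pseudo_dice(net, val_stacks, val_targets) if val_stacks is not None else float("nan")
        history.val_dice.append(vd)
        if np.isfinite(vd) and vd > best_dice:
            best_dice = vd
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            history.best_epoch = epoch
        logger.info("epoch %d: loss=%.4f val_pseudo_dice=%.4f lr=%.5f", epoch, history.loss[-1], vd, lr)

    if best_state is None:
        best_state = net.state_dict()
        history.best_epoch = cfg.epochs - 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(out_dir / "final.npz", net, cfg.recipe,
                        extra={"epoch": cfg.epochs - 1})
        best_net = build_network(net.cfg)
        best_net.load_state_dict(best_state)
        save_checkpoint(out_dir / "best.npz", best_net, cfg.recipe,
                        extra={"epoch": history.best_epoch, "val_pseudo_dice": best_dice})
        history.to_frame().to_csv(out_dir / "history.csv", index=False)
    net.best_state = best_state  # type: ignore[attr-defined]
    net.recipe = cfg.recipe  # type: ignore[attr-defined]
    _tensor.clear_buffers()
    return net, history


@dataclass
class PipelineResult:
    networks: dict[str, Network]
    histories: dict[str, TrainHistory]
    predictions: dict[str, LabelMap]  # validation-case predictions
    priors: dict[str, LabelMap] = field(default_factory=dict)


def _predict_cases(
    net: Network,
    cases: list[CaseRecord],
    recipe: ChannelRecipe,
    patch,
    roi_from_prior: bool = False,
    overlap: float = infer_mod.DEFAULT_OVERLAP,
) -> dict[str, LabelMap]:
    out = {}
    for case in cases:
        roi = case.prior_mask if roi_from_prior else None
        out[case.case_id] = infer_mod.sliding_window_predict(
            net, case, recipe, patch=patch, overlap=overlap, roi=roi
        )
    return out


def run_pre_rt_pipeline(
    variant: Literal["baseline", "c1", "c2"],
    train_cases: list[CaseRecord],
    val_cases: list[CaseRecord],
    cfg1: StageConfig,
    cfg2: StageConfig | None = None,
) -> PipelineResult:
    """Pre-treatment pipeline: stage 1, and for c1/c2 a mask-guided refinement stage.

    Stage-1 predictions on the training cohort (in-sample) become the priors
    of stage 2.  Final inference is unrestricted sliding window for every
    variant.
    """
    if variant not in ("baseline", "c1", "c2"):
        raise ValueError(f"unknown pre-RT variant {variant!r}")
    net1, hist1 = train_stage(cfg1, train_cases, val_cases)
    networks, histories = {"stage1": net1}, {"stage1": hist1}
    if variant == "baseline":
        preds = _predict_cases(net1, val_cases, cfg1.recipe, cfg1.patch_size)
        return PipelineResult(networks, histories, preds)

    if cfg2 is None:
        raise ValueError(f"variant {variant!r} needs a stage-2 config")
    if cfg2.prior_source != "stage1_output":
        raise ValueError("stage-2 config must use prior_source=stage1_output")
    expected = RECIPE_IMAGE_ONLY if variant == "c1" else RECIPE_PRIOR_MASK
    if cfg2.recipe != expected:
        raise ValueError(f"variant {variant!r} requires recipe {expected}")

    stage1_masks = {}
    for case in train_cases + val_cases:
        stage1_masks[case.case_id] = infer_mod.sliding_window_predict(
            net1, case, cfg1.recipe, patch=cfg1.patch_size
        )
    net2, hist2 = train_stage(cfg2, train_cases, val_cases, stage1_masks=stage1_masks)
    networks["stage2"], histories["stage2"] = net2, hist2

    val_with_priors = [_with_prior_mask(c, stage1_masks[c.case_id]) for c in val_cases]
    preds = _predict_cases(net2, val_with_priors, cfg2.recipe, cfg2.patch_size)
    return PipelineResult(networks, histories, preds, priors=stage1_masks)


def run_mid_rt_pipeline(
    variant: Literal["c1", "c3", "staged_c3"],
    train_cases: list[CaseRecord],
    val_cases: list[CaseRecord],
    cfg: StageConfig,
) -> PipelineResult:
    """Mid-treatment pipeline: a single training run per variant.

    c1 ignores the priors entirely; c3 stacks prior image and mask as input
    channels; staged_c3 additionally samples and infers only within the
    prior mask.
    """
    if variant not in ("c1", "c3", "staged_c3"):
        raise ValueError(f"unknown mid-RT variant {variant!r}")
    if variant == "c1":
        cfg = replace(cfg, recipe=RECIPE_IMAGE_ONLY, sampler="default", prior_source="none")
    else:
        for case in train_cases + val_cases:
            if not case.has_prior:
                raise ValueError(f"case {case.case_id}: mid-RT variant {variant} needs priors")
        if variant == "c3":
            cfg = replace(cfg, recipe=RECIPE_FULL_PRIOR, sampler="default", prior_source="none")
        else:
            cfg = replace(
                cfg, recipe=RECIPE_FULL_PRIOR, sampler="masked", prior_source="provided_prior"
            )
    net, hist = train_stage(cfg, train_cases, val_cases)
    preds = _predict_cases(
        net, val_cases, cfg.recipe, cfg.patch_size, roi_from_prior=(variant == "staged_c3")
    )
    priors = {c.case_id: c.prior_mask for c in val_cases if c.prior_mask is not None}
    return PipelineResult({"stage1": net}, {"stage1": hist}, preds, priors=priors)
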