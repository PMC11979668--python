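"""Seeded end-to-end experiments: cohort -> training -> prediction -> report.

An :class:`ExperimentConfig` is fully serializable; a saved config plus its
seeds regenerates the artifact directory bit-identically on one CPU.  The
artifact directory is self-describing::

    out/
      config.json          resolved configuration
      cohort/              generated phantom cases (NIfTI case layout)
      checkpoints/<stage>/ best.npz, final.npz, history.csv
      predictions/         one label map per validation case
      report/              aggdsc.csv, significance.csv, per_case.csv,
                           per_case_dsc.png

Presets: ``desk-smoke`` (seconds, smoke-level), ``desk-study`` (CPU-minutes,
the cohort size used by the mechanism-efficacy experiments), and
``full-scale`` (the full-scale schedule — 1000 epochs × 250 steps, patch
320×256×64 — kept as configuration values; it is not meant to run on a desk).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional

import numpy as np

from .caseio import save_case, write_labelmap
from .evalstats import boxplot_per_case, evaluate_cases, report
from .model import NetConfig, save_checkpoint
from .phantom import PhantomParams, make_cohort
from .sampling import ChannelRecipe, RECIPE_IMAGE_ONLY, RECIPE_PRIOR_MASK
from .train import StageConfig, run_mid_rt_pipeline, run_pre_rt_pipeline

logger = logging.getLogger(__name__)

Task = Literal["pre-rt", "mid-rt"]


@dataclass(frozen=True)
class ExperimentConfig:
    task: Task = "mid-rt"
    variant: str = "staged_c3"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    n_cases: int = 20
    n_val: int = 4
    stage1: StageConfig = field(default_factory=StageConfig)
    stage2: Optional[StageConfig] = None
    seed: int = 0

    def resolved_stage1(self) -> StageConfig:
        return replace(self.stage1, seed=self.stage1.seed + self.seed)

    def resolved_stage2(self) -> Optional[StageConfig]:
        if self.stage2 is None:
            return None
        return replace(self.stage2, seed=self.stage2.seed + self.seed)

    def to_json(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return asdict(o)
            if isinstance(o, (frozenset, set)):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=enc, sort_keys=True, indent=2)

    @staticmethod
    def from_json(text: str) -> "ExperimentConfig":
        raw = json.loads(text)

        def stage(d):
            if d is None:
                return None
            d = dict(d)
            d["recipe"] = ChannelRecipe(**d["recipe"])
            d["patch_size"] = tuple(d["patch_size"])
            d["augmentations"] = frozenset(d["augmentations"])
            if d.get("net") is not None:
                n = dict(d["net"])
                n["kernel"] = tuple(n["kernel"])
                d["net"] = NetConfig(**n)
            return StageConfig(**d)

        ph = dict(raw["phantom"])
        for key in ("shape", "spacing", "gtvp_radius_range", "gtvn_radius_range"):
            ph[key] = tuple(ph[key])
        return ExperimentConfig(
            task=raw["task"],
            variant=raw["variant"],
            phantom=PhantomParams(**ph),
            n_cases=raw["n_cases"],
            n_val=raw["n_val"],
            stage1=stage(raw["stage1"]),
            stage2=stage(raw["stage2"]),
            seed=raw["seed"],
        )


def preset(name: str, seed: int = 0) -> ExperimentConfig:
    """Named experiment presets."""
    if name == "desk-smoke":
        net = NetConfig(n_stages=2, base_channels=2, ds_levels=1)
        s1 = StageConfig(epochs=1, steps_per_epoch=3, patch_size=(16, 16, 16), net=net)
        return ExperimentConfig(
            task="mid-rt", variant="staged_c3",
            phantom=PhantomParams(shape=(32, 32, 16)), n_cases=3, n_val=1,
            stage1=s1, seed=seed,
        )
    if name == "desk-study":
        return ExperimentConfig(task="mid-rt", variant="staged_c3", seed=seed)
    if name == "full-scale":
        # full-scale schedule as configuration values; not meant for desk runs
        net = NetConfig(n_stages=7, base_channels=32, ds_levels=5)
        s1 = StageConfig(
            epochs=1000, steps_per_epoch=250, patch_size=(320, 256, 64),
            batch_size=2, momentum=0.99, net=net,
        )
        return ExperimentConfig(
            task="pre-rt", variant="c2",
            phantom=PhantomParams(shape=(384, 320, 96), spacing=(0.5, 0.5, 1.2)),
            n_cases=150, n_val=30, stage1=s1,
            stage2=replace(
                s1, sampler="masked", prior_source="stage1_output", recipe=RECIPE_PRIOR_MASK
            ),
            seed=seed,
        )
    raise ValueError(f"unknown preset {name!r}")


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path, resume: bool = False) -> Path:
    """Run one seeded experiment end to end and write a self-describing artifact dir."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not resume:
        raise FileExistsError(
            f"{out} already contains a (possibly partial) run; pass resume=True / --resume "
            "to overwrite"
        )
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())

    pairs = make_cohort(cfg.phantom, cfg.n_cases, seed=cfg.seed)
    cohort_dir = out / "cohort"
    for pre, mid in pairs:
        save_case(pre, cohort_dir)
        save_case(mid, cohort_dir)

    if cfg.task == "mid-rt":
        cases = [mid for _, mid in pairs]
    else:
        cases = [pre for pre, _ in pairs]
    n_train = cfg.n_cases - cfg.n_val
    train_cases, val_cases = cases[:n_train], cases[n_train:]

    if cfg.task == "mid-rt":
        result = run_mid_rt_pipeline(cfg.variant, train_cases, val_cases, cfg.resolved_stage1())
    else:
        result = run_pre_rt_pipeline(
            cfg.variant, train_cases, val_cases, cfg.resolved_stage1(), cfg.resolved_stage2()
        )

    for name, net in result.networks.items():
        ck = out / "checkpoints" / name
        ck.mkdir(parents=True, exist_ok=True)
        save_checkpoint(ck / "final.npz", net, recipe=getattr(net, "recipe", None))
        result.histories[name].to_frame().to_csv(ck / "history.csv", index=False)

    pred_dir = out / "predictions"
    for cid, lmap in result.predictions.items():
        write_labelmap(lmap, pred_dir / f"{cid}.nii.gz")

    refs = {c.case_id: c.reference for c in val_cases}
    evalres = evaluate_cases(result.predictions, refs)
    tables = report({cfg.variant: evalres})
    rep_dir = out / "report"
    rep_dir.mkdir(exist_ok=True)
    for name, df in tables.items():
        df.to_csv(rep_dir / f"{name}.csv", index=False)
    boxplot_per_case({cfg.variant: evalres}, rep_dir / "per_case_dsc.png")
    logger.info(
        "experiment %s/%s: avg aggDSC %.2f over %d validation cases",
        cfg.task, cfg.variant, 100 * evalres.aggregated["avg_aggDSC"], evalres.n_cases,
    )
    return out
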