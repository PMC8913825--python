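"""End-to-end orchestration: synth -> clean -> train -> predict -> eval.

A single ``PipelineConfig`` (YAML-serializable) drives all stages; each
stage writes its artifacts into the run directory and can be skipped.  A
single seed fans out to per-stage seeds so later stages are reproducible
without replaying earlier ones.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from PIL import Image

from . import augment as aug
from . import evaluate, fixtures, postprocess, preprocess
from .losses import LossConfig
from .models import ModelConfig, build_model, save_model
from .train import SgdrSchedule, TrainConfig, train

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    """Defaults follow the identified optimum operating point: 256x256
    inputs, dice loss, batch size 16, the seven-transform augmentation
    preset, TTA and CRF enabled."""

    image_size: int = 256
    n_train: int = 32
    n_val: int = 8
    n_test: int = 8
    synth: fixtures.SynthSpec = field(default_factory=fixtures.SynthSpec)
    preprocess_params: preprocess.HairRemovalParams = field(
        default_factory=preprocess.HairRemovalParams)
    clean: bool = True
    augment: aug.AugmentationSpec = field(
        default_factory=lambda: aug.AugmentationSpec(preset="combo7"))
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    schedule: SgdrSchedule = field(default_factory=SgdrSchedule)
    tta: bool = True
    crf: bool = True
    tta_spec: postprocess.TtaSpec = field(default_factory=postprocess.TtaSpec)
    crf_params: postprocess.CrfParams = field(default_factory=postprocess.CrfParams)
    threshold: float = 0.5
    seed: int = 0


_NESTED = {
    "synth": fixtures.SynthSpec,
    "preprocess_params": preprocess.HairRemovalParams,
    "augment": aug.AugmentationSpec,
    "model": ModelConfig,
    "loss": LossConfig,
    "train": TrainConfig,
    "schedule": SgdrSchedule,
    "tta_spec": postprocess.TtaSpec,
    "crf_params": postprocess.CrfParams,
}
_TUPLE_FIELDS = {"image_size", "lesion_area_fraction_range", "hair_count_range",
                 "gamma_limit", "hsv_shift_limit", "motion_blur_limit",
                 "aspp_rates", "transforms"}


def _build_nested(cls, data):
    if isinstance(data, cls):
        return data
    kw = {}
    for k, v in dict(data).items():
        if k in _NESTED and isinstance(v, dict):
            v = _build_nested(_NESTED[k], v)
        elif k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kw[k] = v
    return cls(**kw)


def load_config(path: Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build_nested(PipelineConfig, data)


def save_config(config: PipelineConfig, path: Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)]


def run_pipeline(config: PipelineConfig, out_dir: Path,
                 stages: tuple[str, ...] = ("synth", "clean", "train",
                                            "predict", "eval")) -> dict:
    """Execute the requested stages; returns the final metrics dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(config, out / "config.yaml")
    seeds = _stage_seeds(config.seed)
    log = (out / "run.log").open("a")

    def note(msg: str) -> None:
        log.write(msg + "\n")
        log.flush()

    spec = replace(config.synth,
                   image_size=(config.image_size, config.image_size))

    data = {}
    if "synth" in stages:
        for split, n, s in (("train", config.n_train, seeds[0]),
                            ("val", config.n_val, seeds[1]),
                            ("test", config.n_test, seeds[2])):
            d = out / "data" / split
            fixtures.generate_dataset(n, spec, s, d)
            data[split] = fixtures.load_dataset(d)
            note(f"synth: wrote {n} samples to {d}")

    if "clean" in stages and config.clean:
        for split in data:
            data[split] = [preprocess.clean_sample(s, config.preprocess_params)
                           for s in data[split]]
        note("clean: hair removal applied to all splits")

    model = None
    if "train" in stages:
        tc = replace(config.train, loss=config.loss, augment=config.augment,
                     seed=seeds[3])
        model = build_model(replace(config.model, seed=seeds[4]))
        result = train(model, data["train"], data["val"], tc, config.schedule)
        result.history.to_csv(out / "history.csv", index=False)
        save_model(model, out / "model.npz")
        note(f"train: best val JAC {result.best_val_jaccard:.4f} "
             f"at epoch {result.best_epoch}")

    metrics_out: dict = {}
    if "predict" in stages and model is not None:
        pred_dir = out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        per_image = []
        for s in data["test"]:
            if config.tta:
                prob = postprocess.tta_predict(model, s.image, config.tta_spec)
            else:
                prob = model.predict(s.image)
            if config.crf:
                prob = postprocess.crf_refine(s.image, prob, config.crf_params)
            mask = postprocess.threshold_mask(prob, config.threshold)
            np.save(pred_dir / f"{s.sample_id}_prob.npy", prob)
            Image.fromarray((mask * 255).astype(np.uint8), mode="L"
                            ).save(pred_dir / f"{s.sample_id}_mask.png")
            m = evaluate.evaluate_pair(mask, s.mask)
            per_image.append({"sample_id": s.sample_id, "precision": m.precision,
                              "recall": m.recall, "jaccard": m.jaccard,
                              "dice": m.dice})
        metrics_out["per_image"] = per_image
        note(f"predict: {len(per_image)} test images")

    if "eval" in stages and metrics_out.get("per_image"):
        jacs = [r["jaccard"] for r in metrics_out["per_image"]]
        report = evaluate.jaccard_report(jacs)
        agg = {k: float(np.mean([r[k] for r in metrics_out["per_image"]]))
               for k in ("precision", "recall", "jaccard", "dice")}
        metrics_out["aggregate"] = agg
        metrics_out["jaccard_distribution"] = report
        (out / "metrics.json").write_text(json.dumps(metrics_out, indent=2))
        note(f"eval: mean JAC {agg['jaccard']:.4f}")

    log.close()
    return metrics_out
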