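"""End-to-end orchestration: phantoms -> preprocess -> segment -> augment
-> train -> evaluate, with a manifest that makes every run reproducible.

A single global seed fans out to per-stage seeds by fixed offsets, so one
number reproduces a whole run. Each stage's wall time, artifacts and
metrics land in ``manifest.json`` in the output directory; a stage failure
aborts the run but keeps the partial manifest on disk.

The ``segment.enabled`` switch supports the ablation of interest: with
segmentation off, the classifier trains on raw (unsegmented) crops, which
is the comparison that motivates segmenting before classification.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from toothstage import augment as aug
from toothstage import classifier as clf
from toothstage import dpac, evaluate, phantom, preprocess
from toothstage.image import write_gray, write_mask

_SEED_OFFSETS = {"synth": 0, "augment": 1, "split": 2, "train": 3}


@dataclass
class RunConfig:
    """Pipeline settings; every field has a sensible default.

    Construct from a YAML/dict via :meth:`from_dict`, which rejects unknown
    keys so typos fail loudly.
    """

    seed: int = 0
    outdir: str = "toothstage_run"
    # synth
    n_per_stage: int = 20
    image_side: int = 250
    clutter_level: float = 0.08
    impulse_noise_fraction: float = 0.02
    # preprocess
    median_kernel: int = 7
    use_clahe: bool = False
    # segment
    segment_enabled: bool = True
    n_lines: int = 1200
    radius_length: float = 100.0
    delta: float = 3.0
    # augment
    factor: int = 10
    # train
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    train_fraction: float = 0.8
    save_images: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; "
                             f"known keys: {sorted(known)}")
        return cls(**d)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order and return (and persist) the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "seeds": {k: config.seed + v for k, v in _SEED_OFFSETS.items()},
        "stages": [],
        "metrics": {},
    }

    def _save():
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def _stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as err:
                manifest["failed_stage"] = name
                manifest["error"] = str(err)
                _save()
                raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
            manifest["stages"].append(
                {"name": name, "wall_time_s": round(time.perf_counter() - t0, 3)})
            _save()
            return result
        return deco

    state: dict = {}

    @_stage("synth")
    def _synth():
        cases = phantom.generate_dataset(
            config.n_per_stage, seed=config.seed + _SEED_OFFSETS["synth"],
            image_side=config.image_side, clutter_level=config.clutter_level,
            impulse_noise_fraction=config.impulse_noise_fraction)
        state["cases"] = cases
        manifest["metrics"]["n_cases"] = len(cases)
        return cases

    @_stage("preprocess")
    def _preprocess():
        for case in state["cases"]:
            img = preprocess.adjust_intensity(case.image)
            img = preprocess.median_filter(img, config.median_kernel)
            if config.use_clahe:
                img = preprocess.clahe(img)
            case.image = img
        return state["cases"]

    if config.segment_enabled:
        @_stage("segment")
        def _segment():
            cfg = dpac.DpConfig(delta=config.delta)
            dices = []
            for i, case in enumerate(state["cases"]):
                _, mask = dpac.segment(case.image, n_lines=config.n_lines,
                                       radius_length=config.radius_length, config=cfg)
                case.image = dpac.apply_mask(case.image, mask)
                dices.append(dpac.dice(mask, case.truth_mask))
                if config.save_images:
                    write_gray(outdir / f"roi_{i:04d}.png", case.image)
                    write_mask(outdir / f"mask_{i:04d}.png", mask)
            manifest["metrics"]["segmentation_mean_dice"] = float(np.mean(dices))
            return dices

    @_stage("split")
    def _split():
        items = [aug.LabeledImage(image=c.image, stage=c.label, sex=c.cohort,
                                  ident=f"case{i}")
                 for i, c in enumerate(state["cases"])]
        train_val, test = clf.split_dataset(
            items, config.train_fraction, seed=config.seed + _SEED_OFFSETS["split"])
        state["train_val"], state["test"] = train_val, test
        manifest["metrics"]["n_train_val"] = len(train_val)
        manifest["metrics"]["n_test"] = len(test)

    @_stage("augment")
    def _augment():
        plan = aug.AugmentPlan(factor=config.factor,
                               seed=config.seed + _SEED_OFFSETS["augment"])
        state["train_val"] = aug.expand_dataset(state["train_val"], plan)
        manifest["metrics"]["n_augmented"] = len(state["train_val"])

    @_stage("train")
    def _train():
        tcfg = clf.TrainConfig(optimizer=config.optimizer,
                               learning_rate=config.learning_rate,
                               epochs=config.epochs, batch_size=config.batch_size,
                               train_fraction=config.train_fraction,
                               seed=config.seed + _SEED_OFFSETS["train"])
        model = clf.build_model(clf.reference_spec(),
                                seed=config.seed + _SEED_OFFSETS["train"])
        hist = clf.train(model, state["train_val"], tcfg)
        state["model"], state["history"] = model, hist
        manifest["metrics"]["final_train_acc"] = hist.train_acc[-1]
        manifest["metrics"]["final_val_acc"] = hist.val_acc[-1]
        (outdir / "history.csv").write_text(
            "epoch,train_loss,train_acc,val_loss,val_acc\n" + "\n".join(
                f"{i+1},{tl:.6f},{ta:.6f},{vl:.6f},{va:.6f}"
                for i, (tl, ta, vl, va) in enumerate(zip(
                    hist.train_loss, hist.train_acc, hist.val_loss, hist.val_acc))))

    @_stage("evaluate")
    def _evaluate():
        true_s, pred_s = clf.evaluate_on(state["model"], state["test"])
        report = evaluate.agreement_report(true_s, pred_s)
        report["history_summary"] = evaluate.summarize_history(state["history"])
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        manifest["metrics"]["test_accuracy"] = report["overall_accuracy"]
        manifest["metrics"]["kappa"] = report["kappa"]
        state["report"] = report

    manifest["report"] = state["report"]
    _save()
    return manifest
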