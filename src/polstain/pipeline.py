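"""End-to-end pipeline: phantom rendering -> training -> evaluation -> report.

Each stage writes into ``<out_root>/<stage>/`` with a serialized copy of
the run configuration, the stage seed and the package version, so any
artifact directory carries enough metadata to reproduce it.  Completed
stages (marker file present) are skipped on re-run unless forced.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import __version__, io as pio
from .config import RunConfig, stage_seed
from .metrics import evaluate_pairs
from .phantom import DatasetConfig, PhantomParams, make_dataset
from .translator import (
    DiscriminatorSpec,
    GeneratorSpec,
    TrainConfig,
    history_to_csv,
    load_checkpoint,
    save_checkpoint,
    train,
    translate,
)

logger = logging.getLogger(__name__)

STAGES = ("phantom", "train", "evaluate", "report")


class DependencyError(RuntimeError):
    """A stage's input artifact is missing; names the producing stage."""


def _stage_dir(cfg: RunConfig, stage: str) -> Path:
    return Path(cfg.out_root) / stage


def _mark_done(cfg: RunConfig, stage: str) -> None:
    d = _stage_dir(cfg, stage)
    d.mkdir(parents=True, exist_ok=True)
    (d / "run_config.yaml").write_text(cfg.to_yaml())
    (d / "provenance.json").write_text(
        json.dumps(
            {"stage": stage, "seed": stage_seed(cfg.seed, stage), "version": __version__},
            indent=1,
        )
    )
    (d / ".done").write_text("ok\n")


def _is_done(cfg: RunConfig, stage: str) -> bool:
    return (_stage_dir(cfg, stage) / ".done").exists()


def _require(cfg: RunConfig, stage: str) -> Path:
    if not _is_done(cfg, stage):
        raise DependencyError(f"missing artifact from stage {stage!r}; run it first")
    return _stage_dir(cfg, stage)


def _run_phantom(cfg: RunConfig) -> None:
    p = cfg.phantom
    make_dataset(
        DatasetConfig(
            out_dir=str(_stage_dir(cfg, "phantom")),
            n_scenes=p.n_scenes,
            train_fraction=p.train_fraction,
            palette=p.palette,
            sop=p.sop,
            paired=p.paired,
            scene_params=PhantomParams(
                size=(p.size, p.size), n_nuclei=p.n_nuclei, n_fibers=p.n_fibers
            ),
            magnifications=tuple(p.magnifications),
            seed=stage_seed(cfg.seed, "phantom"),
        )
    )


def _load_training_arrays(cfg: RunConfig):
    ds = _require(cfg, "phantom")
    manifest = json.loads((ds / "manifest.json").read_text())
    if manifest["paired"]:
        pol = [pio.read_stack(ds / e["stokes_encoded"]) for e in manifest["train"]]
        bf = [pio.read_png(ds / e["brightfield"]) for e in manifest["train"]]
    else:
        pol = [pio.read_stack(ds / f) for f in manifest["train_polarimetric"]]
        bf = [pio.read_png(ds / f) for f in manifest["train_brightfield"]]
    x = np.stack(pol)
    y = np.stack([b / 127.5 - 1.0 for b in bf]).astype(np.float32)
    return x, y, manifest


def _run_train(cfg: RunConfig) -> None:
    t = cfg.train
    x, y, _ = _load_training_arrays(cfg)
    pair = train(
        x,
        y,
        TrainConfig(
            epochs=t.epochs,
            flat_epochs=t.flat_epochs,
            batch_size=t.batch_size,
            lr0=t.lr0,
            lambda_cyc=t.lambda_cyc,
            gan_mode=t.gan_mode,
            seed=stage_seed(cfg.seed, "train"),
        ),
        GeneratorSpec(in_channels=x.shape[-1], out_channels=3, base_width=t.base_width,
                      n_res_blocks=t.n_res_blocks),
        DiscriminatorSpec(widths=tuple(t.disc_widths)),
    )
    out = _stage_dir(cfg, "train")
    out.mkdir(parents=True, exist_ok=True)
    save_checkpoint(pair, out / "model.npz")
    (out / "history.csv").write_text(history_to_csv(pair.history))


def _run_evaluate(cfg: RunConfig) -> None:
    ds = _require(cfg, "phantom")
    ckpt = _require(cfg, "train") / "model.npz"
    manifest = json.loads((ds / "manifest.json").read_text())
    pair = load_checkpoint(ckpt)
    preds, refs = [], []
    for e in manifest["test"]:
        enc = pio.read_stack(ds / e["stokes_encoded"])
        gen = translate(pair.g, enc)
        if cfg.evaluate.mode == "paired":
            preds.append(gen)
            refs.append(pio.read_png(ds / e["brightfield"]))
        else:  # cycle-reconstruction: compare x with F(G(x)) on the 0-255 scale
            rec, _ = pair.f.forward((gen.transpose(2, 0, 1)[None] / 127.5 - 1.0).astype(np.float32))
            rec_img = np.clip(np.rint((rec[0].transpose(1, 2, 0) + 1.0) * 127.5), 0, 255)
            preds.append(rec_img)
            refs.append(np.clip(np.rint((enc + 1.0) * 127.5), 0, 255))
    report = evaluate_pairs(preds, refs)
    out = _stage_dir(cfg, "evaluate")
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(
        json.dumps({"encodings": {"stokes_" + cfg.phantom.sop: report.as_dict()}}, indent=1)
    )


def run_pipeline(cfg: RunConfig, stages=None, force: bool = False) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run root.  Idempotent: completed stages are skipped unless
    ``force`` is set.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    requested = list(stages) if stages else [s for s in STAGES if s != "report"]
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
    runners = {
        "phantom": _run_phantom,
        "train": _run_train,
        "evaluate": _run_evaluate,
        "report": lambda c: report(Path(c.out_root)),
    }
    for stage in STAGES:
        if stage not in requested:
            continue
        if _is_done(cfg, stage) and not force:
            logger.info("stage %s already complete, skipping", stage)
            continue
        logger.info("running stage %s", stage)
        runners[stage](cfg)
        _mark_done(cfg, stage)
    return Path(cfg.out_root)


def report(run_dir: Path) -> str:
    """Summarize evaluation results as a per-encoding metric table.

    Rows are input encodings, columns the four metrics; returned as CSV
    text and written to ``<run_dir>/report/report.csv``.
    """
    run_dir = Path(run_dir)
    metrics_path = run_dir / "evaluate" / "metrics.json"
    if not metrics_path.exists():
        raise DependencyError("missing artifact from stage 'evaluate'; run it first")
    data = json.loads(metrics_path.read_text())
    lines = ["encoding,ssim,rmse,jsd,emd"]
    for name, rep in data["encodings"].items():
        lines.append(f"{name},{rep['ssim']:.4f},{rep['rmse']:.4f},{rep['jsd']:.4f},{rep['emd']:.4f}")
    text = "\n".join(lines) + "\n"
    out = run_dir / "report"
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.csv").write_text(text)
    return text
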