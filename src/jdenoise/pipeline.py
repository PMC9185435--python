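"""End-to-end pipeline: simulate -> train -> denoise -> evaluate.

Given one resolved configuration, the pipeline generates (or loads) clean
images, corrupts them with the requested noise model, trains the denoiser
self-supervised on the noisy set (or supervised in baseline mode),
denoises a held-out set with test-time averaging, and writes every
artifact — noisy images, checkpoint, denoised images, metric report,
resolved config, and a log — under one output directory.  A fixed seed
makes the whole run, including the report bytes, reproducible on one
machine.
"""

from __future__ import annotations

import time
from dataclasses import asdict, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import read_gray, write_gray, denoise_tta
from .losses import LossSpec
from .metrics import MetricConfig, evaluate_pair_table, format_report
from .network import NetSpec
from .noise import NoiseSpec, apply_noise, make_synthetic_clean
from .trainer import TrainConfig, train

__all__ = ["PipelineConfig", "run_pipeline", "default_pipeline_config"]


def default_pipeline_config() -> dict:
    """A small, fully resolved default configuration (dict form so it can
    round-trip through YAML and flag overrides)."""
    return {
        "seed": 0,
        "images": {
            "source": "synthetic",      # or a directory of clean images
            "kinds": ["shapes", "shapes", "gradient", "texture"],
            "height": 96, "width": 96,
            "n_test": 2,
        },
        "noise": {"family": "fusion", "sigma_g": 25.0, "sigma_s": 5.0,
                  "d": 0.25},
        "net": {"donut_K": 3, "paths": [[2, 2], [3, 2]], "channels": 16,
                "head_depth": 2, "skip": True, "baseline_n2c": False},
        "loss": {"family": "adss", "lam": 10.0, "alpha": 0.0,
                 "epsilon": 0.2, "detach_weights": True},
        "train": {"batch_size": 8, "patch_size": 48, "steps": 200,
                  "initial_lr": 0.03, "decay_rate": 0.9,
                  "decay_interval": 2000, "augment": True,
                  "mode": "self-supervised"},
        "metrics": {"max_val": 1.0, "k1": 0.01, "k2": 0.03,
                    "window": "gaussian11", "sigma": 1.5},
    }


class PipelineConfig:
    """Thin wrapper turning the nested dict into typed specs."""

    def __init__(self, cfg: dict):
        self.raw = cfg
        self.seed = int(cfg.get("seed", 0))
        n = cfg["noise"]
        self.noise = NoiseSpec(family=n["family"],
                               sigma_g=float(n.get("sigma_g", 0.0)),
                               sigma_s=float(n.get("sigma_s", 0.0)),
                               d=float(n.get("d", 0.0)), seed=self.seed)
        net = dict(cfg["net"])
        net["paths"] = tuple(tuple(p) for p in net["paths"])
        self.net = NetSpec(**net)
        self.loss = LossSpec(**cfg["loss"])
        self.train = TrainConfig(net=self.net, loss=self.loss,
                                 seed=self.seed, **cfg["train"])
        self.metrics = MetricConfig(**cfg["metrics"])
        self.images = cfg["images"]


def _load_cleans(cfg: PipelineConfig) -> tuple[list, list]:
    """(training cleans, held-out test cleans)."""
    imgs = cfg.images
    if imgs.get("source", "synthetic") == "synthetic":
        h, w = int(imgs.get("height", 96)), int(imgs.get("width", 96))
        kinds = list(imgs.get("kinds", ["shapes"]))
        cleans = [make_synthetic_clean(k, h, w, seed=cfg.seed + i)
                  for i, k in enumerate(kinds)]
        n_test = int(imgs.get("n_test", 1))
        tests = [make_synthetic_clean(kinds[i % len(kinds)], h, w,
                                      seed=cfg.seed + 1000 + i)
                 for i in range(n_test)]
        return cleans, tests
    src = Path(imgs["source"])
    paths = sorted(p for p in src.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not paths:
        raise ValueError(f"no images in {src}")
    cleans = [read_gray(p) for p in paths]
    n_test = min(int(imgs.get("n_test", 1)), len(cleans))
    return cleans, cleans[-n_test:]


def run_pipeline(cfg: dict | PipelineConfig, outdir) -> dict:
    """Run the full chain; returns a summary dict and leaves all
    artifacts under `outdir`."""
    if isinstance(cfg, dict):
        cfg = PipelineConfig(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{time.strftime('%Y-%m-%d %H:%M:%S')}\t"
                         f"{stage}\t{msg}")

    def stage(name, fn):
        try:
            log(name, "start")
            out = fn()
            log(name, "done")
            return out
        except Exception as exc:
            log(name, f"FAILED: {exc}")
            (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") \
                from exc

    def do_simulate():
        cleans, tests = _load_cleans(cfg)
        noisy = [apply_noise(im, replace(cfg.noise, seed=cfg.seed + 10 * i))
                 for i, im in enumerate(cleans)]
        noisy_test = [apply_noise(im, replace(cfg.noise,
                                              seed=cfg.seed + 9000 + i))
                      for i, im in enumerate(tests)]
        for i, im in enumerate(noisy):
            write_gray(im, outdir / "noisy" / f"train_{i:03d}.tif", "float")
        for i, (c, x) in enumerate(zip(tests, noisy_test)):
            write_gray(c, outdir / "clean" / f"test_{i:03d}.tif", "float")
            write_gray(x, outdir / "noisy_test" / f"test_{i:03d}.tif",
                       "float")
        return cleans, tests, noisy, noisy_test

    cleans, tests, noisy, noisy_test = stage("simulate", do_simulate)

    def do_train():
        ck = train(cfg.train, noisy,
                   clean_images=cleans
                   if cfg.train.mode == "supervised-baseline" else None)
        ck.save(outdir / "checkpoint.npz")
        trace = "\n".join(f"{s}\t{lr:.6g}\t{v:.8g}"
                          for s, lr, v in ck.loss_trace)
        (outdir / "training_log.tsv").write_text(
            "step\tlr\tloss\n" + trace + ("\n" if trace else ""))
        return ck

    ck = stage("train", do_train)

    def do_denoise():
        outs = [denoise_tta(ck.net, x) for x in noisy_test]
        for i, im in enumerate(outs):
            write_gray(im, outdir / "denoised" / f"test_{i:03d}.tif",
                       "float")
        return outs

    stage("denoise", do_denoise)

    def do_evaluate():
        prov = (f"jdenoise={__version__} seed={cfg.seed} "
                f"noise={cfg.noise.family} net=K{cfg.net.donut_K}"
                f"{list(cfg.net.paths)} loss={cfg.loss.family}")
        rows, means = evaluate_pair_table(outdir / "clean",
                                          outdir / "denoised", cfg.metrics)
        report = format_report(rows, means, cfg.metrics, provenance=prov)
        (outdir / "report.tsv").write_text(report)
        rows_n, means_n = evaluate_pair_table(outdir / "clean",
                                              outdir / "noisy_test",
                                              cfg.metrics)
        (outdir / "report_noisy.tsv").write_text(
            format_report(rows_n, means_n, cfg.metrics, provenance=prov))
        return means, means_n

    means, means_noisy = stage("evaluate", do_evaluate)

    resolved = dict(cfg.raw)
    resolved["package_version"] = __version__
    (outdir / "config.resolved.yaml").write_text(
        yaml.safe_dump(resolved, sort_keys=True))
    (outdir / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    return {
        "psnr_denoised": means[0], "ssim_denoised": means[1],
        "psnr_noisy": means_noisy[0], "ssim_noisy": means_noisy[1],
        "final_loss": ck.loss_trace[-1][2] if ck.loss_trace else None,
    }
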