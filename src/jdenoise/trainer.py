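"""Mask-free self-supervised training loop.

Because the network is J-invariant by construction, training simply fits
f(x) to the noisy image x itself — no blind-spot masking, no pixel
in-painting.  The protocol follows the common recipe for this family of
denoisers: RAdam, initial learning rate 0.03 with continuous exponential
decay, focusing parameter lambda = 10 for the adaptive loss, and random
rotation/mirror augmentation of training patches.  A supervised
"noise2clean" baseline mode shares all of the plumbing but targets the
clean images with a regular (unmasked) front kernel; it serves as the
performance upper bound in comparisons.

Patch size, step count, batch size and the decay constants are desk-scale
engineering defaults, recorded in every checkpoint for provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from ._nn import RAdam
from .network import NetSpec, DenoiserNet, build_network
from .losses import LossSpec

__all__ = ["TrainConfig", "Checkpoint", "lr_at", "make_patch_stream",
           "train", "TrainingDivergedError"]


class TrainingDivergedError(RuntimeError):
    """The training loss became non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    net: NetSpec = NetSpec()
    loss: LossSpec = LossSpec(family="adss", lam=10.0)
    batch_size: int = 64
    patch_size: int = 64
    steps: int = 20000
    initial_lr: float = 0.03
    decay_rate: float = 0.9
    decay_interval: int = 2000
    augment: bool = True
    mode: str = "self-supervised"   # or "supervised-baseline"
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.patch_size < 1 or self.steps < 0:
            raise ValueError("batch_size, patch_size must be positive and "
                             "steps non-negative")
        if not (0 < self.decay_rate <= 1) or self.decay_interval < 1:
            raise ValueError("decay_rate in (0,1], decay_interval >= 1")
        if self.mode not in ("self-supervised", "supervised-baseline"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Checkpoint:
    net_spec: NetSpec
    config: TrainConfig
    step: int
    loss_trace: list = field(default_factory=list)   # (step, lr, loss)
    _net: DenoiserNet | None = None

    @property
    def net(self) -> DenoiserNet:
        return self._net

    def save(self, path) -> None:
        meta = {
            "format_version": 1,
            "net_spec": asdict(self.net_spec),
            "config": _config_dict(self.config),
            "step": self.step,
            "loss_trace": self.loss_trace,
            "init_seed": self._net.seed,
        }
        arrays = {f"p{i}": a for i, a in
                  enumerate(self._net.state_arrays())}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            arrays = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        spec = NetSpec.from_json(json.dumps(meta["net_spec"]))
        cfg = _config_from_dict(meta["config"])
        net = build_network(spec, seed=meta["init_seed"])
        net.load_state_arrays(arrays)
        ck = cls(net_spec=spec, config=cfg, step=meta["step"],
                 loss_trace=[tuple(t) for t in meta["loss_trace"]])
        ck._net = net
        return ck


def _config_dict(cfg: TrainConfig) -> dict:
    d = asdict(cfg)
    return d


def _config_from_dict(d: dict) -> TrainConfig:
    d = dict(d)
    net = d.pop("net")
    net["paths"] = tuple(tuple(p) for p in net["paths"])
    loss = d.pop("loss")
    return TrainConfig(net=NetSpec(**net), loss=LossSpec(**loss), **d)


def lr_at(step: int, initial_lr: float, decay_rate: float,
          decay_interval: int) -> float:
    """Continuous exponential decay: lr = lr0 * rate^(step/interval)."""
    if step < 0:
        raise ValueError("step must be non-negative")
    return initial_lr * decay_rate ** (step / decay_interval)


def dihedral(img: np.ndarray, k: int) -> np.ndarray:
    """The 8 symmetries of the square: k%4 quarter-turns, then a
    left-right flip if k >= 4."""
    out = np.rot90(img, k % 4, axes=(-2, -1))
    if k >= 4:
        out = out[..., ::-1]
    return out


def dihedral_inverse(img: np.ndarray, k: int) -> np.ndarray:
    if k >= 4:
        img = img[..., ::-1]
    return np.rot90(img, -(k % 4), axes=(-2, -1))


def make_patch_stream(images, patch_size: int, batch_size: int,
                      augment: bool, seed: int, clean_images=None):
    """Infinite iterator of (noisy_batch, clean_batch|None) float32 arrays
    of shape (B, 1, p, p).

    Patches are uniform random crops; with `augment` each patch is
    independently given one of the 8 dihedral transforms.  Identical
    crop/transform draws are applied to the clean counterpart when given.
    Undersized images are rejected eagerly, before the first batch.
    """
    images = [np.asarray(im, dtype=np.float32) for im in images]
    for i, im in enumerate(images):
        if im.shape[0] < patch_size or im.shape[1] < patch_size:
            raise ValueError(f"image #{i} of shape {im.shape} is smaller "
                             f"than patch_size={patch_size}")
    if clean_images is not None:
        clean_images = [np.asarray(im, dtype=np.float32)
                        for im in clean_images]
        if len(clean_images) != len(images):
            raise ValueError("noisy and clean image lists differ in length")
    return _patch_iter(images, patch_size, batch_size, augment, seed,
                       clean_images)


def _patch_iter(images, patch_size, batch_size, augment, seed,
                clean_images):
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), 555))))
    p = patch_size
    while True:
        noisy = np.empty((batch_size, 1, p, p), dtype=np.float32)
        clean = (np.empty_like(noisy) if clean_images is not None else None)
        for b in range(batch_size):
            i = int(rng.integers(len(images)))
            im = images[i]
            top = int(rng.integers(im.shape[0] - p + 1))
            left = int(rng.integers(im.shape[1] - p + 1))
            k = int(rng.integers(8)) if augment else 0
            noisy[b, 0] = dihedral(im[top:top + p, left:left + p], k)
            if clean is not None:
                clean[b, 0] = dihedral(
                    clean_images[i][top:top + p, left:left + p], k)
        yield noisy, clean


def train(config: TrainConfig, noisy_images, clean_images=None) -> Checkpoint:
    """Run `config.steps` optimization steps; returns a checkpoint with
    the loss trace.

    Self-supervised mode fits f(batch) to the noisy batch itself and
    ignores `clean_images`; supervised-baseline mode requires them and
    fits f(batch) to the clean patches.  The donut mask is re-applied on
    every forward pass, so J-invariance survives any number of updates.
    """
    supervised = config.mode == "supervised-baseline"
    if supervised and clean_images is None:
        raise ValueError("supervised-baseline mode requires clean_images")
    net = build_network(config.net, seed=config.seed)
    opt = RAdam(net.param_grad_pairs())
    stream = make_patch_stream(
        noisy_images, config.patch_size, config.batch_size,
        config.augment, config.seed,
        clean_images=clean_images if supervised else None)
    trace = []
    for step in range(config.steps):
        noisy, clean = next(stream)
        target = clean if supervised else noisy
        net.zero_grad()
        pred = net.forward(noisy, cache=True)
        value, g = config.loss.value_and_grad(pred, target)
        if not np.isfinite(value):
            raise TrainingDivergedError(
                f"non-finite loss {value} at step {step}")
        net.backward(g.astype(np.float32))
        lr = lr_at(step, config.initial_lr, config.decay_rate,
                   config.decay_interval)
        opt.step(lr)
        trace.append((step, lr, float(value)))
    ck = Checkpoint(net_spec=config.net, config=config,
                    step=config.steps, loss_trace=trace)
    ck._net = net
    return ck
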