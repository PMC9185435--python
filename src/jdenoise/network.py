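"""The J-invariant dilated-convolution denoising network.

A function f is J-invariant when its output at pixel j does not depend on
the input value at pixel j.  Such a network can be trained with plain
self-supervision (fit f(x) to the noisy x itself) without ever collapsing
to the identity map, so no blind-spot masking scheme is needed.

The architecture achieves this *by construction*:

* a first "donut" convolution — a K x K kernel whose center weight is
  structurally zero — so the first features at j never see x_j;
* two parallel stacks of 3x3 dilated convolutions (dilations 2 and 3 by
  default).  A d-dilated 3x3 layer moves information by offsets in
  {-d, 0, +d}^2 only; as long as every dilation satisfies d > floor(K/2),
  no chain of such moves can bring the excluded center offset back;
* the two paths see complementary offset lattices (coset patterns of the
  dilation-2 and dilation-3 grids) and are merged by channel concatenation
  followed by 1x1 convolutions, which are spatially pointwise and hence
  preserve the excluded offset;
* a skip connection re-injects the donut-layer features after the merge.

`receptive_field` computes the exact offset set analytically by iterating
the stencil recurrence; `dependency_map_bruteforce` recovers the same set
empirically from a built network and serves as its oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._nn import Conv2d, LeakyReLU

__all__ = [
    "NetSpec", "OffsetSet", "DenoiserNet", "JInvarianceError",
    "donut_mask", "receptive_field", "build_network",
    "verify_j_invariance", "dependency_map_bruteforce",
]

OffsetSet = frozenset  # of (dy, dx) integer tuples


class JInvarianceError(ValueError):
    """A network specification that cannot be J-invariant."""


@dataclass(frozen=True)
class NetSpec:
    """Architecture hyperparameters; J-invariance is decidable from these.

    ``paths`` lists (dilation, depth) pairs; every dilation must exceed
    floor(donut_K / 2) unless ``baseline_n2c`` swaps the donut for a full
    kernel (the supervised Noise2Clean baseline, which is deliberately
    NOT J-invariant).
    """

    donut_K: int = 3
    paths: tuple = ((2, 2), (3, 2))
    channels: int = 64
    head_depth: int = 2
    skip: bool = True
    baseline_n2c: bool = False

    def __post_init__(self):
        object.__setattr__(self, "paths",
                           tuple((int(d), int(m)) for d, m in self.paths))
        if self.donut_K < 3 or self.donut_K % 2 == 0:
            raise ValueError("donut_K must be an odd integer >= 3")
        if not self.paths:
            raise ValueError("at least one dilated path is required")
        for d, m in self.paths:
            if d < 1 or m < 0:
                raise ValueError("path dilations must be >= 1, depths >= 0")
        if self.channels < 1 or self.head_depth < 1:
            raise ValueError("channels and head_depth must be positive")

    @property
    def invariant(self) -> bool:
        return all(d > self.donut_K // 2 for d, _ in self.paths)

    def validate_invariance(self) -> None:
        if not self.baseline_n2c and not self.invariant:
            bad = [d for d, _ in self.paths if d <= self.donut_K // 2]
            raise JInvarianceError(
                f"dilation(s) {bad} violate d > floor(K/2) = "
                f"{self.donut_K // 2}; the network would see its own "
                f"center pixel")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetSpec":
        d = json.loads(s)
        d["paths"] = tuple(tuple(p) for p in d["paths"])
        return cls(**d)


def donut_mask(K: int) -> np.ndarray:
    """K x K mask of ones with a single structural zero at the center."""
    if K < 3 or K % 2 == 0:
        raise ValueError("K must be an odd integer >= 3")
    m = np.ones((K, K), dtype=np.float64)
    m[K // 2, K // 2] = 0.0
    return m


def _stencil(d: int) -> list[tuple[int, int]]:
    return [(a, b) for a in (-d, 0, d) for b in (-d, 0, d)]


def receptive_field(spec: NetSpec) -> OffsetSet:
    """Exact input-offset set one output pixel may depend on.

    Iterates the recurrence RF(k) = union over stencil offsets j of
    (RF(k-1) + j), seeded with the donut ring (or the full K x K block
    for the supervised baseline).  The 1x1 merge/head layers and the skip
    addition contribute no new offsets.
    """
    half = spec.donut_K // 2
    seed = {(a, b) for a in range(-half, half + 1)
            for b in range(-half, half + 1)}
    if not spec.baseline_n2c:
        seed.discard((0, 0))
    total: set[tuple[int, int]] = set()
    for d, depth in spec.paths:
        cur = set(seed)
        for _ in range(depth):
            cur = {(i + a, j + b) for (i, j) in cur for (a, b) in _stencil(d)}
        total |= cur
    if spec.skip:
        total |= seed
    return frozenset(total)


def path_receptive_field(spec: NetSpec, path_index: int) -> OffsetSet:
    """Offset set contributed by a single dilated path (diagnostic)."""
    one = NetSpec(donut_K=spec.donut_K, paths=(spec.paths[path_index],),
                  channels=spec.channels, head_depth=spec.head_depth,
                  skip=False, baseline_n2c=spec.baseline_n2c)
    return receptive_field(one)


class DenoiserNet:
    """A built network: spec + parameters + apply().

    Layer graph::

        x -> donut KxK conv -> lrelu                       (y0)
        y0 -> [3x3 d-dilated conv + lrelu] * depth          (per path)
        concat(paths) -> 1x1 merge conv + lrelu (+ y0 skip)
        -> [1x1 conv + lrelu] * (head_depth - 1) -> 1x1 conv -> output

    Everything after the paths is spatially pointwise, so the offset
    analysis of `receptive_field` transfers unchanged.  Zero padding is
    used throughout: reflective padding would fold a border pixel's own
    value back into its neighborhood and silently break J-invariance at
    the image boundary.
    """

    def __init__(self, spec: NetSpec, seed: int = 0):
        spec.validate_invariance()
        self.spec = spec
        self.seed = int(seed)
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((int(seed), 1315))))
        C, K = spec.channels, spec.donut_K
        mask = None if spec.baseline_n2c else donut_mask(K)
        self.front = Conv2d(1, C, K, 1, rng, mask=mask)
        self.front_act = LeakyReLU()
        self.paths = []
        for d, depth in spec.paths:
            layers = []
            for _ in range(depth):
                layers.append(Conv2d(C, C, 3, d, rng))
                layers.append(LeakyReLU())
            self.paths.append(layers)
        self.merge = Conv2d(len(spec.paths) * C, C, 1, 1, rng)
        self.merge_act = LeakyReLU()
        self.head = []
        for _ in range(spec.head_depth - 1):
            self.head.append(Conv2d(C, C, 1, 1, rng))
            self.head.append(LeakyReLU())
        self.head.append(Conv2d(C, 1, 1, 1, rng))

    # -- plumbing ---------------------------------------------------------

    def _modules(self):
        yield self.front
        yield self.front_act
        for layers in self.paths:
            yield from layers
        yield self.merge
        yield self.merge_act
        yield from self.head

    def param_grad_pairs(self):
        for m in self._modules():
            yield from m.params()

    def parameters(self) -> list[np.ndarray]:
        return [p for p, _ in self.param_grad_pairs()]

    def zero_grad(self) -> None:
        for m in self._modules():
            m.zero_grad()

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        """x: (B, 1, H, W) float32 -> (B, 1, H, W)."""
        y0 = self.front_act.forward(self.front.forward(x, cache), cache)
        outs = []
        for layers in self.paths:
            h = y0
            for layer in layers:
                h = layer.forward(h, cache)
            outs.append(h)
        z = np.concatenate(outs, axis=1)
        z = self.merge_act.forward(self.merge.forward(z, cache), cache)
        if self.spec.skip:
            z = z + y0
        for layer in self.head:
            z = layer.forward(z, cache)
        return z

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.head):
            g = layer.backward(g)
        g_skip = g if self.spec.skip else None
        g = self.merge.backward(self.merge_act.backward(g))
        C = self.spec.channels
        gy0 = np.zeros_like(g[:, :C])
        for i, layers in enumerate(self.paths):
            gp = g[:, i * C:(i + 1) * C]
            for layer in reversed(layers):
                gp = layer.backward(gp)
            gy0 += gp
        if g_skip is not None:
            gy0 += g_skip
        return self.front.backward(self.front_act.backward(gy0))

    def apply(self, img: np.ndarray) -> np.ndarray:
        """Denoise a single (H, W) image; shape-preserving."""
        img = np.asarray(img, dtype=np.float32)
        if img.ndim != 2:
            raise ValueError("apply expects a single 2-D image")
        out = self.forward(img[None, None])
        return out[0, 0].astype(np.float64)

    # -- (de)serialization -------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        return self.parameters()

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("parameter count mismatch")
        for p, a in zip(params, arrays):
            if p.shape != a.shape:
                raise ValueError("parameter shape mismatch")
            p[...] = a


def build_network(spec: NetSpec, seed: int = 0) -> DenoiserNet:
    """Deterministically initialize a network; raises `JInvarianceError`
    at build time if the spec cannot be J-invariant (unless it is the
    declared supervised baseline)."""
    return DenoiserNet(spec, seed)


def verify_j_invariance(net: DenoiserNet, img: np.ndarray, trials: int = 16,
                        seed: int = 0, delta: float = 1.0,
                        include_corners: bool = True) -> float:
    """Worst-case dependence of output pixel j on input pixel j.

    For `trials` random pixels (plus the four image corners, where padding
    mistakes would surface) the input is perturbed at exactly that pixel
    and the output change *at the same pixel* is measured; the analytic
    derivative d out_j / d in_j from a backward pass is checked as well.
    A J-invariant network returns 0 up to float noise; the supervised
    baseline returns a clearly positive value.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    img = np.asarray(img, dtype=np.float32)
    h, w = img.shape
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), 4242))))
    pixels = [(int(rng.integers(h)), int(rng.integers(w)))
              for _ in range(trials)]
    if include_corners:
        pixels += [(0, 0), (0, w - 1), (h - 1, 0), (h - 1, w - 1)]
    base = net.forward(img[None, None])[0, 0]
    worst = 0.0
    for (i, j) in pixels:
        pert = img.copy()
        pert[i, j] += delta
        out = net.forward(pert[None, None])[0, 0]
        worst = max(worst, abs(float(out[i, j] - base[i, j])))
        # derivative of out[i, j] w.r.t. the full input
        net.zero_grad()
        net.forward(img[None, None], cache=True)
        g = np.zeros((1, 1, h, w), dtype=np.float32)
        g[0, 0, i, j] = 1.0
        dx = net.backward(g)
        worst = max(worst, abs(float(dx[0, 0, i, j])))
        net.zero_grad()
    return worst


def dependency_map_bruteforce(net: DenoiserNet, extent: int,
                              probes: int = 2, seed: int = 0) -> OffsetSet:
    """Empirical offset set of the center output pixel.

    On a (2*extent+1)^2 random base image, every input pixel is perturbed
    (one perturbed copy per batch element, evaluated in a single batched
    forward pass) and offsets whose perturbation moves the center output
    are collected; the analytic derivative map from a backward pass is
    unioned in.  `extent` must cover the analytic receptive field.
    """
    if extent < 1:
        raise ValueError("extent must be >= 1")
    side = 2 * extent + 1
    c = extent
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), 777))))
    found: set[tuple[int, int]] = set()
    for _ in range(probes):
        base = rng.random((side, side), dtype=np.float32)
        # last batch element stays unperturbed: comparing within one
        # batched forward keeps the float rounding path identical
        batch = np.repeat(base[None, None], side * side + 1, axis=0)
        idx = np.arange(side * side)
        batch[idx, 0, idx // side, idx % side] += 0.5
        outs = net.forward(batch)[:, 0, c, c]
        hit = np.flatnonzero(outs[:-1] != outs[-1])
        found |= {(int(k // side) - c, int(k % side) - c) for k in hit}
        # derivative of the center output w.r.t. every input pixel
        net.zero_grad()
        net.forward(base[None, None], cache=True)
        g = np.zeros((1, 1, side, side), dtype=np.float32)
        g[0, 0, c, c] = 1.0
        dx = net.backward(g)[0, 0]
        net.zero_grad()
        ii, jj = np.nonzero(dx)
        found |= {(int(a) - c, int(b) - c) for a, b in zip(ii, jj)}
    return frozenset(found)


def analytic_extent(spec: NetSpec) -> int:
    """A radius guaranteed to cover the receptive field, from the layer
    footprints alone: donut radius + sum over paths of depth * dilation."""
    half = spec.donut_K // 2
    return half + max((d * m for d, m in spec.paths), default=0)
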