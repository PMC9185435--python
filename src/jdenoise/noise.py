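"""Noise simulators and a procedural clean-image generator.

Four corruption models on [0,1] grayscale images:

* additive white Gaussian noise (AWGN): ``y = x + n``, ``n ~ N(0, sg^2)``
* multiplicative speckle: ``y = x + n * x`` with ``n`` zero-mean uniform of
  standard deviation ``ss`` (support ``[-sqrt(3) ss, +sqrt(3) ss]``)
* salt-and-pepper: each pixel independently replaced with probability ``d``
  by 0 or 1 (equiprobable)
* fusion: the composition salt_pepper(speckle(awgn(x)))

Noise levels ``sigma_g`` / ``sigma_s`` follow the printed 0-255 convention
of the denoising benchmark literature and are divided by 255 internally;
``d`` is a probability in [0,1].  AWGN and speckle outputs are deliberately
NOT clipped to [0,1]: the self-supervision theory requires the injected
perturbation to stay zero-mean, and clipping would bias it.  Clip at
metric or export time instead.

Each seed expands into independent named substreams (gaussian, uniform,
mask, value), so disabling one fusion component never shifts the draws of
another: fusion with two components off is bit-identical to the remaining
single-noise simulator at the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NoiseSpec", "add_awgn", "add_speckle", "add_salt_pepper", "add_fusion",
    "apply_noise", "make_synthetic_clean", "SYNTHETIC_KINDS",
]

_FAMILIES = ("awgn", "speckle", "salt_pepper", "fusion")

# fixed substream labels: gaussian draws, uniform draws, replacement mask,
# replacement values
_STREAMS = {"gaussian": 0, "uniform": 1, "mask": 2, "value": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), _STREAMS[stream]))))


@dataclass(frozen=True)
class NoiseSpec:
    """A noise family plus its parameters on the printed scales."""

    family: str = "fusion"
    sigma_g: float = 0.0   # Gaussian std, 0-255 scale
    sigma_s: float = 0.0   # speckle std, 0-255 scale
    d: float = 0.0         # replacement probability in [0, 1]
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; "
                             f"expected one of {_FAMILIES}")
        if self.sigma_g < 0 or self.sigma_s < 0:
            raise ValueError("sigma_g and sigma_s must be non-negative")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must lie in [0, 1]")


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("expected a 2-D grayscale image")
    return img


def add_awgn(img: np.ndarray, sigma_g: float, seed: int) -> np.ndarray:
    """Additive white Gaussian noise with std ``sigma_g/255``."""
    img = _check_image(img)
    if sigma_g < 0:
        raise ValueError("sigma_g must be non-negative")
    if sigma_g == 0:
        return img.copy()
    n = _rng(seed, "gaussian").standard_normal(img.shape) * (sigma_g / 255.0)
    return img + n


def add_speckle(img: np.ndarray, sigma_s: float, seed: int) -> np.ndarray:
    """Multiplicative zero-mean uniform speckle with std ``sigma_s/255``."""
    img = _check_image(img)
    if sigma_s < 0:
        raise ValueError("sigma_s must be non-negative")
    if sigma_s == 0:
        return img.copy()
    half = np.sqrt(3.0) * sigma_s / 255.0
    n = _rng(seed, "uniform").uniform(-half, half, size=img.shape)
    return img + n * img


def add_salt_pepper(img: np.ndarray, d: float, seed: int) -> np.ndarray:
    """Replace each pixel with prob ``d`` by 0 or 1 (equiprobable)."""
    img = _check_image(img)
    if not 0.0 <= d <= 1.0:
        raise ValueError("d must lie in [0, 1]")
    if d == 0:
        return img.copy()
    replace = _rng(seed, "mask").random(img.shape) < d
    salt = _rng(seed, "value").random(img.shape) < 0.5
    out = img.copy()
    out[replace] = salt[replace].astype(np.float64)
    return out


def add_fusion(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Gaussian, then speckle on the Gaussian-corrupted signal, then
    salt-and-pepper replacement — in exactly that order."""
    if spec.family != "fusion":
        raise ValueError("add_fusion requires a spec with family='fusion'")
    out = add_awgn(img, spec.sigma_g, spec.seed)
    out = add_speckle(out, spec.sigma_s, spec.seed)
    return add_salt_pepper(out, spec.d, spec.seed)


def apply_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Dispatch on ``spec.family``."""
    if spec.family == "awgn":
        return add_awgn(img, spec.sigma_g, spec.seed)
    if spec.family == "speckle":
        return add_speckle(img, spec.sigma_s, spec.seed)
    if spec.family == "salt_pepper":
        return add_salt_pepper(img, spec.d, spec.seed)
    return add_fusion(img, spec)


SYNTHETIC_KINDS = ("flat", "gradient", "shapes", "checker", "texture")


def make_synthetic_clean(kind: str, height: int, width: int,
                         seed: int = 0) -> np.ndarray:
    """Deterministic clean test images in [0,1].

    The generator emulates the piecewise-smooth structure of natural
    grayscale photographs at desk scale: ``flat`` (constant region),
    ``gradient`` (smooth shading ramp), ``shapes`` (piecewise-constant
    regions with sharp edges — the regime where brightness preservation
    and total-variation behavior are visible), ``checker`` (periodic
    high-contrast edges) and ``texture`` (band-limited smooth random
    field standing in for fine texture).
    """
    if kind not in SYNTHETIC_KINDS:
        raise ValueError(f"unknown synthetic kind {kind!r}; "
                         f"expected one of {SYNTHETIC_KINDS}")
    if height < 16 or width < 16:
        raise ValueError("height and width must be at least 16")
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence((int(seed), 97))))
    if kind == "flat":
        level = 0.2 + 0.6 * rng.random()
        return np.full((height, width), level, dtype=np.float64)
    if kind == "gradient":
        col = np.linspace(0.0, 1.0, height)
        return np.repeat(col[:, None], width, axis=1)
    if kind == "checker":
        cell = max(4, min(height, width) // 8)
        yy, xx = np.mgrid[0:height, 0:width]
        return (((yy // cell) + (xx // cell)) % 2).astype(np.float64)
    if kind == "texture":
        # band-limited: low-res Gaussian field, bilinearly upsampled,
        # rescaled to [0.1, 0.9]
        low = rng.standard_normal((max(4, height // 8), max(4, width // 8)))
        ys = np.linspace(0, low.shape[0] - 1, height)
        xs = np.linspace(0, low.shape[1] - 1, width)
        y0 = np.clip(ys.astype(int), 0, low.shape[0] - 2)
        x0 = np.clip(xs.astype(int), 0, low.shape[1] - 2)
        fy = (ys - y0)[:, None]
        fx = (xs - x0)[None, :]
        img = ((1 - fy) * (1 - fx) * low[np.ix_(y0, x0)]
               + (1 - fy) * fx * low[np.ix_(y0, x0 + 1)]
               + fy * (1 - fx) * low[np.ix_(y0 + 1, x0)]
               + fy * fx * low[np.ix_(y0 + 1, x0 + 1)])
        lo, hi = img.min(), img.max()
        if hi - lo < 1e-12:
            return np.full((height, width), 0.5)
        return 0.1 + 0.8 * (img - lo) / (hi - lo)
    # shapes: dark background, a handful of constant-intensity rectangles
    # and disks with sharp edges
    img = np.full((height, width), 0.15, dtype=np.float64)
    yy, xx = np.mgrid[0:height, 0:width]
    for _ in range(6):
        level = 0.2 + 0.75 * rng.random()
        if rng.random() < 0.5:
            h = int(height * (0.15 + 0.3 * rng.random()))
            w = int(width * (0.15 + 0.3 * rng.random()))
            top = rng.integers(0, max(1, height - h))
            left = rng.integers(0, max(1, width - w))
            img[top:top + h, left:left + w] = level
        else:
            cy = rng.integers(0, height)
            cx = rng.integers(0, width)
            r = max(3, int(min(height, width) * (0.08 + 0.15 * rng.random())))
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = level
    return img
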