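"""Full-reference image quality metrics: PSNR and SSIM.

PSNR(ref, test) = 20 log10(MAX / sqrt(MSE)).  SSIM follows the standard
luminance/contrast/structure form

    SSIM = (2 mu_x mu_y + c1)(2 sigma_xy + c2)
           / ((mu_x^2 + mu_y^2 + c1)(sigma_x^2 + sigma_y^2 + c2))

with c1 = (k1 L)^2, c2 = (k2 L)^2, k1 = 0.01, k2 = 0.03 and L the dynamic
range.  Two window conventions are provided: the de-facto standard local
11x11 Gaussian window (sigma = 1.5, mean over locations after trimming
the filter radius) and a whole-image single-window mode in which the
statistics are global — useful for closed-form checks on constant images.

Inputs are clipped to [0, max_val] before evaluation; network outputs and
unclipped noisy images may exceed the nominal range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["MetricConfig", "psnr", "ssim", "evaluate_pair_table",
           "format_report"]


@dataclass(frozen=True)
class MetricConfig:
    max_val: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    window: str = "gaussian11"   # or "global"
    sigma: float = 1.5

    def __post_init__(self):
        if self.max_val <= 0 or self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("max_val, k1, k2 must be positive")
        if self.window not in ("gaussian11", "global"):
            raise ValueError("window must be 'gaussian11' or 'global'")


def _prep(ref, test, max_val):
    ref = np.clip(np.asarray(ref, dtype=np.float64), 0.0, max_val)
    test = np.clip(np.asarray(test, dtype=np.float64), 0.0, max_val)
    if ref.shape != test.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {test.shape}")
    return ref, test


def psnr(ref: np.ndarray, test: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    ref, test = _prep(ref, test, max_val)
    mse = float(np.mean((ref - test) ** 2))
    if mse == 0.0:
        return math.inf
    return 20.0 * math.log10(max_val / math.sqrt(mse))


def ssim(ref: np.ndarray, test: np.ndarray,
         config: MetricConfig = MetricConfig()) -> float:
    """Structural similarity in [-1, 1]; 1 iff the clipped images are
    identical."""
    ref, test = _prep(ref, test, config.max_val)
    L = config.max_val
    c1 = (config.k1 * L) ** 2
    c2 = (config.k2 * L) ** 2
    if config.window == "global":
        mx, my = ref.mean(), test.mean()
        vx, vy = ref.var(), test.var()
        cxy = float(np.mean((ref - mx) * (test - my)))
        return ((2 * mx * my + c1) * (2 * cxy + c2)
                / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    win = 11
    if min(ref.shape) < win:
        raise ValueError(f"image smaller than the {win}x{win} SSIM window")
    # truncate so the Gaussian kernel spans exactly the 11x11 window
    r = (win - 1) // 2
    truncate = (win - 1) / (2.0 * config.sigma)

    def f(a):
        return gaussian_filter(a, sigma=config.sigma, truncate=truncate,
                               mode="reflect")

    ux, uy = f(ref), f(test)
    vx = f(ref * ref) - ux * ux
    vy = f(test * test) - uy * uy
    cxy = f(ref * test) - ux * uy
    s = ((2 * ux * uy + c1) * (2 * cxy + c2)
         / ((ux * ux + uy * uy + c1) * (vx + vy + c2)))
    return float(s[r:-r, r:-r].mean())


def evaluate_pair_table(clean_dir, denoised_dir,
                        config: MetricConfig = MetricConfig()):
    """Per-image and mean PSNR/SSIM for matching filenames in two
    directories.  Returns (rows, means); rows are (name, psnr, ssim)."""
    from .io import read_gray

    clean_dir, denoised_dir = Path(clean_dir), Path(denoised_dir)
    names = sorted(p.name for p in clean_dir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not names:
        raise ValueError(f"no images found in {clean_dir}")
    missing = [n for n in names if not (denoised_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"missing counterpart file(s) in {denoised_dir}: {missing}")
    rows = []
    for n in names:
        ref = read_gray(clean_dir / n)
        test = read_gray(denoised_dir / n)
        rows.append((n, psnr(ref, test, config.max_val),
                     ssim(ref, test, config)))
    mean_psnr = float(np.mean([r[1] for r in rows]))
    mean_ssim = float(np.mean([r[2] for r in rows]))
    return rows, (mean_psnr, mean_ssim)


def format_report(rows, means, config: MetricConfig,
                  provenance: str = "") -> str:
    """Deterministic tab-separated report with the metric config in the
    header."""
    lines = [
        f"# metric_config\tmax_val={config.max_val}\tk1={config.k1}\t"
        f"k2={config.k2}\twindow={config.window}\tsigma={config.sigma}",
    ]
    if provenance:
        lines.append(f"# provenance\t{provenance}")
    lines.append("image\tpsnr_db\tssim")
    for name, p, s in rows:
        lines.append(f"{name}\t{p:.4f}\t{s:.6f}")
    lines.append(f"mean\t{means[0]:.4f}\t{means[1]:.6f}")
    return "\n".join(lines) + "\n"
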