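"""Self-supervision loss family.

For a J-invariant network f and zero-mean noise, the self-supervision
loss E||f(x) - x||^2 decomposes into the supervised loss plus the noise
variance, so minimizing it trains a genuine denoiser without clean
targets.  Impulse noise (salt-and-pepper) breaks the zero-mean premise:
a pixel replaced by 0/1 pulls the prediction toward the replacement
value and shifts the restored brightness.  The adaptive self-supervision
(ADSS) loss counters this by down-weighting pixels whose residual
|f(x)_j - x_j| is large — exactly the pixels most likely to be impulse
noise:

    L_adss = mean_j[ w_j (f(x)_j - x_j)^2 ],   w_j = 1 / (1 + lambda |r_j|)

with the focusing parameter lambda (0 recovers plain L2).  By default the
weights are treated as constants during differentiation ("detached"), so
backpropagation from outlier pixels is suppressed rather than redirected.
A clipped variant (cap each squared residual at epsilon) is the blunt,
non-adaptive precursor of the same idea, and an anisotropic total-
variation term can be added to smooth out residual pixel-level artifacts.

All losses accept (..., H, W) arrays and reduce by the mean over every
pixel of the batch; gradient helpers return d loss / d pred of the same
shape for the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LossSpec", "loss_l2", "adss_weights", "loss_adss", "loss_tv",
    "loss_adss_tv", "loss_clipped", "check_loss_decomposition",
]


@dataclass(frozen=True)
class LossSpec:
    """family in {'l2', 'adss', 'clipped'} plus its knobs."""

    family: str = "adss"
    lam: float = 10.0
    alpha: float = 0.0
    epsilon: float = 0.2
    detach_weights: bool = True

    def __post_init__(self):
        if self.family not in ("l2", "adss", "clipped"):
            raise ValueError(f"unknown loss family {self.family!r}")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.family == "clipped" and self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    def value(self, pred: np.ndarray, noisy: np.ndarray) -> float:
        if self.family == "l2":
            data = loss_l2(pred, noisy)
        elif self.family == "adss":
            data = loss_adss(pred, noisy, self.lam, self.detach_weights)
        else:
            data = loss_clipped(pred, noisy, self.epsilon)
        if self.alpha > 0:
            data += self.alpha * loss_tv(pred)
        return data

    def value_and_grad(self, pred: np.ndarray, noisy: np.ndarray):
        """(scalar loss, d loss / d pred) for the optimizer."""
        _check_shapes(pred, noisy)
        r = pred - noisy
        n = r.size
        if self.family == "l2":
            data = float(np.mean(r * r))
            g = (2.0 / n) * r
        elif self.family == "adss":
            w = adss_weights(r, self.lam)
            data = float(np.mean(w * r * r))
            if self.detach_weights:
                g = (2.0 / n) * w * r
            else:
                # d/dr [r^2 / (1 + lam|r|)] = r (2 + lam|r|) / (1 + lam|r|)^2
                g = (1.0 / n) * r * (2.0 + self.lam * np.abs(r)) * w * w
        else:
            r2 = r * r
            data = float(np.mean(np.minimum(r2, self.epsilon)))
            g = np.where(r2 < self.epsilon, (2.0 / n) * r, 0.0)
        if self.alpha > 0:
            tv, gtv = _tv_value_grad(pred)
            data += self.alpha * tv
            g = g + self.alpha * gtv
        return data, g


def _check_shapes(pred: np.ndarray, noisy: np.ndarray) -> None:
    if np.shape(pred) != np.shape(noisy):
        raise ValueError(f"shape mismatch: {np.shape(pred)} vs "
                         f"{np.shape(noisy)}")


def loss_l2(pred: np.ndarray, noisy: np.ndarray) -> float:
    """Plain self-supervision: mean squared residual against the noisy
    input itself."""
    _check_shapes(pred, noisy)
    r = np.asarray(pred, dtype=np.float64) - np.asarray(noisy,
                                                        dtype=np.float64)
    return float(np.mean(r * r))


def adss_weights(residual: np.ndarray, lam: float) -> np.ndarray:
    """w = 1 / (1 + lambda |residual|), elementwise, in (0, 1]."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return 1.0 / (1.0 + lam * np.abs(residual))


def loss_adss(pred: np.ndarray, noisy: np.ndarray, lam: float,
              detach_weights: bool = True) -> float:
    """Adaptive self-supervision loss; `detach_weights` only affects
    gradients, not the value."""
    _check_shapes(pred, noisy)
    del detach_weights
    r = np.asarray(pred, dtype=np.float64) - np.asarray(noisy,
                                                        dtype=np.float64)
    return float(np.mean(adss_weights(r, lam) * r * r))


def loss_tv(pred: np.ndarray) -> float:
    """Anisotropic total variation: sum of |forward differences| along
    both axes (no wraparound), summed over pixels, averaged over any
    leading batch axes."""
    p = np.asarray(pred, dtype=np.float64)
    if p.ndim < 2:
        raise ValueError("TV needs at least a 2-D image")
    if p.shape[-1] < 2 and p.shape[-2] < 2:
        return 0.0
    batch = int(np.prod(p.shape[:-2])) if p.ndim > 2 else 1
    tv = (np.abs(np.diff(p, axis=-1)).sum()
          + np.abs(np.diff(p, axis=-2)).sum())
    return float(tv / batch)


def _tv_value_grad(pred: np.ndarray):
    p = np.asarray(pred, dtype=np.float64)
    batch = int(np.prod(p.shape[:-2])) if p.ndim > 2 else 1
    g = np.zeros_like(p)
    dh = np.diff(p, axis=-1)
    sh = np.sign(dh)
    g[..., :, 1:] += sh
    g[..., :, :-1] -= sh
    dv = np.diff(p, axis=-2)
    sv = np.sign(dv)
    g[..., 1:, :] += sv
    g[..., :-1, :] -= sv
    tv = (np.abs(dh).sum() + np.abs(dv).sum()) / batch
    return float(tv), g / batch


def loss_adss_tv(pred: np.ndarray, noisy: np.ndarray, lam: float,
                 alpha: float, detach_weights: bool = True) -> float:
    """ADSS data term plus alpha times the TV of the prediction."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return loss_adss(pred, noisy, lam, detach_weights) + alpha * loss_tv(pred)


def loss_clipped(pred: np.ndarray, noisy: np.ndarray,
                 epsilon: float) -> float:
    """Mean of per-pixel squared residual clamped above at epsilon."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    _check_shapes(pred, noisy)
    r = np.asarray(pred, dtype=np.float64) - np.asarray(noisy,
                                                        dtype=np.float64)
    return float(np.mean(np.minimum(r * r, epsilon)))


def check_loss_decomposition(net, clean: np.ndarray, noise_spec,
                             replicates: int = 200):
    """Monte-Carlo check of the self-supervision decomposition.

    For a J-invariant net f under zero-mean noise,
    E||f(x)-x||^2 = E||f(x)-y||^2 + E||x-y||^2.  Draws `replicates`
    independent noise realizations of the clean image y, evaluates both
    sides per draw, and returns a dict with the two means and the
    standard error of their paired difference, so a caller can assert
    |lhs - rhs| <= 3 se for zero-mean noise and > 3 se for the
    salt-and-pepper negative control.
    """
    from dataclasses import replace
    from .noise import apply_noise

    clean = np.asarray(clean, dtype=np.float64)
    lhs = np.empty(replicates)
    rhs = np.empty(replicates)
    for k in range(replicates):
        spec_k = replace(noise_spec, seed=noise_spec.seed + k)
        x = apply_noise(clean, spec_k)
        f = net.apply(x)
        lhs[k] = np.mean((f - x) ** 2)
        rhs[k] = np.mean((f - clean) ** 2) + np.mean((x - clean) ** 2)
    diff = lhs - rhs
    se = float(diff.std(ddof=1) / np.sqrt(replicates))
    return {
        "self_supervised": float(lhs.mean()),
        "supervised_plus_variance": float(rhs.mean()),
        "gap": float(diff.mean()),
        "gap_se": se,
        "replicates": replicates,
    }
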