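"""Segmentation loss families: binary cross-entropy, focal, Tversky, focal Tversky.

All losses take a binary target volume ``y`` and a predicted probability
volume ``yhat`` of the same shape.  The voxel-wise losses (cross-entropy,
focal) are reduced by the mean over all voxels; the Tversky index is a
global soft-overlap statistic

    T = (sum y*yhat + eps) / (sum y*yhat + beta * sum (1-y)*yhat
                              + (1-beta) * sum y*(1-yhat) + eps)

with ``beta`` weighting false positives against false negatives (beta = 0.5
recovers the Dice coefficient, so the Tversky loss 1 - T equals 1 - Dice).
The focal Tversky loss is ``(1 - T) ** (1/gamma)``: the exponent is 1/gamma,
which flattens rather than sharpens the loss near T = 1.  Some authors apply
gamma directly instead; ``focal_tversky_loss(..., exponent="direct")``
provides that variant, but the default is the 1/gamma form.

The beta grid used for model selection is 0.45, 0.50, ..., 0.95; the focal
exponent defaults to gamma = 2.

``loss_and_grad`` additionally returns d(loss)/d(yhat) for the training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EPS_CLIP = 1e-7  # probability clipping for log terms
EPS_SMOOTH = 1.0  # Tversky smoothing; defines the empty-mask case

__all__ = [
    "LossSpec",
    "tversky_beta_grid",
    "binary_cross_entropy",
    "focal_loss",
    "tversky_loss",
    "focal_tversky_loss",
    "evaluate_loss",
    "loss_and_grad",
]

_FAMILIES = ("binary_cross_entropy", "focal", "tversky", "focal_tversky")


@dataclass(frozen=True)
class LossSpec:
    """A loss family plus its parameters (beta for Tversky, gamma for focal)."""

    family: str
    beta: float | None = None
    gamma: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown loss family {self.family!r}")
        is_tversky = self.family in ("tversky", "focal_tversky")
        if is_tversky:
            if self.beta is None or not 0.0 <= self.beta <= 1.0:
                raise ValueError("Tversky losses require beta in [0, 1]")
        elif self.beta is not None:
            raise ValueError(f"{self.family} takes no beta")
        if self.family in ("focal", "focal_tversky"):
            g = 2.0 if self.gamma is None else self.gamma
            if g <= 0:
                raise ValueError("gamma must be > 0")
            object.__setattr__(self, "gamma", g)
        elif self.gamma is not None:
            raise ValueError(f"{self.family} takes no gamma")

    @property
    def label(self) -> str:
        name = {
            "binary_cross_entropy": "Binary cross-entropy",
            "focal": "Focal",
            "tversky": "Tversky",
            "focal_tversky": "Focal Tversky",
        }[self.family]
        return f"{name} ({self.beta:.2f})" if self.beta is not None else name


def tversky_beta_grid() -> list[float]:
    """The beta grid used for loss selection: 0.45 to 0.95 in steps of 0.05."""
    return [round(0.45 + 0.05 * i, 2) for i in range(11)]


def _check(y, yhat):
    y = np.asarray(y)
    yhat = np.asarray(yhat)
    if y.shape != yhat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {yhat.shape}")
    return y.astype(np.float64), np.clip(yhat.astype(np.float64), EPS_CLIP, 1.0 - EPS_CLIP)


def binary_cross_entropy(y, yhat) -> float:
    """Mean over voxels of -[y log yhat + (1-y) log(1-yhat)]."""
    y, p = _check(y, yhat)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def focal_loss(y, yhat, gamma: float = 2.0) -> float:
    """Mean of -(1-p_t)^gamma log(p_t) with p_t = yhat where y=1, else 1-yhat."""
    y, p = _check(y, yhat)
    pt = np.where(y > 0.5, p, 1.0 - p)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def _tversky_index(y, p, beta):
    tp = float(np.sum(y * p))
    fp = float(np.sum((1.0 - y) * p))
    fn = float(np.sum(y * (1.0 - p)))
    num = tp + EPS_SMOOTH
    den = tp + beta * fp + (1.0 - beta) * fn + EPS_SMOOTH
    return num, den


def tversky_loss(y, yhat, beta: float) -> float:
    """1 - T(y, yhat); beta = 0.5 gives 1 - Dice."""
    y, p = _check(y, yhat)
    num, den = _tversky_index(y, p, beta)
    return float(1.0 - num / den)


def focal_tversky_loss(y, yhat, beta: float, gamma: float = 2.0, exponent: str = "inverse") -> float:
    """(1 - T)^(1/gamma); ``exponent='direct'`` uses (1 - T)^gamma instead."""
    lt = tversky_loss(y, yhat, beta)
    e = 1.0 / gamma if exponent == "inverse" else gamma
    return float(lt**e)


def evaluate_loss(spec: LossSpec, y, yhat) -> float:
    """Dispatch on a LossSpec."""
    if spec.family == "binary_cross_entropy":
        return binary_cross_entropy(y, yhat)
    if spec.family == "focal":
        return focal_loss(y, yhat, spec.gamma)
    if spec.family == "tversky":
        return tversky_loss(y, yhat, spec.beta)
    return focal_tversky_loss(y, yhat, spec.beta, spec.gamma)


def loss_and_grad(spec: LossSpec, y, yhat):
    """Loss value and gradient d(loss)/d(yhat), for the training loop.

    Gradients are exact for the clipped probabilities (voxels at the clip
    boundary get the clipped-point gradient, which is bounded).
    """
    yb = np.asarray(y).astype(np.float32)
    p = np.clip(np.asarray(yhat, dtype=np.float32), EPS_CLIP, 1.0 - EPS_CLIP)
    n = p.size
    if spec.family == "binary_cross_entropy":
        val = float(-np.mean(yb * np.log(p) + (1.0 - yb) * np.log(1.0 - p)))
        grad = (p - yb) / (p * (1.0 - p)) / n
        return val, grad.astype(np.float32)
    if spec.family == "focal":
        g = spec.gamma
        pt = np.where(yb > 0.5, p, 1.0 - p)
        one_m = 1.0 - pt
        val = float(np.mean(-(one_m**g) * np.log(pt)))
        dpt = g * one_m ** (g - 1.0) * np.log(pt) - one_m**g / pt
        sign = np.where(yb > 0.5, 1.0, -1.0)
        return val, (dpt * sign / n).astype(np.float32)
    # Tversky families
    beta = spec.beta
    tp = float(np.sum(yb * p))
    fp = float(np.sum((1.0 - yb) * p))
    fn = float(np.sum(yb * (1.0 - p)))
    num = tp + EPS_SMOOTH
    den = tp + beta * fp + (1.0 - beta) * fn + EPS_SMOOTH
    T = num / den
    # dT/dp_i = (y_i * den - num * beta) / den^2   (d(den)/dp_i == beta for all i)
    dT = (yb * den - num * beta) / (den * den)
    if spec.family == "tversky":
        return float(1.0 - T), (-dT).astype(np.float32)
    e = 1.0 / spec.gamma
    lt = max(1.0 - T, 1e-12)
    val = float(lt**e)
    dval = e * lt ** (e - 1.0)
    return val, (-dval * dT).astype(np.float32)
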