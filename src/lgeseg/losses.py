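"""Training losses for both segmentation stages.

The anatomical stage minimises cross-entropy plus a (negative) soft Dice
term; the pathological stage minimises a composite of a multi-class soft
IoU segmentation term, a Frobenius-norm inclusion term on frozen-CVAE
reconstructions, and a binary patient-class cross-entropy, weighted by
(λ_IC, λ_CC).

Conventions: the class axis is axis 0 for unbatched (K, X, Y, Z) grids and
axis 1 for batched (N, K, ...) grids; Dice keeps the negative sign (optimum
−1 with every class present); the soft-IoU loss is 1 − mean per-class IoU
overlap (optimum 0), with the raw overlap exposed separately.  All ratio
losses carry an ε-guard so that classes absent from both inputs contribute
zero overlap without dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, softmax

EPS = 1e-6


@dataclass
class LossWeights:
    """The (λ_IC, λ_CC) regularisation pair; defaults from the tuned
    interval (10⁻², 10⁻¹)."""

    lambda_ic: float = 1e-2
    lambda_cc: float = 1e-1

    def __post_init__(self):
        if self.lambda_ic < 0 or self.lambda_cc < 0:
            raise ValueError("loss weights must be >= 0")


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _class_axis(x: Tensor) -> int:
    return 0 if x.ndim == 4 else 1


def _nonclass_axes(x: Tensor) -> tuple:
    ca = _class_axis(x)
    return tuple(a for a in range(x.ndim) if a != ca)


def loss_dice(u, v, eps: float = EPS) -> Tensor:
    """Negative soft Dice: −(2/|K|)·Σ_k Σ_i u·v / max(Σ_i u + Σ_i v, ε)."""
    u, v = _t(u), _t(v)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    axes = _nonclass_axes(u)
    inter = (u * v).sum(axis=axes)
    denom = (u.sum(axis=axes) + v.sum(axis=axes)).clamp_min(eps)
    k = u.shape[_class_axis(u)]
    return (inter / denom).sum() * (-2.0 / k)


def loss_ce(u, v, eps: float = 1e-12) -> Tensor:
    """Mean over voxels of −log u at the true class (ε-clamped)."""
    u, v = _t(u), _t(v)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch {u.shape} vs {v.shape}")
    n_vox = u.data.size // u.shape[_class_axis(u)]
    return -(v * u.clamp_min(eps).log()).sum() * (1.0 / n_vox)


def loss_anatomical(u, v) -> Tensor:
    """Cross-entropy + Dice; the anatomical training objective."""
    return loss_ce(u, v) + loss_dice(u, v)


def soft_iou_overlap(p, pstar, eps: float = EPS) -> Tensor:
    """Mean per-class soft IoU: (1/|C|)·Σ_c Σ_i p·p* / Σ_i (p + p* − p·p*)."""
    p, pstar = _t(p), _t(pstar)
    if p.shape != pstar.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {pstar.shape}")
    axes = _nonclass_axes(p)
    num = (p * pstar).sum(axis=axes)
    den = ((p + pstar - p * pstar).sum(axis=axes)).clamp_min(eps)
    k = p.shape[_class_axis(p)]
    return (num / den).sum() * (1.0 / k)


def loss_soft_iou(p, pstar, eps: float = EPS) -> Tensor:
    """Segmentation loss 1 − mean soft IoU (minimised; 0 at perfection)."""
    return 1.0 - soft_iou_overlap(p, pstar, eps)


def loss_inclusion(rp, rg, normalize: bool = False) -> Tensor:
    """Σ over the batch of squared Frobenius norms of RP − RG.

    With ``normalize=True`` the sum is divided by the number of grid
    entries (a per-entry mean squared error), which keeps the term on the
    same O(1) scale as the segmentation loss regardless of window size —
    the form used inside the training objective so the published λ range
    stays meaningful.
    """
    rp, rg = _t(rp), _t(rg)
    if rp.shape != rg.shape:
        raise ValueError(f"shape mismatch {rp.shape} vs {rg.shape}")
    d = rp - rg
    out = (d * d).sum()
    if normalize:
        out = out * (1.0 / d.data.size)
    return out


def loss_class(scores, patient_label, eps: float = 1e-12) -> Tensor:
    """Binary cross-entropy of softmaxed 2-class scores.

    `patient_label` is 0 (normal) / 1 (infarcted), scalar or per-sample.
    """
    s = _t(scores)
    if s.ndim == 1:
        s = s.reshape(1, -1)
    labels = np.atleast_1d(np.asarray(patient_label))
    onehot = np.zeros(s.shape, dtype=np.float64)
    onehot[np.arange(len(labels)), labels.astype(int)] = 1.0
    p = softmax(s, axis=1)
    return -(Tensor(onehot) * p.clamp_min(eps).log()).sum() * (1.0 / len(labels))


def loss_final(p, pstar, rp, rg, scores, patient_label,
               weights: LossWeights, normalize_ic: bool = False) -> Tensor:
    """L = L_seg + λ_IC·L_IC + λ_CC·L_CC (the pathological objective)."""
    total = loss_soft_iou(p, pstar)
    if weights.lambda_ic:
        total = total + weights.lambda_ic * loss_inclusion(
            rp, rg, normalize=normalize_ic)
    if weights.lambda_cc:
        total = total + weights.lambda_cc * loss_class(scores, patient_label)
    return total


def kl_divergence(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL(q‖N(0,I)) per batch sample, summed over latent dims."""
    n = mu.shape[0]
    return (mu * mu + logvar.exp() - logvar - 1.0).sum() * (0.5 / n)


def onehot_encode(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(K, X, Y, Z) one-hot of an integer grid (or (N, K, ...) if batched)."""
    arr = np.asarray(labels)
    eye = np.eye(n_classes, dtype=np.float32)
    oh = eye[arr]  # (..., K)
    return np.moveaxis(oh, -1, 0 if arr.ndim == 3 else 1)
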