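"""Multi-task objective: hybrid segmentation loss + staging cross-entropy.

The total loss combines a segmentation term (soft Jaccard + focal) and
a classification term (cross-entropy) under trainable task weights.
The default weighting is homoscedastic-uncertainty style: each task
weight is exp(-s) with a trainable log-precision s (plus the s
regulariser), initialised at s = 0 so both effective weights start at
1 and adapt during training.  A fixed-weight mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "soft_jaccard_loss",
    "focal_loss",
    "cross_entropy_cls",
    "combined_loss",
]

JACCARD_SMOOTH = 1.0
FOCAL_GAMMA = 2.0
FOCAL_ALPHA = 0.25
PROB_CLIP = 1e-7


class LossWeights:
    """Trainable task weights λ_seg = exp(-s_seg), λ_cls = exp(-s_cls).

    With ``trainable=False`` the weights stay fixed at their initial
    value of 1 (s = 0 and no gradient).
    """

    def __init__(self, trainable: bool = True, dtype=np.float32):
        self.trainable = trainable
        self.s_seg = Tensor(np.zeros((), dtype=dtype), requires_grad=trainable)
        self.s_cls = Tensor(np.zeros((), dtype=dtype), requires_grad=trainable)

    def parameters(self) -> list[Tensor]:
        return [self.s_seg, self.s_cls] if self.trainable else []

    @property
    def lambda_seg(self) -> float:
        return float(np.exp(-self.s_seg.data))

    @property
    def lambda_cls(self) -> float:
        return float(np.exp(-self.s_cls.data))


@dataclass
class LossBreakdown:
    """Components of one evaluation of the combined objective."""

    total: Tensor
    seg_component: float
    cls_component: float
    jaccard: float
    focal: float
    lambda_seg: float
    lambda_cls: float


def soft_jaccard_loss(pred: Tensor, truth: Tensor, smooth: float = JACCARD_SMOOTH) -> Tensor:
    """1 - (Σ p̂·p + ε) / (Σ p̂ + Σ p − Σ p̂·p + ε) over all voxels."""
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    inter = (pred * truth).sum()
    union = pred.sum() + truth.sum() - inter
    return 1.0 - (inter + smooth) / (union + smooth)


def focal_loss(pred: Tensor, truth: Tensor, gamma: float = FOCAL_GAMMA,
               alpha: float = FOCAL_ALPHA) -> Tensor:
    """Mean focal loss −α_t (1 − p_t)^γ log p_t on a binary target.

    p_t is the predicted probability of the true class; α weights the
    foreground and (1 − α) the background.  With γ = 0 this reduces to
    α-weighted binary cross-entropy.
    """
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred.clip(PROB_CLIP, 1.0 - PROB_CLIP)
    pt = p * truth + (1.0 - p) * (1.0 - truth)
    alpha_t = alpha * truth + (1.0 - alpha) * (1.0 - truth)
    modulator = (1.0 - pt) ** gamma if gamma != 0 else 1.0
    return -(alpha_t * modulator * pt.log()).mean()


def cross_entropy_cls(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Mean −log p(true stage) over a batch; labels are stages in 1..4."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 1 or labels.max() > probs.shape[-1]:
        raise ValueError(f"stage labels must lie in 1..{probs.shape[-1]}")
    n = probs.shape[0]
    picked = probs[np.arange(n), labels - 1]
    return -(picked.clip(PROB_CLIP, 1.0).log()).mean()


def segmentation_loss(pred: Tensor, truth: Tensor, gamma: float = FOCAL_GAMMA,
                      alpha: float = FOCAL_ALPHA) -> tuple[Tensor, Tensor]:
    """The hybrid segmentation term: (jaccard, focal), summed unweighted by callers."""
    return soft_jaccard_loss(pred, truth), focal_loss(pred, truth, gamma, alpha)


def combined_loss(seg_pred: Tensor, seg_truth: Tensor, cls_probs: Tensor,
                  cls_labels: np.ndarray, weights: LossWeights,
                  gamma: float = FOCAL_GAMMA, alpha: float = FOCAL_ALPHA) -> LossBreakdown:
    """Total = e^{−s_seg}·L_seg + e^{−s_cls}·L_cls + s_seg + s_cls.

    At initialisation (s = 0) the total is exactly L_seg + L_cls.  With
    non-trainable weights the regulariser terms are constants with zero
    gradient, so the objective degenerates to the fixed 1·L_seg + 1·L_cls.
    """
    jac, foc = segmentation_loss(seg_pred, seg_truth, gamma, alpha)
    l_seg = jac + foc
    l_cls = cross_entropy_cls(cls_probs, cls_labels)
    for name, term in (("segmentation", l_seg), ("classification", l_cls)):
        if not np.isfinite(term.data):
            raise FloatingPointError(f"non-finite {name} loss component: {term.data}")
    w_seg = (-weights.s_seg).exp()
    w_cls = (-weights.s_cls).exp()
    total = w_seg * l_seg + w_cls * l_cls + weights.s_seg + weights.s_cls
    return LossBreakdown(
        total=total,
        seg_component=float(l_seg.data),
        cls_component=float(l_cls.data),
        jaccard=float(jac.data),
        focal=float(foc.data),
        lambda_seg=float(w_seg.data),
        lambda_cls=float(w_cls.data),
    )
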