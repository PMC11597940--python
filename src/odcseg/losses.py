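"""Loss functions of the style-contrastive / domain-adversarial framework.

All losses accept either plain numpy arrays or autodiff
:class:`~odcseg.nn.Tensor` objects and return a scalar ``Tensor`` (use
``float()`` or ``.item()`` on it).  Gradients flow whenever the inputs
require them.

The components:

* ``soft_dice_loss`` — pixel-level supervision: per-channel soft Dice
  ``1 - 2*sum(p*y) / (sum(p^2) + sum(y^2))`` averaged over the three
  classes (background, rim, cup).
* ``gram_matrix`` — channel co-occurrence matrix ``R^T R`` of a C-channel
  map reshaped to HWxC; the style descriptor.
* ``style_gap_loss`` — mean squared difference between two Gram matrices,
  normalised by C*C; the contrastive style distance between a normal-class
  and a glaucoma-class prediction.
* ``discriminator_bce_loss`` — patch binary cross-entropy of a domain
  discriminator with true labels (glaucoma = 1, normal = 0).
* ``adversarial_domain_loss`` — the generator-side domain gap: the cost
  of normal-sample predictions *not* being classified as glaucoma, in the
  encoding and output spaces, combined with weights ``w_e``/``w_o``.
* ``total_objective`` — the weighted sum
  ``w_seg*L_seg + w_style*L_style + w_domain*(w_e*L_enc + w_o*L_out)``.

Patch/pixel reductions are means by default for scale stability across
image sizes; ``reduction="sum"`` reproduces the raw-sum formulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "EPS",
    "GramMatrix",
    "LossWeights",
    "LossBreakdown",
    "soft_dice_loss",
    "gram_matrix",
    "style_gap_loss",
    "discriminator_bce_loss",
    "adversarial_domain_loss",
    "total_objective",
]

#: numerical floor inside logs and dice denominators
EPS = 1e-7


@dataclass(frozen=True)
class GramMatrix:
    """CxC channel co-occurrence matrix plus the shape it came from."""

    matrix: Tensor
    source_shape: tuple[int, int, int]

    def numpy(self) -> np.ndarray:
        return self.matrix.data


@dataclass(frozen=True)
class LossWeights:
    """Scalar weights of the overall objective.

    ``w_e + w_o`` must equal 1 (defaults 0.2 / 0.8).  The two-phase
    schedule uses :meth:`phase1` (1.0, 0.05, 0.0) for supervised + style
    warm-up and :meth:`phase2` (0.0, 0.0, 1.0) for adversarial refinement.
    """

    w_seg: float = 1.0
    w_style: float = 0.05
    w_domain: float = 0.0
    w_e: float = 0.2
    w_o: float = 0.8

    def __post_init__(self):
        for name in ("w_seg", "w_style", "w_domain", "w_e", "w_o"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if abs(self.w_e + self.w_o - 1.0) > 1e-9:
            raise ValueError("w_e and w_o must sum to 1")

    @classmethod
    def phase1(cls) -> "LossWeights":
        return cls(w_seg=1.0, w_style=0.05, w_domain=0.0)

    @classmethod
    def phase2(cls) -> "LossWeights":
        return cls(w_seg=0.0, w_style=0.0, w_domain=1.0)


@dataclass
class LossBreakdown:
    l_seg: float = 0.0
    l_style: float = 0.0
    l_domain_enc: float = 0.0
    l_domain_out: float = 0.0
    l_total: float = 0.0
    l_disc: float = 0.0


def _reduce(t: Tensor, reduction: str) -> Tensor:
    if reduction == "mean":
        return t.mean()
    if reduction == "sum":
        return t.sum()
    raise ValueError(f"unknown reduction {reduction!r}")


def soft_dice_loss(probs, target) -> Tensor:
    """Per-channel soft Dice loss averaged over channels; in [0, 1].

    ``probs`` and ``target`` are (C, H, W) or (N, C, H, W) with the
    channel sums running over every pixel (and batch element) of a
    channel.
    """
    p = as_tensor(probs)
    y = as_tensor(target)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs target {y.shape}")
    if p.ndim == 3:
        p = p.reshape((1,) + p.shape)
        y = y.reshape((1,) + y.shape)
    n_channels = p.shape[1]
    spatial = (0, 2, 3)
    num = (p * y).sum(axis=spatial)
    den = (p**2.0).sum(axis=spatial) + (y**2.0).sum(axis=spatial)
    dice = (2.0 * num) / (den + EPS)
    return (1.0 - dice).sum() * (1.0 / n_channels)


def gram_matrix(feature) -> GramMatrix:
    """Channel-wise Gram matrix ``R^T R`` of a (C, H, W) map (no normalisation)."""
    f = as_tensor(feature)
    if f.ndim != 3:
        raise ValueError(f"expected a (C, H, W) feature map, got shape {f.shape}")
    c, h, w = f.shape
    r = f.reshape((c, h * w)).transpose()     # HW x C
    return GramMatrix(matrix=r.transpose() @ r, source_shape=(c, h, w))


def _pairwise_gap(a: Tensor, b: Tensor) -> Tensor:
    c, h, w = a.shape
    scale = float(h * w * b.shape[1] * b.shape[2]) ** 0.25
    ga = gram_matrix(a).matrix
    gb = gram_matrix(b).matrix
    return (((ga - gb) * (1.0 / scale)) ** 2.0).sum() * (1.0 / (c * c))


def style_gap_loss(pred_a, pred_b) -> Tensor:
    """Squared Gram difference normalised by channel pairs and pixel count.

    The Gram matrices are compared after dividing by the pixel count
    H*W once — i.e. the loss is ``sum((Gram_a - Gram_b)^2) / (C^2 * HW)``
    for equally sized maps — so the style gap of softmax predictions
    lives on a scale where the shipped weight of 0.05 balances a Dice
    loss in [0, 1] rather than swamping it (raw Grams grow with the
    squared pixel count).  Accepts single (C, H, W) maps or batches
    (N, C, H, W); with batches the loss is averaged over all cross pairs
    (a_i, b_j).
    """
    a = as_tensor(pred_a)
    b = as_tensor(pred_b)
    if a.ndim == 3:
        a = a.reshape((1,) + a.shape)
    if b.ndim == 3:
        b = b.reshape((1,) + b.shape)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"channel mismatch: {a.shape[1]} vs {b.shape[1]}")
    pairs = []
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            pairs.append(_pairwise_gap(_index0(a, i), _index0(b, j)))
    total = pairs[0]
    for p in pairs[1:]:
        total = total + p
    return total * (1.0 / len(pairs))


def _index0(t: Tensor, i: int) -> Tensor:
    """Select t[i] along axis 0, keeping the autodiff graph."""
    n = t.shape[0]
    if n == 1:
        return t.reshape(t.shape[1:])
    sel = np.zeros((1, n), dtype=np.float32)
    sel[0, i] = 1.0
    flat = t.reshape((n, -1))
    picked = as_tensor(sel) @ flat
    return picked.reshape(t.shape[1:])


def _log_sigmoid(logits: Tensor) -> Tensor:
    return logits.sigmoid().clip(EPS, 1.0 - EPS).log()


def _log_one_minus_sigmoid(logits: Tensor) -> Tensor:
    return (1.0 - logits.sigmoid()).clip(EPS, 1.0 - EPS).log()


def discriminator_bce_loss(logits, domain_label: int,
                           reduction: str = "mean") -> Tensor:
    """Patch BCE of domain logits against a scalar domain label.

    ``domain_label`` is 1 for glaucoma, 0 for normal.
    """
    if domain_label not in (0, 1):
        raise ValueError(f"domain_label must be 0 or 1, got {domain_label!r}")
    z = float(domain_label)
    l = as_tensor(logits)
    loss = -(z * _log_sigmoid(l) + (1.0 - z) * _log_one_minus_sigmoid(l))
    return _reduce(loss, reduction)


def adversarial_domain_loss(enc_logits, out_logits,
                            weights: LossWeights,
                            reduction: str = "mean") -> Tensor:
    """Generator-side domain gap for normal-sample predictions.

    Each space contributes ``-log sigma(logit)`` per patch position (the
    cost of the discriminator *not* being fooled into the glaucoma
    label); the spaces combine as ``w_e * L_enc + w_o * L_out``.
    """
    if abs(weights.w_e + weights.w_o - 1.0) > 1e-9:
        raise ValueError("w_e and w_o must sum to 1")
    l_enc = _reduce(-_log_sigmoid(as_tensor(enc_logits)), reduction)
    l_out = _reduce(-_log_sigmoid(as_tensor(out_logits)), reduction)
    return weights.w_e * l_enc + weights.w_o * l_out


def total_objective(l_seg, l_style, l_domain_enc, l_domain_out,
                    weights: LossWeights) -> tuple[Tensor, LossBreakdown]:
    """Combine the components into the overall objective.

    Returns the scalar total (a Tensor carrying gradients when the
    components do) plus a float breakdown for logging.
    """
    l_seg = as_tensor(l_seg)
    l_style = as_tensor(l_style)
    l_enc = as_tensor(l_domain_enc)
    l_out = as_tensor(l_domain_out)
    l_domain = weights.w_e * l_enc + weights.w_o * l_out
    total = (weights.w_seg * l_seg + weights.w_style * l_style
             + weights.w_domain * l_domain)
    breakdown = LossBreakdown(
        l_seg=float(l_seg), l_style=float(l_style),
        l_domain_enc=float(l_enc), l_domain_out=float(l_out),
        l_total=float(total))
    return total, breakdown
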