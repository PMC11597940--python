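"""Glaucoma-oriented evaluation suite.

Three complementary views of segmentation quality:

* per-region Dice (optic disc, optic cup, neuroretinal rim) and their
  mean, M-Dice — raw overlap accuracy;
* CDR_MSE — mean squared error of the cup-to-disc ratio measured in both
  the vertical and horizontal directions, the biomarker clinicians track;
* G-score — a composite: mean IoU of disc and cup scaled to [0, 50]
  minus a relative vertical-CDR error penalty (x100).  A perfect
  prediction scores exactly 50.

Diameters are axis-aligned bounding-box extents of the largest connected
component of each structure, which makes the CDR robust to stray pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "CdrPair",
    "MetricsReport",
    "confusion_counts",
    "dice_coefficient",
    "iou",
    "largest_component",
    "extract_cdr",
    "cdr_mse",
    "g_score",
    "decode_prediction",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass(frozen=True)
class CdrPair:
    """Cup-to-disc ratio along the vertical and horizontal axes."""

    vertical: float
    horizontal: float


@dataclass(frozen=True)
class MetricsReport:
    dice_od: float
    dice_oc: float
    dice_rim: float
    m_dice: float
    cdr_mse: float
    g_score: float
    n_samples: int


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def confusion_counts(pred_mask, gt_mask) -> ConfusionCounts:
    p = np.asarray(pred_mask).astype(bool)
    g = np.asarray(gt_mask).astype(bool)
    _check_shapes(p, g)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dice_coefficient(pred_mask, gt_mask) -> float:
    """2*TP / (2*TP + FP + FN); 1.0 when both masks are empty."""
    c = confusion_counts(pred_mask, gt_mask)
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        return 1.0
    return 2.0 * c.tp / denom


def iou(pred_mask, gt_mask) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    c = confusion_counts(pred_mask, gt_mask)
    union = c.tp + c.fp + c.fn
    if union == 0:
        return 1.0
    return c.tp / union


def largest_component(mask) -> np.ndarray:
    """Largest 8-connected component of a binary mask (empty in -> empty out)."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return m
    labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return m
    sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _extents(mask: np.ndarray) -> tuple[int, int]:
    rows = np.any(mask, axis=1)
    cols = np.any(mask, axis=0)
    r = np.flatnonzero(rows)
    c = np.flatnonzero(cols)
    return int(r[-1] - r[0] + 1), int(c[-1] - c[0] + 1)


def extract_cdr(od_mask, oc_mask) -> CdrPair:
    """Cup-to-disc ratio of bounding-box extents (largest components).

    Empty cup gives (0, 0); empty disc is an error.
    """
    od = np.asarray(od_mask).astype(bool)
    oc = np.asarray(oc_mask).astype(bool)
    _check_shapes(od, oc)
    if not od.any():
        raise ValueError("optic disc mask is empty; CDR undefined")
    od_v, od_h = _extents(largest_component(od))
    if not oc.any():
        return CdrPair(vertical=0.0, horizontal=0.0)
    oc_v, oc_h = _extents(largest_component(oc))
    return CdrPair(vertical=oc_v / od_v, horizontal=oc_h / od_h)


def cdr_mse(preds: list[CdrPair], gts: list[CdrPair]) -> float:
    """Mean over samples of (dH)^2 + (dV)^2."""
    if len(preds) != len(gts):
        raise ValueError(f"length mismatch: {len(preds)} vs {len(gts)}")
    if not preds:
        raise ValueError("need at least one sample")
    total = 0.0
    for p, g in zip(preds, gts):
        total += (p.horizontal - g.horizontal) ** 2 + (p.vertical - g.vertical) ** 2
    return total / len(preds)


def _sample_g_score(pred_od, pred_oc, gt_od, gt_oc) -> float:
    overlap = 0.5 * (iou(pred_od, gt_od) + iou(pred_oc, gt_oc))
    gt_cdr = extract_cdr(gt_od, gt_oc).vertical
    if gt_cdr <= 0:
        raise ValueError("ground-truth vertical CDR must be positive")
    pred_od = np.asarray(pred_od).astype(bool)
    if pred_od.any():
        pred_cdr = extract_cdr(pred_od, pred_oc).vertical
    else:
        pred_cdr = 0.0
    return overlap * 100.0 / 2.0 - abs(pred_cdr - gt_cdr) / gt_cdr * 100.0


def g_score(pred_ods, pred_ocs, gt_ods, gt_ocs) -> float:
    """Mean per-sample G-score over a prediction set.

    Also accepts single masks (2-D arrays) for a one-sample score.
    """
    if not isinstance(pred_ods, (list, tuple)):
        return _sample_g_score(pred_ods, pred_ocs, gt_ods, gt_ocs)
    n = len(pred_ods)
    if not (len(pred_ocs) == len(gt_ods) == len(gt_ocs) == n):
        raise ValueError("all mask lists must have equal length")
    return float(np.mean([
        _sample_g_score(pred_ods[i], pred_ocs[i], gt_ods[i], gt_ocs[i])
        for i in range(n)
    ]))


def decode_prediction(probs: np.ndarray,
                      clean: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Argmax-decode a (3, H, W) probability map into (od_mask, oc_mask).

    Classes are {0: background, 1: rim, 2: cup}; OD = rim | cup, OC = cup.
    With ``clean=True`` each structure is reduced to its largest connected
    component (and the cup clipped to the disc) for nested output masks.
    """
    labels = np.asarray(probs).argmax(axis=0)
    od = labels > 0
    oc = labels == 2
    if clean:
        od = largest_component(od)
        oc = largest_component(oc & od)
    return od, oc


def evaluate_model(predictor, samples) -> MetricsReport:
    """Evaluate a predictor over a split of samples.

    ``predictor`` is a callable mapping a sample to a (3, H, W)
    probability map (e.g. ``lambda s: segmenter.predict_probs(s.image)``)
    or an object with a ``predict_probs(image)`` method.  ``samples`` is a
    sequence with ``image``, ``od_mask`` and ``oc_mask`` attributes.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("cannot evaluate on an empty split")
    if hasattr(predictor, "predict_probs"):
        model = predictor
        predictor = lambda s: model.predict_probs(s.image)  # noqa: E731
    dices_od, dices_oc, dices_rim = [], [], []
    pred_cdrs, gt_cdrs, scores = [], [], []
    for s in samples:
        probs = predictor(s)
        pred_od, pred_oc = decode_prediction(probs)
        gt_od = np.asarray(s.od_mask).astype(bool)
        gt_oc = np.asarray(s.oc_mask).astype(bool)
        dices_od.append(dice_coefficient(pred_od, gt_od))
        dices_oc.append(dice_coefficient(pred_oc, gt_oc))
        dices_rim.append(dice_coefficient(pred_od & ~pred_oc, gt_od & ~gt_oc))
        if pred_od.any():
            pred_cdrs.append(extract_cdr(pred_od, pred_oc))
        else:
            pred_cdrs.append(CdrPair(0.0, 0.0))
        gt_cdrs.append(extract_cdr(gt_od, gt_oc))
        scores.append(_sample_g_score(pred_od, pred_oc, gt_od, gt_oc))
    d_od = float(np.mean(dices_od))
    d_oc = float(np.mean(dices_oc))
    d_rim = float(np.mean(dices_rim))
    return MetricsReport(
        dice_od=d_od, dice_oc=d_oc, dice_rim=d_rim,
        m_dice=float(np.mean([d_od, d_oc, d_rim])),
        cdr_mse=cdr_mse(pred_cdrs, gt_cdrs),
        g_score=float(np.mean(scores)),
        n_samples=len(samples),
    )
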