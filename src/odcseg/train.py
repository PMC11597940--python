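"""Dual-step min-max training with the two-phase weight schedule.

Each iteration alternates two updates:

* **Step 1** (segmenter): with the discriminators frozen, minimise
  ``w_seg*L_seg + w_style*L_style + w_domain*L_domain`` over the
  segmenter parameters.  Pixel supervision uses only samples carrying
  pixel annotations; the style term contrasts normal-side and
  glaucoma-side predictions through their Gram matrices; the domain term
  pushes normal-sample predictions toward the glaucoma label of the
  discriminators in both the encoding and output spaces.
* **Step 2** (discriminators): with the segmenter frozen, minimise the
  patch BCE of both discriminators against the true domain labels.

The schedule has two phases: a supervised + style warm-up with weights
(1.0, 0.05, 0.0) and an adversarial refinement phase with weights
(0.0, 0.0, 1.0), during which Step 2 runs after every Step 1.  In
Scenario 2 (annotated glaucoma subset + unannotated glaucomas, no
annotated normals) adversarial learning is undefined — the discriminator
needs both domains — so the procedure keeps the warm-up weights for all
epochs, never updates a discriminator, and the style term pairs
annotated-glaucoma with unannotated-glaucoma predictions.

Per-epoch diagnostics record the loss components plus the style gap
between glaucoma-validation predictions and the glaucoma ground truth
(the curve that should fall faster for the style+domain model than for a
purely pixel-supervised baseline).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .losses import (
    LossBreakdown,
    LossWeights,
    discriminator_bce_loss,
    soft_dice_loss,
    style_gap_loss,
    total_objective,
)
from .metrics import MetricsReport, evaluate_model
from .models import (
    DiscriminatorSpec,
    PatchDiscriminator,
    SegmenterSpec,
    UNetSegmenter,
)
from .nn import Adam, StepLR, Tensor, upsample_bilinear2d
from .preprocess import encode_labels
from .synth import GLAUCOMA, NORMAL, SyntheticSample

__all__ = [
    "TrainConfig",
    "TrainResult",
    "ConfigurationError",
    "TrainItem",
    "prepare_item",
    "segmenter_step",
    "discriminator_step",
    "run_training",
]


class ConfigurationError(ValueError):
    """A batch or manifest does not match the requested training mode."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run (defaults follow the recipe:
    batch of two 256x256x3 images, Adam with lr 1e-4 / betas (0.9, 0.99)
    for the segmenter, lr 1e-2 for the discriminators, per-epoch StepLR
    decay with gamma 0.95)."""

    scenario: int = 1
    epochs: int = 30
    phase1_fraction: float = 0.8
    image_size: int = 256
    base_width: int = 64
    batch_size: int = 2
    lr_seg: float = 1e-4
    lr_disc: float = 1e-2
    betas: tuple[float, float] = (0.9, 0.99)
    lr_gamma: float = 0.95
    w_e: float = 0.2
    w_o: float = 0.8
    use_style: bool = True
    use_domain: bool = True
    keep_seg_in_phase2: bool = True
    upsample_encoding: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if not (0.0 < self.phase1_fraction <= 1.0):
            raise ValueError("phase1_fraction must be in (0, 1]")

    @property
    def phase1_epochs(self) -> int:
        if not (self.use_style or self.use_domain):
            return self.epochs          # supervised baseline: no phase switch
        if self.scenario == 2 or not self.use_domain:
            return self.epochs          # no adversarial phase without both domains
        return max(1, int(round(self.phase1_fraction * self.epochs)))

    def weights_for_epoch(self, epoch: int) -> LossWeights:
        """Two-phase schedule: supervised + style warm-up, then adversarial.

        With ``keep_seg_in_phase2`` (default) the refinement phase keeps
        the warm-up terms alongside the adversarial one — the update rule
        of the dual-step procedure applies all three weighted losses in
        every segmenter step; the printed phase-2 setting (0, 0, 1) is
        reachable by disabling the flag.
        """
        base = dict(w_e=self.w_e, w_o=self.w_o)
        w_style = 0.05 if self.use_style else 0.0
        if epoch < self.phase1_epochs:
            return LossWeights(w_seg=1.0, w_style=w_style, w_domain=0.0, **base)
        if self.keep_seg_in_phase2:
            return LossWeights(w_seg=1.0, w_style=w_style, w_domain=1.0, **base)
        return LossWeights(w_seg=0.0, w_style=0.0, w_domain=1.0, **base)


@dataclass
class TrainResult:
    segmenter: UNetSegmenter
    discriminators: dict[str, PatchDiscriminator]
    history: pd.DataFrame
    config: TrainConfig
    disc_update_count: int
    final_validation: MetricsReport | None = None


@dataclass
class TrainItem:
    """One sample prepared for the network: normalised image + optional target."""

    x: np.ndarray                 # (1, 3, H, W) float32 in [0, 1]
    y: np.ndarray | None          # (1, 3, H, W) one-hot target or None
    domain_label: int
    sample_id: str = ""


def prepare_item(sample: SyntheticSample) -> TrainItem:
    x = np.asarray(sample.image, dtype=np.float32) / 255.0
    x = x.transpose(2, 0, 1)[None]
    y = None
    if sample.has_pixel_annotation:
        y = encode_labels(sample.od_mask, sample.oc_mask)[None]
    return TrainItem(x=x, y=y, domain_label=sample.domain_label,
                     sample_id=sample.sample_id)


def _forward(segmenter: UNetSegmenter, item: TrainItem):
    return segmenter(Tensor(item.x))


def _style_pairs(items: Sequence[TrainItem]):
    """Indices of (style-source, style-target) prediction pairs in a batch.

    With both domains present the pairs run normal x glaucoma; with a
    single domain (Scenario 2) they run annotated x unannotated.
    """
    normals = [i for i, it in enumerate(items) if it.domain_label == NORMAL]
    glaucomas = [i for i, it in enumerate(items) if it.domain_label == GLAUCOMA]
    if normals and glaucomas:
        return [(a, b) for a in normals for b in glaucomas]
    annotated = [i for i, it in enumerate(items) if it.y is not None]
    unannotated = [i for i, it in enumerate(items) if it.y is None]
    return [(a, b) for a in annotated for b in unannotated]


def segmenter_step(segmenter: UNetSegmenter,
                   discriminators: dict[str, PatchDiscriminator],
                   optimizer: Adam,
                   items: Sequence[TrainItem],
                   weights: LossWeights,
                   upsample_encoding: bool = False) -> LossBreakdown:
    """Step 1: one Adam update of the segmenter; discriminators untouched."""
    annotated = [it for it in items if it.y is not None]
    if weights.w_seg > 0 and not annotated:
        raise ConfigurationError(
            "pixel supervision requested (w_seg > 0) but the batch has no "
            "pixel-annotated sample")
    # forward only the samples a loss term will consume
    needed: set[int] = set()
    if weights.w_seg > 0:
        needed.update(i for i, it in enumerate(items) if it.y is not None)
    if weights.w_style > 0:
        for a, b in _style_pairs(items):
            needed.update((a, b))
    if weights.w_domain > 0:
        needed.update(i for i, it in enumerate(items)
                      if it.domain_label == NORMAL)
    outputs = [(_forward(segmenter, it) if i in needed else None)
               for i, it in enumerate(items)]

    zero = Tensor(0.0)
    l_seg = zero
    if weights.w_seg > 0:
        terms = [soft_dice_loss(out.probability_map, Tensor(it.y))
                 for it, out in zip(items, outputs) if it.y is not None]
        l_seg = terms[0]
        for t in terms[1:]:
            l_seg = l_seg + t
        l_seg = l_seg * (1.0 / len(terms))

    l_style = zero
    if weights.w_style > 0:
        pairs = _style_pairs(items)
        if pairs:
            terms = [style_gap_loss(outputs[a].probability_map.reshape(
                         outputs[a].probability_map.shape[1:]),
                     outputs[b].probability_map.reshape(
                         outputs[b].probability_map.shape[1:]))
                     for a, b in pairs]
            l_style = terms[0]
            for t in terms[1:]:
                l_style = l_style + t
            l_style = l_style * (1.0 / len(terms))

    l_enc = zero
    l_out = zero
    if weights.w_domain > 0:
        normal_outputs = [out for it, out in zip(items, outputs)
                          if it.domain_label == NORMAL]
        if not normal_outputs:
            raise ConfigurationError(
                "adversarial domain loss requires a normal-domain sample")
        enc_terms, out_terms = [], []
        for out in normal_outputs:
            enc_feat = out.encoding_feature
            if upsample_encoding:
                enc_feat = upsample_bilinear2d(
                    enc_feat, out.probability_map.shape[2:])
            enc_terms.append(discriminators["encoding"](enc_feat))
            out_terms.append(discriminators["output"](out.probability_map))
        l_enc_acc = -_mean_log_sigmoid(enc_terms)
        l_out_acc = -_mean_log_sigmoid(out_terms)
        l_enc, l_out = l_enc_acc, l_out_acc

    total, breakdown = total_objective(l_seg, l_style, l_enc, l_out, weights)
    segmenter.zero_grad()
    for disc in discriminators.values():
        disc.zero_grad()
    if total.requires_grad:
        total.backward()
        optimizer.step()
    # Step 1 never moves the discriminators: drop any gradient that flowed
    # through them on the way to the segmenter.
    for disc in discriminators.values():
        disc.zero_grad()
    return breakdown


def _mean_log_sigmoid(logit_tensors) -> Tensor:
    from .losses import EPS
    total = None
    for t in logit_tensors:
        term = t.sigmoid().clip(EPS, 1.0 - EPS).log().mean()
        total = term if total is None else total + term
    return total * (1.0 / len(logit_tensors))


def discriminator_step(segmenter: UNetSegmenter,
                       discriminators: dict[str, PatchDiscriminator],
                       disc_optimizers: dict[str, Adam],
                       items: Sequence[TrainItem],
                       upsample_encoding: bool = False) -> float:
    """Step 2: one Adam update of each discriminator; segmenter frozen.

    Features are regenerated from the (just-updated) segmenter and
    detached, so no gradient can reach the segmenter parameters.
    """
    domains = {it.domain_label for it in items}
    if domains != {NORMAL, GLAUCOMA}:
        raise ConfigurationError(
            "discriminator training needs both normal and glaucoma samples "
            f"in the batch (got domains {sorted(domains)})")
    losses = {"encoding": [], "output": []}
    for it in items:
        out = _forward(segmenter, it)
        enc_feat = out.encoding_feature.detach()
        probs = out.probability_map.detach()
        if upsample_encoding:
            enc_feat = upsample_bilinear2d(enc_feat, probs.shape[2:])
        z = it.domain_label
        losses["encoding"].append(
            discriminator_bce_loss(discriminators["encoding"](enc_feat), z))
        losses["output"].append(
            discriminator_bce_loss(discriminators["output"](probs), z))
    values = []
    for space, terms in losses.items():
        loss = terms[0]
        for t in terms[1:]:
            loss = loss + t
        loss = loss * (1.0 / len(terms))
        discriminators[space].zero_grad()
        loss.backward()
        disc_optimizers[space].step()
        values.append(float(loss))
    return float(np.mean(values))


# ----------------------------------------------------------------------
def _validation_diagnostics(segmenter: UNetSegmenter,
                            val_samples: Sequence[SyntheticSample]):
    """Style gap to glaucoma ground truth + M-Dice on the validation split."""
    if not val_samples:
        return float("nan"), float("nan")
    gaps = []
    probs_cache = {}
    for s in val_samples:
        probs = segmenter.predict_probs(s.image)
        probs_cache[s.sample_id] = probs
        gt = encode_labels(s.od_mask, s.oc_mask)
        gaps.append(float(style_gap_loss(probs, gt)))
    report = evaluate_model(lambda s: probs_cache[s.sample_id], val_samples)
    return float(np.mean(gaps)), report.m_dice


def run_training(config: TrainConfig,
                 splits: dict[str, list[SyntheticSample]]) -> TrainResult:
    """Run the full two-phase procedure on a scenario dataset.

    ``splits`` maps ``source`` / ``target`` / ``validation`` to sample
    lists (see :func:`odcseg.synth.generate_scenario` and
    :func:`odcseg.synth.load_dataset`).
    """
    source = [s for s in splits.get("source", []) if s.has_pixel_annotation]
    if not source:
        raise ConfigurationError("the annotated source pool is empty")
    target = [s for s in splits.get("target", [])
              if not s.has_pixel_annotation and s.domain_label == GLAUCOMA]
    validation = [s for s in splits.get("validation", [])
                  if s.domain_label == GLAUCOMA]

    ss = np.random.SeedSequence(entropy=config.seed)
    seg_seed, disc_e_seed, disc_o_seed, shuffle_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    seg_spec = SegmenterSpec(base_width=config.base_width)
    segmenter = UNetSegmenter(seg_spec, np.random.default_rng(seg_seed))
    enc_channels = config.base_width * 4
    discriminators = {
        "encoding": PatchDiscriminator(
            DiscriminatorSpec(in_channels=enc_channels),
            np.random.default_rng(disc_e_seed)),
        "output": PatchDiscriminator(
            DiscriminatorSpec(in_channels=3),
            np.random.default_rng(disc_o_seed)),
    }
    seg_opt = Adam(segmenter.parameters(), lr=config.lr_seg, betas=config.betas)
    disc_opts = {name: Adam(d.parameters(), lr=config.lr_disc,
                            betas=config.betas)
                 for name, d in discriminators.items()}
    seg_sched = StepLR(seg_opt, step_size=1, gamma=config.lr_gamma)
    disc_scheds = [StepLR(o, step_size=1, gamma=config.lr_gamma)
                   for o in disc_opts.values()]

    source_items = [prepare_item(s) for s in source]
    target_items = [prepare_item(s) for s in target]
    shuffle_rng = np.random.default_rng(shuffle_seed)

    adversarial_possible = (config.use_domain and config.scenario != 2
                            and len(target_items) > 0)
    history_rows = []
    disc_updates = 0
    for epoch in range(config.epochs):
        weights = config.weights_for_epoch(epoch)
        if not adversarial_possible and weights.w_domain > 0:
            weights = replace(weights, w_domain=0.0, w_seg=1.0,
                              w_style=0.05 if config.use_style else 0.0)
        src_order = shuffle_rng.permutation(len(source_items))
        tgt_order = (shuffle_rng.permutation(len(target_items))
                     if target_items else np.array([], dtype=int))
        epoch_losses = {"l_seg": [], "l_style": [], "l_domain": [],
                        "l_disc": []}
        for i, src_idx in enumerate(src_order):
            batch = [source_items[src_idx]]
            needs_partner = config.use_style or weights.w_domain > 0
            if target_items and needs_partner:
                batch.append(target_items[tgt_order[i % len(target_items)]])
            elif config.scenario == 3 and needs_partner:
                # annotated glaucoma partner drawn from the source pool
                partners = [it for it in source_items
                            if it.domain_label != batch[0].domain_label]
                if partners:
                    batch.append(partners[i % len(partners)])
            breakdown = segmenter_step(segmenter, discriminators, seg_opt,
                                       batch, weights,
                                       config.upsample_encoding)
            epoch_losses["l_seg"].append(breakdown.l_seg)
            epoch_losses["l_style"].append(breakdown.l_style)
            epoch_losses["l_domain"].append(
                weights.w_e * breakdown.l_domain_enc
                + weights.w_o * breakdown.l_domain_out)
            if weights.w_domain > 0 and len({it.domain_label
                                             for it in batch}) == 2:
                l_disc = discriminator_step(segmenter, discriminators,
                                            disc_opts, batch,
                                            config.upsample_encoding)
                epoch_losses["l_disc"].append(l_disc)
                disc_updates += 1
        seg_sched.step()
        for sched in disc_scheds:
            sched.step()
        style_gap_gt, val_m_dice = _validation_diagnostics(segmenter,
                                                           validation)
        history_rows.append({
            "epoch": epoch,
            "l_seg": float(np.mean(epoch_losses["l_seg"])),
            "l_style": float(np.mean(epoch_losses["l_style"])),
            "l_domain": float(np.mean(epoch_losses["l_domain"])),
            "l_disc": (float(np.mean(epoch_losses["l_disc"]))
                       if epoch_losses["l_disc"] else 0.0),
            "style_gap_to_glaucoma_gt": style_gap_gt,
            "val_m_dice": val_m_dice,
        })

    history = pd.DataFrame(history_rows)
    final_report = None
    if validation:
        final_report = evaluate_model(segmenter, validation)
    return TrainResult(segmenter=segmenter, discriminators=discriminators,
                       history=history, config=config,
                       disc_update_count=disc_updates,
                       final_validation=final_report)
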