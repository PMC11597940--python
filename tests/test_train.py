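"""Dual-step training contracts: freezing, reductions, determinism, scenarios."""

import dataclasses

import numpy as np
import pytest

from odcseg.losses import LossWeights, discriminator_bce_loss, soft_dice_loss
from odcseg.models import (
    DiscriminatorSpec,
    PatchDiscriminator,
    SegmenterSpec,
    UNetSegmenter,
)
from odcseg.nn import Adam, Tensor
from odcseg.synth import SynthConfig, generate_scenario
from odcseg.train import (
    ConfigurationError,
    TrainConfig,
    discriminator_step,
    prepare_item,
    run_training,
    segmenter_step,
)


def _fresh_parts(seed=0, base_width=8):
    segmenter = UNetSegmenter(SegmenterSpec(base_width=base_width),
                              np.random.default_rng(seed))
    discs = {
        "encoding": PatchDiscriminator(
            DiscriminatorSpec(in_channels=base_width * 4),
            np.random.default_rng(seed + 1)),
        "output": PatchDiscriminator(DiscriminatorSpec(in_channels=3),
                                     np.random.default_rng(seed + 2)),
    }
    return segmenter, discs


def _snapshot(module):
    return {k: v.copy() for k, v in module.state_dict().items()}


def _max_param_delta(module, snapshot):
    return max(np.abs(module.state_dict()[k] - v).max()
               for k, v in snapshot.items() if not k.startswith("buffer:"))


@pytest.fixture(scope="module")
def scenario1_items(tiny_splits):
    normal = prepare_item(tiny_splits["source"][0])
    glaucoma = prepare_item(tiny_splits["target"][0])
    return [normal, glaucoma]


class TestSegmenterStep:
    def test_zero_learning_rate_freezes_segmenter(self, scenario1_items):
        segmenter, discs = _fresh_parts()
        opt = Adam(segmenter.parameters(), lr=0.0)
        before = _snapshot(segmenter)
        segmenter_step(segmenter, discs, opt, scenario1_items,
                       LossWeights.phase1())
        assert _max_param_delta(segmenter, before) == 0.0

    def test_discriminators_bitwise_frozen_in_step1(self, scenario1_items):
        segmenter, discs = _fresh_parts()
        opt = Adam(segmenter.parameters(), lr=1e-3)
        snaps = {k: _snapshot(d) for k, d in discs.items()}
        segmenter_step(segmenter, discs, opt, scenario1_items,
                       LossWeights(w_seg=0.0, w_style=0.0, w_domain=1.0))
        for k, d in discs.items():
            assert _max_param_delta(d, snaps[k]) == 0.0

    def test_pure_supervision_matches_plain_dice_baseline(self, scenario1_items):
        # weights (1, 0, 0) must produce an update bit-identical to a
        # hand-rolled dice-supervised step from the same initialisation
        seg_a, discs = _fresh_parts(seed=5)
        opt_a = Adam(seg_a.parameters(), lr=1e-4, betas=(0.9, 0.99))
        segmenter_step(seg_a, discs, opt_a, scenario1_items[:1],
                       LossWeights(w_seg=1.0, w_style=0.0, w_domain=0.0))

        seg_b, _ = _fresh_parts(seed=5)
        opt_b = Adam(seg_b.parameters(), lr=1e-4, betas=(0.9, 0.99))
        item = scenario1_items[0]
        out = seg_b(Tensor(item.x))
        loss = soft_dice_loss(out.probability_map, Tensor(item.y))
        seg_b.zero_grad()
        loss.backward()
        opt_b.step()

        for (ka, pa), (kb, pb) in zip(seg_a.state_dict().items(),
                                      seg_b.state_dict().items()):
            assert ka == kb
            np.testing.assert_array_equal(pa, pb)

    def test_missing_annotation_with_supervision_raises(self, scenario1_items):
        segmenter, discs = _fresh_parts()
        opt = Adam(segmenter.parameters(), lr=1e-4)
        unannotated = [scenario1_items[1]]
        with pytest.raises(ConfigurationError):
            segmenter_step(segmenter, discs, opt, unannotated,
                           LossWeights.phase1())


class TestDiscriminatorStep:
    def test_segmenter_bitwise_frozen_in_step2(self, scenario1_items):
        segmenter, discs = _fresh_parts()
        opts = {k: Adam(d.parameters(), lr=1e-2) for k, d in discs.items()}
        before = _snapshot(segmenter)
        discriminator_step(segmenter, discs, opts, scenario1_items)
        assert _max_param_delta(segmenter, before) == 0.0

    def test_fresh_discriminator_starts_near_chance(self, scenario1_items):
        segmenter, discs = _fresh_parts(seed=3)
        opts = {k: Adam(d.parameters(), lr=1e-2) for k, d in discs.items()}
        l_disc = discriminator_step(segmenter, discs, opts, scenario1_items)
        assert 0.5 <= l_disc <= 0.9

    def test_single_domain_batch_raises(self, scenario1_items):
        segmenter, discs = _fresh_parts()
        opts = {k: Adam(d.parameters(), lr=1e-2) for k, d in discs.items()}
        with pytest.raises(ConfigurationError, match="both"):
            discriminator_step(segmenter, discs, opts, scenario1_items[:1])

    def test_discriminator_learns_separable_frozen_predictions(self):
        # 200 discriminator-only updates on fixed, well-separated maps
        # drive the BCE well below chance (ln 2)
        rng = np.random.default_rng(0)
        disc = PatchDiscriminator(DiscriminatorSpec(in_channels=3),
                                  np.random.default_rng(1))
        opt = Adam(disc.parameters(), lr=1e-2, betas=(0.9, 0.99))

        def fake_probs(cup_half):
            probs = np.zeros((1, 3, 32, 32), dtype=np.float32)
            probs[0, 0] = 1.0
            probs[0, 0, 8:24, 8:24] = 0.0
            probs[0, 1, 8:24, 8:24] = 1.0
            s = 16 - cup_half, 16 + cup_half
            probs[0, 1, s[0]:s[1], s[0]:s[1]] = 0.0
            probs[0, 2, s[0]:s[1], s[0]:s[1]] = 1.0
            return probs

        normal, glaucoma = fake_probs(3), fake_probs(7)
        loss = None
        for _ in range(200):
            disc.zero_grad()
            loss = (discriminator_bce_loss(disc(normal), 0)
                    + discriminator_bce_loss(disc(glaucoma), 1)) * 0.5
            loss.backward()
            opt.step()
        assert float(loss) < np.log(2) / 2


@pytest.fixture(scope="module")
def micro_splits():
    config = SynthConfig(image_size=64, n_normal=4, n_glaucoma=3,
                         n_val_glaucoma=3, seed=2)
    return generate_scenario(config, 1)


class TestRunTraining:
    def _config(self, **kw):
        defaults = dict(scenario=1, epochs=4, image_size=64, base_width=8,
                        phase1_fraction=0.5, seed=0)
        defaults.update(kw)
        return TrainConfig(**defaults)

    def test_history_has_one_record_per_epoch(self, micro_splits):
        result = run_training(self._config(), micro_splits)
        assert len(result.history) == 4
        assert set(result.history.columns) >= {
            "epoch", "l_seg", "l_style", "l_domain", "l_disc",
            "style_gap_to_glaucoma_gt"}

    def test_identical_seed_reproduces_validation_m_dice(self, micro_splits):
        r1 = run_training(self._config(), micro_splits)
        r2 = run_training(self._config(), micro_splits)
        assert r1.final_validation.m_dice == r2.final_validation.m_dice
        assert r1.history.equals(r2.history)

    def test_scenario2_never_updates_discriminators(self):
        config = SynthConfig(image_size=64, n_normal=2, n_glaucoma=6,
                             n_val_glaucoma=2, seed=3)
        splits = generate_scenario(config, 2)
        result = run_training(self._config(scenario=2), splits)
        assert result.disc_update_count == 0
        assert (result.history.l_disc == 0.0).all()

    def test_scenario1_alternates_one_disc_update_per_iteration(self, micro_splits):
        result = run_training(self._config(), micro_splits)
        # phase 2 = epochs 2-3, 4 source samples per epoch
        assert result.disc_update_count == 2 * 4

    def test_empty_annotated_pool_raises(self, micro_splits):
        splits = {"source": [dataclasses.replace(s, has_pixel_annotation=False)
                             for s in micro_splits["source"]],
                  "target": micro_splits["target"],
                  "validation": micro_splits["validation"]}
        with pytest.raises(ConfigurationError, match="annotated"):
            run_training(self._config(), splits)


class TestPhaseSchedule:
    def test_warmup_then_adversarial_weights(self):
        config = TrainConfig(epochs=10, phase1_fraction=0.5,
                             keep_seg_in_phase2=False)
        w1 = config.weights_for_epoch(0)
        assert (w1.w_seg, w1.w_style, w1.w_domain) == (1.0, 0.05, 0.0)
        w2 = config.weights_for_epoch(5)
        assert (w2.w_seg, w2.w_style, w2.w_domain) == (0.0, 0.0, 1.0)

    def test_scenario2_keeps_warmup_weights_throughout(self):
        config = TrainConfig(scenario=2, epochs=10, phase1_fraction=0.5)
        w = config.weights_for_epoch(9)
        assert w.w_domain == 0.0
        assert w.w_seg == 1.0

    def test_supervised_baseline_never_switches_phase(self):
        config = TrainConfig(epochs=10, use_style=False, use_domain=False)
        w = config.weights_for_epoch(9)
        assert (w.w_seg, w.w_style, w.w_domain) == (1.0, 0.0, 0.0)


class TestUpsampledEncodingVariant:
    def test_segmenter_step_with_literal_upsampled_encoding(self, scenario1_items):
        # the optional variant feeds the Up1 feature to the encoding
        # discriminator at full image resolution
        segmenter, discs = _fresh_parts(seed=4)
        opt = Adam(segmenter.parameters(), lr=1e-4)
        breakdown = segmenter_step(
            segmenter, discs, opt, scenario1_items,
            LossWeights(w_seg=0.0, w_style=0.0, w_domain=1.0),
            upsample_encoding=True)
        assert np.isfinite(breakdown.l_domain_enc)
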