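"""Scaled-down Scenario-1 efficacy benchmark.

Trains, for each seed, the full style-contrastive + domain-adversarial
model and a purely pixel-supervised baseline on the same synthetic
Scenario-1 dataset (annotated normals as source, unannotated glaucomas
as target, glaucoma validation), then compares glaucoma-validation
M-Dice, final style gap to glaucoma ground truth, and CDR_MSE.  The
desk-scale study conditions are 64x64 images, base width 8, 20 annotated
normals, 12 unannotated glaucomas, 12 glaucoma-validation samples and 30
epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .synth import SynthConfig, generate_scenario
from .train import TrainConfig, TrainResult, run_training

__all__ = ["BenchmarkResult", "run_benchmark"]


@dataclass
class BenchmarkResult:
    per_seed: pd.DataFrame
    seeds: list[int] = field(default_factory=list)

    @property
    def n_seeds(self) -> int:
        return len(self.per_seed)

    @property
    def full_wins_m_dice(self) -> int:
        return int((self.per_seed.m_dice_full >= self.per_seed.m_dice_base).sum())

    @property
    def full_wins_style_gap(self) -> int:
        return int((self.per_seed.style_gap_full
                    < self.per_seed.style_gap_base).sum())

    @property
    def mean_cdr_mse_full(self) -> float:
        return float(self.per_seed.cdr_mse_full.mean())

    @property
    def mean_cdr_mse_base(self) -> float:
        return float(self.per_seed.cdr_mse_base.mean())

    def summary(self) -> dict:
        p = self.per_seed
        return {
            "n_seeds": self.n_seeds,
            "full_wins_m_dice": self.full_wins_m_dice,
            "full_wins_style_gap": self.full_wins_style_gap,
            "mean_m_dice_full": float(p.m_dice_full.mean()),
            "mean_m_dice_base": float(p.m_dice_base.mean()),
            "mean_style_gap_full": float(p.style_gap_full.mean()),
            "mean_style_gap_base": float(p.style_gap_base.mean()),
            "mean_cdr_mse_full": self.mean_cdr_mse_full,
            "mean_cdr_mse_base": self.mean_cdr_mse_base,
            "mean_g_score_full": float(p.g_score_full.mean()),
            "mean_g_score_base": float(p.g_score_base.mean()),
        }


def _train_variant(seed: int, *, full: bool, epochs: int, image_size: int,
                   base_width: int,
                   splits: dict) -> TrainResult:
    config = TrainConfig(scenario=1, epochs=epochs, image_size=image_size,
                         base_width=base_width, seed=seed,
                         use_style=full, use_domain=full)
    return run_training(config, splits)


def run_benchmark(seeds=(0, 1, 2, 3, 4), *, epochs: int = 30,
                  image_size: int = 64, base_width: int = 8,
                  n_normal: int = 20, n_glaucoma: int = 12,
                  n_val_glaucoma: int = 12,
                  progress=None) -> BenchmarkResult:
    """Run the full-vs-baseline comparison over the given seeds."""
    rows = []
    for seed in seeds:
        synth_cfg = SynthConfig(image_size=image_size, n_normal=n_normal,
                                n_glaucoma=n_glaucoma,
                                n_val_glaucoma=n_val_glaucoma, seed=seed)
        splits = generate_scenario(synth_cfg, scenario=1)
        results = {}
        for name, full in (("full", True), ("base", False)):
            if progress:
                progress(f"seed {seed}: training {name} model")
            results[name] = _train_variant(seed, full=full, epochs=epochs,
                                           image_size=image_size,
                                           base_width=base_width,
                                           splits=splits)
        row = {"seed": seed}
        for name, res in results.items():
            report = res.final_validation
            row[f"m_dice_{name}"] = report.m_dice
            row[f"cdr_mse_{name}"] = report.cdr_mse
            row[f"g_score_{name}"] = report.g_score
            row[f"style_gap_{name}"] = float(
                res.history.style_gap_to_glaucoma_gt.iloc[-1])
        rows.append(row)
    return BenchmarkResult(per_seed=pd.DataFrame(rows), seeds=list(seeds))
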