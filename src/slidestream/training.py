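"""Epoch-level training loop over weakly labelled images."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augmentation import AugmentConfig, StainModel, sample_plan
from .engine import score_image, train_step
from .evaluation import ScoreTable, roc_auc
from .losses import NoiseTransition
from .nn import AdamW, StreamableNet


@dataclass
class TrainHistory:
    epoch_losses: list[float] = field(default_factory=list)
    epoch_aucs: list[float] = field(default_factory=list)
    epochs_run: int = 0

    @property
    def final_auc(self) -> float | None:
        return self.epoch_aucs[-1] if self.epoch_aucs else None


def evaluate_auc(net: StreamableNet, samples, tile_size: int = 256) -> float:
    """Held-out AUC of sigmoid scores against the weak labels."""
    scores = [score_image(net, img, tile_size=tile_size) for img, _ in samples]
    labels = [lab for _, lab in samples]
    table = ScoreTable(np.arange(len(scores)), np.zeros(len(scores)), scores, labels)
    return roc_auc(table)


def train_classifier(
    net: StreamableNet,
    samples,
    epochs: int = 10,
    seed: int = 0,
    lr: float = 1e-3,
    weight_decay: float = 0.01,
    tile_size: int = 256,
    noise: NoiseTransition | None = None,
    augment: bool = False,
    augment_config: AugmentConfig = AugmentConfig(),
    stain: StainModel | None = None,
    eval_samples=None,
    target_auc: float | None = None,
    log=None,
) -> TrainHistory:
    """Train in place with AdamW, one image per step, shuffled each epoch.

    Evaluates on ``eval_samples`` after every epoch; stops early once
    ``target_auc`` is reached.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    opt = AdamW(lr=lr, weight_decay=weight_decay)
    history = TrainHistory()
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        losses = []
        for i in order:
            image, label = samples[i]
            plan = None
            if augment:
                plan = sample_plan(int(rng.integers(2**31)), augment_config)
            step = train_step(
                net, image, label, noise=noise, optimizer=opt, plan=plan,
                stain=stain, tile_size=tile_size,
            )
            losses.append(step.loss)
        history.epoch_losses.append(float(np.mean(losses)))
        history.epochs_run = epoch + 1
        if eval_samples is not None:
            auc = evaluate_auc(net, eval_samples, tile_size=tile_size)
            history.epoch_aucs.append(auc)
            if log:
                log(f"epoch {epoch + 1}: loss={history.epoch_losses[-1]:.4f} auc={auc:.4f}")
            if target_auc is not None and auc >= target_auc:
                break
        elif log:
            log(f"epoch {epoch + 1}: loss={history.epoch_losses[-1]:.4f}")
    return history
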