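"""Hierarchical transfer learning for a new cultivar.

The adaptation scheme freezes all deep convolutional layers (stem conv +
batch norm, the Inception branches and the SE gate), fine-tunes the last
convolutional layer at a reduced learning rate, and retrains the two fully
connected layers at the standard rate, on a small new-cultivar dataset split
4:1 into fine-tuning and validation subsets.  Frozen parameters are
guaranteed bit-identical before and after fine-tuning (their gradients are
zeroed and the optimizer never touches them; the frozen batch norm also pins
its running statistics).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .dataset import Sample, Standardizer, design_matrix, largest_remainder
from .evaluation import MetricsReport, metrics
from .isnet1d import (BatchNorm1d, ISNetError, Network, TrainConfig,
                      TrainedNet, predict, train)

__all__ = ["TransferError", "TransferPlan", "FineTuneResult",
           "default_transfer_plan", "fine_tune"]


class TransferError(ValueError):
    """Domain error raised by the transfer-learning stage."""


@dataclass(frozen=True)
class TransferPlan:
    """Which layers are frozen / reduced-rate / fully trainable."""

    frozen_layers: tuple[str, ...] = ("stem_conv", "stem_bn", "inception", "se")
    reduced_lr_layers: tuple[str, ...] = ("final_conv",)
    full_lr_layers: tuple[str, ...] = ("fc1", "out")
    lr_factor: float = 0.1
    split_ratio: tuple[int, int] = (4, 1)
    fine_tune_epochs: int = 100
    seed: int = 11

    def __post_init__(self) -> None:
        if not (0.0 < self.lr_factor <= 1.0):
            raise TransferError("lr_factor must be in (0, 1]")
        sets = [set(self.frozen_layers), set(self.reduced_lr_layers),
                set(self.full_lr_layers)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise TransferError("layer sets must be disjoint")


def default_transfer_plan(**overrides) -> TransferPlan:
    return TransferPlan(**overrides)


@dataclass
class FineTuneResult:
    """Fine-tuned network with before/after validation metrics."""

    network: TrainedNet
    before: MetricsReport
    after: MetricsReport
    before_train: MetricsReport
    after_train: MetricsReport
    history: object


def _lr_multipliers(net: Network, plan: TransferPlan) -> dict[str, float]:
    mult: dict[str, float] = {}
    named = dict(net.layers)
    all_trainable = {name for name, layer in net.layers if layer.params()}
    covered = set(plan.frozen_layers) | set(plan.reduced_lr_layers) | \
        set(plan.full_lr_layers)
    missing = all_trainable - covered
    if missing:
        raise TransferError(f"plan does not cover trainable layers: {missing}")
    for group, factor in ((plan.frozen_layers, 0.0),
                          (plan.reduced_lr_layers, plan.lr_factor),
                          (plan.full_lr_layers, 1.0)):
        for lname in group:
            if lname not in named:
                raise TransferError(f"no layer named {lname!r}")
            for p in named[lname].params():
                mult[p.name] = factor
    return mult


def fine_tune(
    pretrained: TrainedNet,
    new_samples: Sequence[Sample],
    standardizer: Standardizer,
    plan: TransferPlan | None = None,
    train_config: TrainConfig | None = None,
) -> FineTuneResult:
    """Adapt a pretrained network to a new cultivar.

    ``new_samples`` are standardized with the ORIGINAL training
    standardizer (the network's input convention must not change).  The new
    data are shuffled and split train:validation per ``plan.split_ratio``;
    metrics of the pretrained and the fine-tuned network on the same
    held-out subset are both reported.
    """
    plan = plan or TransferPlan()
    if len(new_samples) < 10:
        raise TransferError("need at least 10 new-cultivar samples")
    X, y = design_matrix(new_samples, standardizer)
    if X.shape[1] != pretrained.network.input_length:
        raise TransferError("architecture/input-length mismatch")

    rng = np.random.default_rng(plan.seed)
    order = rng.permutation(len(X))
    n_train, n_val = largest_remainder(len(X), plan.split_ratio)
    tr, va = order[:n_train], order[n_train:n_train + n_val]
    X_tr, y_tr, X_va, y_va = X[tr], y[tr], X[va], y[va]

    before_val = metrics(y_va, predict(pretrained, X_va), label="validation")
    before_tr = metrics(y_tr, predict(pretrained, X_tr), label="train")

    net = copy.deepcopy(pretrained.network)
    frozen_before = {
        p.name: p.value.copy()
        for lname in plan.frozen_layers for p in net.layer(lname).params()
    }
    for lname in plan.frozen_layers:
        layer = net.layer(lname)
        if isinstance(layer, BatchNorm1d):
            layer.frozen_stats = True

    base = train_config or pretrained.train_config
    cfg = TrainConfig(
        batch_size=base.batch_size,
        initial_lr=base.initial_lr,
        lr_drop_factor=base.lr_drop_factor,
        lr_drop_period=base.lr_drop_period,
        l2_lambda=base.l2_lambda,
        max_epochs=plan.fine_tune_epochs,
        early_stopping_patience=min(base.early_stopping_patience,
                                    plan.fine_tune_epochs),
        seed=plan.seed,
    )
    mult = _lr_multipliers(net, plan)
    tuned, history = train(
        net, X_tr, y_tr, X_va, y_va, cfg,
        isnet_config=pretrained.isnet_config,
        lr_multipliers=mult,
        init_output_bias=False,
    )

    for lname in plan.frozen_layers:
        for p in tuned.network.layer(lname).params():
            if not np.array_equal(p.value, frozen_before[p.name]):
                raise AssertionError(
                    f"frozen parameter {p.name} changed during fine-tuning"
                )

    after_val = metrics(y_va, predict(tuned, X_va), label="validation")
    after_tr = metrics(y_tr, predict(tuned, X_tr), label="train")
    return FineTuneResult(network=tuned, before=before_val, after=after_val,
                          before_train=before_tr, after_train=after_tr,
                          history=history)
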