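"""Two-stage transfer-learning training.

Stage one pretrains on a source-domain cohort in which each subject
contributes paired T1w and T2w volumes sharing a single ground-truth mask;
both modalities enter as independent training samples, which pushes the
weights toward the spatial structure of the head rather than any one
contrast's intensity distribution. Stage two fine-tunes every layer (no
freezing) on the target-domain cohort. After each epoch the model is scored
by mean volume-level Dice on the validation subjects and the best-scoring
checkpoint is the stage's result.

Optimization is Adam (lr 1e-4, beta1 0.9, beta2 0.999) on the softmax
binary cross-entropy of the foreground channel. Shuffling is seeded per
epoch from config.seed, so a fixed seed plus fixed data reproduces the run
exactly, and a run resumed from a mid-training checkpoint matches the
uninterrupted one.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import network as net
from .exceptions import DataError, SpecError
from .nn import Adam
from .phantom import SubjectRecord
from .slice_pipeline import extract_volume, make_net_input, prepare_stack
from .evaluation import compute_metrics, confusion_counts


@dataclass
class TrainConfig:
    stage: str = "finetune"
    epochs: int = 40
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 8
    seed: int = 0
    freeze_policy: str = "none"
    slice_axis: int = 2
    channel_policy: str = "replicate"
    slice_step: int = 1  # train on every slice_step-th slice
    start_epoch: int = 0
    stop_at_val: float | None = None  # stop once validation Dice reaches this

    def __post_init__(self):
        if self.stage not in ("pretrain", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.freeze_policy != "none":
            raise ValueError("all layers are updated; freeze_policy must be 'none'")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")

    @classmethod
    def pretrain_defaults(cls, **kw) -> "TrainConfig":
        kw.setdefault("epochs", 10)
        return cls(stage="pretrain", **kw)

    @classmethod
    def finetune_defaults(cls, **kw) -> "TrainConfig":
        kw.setdefault("epochs", 40)
        return cls(stage="finetune", **kw)


@dataclass
class TrainRecord:
    losses: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    checkpoints: list[str] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        if not self.val_dice:
            return -1
        return int(np.argmax(self.val_dice))


def _training_slices(dataset: list[SubjectRecord], grid, axis: int,
                     policy: str, step: int,
                     modalities=("t1", "t2")) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a cohort into model-input slices and per-pixel labels.

    Each available modality volume of a subject becomes its own sample
    stream against the subject's shared mask.
    """
    xs, ys = [], []
    for rec in dataset:
        if rec.mask is None:
            raise DataError(f"subject {rec.subject_id} has no mask")
        mask_stack = prepare_stack(rec.mask, grid, axis)
        for mod in modalities:
            vol = getattr(rec, mod, None)
            if vol is None:
                continue
            stack = prepare_stack(vol, grid, axis)
            ni = make_net_input(stack, policy)
            xs.append(ni.tensor[::step])
            ys.append(np.stack(mask_stack.slices)[::step].astype(np.float32))
    if not xs:
        raise DataError("dataset contains no image volumes")
    return np.concatenate(xs), np.concatenate(ys)


def validate(state: net.ModelState, dataset: list[SubjectRecord],
             axis: int = 2, policy: str = "replicate",
             modality: str = "t1") -> float:
    """Mean volume-level Dice over subjects via the full extraction pipeline."""
    if not dataset:
        raise DataError("validation dataset is empty")
    dices = []
    for rec in dataset:
        if rec.mask is None:
            raise DataError(f"subject {rec.subject_id} has no mask")
        vol = getattr(rec, modality)
        pred = extract_volume(state, vol, axis=axis, policy=policy)
        dices.append(compute_metrics(confusion_counts(pred, rec.mask)).dice)
    return float(np.mean(dices))


def _train_loop(state: net.ModelState, X: np.ndarray, Y: np.ndarray,
                config: TrainConfig, val_dataset: list[SubjectRecord] | None,
                record: TrainRecord | None = None
                ) -> tuple[net.ModelState, TrainRecord]:
    model = state.model
    opt = Adam(lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    if state.optimizer_state:
        opt.load_state_dict(state.optimizer_state)
    record = record or TrainRecord()
    n = X.shape[0]
    best = (None, -np.inf)
    if val_dataset and record.val_dice:
        prior = [d for d in record.val_dice if np.isfinite(d)]
        if prior:
            # resuming: the checkpoint state stands in for the best-so-far
            best = (state.clone(), max(prior))
    for epoch in range(config.start_epoch, config.epochs):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed) % (2 ** 31), epoch]))
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i:i + config.batch_size]
            xb, yb = X[idx], Y[idx]
            model.zero_grad()
            scores = model.forward(xb, train=True)
            p = net.softmax_fg(scores)
            losses.append(net.bce_loss(p, yb))
            model.backward(net.softmax_bce_score_grad(scores, yb))
            opt.step(model.parameters(), model.gradients())
        state.epoch = epoch + 1
        state.optimizer_state = opt.state_dict()
        record.losses.append(float(np.mean(losses)))
        if val_dataset:
            vd = validate(state, val_dataset, axis=config.slice_axis,
                          policy=config.channel_policy)
        else:
            vd = float("nan")
        record.val_dice.append(vd)
        if val_dataset and vd > best[1]:
            best = (state.clone(), vd)
        if (config.stop_at_val is not None and val_dataset
                and vd >= config.stop_at_val):
            break
    final = best[0] if best[0] is not None else state
    return final, record


def pretrain(dataset: list[SubjectRecord], config: TrainConfig,
             spec: net.ArchSpec,
             val_dataset: list[SubjectRecord] | None = None
             ) -> tuple[net.ModelState, TrainRecord]:
    """Stage one: train from scratch on paired-modality source data and keep
    the best-on-validation checkpoint."""
    if not dataset:
        raise DataError("pretraining dataset is empty")
    state = net.build_network(spec, config.seed)
    X, Y = _training_slices(dataset, spec.grid, config.slice_axis,
                            config.channel_policy, config.slice_step)
    return _train_loop(state, X, Y, config, val_dataset)


def finetune(init: net.ModelState, dataset: list[SubjectRecord],
             config: TrainConfig,
             val_dataset: list[SubjectRecord] | None = None,
             record: TrainRecord | None = None,
             modalities=("t1",)) -> tuple[net.ModelState, TrainRecord]:
    """Stage two: update all layers of an initialized model on target data.

    With epochs == 0 the initial state is returned unchanged with an empty
    record. Passing a mid-training checkpoint plus its record and
    config.start_epoch resumes the original run exactly.
    """
    if not dataset:
        raise DataError("fine-tuning dataset is empty")
    if config.epochs == 0:
        return init, record or TrainRecord()
    state = init.clone()
    if config.start_epoch == 0:
        state.optimizer_state = None  # fresh Adam for a fresh stage
        state.epoch = 0
    X, Y = _training_slices(dataset, state.spec.grid, config.slice_axis,
                            config.channel_policy, config.slice_step,
                            modalities=modalities)
    return _train_loop(state, X, Y, config, val_dataset, record=record)
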