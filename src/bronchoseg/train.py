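"""Optimization loop, stratified k-fold splitting, and parameter sweeps.

Training minimizes the cooperative multi-task loss with AdamW (batch size
1), a cosine-annealed learning rate, and early stopping on validation
loss; the best-validation parameter state is retained.  One master seed
fans out to the shuffling stream, the augmentation stream and the model
initialization, so a run is a pure function of (data, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frequency import extract_high_frequency
from .losses import LossWeights, bce_loss, cls_loss, combined_loss, soft_iou_loss
from .metrics import (ConfusionCounts, auprc, classification_metrics,
                      segmentation_metrics)
from .model import ModelConfig, MultiTaskModel
from .nn import AdamW, cosine_lr
from .synthetic import ImageSample, augment

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "kfold", "sweep"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 2e-4
    lr_min: float = 1e-6
    batch_size: int = 1
    max_epochs: int = 100
    max_steps: int | None = None     # hard cap on optimizer steps (desk scale)
    patience: int = 10
    weight_decay: float = 0.01
    loss_weights: LossWeights = field(default_factory=LossWeights)
    augment_prob: float = 0.0
    seed: int = 0

    def validate(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size != 1:
            raise ValueError("the optimization regime is batch size 1")
        self.loss_weights.validate()


@dataclass
class TrainResult:
    model: MultiTaskModel
    history: list            # per-epoch dicts of train/val loss parts
    best_state: dict
    best_val_loss: float
    steps: int


def _cache_hfc(model: MultiTaskModel, samples: list) -> list:
    return [model.high_frequency_image(s.image) for s in samples]


def _step_losses(model, sample: ImageSample, hfc, weights):
    out = model.forward(sample.image, hfc=hfc)
    mask = sample.mask.astype(np.float64)[None]
    l_b = bce_loss(out.mask_logits, np.broadcast_to(mask, out.mask_logits.shape))
    l_i = soft_iou_loss(out.mask_logits, np.broadcast_to(mask, out.mask_logits.shape))
    l_c = cls_loss(out.class_logit, sample.label)
    return combined_loss(l_b, l_i, l_c, weights, n_pixels=sample.mask.size)


def train(model_config: ModelConfig, train_samples: list,
          val_samples: list | None = None,
          train_config: TrainConfig = TrainConfig(),
          log_path=None) -> TrainResult:
    """Optimize the multi-task objective; returns the best-validation model."""
    train_config.validate()
    if not train_samples:
        raise ValueError("no training samples")
    model = MultiTaskModel(model_config)
    opt = AdamW(model.parameters(), lr=train_config.learning_rate,
                weight_decay=train_config.weight_decay)
    rng = np.random.default_rng(train_config.seed)
    aug_rng = np.random.default_rng(train_config.seed + 1)
    hfc_train = _cache_hfc(model, train_samples)
    hfc_val = _cache_hfc(model, val_samples) if val_samples else None

    total_steps = train_config.max_steps or (
        train_config.max_epochs * len(train_samples))
    history, step = [], 0
    best_val, best_state, bad_epochs = np.inf, model.state_dict(), 0
    log_f = open(log_path, "w") if log_path else None
    try:
        for epoch in range(train_config.max_epochs):
            order = rng.permutation(len(train_samples))
            train_losses = []
            for idx in order:
                if step >= total_steps:
                    break
                sample, hfc = train_samples[idx], hfc_train[idx]
                if (train_config.augment_prob > 0
                        and aug_rng.random() < train_config.augment_prob):
                    sample = augment(sample, int(aug_rng.integers(2 ** 31)))
                    hfc = model.high_frequency_image(sample.image)
                loss_t, report = _step_losses(model, sample, hfc,
                                              train_config.loss_weights)
                if not np.isfinite(report.l_total):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: {report}")
                model.zero_grad()
                loss_t.backward()
                opt.lr = cosine_lr(step, total_steps, train_config.learning_rate,
                                   train_config.lr_min)
                opt.step()
                step += 1
                train_losses.append(report.l_total)
                if log_f:
                    log_f.write(f'{{"step": {step}, "loss": {report.l_total:.6f}, '
                                f'"lr": {opt.lr:.3e}}}\n')
            entry = {"epoch": epoch, "train_loss": float(np.mean(train_losses))
                     if train_losses else np.nan, "steps": step}
            if val_samples:
                from .autodiff import no_grad
                model.cls_head.bn.training = False
                with no_grad():
                    vls = [_step_losses(model, s, h, train_config.loss_weights)[1]
                           .l_total for s, h in zip(val_samples, hfc_val)]
                model.cls_head.bn.training = True
                entry["val_loss"] = float(np.mean(vls))
                if entry["val_loss"] < best_val:
                    best_val, best_state, bad_epochs = (
                        entry["val_loss"], model.state_dict(), 0)
                else:
                    bad_epochs += 1
            else:
                # no validation set: keep the final state (checkpoint selection
                # is a validation-loss concept)
                best_val, best_state = entry["train_loss"], model.state_dict()
            history.append(entry)
            if val_samples and bad_epochs >= train_config.patience:
                break
            if step >= total_steps:
                break
    finally:
        if log_f:
            log_f.close()
    model.load_state_dict(best_state)
    return TrainResult(model=model, history=history, best_state=best_state,
                       best_val_loss=float(best_val), steps=step)


def evaluate(model: MultiTaskModel, samples: list) -> dict:
    """Segmentation + classification metrics of a model on a sample list."""
    preds = [model.predict(s.image) for s in samples]
    seg = segmentation_metrics([p.binary_mask for p in preds],
                               [s.mask for s in samples])
    labels = np.array([s.label for s in samples])
    pred_labels = np.array([p.predicted_label for p in preds])
    scores = np.array([p.class_prob for p in preds])
    counts = ConfusionCounts(
        tp=int(((pred_labels == 1) & (labels == 1)).sum()),
        fp=int(((pred_labels == 1) & (labels == 0)).sum()),
        tn=int(((pred_labels == 0) & (labels == 0)).sum()),
        fn=int(((pred_labels == 0) & (labels == 1)).sum()))
    cls = classification_metrics(counts)
    out = {f"seg_{k}": v for k, v in seg.items() if k in
           ("oAcc", "mAcc", "mIoU", "mDice", "mPrec", "mRecall")}
    out.update({f"cls_{k}": v for k, v in cls.items() if k != "undefined"})
    if 0 < labels.sum() < len(labels):
        out["cls_auprc"] = auprc(scores, labels)
    out["counts"] = counts
    return out


def kfold(samples: list, k: int = 10, seed: int = 0,
          val_fraction_of_rest: float = 1.0 / 9.0):
    """Stratified k-fold iterator yielding (train, val, test) sample lists.

    Every sample lands in exactly one test fold; within each round the
    remaining data is split train/val (val defaults to 1/9 of the rest,
    i.e. ~10% of the whole set).
    """
    from sklearn.model_selection import StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([s.label for s in samples])
    for count in np.bincount(labels):
        if count < k:
            raise ValueError(f"cannot stratify {k} folds: a class has only "
                             f"{count} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    from .synthetic import split_dataset
    for fold, (rest_idx, test_idx) in enumerate(skf.split(labels, labels)):
        rest = [samples[i] for i in rest_idx]
        test = [samples[i] for i in test_idx]
        tr, va, _ = split_dataset(
            rest, (1.0 - val_fraction_of_rest, val_fraction_of_rest, 0.0),
            seed=seed + fold)
        yield tr, va, test


def sweep(param: str, values, base_model_config: ModelConfig,
          train_samples: list, eval_samples: list,
          train_config: TrainConfig = TrainConfig()) -> list:
    """One train/eval cycle per value of ``param`` ('m' or 'lambda_cls')."""
    from dataclasses import replace

    if param not in ("m", "lambda_cls"):
        raise ValueError("sweep supports 'm' (mask ratio) or 'lambda_cls'")
    if not len(list(values)):
        raise ValueError("sweep needs at least one value")
    rows = []
    for v in values:
        mc, tc = base_model_config, train_config
        if param == "m":
            mc = replace(mc, mask_ratio=float(v))
        else:
            tc = replace(tc, loss_weights=replace(tc.loss_weights, cls=float(v)))
        result = train(mc, train_samples, None, tc)
        row = {param: float(v)}
        row.update({k: val for k, val in evaluate(result.model, eval_samples).items()
                    if k != "counts"})
        rows.append(row)
    return rows
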