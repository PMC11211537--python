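"""Training orchestration: per-fold optimisation, cross-validation, ablations.

The protocol follows the multi-task recipe: Adam on the combined
(uncertainty-weighted) loss, ReduceLROnPlateau on the validation loss,
stop when the learning rate falls below the floor or the epoch budget
is reached, keep the checkpoint with the best validation loss.

Three training modes:

* ``full``       — joint end-to-end training with attention fusion;
* ``wo_ffa``     — joint training, fusion by plain concatenation;
* ``separate``   — two-phase: segmentation first, then the staging
  network on the frozen segmentation's masked output and taps.

``run_cv`` performs stage-stratified k-fold cross-validation and pools
out-of-fold predictions for cohort-level metrics, so every case is
scored exactly once by a model that never saw it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .losses import LossWeights, combined_loss, cross_entropy_cls, segmentation_loss
from .networks import MultiTaskModel, NetConfig
from .nn import Adam, ReduceLROnPlateau, Tensor, no_grad
from .phantoms import PhantomCase
from .preprocess import preprocess_case, stratified_kfold
from .metrics import dsc as dice_score

__all__ = [
    "TrainConfig",
    "RunRecord",
    "CVResult",
    "prepare_arrays",
    "train_fold",
    "run_cv",
    "run_ablation",
    "predict_case",
    "save_checkpoint",
    "load_checkpoint",
]

MODES = ("full", "separate", "wo_ffa")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation protocol settings.

    The defaults of the clinical-scale recipe are kept for batch size
    and the stop rule; the learning rate and epoch budget default to
    desk-scale values suited to the small phantom grids (full-scale
    values are a matter of overriding ``lr=2e-4, max_epochs=300``).
    """

    batch_size: int = 4
    lr: float = 3e-3
    cls_lr_scale: float = 1.0     # learning-rate multiplier for staging-only params
    max_epochs: int = 12
    scheduler_factor: float = 0.2
    scheduler_patience: int = 10
    stop_lr: float = 1e-9
    mode: str = "full"
    augment: bool = False
    seed: int = 0
    train_spacing: tuple[float, float, float] = (6.0, 1.0, 1.0)
    train_shape: tuple[int, int, int] = (12, 24, 24)
    net: NetConfig = field(default_factory=lambda: NetConfig(
        input_shape=(12, 24, 24), base_channels=4, channel_cap=16, backbone_width=4))
    trainable_weights: bool = True

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.lr <= self.stop_lr:
            raise ValueError("initial lr must exceed the stop threshold")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if tuple(self.net.input_shape) != tuple(self.train_shape):
            from dataclasses import replace
            object.__setattr__(self, "net", replace(self.net,
                                                    input_shape=tuple(self.train_shape)))


@dataclass
class RunRecord:
    """History and outcome of one training run on one fold."""

    fold: int
    mode: str
    seed: int
    history: list[dict] = field(default_factory=list)
    stop_reason: str = ""
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    state: dict | None = None
    fingerprint: str = ""
    case_order: list[list[str]] = field(default_factory=list)

    def epochs_run(self) -> int:
        return len(self.history)


@dataclass
class CVResult:
    records: list[RunRecord]
    case_ids: list[str]
    true_stages: np.ndarray
    pred_stages: np.ndarray
    stage_probs: np.ndarray           # n x 4 out-of-fold probabilities
    dsc: np.ndarray                   # out-of-fold Dice per case
    pred_masks: dict[str, np.ndarray]
    truth_masks: dict[str, np.ndarray]


def prepare_arrays(cases: list[PhantomCase], cfg: TrainConfig) -> dict[str, dict]:
    """Preprocess every case once: resample, normalise, crop to the train grid."""
    out = {}
    for case in cases:
        img, msk = preprocess_case(case.image, case.mask, case.spacing,
                                   cfg.train_spacing, cfg.train_shape)
        out[case.case_id] = {"image": img, "mask": msk, "stage": case.stage}
    return out


def _augment(img: np.ndarray, msk: np.ndarray, rng: np.random.Generator):
    """Random in-plane flips, ±10° in-plane rotation, ±10% intensity scale."""
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[:, :, ::-1], msk[:, :, ::-1]
    angle = rng.uniform(-10, 10)
    img = ndimage.rotate(img, angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
    msk = ndimage.rotate(msk, angle, axes=(1, 2), reshape=False, order=0, mode="nearest")
    img = img * rng.uniform(0.9, 1.1)
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _batches(ids: list[str], batch_size: int):
    for i in range(0, len(ids), batch_size):
        yield ids[i:i + batch_size]


def _stack(data: dict, ids: list[str], rng=None, augment=False):
    imgs, msks, stages = [], [], []
    for cid in ids:
        img, msk = data[cid]["image"], data[cid]["mask"]
        if augment:
            img, msk = _augment(img, msk, rng)
        imgs.append(img)
        msks.append(msk)
        stages.append(data[cid]["stage"])
    x = Tensor(np.stack(imgs)[:, None].astype(np.float32))
    t = Tensor(np.stack(msks)[:, None].astype(np.float32))
    return x, t, np.asarray(stages, dtype=int)


def _loss_for_mode(model, weights, x, truth, stages, phase: str):
    """Forward + loss for a training phase; returns (loss Tensor, breakdown dict)."""
    if phase == "seg_only":
        seg = model.segnet(x)
        jac, foc = segmentation_loss(seg.prob_map, truth)
        loss = jac + foc
        return loss, {"seg_loss": float(loss.data), "cls_loss": float("nan"),
                      "lambda_seg": 1.0, "lambda_cls": 1.0, "total": float(loss.data)}
    if phase == "cls_only":
        with no_grad():
            seg = model.segnet(x)
        taps = (seg.tap_e7.detach(), seg.tap_e8.detach(), seg.tap_d1.detach())
        masked = x * seg.prob_map.detach()
        feat = model.backbone(masked)
        pred = model.classifier(model.ffa(taps, feat))
        loss = cross_entropy_cls(pred.probs, stages)
        return loss, {"seg_loss": float("nan"), "cls_loss": float(loss.data),
                      "lambda_seg": 1.0, "lambda_cls": 1.0, "total": float(loss.data)}
    seg, pred = model(x)
    bd = combined_loss(seg.prob_map, truth, pred.probs, stages, weights)
    return bd.total, {"seg_loss": bd.seg_component, "cls_loss": bd.cls_component,
                      "lambda_seg": bd.lambda_seg, "lambda_cls": bd.lambda_cls,
                      "total": float(bd.total.data)}


def _validate(model, data, ids, batch_size, weights):
    """Validation loss, mean Dice at 0.5 threshold, staging accuracy."""
    losses, dices, correct = [], [], 0
    for chunk in _batches(ids, batch_size):
        x, t, stages = _stack(data, chunk)
        with no_grad():
            seg, pred = model(x)
        bd = combined_loss(seg.prob_map, t, pred.probs, stages, weights)
        losses.append(float(bd.total.data) * len(chunk))
        pm = seg.prob_map.data[:, 0] >= 0.5
        for i, cid in enumerate(chunk):
            dices.append(dice_score(pm[i], data[cid]["mask"]))
        correct += int((np.argmax(pred.probs.data, axis=1) + 1 == stages).sum())
    return sum(losses) / len(ids), float(np.mean(dices)), correct / len(ids)


def train_fold(data: dict[str, dict], train_ids: list[str], val_ids: list[str],
               cfg: TrainConfig, fold: int = 0) -> RunRecord:
    """Train one fold; returns the record with the best-validation state."""
    for stage in range(1, 5):
        if not any(data[c]["stage"] == stage for c in train_ids):
            import warnings
            warnings.warn(f"stage T{stage} absent from the training portion of fold {fold}")
    rng = np.random.default_rng(cfg.seed + 1000 * fold)
    model = MultiTaskModel(cfg.net, seed=cfg.seed + 1000 * fold,
                           mode="wo_ffa" if cfg.mode == "wo_ffa" else "full")
    weights = LossWeights(trainable=cfg.trainable_weights and cfg.mode != "separate")
    record = RunRecord(fold=fold, mode=cfg.mode, seed=cfg.seed,
                       fingerprint=cfg.net.fingerprint())
    # the separate ablation splits the same total epoch budget between its
    # two phases, so every mode consumes identical optimisation budgets
    if cfg.mode == "separate":
        phases = [("seg_only", model.seg_parameters(), cfg.max_epochs - cfg.max_epochs // 2),
                  ("cls_only", model.cls_parameters(), cfg.max_epochs // 2)]
    else:
        phases = [("joint", model.parameters() + weights.parameters(), cfg.max_epochs)]
    cls_ids = {id(p) for p in model.cls_parameters()}
    for phase, params, phase_epochs in phases:
        seg_state_before = ({k: v.copy() for k, v in model.segnet.state_dict().items()}
                            if phase == "cls_only" else None)
        scales = [cfg.cls_lr_scale if id(p) in cls_ids else 1.0 for p in params]
        opt = Adam(params, lr=cfg.lr, lr_scales=scales)
        sched = ReduceLROnPlateau(opt, factor=cfg.scheduler_factor,
                                  patience=cfg.scheduler_patience, min_lr=0.0)
        stop_reason = "max_epochs"
        for epoch in range(phase_epochs):
            if opt.lr < cfg.stop_lr:
                stop_reason = "min_lr"
                break
            order = list(train_ids)
            rng.shuffle(order)
            record.case_order.append(list(order))
            model.train(True)
            for chunk in _batches(order, cfg.batch_size):
                x, t, stages = _stack(data, chunk, rng, cfg.augment)
                loss, parts = _loss_for_mode(model, weights, x, t, stages, phase)
                opt.zero_grad()
                loss.backward()
                opt.step()
            model.train(False)
            val_loss, val_dsc, val_acc = _validate(model, data, val_ids,
                                                   cfg.batch_size, weights)
            record.history.append({"phase": phase, "epoch": epoch, "lr": opt.lr,
                                   "val_loss": val_loss, "val_dsc": val_dsc,
                                   "val_acc": val_acc, **parts})
            sched.step(val_loss)
            if val_loss < record.best_val_loss:
                record.best_val_loss = val_loss
                record.best_epoch = len(record.history) - 1
                record.state = model.state_dict()
        record.stop_reason = stop_reason
        if phase == "cls_only":
            after = model.segnet.state_dict()
            if any(not np.array_equal(seg_state_before[k], after[k]) for k in after):
                raise AssertionError("segmentation weights changed during the frozen phase")
    if record.state is None:
        record.state = model.state_dict()
    model.load_state_dict(record.state)
    record.state = model.state_dict()
    return record


def _model_from_record(record: RunRecord, cfg: TrainConfig) -> MultiTaskModel:
    model = MultiTaskModel(cfg.net, seed=0,
                           mode="wo_ffa" if record.mode == "wo_ffa" else "full")
    model.load_state_dict(record.state)
    return model


def run_cv(cases: list[PhantomCase], cfg: TrainConfig, k: int = 3,
           data: dict[str, dict] | None = None) -> CVResult:
    """Stratified k-fold cross-validation with pooled out-of-fold predictions.

    ``data`` may hold the output of :func:`prepare_arrays` to reuse the
    preprocessing across runs on the same cohort and grid.
    """
    labels = {c.case_id: c.stage for c in cases}
    split = stratified_kfold(labels, k, cfg.seed)
    if data is None:
        data = prepare_arrays(cases, cfg)
    records = []
    ids_all, stages_all, preds_all, probs_all, dsc_all = [], [], [], [], []
    pred_masks, truth_masks = {}, {}
    for fold in range(k):
        val_ids = sorted(split.cases_in_fold(fold))
        train_ids = sorted(set(labels) - set(val_ids))
        record = train_fold(data, train_ids, val_ids, cfg, fold)
        records.append(record)
        model = _model_from_record(record, cfg)
        for chunk in _batches(val_ids, cfg.batch_size):
            x, t, stages = _stack(data, chunk)
            with no_grad():
                seg, pred = model(x)
            pm = seg.prob_map.data[:, 0] >= 0.5
            for i, cid in enumerate(chunk):
                ids_all.append(cid)
                stages_all.append(data[cid]["stage"])
                probs_all.append(pred.probs.data[i])
                preds_all.append(int(np.argmax(pred.probs.data[i])) + 1)
                dsc_all.append(dice_score(pm[i], data[cid]["mask"]))
                pred_masks[cid] = pm[i].astype(np.uint8)
                truth_masks[cid] = data[cid]["mask"]
    return CVResult(records=records, case_ids=ids_all,
                    true_stages=np.asarray(stages_all), pred_stages=np.asarray(preds_all),
                    stage_probs=np.asarray(probs_all), dsc=np.asarray(dsc_all),
                    pred_masks=pred_masks, truth_masks=truth_masks)


def run_ablation(mode: str, cases: list[PhantomCase], cfg: TrainConfig,
                 k: int = 3) -> CVResult:
    """Run an ablation CV with identical data, seed and budget to the full model."""
    if mode not in ("separate", "wo_ffa"):
        raise ValueError(f"ablation mode must be 'separate' or 'wo_ffa', got {mode!r}")
    from dataclasses import replace
    return run_cv(cases, replace(cfg, mode=mode), k)


# ---------------------------------------------------------------------
# Checkpoints and single-case prediction
# ---------------------------------------------------------------------

def save_checkpoint(record: RunRecord, cfg: TrainConfig, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"fingerprint": record.fingerprint, "fold": record.fold, "mode": record.mode,
            "seed": record.seed, "best_epoch": record.best_epoch,
            "best_val_loss": record.best_val_loss}
    np.savez_compressed(path, __meta__=json.dumps(meta),
                        **{f"param/{k}": v for k, v in record.state.items()})


def load_checkpoint(path: str | Path, cfg: TrainConfig) -> tuple[MultiTaskModel, dict]:
    with np.load(path, allow_pickle=False) as npz:
        meta = json.loads(str(npz["__meta__"]))
        state = {k[len("param/"):]: npz[k] for k in npz.files if k.startswith("param/")}
    if meta["fingerprint"] != cfg.net.fingerprint():
        raise ValueError("checkpoint architecture fingerprint does not match the config")
    model = MultiTaskModel(cfg.net, seed=0,
                           mode="wo_ffa" if meta["mode"] == "wo_ffa" else "full")
    model.load_state_dict(state)
    return model, meta


def predict_case(model: MultiTaskModel, image: np.ndarray, spacing, cfg: TrainConfig,
                 threshold: float = 0.5):
    """Segment and stage one raw volume; returns (prob_map, mask, StagePrediction).

    The volume goes through the same preprocessing chain as training
    (without a mask, so the crop is centred on the volume).
    """
    img, _ = preprocess_case(image, None, spacing, cfg.train_spacing, cfg.train_shape)
    x = Tensor(img[None, None].astype(np.float32))
    with no_grad():
        seg, pred = model(x)
    prob_map = seg.prob_map.data[0, 0]
    return prob_map, (prob_map >= threshold).astype(np.uint8), pred
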