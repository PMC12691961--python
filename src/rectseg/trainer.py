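"""Two-stage training protocol and cross-validation.

The protocol has two independently trained stages:

1. a sex classifier trained on images alone,
2. a sex-conditioned segmenter trained with the **ground-truth** sex as
   constant one-hot input channels (so segmentation learning is not
   confounded by classification errors),

and a joint inference path where the trained classifier's *predicted* sex
conditions the segmenter.  Splitting is at the patient level, stratified
by sex/diagnosis: an 80:20 train/test split, 20% of the training pool
held out for validation, and 5-fold cross-validation over the training
pool.  Training uses Adam, binary cross-entropy on sigmoid outputs, and
early stopping on validation loss with a 7-epoch patience.

At desk scale the pipeline operates on the central axial slice of each
(1 mm in-plane) volume in 2D mode; the identical code path runs in 3D.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .evalmetrics import MetricConfig, MetricRow, classification_report, evaluate_pair
from .imgio import SegMask, SubjectRecord, VolumeGrid, read_volume
from .nets import (
    Adam,
    NetConfig,
    SexLabel,
    bce_with_logits,
    build_classifier,
    build_segmenter,
    condition_input,
)
from .prep import extract_rectum_mask, zscore_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "SliceDataset",
    "stratified_split",
    "build_dataset",
    "EarlyStopping",
    "train_classifier",
    "train_segmenter",
    "predict_pipeline",
    "crossvalidate",
    "TwoStagePipeline",
    "PipelineResults",
]


@dataclass
class TrainConfig:
    """Optimization and protocol hyperparameters.

    Defaults follow the clinical-scale protocol (Adam lr 1e-4, up to 100
    epochs, patience 7, 80:20 split with 20% of training for validation,
    5-fold CV).  ``sex_aware=False`` trains an otherwise identical
    unconditioned segmenter — the baseline for the conditioning-benefit
    comparison.
    """

    lr: float = 1e-4
    max_epochs: int = 100
    patience: int = 7
    batch_size: int = 8
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    k_folds: int = 5
    seed: int = 0
    threshold: float = 0.5
    sex_aware: bool = True
    net: NetConfig = field(default_factory=NetConfig)

    def __post_init__(self) -> None:
        if not (0 < self.test_fraction < 1 and 0 < self.val_fraction_of_train < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be < max_epochs")
        if self.lr <= 0:
            raise ValueError("lr must be > 0")


def desk_scale_config(seed: int = 0, sex_aware: bool = True) -> TrainConfig:
    """Desk-scale regime: 2D mid-pelvis slices, a small U-Net and a larger
    learning rate suited to the smaller network and cohort."""
    return TrainConfig(
        lr=1e-3,
        max_epochs=45,
        seed=seed,
        sex_aware=sex_aware,
        net=NetConfig(n_levels=3, base_channels=8, dims=2),
    )


@dataclass
class SplitPlan:
    """Patient-level split assignment, stratified by sex."""

    test_ids: list[str]
    train_ids: list[str]  # training pool (includes val)
    val_ids: list[str]  # validation subset of the training pool
    fold_of: dict[str, int]  # training-pool subject -> CV fold index

    def __post_init__(self) -> None:
        if set(self.test_ids) & set(self.train_ids):
            raise ValueError("test/train overlap")
        if not set(self.val_ids) <= set(self.train_ids):
            raise ValueError("val ids must come from the training pool")

    def assert_no_leakage(self) -> None:
        assert not set(self.test_ids) & set(self.train_ids), "split leakage detected"


def stratified_split(records: Sequence[SubjectRecord], config: TrainConfig) -> SplitPlan:
    """Stratified patient-level split plus a k-fold plan over the pool.

    Deterministic for a seed; each sex's test share matches
    ``test_fraction`` to within one subject.
    """
    ids = [r.subject_id for r in records]
    sexes = [r.sex for r in records]
    counts = pd.Series(sexes).value_counts()
    if (counts < config.k_folds).any():
        raise ValueError(
            f"stratum too small for {config.k_folds}-fold CV: {counts.to_dict()}"
        )
    train_ids, test_ids = train_test_split(
        ids, test_size=config.test_fraction, stratify=sexes,
        random_state=config.seed,
    )
    sex_of = dict(zip(ids, sexes))
    train_sexes = [sex_of[i] for i in train_ids]
    _, val_ids = train_test_split(
        train_ids, test_size=config.val_fraction_of_train,
        stratify=train_sexes, random_state=config.seed + 1,
    )
    skf = StratifiedKFold(n_splits=config.k_folds, shuffle=True,
                          random_state=config.seed)
    fold_of = {}
    train_arr = np.asarray(train_ids)
    for fold, (_, val_idx) in enumerate(
        skf.split(train_arr, [sex_of[i] for i in train_ids])
    ):
        for sid in train_arr[val_idx]:
            fold_of[str(sid)] = fold
    return SplitPlan(
        test_ids=list(test_ids),
        train_ids=list(train_ids),
        val_ids=list(val_ids),
        fold_of=fold_of,
    )


@dataclass
class SliceDataset:
    """In-memory training arrays: images (N, *S), masks (N, *S), sexes."""

    subject_ids: list[str]
    images: np.ndarray
    masks: np.ndarray
    sexes: list[str]
    spacing: tuple[float, ...] = (1.0, 1.0)

    def __len__(self) -> int:
        return len(self.subject_ids)

    def subset(self, ids: Sequence[str]) -> "SliceDataset":
        wanted = set(ids)
        keep = [i for i, s in enumerate(self.subject_ids) if s in wanted]
        return SliceDataset(
            subject_ids=[self.subject_ids[i] for i in keep],
            images=self.images[keep],
            masks=self.masks[keep],
            sexes=[self.sexes[i] for i in keep],
            spacing=self.spacing,
        )


def build_dataset(records: Sequence[SubjectRecord], dims: int = 2) -> SliceDataset:
    """Load, normalize and (in 2D mode) slice a cohort into arrays.

    2D mode takes the central axial slice of each volume — the CT lattice
    is isotropic in-plane, so no resampling is needed; 3D mode keeps whole
    volumes.  Images are z-score normalized per subject.
    """
    images, masks, sexes, ids = [], [], [], []
    for rec in records:
        grid = read_volume(rec.image_path)
        labels = read_volume(rec.label_path)
        mask = extract_rectum_mask(labels)
        norm = zscore_normalize(grid)
        if dims == 2:
            k = grid.shape[2] // 2
            images.append(norm.values[:, :, k])
            masks.append(mask.values[:, :, k])
        else:
            images.append(norm.values)
            masks.append(mask.values)
        sexes.append(rec.sex)
        ids.append(rec.subject_id)
    return SliceDataset(
        subject_ids=ids,
        images=np.stack(images).astype(np.float32),
        masks=np.stack(masks).astype(np.float32),
        sexes=sexes,
        spacing=(1.0,) * dims,
    )


def _sex_targets(sexes: Sequence[str]) -> np.ndarray:
    return np.asarray([1.0 if s == "male" else 0.0 for s in sexes], dtype=np.float32)


def _classifier_inputs(ds: SliceDataset) -> np.ndarray:
    return ds.images[:, None]  # (N, 1, *S)


def _segmenter_inputs(ds: SliceDataset, sex_aware: bool,
                      sexes: Optional[Sequence[str]] = None) -> np.ndarray:
    sexes = list(sexes) if sexes is not None else ds.sexes
    if sex_aware:
        return np.stack([
            condition_input(img, sex) for img, sex in zip(ds.images, sexes)
        ])
    return ds.images[:, None]


def _dsc_batch(pred_masks: np.ndarray, true_masks: np.ndarray) -> np.ndarray:
    axes = tuple(range(1, pred_masks.ndim))
    inter = (pred_masks * true_masks).sum(axis=axes)
    return (2 * inter + 1.0) / (pred_masks.sum(axes) + true_masks.sum(axes) + 1.0)


class EarlyStopping:
    """Validation-loss early stopping with best-checkpoint bookkeeping.

    ``update`` returns True when ``patience`` epochs have elapsed without
    an improvement over the best validation loss seen so far; epoch
    indices are 0-based.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.since_best = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss, self.best_epoch, self.since_best = val_loss, epoch, 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


def _fit(net, inputs, targets, val_inputs, val_targets, config: TrainConfig,
         is_segmenter: bool):
    """Shared minibatch-Adam loop with best-checkpoint early stopping."""
    rng = np.random.default_rng(config.seed + 17)
    opt = Adam(net, lr=config.lr)
    history = {"train_loss": [], "val_loss": []}
    if is_segmenter:
        history["val_dsc"] = []
    stopper = EarlyStopping(config.patience)
    best_weights = None
    n = len(inputs)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            z = net.forward_logits(inputs[idx], train=True)
            loss, g = bce_with_logits(z, targets[idx])
            net.backward(g)
            opt.step()
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)
        val_z = net.forward_logits(val_inputs, train=False)
        val_loss, _ = bce_with_logits(val_z, val_targets)
        history["val_loss"].append(val_loss)
        if is_segmenter:
            from .nets import sigmoid

            pred = (sigmoid(val_z) >= config.threshold).astype(np.float32)
            history["val_dsc"].append(float(_dsc_batch(pred, val_targets).mean()))
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_weights = net.get_weights()
        if stop:
            logger.info("early stop at epoch %d (best %d)",
                        epoch + 1, stopper.best_epoch + 1)
            break
    if best_weights is not None:
        net.set_weights(best_weights)
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = epoch
    return net, history


def train_classifier(train_ds: SliceDataset, val_ds: SliceDataset,
                     config: TrainConfig):
    """Train the sex classifier; returns (model, history).

    The best-validation-loss checkpoint is restored before returning.
    """
    if len(set(train_ds.sexes)) < 2:
        raise ValueError("single-sex training set: classifier cannot be trained")
    net = build_classifier(config.net, seed=config.seed)
    return _fit(
        net,
        _classifier_inputs(train_ds), _sex_targets(train_ds.sexes),
        _classifier_inputs(val_ds), _sex_targets(val_ds.sexes),
        config, is_segmenter=False,
    )


def train_segmenter(train_ds: SliceDataset, val_ds: SliceDataset,
                    config: TrainConfig):
    """Train the (optionally sex-conditioned) segmenter with ground-truth
    sex channels; returns (model, history) with per-epoch validation DSC."""
    empty = sum(1 for m in train_ds.masks if not m.any())
    if empty > 0.5 * len(train_ds):
        raise ValueError(
            f"{empty}/{len(train_ds)} training masks are empty: aborting"
        )
    net_config = config.net if config.sex_aware else replace(config.net, sex_channels=0)
    net = build_segmenter(net_config, seed=config.seed + 1)
    return _fit(
        net,
        _segmenter_inputs(train_ds, config.sex_aware), train_ds.masks[:, None],
        _segmenter_inputs(val_ds, config.sex_aware), val_ds.masks[:, None],
        config, is_segmenter=True,
    )


def predict_pipeline(classifier, segmenter, image: np.ndarray,
                     config: TrainConfig):
    """Joint inference: classifier's predicted sex conditions the segmenter.

    Returns (male probability, binary mask array, probability map).  A
    classifier probability of exactly 0.5 is broken to male.
    """
    img = np.asarray(image, dtype=np.float32)
    p_male = float(classifier.forward(img[None, None])[0])
    sex = "male" if p_male >= 0.5 else "female"  # tie -> male
    if segmenter.config.sex_channels > 0:
        x = condition_input(img, sex)[None]
    else:
        x = img[None, None]
    prob_map = segmenter.forward(x)[0, 0]
    mask = prob_map >= config.threshold
    return p_male, mask, prob_map


def _evaluate_subjects(classifier, segmenter, ds: SliceDataset,
                       config: TrainConfig) -> tuple[pd.DataFrame, dict]:
    """Run joint inference over a dataset; per-subject metrics + report."""
    rows, pred_sexes, probs = [], [], []
    mcfg = MetricConfig()
    for i, sid in enumerate(ds.subject_ids):
        p_male, mask, _ = predict_pipeline(classifier, segmenter, ds.images[i], config)
        probs.append(p_male)
        pred_sexes.append("male" if p_male >= 0.5 else "female")
        shape3 = ds.images[i].shape + (1,) * (3 - ds.images[i].ndim)
        spacing3 = ds.spacing + (1.0,) * (3 - len(ds.spacing))
        pred = SegMask(values=mask.reshape(shape3), spacing=spacing3)
        ref = SegMask(values=ds.masks[i].astype(bool).reshape(shape3), spacing=spacing3)
        if pred.voxel_count == 0 or ref.voxel_count == 0:
            row = MetricRow(sid, float(_dsc_batch(mask[None].astype(np.float32),
                                                  ds.masks[i][None])[0]),
                            float("nan"), float("nan"), float("inf"), float("inf"),
                            pred.volume_cm3, ref.volume_cm3)
        else:
            row = evaluate_pair(sid, pred, ref, mcfg)
        rows.append(row)
    metrics = pd.DataFrame([vars(r) for r in rows])
    metrics["sex"] = ds.sexes
    metrics["diagnosis"] = ["prostate" if s == "male" else "cervical" for s in ds.sexes]
    metrics["pred_sex"] = pred_sexes
    metrics["p_male"] = probs
    report = classification_report(ds.sexes, pred_sexes, probs)
    return metrics, report


def crossvalidate(dataset: SliceDataset, plan: SplitPlan, config: TrainConfig):
    """k-fold CV over the training pool.

    Trains one (classifier, segmenter) pair per fold on the non-fold
    subjects and evaluates on the fold's validation subjects; returns
    (per-subject metric table with a ``fold`` column, per-fold
    classification reports).
    """
    tables, reports = [], []
    for fold in range(config.k_folds):
        val_ids = [s for s, f in plan.fold_of.items() if f == fold]
        fit_ids = [s for s in plan.train_ids if plan.fold_of[s] != fold]
        assert not set(val_ids) & set(fit_ids), "fold leakage"
        fold_cfg = replace(config, seed=config.seed + 101 * (fold + 1))
        train_ds = dataset.subset(fit_ids)
        val_ds = dataset.subset(val_ids)
        clf, _ = train_classifier(train_ds, val_ds, fold_cfg)
        seg, _ = train_segmenter(train_ds, val_ds, fold_cfg)
        metrics, report = _evaluate_subjects(clf, seg, val_ds, fold_cfg)
        metrics["fold"] = fold
        tables.append(metrics)
        reports.append(report)
    return pd.concat(tables, ignore_index=True), reports


@dataclass
class PipelineResults:
    """Fitted two-stage pipeline: models, histories, held-out evaluation."""

    classifier: object
    segmenter: object
    classifier_history: dict
    segmenter_history: dict
    plan: SplitPlan
    test_metrics: pd.DataFrame
    classification: dict
    config: TrainConfig
    cv_metrics: Optional[pd.DataFrame] = None
    cv_reports: Optional[list] = None

    def summary(self) -> str:
        lines = [
            "Two-stage sex-aware rectum segmentation — held-out test results",
            "=" * 64,
            f"subjects: {len(self.plan.test_ids)} test / "
            f"{len(self.plan.train_ids)} train "
            f"(sex-aware={self.config.sex_aware})",
            "",
            "Sex classification (male = positive class):",
        ]
        for key in ("accuracy", "sensitivity_male", "specificity_female",
                    "ppv", "npv", "f1", "auc"):
            if key in self.classification:
                lines.append(f"  {key:20s} {self.classification[key]:.4f}")
        lines.append("")
        lines.append("Segmentation (per-cohort mean):")
        for diag, sub in self.test_metrics.groupby("diagnosis"):
            lines.append(
                f"  {diag:9s} DSC={sub.dsc.mean():.3f}  "
                f"HD={sub.hd_mm.mean():.2f} mm  ASD={sub.asd_mm.mean():.2f} mm  "
                f"(n={len(sub)})"
            )
        return "\n".join(lines)


class TwoStagePipeline:
    """High-level model object: cohort in, fitted two-stage pipeline out.

    Mirrors the fit/results idiom: construct from a manifest (or records),
    call :meth:`fit`, receive a :class:`PipelineResults` carrying the
    trained stages, the split plan, held-out metrics and ``summary()``.
    """

    def __init__(self, records: Sequence[SubjectRecord], config: TrainConfig):
        self.records = list(records)
        self.config = config

    @classmethod
    def from_manifest(cls, manifest_path, config: TrainConfig) -> "TwoStagePipeline":
        from .imgio import read_manifest

        return cls(read_manifest(manifest_path), config)

    def fit(self, crossval: bool = False) -> PipelineResults:
        config = self.config
        plan = stratified_split(self.records, config)
        plan.assert_no_leakage()
        dataset = build_dataset(self.records, dims=config.net.dims)
        fit_ids = [s for s in plan.train_ids if s not in set(plan.val_ids)]
        train_ds = dataset.subset(fit_ids)
        val_ds = dataset.subset(plan.val_ids)
        clf, clf_hist = train_classifier(train_ds, val_ds, config)
        seg, seg_hist = train_segmenter(train_ds, val_ds, config)
        test_ds = dataset.subset(plan.test_ids)
        test_metrics, report = _evaluate_subjects(clf, seg, test_ds, config)
        cv_metrics = cv_reports = None
        if crossval:
            cv_metrics, cv_reports = crossvalidate(dataset, plan, config)
        return PipelineResults(
            classifier=clf,
            segmenter=seg,
            classifier_history=clf_hist,
            segmenter_history=seg_hist,
            plan=plan,
            test_metrics=test_metrics,
            classification=report,
            config=config,
            cv_metrics=cv_metrics,
            cv_reports=cv_reports,
        )
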