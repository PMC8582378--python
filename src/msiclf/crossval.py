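"""Patient-safe cross-validation designs, metrics, and group fusion.

Two designs are provided. *Leave-one-TMA-out* holds out every tissue group on
one physical microarray per fold — the realistic scenario of predicting on a
newly acquired array — and requires each patient's material to sit on a single
TMA. *Balanced k-fold* draws a fixed number of validation groups per class for
each fold (sampling without replacement within a fold, with recurrence across
folds permitted when a class is small), which keeps per-fold accuracy and
balanced accuracy identical by construction.

Per-spectrum confidences are summarized per fold (accuracy, balanced accuracy,
sensitivity, specificity, ROC AUC) and fused into per-tissue-group decisions
by taking the median confidence over the group's spectra and thresholding it.
Every split is checked for patient-level leakage before any training happens.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .featurize import FeatureMatrix, BinSpec, build_feature_matrix
from .models import (ConvNetSpec, MLPSpec, TrainedEnsemble, classify,
                     predict_confidences, train_ensemble)
from .msi_io import TissueGroup

logger = logging.getLogger(__name__)


class LeakageError(RuntimeError):
    """A patient's data appears on both sides of one split."""


@dataclass(frozen=True)
class CVSplit:
    split_id: str
    train_group_ids: tuple[str, ...]
    val_group_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_group_ids) & set(self.val_group_ids)
        if overlap:
            raise ValueError(f"split {self.split_id}: groups on both sides: {sorted(overlap)[:5]}")


@dataclass(frozen=True)
class MetricsReport:
    """Per-fold binary-classification metrics at a fixed threshold.

    ``auc`` is the rank-based ROC area (ties count one half), undefined (NaN)
    when the fold contains a single class; sensitivity/specificity are NaN
    when their class is absent.
    """

    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class GroupPrediction:
    group_id: str
    median_confidence: float
    predicted_label: int
    true_label: int | None = None


def compute_metrics(
    true_labels: np.ndarray, confidences: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Score confidences against binary truth at the given threshold."""
    y = np.asarray(true_labels, dtype=int)
    conf = np.asarray(confidences, dtype=float)
    if len(y) != len(conf):
        raise ValueError("label and confidence vectors differ in length")
    pred = classify(conf, threshold)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    n_pos, n_neg = tp + fn, tn + fp
    sens = tp / n_pos if n_pos else float("nan")
    spec = tn / n_neg if n_neg else float("nan")
    if n_pos and n_neg:
        auc = float(roc_auc_score(y, conf))
    else:
        auc = float("nan")
        logger.warning("AUC undefined: validation fold contains one class only")
    return MetricsReport(
        accuracy=(tp + tn) / len(y),
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def fuse_group(
    confidences_of_group: np.ndarray,
    threshold: float = 0.5,
    group_id: str = "",
    true_label: int | None = None,
) -> GroupPrediction:
    """Median-fuse a group's per-spectrum confidences into one decision.

    With an even spectrum count the median is the mean of the two middle
    confidences; a median exactly at the threshold classifies positive.
    """
    conf = np.asarray(confidences_of_group, dtype=float)
    if conf.size == 0:
        raise ValueError(f"group {group_id!r}: no confidences to fuse")
    med = float(np.median(conf))
    label = int(classify(np.array([med]), threshold)[0])
    return GroupPrediction(group_id=group_id, median_confidence=med,
                           predicted_label=label, true_label=true_label)


def _group_table(groups: list[TissueGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            group_id=[g.group_id for g in groups],
            patient_id=[g.patient_id for g in groups],
            label=[g.label for g in groups],
            tma_id=[g.tma_id for g in groups],
        )
    )


def make_leave_one_tma_out_splits(groups: list[TissueGroup]) -> list[CVSplit]:
    """One split per TMA: its groups validate, everything else trains."""
    tab = _group_table(groups)
    if tab["tma_id"].nunique() < 2:
        raise ValueError("leave-one-TMA-out needs at least 2 TMAs")
    spread = tab.groupby("patient_id")["tma_id"].nunique()
    multi = spread[spread > 1]
    if len(multi):
        raise LeakageError(
            f"patients with material on several TMAs: {list(multi.index[:5])}"
        )
    splits = []
    for tma in sorted(tab["tma_id"].unique()):
        val = tab.loc[tab.tma_id == tma, "group_id"]
        train = tab.loc[tab.tma_id != tma, "group_id"]
        splits.append(CVSplit(split_id=f"tma:{tma}",
                              train_group_ids=tuple(train),
                              val_group_ids=tuple(val)))
    return splits


def make_balanced_folds(
    groups: list[TissueGroup],
    k: int = 10,
    n_per_class: int = 10,
    seed: int = 0,
) -> list[CVSplit]:
    """k folds whose validation sets hold exactly n_per_class groups per class.

    Each fold's validation set is sampled independently (without replacement
    within the fold) from the full class pools, so groups of a small class
    recur across folds; the training set excludes every group belonging to a
    patient represented in that fold's validation set.
    """
    tab = _group_table(groups)
    rng = np.random.default_rng(seed)
    pools = {c: tab.loc[tab.label == c, "group_id"].to_numpy() for c in (0, 1)}
    for c, pool in pools.items():
        if len(pool) < n_per_class:
            raise ValueError(
                f"class {c} has {len(pool)} groups, fewer than n_per_class={n_per_class}"
            )
    patient_of = dict(zip(tab.group_id, tab.patient_id))
    splits = []
    for i in range(k):
        val = np.concatenate(
            [rng.choice(pools[c], size=n_per_class, replace=False) for c in (0, 1)]
        )
        val_patients = {patient_of[g] for g in val}
        train = tab.loc[~tab.patient_id.isin(val_patients), "group_id"]
        splits.append(CVSplit(split_id=f"fold:{i}",
                              train_group_ids=tuple(train),
                              val_group_ids=tuple(val)))
    return splits


def assert_patient_disjoint(split: CVSplit, patient_of: dict[str, str]) -> None:
    train_p = {patient_of[g] for g in split.train_group_ids}
    val_p = {patient_of[g] for g in split.val_group_ids}
    overlap = train_p & val_p
    if overlap:
        raise LeakageError(
            f"split {split.split_id}: patients on both sides: {sorted(overlap)[:5]}"
        )


@dataclass
class CVResult:
    """Everything one cross-validation run produces."""

    splits: list[CVSplit]
    fold_metrics: list[MetricsReport]              # spectrum level, per fold
    group_predictions: list[list[GroupPrediction]]  # per fold
    fold_group_accuracy: pd.DataFrame              # overall / per class, per fold
    pooled_metrics: MetricsReport | None = None    # diagnostics only
    seed: int = 0

    @property
    def mean_spectrum_metrics(self) -> dict[str, float]:
        """Unweighted mean over folds of each spectrum-level metric."""
        return {
            name: float(np.mean([getattr(m, name) for m in self.fold_metrics]))
            for name in ("accuracy", "balanced_accuracy", "sensitivity",
                         "specificity", "auc")
        }

    @property
    def mean_group_accuracy(self) -> float:
        return float(self.fold_group_accuracy["accuracy_all"].mean())

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for split, m in zip(self.splits, self.fold_metrics):
            rows.append(dict(split_id=split.split_id, accuracy=m.accuracy,
                             balanced_accuracy=m.balanced_accuracy,
                             sensitivity=m.sensitivity, specificity=m.specificity,
                             auc=m.auc, tp=m.tp, fp=m.fp, tn=m.tn, fn=m.fn))
        return pd.DataFrame(rows)

    def group_table(self) -> pd.DataFrame:
        rows = []
        for split, preds in zip(self.splits, self.group_predictions):
            for p in preds:
                rows.append(dict(split_id=split.split_id, group_id=p.group_id,
                                 true_label=p.true_label,
                                 median_confidence=p.median_confidence,
                                 predicted_label=p.predicted_label))
        return pd.DataFrame(rows)


def _group_accuracy_row(split_id: str, preds: list[GroupPrediction]) -> dict:
    correct = np.array([p.predicted_label == p.true_label for p in preds])
    labels = np.array([p.true_label for p in preds])
    row = dict(split_id=split_id, accuracy_all=float(correct.mean()))
    for c, name in ((0, "accuracy_negative"), (1, "accuracy_positive")):
        mask = labels == c
        row[name] = float(correct[mask].mean()) if mask.any() else float("nan")
    return row


def run_cross_validation(
    groups: list[TissueGroup],
    bin_spec: BinSpec,
    *,
    design: str = "leave_one_tma_out",
    k: int = 10,
    n_per_class: int = 10,
    apply_sqrt: bool = True,
    threshold: float = 0.5,
    seed: int = 0,
    specs: list[MLPSpec | ConvNetSpec] | None = None,
    matrix: FeatureMatrix | None = None,
) -> CVResult:
    """Run a full cross-validated evaluation of the two-network ensemble.

    For each split: train the ensemble on the training groups' spectra,
    predict confidences for the validation spectra, score spectrum-level
    metrics, fuse per group by median, and tally the fraction of groups
    classified correctly (overall and per class). The aggregate over folds is
    the unweighted mean of per-fold metrics; pooled-spectrum metrics over all
    folds are additionally computed for diagnostics.

    ``matrix`` may supply a precomputed feature matrix (binning is
    per-spectrum, so computing it once leaks nothing across splits).
    """
    if matrix is None:
        matrix = build_feature_matrix(groups, bin_spec, apply_sqrt=apply_sqrt)
    if design == "leave_one_tma_out":
        splits = make_leave_one_tma_out_splits(groups)
    elif design == "balanced_kfold":
        splits = make_balanced_folds(groups, k=k, n_per_class=n_per_class, seed=seed)
    else:
        raise ValueError(f"unknown CV design {design!r}")

    patient_of = {g.group_id: g.patient_id for g in groups}
    label_of = {g.group_id: g.label for g in groups}
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(splits)) % (2**31)

    fold_metrics: list[MetricsReport] = []
    group_preds: list[list[GroupPrediction]] = []
    acc_rows = []
    pooled_y, pooled_conf = [], []
    for split, fold_seed in zip(splits, fold_seeds):
        assert_patient_disjoint(split, patient_of)
        logger.info("split %s: patient-disjointness check passed", split.split_id)
        train_mask = matrix.rows_for_groups(split.train_group_ids)
        ens = train_ensemble(
            (matrix.X[train_mask], matrix.labels[train_mask]),
            seed=int(fold_seed), specs=specs,
        )
        val_mask = matrix.rows_for_groups(split.val_group_ids)
        conf = predict_confidences(ens, matrix.X[val_mask])
        y = matrix.labels[val_mask]
        fold_metrics.append(compute_metrics(y, conf, threshold))
        pooled_y.append(y)
        pooled_conf.append(conf)

        val_gids = matrix.group_ids[val_mask]
        preds = []
        for gid in split.val_group_ids:
            sel = val_gids == gid
            if not sel.any():        # group can validate in several folds
                continue
            preds.append(fuse_group(conf[sel], threshold, group_id=gid,
                                    true_label=label_of[gid]))
        group_preds.append(preds)
        acc_rows.append(_group_accuracy_row(split.split_id, preds))

    pooled = compute_metrics(np.concatenate(pooled_y),
                             np.concatenate(pooled_conf), threshold)
    result = CVResult(
        splits=splits,
        fold_metrics=fold_metrics,
        group_predictions=group_preds,
        fold_group_accuracy=pd.DataFrame(acc_rows),
        pooled_metrics=pooled,
        seed=seed,
    )
    logger.info(
        "cross-validation done: mean spectrum AUC %.4f, mean group accuracy %.4f",
        result.mean_spectrum_metrics["auc"], result.mean_group_accuracy,
    )
    return result
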