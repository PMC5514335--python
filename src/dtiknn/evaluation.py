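"""Negative-pair sampling, the 10-fold protocol and the metric suite.

Benchmark interaction datasets list only known (positive) drug-target
pairs.  Presumed non-interacting pairs are constructed by *recoupling*: the
candidate pool is the full cross product of the drugs and targets observed
in the positive set, minus the positives, and negatives are drawn uniformly
without replacement until they number ``ratio`` times the positives
(ratio 2 by default).

Evaluation is stratified 10-fold cross-validation.  Every fitting step that
sees labels or feature distributions (per-feature scaling, per-classifier k
selection) runs on the training folds only.  The property PCA uses no
labels and no drug/pair information, so it is fit once globally.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import aa_properties, drug_features, protein_encoder
from .drug_features import DescriptorTable, pair_matrix
from .ensemble import UNANIMITY, KNNConfig, build_subspaces, fit_ensemble
from .errors import ConfigError, InputError

CLASS_TAGS = ("enzymes", "ion channels", "GPCRs", "nuclear receptors", "custom")

#: Sentinel for metric ratios with a zero denominator.
UNDEFINED = float("nan")


@dataclass
class InteractionDataset:
    """Positive and sampled-negative drug-target pairs of one target class."""

    positives: set[tuple[str, str]]
    negatives: set[tuple[str, str]]
    class_tag: str = "custom"

    def __post_init__(self) -> None:
        self.positives = set(self.positives)
        self.negatives = set(self.negatives)
        overlap = self.positives & self.negatives
        if overlap:
            raise ConfigError(f"pairs in both classes: {sorted(overlap)[:5]}")

    def pair_list(self) -> list[tuple[str, str, int]]:
        """Deterministically ordered labeled pairs (positives first)."""
        return [(d, p, 1) for d, p in sorted(self.positives)] + [
            (d, p, 0) for d, p in sorted(self.negatives)
        ]

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


def sample_negatives(
    positives: set[tuple[str, str]] | list[tuple[str, str]],
    n_ratio: float = 2.0,
    seed: int = 0,
) -> set[tuple[str, str]]:
    """Recouple observed drugs and targets into presumed negatives.

    Draws ``round(n_ratio * len(positives))`` pairs uniformly without
    replacement from (drugs x targets) \\ positives.

    Raises
    ------
    InputError
        If the candidate pool is smaller than the requested negative count
        (the pool size is reported).
    """
    if n_ratio <= 0:
        raise ConfigError(f"n_ratio must be positive, got {n_ratio}")
    pos = set(positives)
    if not pos:
        raise InputError("cannot sample negatives from an empty positive set")
    drugs = sorted({d for d, _ in pos})
    targets = sorted({p for _, p in pos})
    pool = [
        dp for dp in itertools.product(drugs, targets) if dp not in pos
    ]
    n_neg = int(round(n_ratio * len(pos)))
    if len(pool) < n_neg:
        raise InputError(
            f"candidate pool ({len(pool)} recoupled pairs) is smaller than "
            f"the requested {n_neg} negatives"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n_neg, replace=False)
    return {pool[i] for i in chosen}


def kfold_split(
    labels: np.ndarray,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
) -> list[np.ndarray]:
    """Disjoint test-fold index arrays covering every instance once.

    Stratified by default, so per-class fold sizes differ by at most 1.
    """
    y = np.asarray(labels, dtype=int)
    if stratified:
        counts = np.bincount(y)
        if (counts[counts > 0] < k).any():
            raise InputError(
                f"every class needs at least k={k} instances for stratified folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        from sklearn.model_selection import KFold

        if len(y) < k:
            raise InputError(f"need at least k={k} instances")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(np.zeros((len(y), 1)), y)]


@dataclass
class EvaluationReport:
    """Confusion counts with the derived recall / precision / accuracy /
    MCC / F1.

    Ratios with a zero denominator are reported as NaN sentinels with an
    entry in ``warnings`` — except MCC, which follows the standard limit
    convention MCC = 0 for a constant predictor (still warned)."""

    tp: int
    fp: int
    tn: int
    fn: int
    rec: float
    prec: float
    acc: float
    mcc: float
    f1: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "rec": self.rec, "prec": self.prec, "acc": self.acc,
            "mcc": self.mcc, "f1": self.f1, "warnings": list(self.warnings),
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationReport:
    """Confusion counts -> recall, precision, accuracy, MCC and F1.

    Rec = TP/(TP+FN); Prec = TP/(TP+FP); Acc = (TP+TN)/(TP+FN+FP+TN);
    F1 = 2*Prec*Rec/(Prec+Rec);
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ConfigError(f"{name} must be non-negative, got {v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise InputError("all confusion counts are zero")

    notes: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            notes.append(f"{name} undefined (zero denominator)")
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return UNDEFINED
        return num / den

    rec = ratio(tp, tp + fn, "recall")
    prec = ratio(tp, tp + fp, "precision")
    acc = (tp + tn) / total

    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if mcc_den == 0:
        notes.append("mcc denominator zero; constant-predictor convention mcc=0")
        warnings.warn("MCC denominator zero; reporting 0 by convention", stacklevel=2)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den)

    if math.isnan(rec) or math.isnan(prec) or (prec + rec) == 0:
        notes.append("f1 undefined")
        f1 = UNDEFINED
    else:
        f1 = 2 * prec * rec / (prec + rec)

    return EvaluationReport(tp, fp, tn, fn, rec, prec, acc, mcc, f1, notes)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) from parallel 0/1 vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    return tp, fp, tn, fn


@dataclass
class RunConfig:
    """Pipeline geometry and protocol settings (full-scale defaults:
    7 components, 10 fragments, unanimity vote, 1:2 negatives, 10 folds)."""

    n_pca: int = 7
    n_frag: int = 10
    vote_rule: str = UNANIMITY
    weighting: str = "distance"
    k: int | None = None
    k_max: int | None = None
    ratio: float = 2.0
    folds: int = 10
    stratified: bool = True
    seed: int = 0

    def knn_config(self) -> KNNConfig:
        return KNNConfig(k=self.k, k_max=self.k_max, weighting=self.weighting)


@dataclass
class CrossValResult:
    """Per-fold, pooled and per-subspace cross-validation reports."""

    fold_reports: list[EvaluationReport]
    pooled: EvaluationReport
    subspace_reports: dict[tuple[int, int], EvaluationReport]
    fold_sizes: list[int]
    config: RunConfig

    def subspace_table(self):
        """Per-classifier breakdown as a DataFrame (component, drug group,
        Rec/Acc/Prec/F1), the audit view of the grid."""
        import pandas as pd

        rows = [
            {
                "component": i, "drug_group": j,
                "rec": r.rec, "acc": r.acc, "prec": r.prec,
                "f1": r.f1, "mcc": r.mcc,
            }
            for (i, j), r in sorted(self.subspace_reports.items())
        ]
        return pd.DataFrame(rows)


def cross_validate_vectors(
    x: np.ndarray,
    y: np.ndarray,
    subspaces,
    config: RunConfig,
) -> CrossValResult:
    """Stratified k-fold cross-validation of the subspace ensemble on
    prebuilt pair vectors.

    For each fold the full ensemble (scalers, per-classifier k) is refit on
    the training folds only; pooled confusion counts aggregate the
    out-of-fold predictions, so every instance is tested exactly once.
    Per-subspace reports pool each classifier's own out-of-fold votes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, k=config.folds, stratified=config.stratified, seed=config.seed)

    n_clf = len(subspaces)
    pooled_pred = np.empty(len(y), dtype=int)
    pooled_votes = np.empty((len(y), n_clf), dtype=int)
    fold_reports = []
    for f, test_idx in enumerate(folds):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        try:
            ens = fit_ensemble(
                (x[train_mask], y[train_mask]),
                subspaces,
                config.knn_config(),
                vote_rule=config.vote_rule,
            )
            labels, votes = ens.predict(x[test_idx])
        except (InputError, ConfigError) as exc:
            raise InputError(f"fold {f}: {exc}") from exc
        pooled_pred[test_idx] = labels
        pooled_votes[test_idx] = votes
        fold_reports.append(compute_metrics(*confusion_counts(y[test_idx], labels)))

    pooled = compute_metrics(*confusion_counts(y, pooled_pred))
    subspace_reports = {
        (sub.target_component, sub.drug_group): compute_metrics(
            *confusion_counts(y, pooled_votes[:, m])
        )
        for m, sub in enumerate(subspaces)
    }
    return CrossValResult(
        fold_reports, pooled, subspace_reports, [len(t) for t in folds], config
    )


def cross_validate(
    dataset: InteractionDataset,
    drug_table: DescriptorTable,
    protein_records,
    property_table,
    config: RunConfig | None = None,
) -> CrossValResult:
    """End-to-end protocol: property PCA -> encodings -> pair vectors ->
    per-fold ensemble fits -> pooled report.

    The property PCA is label-free, so it is fit once on the property table;
    everything label- or distribution-dependent is refit inside each fold.
    """
    config = config or RunConfig()
    std = aa_properties.standardize(property_table)
    model = aa_properties.fit_pca(std, n_components=config.n_pca)
    encoded = protein_encoder.encode_proteins(protein_records, model, config.n_frag)
    clean = drug_features.clean_descriptors(drug_table)
    pairs = drug_features.build_pair_vectors(dataset.pair_list(), clean, encoded)
    x, y = pair_matrix(pairs)
    partition = drug_features.partition_descriptors(clean.n_descriptors, config.n_pca)
    subspaces = build_subspaces(config.n_pca, config.n_frag, partition)
    return cross_validate_vectors(x, y, subspaces, config)
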