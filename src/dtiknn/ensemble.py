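"""The grid of feature-subspace kNN classifiers and its vote rules.

Each of the n_pca protein component groups Ft_i is paired with each of the
n_pca drug descriptor groups Fd_j, giving n_pca^2 feature subspaces (49 at
the default 7 components; 200 + 206 = 406 features each at the full-scale
geometry).  One kNN classifier is trained per subspace on min-max-scaled
Euclidean distances, its neighbor count selected by leave-one-out
cross-validation over odd k.  The ensemble calls a pair interacting under
the UNANIMITY rule (all classifiers vote positive; the default) or a simple
MAJORITY rule.

Vote conventions (fixed for determinism, documented in docs/methods.md):

* inverse-distance weighting is the default; any neighbor at (numerically)
  zero distance dominates — the vote becomes the majority label among the
  zero-distance neighbors;
* a classifier votes positive iff the positive weight fraction is strictly
  greater than 1/2, so exact ties break to NEGATIVE (conservative for
  interaction calls), as does an exactly-half majority vote of the grid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .drug_features import DescriptorGroupPartition, PairVector, pair_matrix
from .errors import ConfigError, InputError
from .protein_encoder import N_AA, component_feature_group

_ZERO_DIST = 1e-12

UNANIMITY = "unanimity"
MAJORITY = "majority"


@dataclass(frozen=True)
class SubspacePair:
    """One (protein component, drug group) feature subspace.

    ``feature_indices`` are the union Ft_i u Fd_j mapped into pair-vector
    coordinates (drug block first), strictly increasing.
    """

    target_component: int  # i, 1-based
    drug_group: int  # j, 1-based
    feature_indices: np.ndarray

    @property
    def n_features(self) -> int:
        return self.feature_indices.size


def build_subspaces(
    n_pca: int,
    n_frag: int,
    partition: DescriptorGroupPartition,
) -> list[SubspacePair]:
    """All n_pca^2 subspaces, ordered row-major by (component, drug group)."""
    if partition.n_groups != n_pca:
        raise ConfigError(
            f"descriptor partition has {partition.n_groups} groups, "
            f"expected n_pca = {n_pca}"
        )
    n_desc = partition.n_descriptors
    out = []
    for i in range(1, n_pca + 1):
        prot_idx = component_feature_group(i, n_pca, n_frag) + n_desc
        for j in range(1, n_pca + 1):
            drug_idx = partition.group_indices(j)
            out.append(
                SubspacePair(i, j, np.concatenate([drug_idx, prot_idx]))
            )
    return out


@dataclass
class KNNConfig:
    """Tunables of a single subspace kNN.

    ``k=None`` triggers per-classifier leave-one-out selection over odd k in
    {1, 3, ..., k_max}; ``k_max=None`` defaults to 2*ceil(sqrt(n))+1.
    """

    k: int | None = None
    k_max: int | None = None
    weighting: str = "distance"  # "distance" (1/d) or "uniform"

    def __post_init__(self) -> None:
        if self.weighting not in ("distance", "uniform"):
            raise ConfigError(f"unknown weighting {self.weighting!r}")
        if self.k is not None and self.k < 1:
            raise ConfigError("k must be positive")


def _default_k_max(n: int) -> int:
    return 2 * math.ceil(math.sqrt(n)) + 1


def _minmax_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = x.min(axis=0)
    rng = x.max(axis=0) - lo
    rng[rng == 0.0] = 1.0  # degenerate features map to a constant 0
    return lo, rng


def _vote(dist: np.ndarray, neigh_labels: np.ndarray, weighting: str) -> np.ndarray:
    """Positive-class score per query row from neighbor distances/labels."""
    if weighting == "uniform":
        w = np.ones_like(dist)
    else:
        zero = dist <= _ZERO_DIST
        w = np.empty_like(dist)
        has_zero = zero.any(axis=1)
        with np.errstate(divide="ignore"):
            w[~has_zero] = 1.0 / dist[~has_zero]
        w[has_zero] = zero[has_zero].astype(float)
    return (w * neigh_labels).sum(axis=1) / w.sum(axis=1)


@dataclass
class KNNModel:
    """A fitted subspace kNN: scaled training data, labels and vote policy."""

    training_vectors: np.ndarray  # already min-max scaled
    labels: np.ndarray
    k: int
    weighting: str
    scaler_offset: np.ndarray
    scaler_scale: np.ndarray
    _nn: NearestNeighbors = field(default=None, repr=False)  # type: ignore

    def __post_init__(self) -> None:
        if self.k > len(self.labels):
            raise ConfigError("k exceeds the number of training instances")
        if self._nn is None:
            self._nn = NearestNeighbors(algorithm="brute").fit(self.training_vectors)

    def transform(self, queries: np.ndarray) -> np.ndarray:
        return (np.asarray(queries, dtype=float) - self.scaler_offset) / self.scaler_scale

    def predict(self, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels and positive-class scores for query rows (subspace coords,
        unscaled)."""
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        if q.shape[1] != self.training_vectors.shape[1]:
            raise InputError(
                f"query dimension {q.shape[1]} != model dimension "
                f"{self.training_vectors.shape[1]}"
            )
        dist, idx = self._nn.kneighbors(self.transform(q), n_neighbors=self.k)
        scores = _vote(dist, self.labels[idx], self.weighting)
        return (scores > 0.5).astype(int), scores


def _loo_neighbor_tables(
    x: np.ndarray, k_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out neighbor distances/indices (self excluded), per row."""
    n = x.shape[0]
    k_query = min(k_max + 1, n)
    nn = NearestNeighbors(algorithm="brute").fit(x)
    dist, idx = nn.kneighbors(x, n_neighbors=k_query)
    rows = np.arange(n)
    out_d = np.empty((n, k_query - 1))
    out_i = np.empty((n, k_query - 1), dtype=int)
    for r in rows:
        self_pos = np.flatnonzero(idx[r] == r)
        drop = self_pos[0] if self_pos.size else k_query - 1
        keep = np.concatenate([np.arange(drop), np.arange(drop + 1, k_query)])
        out_d[r] = dist[r, keep]
        out_i[r] = idx[r, keep]
    return out_d, out_i


def select_k(
    vectors: np.ndarray,
    labels: np.ndarray,
    k_candidates: list[int] | None = None,
    seed: int | None = None,
    weighting: str = "distance",
) -> int:
    """Pick k by leave-one-out accuracy; ties go to the smallest k.

    The default candidate grid is the odd integers 1, 3, ..., k_max with
    k_max = 2*ceil(sqrt(n))+1 (capped at n-1).  The procedure is
    deterministic; ``seed`` is accepted for interface uniformity.
    """
    x = np.asarray(vectors, dtype=float)
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if len(np.unique(y)) < 2:
        raise InputError("k selection requires both classes in the training set")
    if k_candidates is None:
        k_candidates = list(range(1, min(_default_k_max(n), n - 1) + 1, 2))
    if not k_candidates:
        raise ConfigError("k_candidates must be non-empty")
    if max(k_candidates) > n - 1:
        raise ConfigError("k candidates must leave at least one other instance (k <= n-1)")
    if len(k_candidates) == 1:
        return int(k_candidates[0])

    dist, idx = _loo_neighbor_tables(x, max(k_candidates))
    neigh_labels = y[idx]
    best_k, best_acc = None, -1.0
    for k in sorted(k_candidates):
        scores = _vote(dist[:, :k], neigh_labels[:, :k], weighting)
        acc = float(((scores > 0.5).astype(int) == y).mean())
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return int(best_k)


def fit_subspace_knn(
    pairs: list[PairVector] | tuple[np.ndarray, np.ndarray],
    subspace: SubspacePair,
    config: KNNConfig | None = None,
) -> KNNModel:
    """Fit one subspace classifier.

    The min-max scaler and (if requested) the LOO-selected k are fit on the
    given training instances only, so cross-validation stays leakage-free.
    """
    config = config or KNNConfig()
    if isinstance(pairs, tuple):
        x_full, y = pairs
    else:
        x_full, y = pair_matrix(pairs)
    if subspace.n_features == 0:
        raise ConfigError("empty feature subspace")
    if len(np.unique(y)) < 2:
        raise InputError("training set must contain both classes")
    x = np.asarray(x_full, dtype=float)[:, subspace.feature_indices]
    lo, rng = _minmax_fit(x)
    xs = (x - lo) / rng
    if config.k is not None:
        k = config.k
    else:
        n = len(y)
        k_max = config.k_max if config.k_max is not None else _default_k_max(n)
        k_max = min(k_max, n - 1)
        k = select_k(xs, y, list(range(1, k_max + 1, 2)), weighting=config.weighting)
    return KNNModel(xs, np.asarray(y, dtype=int), k, config.weighting, lo, rng)


@dataclass
class SubspaceEnsemble:
    """The complete n_pca x n_pca grid of subspace kNN classifiers."""

    subspaces: list[SubspacePair]
    classifiers: list[KNNModel]
    n_pca: int
    vote_rule: str = UNANIMITY

    def __post_init__(self) -> None:
        if self.vote_rule not in (UNANIMITY, MAJORITY):
            raise ConfigError(f"unknown vote rule {self.vote_rule!r}")
        if len(self.classifiers) != self.n_pca**2 or len(self.subspaces) != self.n_pca**2:
            raise ConfigError(
                f"ensemble must hold n_pca^2 = {self.n_pca**2} classifiers"
            )

    @property
    def n_classifiers(self) -> int:
        return len(self.classifiers)

    def votes(self, x_full: np.ndarray) -> np.ndarray:
        """Per-classifier 0/1 votes, shape (n_queries, n_classifiers)."""
        x = np.atleast_2d(np.asarray(x_full, dtype=float))
        cols = []
        for sub, clf in zip(self.subspaces, self.classifiers):
            labels, _ = clf.predict(x[:, sub.feature_indices])
            cols.append(labels)
        return np.column_stack(cols)

    def predict(
        self, x_full: np.ndarray, vote_rule: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Final labels plus the per-classifier vote matrix (for audit)."""
        rule = vote_rule or self.vote_rule
        votes = self.votes(x_full)
        if rule == UNANIMITY:
            labels = votes.all(axis=1).astype(int)
        elif rule == MAJORITY:
            labels = (votes.sum(axis=1) > self.n_classifiers / 2).astype(int)
        else:
            raise ConfigError(f"unknown vote rule {rule!r}")
        return labels, votes

    # -- persistence -------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        """Persist the trained grid to a directory (manifest + .npy arrays)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "dtiknn.ensemble",
            "version": 1,
            "n_pca": self.n_pca,
            "vote_rule": self.vote_rule,
            "classifiers": [],
        }
        for m, (sub, clf) in enumerate(zip(self.subspaces, self.classifiers)):
            stem = f"clf_{m:03d}"
            np.save(d / f"{stem}_X.npy", clf.training_vectors)
            np.save(d / f"{stem}_y.npy", clf.labels)
            np.save(d / f"{stem}_scaler.npy", np.vstack([clf.scaler_offset, clf.scaler_scale]))
            np.save(d / f"{stem}_features.npy", sub.feature_indices)
            manifest["classifiers"].append(
                {
                    "stem": stem,
                    "target_component": sub.target_component,
                    "drug_group": sub.drug_group,
                    "k": clf.k,
                    "weighting": clf.weighting,
                }
            )
        (d / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "SubspaceEnsemble":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        if manifest.get("format") != "dtiknn.ensemble":
            raise InputError(f"{d} does not contain an ensemble bundle")
        subspaces, classifiers = [], []
        for entry in manifest["classifiers"]:
            stem = entry["stem"]
            scaler = np.load(d / f"{stem}_scaler.npy")
            subspaces.append(
                SubspacePair(
                    entry["target_component"],
                    entry["drug_group"],
                    np.load(d / f"{stem}_features.npy"),
                )
            )
            classifiers.append(
                KNNModel(
                    np.load(d / f"{stem}_X.npy"),
                    np.load(d / f"{stem}_y.npy"),
                    entry["k"],
                    entry["weighting"],
                    scaler[0],
                    scaler[1],
                )
            )
        return cls(subspaces, classifiers, manifest["n_pca"], manifest["vote_rule"])


def fit_ensemble(
    pairs: list[PairVector] | tuple[np.ndarray, np.ndarray],
    subspaces: list[SubspacePair],
    config: KNNConfig | None = None,
    vote_rule: str = UNANIMITY,
) -> SubspaceEnsemble:
    """Train every subspace classifier on the same instance set."""
    n_pca = int(round(math.sqrt(len(subspaces))))
    if n_pca**2 != len(subspaces):
        raise ConfigError("subspace list must form a complete square grid")
    if isinstance(pairs, tuple):
        xy: tuple[np.ndarray, np.ndarray] = pairs
    else:
        xy = pair_matrix(pairs)
    classifiers = [fit_subspace_knn(xy, sub, config) for sub in subspaces]
    return SubspaceEnsemble(subspaces, classifiers, n_pca, vote_rule)
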