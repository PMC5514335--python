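"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths (and sklearn's
neighbor machinery) so they can serve as second opinions: plain loops,
explicit arithmetic, exact fractions where possible.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

ZERO_DIST = 1e-12


def brute_knn_scores(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_query: np.ndarray,
    k: int,
    weighting: str,
) -> np.ndarray:
    """Per-query positive-class score by exhaustive distance scan."""
    scores = []
    for q in np.atleast_2d(x_query):
        d = np.sqrt(((x_train - q) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")[:k]
        dk, yk = d[order], y_train[order]
        if weighting == "uniform":
            w = np.ones(k)
        else:
            zero = dk <= ZERO_DIST
            w = zero.astype(float) if zero.any() else 1.0 / dk
        scores.append(float((w * yk).sum() / w.sum()))
    return np.array(scores)


def brute_knn_predict(x_train, y_train, x_query, k, weighting) -> np.ndarray:
    return (brute_knn_scores(x_train, y_train, x_query, k, weighting) > 0.5).astype(int)


def brute_loo_accuracy(x, y, k, weighting) -> float:
    """Leave-one-out accuracy by refitting on n point-deleted sets."""
    n = len(y)
    hits = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        pred = brute_knn_predict(x[mask], y[mask], x[i : i + 1], k, weighting)[0]
        hits += int(pred == y[i])
    return hits / n


def brute_select_k(x, y, k_candidates, weighting) -> int:
    """Exhaustive best-of-grid LOO k selection; smallest k wins ties."""
    best_k, best_acc = None, -1.0
    for k in sorted(k_candidates):
        acc = brute_loo_accuracy(x, y, k, weighting)
        if acc > best_acc + 1e-12:
            best_k, best_acc = k, acc
    return best_k


def exact_metrics(tp: int, fp: int, tn: int, fn: int) -> dict:
    """Confusion-matrix metrics in exact rational arithmetic (MCC as float)."""
    out = {}
    out["rec"] = Fraction(tp, tp + fn) if tp + fn else None
    out["prec"] = Fraction(tp, tp + fp) if tp + fp else None
    out["acc"] = Fraction(tp + tn, tp + fp + tn + fn)
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(den) if den else None
    if out["rec"] is None or out["prec"] is None or out["rec"] + out["prec"] == 0:
        out["f1"] = None
    else:
        out["f1"] = 2 * out["prec"] * out["rec"] / (out["prec"] + out["rec"])
    return out


def tally_composition(seq: str, bounds, alphabet) -> np.ndarray:
    """Character-by-character composition tally, independent of numpy coding."""
    counts = np.zeros((len(bounds), len(alphabet)), dtype=int)
    for j, (a, b) in enumerate(bounds):
        for ch in seq[a:b]:
            counts[j][alphabet.index(ch)] += 1
    return counts


def triple_loop_encoding(loadings: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Naive (l, j, n) loop over the fragment-composition encoding."""
    n_pca, n_aa = loadings.shape
    n_frag = counts.shape[0]
    out = np.zeros(n_pca * n_frag * n_aa)
    pos = 0
    for l in range(n_pca):
        for j in range(n_frag):
            for n in range(n_aa):
                out[pos] = loadings[l, n] * counts[j, n]
                pos += 1
    return out
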