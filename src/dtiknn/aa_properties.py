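"""Amino-acid property tables and the principal components that summarise them.

Target proteins are encoded with numerical amino-acid indices (one value per
residue type per property).  Collections such as AAindex1 hold hundreds of
highly correlated properties; a PCA across properties (observations = the
properties, variables = the 20 residue types) compresses them into a handful
of orthonormal 20-long loading vectors that retain most of the variance.
Those loading vectors are what the protein encoder consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ParseError

#: The 20 standard residues in the two-row order used by AAindex ``I`` fields
#: (first row A R N D C Q E G H I, second row L K M F P S T W Y V).  This is
#: the canonical column order of every property table and loading vector in
#: the package.
AMINO_ACIDS: tuple[str, ...] = (
    "A", "R", "N", "D", "C", "Q", "E", "G", "H", "I",
    "L", "K", "M", "F", "P", "S", "T", "W", "Y", "V",
)

N_AA = len(AMINO_ACIDS)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class AAPropertyTable:
    """A matrix of P amino-acid properties over the 20 standard residues.

    Parameters
    ----------
    accessions : list of str
        One identifier per property (e.g. AAindex accessions).
    descriptions : list of str
        Free-text description per property.
    values : ndarray of shape (P, 20)
        Property values in :data:`AMINO_ACIDS` column order.  Missing cells
        are NaN.
    flagged : ndarray of bool, shape (P,)
        Properties excluded from downstream PCA (missing values, or zero
        variance after standardization).
    """

    accessions: list[str]
    descriptions: list[str]
    values: np.ndarray
    flagged: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_AA:
            raise ParseError(
                f"property table must have {N_AA} residue columns, "
                f"got shape {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ParseError("property table must contain at least one property")
        if self.flagged is None:
            self.flagged = ~np.isfinite(self.values).all(axis=1)
        self.flagged = np.asarray(self.flagged, dtype=bool)

    @property
    def n_properties(self) -> int:
        return self.values.shape[0]

    def unflagged_values(self) -> np.ndarray:
        """Rows that participate in PCA, shape (P_kept, 20)."""
        return self.values[~self.flagged]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(AMINO_ACIDS))
        df.insert(0, "accession", self.accessions)
        return df


def read_aaindex1(path: str | Path) -> AAPropertyTable:
    """Parse an AAindex1 flat file into an :class:`AAPropertyTable`.

    Each record carries ``H`` (accession), ``D`` (description) and an ``I``
    field whose two data rows list the 20 values in the order
    A R N D C Q E G H I / L K M F P S T W Y V.  Records with the ``NA``
    missing marker are kept but flagged, so they are excluded from PCA.

    Raises
    ------
    ParseError
        If the file is empty or a record's ``I`` field does not contain
        exactly 20 entries (the accession is named in the message).
    """
    text = Path(path).read_text()
    records = [r for r in text.split("//") if r.strip()]
    if not records:
        raise ParseError(f"no AAindex records found in {path}")

    accessions: list[str] = []
    descriptions: list[str] = []
    rows: list[list[float]] = []
    for rec in records:
        accession = ""
        description_parts: list[str] = []
        tokens: list[str] = []
        current = None
        for line in rec.splitlines():
            if not line.strip():
                continue
            if line[0] not in " \t":
                current = line[0]
                body = line[1:].strip()
            else:
                body = line.strip()
            if current == "H" and not accession:
                accession = body.split()[0] if body else ""
            elif current == "D":
                description_parts.append(body)
            elif current == "I":
                # skip the I header line itself (residue pair labels like A/L)
                if "/" in body:
                    continue
                tokens.extend(body.split())
        if not accession:
            raise ParseError("AAindex record without an H (accession) field")
        if len(tokens) != N_AA:
            raise ParseError(
                f"record {accession}: expected {N_AA} values in I field, "
                f"got {len(tokens)}"
            )
        row = [float("nan") if t.upper() == "NA" else float(t) for t in tokens]
        accessions.append(accession)
        descriptions.append(" ".join(description_parts))
        rows.append(row)

    return AAPropertyTable(accessions, descriptions, np.array(rows, dtype=float))


def read_property_csv(path: str | Path) -> AAPropertyTable:
    """Read a plain property matrix CSV: first column accession, 20 residue
    columns named by single letters (any order; mapped to canonical order)."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] != N_AA + 1:
        raise ParseError(
            f"property CSV needs 1 id column + {N_AA} residue columns, "
            f"got {df.shape[1]} columns"
        )
    id_col = df.columns[0]
    residue_cols = [c.strip().upper() for c in df.columns[1:]]
    if sorted(residue_cols) != sorted(AMINO_ACIDS):
        raise ParseError("property CSV residue columns must be the 20 standard letters")
    order = [residue_cols.index(aa) for aa in AMINO_ACIDS]
    values = df.iloc[:, 1:].to_numpy(dtype=float)[:, order]
    accessions = [str(a) for a in df[id_col]]
    return AAPropertyTable(accessions, [""] * len(accessions), values)


def standardize(table: AAPropertyTable) -> AAPropertyTable:
    """Z-score every unflagged property across the 20 residues.

    Each property row gets mean 0 and (population) standard deviation 1, so
    properties expressed in wildly different units contribute comparably to
    the PCA.  Rows with zero variance cannot be scaled and are flagged.
    The operation is idempotent on already-standardized rows.
    """
    if int((~table.flagged).sum()) < 2:
        raise ConfigError("need at least 2 unflagged properties to standardize")
    values = table.values.copy()
    flagged = table.flagged.copy()
    keep = ~flagged
    mu = values[keep].mean(axis=1, keepdims=True)
    sd = values[keep].std(axis=1, keepdims=True)
    zero_var = (sd.ravel() == 0.0)
    sd[sd == 0.0] = 1.0
    values[keep] = (values[keep] - mu) / sd
    keep_idx = np.flatnonzero(keep)
    flagged[keep_idx[zero_var]] = True
    if flagged.all():
        raise ConfigError("all properties flagged after standardization")
    return AAPropertyTable(
        list(table.accessions), list(table.descriptions), values, flagged
    )


@dataclass
class PrincipalComponentModel:
    """Top-L principal components of a property table.

    ``loadings`` is an (L, 20) matrix of orthonormal row vectors in residue
    space; ``variance_fractions`` the fraction of total property variance
    each component explains (non-increasing).  ``center``/``scale`` record
    the residue-wise affine transform applied before projection so encodings
    are reproducible from a serialized model.
    """

    loadings: np.ndarray
    variance_fractions: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.loadings.ndim != 2 or self.loadings.shape[1] != N_AA:
            raise ConfigError("loadings must have shape (L, 20)")
        if len(self.variance_fractions) != self.loadings.shape[0]:
            raise ConfigError("one variance fraction per component required")
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.loadings.shape[0]), atol=1e-8):
            raise ConfigError("loading vectors must be orthonormal (tol 1e-8)")
        if np.any(np.diff(self.variance_fractions) > 1e-12):
            raise ConfigError("variance fractions must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def project(self, residue_matrix: np.ndarray) -> np.ndarray:
        """Project rows of a (n, 20) matrix onto the components."""
        x = (np.asarray(residue_matrix, dtype=float) - self.center) / self.scale
        return x @ self.loadings.T

    # -- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "dtiknn.pca",
            "version": 1,
            "amino_acids": list(AMINO_ACIDS),
            "loadings": self.loadings.tolist(),
            "variance_fractions": self.variance_fractions.tolist(),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrincipalComponentModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "dtiknn.pca":
            raise ParseError(f"{path} is not a serialized component model")
        return cls(
            np.array(payload["loadings"], dtype=float),
            np.array(payload["variance_fractions"], dtype=float),
            np.array(payload["center"], dtype=float),
            np.array(payload["scale"], dtype=float),
        )


def fit_pca(
    table: AAPropertyTable,
    n_components: int | None = None,
    variance_target: float | None = None,
) -> PrincipalComponentModel:
    """Fit a PCA of the (standardized) property table.

    Properties are the observations and the 20 residue types the variables,
    so each component is a 20-long loading vector.  Exactly one of
    ``n_components`` / ``variance_target`` selects how many components to
    keep: either a fixed count, or the smallest count whose cumulative
    explained-variance fraction reaches the target.

    The sign of each component is fixed so that its largest-magnitude entry
    is positive (PCA sign is otherwise arbitrary).
    """
    from sklearn.decomposition import PCA

    if (n_components is None) == (variance_target is None):
        raise ConfigError("specify exactly one of n_components / variance_target")
    if variance_target is not None and not (0.0 < variance_target <= 1.0):
        raise ConfigError(f"variance_target must be in (0, 1], got {variance_target}")

    x = table.unflagged_values()
    if not np.isfinite(x).all():
        raise ConfigError("unflagged property rows contain non-finite values")
    full_rank = min(x.shape[0], N_AA)
    if n_components is not None:
        if not 1 <= n_components <= N_AA:
            raise ConfigError(f"n_components must be in [1, {N_AA}]")
        if n_components > x.shape[0]:
            raise ConfigError(
                f"{n_components} components requested but only "
                f"{x.shape[0]} unflagged properties available"
            )

    pca = PCA(n_components=full_rank, svd_solver="full")
    pca.fit(x)
    ratios = pca.explained_variance_ratio_

    if n_components is not None:
        n_keep = n_components
    else:
        cum = np.cumsum(ratios)
        n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
        n_keep = min(n_keep, full_rank)

    loadings = pca.components_[:n_keep].copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PrincipalComponentModel(
        loadings=loadings,
        variance_fractions=ratios[:n_keep].copy(),
        center=pca.mean_.copy(),
        scale=np.ones(N_AA),
    )


def cumulative_variance(model: PrincipalComponentModel, k: int) -> float:
    """Total variance fraction explained by the first ``k`` components."""
    if not 1 <= k <= model.n_components:
        raise ConfigError(
            f"k must be in [1, {model.n_components}], got {k}"
        )
    return float(model.variance_fractions[:k].sum())
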