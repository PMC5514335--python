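"""Drug descriptor tables, descriptor-group partitions and pair vectors.

Drugs arrive as a precomputed table of 1D/2D molecular descriptors (e.g. a
PaDEL-Descriptor export: one ``Name`` id column plus numeric columns).  The
descriptors are cleaned (non-finite or constant columns dropped — kNN
distances must be finite and informative), partitioned in file order into
``n_groups`` contiguous groups, and concatenated with the protein encoding
into labeled drug-target pair vectors: drug block first, protein block
second, giving (D + n_pca * n_frag * 20)-dimensional instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError


@dataclass
class DescriptorTable:
    """Drugs x descriptors matrix with file-ordered descriptor names."""

    drug_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.drug_ids), len(self.descriptor_names)):
            raise ConfigError("descriptor matrix shape does not match id/name lists")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_descriptors(self) -> int:
        return len(self.descriptor_names)

    def row(self, drug_id: str) -> np.ndarray:
        return self.values[self.drug_ids.index(drug_id)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.drug_ids, columns=self.descriptor_names
        )
        df.index.name = "Name"
        return df


def read_descriptor_table(path: str | Path) -> DescriptorTable:
    """Read a descriptor CSV (first column = drug id, rest numeric).

    Non-numeric cells and literal ``Inf`` values are recorded as missing
    (NaN) and handled by :func:`clean_descriptors`.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: descriptor CSV has no descriptor columns")
    ids = [str(x) for x in df.iloc[:, 0]]
    dup = sorted({x for x in ids if ids.count(x) > 1})
    if dup:
        raise InputError(f"duplicate drug ids in {path}: {dup}")
    values = (
        df.iloc[:, 1:]
        .apply(pd.to_numeric, errors="coerce")
        .to_numpy(dtype=float)
    )
    values[~np.isfinite(values)] = np.nan
    return DescriptorTable(ids, [str(c) for c in df.columns[1:]], values)


def clean_descriptors(table: DescriptorTable) -> DescriptorTable:
    """Drop descriptors that are missing/non-finite for any drug or constant
    across all drugs; survivors keep their original order."""
    finite = np.isfinite(table.values).all(axis=0)
    with np.errstate(invalid="ignore"):
        varying = np.nanstd(table.values, axis=0) > 0.0
    keep = finite & varying
    if not keep.any():
        raise InputError("every descriptor was dropped during cleaning")
    dropped = [n for n, k in zip(table.descriptor_names, keep) if not k]
    return DescriptorTable(
        list(table.drug_ids),
        [n for n, k in zip(table.descriptor_names, keep) if k],
        table.values[:, keep],
        dropped=dropped,
    )


@dataclass
class DescriptorGroupPartition:
    """Ordered, contiguous half-open descriptor index ranges (the drug-side
    feature groups Fd_1 .. Fd_n)."""

    group_bounds: list[tuple[int, int]]

    @property
    def n_groups(self) -> int:
        return len(self.group_bounds)

    @property
    def n_descriptors(self) -> int:
        return self.group_bounds[-1][1]

    def group_indices(self, j: int) -> np.ndarray:
        """Descriptor indices of group ``j`` (1-based)."""
        if not 1 <= j <= self.n_groups:
            raise ConfigError(f"group index must be in [1, {self.n_groups}], got {j}")
        a, b = self.group_bounds[j - 1]
        return np.arange(a, b)

    def sizes(self) -> list[int]:
        return [b - a for a, b in self.group_bounds]


def partition_descriptors(n_descriptors: int, n_groups: int) -> DescriptorGroupPartition:
    """Split D descriptors in order into n_groups contiguous groups, the
    first n_groups - 1 of size INT(D/n_groups), the last absorbing the
    remainder (same convention as the protein fragmenter; with D = 1444 and
    7 groups this gives six groups of 206 and one of 208)."""
    if n_groups < 1:
        raise ConfigError(f"n_groups must be positive, got {n_groups}")
    if n_descriptors < n_groups:
        raise InputError(
            f"{n_descriptors} descriptors cannot form {n_groups} non-empty groups"
        )
    base = n_descriptors // n_groups
    bounds = [(j * base, (j + 1) * base) for j in range(n_groups - 1)]
    bounds.append(((n_groups - 1) * base, n_descriptors))
    return DescriptorGroupPartition(bounds)


@dataclass
class PairVector:
    """One labeled drug-target instance: drug descriptor block first, then
    the protein feature block."""

    drug_id: str
    protein_id: str
    values: np.ndarray
    label: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.label not in (0, 1):
            raise ConfigError(f"label must be 0/1, got {self.label}")

    def __len__(self) -> int:
        return self.values.size


def build_pair_vectors(
    pairs: list[tuple[str, str, int]],
    drugs: DescriptorTable,
    proteins: pd.DataFrame,
) -> list[PairVector]:
    """Concatenate drug and protein encodings for every labeled id pair.

    ``proteins`` is the encoded protein matrix (index = protein id), as
    produced by :func:`dtiknn.protein_encoder.encode_proteins`.  Output order
    equals input pair order.  Unknown ids raise a single error listing every
    missing id.
    """
    drug_index = {d: i for i, d in enumerate(drugs.drug_ids)}
    missing_d = sorted({d for d, _, _ in pairs if d not in drug_index})
    missing_p = sorted({p for _, p, _ in pairs if p not in proteins.index})
    if missing_d or missing_p:
        raise InputError(
            f"unknown ids in pair list: drugs {missing_d}, proteins {missing_p}"
        )
    prot_values = proteins.to_numpy(dtype=float)
    prot_index = {p: i for i, p in enumerate(proteins.index)}
    out = []
    for d, p, label in pairs:
        vec = np.concatenate(
            [drugs.values[drug_index[d]], prot_values[prot_index[p]]]
        )
        out.append(PairVector(d, p, vec, int(label)))
    return out


def pair_matrix(pairs: list[PairVector]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pair vectors into (X, y) arrays for the ensemble."""
    x = np.vstack([p.values for p in pairs])
    y = np.array([p.label for p in pairs], dtype=int)
    return x, y


def compute_descriptors(smiles: dict[str, str]) -> DescriptorTable:
    """Optional adapter: compute 1D/2D descriptors from SMILES with RDKit.

    Produces the same :class:`DescriptorTable` contract as a precomputed
    CSV (the canonical input path), so downstream cleaning/partitioning is
    unchanged.  Requires ``rdkit``.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    names = [name for name, _ in Descriptors.descList]
    ids, rows = [], []
    for drug_id, smi in smiles.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise InputError(f"unparseable SMILES for drug {drug_id!r}: {smi!r}")
        values = Descriptors.CalcMolDescriptors(mol)
        ids.append(str(drug_id))
        rows.append([float(values[n]) for n in names])
    return DescriptorTable(ids, names, np.array(rows, dtype=float))


def read_pairs_csv(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a ``drug_id,protein_id,label`` CSV into a pair list."""
    df = pd.read_csv(path, comment="#", dtype=str)
    required = {"drug_id", "protein_id", "label"}
    if not required.issubset(df.columns):
        raise InputError(f"{path}: pair CSV must have columns {sorted(required)}")
    labels = df["label"].astype(int)
    if not labels.isin([0, 1]).all():
        raise InputError(f"{path}: labels must be 0/1")
    return list(zip(df["drug_id"].astype(str), df["protein_id"].astype(str), labels))
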