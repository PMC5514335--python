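"""Fragment-composition encoding of target proteins.

A protein sequence of length ``Len`` is cut into ``n_frag`` contiguous
fragments of INT(Len/n_frag) residues from N- to C-terminus (the last
fragment absorbs the remainder).  Within each fragment the 20 residue types
are counted.  Each property principal component ``l`` then scores fragment
``j`` elementwise: feature (l, j, n) = loading_l(residue n) x count_j(residue
n).  Concatenating all components and fragments yields a vector of length
n_pca x n_frag x 20 (1400 at the 7-component / 10-fragment defaults).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aa_properties import AMINO_ACIDS, N_AA, _AA_INDEX, PrincipalComponentModel
from .errors import ConfigError, InputError

ResiduePolicy = str  # "reject" | "skip"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with an identifier."""

    id: str
    sequence: str


@dataclass
class FragmentComposition:
    """Residue-type counts per fragment.

    ``counts`` has shape (n_frag, 20) in canonical residue order;
    ``fragment_bounds`` the half-open index ranges of each fragment in the
    (cleaned) sequence, ordered N-terminal to C-terminal.
    """

    counts: np.ndarray
    fragment_bounds: list[tuple[int, int]]

    @property
    def n_fragments(self) -> int:
        return self.counts.shape[0]

    def fragment_lengths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.fragment_bounds])


@dataclass
class ProteinFeatureVector:
    """The concatenated component x fragment x residue encoding.

    ``values`` is ordered component-major: index ((l * n_frag) + j) * 20 + n,
    so the block of one component is contiguous (which is what the subspace
    ensemble slices on).
    """

    values: np.ndarray
    n_pca: int
    n_frag: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.n_pca * self.n_frag * N_AA:
            raise ConfigError(
                f"encoding length {self.values.size} != "
                f"{self.n_pca} x {self.n_frag} x {N_AA}"
            )

    def __len__(self) -> int:
        return self.values.size

    def component_block(self, l: int) -> np.ndarray:
        """Values of component ``l`` (1-based), shape (n_frag * 20,)."""
        idx = component_feature_group(l, self.n_pca, self.n_frag)
        return self.values[idx]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; the id is the first header token."""
    from Bio import SeqIO

    records = [
        ProteinRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def clean_sequence(seq: str, policy: ResiduePolicy = "reject") -> str:
    """Apply the non-standard-residue policy.

    ``reject`` (default) raises on any character outside the 20-letter
    alphabet; ``skip`` removes such characters, so fragment boundaries are
    computed on the cleaned sequence.
    """
    seq = seq.upper()
    bad = sorted({c for c in seq if c not in _AA_INDEX})
    if not bad:
        return seq
    if policy == "reject":
        raise InputError(
            f"sequence contains non-standard residues {bad!r}; "
            "use policy='skip' to drop them"
        )
    if policy == "skip":
        return "".join(c for c in seq if c in _AA_INDEX)
    raise ConfigError(f"unknown residue policy {policy!r}")


def fragment_sequence(seq_len: int | str, n_frag: int) -> list[tuple[int, int]]:
    """Half-open fragment bounds: n_frag contiguous pieces covering the
    sequence, the first n_frag-1 of length INT(Len/n_frag), the last
    absorbing the remainder."""
    length = len(seq_len) if isinstance(seq_len, str) else int(seq_len)
    if n_frag < 1:
        raise ConfigError(f"n_frag must be positive, got {n_frag}")
    if length < n_frag:
        raise InputError(
            f"sequence length {length} < n_frag {n_frag}: empty fragment"
        )
    base = length // n_frag
    bounds = [(j * base, (j + 1) * base) for j in range(n_frag - 1)]
    bounds.append(((n_frag - 1) * base, length))
    return bounds


def count_composition(
    seq: str, bounds: list[tuple[int, int]]
) -> FragmentComposition:
    """Count the 20 residue types inside each fragment of ``seq``."""
    if bounds[-1][1] != len(seq):
        raise InputError("fragment bounds do not cover the sequence")
    counts = np.zeros((len(bounds), N_AA), dtype=int)
    codes = np.array([_AA_INDEX.get(c, -1) for c in seq])
    if (codes < 0).any():
        bad = sorted({seq[i] for i in np.flatnonzero(codes < 0)})
        raise InputError(f"non-standard residues {bad!r}; clean the sequence first")
    for j, (a, b) in enumerate(bounds):
        counts[j] = np.bincount(codes[a:b], minlength=N_AA)
    return FragmentComposition(counts, list(bounds))


def encode_protein(
    rec: ProteinRecord,
    model: PrincipalComponentModel,
    n_frag: int = 10,
    policy: ResiduePolicy = "reject",
    frequencies: bool = False,
) -> ProteinFeatureVector:
    """Encode one protein as its component x fragment x residue feature vector.

    Parameters
    ----------
    rec : ProteinRecord
    model : PrincipalComponentModel
        Supplies the n_pca loading vectors.
    n_frag : int
        Number of sequence fragments (default 10).
    policy : {"reject", "skip"}
        Handling of non-standard residues.
    frequencies : bool
        If True, fragment counts are divided by the fragment length before
        scoring (off by default: raw counts).
    """
    seq = clean_sequence(rec.sequence, policy)
    bounds = fragment_sequence(len(seq), n_frag)
    comp = count_composition(seq, bounds)
    counts = comp.counts.astype(float)
    if frequencies:
        counts = counts / comp.fragment_lengths()[:, None]
    # (l, j, n) = loading_l(n) * count_j(n), component-major flattening
    values = np.einsum("ln,jn->ljn", model.loadings, counts).ravel()
    return ProteinFeatureVector(values, model.n_components, n_frag)


def component_feature_group(l: int, n_pca: int, n_frag: int) -> np.ndarray:
    """Indices of the features belonging to component ``l`` (1-based).

    The groups are contiguous, pairwise disjoint and partition the full
    index range 0 .. n_pca * n_frag * 20.
    """
    if not 1 <= l <= n_pca:
        raise ConfigError(f"component index must be in [1, {n_pca}], got {l}")
    block = n_frag * N_AA
    return np.arange((l - 1) * block, l * block)


def feature_names(n_pca: int, n_frag: int) -> list[str]:
    """Column names ``c{l}_f{j}_{residue}`` matching the flattening order."""
    return [
        f"c{l}_f{j}_{aa}"
        for l in range(1, n_pca + 1)
        for j in range(1, n_frag + 1)
        for aa in AMINO_ACIDS
    ]


def encode_proteins(
    records: list[ProteinRecord],
    model: PrincipalComponentModel,
    n_frag: int = 10,
    policy: ResiduePolicy = "reject",
    frequencies: bool = False,
) -> pd.DataFrame:
    """Encode many proteins into a DataFrame (index = protein id)."""
    rows = {
        rec.id: encode_protein(rec, model, n_frag, policy, frequencies).values
        for rec in records
    }
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=feature_names(model.n_components, n_frag)
    )
    df.index.name = "protein_id"
    return df
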