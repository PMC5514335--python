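"""Synthetic data generators with the statistical structure the method assumes.

Three generators cover the pipeline's inputs:

* a property table with low-rank-plus-noise structure, so a PCA of rank
  ``property_rank`` recovers almost all variance;
* random protein sequences over the 20-letter alphabet;
* a drug descriptor table plus labeled pairs with a *planted* signal: the
  descriptor columns of one drug group are mean-shifted (by ``effect_size``
  standard deviations) for the drugs of positive pairs, so the label is
  detectable exactly in the subspaces containing that drug group.  With
  ``signal_subspace=None`` every descriptor column is shifted instead
  (a globally informative dataset, on which the full ensemble can succeed).

Every generator is a pure function of the spec + seed; the manifest written
alongside a fixture directory is sufficient to regenerate it byte-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .aa_properties import AMINO_ACIDS, N_AA, AAPropertyTable
from .drug_features import DescriptorTable, partition_descriptors
from .errors import ConfigError
from .evaluation import InteractionDataset
from .protein_encoder import ProteinRecord


@dataclass
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults mirror the full-scale study conditions where they exist
    (7 components, 10 fragments, 1444 descriptors, 544 properties, 1:2
    positives:negatives); the planted-signal strength and dataset size are
    the package's own choices, documented in docs/methods.md.
    """

    n_drugs: int = 300
    n_proteins: int = 30
    n_positive: int = 100
    seq_len_range: tuple[int, int] = (80, 300)
    n_descriptors: int = 1444
    n_properties: int = 544
    property_rank: int = 7
    property_noise_sd: float = 0.05
    signal_subspace: tuple[int, int] | None = (3, 7)  # (component i, drug group j), 1-based
    effect_size: float = 3.0
    noise_sd: float = 1.0
    n_pca: int = 7
    n_frag: int = 10
    ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.property_rank > N_AA:
            raise ConfigError(f"property_rank must be <= {N_AA}")
        n_pairs = self.n_pairs
        if n_pairs > self.n_drugs:
            raise ConfigError(
                f"need n_drugs >= {n_pairs} (one drug per pair) for exact "
                "per-pair signal planting"
            )
        if self.n_positive > self.n_drugs * self.n_proteins / (1 + self.ratio):
            raise ConfigError("not enough drug x protein room for the negatives")
        if self.seq_len_range[0] < self.n_frag:
            raise ConfigError("minimum sequence length must be >= n_frag")

    @property
    def n_pairs(self) -> int:
        return self.n_positive + int(round(self.ratio * self.n_positive))

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["seq_len_range"] = list(self.seq_len_range)
        d["signal_subspace"] = (
            list(self.signal_subspace) if self.signal_subspace else None
        )
        d["generator"] = "dtiknn.fixtures"
        d["rule"] = (
            "positive-pair drugs mean-shifted by effect_size*noise_sd in "
            + (
                f"descriptor group {self.signal_subspace[1]}"
                if self.signal_subspace
                else "all descriptor groups"
            )
        )
        return d

    @classmethod
    def from_manifest(cls, d: dict) -> "FixtureSpec":
        d = dict(d)
        d.pop("generator", None)
        d.pop("rule", None)
        d["seq_len_range"] = tuple(d["seq_len_range"])
        if d.get("signal_subspace") is not None:
            d["signal_subspace"] = tuple(d["signal_subspace"])
        return cls(**d)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def make_property_table(spec: FixtureSpec) -> AAPropertyTable:
    """A P x 20 property matrix = rank-r structure + Gaussian noise.

    Rows are unit-scale linear combinations of ``property_rank`` latent
    residue profiles, so after row standardization the top-r principal
    components recover nearly all variance.
    """
    if not 1 <= spec.property_rank <= N_AA:
        raise ConfigError(f"property_rank must be in [1, {N_AA}]")
    rng = _rng(spec, 1)
    u = rng.standard_normal((spec.n_properties, spec.property_rank))
    v = rng.standard_normal((spec.property_rank, N_AA))
    values = u @ v + spec.property_noise_sd * rng.standard_normal(
        (spec.n_properties, N_AA)
    )
    accessions = [f"SYN{i:05d}" for i in range(1, spec.n_properties + 1)]
    return AAPropertyTable(
        accessions, ["synthetic rank-structured property"] * spec.n_properties, values
    )


def make_sequences(spec: FixtureSpec) -> list[ProteinRecord]:
    """Random protein sequences, lengths uniform in ``seq_len_range``,
    residues i.i.d. uniform over the 20-letter alphabet."""
    rng = _rng(spec, 2)
    lo, hi = spec.seq_len_range
    records = []
    for i in range(1, spec.n_proteins + 1):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(np.array(AMINO_ACIDS)[rng.integers(0, N_AA, size=length)])
        records.append(ProteinRecord(f"P{i:04d}", seq))
    return records


def make_labeled_pairs(
    spec: FixtureSpec,
) -> tuple[DescriptorTable, InteractionDataset, dict]:
    """Descriptor table + labeled pairs with the planted subspace signal.

    Each pair uses a distinct drug (so a per-pair descriptor shift is
    consistent); positives get their drug's ``signal_subspace`` descriptor
    group shifted by ``effect_size * noise_sd``.  Returns the table, the
    dataset and the regeneration manifest.
    """
    rng = _rng(spec, 3)
    n_pairs = spec.n_pairs
    drug_ids = [f"D{i:04d}" for i in range(1, spec.n_drugs + 1)]
    values = spec.noise_sd * rng.standard_normal((spec.n_drugs, spec.n_descriptors))

    pair_drugs = rng.permutation(spec.n_drugs)[:n_pairs]
    pair_prots = rng.integers(0, spec.n_proteins, size=n_pairs)
    labels = np.zeros(n_pairs, dtype=int)
    labels[: spec.n_positive] = 1
    labels = labels[rng.permutation(n_pairs)]

    if spec.signal_subspace is not None:
        _, j = spec.signal_subspace
        part = partition_descriptors(spec.n_descriptors, spec.n_pca)
        cols = part.group_indices(j)
    else:
        cols = np.arange(spec.n_descriptors)
    shift = spec.effect_size * spec.noise_sd
    pos_drugs = pair_drugs[labels == 1]
    values[np.ix_(pos_drugs, cols)] += shift

    positives = {
        (drug_ids[d], f"P{p + 1:04d}")
        for d, p, lab in zip(pair_drugs, pair_prots, labels)
        if lab == 1
    }
    negatives = {
        (drug_ids[d], f"P{p + 1:04d}")
        for d, p, lab in zip(pair_drugs, pair_prots, labels)
        if lab == 0
    }
    table = DescriptorTable(
        drug_ids, [f"desc{k:04d}" for k in range(1, spec.n_descriptors + 1)], values
    )
    dataset = InteractionDataset(positives, negatives, class_tag="custom")
    return table, dataset, spec.to_manifest()


def write_fixture_dir(spec: FixtureSpec, directory: str | Path) -> dict[str, Path]:
    """Materialize a fixture as the same FASTA/CSV files the pipeline reads.

    Writes ``proteins.fasta``, ``properties.csv``, ``descriptors.csv``,
    ``pairs.csv`` and the ``fixtures.yaml`` manifest; returns the paths.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    table = make_property_table(spec)
    records = make_sequences(spec)
    drugs, dataset, manifest = make_labeled_pairs(spec)

    paths = {
        "properties": d / "properties.csv",
        "proteins": d / "proteins.fasta",
        "descriptors": d / "descriptors.csv",
        "pairs": d / "pairs.csv",
        "manifest": d / "fixtures.yaml",
    }
    table.to_frame().to_csv(paths["properties"], index=False)
    with open(paths["proteins"], "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k : k + 60] + "\n")
    drugs.to_frame().to_csv(paths["descriptors"])
    with open(paths["pairs"], "w") as fh:
        fh.write("drug_id,protein_id,label\n")
        for drug, prot, label in dataset.pair_list():
            fh.write(f"{drug},{prot},{label}\n")
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=True))
    return paths
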