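"""Readers, writers, and the on-disk species layout.

One directory per species::

    <species_dir>/
        universal.aln.fasta   in-frame concatenated universal-gene alignment
        core.aln.fasta        in-frame concatenated core-gene alignment
        tree.nwk              strain tree with branch lengths (Newick)
        families.tsv          presence/absence matrix, strains x families
        metadata.txt          "key: value" lines (species_id, lifestyle,
                              min_doubling_time, mutation_rate)
        hits.tsv              optional universal-gene hit table

All tabular output is UTF-8 TSV with "NA" for missing values.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .treeutil import parse_newick, to_newick

NA = "NA"
EVALUE_CUTOFF = 1e-5


class MissingFileError(FileNotFoundError):
    """A required file role is absent from a species directory."""

    def __init__(self, role: str, path: Path):
        self.role = role
        super().__init__(f"missing {role} file: {path}")


class ValidationError(ValueError):
    """Cross-file consistency violation (e.g. strain-id mismatch)."""


class FrameError(ValidationError):
    """Alignment length is not a multiple of 3."""


class Lifestyle(str, enum.Enum):
    FREE_LIVING = "free_living"
    COMMENSAL = "commensal"
    OBLIGATE_PATHOGEN = "obligate_pathogen"
    PLANT_PATHOGEN = "plant_pathogen"
    OBLIGATE_INTRACELLULAR = "obligate_intracellular"
    UNKNOWN = "unknown"


@dataclass
class SpeciesMetadata:
    lifestyle: Lifestyle = Lifestyle.UNKNOWN
    min_doubling_time: Optional[float] = None
    mutation_rate: Optional[float] = None

    def __post_init__(self):
        if self.mutation_rate is not None:
            if not (math.isfinite(self.mutation_rate) and self.mutation_rate > 0):
                raise ValidationError(
                    f"mutation_rate must be finite and positive, got {self.mutation_rate}"
                )
        if self.min_doubling_time is not None and self.min_doubling_time <= 0:
            raise ValidationError("min_doubling_time must be positive")


@dataclass
class HitRecord:
    query_gene: str
    strain_id: str
    protein_id: str
    e_value: float
    rank: int


@dataclass
class HitTable:
    """Best-hit records of universal proteins; e-values above 1e-5 rejected."""

    records: list[HitRecord] = field(default_factory=list)

    def __post_init__(self):
        for r in self.records:
            if r.e_value > EVALUE_CUTOFF:
                raise ValidationError(
                    f"hit {r.query_gene}/{r.protein_id} e-value {r.e_value} > {EVALUE_CUTOFF}"
                )


@dataclass
class GeneFamilyMatrix:
    strain_ids: list[str]
    family_ids: list[str]
    presence: np.ndarray  # binary, strains x families
    family_members: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    paralogous_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=np.int8)
        if self.presence.shape != (len(self.strain_ids), len(self.family_ids)):
            raise ValidationError("presence matrix shape does not match ids")

    def presence_fraction(self) -> np.ndarray:
        return self.presence.mean(axis=0)


@dataclass
class SpeciesDataset:
    species_id: str
    strain_ids: list[str]
    universal_alignment: dict[str, str]
    core_alignment: dict[str, str]
    strain_tree: dendropy.Tree
    family_matrix: GeneFamilyMatrix
    metadata: SpeciesMetadata
    hits: Optional[HitTable] = None


def read_fasta_alignment(path: Path) -> dict[str, str]:
    """Uppercased id -> sequence map; enforces rectangular, in-frame rows."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValidationError(f"no sequences in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        raise ValidationError(f"ragged alignment in {path}: lengths {sorted(lengths)}")
    (length,) = lengths
    if length % 3:
        raise FrameError(f"alignment length {length} in {path} is not a multiple of 3")
    return seqs


def write_fasta(seqs: dict[str, str], path: Path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_newick(path: Path) -> dendropy.Tree:
    """Read one Newick tree; multifurcations preserved, leaf names unique."""
    text = Path(path).read_text().strip()
    if not text:
        raise ValidationError(f"empty tree file {path}")
    return parse_newick(text)


def write_newick(tree: dendropy.Tree, path: Path) -> None:
    Path(path).write_text(to_newick(tree) + "\n")


def read_presence_matrix(path: Path) -> GeneFamilyMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    presence = (df.values > 0).astype(np.int8)
    return GeneFamilyMatrix(
        strain_ids=[str(i) for i in df.index],
        family_ids=[str(c) for c in df.columns],
        presence=presence,
    )


def write_presence_matrix(matrix: GeneFamilyMatrix, path: Path) -> None:
    df = pd.DataFrame(
        matrix.presence, index=matrix.strain_ids, columns=matrix.family_ids
    )
    df.to_csv(path, sep="\t", index_label="strain_id")


def read_metadata(path: Path) -> tuple[str, SpeciesMetadata]:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        kv[key.strip()] = value.strip()
    species_id = kv.get("species_id", "")
    if not species_id:
        raise ValidationError(f"metadata {path} lacks species_id")

    def opt_float(key: str) -> Optional[float]:
        v = kv.get(key, NA)
        return None if v in ("", NA) else float(v)

    meta = SpeciesMetadata(
        lifestyle=Lifestyle(kv.get("lifestyle", "unknown")),
        min_doubling_time=opt_float("min_doubling_time"),
        mutation_rate=opt_float("mutation_rate"),
    )
    return species_id, meta


def write_metadata(species_id: str, meta: SpeciesMetadata, path: Path) -> None:
    lines = [
        f"species_id: {species_id}",
        f"lifestyle: {meta.lifestyle.value}",
        f"min_doubling_time: {meta.min_doubling_time if meta.min_doubling_time is not None else NA}",
        f"mutation_rate: {meta.mutation_rate if meta.mutation_rate is not None else NA}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_hit_table(path: Path) -> HitTable:
    df = pd.read_csv(path, sep="\t")
    records = [
        HitRecord(
            query_gene=str(r.query_gene),
            strain_id=str(r.strain_id),
            protein_id=str(r.protein_id),
            e_value=float(r.e_value),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]
    return HitTable(records)


def write_hit_table(hits: HitTable, path: Path) -> None:
    df = pd.DataFrame(
        [
            (r.query_gene, r.strain_id, r.protein_id, r.e_value, r.rank)
            for r in hits.records
        ],
        columns=["query_gene", "strain_id", "protein_id", "e_value", "rank"],
    )
    df.to_csv(path, sep="\t", index=False)


_FILE_ROLES = {
    "universal_alignment": "universal.aln.fasta",
    "core_alignment": "core.aln.fasta",
    "tree": "tree.nwk",
    "family_matrix": "families.tsv",
    "metadata": "metadata.txt",
}


def load_species_dataset(directory: Path) -> SpeciesDataset:
    """Load and cross-validate one species directory.

    Raises :class:`MissingFileError` (per file role), :class:`FrameError`,
    or :class:`ValidationError` naming any strain ids that do not line up
    between the tree, the alignments, and the family matrix.
    """
    directory = Path(directory)
    paths = {}
    for role, name in _FILE_ROLES.items():
        p = directory / name
        if not p.exists():
            raise MissingFileError(role, p)
        paths[role] = p

    universal = read_fasta_alignment(paths["universal_alignment"])
    core = read_fasta_alignment(paths["core_alignment"])
    tree = read_newick(paths["tree"])
    matrix = read_presence_matrix(paths["family_matrix"])
    species_id, meta = read_metadata(paths["metadata"])

    strain_ids = sorted(universal)
    strain_set = set(strain_ids)
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    for name, ids in (
        ("tree", tree_leaves),
        ("core alignment", set(core)),
        ("family matrix", set(matrix.strain_ids)),
    ):
        extra = sorted(ids - strain_set)
        missing = sorted(strain_set - ids)
        if extra or missing:
            raise ValidationError(
                f"strain-id mismatch between universal alignment and {name}: "
                f"unknown={extra} absent={missing}"
            )

    hits_path = directory / "hits.tsv"
    hits = read_hit_table(hits_path) if hits_path.exists() else None
    return SpeciesDataset(
        species_id=species_id,
        strain_ids=strain_ids,
        universal_alignment=universal,
        core_alignment=core,
        strain_tree=tree,
        family_matrix=matrix,
        metadata=meta,
        hits=hits,
    )


def write_results_table(records: list[dict], path: Path) -> None:
    """Per-species results as TSV; None -> "NA"; full-precision floats."""
    if not records:
        raise ValueError("no records to write")
    df = pd.DataFrame.from_records(records)
    df.to_csv(path, sep="\t", index=False, na_rep=NA, float_format="%.17g")


def read_results_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA])
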