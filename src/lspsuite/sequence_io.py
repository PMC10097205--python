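"""Reading, validating and writing protein sequences and annotation tables.

All tabular inputs are plain TSV with a header row; FASTA follows the usual
multi-line convention with ``>`` headers.  Signal-peptide cleavage positions
are 1-based inclusive: residues ``1..sp_cleavage_pos`` are the signal
peptide, so the mature protein starts at ``sp_cleavage_pos + 1``.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


class Modification(str, enum.Enum):
    """Provenance flag recording how a sequence was altered before training."""

    INTACT = "intact"
    SP_REMOVED = "sp_removed"
    SP_REMOVED_MET_RESTORED = "sp_removed_met_restored"
    PREFIX_REMOVED = "prefix_removed"
    DUPLICATED_COPY = "duplicated_copy"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein isoform: identifier, parent gene and validated sequence."""

    id: str
    sequence: str
    gene_id: str = ""
    modified: Modification = Modification.INTACT

    def __len__(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str, modified: Modification) -> "ProteinRecord":
        return replace(self, sequence=sequence, modified=modified)


@dataclass(frozen=True)
class IsoformAnnotation:
    """Per-isoform secretory features plus the secretome-observation flag.

    ``sp_cleavage_pos`` is present iff ``has_sp`` and gives the 1-based
    index of the last signal-peptide residue.
    """

    protein_id: str
    gene_id: str
    has_sp: bool
    sp_cleavage_pos: int | None
    tmd_count: int
    has_gpi: bool
    observed: bool

    def __post_init__(self) -> None:
        if self.has_sp and self.sp_cleavage_pos is None:
            raise ValueError(
                f"{self.protein_id}: has_sp is true but sp_cleavage_pos is missing"
            )
        if not self.has_sp and self.sp_cleavage_pos is not None:
            raise ValueError(
                f"{self.protein_id}: sp_cleavage_pos given but has_sp is false"
            )
        if self.sp_cleavage_pos is not None and self.sp_cleavage_pos < 1:
            raise ValueError(f"{self.protein_id}: sp_cleavage_pos must be >= 1")
        if self.tmd_count < 0:
            raise ValueError(f"{self.protein_id}: tmd_count must be >= 0")


def validate_sequence(raw: str, policy: str = "drop") -> str:
    """Normalise a raw amino-acid sequence to the canonical 20-letter alphabet.

    Uppercases, strips whitespace and a single trailing ``*`` stop.
    Non-canonical residues (X, B, Z, U, O, ...) are handled per *policy*:
    ``"drop"`` removes them with a warning, ``"reject"`` raises.
    Feature formulas are defined over the canonical alphabet only, which is
    why dropped residues are preferable to propagating undefined symbols.
    """
    if policy not in ("drop", "reject"):
        raise ValueError(f"unknown policy {policy!r}")
    seq = "".join(raw.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    bad = [c for c in seq if c not in _CANONICAL_SET]
    if bad:
        if policy == "reject":
            raise ValueError(
                f"sequence contains non-canonical residues {sorted(set(bad))}"
            )
        warnings.warn(
            f"dropping {len(bad)} non-canonical residue(s) {sorted(set(bad))}",
            stacklevel=2,
        )
        seq = "".join(c for c in seq if c in _CANONICAL_SET)
    if not seq:
        raise ValueError("sequence empty after validation")
    return seq


def read_fasta(
    path: str | Path, policy: str = "drop", gene_id_func=None
) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Record ids are the first whitespace-delimited header token and must be
    unique.  ``gene_id_func`` optionally derives a gene id from a protein id
    (default: strip a trailing ``.N`` isoform suffix if present).
    """
    path = Path(path)
    if gene_id_func is None:
        gene_id_func = default_gene_id
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r} in {path}")
        seen.add(entry.id)
        seq = validate_sequence(str(entry.seq), policy=policy)
        records.append(
            ProteinRecord(id=entry.id, sequence=seq, gene_id=gene_id_func(entry.id))
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def default_gene_id(protein_id: str) -> str:
    """Gene id of a protein id: strip one trailing ``.<number>`` isoform suffix."""
    stem, dot, suffix = protein_id.rpartition(".")
    if dot and suffix.isdigit():
        return stem
    return protein_id


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records as FASTA (ids only in headers, fixed line width)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n"}


def _parse_bool(value, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"row {row}: cannot parse boolean {column}={value!r}")


ANNOTATION_COLUMNS = [
    "protein_id",
    "gene_id",
    "has_sp",
    "sp_cleavage_pos",
    "tmd_count",
    "has_gpi",
    "observed",
]


def read_annotations(path: str | Path) -> list[IsoformAnnotation]:
    """Read the per-isoform secretory-feature table (TSV).

    Columns: protein_id, gene_id, has_sp, sp_cleavage_pos, tmd_count,
    has_gpi, observed.  ``sp_cleavage_pos`` may be empty or ``-`` when
    ``has_sp`` is false.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing annotation columns {missing}")
    annotations: list[IsoformAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        has_sp = _parse_bool(row.has_sp, i, "has_sp")
        pos_text = str(row.sp_cleavage_pos).strip()
        if pos_text in ("", "-", "NA", "na", "None"):
            pos: int | None = None
        else:
            pos = int(pos_text)
        if has_sp and pos is None:
            raise ValueError(f"row {i}: has_sp true but sp_cleavage_pos missing")
        try:
            annotations.append(
                IsoformAnnotation(
                    protein_id=str(row.protein_id),
                    gene_id=str(row.gene_id),
                    has_sp=has_sp,
                    sp_cleavage_pos=pos if has_sp else None,
                    tmd_count=int(row.tmd_count),
                    has_gpi=_parse_bool(row.has_gpi, i, "has_gpi"),
                    observed=_parse_bool(row.observed, i, "observed"),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return annotations


def write_annotations(annotations: Iterable[IsoformAnnotation], path: str | Path) -> None:
    rows = [
        {
            "protein_id": a.protein_id,
            "gene_id": a.gene_id,
            "has_sp": str(a.has_sp).lower(),
            "sp_cleavage_pos": "" if a.sp_cleavage_pos is None else a.sp_cleavage_pos,
            "tmd_count": a.tmd_count,
            "has_gpi": str(a.has_gpi).lower(),
            "observed": str(a.observed).lower(),
        }
        for a in annotations
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-id-per-line observation list."""
    with open(path) as handle:
        return [line.strip() for line in handle if line.strip()]


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read an undirected PPI edge list (TSV: protein_id_a, protein_id_b)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: edge list needs two columns")
    return [(str(a), str(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]


def read_assignments(path: str | Path) -> list[tuple[str, str]]:
    """Read a (protein_id, accession) assignment table (PFAM or GO), one row each."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: assignment table needs two columns")
    return [(str(p), str(acc)) for p, acc in zip(df.iloc[:, 0], df.iloc[:, 1])]


def cross_validate_inputs(
    records: Sequence[ProteinRecord], annotations: Sequence[IsoformAnnotation]
) -> None:
    """Check annotations reference known proteins and SP positions fit sequences."""
    by_id = {r.id: r for r in records}
    unknown = [a.protein_id for a in annotations if a.protein_id not in by_id]
    if unknown:
        raise ValueError(f"annotations reference unknown proteins: {unknown[:5]}")
    for a in annotations:
        if a.sp_cleavage_pos is not None and a.sp_cleavage_pos >= len(
            by_id[a.protein_id]
        ):
            raise ValueError(
                f"{a.protein_id}: sp_cleavage_pos {a.sp_cleavage_pos} >= sequence "
                f"length {len(by_id[a.protein_id])}"
            )
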