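"""Labelled training-set assembly for the classifier variants.

Six scheme presets are provided.  The LSPpred schemes train putative LSPs
(UNCLASSIFIED High + Medium confidence) against non-secreted proteins;
the SPLpred schemes emulate the "common feature" hypothesis by training
signal-peptide-removed classically secreted proteins against NONSEC data,
with four alternative sequence-modification designs whose score bias can
be compared downstream:

========  =======================================  ==============================
scheme    positives                                negatives
========  =======================================  ==============================
LSPpred1  UNCLASSIFIED High+Medium, intact         NONSEC intact
LSPpred2  UNCLASSIFIED High+Medium, intact         NONSEC + SEC + SPT intact
SPLpred1  SEC, SP removed                          NONSEC intact
SPLpred2  SEC, SP removed                          NONSEC, mean-SP-length prefix
                                                   removed
SPLpred3  SEC, SP removed, Met restored            NONSEC intact
SPLpred4  SEC, duplicated intact + SP removed      NONSEC intact
========  =======================================  ==============================

Low-confidence and remaining UNCLASSIFIED proteins are never used for
training; they are reserved as evaluation data.  Redundancy within each
class is reduced to a maximum pairwise identity (default 40 %) by greedy
longest-first clustering against a global-alignment identity measure,
before assembly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from lspsuite.features import DEFAULT_REGISTRY, FeatureRegistry, FeatureTable, extract_features
from lspsuite.lspdb import CategoryLabel, LspdbResult
from lspsuite.sequence_io import IsoformAnnotation, Modification, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_THRESHOLD = 0.40


# ---------------------------------------------------------------------------
# sequence modification


def remove_signal_peptide(
    record: ProteinRecord, sp_end: int, restore_met: bool = False
) -> ProteinRecord:
    """Strip residues 1..sp_end (the signal peptide) from a record.

    With ``restore_met`` the translation-initiating methionine is prepended
    to the mature sequence.  The output length is ``len - sp_end`` plus one
    if the methionine is restored.
    """
    if not 1 <= sp_end < len(record.sequence):
        raise ValueError(
            f"{record.id}: sp_end {sp_end} must lie in 1..{len(record.sequence) - 1}"
        )
    mature = record.sequence[sp_end:]
    if restore_met:
        return record.with_sequence("M" + mature, Modification.SP_REMOVED_MET_RESTORED)
    return record.with_sequence(mature, Modification.SP_REMOVED)


def remove_prefix(record: ProteinRecord, prefix_length: int) -> ProteinRecord:
    """Strip a fixed-length N-terminal prefix (mean-SP-length modification)."""
    if not 1 <= prefix_length < len(record.sequence):
        raise ValueError(
            f"{record.id}: prefix {prefix_length} must lie in "
            f"1..{len(record.sequence) - 1}"
        )
    return record.with_sequence(
        record.sequence[prefix_length:], Modification.PREFIX_REMOVED
    )


def mean_sp_length(annotations: Sequence[IsoformAnnotation]) -> int:
    """Mean signal-peptide length over SP-bearing annotations, half-up rounded."""
    lengths = [a.sp_cleavage_pos for a in annotations if a.has_sp]
    if not lengths:
        raise ValueError("no SP-bearing annotations to average")
    mean = sum(lengths) / len(lengths)
    return int(np.floor(mean + 0.5))


# ---------------------------------------------------------------------------
# redundancy reduction


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Fraction of identical columns over the global-alignment length."""
    if aligner is None:
        aligner = _global_aligner()
    alignment = aligner.align(a, b)[0]
    identities = alignment.counts().identities
    return identities / alignment.length


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i: i + k] for i in range(len(seq) - k + 1)}


def reduce_redundancy(
    records: Sequence[ProteinRecord],
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    prefilter: bool = True,
    kmer_size: int = 4,
    min_shared_kmers: int = 8,
) -> list[ProteinRecord]:
    """Greedy longest-first clustering; keep cluster representatives only.

    Records are visited longest first (ties broken by id); a record joins
    an existing representative when their global-alignment identity exceeds
    the threshold, otherwise it founds a new cluster.  The retained set
    therefore has no pair above the threshold.  A shared-k-mer screen skips
    alignments between sequences that cannot plausibly exceed the
    threshold (disable with ``prefilter=False`` for exact behaviour on
    small inputs).
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    aligner = _global_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    representatives: list[ProteinRecord] = []
    rep_kmers: list[set[str]] = []
    for record in ordered:
        kmers = _kmer_set(record.sequence, kmer_size) if prefilter else set()
        redundant = False
        for rep, rk in zip(representatives, rep_kmers):
            if prefilter and len(kmers & rk) < min_shared_kmers:
                continue
            if pairwise_identity(record.sequence, rep.sequence, aligner) > identity_threshold:
                redundant = True
                break
        if not redundant:
            representatives.append(record)
            rep_kmers.append(kmers)
    # restore input order among the retained records
    kept = {r.id for r in representatives}
    return [r for r in records if r.id in kept]


# ---------------------------------------------------------------------------
# schemes


@dataclass(frozen=True)
class SchemeSpec:
    """Declarative description of one classifier variant's training data."""

    name: str
    positive_source: str  # "unclassified_high_medium" or "sec"
    negative_classes: tuple[CategoryLabel, ...]
    positive_modification: str = "none"  # none | sp_removed |
    # sp_removed_met_restored | duplicated_intact_plus_sp_removed
    negative_modification: str = "none"  # none | mean_sp_prefix_removed


SCHEMES: dict[str, SchemeSpec] = {
    "LSPpred1": SchemeSpec(
        "LSPpred1", "unclassified_high_medium", (CategoryLabel.NONSEC,)
    ),
    "LSPpred2": SchemeSpec(
        "LSPpred2",
        "unclassified_high_medium",
        (CategoryLabel.NONSEC, CategoryLabel.SEC, CategoryLabel.SPT),
    ),
    "SPLpred1": SchemeSpec(
        "SPLpred1", "sec", (CategoryLabel.NONSEC,), positive_modification="sp_removed"
    ),
    "SPLpred2": SchemeSpec(
        "SPLpred2",
        "sec",
        (CategoryLabel.NONSEC,),
        positive_modification="sp_removed",
        negative_modification="mean_sp_prefix_removed",
    ),
    "SPLpred3": SchemeSpec(
        "SPLpred3",
        "sec",
        (CategoryLabel.NONSEC,),
        positive_modification="sp_removed_met_restored",
    ),
    "SPLpred4": SchemeSpec(
        "SPLpred4",
        "sec",
        (CategoryLabel.NONSEC,),
        positive_modification="duplicated_intact_plus_sp_removed",
    ),
}


@dataclass
class LabeledDataset:
    """Training records with labels, their feature table and provenance.

    ``unmodified_twins`` maps the id of every modified record back to its
    intact original so that modification bias can be estimated later.
    """

    scheme: SchemeSpec
    records: list[ProteinRecord]
    labels: np.ndarray  # 1 = positive, 0 = negative, aligned with records
    feature_table: FeatureTable
    unmodified_twins: dict[str, ProteinRecord] = field(default_factory=dict)
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    seed: int | None = None

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(len(self.labels) - self.labels.sum())


def _sp_end_of(annotations: Mapping[str, IsoformAnnotation], record: ProteinRecord) -> int:
    annotation = annotations.get(record.id)
    if annotation is None or annotation.sp_cleavage_pos is None:
        raise ValueError(f"{record.id}: no signal-peptide annotation available")
    return annotation.sp_cleavage_pos


def assemble_training_set(
    lspdb: LspdbResult,
    records: Sequence[ProteinRecord],
    annotations: Sequence[IsoformAnnotation],
    scheme: SchemeSpec | str,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    seed: int | None = None,
    reduce: bool = True,
    exclude_ids: Iterable[str] = (),
) -> LabeledDataset:
    """Build the labelled dataset for one scheme.

    All isoforms of each classified gene enter the pool, redundancy is
    reduced per class, positives/negatives are modified per the scheme,
    features are extracted after modification, and min–max scaling is
    fitted on the assembled set.  ``exclude_ids`` supports user-supplied
    curation lists (e.g. ribosomal-complex artefacts).
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    excluded = set(exclude_ids)
    by_id = {r.id: r for r in records}
    annotation_of = {a.protein_id: a for a in annotations}

    def pool(ids: Iterable[str]) -> list[ProteinRecord]:
        return [by_id[p] for p in ids if p in by_id and p not in excluded]

    if scheme.positive_source == "unclassified_high_medium":
        positive_ids = lspdb.unclassified_with_confidence("High", "Medium")
    elif scheme.positive_source == "sec":
        positive_ids = lspdb.proteins_in(CategoryLabel.SEC)
    else:
        raise ValueError(f"unknown positive source {scheme.positive_source!r}")
    positives = pool(positive_ids)
    negatives: list[ProteinRecord] = []
    for label in scheme.negative_classes:
        negatives.extend(pool(lspdb.proteins_in(label)))

    if not positives:
        raise ValueError(f"{scheme.name}: empty positive pool")
    if not negatives:
        raise ValueError(f"{scheme.name}: empty negative pool")

    if reduce:
        positives = reduce_redundancy(positives, identity_threshold)
        negatives = reduce_redundancy(negatives, identity_threshold)

    twins: dict[str, ProteinRecord] = {}

    def modified_positive(record: ProteinRecord) -> list[ProteinRecord]:
        mode = scheme.positive_modification
        if mode == "none":
            return [record]
        sp_end = _sp_end_of(annotation_of, record)
        if mode == "sp_removed":
            out = remove_signal_peptide(record, sp_end, restore_met=False)
        elif mode == "sp_removed_met_restored":
            out = remove_signal_peptide(record, sp_end, restore_met=True)
        elif mode == "duplicated_intact_plus_sp_removed":
            clipped = remove_signal_peptide(record, sp_end, restore_met=False)
            clipped = ProteinRecord(
                id=record.id + "|sp_removed",
                sequence=clipped.sequence,
                gene_id=record.gene_id,
                modified=Modification.SP_REMOVED,
            )
            twins[clipped.id] = record
            intact_copy = ProteinRecord(
                id=record.id,
                sequence=record.sequence,
                gene_id=record.gene_id,
                modified=Modification.DUPLICATED_COPY,
            )
            return [intact_copy, clipped]
        else:
            raise ValueError(f"unknown positive modification {mode!r}")
        twins[out.id] = record
        return [out]

    final_positives: list[ProteinRecord] = []
    for record in positives:
        final_positives.extend(modified_positive(record))

    if scheme.negative_modification == "mean_sp_prefix_removed":
        prefix = mean_sp_length(
            [annotation_of[p.id] for p in pool(lspdb.proteins_in(CategoryLabel.SEC))
             if p.id in annotation_of]
            or [a for a in annotations if a.has_sp]
        )
        modified_negatives = []
        for record in negatives:
            if len(record.sequence) > prefix:
                out = remove_prefix(record, prefix)
                twins[out.id] = record
                modified_negatives.append(out)
            else:
                logger.warning(
                    "%s shorter than mean SP length %d; kept intact", record.id, prefix
                )
                modified_negatives.append(record)
        negatives = modified_negatives
    elif scheme.negative_modification != "none":
        raise ValueError(
            f"unknown negative modification {scheme.negative_modification!r}"
        )

    all_records = final_positives + negatives
    labels = np.array([1] * len(final_positives) + [0] * len(negatives))
    table = extract_features(all_records, registry=registry, scale=True)
    return LabeledDataset(
        scheme=scheme,
        records=all_records,
        labels=labels,
        feature_table=table,
        unmodified_twins=twins,
        identity_threshold=identity_threshold,
        seed=seed,
    )
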