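"""LSPDB construction: gene categories and tiered LSP confidence scores.

Genes are partitioned by their isoforms' secretory features (signal
peptide, GPI anchor, transmembrane domains) and secretome observation
status into six categories:

* ``SEC`` — secretory features, observed in a secretome;
* ``SPT`` — secretory features, unobserved ("signal-peptide theory");
* ``UNCLASSIFIED`` — observed without secretory features (LSP candidates);
* ``NONSEC`` — neither features nor observation;
* ``SECRETORY_ISOFORM`` — isoforms disagree on SP/GPI possession; excluded;
* ``TM_ONLY`` — transmembrane domains are the only secretory feature; excluded.

Each UNCLASSIFIED protein is then scored against three evidence
categories — PPI-network neighbourhood, PFAM domains and GO terms — on a
1–3-point tier scale per category (highest qualifying tier only), and the
total maps to a confidence label: High (>= 5), Medium (3–4), Low (< 3).
A self-interaction (homodimer) is annotated at 0.5 points for interest but
never enters the total or changes the label.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lspsuite.sequence_io import IsoformAnnotation

#: NONSEC-partner cutoff separating network Tier 3 from Tier 2.  A
#: dataset-derived constant; other corpora will likely need retuning.
DEFAULT_NONSEC_CUTOFF = 33

#: Fraction of an accession's carriers that must lie in SEC u SPT for the
#: "predominantly in SEC, possibly in SPT" Tier-1 annotation rule.
DEFAULT_PREDOMINANCE = 0.5


class CategoryLabel(str, enum.Enum):
    SEC = "SEC"
    SPT = "SPT"
    UNCLASSIFIED = "UNCLASSIFIED"
    NONSEC = "NONSEC"
    SECRETORY_ISOFORM = "SECRETORY_ISOFORM"
    TM_ONLY = "TM_ONLY"


@dataclass(frozen=True)
class EvidenceScore:
    """Per-protein tier points, homodimer annotation and confidence label."""

    protein_id: str
    network_tier: int
    pfam_tier: int
    go_tier: int
    homodimer: bool = False

    def __post_init__(self) -> None:
        for tier in (self.network_tier, self.pfam_tier, self.go_tier):
            if tier not in (0, 1, 2, 3):
                raise ValueError(f"tier points must be in 0..3, got {tier}")

    @property
    def total(self) -> int:
        return self.network_tier + self.pfam_tier + self.go_tier

    @property
    def confidence(self) -> str:
        if self.total >= 5:
            return "High"
        if self.total >= 3:
            return "Medium"
        return "Low"

    #: Annotation value of a homodimer flag; recorded, never added to total.
    HOMODIMER_POINTS = 0.5


@dataclass(frozen=True)
class InteractionProfile:
    """Undirected PPI neighbourhood of one protein, split by partner class."""

    protein_id: str
    n_sec_partners: int = 0
    n_nonsec_partners: int = 0
    spt_partner_ids: tuple[str, ...] = ()
    self_interaction: bool = False


def classify_gene(isoforms: Sequence[IsoformAnnotation]) -> CategoryLabel:
    """Category of one gene from its isoform annotations.

    SP and GPI are the classifying secretory features; isoform disagreement
    on either routes to SECRETORY_ISOFORM, TMDs alone to TM_ONLY.  A gene
    counts as observed if any isoform is observed.
    """
    if not isoforms:
        raise ValueError("classify_gene requires at least one isoform")
    gene_ids = {a.gene_id for a in isoforms}
    if len(gene_ids) != 1:
        raise ValueError(f"isoforms span multiple genes: {sorted(gene_ids)}")

    classifying = [a.has_sp or a.has_gpi for a in isoforms]
    if any(classifying) and not all(classifying):
        return CategoryLabel.SECRETORY_ISOFORM

    has_features = all(classifying) and bool(classifying)
    has_tmd = any(a.tmd_count > 0 for a in isoforms)
    observed = any(a.observed for a in isoforms)

    if not has_features and has_tmd:
        return CategoryLabel.TM_ONLY
    if has_features:
        return CategoryLabel.SEC if observed else CategoryLabel.SPT
    return CategoryLabel.UNCLASSIFIED if observed else CategoryLabel.NONSEC


def classify_genes(
    annotations: Sequence[IsoformAnnotation],
) -> dict[str, CategoryLabel]:
    """Classify every gene appearing in the annotation table."""
    by_gene: dict[str, list[IsoformAnnotation]] = defaultdict(list)
    for annotation in annotations:
        by_gene[annotation.gene_id].append(annotation)
    return {gene: classify_gene(isoforms) for gene, isoforms in by_gene.items()}


def build_interaction_profiles(
    edges: Iterable[tuple[str, str]],
    categories: Mapping[str, CategoryLabel],
    gene_of: Mapping[str, str],
) -> dict[str, InteractionProfile]:
    """Undirected partner counts per protein, classified by partner gene class.

    Self edges set ``self_interaction`` and are excluded from partner
    counts.  Every protein in ``gene_of`` receives a profile (all-zero when
    it has no edges).
    """
    unknown = sorted(
        {p for edge in edges for p in edge if p not in gene_of}
    )
    if unknown:
        raise ValueError(f"PPI edges reference unknown proteins: {unknown[:10]}")

    n_sec: dict[str, int] = defaultdict(int)
    n_nonsec: dict[str, int] = defaultdict(int)
    spt_partners: dict[str, list[str]] = defaultdict(list)
    self_loop: set[str] = set()

    def register(protein: str, partner: str) -> None:
        label = categories.get(gene_of[partner])
        if label is CategoryLabel.SEC:
            n_sec[protein] += 1
        elif label is CategoryLabel.NONSEC:
            n_nonsec[protein] += 1
        elif label is CategoryLabel.SPT:
            spt_partners[protein].append(partner)

    for a, b in edges:
        if a == b:
            self_loop.add(a)
            continue
        register(a, b)
        register(b, a)

    return {
        protein: InteractionProfile(
            protein_id=protein,
            n_sec_partners=n_sec[protein],
            n_nonsec_partners=n_nonsec[protein],
            spt_partner_ids=tuple(spt_partners[protein]),
            self_interaction=protein in self_loop,
        )
        for protein in gene_of
    }


def network_tier(
    profile: InteractionProfile,
    all_profiles: Mapping[str, InteractionProfile],
    nonsec_cutoff: int = DEFAULT_NONSEC_CUTOFF,
) -> int:
    """Network evidence points for an UNCLASSIFIED protein.

    Tiers are tested highest first: 3 points for > 1 SEC partner with at
    most ``nonsec_cutoff`` NONSEC partners; 2 points for > 1 SEC partner
    above the cutoff; 1 point when some SPT partner's own profile shows
    > 1 SEC and 0 NONSEC partners.
    """
    if profile.n_sec_partners > 1 and profile.n_nonsec_partners <= nonsec_cutoff:
        return 3
    if profile.n_sec_partners > 1 and profile.n_nonsec_partners > nonsec_cutoff:
        return 2
    for partner in profile.spt_partner_ids:
        partner_profile = all_profiles.get(partner)
        if (
            partner_profile is not None
            and partner_profile.n_sec_partners > 1
            and partner_profile.n_nonsec_partners == 0
        ):
            return 1
    return 0


def annotation_tier(
    protein_id: str,
    assignments: Mapping[str, Sequence[str]],
    carriers: Mapping[str, Sequence[str]],
    class_of_protein: Mapping[str, CategoryLabel],
    predominance: float = DEFAULT_PREDOMINANCE,
) -> int:
    """PFAM/GO evidence points for an UNCLASSIFIED protein.

    For each accession the protein carries, its class-occupancy set over
    all carrier proteins decides the tier: 3 points if some accession
    occurs only on SEC and UNCLASSIFIED proteins; 2 points if only on SEC,
    SPT and UNCLASSIFIED; 1 point if SEC u SPT carriers reach the
    predominance fraction with at least one SEC carrier.  The single
    highest qualifying tier counts.
    """
    best = 0
    for accession in assignments.get(protein_id, ()):
        carrier_classes = [
            class_of_protein[p] for p in carriers[accession] if p in class_of_protein
        ]
        others = [
            c for p, c in zip(carriers[accession],
                              (class_of_protein.get(p) for p in carriers[accession]))
            if p != protein_id and c is not None
        ]
        class_set = set(others)
        has_sec = CategoryLabel.SEC in class_set
        if has_sec and class_set <= {CategoryLabel.SEC, CategoryLabel.UNCLASSIFIED}:
            best = max(best, 3)
            continue
        if has_sec and class_set <= {
            CategoryLabel.SEC,
            CategoryLabel.SPT,
            CategoryLabel.UNCLASSIFIED,
        }:
            best = max(best, 2)
            continue
        if carrier_classes and has_sec:
            sec_spt = sum(
                1
                for c in carrier_classes
                if c in (CategoryLabel.SEC, CategoryLabel.SPT)
            )
            if sec_spt / len(carrier_classes) >= predominance:
                best = max(best, 1)
    return best


def score_confidence(
    protein_id: str,
    network_points: int,
    pfam_points: int,
    go_points: int,
    homodimer: bool = False,
) -> EvidenceScore:
    """Combine per-category tier points into an :class:`EvidenceScore`."""
    return EvidenceScore(
        protein_id=protein_id,
        network_tier=network_points,
        pfam_tier=pfam_points,
        go_tier=go_points,
        homodimer=homodimer,
    )


@dataclass
class LspdbResult:
    """Full LSPDB output: gene categories and UNCLASSIFIED evidence scores."""

    gene_categories: dict[str, CategoryLabel]
    protein_categories: dict[str, CategoryLabel]
    scores: dict[str, EvidenceScore]
    profiles: dict[str, InteractionProfile]

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {label.value: 0 for label in CategoryLabel}
        for label in self.gene_categories.values():
            counts[label.value] += 1
        return counts

    def confidence_counts(self) -> dict[str, int]:
        counts = {"High": 0, "Medium": 0, "Low": 0}
        for score in self.scores.values():
            counts[score.confidence] += 1
        return counts

    def proteins_in(self, label: CategoryLabel) -> list[str]:
        return sorted(
            p for p, c in self.protein_categories.items() if c is label
        )

    def unclassified_with_confidence(self, *levels: str) -> list[str]:
        wanted = set(levels)
        return sorted(
            p for p, s in self.scores.items() if s.confidence in wanted
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            sorted(self.gene_categories.items()),
            columns=["gene_id", "label"],
        ).assign(label=lambda d: d["label"].map(lambda v: v.value)).to_csv(
            out_dir / "lspdb_classes.tsv", sep="\t", index=False
        )
        rows = [
            {
                "protein_id": s.protein_id,
                "network_tier": s.network_tier,
                "pfam_tier": s.pfam_tier,
                "go_tier": s.go_tier,
                "homodimer": str(s.homodimer).lower(),
                "total": s.total,
                "confidence": s.confidence,
            }
            for _, s in sorted(self.scores.items())
        ]
        pd.DataFrame(
            rows,
            columns=[
                "protein_id", "network_tier", "pfam_tier", "go_tier",
                "homodimer", "total", "confidence",
            ],
        ).to_csv(out_dir / "lspdb_scores.tsv", sep="\t", index=False)
        with open(out_dir / "summary.txt", "w") as handle:
            handle.write("Gene category counts\n")
            for label, count in self.category_counts().items():
                handle.write(f"  {label}\t{count}\n")
            handle.write("UNCLASSIFIED confidence counts\n")
            for level, count in self.confidence_counts().items():
                handle.write(f"  {level}\t{count}\n")


def _group_assignments(
    pairs: Iterable[tuple[str, str]]
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    by_protein: dict[str, list[str]] = defaultdict(list)
    by_accession: dict[str, list[str]] = defaultdict(list)
    for protein, accession in pairs:
        by_protein[protein].append(accession)
        by_accession[accession].append(protein)
    return dict(by_protein), dict(by_accession)


def build_lspdb(
    annotations: Sequence[IsoformAnnotation],
    edges: Iterable[tuple[str, str]] = (),
    pfam: Iterable[tuple[str, str]] = (),
    go: Iterable[tuple[str, str]] = (),
    observations: Iterable[str] | None = None,
    nonsec_cutoff: int = DEFAULT_NONSEC_CUTOFF,
    predominance: float = DEFAULT_PREDOMINANCE,
) -> LspdbResult:
    """Classify every gene and score every UNCLASSIFIED protein.

    ``observations`` optionally overrides the annotations' ``observed``
    flags with a gene-id list (any listed gene counts as observed).
    """
    if observations is not None:
        observed_genes = set(observations)
        annotations = [
            IsoformAnnotation(
                protein_id=a.protein_id,
                gene_id=a.gene_id,
                has_sp=a.has_sp,
                sp_cleavage_pos=a.sp_cleavage_pos,
                tmd_count=a.tmd_count,
                has_gpi=a.has_gpi,
                observed=a.gene_id in observed_genes,
            )
            for a in annotations
        ]

    gene_categories = classify_genes(annotations)
    gene_of = {a.protein_id: a.gene_id for a in annotations}
    protein_categories = {
        protein: gene_categories[gene] for protein, gene in gene_of.items()
    }

    profiles = build_interaction_profiles(list(edges), gene_categories, gene_of)
    pfam_of, pfam_carriers = _group_assignments(pfam)
    go_of, go_carriers = _group_assignments(go)

    scores: dict[str, EvidenceScore] = {}
    for protein, label in protein_categories.items():
        if label is not CategoryLabel.UNCLASSIFIED:
            continue
        profile = profiles[protein]
        scores[protein] = score_confidence(
            protein,
            network_points=network_tier(profile, profiles, nonsec_cutoff),
            pfam_points=annotation_tier(
                protein, pfam_of, pfam_carriers, protein_categories, predominance
            ),
            go_points=annotation_tier(
                protein, go_of, go_carriers, protein_categories, predominance
            ),
            homodimer=profile.self_interaction,
        )

    return LspdbResult(
        gene_categories=gene_categories,
        protein_categories=protein_categories,
        scores=scores,
        profiles=profiles,
    )
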