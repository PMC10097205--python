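"""Synthetic proteome fixtures with consistent annotation tables.

The generator emulates the statistical structure the suite assumes:

* background sequences drawn i.i.d. from Swiss-Prot-like average residue
  frequencies (shipped as a data file), lengths ~ truncated normal;
* classically secreted sequences (SEC/SPT) carry a planted N-terminal
  signal peptide with textbook architecture — initiator methionine, a
  short K/R-enriched n-region, a hydrophobic h-region, and a c-region
  ending in an A-X-A cleavage motif;
* LSP-like sequences (the UNCLASSIFIED positive class) are background
  sequences with a configurable compositional shift, by default glycine
  up-weighted by +0.10, giving a learnable but non-trivial signal;
* PPI / PFAM / GO tables are wired so that configured numbers of
  UNCLASSIFIED proteins satisfy each evidence tier exactly, with the
  ground truth emitted alongside so every test is self-checking.

The generator does not attempt realistic PPI topology or a GO hierarchy;
it produces exactly the evidence patterns the tier rules inspect.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from lspsuite.lspdb import EvidenceScore
from lspsuite.sequence_io import (
    CANONICAL_RESIDUES,
    IsoformAnnotation,
    ProteinRecord,
    write_annotations,
    write_fasta,
)

HYDROPHOBIC_SET = "AILFVMW"


def load_background_frequencies() -> dict[str, float]:
    """Swiss-Prot-like average residue frequencies, normalised to sum 1."""
    source = importlib.resources.files("lspsuite").joinpath(
        "data/background_freqs.tsv"
    )
    with importlib.resources.as_file(source) as path:
        table = pd.read_csv(path, sep="\t")
    frequencies = dict(zip(table["residue"], table["frequency"].astype(float)))
    total = sum(frequencies.values())
    return {r: f / total for r, f in frequencies.items()}


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters for one synthetic fixture."""

    n_sec: int = 20
    n_spt: int = 15
    n_unclassified: int = 24
    n_nonsec: int = 80
    n_secretory_isoform: int = 2
    n_tm_only: int = 2

    length_mean: float = 300.0
    length_sd: float = 80.0
    length_min: int = 50

    # signal-peptide architecture
    sp_n_region: tuple[int, int] = (2, 5)
    sp_h_region: tuple[int, int] = (7, 15)
    sp_c_region: tuple[int, int] = (3, 7)
    sp_kr_enrichment: float = 0.6

    # LSP-like compositional shift
    lsp_shift_residues: str = "G"
    lsp_shift_delta: float = 0.10
    #: give SEC/SPT mature regions the same compositional shift as the
    #: LSP-like class, encoding the "common feature" hypothesis (mature
    #: chains of classical secretory proteins resemble LSPs) so that the
    #: SP-removal training schemes have signal to learn on fixtures
    sec_mature_shifted: bool = True

    # evidence wiring: how many UNCLASSIFIED proteins get each tier
    n_net_tier3: int = 3
    n_net_tier2: int = 2
    n_net_tier1: int = 2
    n_pfam_tier3: int = 2
    n_pfam_tier2: int = 1
    n_pfam_tier1: int = 1
    n_go_tier3: int = 2
    n_go_tier2: int = 2
    n_go_tier1: int = 2
    n_high_combo: int = 2  # network Tier 3 + GO Tier 2 => total 5, High
    n_homodimer_only: int = 2
    nonsec_cutoff: int = 33

    observation_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lsp_shift_delta < 0:
            raise ValueError("lsp_shift_delta must be >= 0")
        planned = (
            self.n_net_tier3 + self.n_net_tier2 + self.n_net_tier1
            + self.n_pfam_tier3 + self.n_pfam_tier2 + self.n_pfam_tier1
            + self.n_go_tier3 + self.n_go_tier2 + self.n_go_tier1
            + self.n_high_combo + self.n_homodimer_only
        )
        if planned > self.n_unclassified:
            raise ValueError(
                f"evidence plan needs {planned} UNCLASSIFIED proteins but only "
                f"{self.n_unclassified} are generated"
            )
        if self.n_net_tier2 and self.n_nonsec <= self.nonsec_cutoff:
            raise ValueError(
                "network Tier 2 wiring needs more NONSEC proteins than the cutoff"
            )


def _sample_length(config: SynthConfig, rng: np.random.Generator) -> int:
    length = rng.normal(config.length_mean, config.length_sd)
    return max(config.length_min, int(round(length)))


def _frequencies_array(frequencies: dict[str, float]) -> np.ndarray:
    return np.array([frequencies[r] for r in CANONICAL_RESIDUES])


def _sample_sequence(
    n_residues: int, probabilities: np.ndarray, rng: np.random.Generator
) -> str:
    codes = rng.choice(20, size=n_residues, p=probabilities)
    return "".join(CANONICAL_RESIDUES[c] for c in codes)


def sample_background(
    n: int,
    config: SynthConfig,
    rng: np.random.Generator,
    prefix: str = "BG",
    frequencies: dict[str, float] | None = None,
) -> list[ProteinRecord]:
    """i.i.d. background sequences; ids ``{prefix}{i:04d}.1``.

    Sequences start with the initiator methionine, as translated proteins
    do; the remaining residues are i.i.d. from the configured frequencies.
    """
    if frequencies is None:
        frequencies = load_background_frequencies()
    p = _frequencies_array(frequencies)
    records = []
    for i in range(n):
        seq = "M" + _sample_sequence(_sample_length(config, rng) - 1, p, rng)
        gene = f"{prefix}{i:04d}"
        records.append(ProteinRecord(id=f"{gene}.1", sequence=seq, gene_id=gene))
    return records


def shifted_frequencies(config: SynthConfig) -> dict[str, float]:
    """Background frequencies with the LSP shift applied and renormalised."""
    frequencies = load_background_frequencies()
    targets = set(config.lsp_shift_residues)
    delta_each = config.lsp_shift_delta / max(len(targets), 1)
    shifted = {
        r: f + (delta_each if r in targets else 0.0) for r, f in frequencies.items()
    }
    total = sum(shifted.values())
    result = {r: f / total for r, f in shifted.items()}
    if any(f <= 0 for f in result.values()):
        raise ValueError("shift produces invalid residue frequencies")
    return result


def sample_lsp_like(
    n: int, config: SynthConfig, rng: np.random.Generator, prefix: str = "LSP"
) -> list[ProteinRecord]:
    """Background-like sequences with the configured compositional shift."""
    return sample_background(
        n, config, rng, prefix=prefix, frequencies=shifted_frequencies(config)
    )


def plant_signal_peptide(
    record: ProteinRecord, config: SynthConfig, rng: np.random.Generator
) -> tuple[ProteinRecord, int]:
    """Prepend M + n-region + h-region + c-region; return the 1-based SP end."""
    background = load_background_frequencies()
    p = _frequencies_array(background)

    n_len = int(rng.integers(config.sp_n_region[0], config.sp_n_region[1] + 1))
    n_region = "".join(
        rng.choice(["K", "R"])
        if rng.random() < config.sp_kr_enrichment
        else _sample_sequence(1, p, rng)
        for _ in range(n_len)
    )
    h_len = int(rng.integers(config.sp_h_region[0], config.sp_h_region[1] + 1))
    h_region = "".join(
        HYDROPHOBIC_SET[c] for c in rng.integers(0, len(HYDROPHOBIC_SET), size=h_len)
    )
    c_len = int(rng.integers(config.sp_c_region[0], config.sp_c_region[1] + 1))
    body = _sample_sequence(max(c_len - 3, 0), p, rng)
    c_region = body + "A" + _sample_sequence(1, p, rng) + "A"

    sp = "M" + n_region + h_region + c_region
    return record.with_sequence(sp + record.sequence, record.modified), len(sp)


@dataclass
class SyntheticFixture:
    """A generated proteome with all annotation tables and ground truth."""

    config: SynthConfig
    records: list[ProteinRecord]
    annotations: list[IsoformAnnotation]
    edges: list[tuple[str, str]]
    pfam: list[tuple[str, str]]
    go: list[tuple[str, str]]
    true_class: dict[str, str]  # gene_id -> generated category
    true_scores: dict[str, EvidenceScore]  # UNCLASSIFIED protein -> expected

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out_dir / "proteome.fasta")
        write_annotations(self.annotations, out_dir / "annotations.tsv")
        pd.DataFrame(self.edges, columns=["protein_id_a", "protein_id_b"]).to_csv(
            out_dir / "ppi.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.pfam, columns=["protein_id", "accession"]).to_csv(
            out_dir / "pfam.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.go, columns=["protein_id", "accession"]).to_csv(
            out_dir / "go.tsv", sep="\t", index=False
        )
        truth_rows = []
        for gene, label in sorted(self.true_class.items()):
            truth_rows.append({"id": gene, "kind": "gene_class", "value": label})
        for protein, score in sorted(self.true_scores.items()):
            truth_rows.append(
                {
                    "id": protein,
                    "kind": "confidence",
                    "value": (
                        f"{score.network_tier},{score.pfam_tier},{score.go_tier},"
                        f"{score.confidence}"
                    ),
                }
            )
        pd.DataFrame(truth_rows).to_csv(
            out_dir / "ground_truth.tsv", sep="\t", index=False
        )


def generate_fixture(config: SynthConfig) -> SyntheticFixture:
    """Generate a full fixture: sequences, annotations, PPI/PFAM/GO, truth."""
    rng = np.random.default_rng(config.seed)

    sample_mature = sample_lsp_like if config.sec_mature_shifted else sample_background
    sec = sample_mature(config.n_sec, config, rng, prefix="SEC")
    spt = sample_mature(config.n_spt, config, rng, prefix="SPT")
    unclassified = sample_lsp_like(config.n_unclassified, config, rng, prefix="UNC")
    nonsec = sample_background(config.n_nonsec, config, rng, prefix="NSC")

    sp_end: dict[str, int] = {}
    planted_sec: list[ProteinRecord] = []
    for record in sec + spt:
        planted, end = plant_signal_peptide(record, config, rng)
        planted_sec.append(planted)
        sp_end[record.id] = end
    sec = planted_sec[: config.n_sec]
    spt = planted_sec[config.n_sec:]

    annotations: list[IsoformAnnotation] = []
    true_class: dict[str, str] = {}
    records: list[ProteinRecord] = []

    def flip(observed: bool) -> bool:
        if config.observation_noise and rng.random() < config.observation_noise:
            return not observed
        return observed

    for record, observed, label, has_sp in (
        [(r, True, "SEC", True) for r in sec]
        + [(r, False, "SPT", True) for r in spt]
        + [(r, True, "UNCLASSIFIED", False) for r in unclassified]
        + [(r, False, "NONSEC", False) for r in nonsec]
    ):
        records.append(record)
        true_class[record.gene_id] = label
        annotations.append(
            IsoformAnnotation(
                protein_id=record.id,
                gene_id=record.gene_id,
                has_sp=has_sp,
                sp_cleavage_pos=sp_end.get(record.id),
                tmd_count=0,
                has_gpi=False,
                observed=flip(observed),
            )
        )

    # excluded categories: isoform-disagreement genes and TM-only genes
    background = load_background_frequencies()
    p = _frequencies_array(background)
    for i in range(config.n_secretory_isoform):
        gene = f"ISO{i:04d}"
        base = "M" + _sample_sequence(_sample_length(config, rng) - 1, p, rng)
        with_sp, end = plant_signal_peptide(
            ProteinRecord(id=f"{gene}.1", sequence=base, gene_id=gene), config, rng
        )
        records.append(with_sp)
        records.append(ProteinRecord(id=f"{gene}.2", sequence=base, gene_id=gene))
        true_class[gene] = "SECRETORY_ISOFORM"
        annotations.append(
            IsoformAnnotation(
                protein_id=f"{gene}.1", gene_id=gene, has_sp=True,
                sp_cleavage_pos=end, tmd_count=0, has_gpi=False, observed=False,
            )
        )
        annotations.append(
            IsoformAnnotation(
                protein_id=f"{gene}.2", gene_id=gene, has_sp=False,
                sp_cleavage_pos=None, tmd_count=0, has_gpi=False, observed=False,
            )
        )
    for i in range(config.n_tm_only):
        gene = f"TMO{i:04d}"
        seq = "M" + _sample_sequence(_sample_length(config, rng) - 1, p, rng)
        records.append(ProteinRecord(id=f"{gene}.1", sequence=seq, gene_id=gene))
        true_class[gene] = "TM_ONLY"
        annotations.append(
            IsoformAnnotation(
                protein_id=f"{gene}.1", gene_id=gene, has_sp=False,
                sp_cleavage_pos=None, tmd_count=int(rng.integers(1, 5)),
                has_gpi=False, observed=bool(rng.random() < 0.5),
            )
        )

    # --- evidence wiring -------------------------------------------------
    edges: list[tuple[str, str]] = []
    pfam: list[tuple[str, str]] = []
    go: list[tuple[str, str]] = []
    true_scores: dict[str, EvidenceScore] = {}

    sec_ids = [r.id for r in sec]
    spt_ids = [r.id for r in spt]
    nonsec_ids = [r.id for r in nonsec]
    queue = [r.id for r in unclassified]

    def pop(n: int) -> list[str]:
        out = queue[:n]
        del queue[:n]
        return out

    def record_score(protein: str, net: int = 0, pf: int = 0, g: int = 0,
                     homodimer: bool = False) -> None:
        true_scores[protein] = EvidenceScore(
            protein_id=protein, network_tier=net, pfam_tier=pf, go_tier=g,
            homodimer=homodimer,
        )

    accession_counter = 0

    def fresh(kind: str) -> str:
        nonlocal accession_counter
        accession_counter += 1
        return f"{kind}{accession_counter:05d}"

    def wire_network_tier3(protein: str) -> None:
        edges.append((protein, sec_ids[0]))
        edges.append((protein, sec_ids[1]))

    def wire_go_tier2(protein: str, table: list[tuple[str, str]]) -> None:
        accession = fresh("ACC")
        table.extend(
            [(protein, accession), (sec_ids[0], accession), (spt_ids[0], accession)]
        )

    for protein in pop(config.n_net_tier3):
        wire_network_tier3(protein)
        record_score(protein, net=3)
    for protein in pop(config.n_net_tier2):
        wire_network_tier3(protein)
        for partner in nonsec_ids[: config.nonsec_cutoff + 1]:
            edges.append((protein, partner))
        record_score(protein, net=2)
    for index, protein in enumerate(pop(config.n_net_tier1)):
        # SPT partner whose own profile is >1 SEC, 0 NONSEC
        partner = spt_ids[-(index + 1)]
        edges.append((protein, partner))
        edges.append((partner, sec_ids[2]))
        edges.append((partner, sec_ids[3]))
        record_score(protein, net=1)
    for protein in pop(config.n_pfam_tier3):
        accession = fresh("PF")
        pfam.extend([(protein, accession), (sec_ids[0], accession)])
        record_score(protein, pf=3)
    for protein in pop(config.n_pfam_tier2):
        wire_go_tier2(protein, pfam)
        record_score(protein, pf=2)
    for protein in pop(config.n_pfam_tier1):
        accession = fresh("PF")
        pfam.extend(
            [
                (protein, accession),
                (sec_ids[0], accession),
                (spt_ids[0], accession),
                (nonsec_ids[0], accession),
            ]
        )
        record_score(protein, pf=1)
    for protein in pop(config.n_go_tier3):
        accession = fresh("GO")
        go.extend([(protein, accession), (sec_ids[0], accession)])
        record_score(protein, g=3)
    for protein in pop(config.n_go_tier2):
        wire_go_tier2(protein, go)
        record_score(protein, g=2)
    for protein in pop(config.n_go_tier1):
        accession = fresh("GO")
        go.extend(
            [
                (protein, accession),
                (sec_ids[0], accession),
                (spt_ids[0], accession),
                (nonsec_ids[0], accession),
            ]
        )
        record_score(protein, g=1)
    for protein in pop(config.n_high_combo):
        wire_network_tier3(protein)
        wire_go_tier2(protein, go)
        record_score(protein, net=3, g=2)
    for protein in pop(config.n_homodimer_only):
        edges.append((protein, protein))
        record_score(protein, homodimer=True)
    for protein in queue:  # remaining UNCLASSIFIED: no evidence, Low
        record_score(protein)

    return SyntheticFixture(
        config=config,
        records=records,
        annotations=annotations,
        edges=edges,
        pfam=pfam,
        go=go,
        true_class=true_class,
        true_scores=true_scores,
    )


def make_benchmark(
    n_positive: int = 60,
    n_negative: int = 600,
    seed: int = 0,
    config: SynthConfig | None = None,
) -> tuple[list[ProteinRecord], np.ndarray]:
    """Flat two-class benchmark: LSP-like positives vs background negatives.

    Used for learnability and FPR-calibration simulations; returns records
    and a 0/1 label array.
    """
    if config is None:
        config = SynthConfig(seed=seed)
    else:
        config = replace(config, seed=seed)
    rng = np.random.default_rng(seed)
    positives = sample_lsp_like(n_positive, config, rng, prefix="POS")
    negatives = sample_background(n_negative, config, rng, prefix="NEG")
    records = positives + negatives
    labels = np.array([1] * n_positive + [0] * n_negative)
    return records, labels
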