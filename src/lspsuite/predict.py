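"""Applying trained bundles to new sequences and forming the consensus.

A score at or above the bundle's FPR-calibrated threshold is a
high-confidence positive; a score at or above 0.5 is a low-confidence
(majority) positive.  The LSPpred/SPLpred consensus combines the two
modules' calls at each confidence level, by default requiring agreement
(AND); an OR mode is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from lspsuite.sequence_io import ProteinRecord
from lspsuite.training import ModelBundle

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PredictionFragment:
    """One module's score and calls for one protein."""

    protein_id: str
    score: float
    high: bool
    low: bool


@dataclass(frozen=True)
class PredictionRow:
    """Combined LSPpred + SPLpred calls with the consensus."""

    protein_id: str
    lsppred_score: float
    splpred_score: float
    lsppred_high: bool
    lsppred_low: bool
    splpred_high: bool
    splpred_low: bool
    consensus_high: bool
    consensus_low: bool


def predict(
    bundle: ModelBundle, records: Sequence[ProteinRecord]
) -> list[PredictionFragment]:
    """Score records with one bundle; equality at a threshold is positive."""
    usable = [r for r in records if len(r.sequence) >= 1]
    skipped = len(records) - len(usable)
    if skipped:
        logger.warning("skipped %d record(s) with empty sequences", skipped)
    scores = bundle.score_records(usable)
    return [
        PredictionFragment(
            protein_id=record.id,
            score=float(score),
            high=bool(score >= bundle.threshold_high),
            low=bool(score >= bundle.threshold_low),
        )
        for record, score in zip(usable, scores)
    ]


def consensus(
    lsp: PredictionFragment, spl: PredictionFragment, mode: str = "and"
) -> PredictionRow:
    """Combine an LSPpred and an SPLpred fragment for the same protein."""
    if lsp.protein_id != spl.protein_id:
        raise ValueError(
            f"consensus id mismatch: {lsp.protein_id!r} vs {spl.protein_id!r}"
        )
    if mode == "and":
        high = lsp.high and spl.high
        low = lsp.low and spl.low
    elif mode == "or":
        high = lsp.high or spl.high
        low = lsp.low or spl.low
    else:
        raise ValueError(f"unknown consensus mode {mode!r}")
    return PredictionRow(
        protein_id=lsp.protein_id,
        lsppred_score=lsp.score,
        splpred_score=spl.score,
        lsppred_high=lsp.high,
        lsppred_low=lsp.low,
        splpred_high=spl.high,
        splpred_low=spl.low,
        consensus_high=high,
        consensus_low=low,
    )


def predict_table(
    lsppred_bundle: ModelBundle,
    splpred_bundle: ModelBundle,
    records: Sequence[ProteinRecord],
    mode: str = "and",
) -> pd.DataFrame:
    """Full prediction table for a record set (deterministic formatting)."""
    lsp_fragments = {f.protein_id: f for f in predict(lsppred_bundle, records)}
    spl_fragments = {f.protein_id: f for f in predict(splpred_bundle, records)}
    rows = []
    for record in records:
        if record.id not in lsp_fragments or record.id not in spl_fragments:
            continue
        row = consensus(lsp_fragments[record.id], spl_fragments[record.id], mode)
        rows.append(
            {
                "protein_id": row.protein_id,
                "lsppred_score": f"{row.lsppred_score:.6f}",
                "splpred_score": f"{row.splpred_score:.6f}",
                "lsppred_high": str(row.lsppred_high).lower(),
                "lsppred_low": str(row.lsppred_low).lower(),
                "splpred_high": str(row.splpred_high).lower(),
                "splpred_low": str(row.splpred_low).lower(),
                "consensus_high": str(row.consensus_high).lower(),
                "consensus_low": str(row.consensus_low).lower(),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "lsppred_score", "splpred_score",
            "lsppred_high", "lsppred_low", "splpred_high", "splpred_low",
            "consensus_high", "consensus_low",
        ],
    )
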