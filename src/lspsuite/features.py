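"""Fixed-length numeric feature vectors for protein sequences.

The registry implements the classic sequence-feature families used for
secretory-protein classification: global physico-chemical properties
(length, molecular weight, isoelectric point, GRAVY), amino-acid
composition, per-residue Shannon entropy terms, compressed-alphabet
compositions, composition–transition–distribution (CTD) encodings on
three-state property alphabets, windowed hydropathy summaries, Moran
autocorrelation of the hydropathy series, terminal features (initiator
methionine, N-/C-terminal hydropathy), and counts of post-translational
modification motifs (the N-glycosylation sequon N-X-[S/T], X != P).

Feature membership is versioned: two tables produced by the same registry
version have identical column sets in identical order.  All features are
finite for every valid sequence of length >= 1; degenerate inputs (single
residues, constant sequences) fall back to documented conventions rather
than NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from lspsuite.scales import (
    CTD_ALPHABETS,
    EMBOSS_PKA,
    KYTE_DOOLITTLE,
    RESIDUE_MASS,
    WATER_MASS,
    PropertyScale,
    group_map,
)
from lspsuite.sequence_io import CANONICAL_RESIDUES, ProteinRecord

_RESIDUE_INDEX = {r: i for i, r in enumerate(CANONICAL_RESIDUES)}


def _encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_RESIDUE_INDEX[c] for c in seq), dtype=np.int64, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc} in sequence") from exc


def _scale_array(scale: PropertyScale) -> np.ndarray:
    return np.array([scale[r] for r in CANONICAL_RESIDUES])


# ---------------------------------------------------------------------------
# elementary feature operations


def aa_composition(seq: str) -> np.ndarray:
    """Frequencies of the 20 canonical residues (sums to 1)."""
    codes = _encode(seq)
    counts = np.bincount(codes, minlength=20).astype(float)
    return counts / len(seq)


def residue_entropy(seq: str) -> np.ndarray:
    """Per-residue-type Shannon terms ``-p log2 p`` (0 where p = 0).

    The sum over the 20 terms is the sequence's residue-composition entropy
    in bits; individual terms expose features such as the glycine entropy.
    """
    p = aa_composition(seq)
    terms = np.zeros(20)
    nonzero = p > 0
    terms[nonzero] = -p[nonzero] * np.log2(p[nonzero])
    return terms


def gravy(seq: str, scale: PropertyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathy: mean residue scale value."""
    return float(_scale_array(scale)[_encode(seq)].mean())


def molecular_weight(seq: str) -> float:
    """Average-isotope peptide mass in daltons."""
    return float(sum(RESIDUE_MASS[c] for c in seq) + WATER_MASS)


def net_charge(seq: str, ph: float, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """Henderson–Hasselbalch net charge of the peptide at the given pH."""
    positive = {"K", "R", "H"}
    charge = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for residue in seq:
        if residue in positive:
            charge += 1.0 / (1.0 + 10 ** (ph - pka[residue]))
        elif residue in ("D", "E", "C", "Y"):
            charge -= 1.0 / (1.0 + 10 ** (pka[residue] - ph))
    return charge


def isoelectric_point(seq: str, pka: Mapping[str, float] = EMBOSS_PKA) -> float:
    """pH at which the net charge is zero, found by root bisection."""
    counts = {r: seq.count(r) for r in "KRHDECY"}
    arr = _encode(seq)  # validates

    def f(ph: float) -> float:
        positive = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
        positive += counts["K"] / (1.0 + 10 ** (ph - pka["K"]))
        positive += counts["R"] / (1.0 + 10 ** (ph - pka["R"]))
        positive += counts["H"] / (1.0 + 10 ** (ph - pka["H"]))
        negative = 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
        negative += counts["D"] / (1.0 + 10 ** (pka["D"] - ph))
        negative += counts["E"] / (1.0 + 10 ** (pka["E"] - ph))
        negative += counts["C"] / (1.0 + 10 ** (pka["C"] - ph))
        negative += counts["Y"] / (1.0 + 10 ** (pka["Y"] - ph))
        return positive - negative

    return float(brentq(f, 0.0, 14.0, xtol=1e-6))


def physchem_summary(seq: str) -> dict[str, float]:
    """Length, molecular weight (Da) and isoelectric point (pH units)."""
    return {
        "length": float(len(seq)),
        "molecular_weight": molecular_weight(seq),
        "isoelectric_point": isoelectric_point(seq),
    }


def reduced_alphabet_composition(seq: str, alphabet: tuple[str, ...]) -> np.ndarray:
    """Group frequencies under a compressed residue alphabet (sums to 1)."""
    mapping = group_map(alphabet)
    lookup = np.array([mapping[r] for r in CANONICAL_RESIDUES])
    groups = lookup[_encode(seq)]
    counts = np.bincount(groups, minlength=len(alphabet)).astype(float)
    return counts / len(seq)


def ctd_features(seq: str, alphabet: tuple[str, str, str]) -> np.ndarray:
    """Composition–transition–distribution encoding on a 3-group alphabet.

    Returns 21 values: 3 group frequencies, 3 adjacent-pair transition
    frequencies (unordered pairs 0-1, 0-2, 1-2, normalised by ``n - 1``),
    and for each group the fractional positions (position / n) of its
    first, 25 %, 50 %, 75 % and last occurrence (0 for absent groups).
    Sequences of length 1 have all transitions 0.
    """
    if len(alphabet) != 3:
        raise ValueError("CTD requires a 3-group alphabet")
    mapping = group_map(alphabet)
    lookup = np.array([mapping[r] for r in CANONICAL_RESIDUES])
    groups = lookup[_encode(seq)]
    n = len(groups)

    composition = np.bincount(groups, minlength=3).astype(float) / n

    transitions = np.zeros(3)
    if n >= 2:
        a, b = groups[:-1], groups[1:]
        differ = a != b
        pair = np.minimum(a, b)[differ] + np.maximum(a, b)[differ]  # 1, 2, 3
        counts = np.bincount(pair, minlength=4).astype(float)
        transitions = counts[1:4] / (n - 1)

    distribution = np.zeros(15)
    for g in range(3):
        positions = np.flatnonzero(groups == g) + 1  # 1-based
        if positions.size:
            k = positions.size
            quartile_idx = [0,
                            max(0, math.ceil(0.25 * k) - 1),
                            max(0, math.ceil(0.50 * k) - 1),
                            max(0, math.ceil(0.75 * k) - 1),
                            k - 1]
            distribution[g * 5: g * 5 + 5] = positions[quartile_idx] / n
    return np.concatenate([composition, transitions, distribution])


def windowed_property(
    seq: str, scale: PropertyScale = KYTE_DOOLITTLE, window: int = 11
) -> dict[str, float]:
    """Max, min and mean of sliding-window means of a residue property.

    When the sequence is shorter than the window the whole-sequence mean is
    the sole window, so all three summaries coincide.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    series = _scale_array(scale)[_encode(seq)]
    if len(series) < window:
        value = float(series.mean())
        return {"max": value, "min": value, "mean": value}
    cumulative = np.concatenate([[0.0], np.cumsum(series)])
    sums = cumulative[window:] - cumulative[:-window]
    means = sums / window
    return {"max": float(means.max()), "min": float(means.min()), "mean": float(means.mean())}


def autocorrelation(seq: str, scale: PropertyScale, lag: int) -> float:
    """Moran autocorrelation of the residue property series at a given lag.

    ``I(d) = [ (1/(n-d)) * sum_{i=1}^{n-d} (x_i - xbar)(x_{i+d} - xbar) ]
    / [ (1/n) * sum_{i=1}^{n} (x_i - xbar)^2 ]`` where ``xbar`` is the
    series mean.  A zero-variance series returns 0 by convention so that
    every feature stays finite.
    """
    series = _scale_array(scale)[_encode(seq)]
    n = len(series)
    if not 1 <= lag < n:
        raise ValueError(f"lag must satisfy 1 <= lag < sequence length ({n})")
    centred = series - series.mean()
    denominator = float((centred**2).mean())
    if denominator == 0.0:
        return 0.0
    numerator = float((centred[:-lag] * centred[lag:]).mean())
    return numerator / denominator


#: PTM motifs counted by :func:`ptm_motif_counts`, as (name, predicate on a
#: window) pairs.  The N-glycosylation sequon is N-X-[S/T] with X != P.
def _count_sequons(seq: str) -> int:
    count = 0
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T"):
            count += 1
    return count


def ptm_motif_counts(seq: str) -> dict[str, int]:
    """Counts of PTM sequence motifs (currently the N-glycosylation sequon)."""
    return {"n_glyc_sequon": _count_sequons(seq)}


# ---------------------------------------------------------------------------
# registry and table


@dataclass(frozen=True)
class FeatureRegistry:
    """Versioned definition of the full feature vector.

    The column order is fixed by construction; changing any membership
    parameter changes the registry and therefore the table layout.
    """

    hydropathy: PropertyScale = KYTE_DOOLITTLE
    window_sizes: tuple[int, ...] = (5, 11, 21)
    autocorrelation_lags: tuple[int, ...] = (1, 2, 3, 4)
    ctd_alphabets: tuple[str, ...] = tuple(CTD_ALPHABETS)
    terminal_width: int = 20
    version: str = "1"

    def feature_names(self) -> list[str]:
        names = ["length", "molecular_weight", "isoelectric_point", "gravy"]
        names += [f"comp_{r}" for r in CANONICAL_RESIDUES]
        names += [f"entropy_{r}" for r in CANONICAL_RESIDUES]
        names += ["entropy_total"]
        for alphabet_name in self.ctd_alphabets:
            for g in range(3):
                names.append(f"reduced_{alphabet_name}_g{g + 1}")
        for alphabet_name in self.ctd_alphabets:
            prefix = f"ctd_{alphabet_name}"
            names += [f"{prefix}_comp_g{g + 1}" for g in range(3)]
            names += [f"{prefix}_trans_{p}" for p in ("g1g2", "g1g3", "g2g3")]
            for g in range(3):
                names += [
                    f"{prefix}_dist_g{g + 1}_{q}"
                    for q in ("first", "q25", "q50", "q75", "last")
                ]
        for window in self.window_sizes:
            names += [f"hydropathy_w{window}_{s}" for s in ("max", "min", "mean")]
        names += [f"hydropathy_moran_lag{lag}" for lag in self.autocorrelation_lags]
        names += ["nterm_is_met", "nterm_gravy", "cterm_gravy"]
        names += ["n_glyc_sequon"]
        return names

    def feature_families(self) -> list[tuple[str, str]]:
        """(feature_name, family) pairs for the registry export."""
        pairs: list[tuple[str, str]] = []
        for name in self.feature_names():
            if name in ("length", "molecular_weight", "isoelectric_point", "gravy"):
                family = "physchem"
            elif name.startswith("comp_"):
                family = "aa_composition"
            elif name.startswith("entropy"):
                family = "entropy"
            elif name.startswith("reduced_"):
                family = "reduced_alphabet"
            elif name.startswith("ctd_"):
                family = "ctd"
            elif "moran" in name:
                family = "autocorrelation"
            elif name.startswith(("nterm", "cterm")):
                family = "terminal"
            elif name.startswith("hydropathy_w"):
                family = "windowed_property"
            else:
                family = "ptm_motif"
            pairs.append((name, family))
        return pairs

    def n_features(self) -> int:
        return len(self.feature_names())

    def vector(self, seq: str) -> np.ndarray:
        """Feature vector for one validated sequence."""
        parts: list[np.ndarray] = []
        summary = physchem_summary(seq)
        parts.append(
            np.array(
                [
                    summary["length"],
                    summary["molecular_weight"],
                    summary["isoelectric_point"],
                    gravy(seq, self.hydropathy),
                ]
            )
        )
        parts.append(aa_composition(seq))
        entropy = residue_entropy(seq)
        parts.append(entropy)
        parts.append(np.array([entropy.sum()]))
        for alphabet_name in self.ctd_alphabets:
            parts.append(
                reduced_alphabet_composition(seq, CTD_ALPHABETS[alphabet_name])
            )
        for alphabet_name in self.ctd_alphabets:
            parts.append(ctd_features(seq, CTD_ALPHABETS[alphabet_name]))
        for window in self.window_sizes:
            summary = windowed_property(seq, self.hydropathy, window)
            parts.append(np.array([summary["max"], summary["min"], summary["mean"]]))
        lag_values = []
        for lag in self.autocorrelation_lags:
            lag_values.append(
                autocorrelation(seq, self.hydropathy, lag) if lag < len(seq) else 0.0
            )
        parts.append(np.array(lag_values))
        # terminal features: initiator methionine and end-anchored hydropathy
        parts.append(
            np.array(
                [
                    1.0 if seq[0] == "M" else 0.0,
                    gravy(seq[: self.terminal_width], self.hydropathy),
                    gravy(seq[-self.terminal_width:], self.hydropathy),
                ]
            )
        )
        parts.append(np.array([float(_count_sequons(seq))]))
        return np.concatenate(parts)

    def export(self, path) -> None:
        """Write the registry as a TSV of (feature_name, family, version)."""
        rows = [
            {"feature_name": name, "family": family, "registry_version": self.version}
            for name, family in self.feature_families()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


DEFAULT_REGISTRY = FeatureRegistry()


@dataclass
class FeatureTable:
    """Protein-by-feature matrix with optional min–max scaling parameters.

    ``scaling`` holds per-feature (min, range) fitted on the table the
    scaling was derived from; it is ``None`` for unscaled tables.
    """

    frame: pd.DataFrame
    scaling: pd.DataFrame | None = None

    @property
    def row_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    def fit_scaling(self) -> "FeatureTable":
        """Min–max scale each column to [0, 1], fitting on this table."""
        minimum = self.frame.min(axis=0)
        span = (self.frame.max(axis=0) - minimum).replace(0.0, 1.0)
        scaled = (self.frame - minimum) / span
        params = pd.DataFrame({"min": minimum, "range": span})
        return FeatureTable(frame=scaled, scaling=params)

    def apply_scaling(self, params: pd.DataFrame) -> "FeatureTable":
        """Apply previously fitted scaling parameters unchanged (no refit)."""
        scaled = (self.frame - params["min"]) / params["range"]
        return FeatureTable(frame=scaled, scaling=params)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.frame.columns]
        if missing:
            raise KeyError(f"features absent from table: {missing[:5]}")
        scaling = self.scaling.loc[list(features)] if self.scaling is not None else None
        return FeatureTable(frame=self.frame[list(features)], scaling=scaling)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="protein_id")


def extract_features(
    records: Sequence[ProteinRecord],
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    scale: bool = False,
) -> FeatureTable:
    """Build the feature table for a set of validated records.

    Deterministic: identical inputs give identical tables, and permuting
    the record order permutes rows only.  With ``scale=True`` min–max
    scaling is fitted on this set (use :meth:`FeatureTable.apply_scaling`
    to transfer training-set scaling to new data without leakage).
    """
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in feature extraction input")
    matrix = np.vstack([registry.vector(r.sequence) for r in records])
    frame = pd.DataFrame(matrix, index=ids, columns=registry.feature_names())
    if frame.isna().any().any():
        raise AssertionError("feature table contains missing values")
    table = FeatureTable(frame=frame)
    return table.fit_scaling() if scale else table
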