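import itertools

import numpy as np
import pytest

from lspsuite.datasets import (
    SCHEMES,
    assemble_training_set,
    mean_sp_length,
    pairwise_identity,
    reduce_redundancy,
    remove_prefix,
    remove_signal_peptide,
)
from lspsuite.lspdb import build_lspdb
from lspsuite.sequence_io import IsoformAnnotation, Modification, ProteinRecord


def sp_annotation(protein, gene, pos):
    return IsoformAnnotation(protein, gene, True, pos, 0, False, True)


class TestModifications:
    RECORD = ProteinRecord(id="p", sequence="MKKLLLLSAADEF", gene_id="g")

    def test_sp_removal_length_arithmetic(self):
        out = remove_signal_peptide(self.RECORD, 7, restore_met=False)
        assert out.sequence == "SAADEF" and len(out) == 13 - 7
        assert out.modified is Modification.SP_REMOVED

    def test_met_restoration(self):
        out = remove_signal_peptide(self.RECORD, 7, restore_met=True)
        assert out.sequence == "MSAADEF" and len(out) == 7
        assert out.modified is Modification.SP_REMOVED_MET_RESTORED

    def test_sp_end_at_length_is_error(self):
        with pytest.raises(ValueError):
            remove_signal_peptide(self.RECORD, len(self.RECORD.sequence))

    def test_prefix_removal(self):
        out = remove_prefix(self.RECORD, 3)
        assert out.sequence == self.RECORD.sequence[3:]
        assert out.modified is Modification.PREFIX_REMOVED

    @pytest.mark.parametrize("sp_end,restore", [(1, False), (5, True), (12, False)])
    def test_length_invariant(self, sp_end, restore):
        out = remove_signal_peptide(self.RECORD, sp_end, restore)
        assert len(out) == len(self.RECORD) - sp_end + (1 if restore else 0)


class TestMeanSpLength:
    def test_simple_mean(self):
        anns = [sp_annotation("a", "g1", 20), sp_annotation("b", "g2", 24)]
        assert mean_sp_length(anns) == 22

    def test_singleton(self):
        assert mean_sp_length([sp_annotation("a", "g", 21)]) == 21

    def test_half_up_rounding(self):
        anns = [sp_annotation("a", "g1", 20), sp_annotation("b", "g2", 21)]
        assert mean_sp_length(anns) == 21

    def test_no_sp_error(self):
        with pytest.raises(ValueError):
            mean_sp_length([IsoformAnnotation("a", "g", False, None, 0, False, False)])


def brute_force_greedy(records, threshold):
    """Independent all-pairs oracle: greedy longest-first clustering."""
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps = []
    for record in ordered:
        if all(
            pairwise_identity(record.sequence, rep.sequence) <= threshold
            for rep in reps
        ):
            reps.append(record)
    return {r.id for r in reps}


class TestRedundancyReduction:
    def test_identical_pair_collapses(self):
        records = [
            ProteinRecord("a", "MKVDEFILWW" * 4),
            ProteinRecord("b", "MKVDEFILWW" * 4),
        ]
        assert len(reduce_redundancy(records, 0.4)) == 1

    def test_dissimilar_pair_retained(self):
        rng = np.random.default_rng(0)
        residues = "ACDEFGHIKLMNPQRSTVWY"
        records = [
            ProteinRecord(c, "".join(rng.choice(list(residues), 60)))
            for c in ("a", "b")
        ]
        assert len(reduce_redundancy(records, 0.4)) == 2

    def test_matches_all_pairs_oracle_on_clustered_fixture(self):
        rng = np.random.default_rng(3)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        base1 = "".join(rng.choice(residues, 80))
        base2 = "".join(rng.choice(residues, 70))

        def mutate(seq, n_mutations):
            chars = list(seq)
            for pos in rng.choice(len(chars), n_mutations, replace=False):
                chars[pos] = str(rng.choice(residues))
            return "".join(chars)

        records = [
            ProteinRecord("c1a", base1),
            ProteinRecord("c1b", mutate(base1, 8)),
            ProteinRecord("c1c", mutate(base1, 12)),
            ProteinRecord("c2a", base2),
            ProteinRecord("c2b", mutate(base2, 10)),
        ]
        kept = {r.id for r in reduce_redundancy(records, 0.4, prefilter=False)}
        assert kept == brute_force_greedy(records, 0.4)
        assert kept == {"c1a", "c2a"}

    def test_retained_pairs_below_threshold(self):
        rng = np.random.default_rng(9)
        residues = list("ACDEFGHIKLMNPQRSTVWY")
        records = [
            ProteinRecord(f"r{i}", "".join(rng.choice(residues, 50 + i)))
            for i in range(12)
        ]
        kept = reduce_redundancy(records, 0.4, prefilter=False)
        for a, b in itertools.combinations(kept, 2):
            assert pairwise_identity(a.sequence, b.sequence) <= 0.4


@pytest.fixture(scope="module")
def lspdb_setup(fixture_proteome):
    fx = fixture_proteome
    result = build_lspdb(fx.annotations, fx.edges, fx.pfam, fx.go)
    return fx, result


class TestAssembleTrainingSet:
    def test_lsppred1_pools(self, lspdb_setup):
        fx, result = lspdb_setup
        dataset = assemble_training_set(
            result, fx.records, fx.annotations, "LSPpred1", reduce=False
        )
        high_medium = set(result.unclassified_with_confidence("High", "Medium"))
        positives = {r.id for r, l in zip(dataset.records, dataset.labels) if l == 1}
        assert positives == high_medium
        assert dataset.n_negative <= sum(
            1 for c in result.protein_categories.values() if c.value == "NONSEC"
        )

    def test_low_confidence_never_trained(self, lspdb_setup):
        fx, result = lspdb_setup
        low = set(result.unclassified_with_confidence("Low"))
        for scheme in ("LSPpred1", "LSPpred2"):
            dataset = assemble_training_set(
                result, fx.records, fx.annotations, scheme, reduce=False
            )
            assert not low & {r.id for r in dataset.records}

    def test_lsppred2_negatives_include_sec_and_spt(self, lspdb_setup):
        fx, result = lspdb_setup
        dataset = assemble_training_set(
            result, fx.records, fx.annotations, "LSPpred2", reduce=False
        )
        negative_ids = {r.id for r, l in zip(dataset.records, dataset.labels) if l == 0}
        assert any(pid.startswith("SEC") for pid in negative_ids)
        assert any(pid.startswith("SPT") for pid in negative_ids)

    def test_splpred1_positives_are_sp_removed(self, lspdb_setup):
        fx, result = lspdb_setup
        dataset = assemble_training_set(
            result, fx.records, fx.annotations, "SPLpred1", reduce=False
        )
        sp_end = {a.protein_id: a.sp_cleavage_pos for a in fx.annotations if a.has_sp}
        originals = {r.id: r for r in fx.records}
        for record, label in zip(dataset.records, dataset.labels):
            if label == 1:
                assert record.modified is Modification.SP_REMOVED
                assert len(record) == len(originals[record.id]) - sp_end[record.id]
                twin = dataset.unmodified_twins[record.id]
                assert twin.sequence == originals[record.id].sequence

    def test_splpred3_restores_methionine(self, lspdb_setup):
        fx, result = lspdb_setup
        dataset = assemble_training_set(
            result, fx.records, fx.annotations, "SPLpred3", reduce=False
        )
        for record, label in zip(dataset.records, dataset.labels):
            if label == 1:
                assert record.sequence.startswith("M")
                assert record.modified is Modification.SP_REMOVED_MET_RESTORED

    def test_splpred4_duplicates_positives_only(self, lspdb_setup):
        fx, result = lspdb_setup
        plain = assemble_training_set(
            result, fx.records, fx.annotations, "SPLpred1", reduce=False
        )
        doubled = assemble_training_set(
            result, fx.records, fx.annotations, "SPLpred4", reduce=False
        )
        assert doubled.n_positive == 2 * plain.n_positive
        assert doubled.n_negative == plain.n_negative

    def test_splpred2_negatives_prefix_removed(self, lspdb_setup):
        fx, result = lspdb_setup
        dataset = assemble_training_set(
            result, fx.records, fx.annotations, "SPLpred2", reduce=False
        )
        originals = {r.id: r for r in fx.records}
        shortened = [
            (record, originals[record.id])
            for record, label in zip(dataset.records, dataset.labels)
            if label == 0 and record.modified is Modification.PREFIX_REMOVED
        ]
        assert shortened
        deltas = {len(orig) - len(rec) for rec, orig in shortened}
        assert len(deltas) == 1  # every negative lost the same mean-SP prefix

    def test_deterministic_under_fixed_inputs(self, lspdb_setup):
        fx, result = lspdb_setup
        first = assemble_training_set(
            result, fx.records, fx.annotations, "LSPpred1", seed=5, reduce=False
        )
        second = assemble_training_set(
            result, fx.records, fx.annotations, "LSPpred1", seed=5, reduce=False
        )
        assert [r.id for r in first.records] == [r.id for r in second.records]
        assert np.allclose(first.feature_table.values, second.feature_table.values)

    def test_all_schemes_resolve(self, lspdb_setup):
        fx, result = lspdb_setup
        for name in SCHEMES:
            dataset = assemble_training_set(
                result, fx.records, fx.annotations, name, reduce=False
            )
            assert dataset.n_positive > 0 and dataset.n_negative > 0
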