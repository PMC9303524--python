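"""Diagnostic-residue scanner and start-codon conservation."""

import pytest
from hypothesis import given, settings, strategies as st

from paralogon import (
    AlignmentBlock,
    ValidationError,
    methionine_conservation,
    scan_diagnostics,
    simulate_alignment_block,
)
from paralogon import datasets


class TestScanDiagnostics:
    def test_identical_sequences_have_no_diagnostics(self):
        seqs = {f"s{i}": "ACDEFGHIK" for i in range(6)}
        labels = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        assert scan_diagnostics(AlignmentBlock("flat", seqs, labels)) == []

    def test_gap_never_counts_as_diagnostic(self):
        seqs = {"a1": "A-DE", "a2": "A-DE", "b1": "AKDE", "b2": "AKDE"}
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        found = scan_diagnostics(AlignmentBlock("g", seqs, labels), allowed_exceptions=0)
        # column 2 distinguishes B (K) from A (gap only); only B may report it
        assert all(d.residues != frozenset({"-"}) for d in found)
        assert {(d.subfamily, d.column) for d in found} == {("B", 2)}

    def test_gap_majority_columns_skipped(self):
        seqs = {"a1": "A-E", "a2": "A-E", "b1": "A-E", "b2": "AKE"}
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        found = scan_diagnostics(AlignmentBlock("g", seqs, labels), allowed_exceptions=1)
        assert all(d.column != 2 for d in found)

    def test_single_divergent_member_tolerated_by_default(self):
        seqs = {"a1": "W", "a2": "W", "a3": "F", "b1": "A", "b2": "A"}
        labels = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        found = scan_diagnostics(AlignmentBlock("d", seqs, labels), max_set=1)
        by_key = {(d.subfamily, d.column): d for d in found}
        assert by_key[("A", 1)].residues == frozenset({"W"})
        assert by_key[("A", 1)].support == pytest.approx(2 / 3)
        # with only two groups the complement column is diagnostic too
        assert by_key[("B", 1)].residues == frozenset({"A"})

    def test_empty_subfamily_rejected(self):
        seqs = {"a1": "AA", "a2": "AA", "b1": "AA"}
        labels = {"a1": "A", "a2": "A", "b1": "B"}
        with pytest.raises(ValidationError):
            scan_diagnostics(AlignmentBlock("x", seqs, labels))

    def test_tightening_thresholds_never_adds_diagnostics(self):
        block = simulate_alignment_block(
            {"A": 5, "B": 5, "C": 4}, width=30,
            planted=[("A", 3, ["W"]), ("B", 11, ["K", "R"])], noise_rate=0.08, seed=21,
        )
        loose = scan_diagnostics(block, max_set=2, allowed_exceptions=1)
        tight_set = scan_diagnostics(block, max_set=1, allowed_exceptions=1)
        tight_exc = scan_diagnostics(block, max_set=2, allowed_exceptions=0)
        loose_keys = {(d.subfamily, d.column) for d in loose}
        assert {(d.subfamily, d.column) for d in tight_set} <= loose_keys
        assert {(d.subfamily, d.column) for d in tight_exc} <= loose_keys

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_order_permutation_invariance(self, seed):
        import numpy as np

        block = simulate_alignment_block(
            {"A": 4, "B": 4, "C": 3}, width=20,
            planted=[("A", 5, ["W"])], noise_rate=0.1, seed=seed,
        )
        rng = np.random.default_rng(seed)
        order = list(block.sequences)
        rng.shuffle(order)
        shuffled = AlignmentBlock(
            block.name,
            {s: block.sequences[s] for s in order},
            {s: block.subfamily[s] for s in order},
        )
        original = {(d.subfamily, d.column, d.residues) for d in scan_diagnostics(block)}
        permuted = {(d.subfamily, d.column, d.residues) for d in scan_diagnostics(shuffled)}
        assert original == permuted

    @pytest.mark.parametrize("seed", range(25))
    def test_noise_free_precision_and_recall_are_perfect(self, seed):
        planted = [("A", 4, ["W"]), ("B", 9, ["K", "R"]), ("C", 14, ["D"])]
        block = simulate_alignment_block(
            {"A": 5, "B": 6, "C": 5}, width=20, planted=planted, noise_rate=0.0, seed=seed
        )
        found = {(d.subfamily, d.column): d.residues for d in scan_diagnostics(block)}
        assert found == {(s, c): frozenset(r) for s, c, r in planted}


class TestHmgBlock:
    def test_documented_diagnostics_recovered(self, hmg_block):
        found = {(d.subfamily, d.column): d.residues for d in scan_diagnostics(hmg_block)}
        assert found == dict(datasets.HMG_EXPECTED_DIAGNOSTICS)

    def test_tcf7l2_has_no_diagnostic_column(self, hmg_block):
        assert all(d.subfamily != "TCF7L2" for d in scan_diagnostics(hmg_block))

    def test_cyclostome_residue_mixture(self):
        block = datasets.hmg_box_block(include_cyclostomes=True)
        col22 = block.column(22)
        col64 = block.column(64)
        assert all(col22[s] == "I" for s in block.members("TCFb"))
        assert all(col64[s] == "S" for s in block.members("TCFb"))
        # TCFc is the most divergent: nine substitutions against the consensus
        consensus = block.column(1)  # any TCF7L2 sequence equals the consensus
        ref = block.sequences[block.members("TCF7L2")[0]]
        tcfc = block.sequences[block.members("TCFc")[0]]
        assert sum(1 for a, b in zip(ref, tcfc) if a != b) == 9


class TestMethionineConservation:
    def test_all_m_column(self):
        seqs = {"a1": "AMA", "a2": "CMC", "b1": "DMD", "b2": "EME"}
        labels = {k: k[0].upper() for k in seqs}
        report = methionine_conservation(AlignmentBlock("m", seqs, labels), 2)
        assert report.conservation == 1.0

    def test_half_planted_fraction(self):
        seqs = {"a1": "MA", "a2": "MA", "b1": "KA", "b2": "KA"}
        labels = {k: k[0].upper() for k in seqs}
        report = methionine_conservation(AlignmentBlock("m", seqs, labels), 1)
        assert report.conservation == 0.5
        assert report.per_subfamily == {"A": 1.0, "B": 0.0}

    def test_out_of_range_column_rejected(self, hmg_block):
        with pytest.raises(ValidationError):
            methionine_conservation(hmg_block, 66)

    def test_exon3_block_pattern(self):
        report = methionine_conservation(datasets.exon3_block(), 33)
        per = report.per_subfamily
        for subfamily in ("TCF7", "LEF1", "TCF7L1", "TCF7L2", "TCFa", "TCFb", "TCFc"):
            assert per[subfamily] == 1.0
        assert per["TCFd"] == 0.0
        assert per["Invertebrate"] == 0.0
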