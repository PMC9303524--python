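"""Feature extraction and ancestral-state reconstruction."""

import numpy as np
import pytest

from paralogon import (
    FeatureMatrix,
    ParalogTree,
    ValidationError,
    extract_features,
    fitch_reconstruct,
    scenario_report,
)
from paralogon import datasets
from paralogon.ancestry import ABSENT, AMBIGUOUS, PRESENT, UNKNOWN, dollo_states

from conftest import oracle_parsimony, random_tree


def _matrix_one_char(states: dict, name: str = "X") -> FeatureMatrix:
    return FeatureMatrix(tuple(states), (name,), {(t, name): s for t, s in states.items()})


class TestExtractFeatures:
    def test_tcf7l1_character_states(self, gene_models):
        matrix = extract_features(gene_models)
        get = lambda c: matrix.state("TCF7L1", c)
        assert get("EXON_IV") == PRESENT
        assert get("LVPQ") == PRESENT
        assert get("SXXSS") == PRESENT
        assert get("DELTA_N_ISOFORM") == ABSENT
        assert get("C_CLAMP") == ABSENT
        assert get("ALT_SPLICE_EXON_VII") == ABSENT

    def test_invertebrate_tcf_is_clamp_bearing_but_motif_poor(self, gene_models):
        matrix = extract_features(gene_models)
        get = lambda c: matrix.state("UrochordateTCF", c)
        assert get("C_CLAMP") == PRESENT
        assert get("LVPQ") == ABSENT
        assert get("EXON_IV") == ABSENT
        assert get("EXON_X_XI_INTRON") == PRESENT

    def test_fused_hmg_nls_exon_means_no_x_xi_intron(self, gene_models):
        matrix = extract_features(gene_models)
        assert matrix.state("AmbulacrariaTCF", "EXON_X_XI_INTRON") == ABSENT

    def test_partial_cyclostome_models_yield_unknowns(self, gene_models):
        matrix = extract_features(gene_models)
        assert matrix.state("TCFc", "EXON_IV") == UNKNOWN
        assert matrix.state("TCFd", "CTBP") == UNKNOWN

    def test_empty_model_list_gives_empty_matrix(self):
        matrix = extract_features([])
        assert matrix.taxa == ()
        assert matrix.characters == ()


class TestFitchWorkedExamples:
    def test_single_gain_on_one_clade_stem(self):
        tree = ParalogTree.from_newick("((TCF7,LEF1)cl1,(TCF7L1,TCF7L2)cl2,outgroup)root;")
        matrix = _matrix_one_char(
            {"TCF7": ABSENT, "LEF1": ABSENT, "TCF7L1": PRESENT, "TCF7L2": PRESENT, "outgroup": ABSENT}
        )
        recon = fitch_reconstruct(matrix, tree)
        assert recon.node_states["root"]["X"] == ABSENT
        assert recon.node_states["cl2"]["X"] == PRESENT
        assert recon.scores["X"] == 1
        assert recon.events == [("X", "root", "cl2", "gain")]

    def test_root_present_with_two_independent_losses(self):
        tree = ParalogTree.from_newick("((TCF7,LEF1)cl1,(TCF7L1,TCF7L2)cl2,outgroup)root;")
        matrix = _matrix_one_char(
            {"TCF7": PRESENT, "LEF1": ABSENT, "TCF7L1": ABSENT, "TCF7L2": PRESENT, "outgroup": PRESENT}
        )
        recon = fitch_reconstruct(matrix, tree)
        assert recon.node_states["root"]["X"] == PRESENT
        assert recon.scores["X"] == 2
        assert sorted(e[3] for e in recon.events) == ["loss", "loss"]

    def test_constant_character_has_no_events(self):
        tree = ParalogTree.from_newick("((a,b),(c,d));")
        matrix = _matrix_one_char({t: PRESENT for t in "abcd"})
        recon = fitch_reconstruct(matrix, tree)
        assert recon.scores["X"] == 0
        assert recon.events == []
        assert all(v == PRESENT for v in recon.node_states["node0"].values())

    def test_missing_taxon_rejected(self):
        tree = ParalogTree.from_newick("((a,b),c);")
        matrix = _matrix_one_char({"a": PRESENT, "b": ABSENT, "z": ABSENT})
        with pytest.raises(ValidationError):
            fitch_reconstruct(matrix, tree)


class TestFitchAgainstBruteForce:
    @pytest.mark.parametrize("seed", range(60))
    def test_score_and_mpr_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        tree = random_tree(rng, n)
        choices = [PRESENT, ABSENT, PRESENT, ABSENT, UNKNOWN]
        states = {f"t{i + 1}": choices[int(rng.integers(5))] for i in range(n)}
        matrix = _matrix_one_char(states)
        recon = fitch_reconstruct(matrix, tree)
        score, mpr = oracle_parsimony(tree, states)
        assert recon.scores["X"] == score
        for node, state_set in mpr.items():
            expected = AMBIGUOUS if len(state_set) == 2 else (PRESENT if 1 in state_set else ABSENT)
            assert recon.node_states[node]["X"] == expected, f"node {node}"

    @pytest.mark.parametrize("seed", range(10))
    def test_leaf_order_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        states = {f"t{i + 1}": (PRESENT if rng.random() < 0.5 else ABSENT) for i in range(5)}
        labels = list(states)
        t1 = ParalogTree.from_newick(f"(({labels[0]},{labels[1]})n1,({labels[2]},{labels[3]})n2,{labels[4]})r;")
        t2 = ParalogTree.from_newick(f"(({labels[1]},{labels[0]})n1,({labels[3]},{labels[2]})n2,{labels[4]})r;")
        m = _matrix_one_char(states)
        r1 = fitch_reconstruct(m, t1)
        r2 = fitch_reconstruct(m, t2)
        assert r1.scores == r2.scores
        assert r1.node_states["r"] == r2.node_states["r"]


class TestScenarioReport:
    def test_event_count_equals_summed_parsimony_score(self, feature_matrix, paralog_tree):
        gnathostome = feature_matrix
        taxa = [t for t in gnathostome.taxa if t not in datasets.CYCLOSTOME_TAXA]
        states = {(t, c): gnathostome.states[(t, c)] for t in taxa for c in gnathostome.characters}
        matrix = FeatureMatrix(tuple(taxa), gnathostome.characters, states)
        recon = fitch_reconstruct(matrix, paralog_tree)
        report = scenario_report(recon, paralog_tree)
        assert len(report.events) == sum(recon.scores.values())

    def test_zero_event_characters_absent_from_narrative(self):
        tree = ParalogTree.from_newick("((a,b),(c,d));")
        matrix = _matrix_one_char({t: PRESENT for t in "abcd"})
        recon = fitch_reconstruct(matrix, tree)
        report = scenario_report(recon, tree)
        assert report.events.empty
        assert "X" not in report.events.get("character", [])

    def test_ambiguous_states_are_question_marked(self):
        tree = ParalogTree.from_newick("((a,b)n1,(c,d)n2)r;")
        matrix = _matrix_one_char({"a": PRESENT, "b": ABSENT, "c": PRESENT, "d": ABSENT})
        recon = fitch_reconstruct(matrix, tree)
        report = scenario_report(recon, tree)
        assert not report.ambiguous.empty
        assert "uncertain (?)" in report.narrative()


class TestDollo:
    def test_gain_at_mrca_of_present_leaves(self):
        tree = ParalogTree.from_newick("((a,b)n1,(c,d)n2)r;")
        states = dollo_states(tree, {"a": PRESENT, "b": ABSENT, "c": PRESENT, "d": ABSENT})
        assert states["r"] == PRESENT  # single gain above the MRCA of a and c
        assert states["n1"] == PRESENT and states["n2"] == PRESENT

    def test_no_present_leaves_all_absent(self):
        tree = ParalogTree.from_newick("((a,b),(c,d));")
        states = dollo_states(tree, {t: ABSENT for t in "abcd"})
        assert set(states.values()) == {ABSENT}

    def test_clade_restricted_character_stays_out_of_root(self):
        tree = ParalogTree.from_newick("((a,b)n1,(c,d)n2)r;")
        states = dollo_states(tree, {"a": PRESENT, "b": PRESENT, "c": ABSENT, "d": ABSENT})
        assert states["n1"] == PRESENT
        assert states["r"] == ABSENT
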