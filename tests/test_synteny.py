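"""Neighborhood definition, classification and contingency construction."""

import pytest

from paralogon import (
    ContingencyTable2x2,
    GeneLocus,
    LinkageGroup,
    OrthologTable,
    ValidationError,
    build_contingency,
    classify_query,
    define_neighborhoods,
    shared_flank_orthology,
)
from paralogon.synteny import OTHER, SHARED
from paralogon.simulate import (
    WgdSimConfig,
    reference_anchor_loci,
    simulate_query_lineage,
    simulate_wgd_genomes,
)


def _toy_dataset():
    """Two reference genomes, anchors for paralogs A and B, a query genome."""

    def locus(g, genome, chrom, pos):
        return GeneLocus(g, genome, chrom, pos)

    data = {
        # colocated with anchor A in mouse only
        "f_a": {"mouse": [locus("f_a.m", "mouse", "chrA", 1)],
                "chicken": [locus("f_a.c", "chicken", "chrZ", 1)],
                "query": [locus("f_a.q", "query", "q1", 1)]},
        # colocated with B in chicken only
        "f_b": {"chicken": [locus("f_b.c", "chicken", "chrB", 2)],
                "query": [locus("f_b.q", "query", "q2", 1)]},
        # colocated with both anchors (different genomes)
        "f_ab": {"mouse": [locus("f_ab.m", "mouse", "chrA", 2)],
                 "chicken": [locus("f_ab.c", "chicken", "chrB", 3)],
                 "query": [locus("f_ab.q", "query", "q1", 2)]},
        # colocated with nothing
        "f_none": {"mouse": [locus("f_n.m", "mouse", "chrZ", 1)],
                   "query": [locus("f_n.q", "query", "q3", 1)]},
        # present in references only, absent from the query
        "f_refonly": {"mouse": [locus("f_r.m", "mouse", "chrA", 3)]},
    }
    anchors = {
        "A": {"mouse": locus("A.m", "mouse", "chrA", 0), "chicken": locus("A.c", "chicken", "chrA2", 0)},
        "B": {"mouse": locus("B.m", "mouse", "chrB2", 0), "chicken": locus("B.c", "chicken", "chrB", 0)},
    }
    clg = LinkageGroup("toy", list(data))
    return OrthologTable(data, genomes=["mouse", "chicken", "query"]), anchors, clg


class TestDefineNeighborhoods:
    def test_colocation_in_one_genome_suffices(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        assert "f_a" in nbh.of("A") and "f_a" not in nbh.of("B")
        assert "f_b" in nbh.of("B") and "f_b" not in nbh.of("A")

    def test_family_can_join_multiple_neighborhoods(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        assert "f_ab" in nbh.of("A") and "f_ab" in nbh.of("B")

    def test_no_colocation_means_no_neighborhood(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        assert nbh.labels_for("f_none") == ()

    def test_missing_anchor_is_configuration_error(self):
        table, anchors, clg = _toy_dataset()
        del anchors["A"]["chicken"]
        with pytest.raises(ValidationError):
            define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)


class TestClassifyQuery:
    def test_category_assignment(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        asg = classify_query(nbh, table, "query", clg)
        assert asg.label == {"f_a": "A", "f_b": "B", "f_ab": SHARED, "f_none": OTHER}

    def test_families_absent_from_query_are_excluded(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        asg = classify_query(nbh, table, "query", clg)
        assert "f_refonly" not in asg.families

    def test_category_counts_partition_query_families(self):
        table, anchors, clg = _toy_dataset()
        nbh = define_neighborhoods(table, ["mouse", "chicken"], anchors, clg)
        asg = classify_query(nbh, table, "query", clg)
        counts = asg.category_counts()
        assert sum(counts.values()) == len(table.present_families("query"))


class TestBuildContingency:
    def test_published_row_reproduced(self, table2_assignment):
        tab = build_contingency(table2_assignment, "TCF7L1", "chr8")
        assert tab.as_tuple() == (7, 3, 45, 101)

    def test_shared_and_other_count_to_no_label_rows(self, table2_assignment):
        tab = build_contingency(table2_assignment, "TCF7L1", "chr8")
        assert tab.row_margins == (10, 146)  # 146 includes the 11 SHARED + 24 OTHER

    def test_chromosome_marginal_invariant_across_labels(self, table2_assignment):
        for chrom, expected in (("chr8", 52), ("chr41", 43), ("chr68", 12)):
            margins = {
                build_contingency(table2_assignment, nbh, chrom).on_chromosome_margin
                for nbh in ("TCF7", "LEF1", "TCF7L1", "TCF7L2")
            }
            assert margins == {expected}

    def test_shared_label_rejected_as_focal(self, table2_assignment):
        with pytest.raises(ValidationError):
            build_contingency(table2_assignment, SHARED, "chr8")

    def test_unknown_chromosome_rejected(self, table2_assignment):
        with pytest.raises(ValidationError):
            build_contingency(table2_assignment, "TCF7", "chr999")

    def test_negative_cells_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(1, -1, 0, 0)


class TestNoNoiseRecovery:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_classification_recovers_truth_without_translocation(self, seed):
        config = WgdSimConfig(n_families=80, translocation_rate=0.0, seed=seed)
        table, truth = simulate_wgd_genomes(config)
        table, truth = simulate_query_lineage(table, truth, "shared_2R", 0.3, seed + 100)
        anchors = reference_anchor_loci(table, truth)
        nbh = define_neighborhoods(table, list(truth.paralogon_chromosomes), anchors, truth.linkage_group)
        asg = classify_query(nbh, table, "query", truth.linkage_group)
        assert dict(asg.label) == dict(truth.expected_query_labels)

    def test_mislabels_grow_with_translocation_noise(self):
        def mislabel_fraction(rate):
            total = bad = 0
            for seed in range(6):
                config = WgdSimConfig(
                    n_families=80, translocation_rate=rate, seed=seed
                )
                table, truth = simulate_wgd_genomes(config)
                table, truth = simulate_query_lineage(table, truth, "shared_2R", 0.2, seed + 100)
                anchors = reference_anchor_loci(table, truth)
                nbh = define_neighborhoods(
                    table, list(truth.paralogon_chromosomes), anchors, truth.linkage_group
                )
                asg = classify_query(nbh, table, "query", truth.linkage_group)
                for fam, lab in asg.label.items():
                    total += 1
                    bad += lab != truth.expected_query_labels[fam]
            return bad / total

        assert mislabel_fraction(0.0) == 0.0
        assert mislabel_fraction(0.0) <= mislabel_fraction(0.15) <= mislabel_fraction(0.6)


class TestSharedFlankOrthology:
    def test_majority_flank_share_assigns(self):
        result = shared_flank_orthology(
            {"qx": ["g1", "g2", "g3", "g4"]},
            {"a": ["g1", "g2", "g3", "g4", "g5"], "b": ["h1", "h2", "h3"]},
        )
        assert result.assigned == {"qx": "a"}
        assert result.ties == ()

    def test_equal_share_reports_tie(self):
        result = shared_flank_orthology(
            {"qx": ["g1", "h1"]},
            {"a": ["g1", "g2"], "b": ["h1", "h2"]},
        )
        assert result.assigned == {}
        assert result.ties == ("qx",)

    def test_empty_flanks_rejected(self):
        with pytest.raises(ValidationError):
            shared_flank_orthology({"qx": []}, {"a": ["g1"]})

    @pytest.mark.parametrize("seed", range(20))
    def test_disjoint_planted_flankers_always_resolve(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        pool = [f"g{i}" for i in range(40)]
        rng.shuffle(pool)
        ref_a, ref_b = pool[:10], pool[10:20]
        qa = list(rng.choice(ref_a, size=6, replace=False))
        qb = list(rng.choice(ref_b, size=6, replace=False))
        result = shared_flank_orthology(
            {"dup1": qa, "dup2": qb}, {"a": ref_a, "b": ref_b}
        )
        assert result.assigned == {"dup1": "a", "dup2": "b"}
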