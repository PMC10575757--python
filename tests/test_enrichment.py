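"""Enrichment factors and per-residue frequency/enrichment matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vhhmine.clustering import cluster_by_cdr3
from vhhmine.enrichment import (
    EnrichmentError,
    enrichment_factor,
    positional_enrichment,
    positional_frequency,
    rank_clusters,
)
from vhhmine.repertoire import AnnotatedVHH


def vhh(seq_id, cdr3, counts):
    return AnnotatedVHH(seq_id=seq_id, cdr1="G", cdr2="S", cdr3=cdr3, counts=counts)


class TestEnrichmentFactor:
    # printed per-cluster read counts with the round totals they came with
    @pytest.mark.parametrize(
        "n_sel, n_base, expected",
        [(2630, 0, 3095), (2991, 1, 1760), (4147, 36, 132), (11954, 888, 16)],
    )
    def test_reproduces_published_fold_changes(self, n_sel, n_base, expected):
        ef = enrichment_factor(n_sel, 754669, n_base, 887881)
        assert round(ef) == expected

    def test_identical_proportions_give_unity(self):
        assert enrichment_factor(10, 100, 10, 100) == pytest.approx(1.0)

    def test_cluster_exceeding_total_rejected(self):
        with pytest.raises(EnrichmentError):
            enrichment_factor(11, 10, 0, 10)

    @settings(max_examples=100, deadline=None)
    @given(
        n_sel=st.integers(0, 9_000),
        n_base=st.integers(0, 9_000),
        t_sel=st.integers(10_000, 1_000_000),
        t_base=st.integers(10_000, 1_000_000),
    )
    def test_monotone_in_cluster_counts(self, n_sel, n_base, t_sel, t_base):
        ef = enrichment_factor(n_sel, t_sel, n_base, t_base)
        assert enrichment_factor(n_sel + 1, t_sel, n_base, t_base) > ef
        assert enrichment_factor(n_sel, t_sel, n_base + 1, t_base) < ef
        assert ef > 0


class TestRankClusters:
    @pytest.fixture()
    def campaign_table(self, campaign_counts):
        clusters, totals = campaign_counts
        seqs = [
            vhh(
                f"c{row.cluster_id}",
                "AAAAAAAACCCCCCCC"[: 8 + row.cluster_id] + "Y" * row.cluster_id,
                {0: row.count_r0, 1: row.count_r1, 2: row.count_r2},
            )
            for row in clusters.itertuples()
        ]
        return cluster_by_cdr3(seqs, threshold=0.99), totals

    def test_enrichment_order_matches_published_ranking(self, campaign_table):
        table, totals = campaign_table
        records = rank_clusters(table, "enrichment", 2, 0, totals=totals)
        assert [r.ef_rounded for r in records] == [3095, 1760, 132, 16]

    def test_frequency_mode_puts_most_read_cluster_first(self, campaign_table):
        table, totals = campaign_table
        records = rank_clusters(table, "frequency", 2, totals=totals)
        assert records[0].n_sel == 11954

    def test_single_cluster_gives_singleton_list(self):
        table = cluster_by_cdr3([vhh("a", "AAAA", {0: 1, 2: 5})])
        assert len(rank_clusters(table, "enrichment", 2, 0)) == 1

    def test_unknown_round_rejected(self, campaign_table):
        table, _ = campaign_table
        with pytest.raises(EnrichmentError):
            rank_clusters(table, "enrichment", 7, 0)


class TestPositionalMatrices:
    def test_single_sequence_gives_one_hot_rows(self):
        mat = positional_frequency([vhh("a", "ACD", {2: 4})], 2)
        assert np.allclose(mat.values.to_numpy().sum(axis=1), 1.0)
        assert mat.values.loc[1, "A"] == 1.0
        assert mat.values.loc[2, "C"] == 1.0
        assert mat.values.loc[3, "D"] == 1.0

    def test_count_weighting_rule(self):
        members = [vhh("a", "ACD", {2: 3}), vhh("b", "AYD", {2: 1})]
        mat = positional_frequency(members, 2)
        assert mat.values.loc[2, "C"] == pytest.approx(0.75)
        assert mat.values.loc[2, "Y"] == pytest.approx(0.25)
        assert mat.values.loc[1, "A"] == 1.0

    def test_equal_counts_split_evenly(self):
        members = [vhh("a", "ACDE", {2: 2}), vhh("b", "ACDY", {2: 2})]
        mat = positional_frequency(members, 2)
        assert mat.values.loc[4, "E"] == pytest.approx(0.5)
        assert mat.values.loc[4, "Y"] == pytest.approx(0.5)

    def test_off_modal_lengths_excluded_and_reported(self):
        members = [vhh("a", "ACDE", {2: 3}), vhh("b", "ACD", {2: 1})]
        mat = positional_frequency(members, 2)
        assert mat.values.shape[0] == 4
        assert mat.excluded_fraction == pytest.approx(0.25)

    def test_identical_rounds_give_unit_enrichment(self):
        members = [vhh("a", "ACD", {1: 5, 2: 5}), vhh("b", "AYD", {1: 5, 2: 5})]
        mat = positional_enrichment(members, 2, 1)
        assert np.allclose(mat.values.to_numpy(), 1.0)

    def test_ratio_rule_follows_stated_formula(self):
        members = [
            vhh("a", "A", {1: 1, 2: 2}),
            vhh("b", "C", {1: 3, 2: 2}),
        ]
        # f_sel(A) = 0.5, f_base(A) = 0.25 -> ratio ~ 2 at tiny pseudocount
        mat = positional_enrichment(members, 2, 1, pseudo=1e-6)
        assert mat.values.loc[1, "A"] == pytest.approx(2.0, abs=1e-4)

    def test_residue_absent_from_baseline_round(self):
        # hand computation: (0.1 + 0.001) / (0 + 0.001) = 101
        members = [
            vhh("a", "A", {1: 1, 2: 5}),
            vhh("b", "C", {1: 3, 2: 4}),
            vhh("c", "D", {1: 0, 2: 1}),
        ]
        mat = positional_enrichment(members, 2, 1, pseudo=0.001)
        assert mat.values.loc[1, "D"] == pytest.approx(101.0)
        f_sel = positional_frequency(members, 2).values
        f_base = positional_frequency(members, 1).values
        expected = (f_sel + 0.001) / (f_base + 0.001)
        assert np.allclose(mat.values.to_numpy(), expected.to_numpy())

    def test_swapping_rounds_inverts_entries_with_matched_pseudo(self):
        members = [vhh("a", "AC", {1: 2, 2: 6}), vhh("b", "AY", {1: 6, 2: 2})]
        fwd = positional_enrichment(members, 2, 1, pseudo=0.01)
        rev = positional_enrichment(members, 1, 2, pseudo=0.01)
        assert np.allclose(
            fwd.values.to_numpy(), 1.0 / rev.values.to_numpy()
        )
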