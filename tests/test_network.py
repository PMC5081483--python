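"""PDI network model: I/O, filtering, degrees, similarities, peak assignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdinet.network import (
    EmptyNetworkError,
    GenomicInterval,
    NetworkFormatError,
    assign_peaks,
    degree_summary,
    density_matrix,
    filter_baits,
    load_edge_list,
    save_edge_list,
    target_profile_similarity,
    tf_profile_similarity,
)
from .conftest import make_network, random_bipartite


class TestEdgeListIO:
    def test_duplicate_rows_collapse_to_binary_edges(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "tf_id\tpromoter_id\tgene_id\tbait_quality\n"
            "tfA\tp1\tg1\tclean\n"
            "tfA\tp1\tg1\tclean\n"
            "tfB\tp2\tg2\tclean\n"
        )
        net = load_edge_list(path)
        assert net.edges == {("tfA", "p1"), ("tfB", "p2")}
        assert net.n_collapsed == 1

    def test_unknown_quality_label_is_rejected_with_row(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text(
            "tf_id\tpromoter_id\tgene_id\tbait_quality\n"
            "tfA\tp1\tg1\tsparkly\n"
        )
        with pytest.raises(NetworkFormatError, match="sparkly"):
            load_edge_list(path)

    def test_missing_column_and_empty_file_errors(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("tf_id\tpromoter_id\n" "a\tb\n")
        with pytest.raises(NetworkFormatError, match="gene_id"):
            load_edge_list(bad)
        empty = tmp_path / "empty.tsv"
        empty.write_text("")
        with pytest.raises(EmptyNetworkError):
            load_edge_list(empty)

    def test_save_load_round_trip_preserves_edges(self, tmp_path):
        net = make_network(
            [("a", "p1"), ("a", "p2"), ("b", "p2")],
            quality={"p1": "moderate_background"},
        )
        path = tmp_path / "net.tsv"
        save_edge_list(net, path)
        back = load_edge_list(path)
        assert back.edges == net.edges
        assert back.bait_quality == net.bait_quality

    def test_dialect_maps_foreign_column_names(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("TF\tBait\tGene\tQuality\nx\tp\tg\tclean\n")
        net = load_edge_list(
            path,
            dialect={"tf_id": "TF", "promoter_id": "Bait",
                     "gene_id": "Gene", "bait_quality": "Quality"},
        )
        assert net.edges == {("x", "p")}


class TestFilterBaits:
    def test_all_clean_is_identity(self):
        net = make_network([("a", "p1"), ("b", "p2")])
        out = filter_baits(net, {"clean"})
        assert out.edges == net.edges

    def test_no_matching_quality_gives_empty_network(self):
        net = make_network(
            [("a", "p1")], quality={"p1": "high_background"}
        )
        out = filter_baits(net, {"clean"})
        assert out.edges == set() and not out.tf_ids

    def test_filtered_edges_subset_and_idempotent(self, standard_world):
        net = standard_world.network
        once = filter_baits(net, {"clean"})
        twice = filter_baits(once, {"clean"})
        assert once.edges <= net.edges
        assert twice.edges == once.edges
        kept_quality = {once.bait_quality[p] for p in once.promoter_ids}
        assert kept_quality <= {"clean"}

    def test_filtering_removes_background_artifacts(self, standard_world):
        # high-background baits carry spurious interactions by construction,
        # so restricting to clean baits must strictly shrink the edge set
        net = standard_world.network
        clean = filter_baits(net, {"clean"})
        assert clean.n_edges() < net.n_edges()
        assert clean.n_tested_promoters == net.n_tested_promoters


class TestDegreeSummary:
    def test_single_tf_two_promoters(self):
        net = make_network([("a", "p1"), ("a", "p2")], n_tested_promoters=2)
        s = degree_summary(net)
        assert s.mean_in_degree == 1.0
        assert s.out_degree["a"] == 2
        assert s.mean_out_degree_fraction == 1.0

    def test_disjoint_single_edges_mean_equals_median_one(self):
        net = make_network([(f"t{i}", f"p{i}") for i in range(7)])
        s = degree_summary(net)
        assert s.mean_in_degree == s.median_in_degree == 1.0

    def test_totals_match_edge_count(self, clean_net):
        s = degree_summary(clean_net)
        assert sum(s.in_degree.values()) == clean_net.n_edges()
        assert sum(s.out_degree.values()) == clean_net.n_edges()

    def test_empty_network_rejected(self):
        net = make_network([("a", "p1")])
        net.edges = set()
        with pytest.raises(EmptyNetworkError):
            degree_summary(net)

    def test_out_degree_fraction_uses_promoters_tested(self):
        net = make_network([("a", "p1")], n_tested_promoters=100)
        s = degree_summary(net)
        assert s.mean_out_degree_fraction == pytest.approx(0.01)


class TestDensityMatrix:
    def test_single_edge_single_cell_density_one(self):
        net = make_network([("a", "p1")])
        d = density_matrix(net)
        assert d["density"].shape == (1, 1)
        assert d["density"][0, 0] == 1.0

    def test_complete_bipartite_all_densities_one(self):
        net = make_network(
            [(t, p) for t in ("a", "b") for p in ("p1", "p2")]
        )
        d = density_matrix(net)
        assert np.all(d["density"][d["edge_counts"] > 0] == 1.0)

    def test_cells_match_brute_force_recount(self, clean_net):
        import math

        d = density_matrix(clean_net)
        tf_bin = {t: int(math.floor(math.log2(len(clean_net.targets_of(t)))))
                  for t in clean_net.tf_ids}
        prom_bin = {p: int(math.floor(math.log2(len(clean_net.binders_of(p)))))
                    for p in clean_net.promoter_ids}
        for i, tb in enumerate(d["tf_bins"]):
            for j, pb in enumerate(d["promoter_bins"]):
                n_edges = sum(
                    1 for (t, p) in clean_net.edges
                    if tf_bin[t] == tb and prom_bin[p] == pb
                )
                n_t = sum(1 for b in tf_bin.values() if b == tb)
                n_p = sum(1 for b in prom_bin.values() if b == pb)
                assert d["edge_counts"][i, j] == n_edges
                if n_edges:
                    assert d["density"][i, j] == pytest.approx(
                        n_edges / (n_t * n_p)
                    )
        assert d["edge_counts"].sum() == clean_net.n_edges()


class TestProfileSimilarity:
    def test_known_target_overlap(self):
        net = make_network(
            [("a", p) for p in ("p1", "p2", "p3")]
            + [("b", p) for p in ("p2", "p3", "p4")]
        )
        assert target_profile_similarity(net, "a", "b") == pytest.approx(0.5)

    def test_identical_targets_score_one(self):
        net = make_network([("a", "p1"), ("b", "p1")])
        assert target_profile_similarity(net, "a", "b") == 1.0

    def test_shared_target_pair_like_redundant_paralogs(self):
        # two TFs sharing 40 of 92 bound promoters: similarity 40/92
        shared = [f"s{i}" for i in range(40)]
        only_a = [f"a{i}" for i in range(26)]
        only_b = [f"b{i}" for i in range(26)]
        net = make_network(
            [("tbxA", p) for p in shared + only_a]
            + [("tbxB", p) for p in shared + only_b]
        )
        sim = target_profile_similarity(net, "tbxA", "tbxB")
        assert sim == pytest.approx(40 / 92)

    def test_tf_profile_similarity_cases(self):
        net = make_network(
            [(t, "x") for t in "ABC"] + [(t, "y") for t in "CD"]
        )
        assert tf_profile_similarity(net, "x", "y") == pytest.approx(0.25)
        net2 = make_network([("A", "x"), ("A", "y")])
        assert tf_profile_similarity(net2, "x", "y") == 1.0
        net3 = make_network([("A", "x"), ("B", "y")])
        assert tf_profile_similarity(net3, "x", "y") == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_similarity_symmetric_bounded_reflexive(self, data):
        net = random_bipartite(6, 10, 18, seed=data.draw(st.integers(0, 10**6)))
        tfs = sorted(net.tf_ids)
        a = data.draw(st.sampled_from(tfs))
        b = data.draw(st.sampled_from(tfs))
        sab = target_profile_similarity(net, a, b)
        sba = target_profile_similarity(net, b, a)
        assert sab == sba
        if sab is not None:
            assert 0.0 <= sab <= 1.0
        if net.targets_of(a):
            assert target_profile_similarity(net, a, a) == 1.0


class TestAssignPeaks:
    PROMS = {"prom1": GenomicInterval("chrI", 0, 500)}

    def test_midpoint_inside_promoter_assigned(self):
        net = assign_peaks([(GenomicInterval("chrI", 100, 200), "tfA")], self.PROMS)
        assert net.edges == {("tfA", "prom1")}

    def test_midpoint_at_promoter_end_not_assigned(self):
        # half-open promoter [0, 500): midpoint 500 is outside
        net = assign_peaks([(GenomicInterval("chrI", 400, 600), "tfA")], self.PROMS)
        assert net.edges == set()

    def test_multiple_peaks_collapse_to_one_interaction(self):
        peaks = [
            (GenomicInterval("chrI", 10, 20), "tfA"),
            (GenomicInterval("chrI", 100, 120), "tfA"),
            (GenomicInterval("chrI", 300, 340), "tfA"),
        ]
        net = assign_peaks(peaks, self.PROMS)
        assert net.n_edges() == 1

    def test_other_chromosome_not_assigned(self):
        net = assign_peaks([(GenomicInterval("chrII", 100, 200), "tfA")], self.PROMS)
        assert net.edges == set()

    def test_malformed_interval_rejected(self):
        with pytest.raises(NetworkFormatError):
            GenomicInterval("chrI", 200, 100)
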