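"""Cofactor sign classification, concordance, and the TF-GO association scan."""

import math

import numpy as np
import pandas as pd
import pytest

from pdinet.annotation import (
    CofactorPPI,
    EvidenceTable,
    GOAnnotation,
    association_scan,
    classify_by_cofactors,
    cofactor_fraction_stats,
    concordance,
    family_composition_test,
    gene_set_enrichment,
    load_cofactor_ppi,
    load_go_annotations,
    tf_go_enrichment,
)
from .conftest import make_network


def ppi(edges, roles):
    return CofactorPPI(edges=set(edges), roles=roles)


ROLES = {"taf": "co-activator", "med": "co-activator",
         "gro": "co-repressor", "hda": "co-repressor", "x": "other"}


class TestClassifyByCofactors:
    def test_only_coactivator_partner_is_activator(self):
        # e.g., a TF whose single mapped partner is a TBP-associated factor
        p = ppi([("tfA", "taf")], ROLES)
        assert classify_by_cofactors(p, "tfA") == "activator"

    def test_mixed_partners_bifunctional(self):
        p = ppi([("tfA", "taf"), ("tfA", "gro")], ROLES)
        assert classify_by_cofactors(p, "tfA") == "bifunctional"

    def test_only_other_partners_unclassified(self):
        p = ppi([("tfA", "x")], ROLES)
        assert classify_by_cofactors(p, "tfA") == "unclassified"

    def test_only_corepressors_is_repressor(self):
        p = ppi([("tfA", "gro"), ("tfA", "hda")], ROLES)
        assert classify_by_cofactors(p, "tfA") == "repressor"

    def test_labels_partition_and_are_order_invariant(self, standard_world):
        world_ppi = standard_world.cofactor_ppi
        labels = {t: classify_by_cofactors(world_ppi, t)
                  for t in sorted(world_ppi.tf_ids)}
        assert set(labels.values()) <= {
            "activator", "repressor", "bifunctional", "unclassified"
        }
        reordered = CofactorPPI(
            edges=set(sorted(world_ppi.edges, reverse=True)),
            roles=world_ppi.roles,
        )
        assert all(
            classify_by_cofactors(reordered, t) == lab
            for t, lab in labels.items()
        )

    def test_planted_signs_recovered_at_fidelity(self, standard_world):
        world_ppi = standard_world.cofactor_ppi
        correct = total = 0
        for tf, sign in standard_world.signs.items():
            if sign == "none":
                continue
            label = classify_by_cofactors(world_ppi, tf)
            total += 1
            if label == sign or label == "bifunctional":
                correct += 1
        assert correct / total >= 0.7

    def test_missing_role_label_rejected(self):
        with pytest.raises(ValueError, match="role"):
            CofactorPPI(edges={("tfA", "unknown")}, roles={})


class TestCofactorFractions:
    def test_maximal_separation(self):
        edges = [("actA", "taf"), ("actB", "med"), ("repA", "gro"), ("repB", "hda")]
        res = cofactor_fraction_stats(
            ppi(edges, ROLES),
            {"actA": "activator", "actB": "activator",
             "repA": "repressor", "repB": "repressor"},
        )
        t = res["table"]
        assert t[t["sign"] == "activator"]["coactivator_fraction"].tolist() == [1.0, 1.0]
        assert t[t["sign"] == "repressor"]["coactivator_fraction"].tolist() == [0.0, 0.0]
        assert res["p_coactivator"] < 0.05

    def test_identical_groups_not_significant(self):
        edges = [(f"t{i}", "taf") for i in range(4)] + [(f"t{i}", "gro") for i in range(4)]
        res = cofactor_fraction_stats(
            ppi(edges, ROLES),
            {f"t{i}": ("activator" if i < 2 else "repressor") for i in range(4)},
        )
        assert res["p_coactivator"] > 0.9

    def test_planted_world_group_means_ordered(self, standard_world):
        res = cofactor_fraction_stats(standard_world.cofactor_ppi,
                                      standard_world.signs)
        t = res["table"]
        act = t[t["sign"] == "activator"]["coactivator_fraction"].mean()
        rep = t[t["sign"] == "repressor"]["coactivator_fraction"].mean()
        assert act > rep


class TestConcordance:
    def test_compatibility_rules(self):
        ev = EvidenceTable({
            "a": {"coexpression": "activator", "cofactor": "activator"},
            "b": {"coexpression": "activator", "cofactor": "repressor"},
            "c": {"coexpression": "bifunctional", "cofactor": "activator"},
            "d": {"coexpression": "activator"},  # single source: excluded
        })
        res = concordance(ev)
        assert res["n_multi_source"] == 3
        assert res["fraction_concordant"] == pytest.approx(2 / 3)

    def test_requires_multi_source_tf(self):
        with pytest.raises(ValueError):
            concordance(EvidenceTable({"a": {"coexpression": "activator"}}))


class TestFisherEnrichment:
    def exact_upper_tail(self, M, n, N, k):
        """Enumeration oracle: P(overlap >= k) for the 2x2 margins."""
        total = math.comb(M, N)
        return sum(
            math.comb(n, j) * math.comb(M - n, N - j)
            for j in range(k, min(n, N) + 1)
        ) / total

    def make_net(self, n_genes, target_genes, tf="tfA"):
        genes = [f"g{i}" for i in range(n_genes)]
        p2g = {f"p{i}": g for i, g in enumerate(genes)}
        edges = [(tf, f"p{i}") for i in range(n_genes)
                 if genes[i] in target_genes]
        return make_network(edges, promoter_to_gene=p2g), genes

    def test_hand_computed_example(self):
        # universe 20, term 5, targets 5, overlap 4:
        # p = [C(5,4) C(15,1) + C(5,5)] / C(20,5) = 76 / 15504
        net, genes = self.make_net(20, set(genes := [f"g{i}" for i in range(5)]))
        ann = GOAnnotation({"T": set(genes[:4]) | {"g19"}})
        p, fold = tf_go_enrichment(net, ann, "tfA", "T")
        assert p == pytest.approx(76 / 15504, rel=1e-9)
        assert fold == pytest.approx(4 / (5 * 5 / 20))

    def test_zero_overlap_p_near_one(self):
        net, genes = self.make_net(25, {"g0", "g1"})
        ann = GOAnnotation({"T": {"g20", "g21"}})
        p, _ = tf_go_enrichment(net, ann, "tfA", "T")
        assert p > 0.9

    def test_term_equal_to_target_set_is_minimal(self):
        targets = {f"g{i}" for i in range(6)}
        net, genes = self.make_net(24, targets)
        ann = GOAnnotation({"T": targets, "U": set(genes[:3]) | {"g20", "g21", "g22"}})
        p_exact, _ = tf_go_enrichment(net, ann, "tfA", "T")
        p_other, _ = tf_go_enrichment(net, ann, "tfA", "U")
        assert p_exact < p_other
        assert p_exact == pytest.approx(
            self.exact_upper_tail(24, 6, 6, 6), rel=1e-9
        )

    def test_matches_enumeration_on_all_small_tables(self):
        # oracle equivalence across every 2x2 margin with universe <= 30
        from scipy import stats

        for M in range(2, 31):
            ns = range(1, M + 1, 3)
            for n in ns:
                for N in range(1, M + 1, 3):
                    for k in range(max(0, n + N - M), min(n, N) + 1):
                        p = float(stats.hypergeom.sf(k - 1, M, n, N))
                        assert p == pytest.approx(
                            self.exact_upper_tail(M, n, N, k), rel=1e-9, abs=1e-12
                        )


class TestAssociationScan:
    def test_planted_coherent_tf_recovered(self, standard_world, clean_net):
        res = association_scan(clean_net, standard_world.go_annotations, seed=0)
        found = set(zip(res["associations"]["tf"], res["associations"]["term"]))
        planted = set(standard_world.planted_associations)
        assert planted <= found

    def test_low_out_degree_tf_excluded(self):
        genes = [f"g{i}" for i in range(40)]
        p2g = {f"p{i}": g for i, g in enumerate(genes)}
        edges = [("small", f"p{i}") for i in range(9)]  # out-degree 9 < 10
        edges += [("big", f"p{i}") for i in range(12)]
        net = make_network(edges, promoter_to_gene=p2g)
        ann = GOAnnotation({"T": set(genes[:12])})
        res = association_scan(net, ann, min_term_targets=5)
        assert "small" not in set(res["all_pairs"]["tf"])

    def test_duplicate_terms_tested_once_and_count_invariant(self):
        genes = [f"g{i}" for i in range(40)]
        p2g = {f"p{i}": g for i, g in enumerate(genes)}
        edges = [("tfA", f"p{i}") for i in range(12)]
        net = make_network(edges, promoter_to_gene=p2g)
        shared = set(genes[:12])
        ann = GOAnnotation({"T1": shared, "T2": set(shared)})
        counts = set()
        for seed in range(5):
            res = association_scan(net, ann, min_term_targets=5, seed=seed)
            tested = set(res["all_pairs"]["term"])
            assert len(tested) == 1
            counts.add(res["n_associations"])
        assert len(counts) == 1  # same p either way: count seed-invariant

    def test_randomized_null_far_below_observed(self, standard_world, clean_net):
        res = association_scan(
            clean_net, standard_world.go_annotations,
            n_randomizations=60, seed=2, swap_attempts_factor=20,
        )
        assert res["n_associations"] > res["null_mean"]
        assert res["z"] > 3


class TestGeneSetEnrichment:
    def test_family_set_enrichment_and_composition(self, standard_world, clean_net):
        # detox-style family analysis on a TF whose targets define the set
        tf = max(clean_net.tf_ids, key=lambda t: len(clean_net.targets_of(t)))
        fam = set(list(clean_net.target_genes_of(tf))[:15])
        p, fold = gene_set_enrichment(clean_net, tf, fam)
        assert p < 0.001 and fold > 1
        res = family_composition_test(
            {tf, "other1"}, {tf}, set(clean_net.tf_ids) | {"other1"}
        )
        assert res["fraction_enriched"] > res["fraction_all"]


class TestIO:
    def test_cofactor_and_go_loaders(self, tmp_path):
        ppi_path = tmp_path / "ppi.tsv"
        ppi_path.write_text(
            "tf_id\tcofactor_id\trole\n"
            "tfA\ttaf\tco-activator\n"
            "tfB\tgro\tco-repressor\n"
        )
        loaded = load_cofactor_ppi(ppi_path)
        assert classify_by_cofactors(loaded, "tfA") == "activator"

        go_path = tmp_path / "go.tsv"
        go_path.write_text("term_id\tgene_id\nT1\tg1\nT1\tg2\nT2\tg2\n")
        ann = load_go_annotations(go_path)
        assert ann.term_genes == {"T1": {"g1", "g2"}, "T2": {"g2"}}

    def test_gaf_loader_keeps_process_aspect_only(self, tmp_path):
        gaf = tmp_path / "ann.gaf"
        cols = ["DB", "ID", "sym", "qual", "go", "ref", "ev", "with",
                "aspect", "name", "syn", "type", "taxon", "date", "by"]
        rows = [
            ["db", "x1", "gene1", "", "GO:1", "r", "IDA", "", "P", "", "", "", "", "", ""],
            ["db", "x2", "gene2", "", "GO:2", "r", "IDA", "", "F", "", "", "", "", "", ""],
        ]
        gaf.write_text(
            "!gaf-version: 2.1\n"
            + "\n".join("\t".join(r) for r in rows) + "\n"
        )
        ann = load_go_annotations(gaf)
        assert "GO:1" in ann.term_genes and "GO:2" not in ann.term_genes
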