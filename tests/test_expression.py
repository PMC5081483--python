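"""Co-expression integration, sign inference, and spatiotemporal overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pdinet.expression import (
    ExpressionCompendium,
    ExpressionDataset,
    TissueExpression,
    build_coexpression,
    calibrate_null_calls,
    load_compendium,
    median_ratio,
    per_tf_overlap_class,
    predict_sign,
    shared_tf_coexpression_enrichment,
    shuffle_null,
    spatiotemporal_overlap,
)
from .conftest import make_network


def toy_compendium(tables, n_experiments=None):
    datasets = []
    for i, table in enumerate(tables):
        df = pd.DataFrame(table).T  # genes x samples
        n = n_experiments[i] if n_experiments else df.shape[1]
        datasets.append(ExpressionDataset(f"d{i}", df, n))
    return ExpressionCompendium(datasets)


class TestBuildCoexpression:
    def test_perfectly_correlated_pair_scores_one(self):
        rng = np.random.default_rng(0)
        tables = []
        for _ in range(3):
            base = rng.uniform(10, 1000, size=6)
            tables.append({"a": base, "b": base * 2, "c": rng.uniform(10, 1000, 6)})
        scores = build_coexpression(toy_compendium(tables), min_coverage=1)
        # log2 of a scaled copy is a shifted copy: correlation exactly 1,
        # clamped inside the Fisher-z machinery
        assert scores.score("a", "b") == pytest.approx(1.0, abs=1e-4)

    def test_weighted_fisher_z_average_matches_hand_computation(self):
        rng = np.random.default_rng(1)
        tables, sizes = [], [8, 5, 4]
        for n in sizes:
            tables.append({"a": rng.uniform(1, 500, n), "b": rng.uniform(1, 500, n)})
        comp = toy_compendium(tables, n_experiments=sizes)
        scores = build_coexpression(comp, min_coverage=1)
        # spreadsheet-style oracle
        zs, ws = [], []
        for table, n in zip(tables, sizes):
            x = np.log2(np.asarray(table["a"]) + 1)
            y = np.log2(np.asarray(table["b"]) + 1)
            r = np.corrcoef(x, y)[0, 1]
            zs.append(math.atanh(r))
            ws.append(n - 3)
        expected = math.tanh(sum(w * z for w, z in zip(ws, zs)) / sum(ws))
        assert scores.score("a", "b") == pytest.approx(expected, rel=1e-9)

    def test_low_coverage_gene_removed(self):
        rng = np.random.default_rng(2)
        tables = []
        for i in range(4):
            t = {"a": rng.uniform(1, 100, 6), "b": rng.uniform(1, 100, 6)}
            if i == 0:
                t["rare"] = rng.uniform(1, 100, 6)
            tables.append(t)
        scores = build_coexpression(toy_compendium(tables), min_coverage=2)
        assert "a" in scores and "rare" not in scores

    def test_low_confidence_datasets_ignored(self):
        rng = np.random.default_rng(3)
        good = {"a": rng.uniform(1, 100, 6), "b": rng.uniform(1, 100, 6)}
        bad = {"a": rng.uniform(1, 100, 3), "b": rng.uniform(1, 100, 3)}
        comp = toy_compendium([good, bad], n_experiments=[6, 3])
        scores = build_coexpression(comp, min_coverage=1)
        only = build_coexpression(
            toy_compendium([good], n_experiments=[6]), min_coverage=1
        )
        assert scores.score("a", "b") == pytest.approx(only.score("a", "b"))

    def test_bottom_decile_genes_dropped(self, standard_world, coexpr_scores):
        # the generator plants genes stuck in the lowest expression decile
        # of most datasets; the noise filter must remove every one of them
        dim = [
            g for g in standard_world.promoter_to_gene.values()
            if g not in coexpr_scores
        ]
        assert len(dim) >= standard_world.params.n_dim_genes
        assert all(g in coexpr_scores for g in standard_world.tf_ids)

    def test_symmetry(self, coexpr_scores):
        assert np.allclose(
            coexpr_scores.matrix, coexpr_scores.matrix.T, equal_nan=True
        )


def scored_stub(tf_score_map, genes):
    """CoexpressionScores stand-in built from explicit vectors."""
    from pdinet.expression import CoexpressionScores

    names = [tf for tf in tf_score_map] + list(genes)
    n = len(names)
    m = np.full((n, n), np.nan)
    np.fill_diagonal(m, 1.0)
    for i, tf in enumerate(tf_score_map):
        for j, g in enumerate(genes):
            m[i, len(tf_score_map) + j] = tf_score_map[tf][j]
            m[len(tf_score_map) + j, i] = tf_score_map[tf][j]
    return CoexpressionScores(genes=names, matrix=m)


class TestPredictSign:
    def make_case(self, target_scores, non_target_scores, tf="tf1"):
        genes = [f"g{i}" for i in range(len(target_scores) + len(non_target_scores))]
        edges = [(tf, f"p{i}") for i in range(len(target_scores))]
        p2g = {f"p{i}": g for i, g in enumerate(genes)}
        net = make_network(edges, promoter_to_gene=p2g)
        scores = scored_stub(
            {tf: list(target_scores) + list(non_target_scores)}, genes
        )
        return net, scores

    def test_extreme_separation_called_activator(self):
        t = np.linspace(0.5, 0.9, 20)
        nt = np.linspace(-0.3, 0.1, 40)
        net, scores = self.make_case(t, nt)
        pred = predict_sign(net, scores, "tf1")
        assert pred.call == "activator"
        _, p_min = stats.mannwhitneyu(t, nt, alternative="two-sided")
        assert pred.p_value == pytest.approx(p_min)

    def test_reversed_separation_called_repressor(self):
        t = np.linspace(-0.9, -0.5, 20)
        nt = np.linspace(0.0, 0.4, 40)
        net, scores = self.make_case(t, nt)
        assert predict_sign(net, scores, "tf1").call == "repressor"

    def test_below_minimum_targets_not_called(self):
        t = np.linspace(0.5, 0.9, 9)
        nt = np.linspace(-0.3, 0.1, 40)
        net, scores = self.make_case(t, nt)
        pred = predict_sign(net, scores, "tf1")
        assert pred.call == "none" and "minimum" in pred.reason

    def test_null_rarely_called(self):
        # identically distributed targets and non-targets: the two-sided
        # call rate stays near alpha across repetitions
        rng = np.random.default_rng(0)
        called = 0
        reps = 200
        for _ in range(reps):
            t = rng.normal(size=20)
            nt = rng.normal(size=60)
            net, scores = self.make_case(t, nt)
            if predict_sign(net, scores, "tf1").call != "none":
                called += 1
        assert called / reps < 0.11

    def test_mann_whitney_matches_exact_permutation_enumeration(self):
        # exhaustive oracle for small tie-free groups
        rng = np.random.default_rng(5)
        for n1, n2 in [(3, 4), (5, 5), (6, 8), (8, 8)]:
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            u_obs, p_greater = stats.mannwhitneyu(x, y, alternative="greater")
            pooled = np.concatenate([x, y])
            total = 0
            at_least = 0
            for idx in itertools.combinations(range(n1 + n2), n1):
                xs = pooled[list(idx)]
                ys = np.delete(pooled, list(idx))
                u = sum((a > b) for a in xs for b in ys)
                total += 1
                if u >= u_obs:
                    at_least += 1
            assert p_greater == pytest.approx(at_least / total, rel=1e-9)

    def test_median_ratio_cases(self):
        t = np.full(12, 0.6)
        nt = np.full(30, 0.3)
        net, scores = self.make_case(t, nt)
        assert median_ratio(net, scores, "tf1") == pytest.approx(2.0)
        net2, scores2 = self.make_case(np.full(12, 0.3), np.full(30, 0.3))
        assert median_ratio(net2, scores2, "tf1") == pytest.approx(1.0)
        # strong excess over near-zero non-targets, like a sparse TF whose
        # few targets are strongly co-expressed
        net3, scores3 = self.make_case(np.full(12, 0.48), np.full(30, 0.04))
        assert median_ratio(net3, scores3, "tf1") == pytest.approx(12.0)

    def test_zero_denominator_flagged(self):
        net, scores = self.make_case(np.full(12, 0.5), np.full(30, 0.0))
        assert median_ratio(net, scores, "tf1") is None


class TestCalibration:
    def test_null_false_call_rate_near_alpha(self):
        res = calibrate_null_calls(n_tfs=300, n_targets=30, n_non_targets=300,
                                   alpha=0.05, seed=2)
        assert res["false_call_rate"] <= 0.07


class TestShuffleNull:
    def test_planted_world_counts_exceed_null(self, clean_net, coexpr_scores):
        res = shuffle_null(clean_net, coexpr_scores, n_randomizations=100, seed=4)
        assert res["observed"]["activator"] > res["null_activators"].mean()
        assert res["z_activators"] > 3
        assert res["z_repressors"] > 3

    def test_single_randomization_degenerate(self, clean_net, coexpr_scores):
        res = shuffle_null(clean_net, coexpr_scores, n_randomizations=1, seed=0)
        assert res["degenerate"]

    def test_pure_noise_counts_near_null(self):
        # network whose targets are unrelated to the score structure
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(80)]
        p2g = {f"p{i}": g for i, g in enumerate(genes)}
        edges = [("tfA", f"p{i}") for i in rng.choice(80, 15, replace=False)]
        net = make_network(edges, promoter_to_gene=p2g)
        scores = scored_stub({"tfA": rng.normal(size=80)}, genes)
        res = shuffle_null(net, scores, n_randomizations=150, seed=9)
        total_obs = res["observed"]["activator"] + res["observed"]["repressor"]
        null_total = res["null_activators"] + res["null_repressors"]
        assert abs(total_obs - null_total.mean()) <= max(2.0, 3 * null_total.std())


class TestSharedTFCoexpression:
    def test_threshold_zero_stratum_enrichment_one(self, clean_net, coexpr_scores):
        table = shared_tf_coexpression_enrichment(
            clean_net, coexpr_scores, jaccard_thresholds=(0.0,),
            top_fractions=(0.05,),
        )
        row = table.iloc[0]
        assert row["enrichment"] == pytest.approx(1.0, abs=1e-9)

    def test_permuted_scores_enrichment_near_one(self, clean_net, coexpr_scores):
        # destroy the score-profile link by permuting the gene labels of
        # the score matrix; enrichment collapses toward 1
        from pdinet.expression import CoexpressionScores

        rng = np.random.default_rng(11)
        perm = rng.permutation(len(coexpr_scores.genes))
        shuffled = CoexpressionScores(
            genes=[coexpr_scores.genes[i] for i in perm],
            matrix=coexpr_scores.matrix,
        )
        table = shared_tf_coexpression_enrichment(
            clean_net, shuffled, jaccard_thresholds=(0.2,), top_fractions=(0.10,)
        )
        row = table.iloc[0]
        if not row["flagged_empty"] and row["n_pairs"] >= 30:
            assert row["enrichment"] == pytest.approx(1.0, abs=0.75)


class TestSpatiotemporal:
    def test_identical_profiles_overlap(self):
        profile = np.arange(11.0)
        table = pd.DataFrame(
            {f"c{i}": [profile[i], profile[i], 10 - profile[i]]
             for i in range(11)},
            index=["tfA", "gT", "gN"],
        )
        net = make_network([("tfA", "pT")], promoter_to_gene={"pT": "gT", "pN": "gN"})
        res = spatiotemporal_overlap(net, TissueExpression(table))
        assert res["table"][0, 0] == 1  # interacting pair overlaps

    def test_odds_ratio_arithmetic(self):
        # contingency 30/70 vs 10/90: OR = (30*90)/(70*10) = 27/7
        table = np.array([[30, 70], [10, 90]])
        from pdinet.expression import _odds_ratio

        assert _odds_ratio(table) == pytest.approx(27 / 7)

    def test_random_profiles_or_near_one(self):
        rng = np.random.default_rng(21)
        ors = []
        for rep in range(10):
            genes = [f"g{i}" for i in range(60)]
            tissue = TissueExpression(pd.DataFrame(
                rng.normal(size=(62, 11)), index=["tfA", "tfB"] + genes
            ))
            p2g = {f"p{i}": g for i, g in enumerate(genes)}
            edges = [(tf, f"p{i}") for tf in ("tfA", "tfB")
                     for i in rng.choice(60, 20, replace=False)]
            net = make_network(edges, promoter_to_gene=p2g)
            ors.append(spatiotemporal_overlap(net, tissue)["odds_ratio"])
        assert 0.5 < np.median(ors) < 2.0

    def test_planted_activator_world_enriched(self, standard_world, clean_net):
        res = spatiotemporal_overlap(clean_net, standard_world.tissue)
        assert res["odds_ratio"] > 1
        assert res["p"] < 0.05
        # the cutoff is recomputed from data, not hard-coded
        assert res["cutoff"] != 0.29

    def test_per_tf_overlap_label(self, standard_world, clean_net):
        activators = [t for t, s in standard_world.signs.items()
                      if s == "activator"]
        labels = [
            per_tf_overlap_class(clean_net, standard_world.tissue, t)["label"]
            for t in activators
        ]
        assert labels.count("targets-overlap") > len(labels) / 2

    def test_per_tf_haldane_correction_flagged(self):
        profile = np.arange(11.0)
        table = pd.DataFrame(
            [profile, profile + 0.1, -profile],
            index=["tfA", "gT", "gN"],
        )
        net = make_network([("tfA", "pT")],
                           promoter_to_gene={"pT": "gT", "pN": "gN"})
        res = per_tf_overlap_class(net, TissueExpression(table), "tfA",
                                   cutoff=0.9)
        assert res["haldane_corrected"]


class TestCompendiumIO:
    def test_manifest_round_trip(self, tmp_path, standard_world):
        from pdinet.synthetic import emit_datasets

        emit_datasets(standard_world, tmp_path)
        comp = load_compendium(tmp_path / "compendium" / "manifest.tsv")
        assert len(comp.datasets) == standard_world.params.n_datasets
        orig = standard_world.compendium.datasets[0].table
        back = comp.datasets[0].table
        assert np.allclose(orig.to_numpy(), back.to_numpy())
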