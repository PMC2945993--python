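from dataclasses import replace

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gridwave.expression_mapping import label_samples, map_expression_to_reactions
from gridwave.pipeline import RunConfig, analyze, embed_pathways
from gridwave.stats_ranking import per_reaction_regulation, wilcoxon_matrix
from gridwave.synthetic_data import (
    SimulationDesign,
    benchmark_sensitivity,
    clinical_table,
    generate_expression,
    generate_pathways,
)
from gridwave.wavelet_features import cascade, enumerate_nontrivial


class TestDesign:
    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            SimulationDesign(n_pathways=0)
        with pytest.raises(ValueError):
            SimulationDesign(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationDesign(pattern="ramp")
        with pytest.raises(ValueError):
            SimulationDesign(n_planted=7, n_pathways=6)

    def test_null_or_zero_effect_plants_nothing(self):
        assert SimulationDesign(pattern="null").planted_ids == []
        assert SimulationDesign(effect_size=0.0).planted_ids == []


class TestGeneratePathways:
    def test_size_and_connectivity(self):
        design = SimulationDesign(reactions_per_pathway=6, seed=4)
        for pw in generate_pathways(design):
            assert pw.n_reactions == 6
            assert pw.n_edges >= 5
            assert nx.is_connected(pw.to_networkx())

    def test_deterministic_per_seed(self):
        d = SimulationDesign(seed=9)
        a, b = generate_pathways(d), generate_pathways(d)
        for x, y in zip(a, b):
            assert x.reactions == y.reactions
            assert np.array_equal(x.adjacency, y.adjacency)

    def test_zero_extra_edges_yields_tree(self):
        d = SimulationDesign(extra_edge_fraction=0.0, reactions_per_pathway=9, seed=2)
        for pw in generate_pathways(d):
            assert pw.n_edges == pw.n_reactions - 1


class TestGenerateExpression:
    def test_reproducible_and_shapes(self):
        d = SimulationDesign(seed=5)
        pws = generate_pathways(d)
        e1, c1, t1 = generate_expression(d, pws)
        e2, c2, t2 = generate_expression(d, pws)
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(c1, c2)
        assert e1.shape == (
            d.n_pathways * d.reactions_per_pathway * d.genes_per_reaction,
            d.n_favorable + d.n_unfavorable,
        )

    def test_truth_reactions_belong_to_planted_pathways(self):
        d = SimulationDesign(pattern="block_up", n_planted=2, seed=6)
        pws = generate_pathways(d)
        _, _, truth = generate_expression(d, pws)
        by_id = {p.pathway_id: p for p in pws}
        assert set(truth["planted"]) == set(d.planted_ids)
        for pid, shifts in truth["planted"].items():
            assert set(shifts) <= set(by_id[pid].reaction_ids)

    def test_switch_planted_on_adjacent_pair(self):
        d = SimulationDesign(pattern="switch", seed=7)
        pws = generate_pathways(d)
        _, _, truth = generate_expression(d, pws)
        (shifts,) = truth["planted"].values()
        (up,) = [r for r, s in shifts.items() if s > 0]
        (down,) = [r for r, s in shifts.items() if s < 0]
        pw = pws[0]
        i, j = pw.reaction_ids.index(up), pw.reaction_ids.index(down)
        assert pw.adjacency[i, j] == 1

    def test_null_pattern_has_no_group_shift(self):
        d = SimulationDesign(pattern="null", n_favorable=200, n_unfavorable=200, seed=8)
        pws = generate_pathways(d)
        expr, clinical, truth = generate_expression(d, pws)
        assert truth["planted"] == {}
        unfav = [s for s in expr.columns if s.startswith("U")]
        fav = [s for s in expr.columns if s.startswith("F")]
        diff = expr[unfav].mean(axis=1) - expr[fav].mean(axis=1)
        assert np.abs(diff.mean()) < 0.05

    def test_clinical_encodes_intended_labels(self):
        labels = label_samples(clinical_table(["F000", "F001", "U000"]))
        assert list(labels) == ["favorable", "favorable", "unfavorable"]

    def test_switch_detected_per_reaction_both_directions(self):
        """delta = 2 SD on an adjacent pair is found by the rank test in
        both directions in most replicate datasets."""
        base = SimulationDesign(pattern="switch", effect_size=2.0, seed=10)
        pws = generate_pathways(base)
        hits = 0
        n_rep = 25
        for rep in range(n_rep):
            d = replace(base, seed=10_000 + rep)
            expr, clinical, truth = generate_expression(d, pws)
            labels = label_samples(clinical)
            (shifts,) = truth["planted"].values()
            rvals, measured = map_expression_to_reactions(expr, pws[0])
            reg = per_reaction_regulation(rvals, measured, labels)
            (up,) = [r for r, s in shifts.items() if s > 0]
            (down,) = [r for r, s in shifts.items() if s < 0]
            hits += reg[up] == "up" and reg[down] == "down"
        assert hits / n_rep > 0.8


class TestTypeIErrorCalibration:
    def test_per_feature_type_one_error_near_nominal(self):
        """Null-feature rejection rate at alpha=0.05 stays in [0.03, 0.07]."""
        base = SimulationDesign(pattern="null", seed=20)
        pws = generate_pathways(base)
        config = RunConfig(backend="heuristic", seed=0)
        embs = embed_pathways(pws, config)
        ps = []
        for rep in range(60):
            d = replace(base, seed=20_000 + rep)
            expr, clinical, _ = generate_expression(d, pws)
            labels = label_samples(clinical)
            mask_u = (labels.reindex(expr.columns) == "unfavorable").to_numpy()
            for pw in pws:
                rvals, _ = map_expression_to_reactions(expr, pw)
                from gridwave.expression_mapping import paint_image_stack

                stack, _ = paint_image_stack(embs[pw.pathway_id], rvals)
                table = enumerate_nontrivial(
                    cascade(stack, embs[pw.pathway_id].placement, pw.pathway_id,
                            list(expr.columns))
                )
                ps.append(wilcoxon_matrix(table.values, mask_u, ~mask_u))
        ps = np.concatenate(ps)
        assert ps.size >= 2000
        rate = float(np.mean(ps <= 0.05))
        assert 0.03 <= rate <= 0.07


class TestBenchmark:
    def test_null_only_design_fpr_near_threshold(self):
        d = SimulationDesign(pattern="null", seed=3)
        res = benchmark_sensitivity(d, methods=("fisher",), n_replicates=20, seed=3)
        row = res.roc_table.query("method == 'fisher' and threshold == 0.05").iloc[0]
        assert row["specificity"] > 0.85  # FPR at 0.05 stays near nominal

    def test_large_effect_reaches_full_sensitivity(self):
        d = SimulationDesign(pattern="block_up", effect_size=6.0, seed=4)
        res = benchmark_sensitivity(
            d, methods=("gridwave",), n_replicates=5, seed=4,
            thresholds=(0.05,),
        )
        row = res.roc_table.iloc[0]
        assert row["sensitivity"] == 1.0

    def test_roc_table_shape_and_determinism(self):
        d = SimulationDesign(pattern="switch", seed=5)
        r1 = benchmark_sensitivity(d, methods=("fisher",), n_replicates=5, seed=5,
                                   thresholds=(0.01, 0.05))
        r2 = benchmark_sensitivity(d, methods=("fisher",), n_replicates=5, seed=5,
                                   thresholds=(0.01, 0.05))
        pd.testing.assert_frame_equal(r1.roc_table, r2.roc_table)
        assert r1.auc == r2.auc
        assert len(r1.roc_table) == 2

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown methods"):
            benchmark_sensitivity(SimulationDesign(), methods=("gsea",), n_replicates=5)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError, match="replicates"):
            benchmark_sensitivity(SimulationDesign(), n_replicates=1)


def test_pipeline_recovers_planted_block(tmp_path):
    d = SimulationDesign(pattern="block_up", effect_size=2.0, seed=17)
    pws = generate_pathways(d)
    expr, clinical, _ = generate_expression(d, pws)
    res, tables, embs = analyze(pws, expr, clinical, RunConfig(backend="heuristic"))
    assert res[0].pathway_id == d.planted_ids[0]
    assert res[0].p_adjusted < 0.05
    assert res[0].significant  # block of 4 reactions passes the ">3" filter
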