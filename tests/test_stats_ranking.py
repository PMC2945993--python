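import itertools

import numpy as np
import pandas as pd
import pytest

from gridwave.expression_mapping import FAVORABLE, UNFAVORABLE
from gridwave.stats_ranking import (
    bonferroni,
    differential_genes,
    fisher_enrichment,
    per_reaction_regulation,
    rank_enrichment_baseline,
    rank_pathways,
    results_frame,
    wilcoxon_rank_sum,
    wilcoxon_matrix,
)
from gridwave.wavelet_features import FeatureDescriptor, FeatureTable
from helpers import exact_rank_sum_p


class TestWilcoxon:
    def test_reference_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_symmetric_null_case(self):
        p = wilcoxon_rank_sum([1, 2], [1, 2])
        assert p == pytest.approx(1.0, abs=0.15)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=6), rng.normal(1.0, size=7)
        p1 = wilcoxon_rank_sum(a, b)
        p2 = wilcoxon_rank_sum(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_exact_refuses_ties_with_fallback(self):
        with pytest.warns(UserWarning, match="ties"):
            wilcoxon_rank_sum([1, 1, 2], [2, 3, 4], mode="exact")

    @pytest.mark.parametrize(
        "na,nb", [(na, nb) for na in range(1, 8) for nb in range(1, 8) if na + nb <= 8]
    )
    def test_exact_matches_enumeration_oracle(self, na, nb):
        rng = np.random.default_rng(na * 10 + nb)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na], pooled[na:]
            assert wilcoxon_rank_sum(a, b, mode="exact") == pytest.approx(
                exact_rank_sum_p(a, b)
            )

    def test_matrix_version_agrees_with_scalar(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 20))
        mask_a = np.arange(20) < 8
        p = wilcoxon_matrix(vals, mask_a, ~mask_a)
        for k in range(5):
            assert p[k] == pytest.approx(
                wilcoxon_rank_sum(vals[k, mask_a], vals[k, ~mask_a], "normal_approx")
            )

    def test_matrix_constant_rows_get_p_one(self):
        vals = np.ones((2, 10))
        mask = np.arange(10) < 5
        np.testing.assert_array_equal(wilcoxon_matrix(vals, mask, ~mask), [1.0, 1.0])


class TestBonferroni:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(bonferroni([0.004, 0.2], 10), [0.04, 1.0])

    def test_identity_family(self):
        assert bonferroni([0.3], 1)[0] == pytest.approx(0.3)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 5)
        with pytest.raises(ValueError):
            bonferroni([0.1, 0.2], 1)


def _labels(n_f, n_u):
    idx = [f"F{k}" for k in range(n_f)] + [f"U{k}" for k in range(n_u)]
    return pd.Series(
        [FAVORABLE] * n_f + [UNFAVORABLE] * n_u, index=idx, name="label"
    )


class TestPerReactionRegulation:
    def test_fully_separated_groups_called_up(self):
        labels = _labels(10, 10)
        vals = pd.DataFrame(
            [np.r_[np.zeros(10), np.full(10, 2.0)]], index=["R1"], columns=labels.index
        )
        measured = pd.Series([True], index=["R1"])
        reg = per_reaction_regulation(vals, measured, labels)
        assert reg["R1"] == "up"

    def test_identical_distributions_unchanged(self):
        labels = _labels(10, 10)
        vals = pd.DataFrame(
            [np.r_[np.arange(10.0), np.arange(10.0)]], index=["R1"], columns=labels.index
        )
        reg = per_reaction_regulation(vals, pd.Series([True], index=["R1"]), labels)
        assert reg["R1"] == "unchanged"

    def test_unmeasured_always_unchanged(self):
        labels = _labels(10, 10)
        vals = pd.DataFrame(
            [np.r_[np.zeros(10), np.full(10, 5.0)]], index=["R1"], columns=labels.index
        )
        reg = per_reaction_regulation(vals, pd.Series([False], index=["R1"]), labels)
        assert reg["R1"] == "unchanged"

    def test_downshift_called_down(self):
        labels = _labels(10, 10)
        vals = pd.DataFrame(
            [np.r_[np.zeros(10), np.full(10, -2.0)]], index=["R1"], columns=labels.index
        )
        reg = per_reaction_regulation(vals, pd.Series([True], index=["R1"]), labels)
        assert reg["R1"] == "down"


def _feature_table(pid, values, samples):
    descs = [
        FeatureDescriptor(pid, 0, (0, k), (0, 0), 1, frozenset({f"{pid}_R{k}"}))
        for k in range(values.shape[0])
    ]
    return FeatureTable(descs, values, samples)


class TestRankPathways:
    def _setup(self, n_diff_a=5):
        labels = _labels(10, 10)
        samples = list(labels.index)
        rng = np.random.default_rng(0)
        shift = np.r_[np.zeros(10), np.full(10, 3.0)]
        # pathway A: strong feature + n_diff_a shifted reactions
        fa = _feature_table("A", rng.normal(size=(4, 20)) + shift, samples)
        ra = pd.DataFrame(
            rng.normal(size=(8, 20)) + np.where(np.arange(8)[:, None] < n_diff_a, shift, 0),
            index=[f"A_R{k}" for k in range(8)],
            columns=samples,
        )
        fb = _feature_table("B", rng.normal(size=(4, 20)), samples)
        rb = pd.DataFrame(
            rng.normal(size=(8, 20)), index=[f"B_R{k}" for k in range(8)], columns=samples
        )
        tables = {"A": fa, "B": fb}
        reactions = {
            "A": (ra, pd.Series(True, index=ra.index)),
            "B": (rb, pd.Series(True, index=rb.index)),
        }
        return tables, reactions, labels

    def test_strong_pathway_significant_and_first(self):
        tables, reactions, labels = self._setup(n_diff_a=5)
        res = rank_pathways(tables, reactions, labels)
        assert res[0].pathway_id == "A"
        assert res[0].significant
        assert res[0].n_diff_regulated >= 4
        assert not res[1].significant

    def test_min_reactions_filter_blocks_small_patterns(self):
        tables, reactions, labels = self._setup(n_diff_a=2)
        res = rank_pathways(tables, reactions, labels)
        assert res[0].pathway_id == "A"
        assert res[0].p_adjusted <= 0.05
        assert not res[0].significant  # only 2 regulated reactions: fails ">3"

    def test_full_ranking_returned_when_nothing_passes(self):
        labels = _labels(5, 5)
        samples = list(labels.index)
        rng = np.random.default_rng(1)
        tables = {
            p: _feature_table(p, rng.normal(size=(3, 10)), samples) for p in ("A", "B")
        }
        reactions = {
            p: (
                pd.DataFrame(rng.normal(size=(4, 10)),
                             index=[f"{p}R{k}" for k in range(4)], columns=samples),
                pd.Series(True, index=[f"{p}R{k}" for k in range(4)]),
            )
            for p in ("A", "B")
        }
        res = rank_pathways(tables, reactions, labels)
        assert len(res) == 2 and not any(r.significant for r in res)
        frame = results_frame(res)
        assert list(frame["rank"]) == [1, 2]
        assert frame["p_value"].is_monotonic_increasing

    def test_adjusted_at_least_raw_and_family_scope(self):
        tables, reactions, labels = self._setup()
        for scope in ("global", "per_pathway"):
            for r in rank_pathways(tables, reactions, labels, family_scope=scope):
                assert r.p_adjusted >= r.p_raw
                assert r.n_up + r.n_down == r.n_diff_regulated <= r.n_reactions

    def test_scale_invariance_of_feature_pvalues(self):
        tables, reactions, labels = self._setup()
        scaled = {
            pid: FeatureTable(t.descriptors, 17.3 * t.values, t.sample_ids)
            for pid, t in tables.items()
        }
        r1 = rank_pathways(tables, reactions, labels)
        r2 = rank_pathways(scaled, reactions, labels)
        assert [x.p_raw for x in r1] == pytest.approx([x.p_raw for x in r2])


class TestFisher:
    def test_hypergeometric_example(self):
        universe = set(range(10))
        de = set(range(5))
        assert fisher_enrichment(de, de, universe) == pytest.approx(2 / 252)

    def test_independent_margins_p_one(self):
        universe = set(range(20))
        de = set(range(10))                      # half of everything
        pathway = set(range(5)) | set(range(10, 15))  # half in DE, half out
        assert fisher_enrichment(de, pathway, universe) == pytest.approx(1.0)

    def test_depletion_is_detected_two_sidedly(self):
        universe = set(range(10))
        de = set(range(5))
        pathway = set(range(5, 10))  # no overlap with DE
        assert fisher_enrichment(de, pathway, universe) == pytest.approx(2 / 252)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_enrichment(set(), set(), set())

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment({"x"}, set(), {"y"})


class TestRankEnrichment:
    def _expr(self, planted_shift=0.0, seed=0, n_genes=20, n_per_group=10):
        rng = np.random.default_rng(seed)
        labels = _labels(n_per_group, n_per_group)
        vals = rng.normal(size=(n_genes, 2 * n_per_group))
        vals[:5, n_per_group:] += planted_shift  # pathway genes are the first 5
        expr = pd.DataFrame(
            vals, index=[f"g{k}" for k in range(n_genes)], columns=labels.index
        )
        return expr, labels, {f"g{k}" for k in range(5)}

    def test_coordinated_enrichment_yields_small_p(self):
        for seed in range(3):
            expr, labels, genes = self._expr(
                planted_shift=2.0, seed=seed, n_genes=40, n_per_group=30
            )
            es, p = rank_enrichment_baseline(expr, labels, genes, 200, seed=seed)
            assert es > 0
            assert 1 / 201 <= p <= 0.05  # small, but bounded by the permutation count

    def test_score_sign_flips_with_direction(self):
        expr, labels, genes = self._expr(planted_shift=10.0)
        es_up, _ = rank_enrichment_baseline(expr, labels, genes, 100, seed=1)
        es_dn, _ = rank_enrichment_baseline(-expr, labels, genes, 100, seed=1)
        assert np.sign(es_up) == -np.sign(es_dn)

    def test_deterministic_given_seed(self):
        expr, labels, genes = self._expr(planted_shift=1.0)
        out1 = rank_enrichment_baseline(expr, labels, genes, 150, seed=3)
        out2 = rank_enrichment_baseline(expr, labels, genes, 150, seed=3)
        assert out1 == out2

    def test_null_pvalues_not_concentrated(self):
        ps = []
        for seed in range(30):
            expr, labels, genes = self._expr(planted_shift=0.0, seed=seed)
            _, p = rank_enrichment_baseline(expr, labels, genes, 100, seed=seed)
            ps.append(p)
        assert 0.2 < np.mean(ps) < 0.8

    def test_too_few_permutations_rejected(self):
        expr, labels, genes = self._expr()
        with pytest.raises(ValueError, match="100"):
            rank_enrichment_baseline(expr, labels, genes, n_permutations=50)


def test_differential_genes_catches_planted_shift():
    rng = np.random.default_rng(2)
    labels = _labels(15, 15)
    vals = rng.normal(size=(10, 30))
    vals[0, 15:] += 3.0
    expr = pd.DataFrame(vals, index=[f"g{k}" for k in range(10)], columns=labels.index)
    de = differential_genes(expr, labels)
    assert "g0" in de
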