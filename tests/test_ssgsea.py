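import warnings

import numpy as np
import pandas as pd
import pytest

from oracles import naive_walk_es
from stemscore import (
    ExpressionMatrix,
    GeneSetCollection,
    enrichment_score,
    infiltration_scores,
    rank_genes,
    score_all,
)


def _expr(arr, genes=None, samples=None):
    arr = np.asarray(arr, float)
    genes = genes or [f"g{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


class TestRankGenes:
    @pytest.mark.parametrize(
        "values,tie_rule,expected",
        [
            ([5, 1, 3], "average", [3, 1, 2]),
            ([1, 1, 1], "average", [2, 2, 2]),
            ([2, 2, 9], "average", [1.5, 1.5, 3]),
            ([2, 2, 9], "min", [1, 1, 3]),
        ],
    )
    def test_rank_examples(self, values, tie_rule, expected):
        x = _expr(np.array(values, float)[:, None])
        ranks = rank_genes(x, "s0", tie_rule=tie_rule)
        assert ranks.tolist() == expected

    def test_unknown_sample(self, small_expr):
        with pytest.raises(KeyError):
            rank_genes(small_expr, "nope")


class TestEnrichmentScore:
    def test_top_gene_fixture(self):
        ranks = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])
        assert enrichment_score(ranks, ["g1"], alpha=1) == pytest.approx(2.0, abs=1e-12)

    def test_bottom_gene_fixture(self):
        ranks = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])
        assert enrichment_score(ranks, ["g4"], alpha=1) == pytest.approx(-2.0, abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_naive_walk_on_random_instances(self, alpha):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 21))
            genes = [f"g{i:02d}" for i in range(n)]
            vals = rng.normal(size=n)
            if rng.random() < 0.3:  # force ties sometimes
                vals = np.round(vals, 1)
            ranks = pd.Series(
                pd.Series(vals).rank(method="average").to_numpy(), index=genes
            )
            k = int(rng.integers(1, n))
            gene_set = list(rng.choice(genes, size=k, replace=False))
            got = enrichment_score(ranks, gene_set, alpha=alpha)
            want = naive_walk_es(dict(ranks), set(gene_set), alpha)
            assert got == pytest.approx(want, abs=1e-12)

    def test_absent_genes_dropped_before_scoring(self):
        ranks = pd.Series([4.0, 3.0, 2.0, 1.0], index=["g1", "g2", "g3", "g4"])
        assert enrichment_score(ranks, ["g1", "zz"], alpha=1) == pytest.approx(2.0)

    def test_empty_intersection_rejected(self):
        ranks = pd.Series([2.0, 1.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="no overlap"):
            enrichment_score(ranks, ["zz"])

    def test_full_universe_rejected(self):
        ranks = pd.Series([2.0, 1.0], index=["g1", "g2"])
        with pytest.raises(ValueError, match="whole gene universe"):
            enrichment_score(ranks, ["g1", "g2"])

    def test_complement_antisymmetry_at_alpha_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 15))
            genes = [f"g{i:02d}" for i in range(n)]
            ranks = pd.Series(
                pd.Series(rng.normal(size=n)).rank().to_numpy(), index=genes
            )
            k = int(rng.integers(1, n))
            sub = list(rng.choice(genes, size=k, replace=False))
            comp = [g for g in genes if g not in sub]
            assert enrichment_score(ranks, sub, alpha=0) == pytest.approx(
                -enrichment_score(ranks, comp, alpha=0), abs=1e-12
            )


class TestScoreAll:
    def test_global_range_normalization(self, small_expr, small_sets):
        em = score_all(small_expr, small_sets, alpha=0.25, norm="global_range")
        rng = em.es.to_numpy().max() - em.es.to_numpy().min()
        assert em.norm_constant == pytest.approx(rng)
        assert np.allclose(em.nes.to_numpy(), em.es.to_numpy() / rng)
        span = em.nes.to_numpy().max() - em.nes.to_numpy().min()
        assert span == pytest.approx(1.0)

    def test_norm_none_is_identity(self, small_expr, small_sets):
        em = score_all(small_expr, small_sets, norm="none")
        pd.testing.assert_frame_equal(em.es, em.nes)

    def test_rank_invariance_under_monotone_transform(self, small_sets):
        rng = np.random.default_rng(5)
        x = _expr(rng.normal(6, 2, (30, 6)))
        y = ExpressionMatrix(np.exp(x.data / 4.0))
        es_x = score_all(x, small_sets, norm="none").es
        es_y = score_all(y, small_sets, norm="none").es
        pd.testing.assert_frame_equal(es_x, es_y)

    def test_gene_row_permutation_invariance(self, small_expr, small_sets):
        perm = small_expr.data.sample(frac=1.0, random_state=9)
        es_a = score_all(small_expr, small_sets, norm="none").es
        es_b = score_all(ExpressionMatrix(perm), small_sets, norm="none").es
        pd.testing.assert_frame_equal(es_a, es_b)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_top_set_positive_bottom_set_negative(self, alpha):
        rng = np.random.default_rng(8)
        x = _expr(rng.normal(size=(40, 3)))
        for s in x.sample_ids:
            order = x.data[s].sort_values(ascending=False).index
            top = GeneSetCollection({"top": list(order[:6])})
            bot = GeneSetCollection({"bot": list(order[-6:])})
            assert score_all(x, top, alpha=alpha, norm="none").es.loc["top", s] > 0
            assert score_all(x, bot, alpha=alpha, norm="none").es.loc["bot", s] < 0

    def test_zero_overlap_set_dropped_with_warning(self, small_expr):
        sets = GeneSetCollection({"ok": small_expr.gene_ids[:4], "alien": ["zz", "yy"]})
        with pytest.warns(UserWarning, match="alien"):
            em = score_all(small_expr, sets)
        assert em.set_names == ["ok"]

    def test_all_sets_missing_rejected(self, small_expr):
        sets = GeneSetCollection({"alien": ["zz", "yy"]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="no gene set"):
                score_all(small_expr, sets)

    def test_infiltration_scores_alias(self, small_expr, small_sets):
        a = score_all(small_expr, small_sets)
        b = infiltration_scores(small_expr, small_sets)
        pd.testing.assert_frame_equal(a.nes, b.nes)
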