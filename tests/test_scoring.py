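"""EMT scores, marker scores, group comparisons and pre-ranked GSEA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from mir200sig import (
    DataFormatError,
    ExpressionMatrix,
    GeneSetCollection,
    compare_gene_across_groups,
    emt_76gs,
    emt_kgene,
    emt_ks,
    marker_scores,
    preranked_gsea,
    rank_genes_by_weight_association,
)


def matrix_from(rows: dict, samples=None):
    genes = list(rows)
    arr = np.array([rows[g] for g in genes], dtype=float)
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), "logCPM")


class TestEmt76gs:
    def test_hand_computed_example(self):
        # anchor [1,2,3]; A tracks it (w=1), B anti-tracks (w=-1)
        em = matrix_from({"CDH1": [1, 2, 3], "A": [1, 2, 3], "B": [3, 2, 1]})
        score = emt_76gs(em, ["A", "B"], anchor_gene="CDH1")
        assert np.allclose(score.to_numpy(), [-2.0, 0.0, 2.0])
        assert score.idxmax() == "S3"  # most epithelial

    def test_constant_genes_zero_scores(self):
        em = matrix_from({"CDH1": [1, 2, 3], "A": [5, 5, 5], "B": [2, 2, 2]})
        with pytest.warns(UserWarning, match="constant"):
            score = emt_76gs(em, ["A", "B"])
        assert np.allclose(score.to_numpy(), 0.0)

    def test_per_gene_offset_cancels(self, rng):
        vals = rng.normal(size=(6, 8))
        genes = ["CDH1"] + [f"G{i}" for i in range(5)]
        em = matrix_from(dict(zip(genes, vals)))
        base = emt_76gs(em, genes[1:])
        shifted_rows = dict(zip(genes, vals))
        shifted_rows["G2"] = vals[3] + 100.0
        em2 = matrix_from(shifted_rows)
        shifted = emt_76gs(em2, genes[1:])
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-9)

    def test_missing_anchor_rejected(self, tiny_matrix):
        with pytest.raises(DataFormatError, match="anchor"):
            emt_76gs(tiny_matrix, ["GA", "GB"], anchor_gene="NOPE")


class TestEmtKs:
    def test_full_separation_is_plus_one(self):
        em = matrix_from({"E1": [1], "E2": [2], "E3": [3],
                          "M1": [4], "M2": [5], "M3": [6]})
        score = emt_ks(em, ["E1", "E2", "E3"], ["M1", "M2", "M3"])
        assert score.iloc[0] == 1.0  # fully mesenchymal

    def test_identical_multisets_zero(self):
        em = matrix_from({"E1": [1], "E2": [2], "M1": [1], "M2": [2]})
        score = emt_ks(em, ["E1", "E2"], ["M1", "M2"])
        assert score.iloc[0] == 0.0

    def test_antisymmetry_exact(self, rng):
        genes = {f"E{i}": rng.normal(size=5) for i in range(6)}
        genes.update({f"M{i}": rng.normal(size=5) for i in range(7)})
        em = matrix_from(genes)
        epi = [g for g in genes if g.startswith("E")]
        mes = [g for g in genes if g.startswith("M")]
        fwd = emt_ks(em, epi, mes)
        rev = emt_ks(em, mes, epi)
        assert np.array_equal(fwd.to_numpy(), -rev.to_numpy())

    def test_magnitude_matches_ks_statistic(self, rng):
        genes = {f"E{i}": rng.normal(size=10) for i in range(8)}
        genes.update({f"M{i}": rng.normal(1.0, 1.0, size=10) for i in range(9)})
        em = matrix_from(genes)
        epi = [g for g in genes if g.startswith("E")]
        mes = [g for g in genes if g.startswith("M")]
        score = emt_ks(em, epi, mes)
        for j, s in enumerate(em.sample_ids):
            e = em.values.loc[epi, s]
            m = em.values.loc[mes, s]
            ks = stats.ks_2samp(e, m).statistic
            assert abs(score[s]) == pytest.approx(ks, abs=1e-12)

    def test_overlapping_sets_rejected(self, rng):
        em = matrix_from({g: rng.normal(size=3) for g in "ABCD"})
        with pytest.raises(DataFormatError, match="overlap"):
            emt_ks(em, ["A", "B"], ["B", "C"])


class TestEmtKgene:
    def test_single_mesenchymal_gene_is_its_zscore(self, rng):
        vals = rng.normal(size=6)
        em = matrix_from({"VIM": vals})
        score = emt_kgene(em, ["VIM"], {"VIM": "mesenchymal"})
        z = (vals - vals.mean()) / vals.std(ddof=1)
        assert np.allclose(score.to_numpy(), z, atol=1e-12)

    def test_opposite_directions_cancel(self, rng):
        vals = rng.normal(size=5)
        em = matrix_from({"A": vals, "B": vals})
        score = emt_kgene(em, ["A", "B"], {"A": "epithelial", "B": "mesenchymal"})
        assert np.allclose(score.to_numpy(), 0.0, atol=1e-12)

    def test_matches_brute_force_panel(self, rng):
        genes = {f"G{i}": rng.normal(size=9) for i in range(7)}
        dirs = {g: ("epithelial" if i % 2 else "mesenchymal")
                for i, g in enumerate(genes)}
        em = matrix_from(genes)
        score = emt_kgene(em, list(genes), dirs)
        brute = np.zeros(9)
        for g, v in genes.items():
            z = (np.asarray(v) - np.mean(v)) / np.std(v, ddof=1)
            brute += z if dirs[g] == "mesenchymal" else -z
        brute /= len(genes)
        assert np.allclose(score.to_numpy(), brute, atol=1e-12)


class TestMarkerScores:
    def test_mean_of_two_markers(self):
        em = matrix_from({"g1": [2.0], "g2": [4.0]})
        table = marker_scores(em, GeneSetCollection({"POP": ["g1", "g2"]}))
        assert table.loc["S1", "POP"] == 3.0

    def test_single_marker_identity(self, rng):
        vals = rng.normal(size=4)
        em = matrix_from({"g1": vals})
        table = marker_scores(em, GeneSetCollection({"POP": ["g1"]}))
        assert np.allclose(table["POP"].to_numpy(), vals)

    def test_absent_population_omitted_with_warning(self, rng):
        em = matrix_from({"g1": rng.normal(size=3)})
        sets = GeneSetCollection({"A": ["g1"], "B": ["nope"]})
        with pytest.warns(UserWarning, match="no marker gene"):
            table = marker_scores(em, sets)
        assert list(table.columns) == ["A"]

    def test_planted_lymphocyte_signal_anticorrelates_with_proportion(self, small_cohort):
        table = marker_scores(
            small_cohort.expression,
            GeneSetCollection({"LYM": small_cohort.gene_sets["MARKERS_LYMPHOCYTES"]}),
        )
        rho = stats.spearmanr(
            table["LYM"], small_cohort.truth["true_proportion"]
        ).statistic
        assert rho < -0.5


class TestCompareGene:
    def test_identical_groups_p_near_one(self):
        em = matrix_from({"g": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        res = compare_gene_across_groups(
            em, "g", {"A": ["S1", "S2", "S3"], "B": ["S4", "S5", "S6"]}
        )
        assert res["p_value"] > 0.9

    def test_disjoint_ranges_exact_tail(self):
        em = matrix_from({"g": [1, 2, 3, 4, 5, 11, 12, 13, 14, 15]})
        groups = {"A": [f"S{i}" for i in range(1, 6)],
                  "B": [f"S{i}" for i in range(6, 11)]}
        res = compare_gene_across_groups(em, "g", groups)
        # extreme rank-sum: two-sided exact p = 2 / C(10,5)
        assert res["p_value"] == pytest.approx(2 / comb(10, 5), rel=1e-9)
        assert res["groups"]["B"]["median"] == 13

    def test_three_groups_use_kruskal(self, rng):
        em = matrix_from({"g": rng.normal(size=9)})
        groups = {"A": ["S1", "S2", "S3"], "B": ["S4", "S5", "S6"],
                  "C": ["S7", "S8", "S9"]}
        res = compare_gene_across_groups(em, "g", groups)
        assert res["test"] == "kruskal-wallis"

    def test_null_pvalues_roughly_uniform(self, rng):
        ps = []
        for _ in range(200):
            vals = rng.normal(size=30)
            em = matrix_from({"g": vals})
            ids = list(em.sample_ids)
            perm = rng.permutation(ids)
            groups = {"A": list(perm[:15]), "B": list(perm[15:])}
            ps.append(compare_gene_across_groups(em, "g", groups)["p_value"])
        # rank-sum p is discrete; check calibration at conventional levels
        ps = np.asarray(ps)
        assert abs((ps <= 0.05).mean() - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 200)
        assert 0.4 < ps.mean() < 0.6


class TestWeightAssociationRanking:
    def make_weights(self, ups, ids):
        from mir200sig import MixtureWeights
        from mir200sig.io import CLASS_DOWN, CLASS_UP
        w = pd.DataFrame({CLASS_DOWN: 1 - np.asarray(ups), CLASS_UP: ups}, index=ids)
        return MixtureWeights(w, pd.Series(0.0, index=ids))

    def test_proportional_gene_ranks_first(self, rng):
        ups = rng.uniform(0, 1, 10)
        em = matrix_from(
            {"POS": ups * 2 + 1, "NEG": -ups, "RND": rng.normal(size=10)},
            samples=[f"S{i}" for i in range(10)],
        )
        ranking = rank_genes_by_weight_association(
            em, self.make_weights(ups, em.sample_ids)
        )
        assert ranking.index[0] == "POS"
        assert ranking.index[-1] == "NEG"
        assert ranking["r"].iloc[0] == pytest.approx(1.0)

    def test_matches_brute_force_correlation_sort(self, rng):
        ups = rng.uniform(0, 1, 15)
        rows = {f"G{i:02d}": rng.normal(size=15) for i in range(50)}
        em = matrix_from(rows, samples=[f"S{i}" for i in range(15)])
        ranking = rank_genes_by_weight_association(
            em, self.make_weights(ups, em.sample_ids)
        )
        brute = {
            g: np.corrcoef(em.values.loc[g], ups)[0, 1] for g in em.gene_ids
        }
        order = sorted(brute, key=lambda g: (-brute[g], g))
        assert list(ranking.index) == order
        for g in em.gene_ids:
            assert ranking.loc[g, "r"] == pytest.approx(brute[g], abs=1e-12)


class TestPrerankedGsea:
    def ranking(self, rng, n=500):
        stats_ = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(stats_, index=[f"g{i:04d}" for i in range(n)], name="r")

    def test_whole_ranking_es_one(self, rng):
        ranked = self.ranking(rng, 50)
        res = preranked_gsea(ranked, set(ranked.index), n_perm=10, rng=1)
        assert res.es == 1.0

    def test_top_block_with_exponent_zero(self, rng):
        ranked = self.ranking(rng, 100)
        top = set(ranked.index[:10])
        res = preranked_gsea(ranked, top, p_exponent=0.0, n_perm=10, rng=1)
        assert res.es == pytest.approx(1.0)

    def test_es_matches_brute_force_running_sum(self, rng):
        for _ in range(20):
            ranked = self.ranking(rng, 200)
            members = set(rng.choice(ranked.index, 25, replace=False))
            res = preranked_gsea(ranked, members, n_perm=5, rng=2)
            # independent re-computation of the weighted running sum
            r = ranked.to_numpy()
            hits = np.array([g in members for g in ranked.index])
            inc = np.abs(r) ** 1.0
            inc = np.where(hits, inc / inc[hits].sum(), -1.0 / (len(r) - hits.sum()))
            running = np.cumsum(inc)
            es = running[np.argmax(np.abs(running))]
            assert res.es == pytest.approx(es, abs=1e-12)

    def test_null_pvalues_uniform(self, rng):
        ps = []
        gen = np.random.default_rng(77)
        ranked = self.ranking(rng, 300)
        for _ in range(150):
            members = set(gen.choice(ranked.index, 20, replace=False))
            ps.append(preranked_gsea(ranked, members, n_perm=199, rng=gen).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_p_resolution(self, rng):
        ranked = self.ranking(rng, 100)
        res = preranked_gsea(ranked, set(ranked.index[:5]), n_perm=99, rng=3)
        assert res.p_value >= 1 / 100
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))

    def test_empty_intersection_rejected(self, rng):
        ranked = self.ranking(rng, 50)
        with pytest.raises(DataFormatError, match="intersect"):
            preranked_gsea(ranked, {"absent"}, n_perm=10, rng=1)
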