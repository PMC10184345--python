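"""Constrained deconvolution: panel selection, weight estimation, model
fitting, classification and quartiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mir200sig import (
    CLASS_DOWN,
    CLASS_UP,
    ClassCentroids,
    DataFormatError,
    ExpressionMatrix,
    MixtureWeights,
    SimulationParams,
    classify,
    estimate_weights,
    estimate_weights_matrix,
    fit_model,
    quartile_bins,
    select_centroid_panel,
    simulate_cohort,
)


def two_class_centroids(rng, n_genes=30, sep=2.0):
    genes = [f"G{i:03d}" for i in range(n_genes)]
    base = rng.normal(7, 2, n_genes)
    delta = rng.choice([-1.0, 1.0], n_genes) * sep / 2
    return ClassCentroids(
        pd.DataFrame({CLASS_DOWN: base - delta, CLASS_UP: base + delta}, index=genes)
    )


def grid_search_weight(x, c_down, c_up, step=0.001):
    """Independent oracle: brute-force the constrained objective on a grid."""
    ws = np.arange(0.0, 1.0 + step / 2, step)
    mix = np.outer(c_up, ws) + np.outer(c_down, 1.0 - ws)
    obj = ((x[:, None] - mix) ** 2).sum(axis=0)
    return ws[np.argmin(obj)]


class TestEstimateWeights:
    def test_endpoint_is_exact(self, rng):
        cents = two_class_centroids(rng)
        x = cents.profiles[CLASS_UP].rename("S1")
        w, resid = estimate_weights(x, cents)
        assert w[CLASS_UP] == pytest.approx(1.0, abs=1e-12)
        assert w[CLASS_DOWN] == pytest.approx(0.0, abs=1e-12)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_exact_convex_combination(self, rng):
        cents = two_class_centroids(rng)
        x = (0.3 * cents.profiles[CLASS_UP] + 0.7 * cents.profiles[CLASS_DOWN])
        w, resid = estimate_weights(x.rename("S1"), cents)
        assert w[CLASS_UP] == pytest.approx(0.3, abs=1e-9)
        assert resid == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_on_noisy_mixtures(self, rng):
        cents = two_class_centroids(rng, n_genes=50)
        c_down = cents.profiles[CLASS_DOWN].to_numpy()
        c_up = cents.profiles[CLASS_UP].to_numpy()
        for _ in range(100):
            p = rng.uniform(-0.2, 1.2)  # include out-of-simplex targets
            x = p * c_up + (1 - p) * c_down + rng.normal(0, 0.5, 50)
            w, _ = estimate_weights(
                pd.Series(x, index=cents.gene_ids, name="S"), cents
            )
            oracle = grid_search_weight(x, c_down, c_up)
            assert w[CLASS_UP] == pytest.approx(oracle, abs=0.002)

    def test_identical_centroids_rejected(self, rng):
        genes = [f"G{i}" for i in range(5)]
        prof = pd.DataFrame(
            {CLASS_DOWN: np.ones(5), CLASS_UP: np.ones(5)}, index=genes
        )
        cents = ClassCentroids(prof)
        with pytest.raises(DataFormatError, match="degenerate centroids"):
            estimate_weights(pd.Series(np.ones(5), index=genes, name="S"), cents)

    def test_matrix_version_agrees_with_per_sample(self, rng):
        cents = two_class_centroids(rng, n_genes=40)
        vals = rng.normal(7, 2, size=(40, 6))
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=cents.gene_ids,
                         columns=[f"S{j}" for j in range(6)]),
            "logCPM",
        )
        mw = estimate_weights_matrix(em, cents)
        for s in em.sample_ids:
            w, resid = estimate_weights(em.values[s], cents)
            assert np.allclose(mw.weights.loc[s], w, atol=1e-12)
            assert mw.residual[s] == pytest.approx(resid, abs=1e-9)

    def test_panel_coverage_guard(self, rng):
        cents = two_class_centroids(rng, n_genes=40)
        em = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(10, 3)),
                         index=cents.gene_ids[:10],
                         columns=["S1", "S2", "S3"]),
            "logCPM",
        )
        with pytest.raises(DataFormatError, match="panel genes present"):
            estimate_weights_matrix(em, cents)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.floats(0.0, 1.0),
        noise=st.floats(0.0, 2.0),
        seed=st.integers(0, 10_000),
    )
    def test_simplex_invariants_hold(self, p, noise, seed):
        rng = np.random.default_rng(seed)
        cents = two_class_centroids(rng)
        x = (p * cents.profiles[CLASS_UP] + (1 - p) * cents.profiles[CLASS_DOWN]
             + rng.normal(0, noise, len(cents.gene_ids)))
        w, resid = estimate_weights(x.rename("S"), cents)
        assert 0.0 <= w[CLASS_UP] <= 1.0
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert resid >= 0.0

    def test_monotone_in_true_proportion(self, rng):
        cents = two_class_centroids(rng)
        ps = np.linspace(0, 1, 21)
        est = []
        for p in ps:
            x = p * cents.profiles[CLASS_UP] + (1 - p) * cents.profiles[CLASS_DOWN]
            w, _ = estimate_weights(x.rename("S"), cents)
            est.append(w[CLASS_UP])
        assert (np.diff(est) >= -1e-12).all()

    def test_three_class_fallback_normalizes(self, rng):
        genes = [f"G{i:02d}" for i in range(30)]
        prof = pd.DataFrame(
            rng.normal(7, 2, size=(30, 3)), index=genes, columns=["a", "b", "c"]
        )
        cents = ClassCentroids(prof)
        x = (0.5 * prof["a"] + 0.3 * prof["b"] + 0.2 * prof["c"]).rename("S")
        w, resid = estimate_weights(x, cents)
        assert w.sum() == pytest.approx(1.0, abs=1e-9)
        assert w["a"] == pytest.approx(0.5, abs=1e-6)


class TestCentroidPanel:
    def test_selects_discriminant_genes(self, rng):
        genes = [f"G{i}" for i in range(10)]
        vals = rng.normal(0, 0.05, size=(10, 8))
        vals[0, 4:] += 5.0
        vals[1, 4:] += 5.0
        vals[2, 4:] -= 5.0
        vals[3, 4:] -= 5.0
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{j}" for j in range(8)]),
            "logCPM",
        )
        labels = pd.Series([CLASS_DOWN] * 4 + [CLASS_UP] * 4, index=em.sample_ids)
        panel = select_centroid_panel(em, labels, 4)
        assert set(panel) == {"G0", "G1", "G2", "G3"}

    def test_saturation_returns_all_with_warning(self, rng):
        em = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(5, 6)),
                         index=[f"G{i}" for i in range(5)],
                         columns=[f"S{j}" for j in range(6)]),
            "logCPM",
        )
        labels = pd.Series([CLASS_DOWN] * 3 + [CLASS_UP] * 3, index=em.sample_ids)
        with pytest.warns(UserWarning, match="returning all genes"):
            panel = select_centroid_panel(em, labels, 5)
        assert sorted(panel) == sorted(em.gene_ids)

    def test_label_swap_symmetry(self, rng):
        em = ExpressionMatrix(
            pd.DataFrame(rng.normal(size=(60, 10)),
                         index=[f"G{i:02d}" for i in range(60)],
                         columns=[f"S{j}" for j in range(10)]),
            "logCPM",
        )
        labels = pd.Series([CLASS_DOWN] * 5 + [CLASS_UP] * 5, index=em.sample_ids)
        swapped = labels.map({CLASS_DOWN: CLASS_UP, CLASS_UP: CLASS_DOWN})
        assert select_centroid_panel(em, labels, 20) == \
            select_centroid_panel(em, swapped, 20)

    def test_direction_balance_quota(self, rng):
        # 20 strong up-genes, 2 weak down-genes among noise: panel of 8 must
        # still carry at least 2 (25%) down genes
        genes = [f"U{i:02d}" for i in range(20)] + ["D0", "D1"] + \
            [f"N{i:02d}" for i in range(20)]
        vals = rng.normal(0, 0.05, size=(42, 10))
        vals[:20, 5:] += 5.0
        vals[20:22, 5:] -= 1.0
        em = ExpressionMatrix(
            pd.DataFrame(vals, index=genes, columns=[f"S{j}" for j in range(10)]),
            "logCPM",
        )
        labels = pd.Series([CLASS_DOWN] * 5 + [CLASS_UP] * 5, index=em.sample_ids)
        panel = select_centroid_panel(em, labels, 8)
        assert {"D0", "D1"} <= set(panel)


class TestFitModel:
    def test_pure_cohort_converges_first_iteration(self, rng):
        cents = two_class_centroids(rng, n_genes=60)
        n_half = 6
        cols = {}
        for i in range(n_half):
            cols[f"D{i}"] = cents.profiles[CLASS_DOWN] + rng.normal(0, 1e-6, 60)
            cols[f"U{i}"] = cents.profiles[CLASS_UP] + rng.normal(0, 1e-6, 60)
        em = ExpressionMatrix(pd.DataFrame(cols), "logCPM")
        labels = pd.Series(
            [CLASS_DOWN if s.startswith("D") else CLASS_UP for s in em.sample_ids],
            index=em.sample_ids,
        )
        model = fit_model(em, labels, n_panel=30, purity_threshold=0.95)
        assert model.iterations == 1
        assert sorted(model.pure_samples[CLASS_DOWN]) == sorted(
            s for s in em.sample_ids if s.startswith("D")
        )

    def test_intermediates_excluded_from_pure_sets(self):
        cohort = simulate_cohort(
            SimulationParams(n_samples=60, n_genes=400, n_program_genes=100,
                             n_secondary_genes=0, noise_sd=0.1,
                             anchor_noise_sd=0.0, seed=23)
        )
        truth = cohort.truth["true_proportion"]
        labels = pd.Series(
            np.where(truth > 0.5, CLASS_UP, CLASS_DOWN), index=truth.index
        )
        model = fit_model(cohort.expression, labels, n_panel=80,
                          purity_threshold=0.9)
        pure = set(model.pure_samples[CLASS_DOWN]) | set(model.pure_samples[CLASS_UP])
        intermediates = set(truth.index[(truth > 0.35) & (truth < 0.65)])
        assert not (pure & intermediates)

    def test_recovered_centroids_near_truth(self):
        cohort = simulate_cohort(
            SimulationParams(n_samples=100, n_genes=800, n_program_genes=150,
                             n_secondary_genes=0, noise_sd=0.5, seed=29)
        )
        truth = cohort.truth["true_proportion"]
        labels = pd.Series(
            np.where(truth > 0.5, CLASS_UP, CLASS_DOWN), index=truth.index
        )
        model = fit_model(cohort.expression, labels, n_panel=150)
        true_c = cohort.centroids.profiles.loc[model.panel]
        err = (model.centroids.profiles - true_c).abs().mean().mean()
        assert err < 0.2

    def test_class_name_exchange_swaps_weights(self, small_cohort):
        truth = small_cohort.truth["true_proportion"]
        labels = pd.Series(
            np.where(truth > 0.5, CLASS_UP, CLASS_DOWN), index=truth.index
        )
        model = fit_model(small_cohort.expression, labels, n_panel=60)
        sub = small_cohort.expression.subset_genes(model.panel)
        w = estimate_weights_matrix(sub, model.centroids)
        flipped = ClassCentroids(
            model.centroids.profiles[[CLASS_UP, CLASS_DOWN]]
        )
        w2 = estimate_weights_matrix(sub, flipped)
        assert np.allclose(w.weights[CLASS_UP], w2.weights[CLASS_UP], atol=1e-12)

    def test_sample_order_invariance(self, small_cohort):
        truth = small_cohort.truth["true_proportion"]
        labels = pd.Series(
            np.where(truth > 0.5, CLASS_UP, CLASS_DOWN), index=truth.index
        )
        m1 = fit_model(small_cohort.expression, labels, n_panel=60)
        perm = list(reversed(small_cohort.expression.sample_ids))
        m2 = fit_model(small_cohort.expression.subset_samples(perm),
                       labels.loc[perm], n_panel=60)
        assert m1.panel == m2.panel
        assert np.allclose(m1.centroids.profiles, m2.centroids.profiles, atol=1e-12)


class TestClassifyAndBins:
    def make_weights(self, ups, ids=None):
        ids = ids or [f"S{i + 1:03d}" for i in range(len(ups))]
        ups = np.asarray(ups, dtype=float)
        w = pd.DataFrame({CLASS_DOWN: 1 - ups, CLASS_UP: ups}, index=ids)
        return MixtureWeights(w, pd.Series(0.0, index=ids))

    def test_above_cutoff_up(self):
        cls = classify(self.make_weights([0.7]))
        assert cls.iloc[0] == CLASS_UP

    def test_boundary_down_with_warning(self):
        with pytest.warns(UserWarning, match="cutoff"):
            cls = classify(self.make_weights([0.5]))
        assert cls.iloc[0] == CLASS_DOWN

    def test_eight_distinct_weights_even_bins(self):
        bins = quartile_bins(self.make_weights(np.linspace(0.1, 0.9, 8)))
        assert bins.value_counts().tolist() == [2, 2, 2, 2]
        # lowest weights in Q1
        assert bins["S001"] == "Q1" and bins["S008"] == "Q4"

    def test_five_samples_remainder_in_low_bin(self):
        bins = quartile_bins(self.make_weights([0.1, 0.2, 0.3, 0.4, 0.5]))
        counts = bins.value_counts()
        assert counts["Q1"] == 2
        assert counts["Q2"] == counts["Q3"] == counts["Q4"] == 1

    def test_bin_means_increase(self, rng):
        ups = rng.uniform(0, 1, 1000)
        mw = self.make_weights(ups)
        bins = quartile_bins(mw)
        means = mw.up_weight().groupby(bins).mean()
        assert list(means.index) == ["Q1", "Q2", "Q3", "Q4"]
        assert (np.diff(means.to_numpy()) > 0).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(DataFormatError, match=">= 4"):
            quartile_bins(self.make_weights([0.1, 0.5, 0.9]))

    def test_weight_validation(self):
        with pytest.raises(DataFormatError, match="sum to 1"):
            MixtureWeights(
                pd.DataFrame({CLASS_DOWN: [0.5], CLASS_UP: [0.6]}, index=["S1"]),
                pd.Series([0.0], index=["S1"]),
            )
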