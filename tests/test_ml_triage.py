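"""ML triage tests: descriptors, normalization, PCA, F-beta, KNN tuning,
training-set assembly."""

import numpy as np
import pytest

from panscreen import features as feat
from panscreen import knn as K
from panscreen.features import featurize, fit_pca, normalize
from panscreen.knn import (ClassImbalanceError, StratificationError,
                           build_training_set, fbeta, tune_knn)


class TestFeaturize:
    def test_homopolymer_frequencies(self):
        m, errors = featurize(["AAAA"])
        assert errors == []
        row = m.iloc[0]
        assert row["freq_A"] == 1.0
        assert all(row[f"freq_{aa}"] == 0.0 for aa in feat.AA_ORDER if aa != "A")
        assert row["length"] == 4

    def test_net_charge_of_polylysine(self):
        m, _ = featurize(["KKKK"])
        assert m.iloc[0]["net_charge"] == pytest.approx(4.0)

    def test_kyte_doolittle_mean(self):
        m, _ = featurize(["AI"])
        assert m.iloc[0]["hydropathy"] == pytest.approx((1.8 + 4.5) / 2)

    def test_aromaticity(self):
        m, _ = featurize(["FWYA"])
        assert m.iloc[0]["aromaticity"] == pytest.approx(0.75)

    def test_nonstandard_residue_recorded_as_error(self):
        m, errors = featurize(["AAAA", "AXAA", "KKKK"])
        assert errors == [(1, "AXAA")]
        assert list(m.index) == [0, 2]

    def test_cdr3_length_column(self):
        m, _ = featurize(["AAAA", "KKKK"], cdr3_lengths=[7, 9])
        assert list(m["cdr3_length"]) == [7.0, 9.0]
        assert m.shape[1] == 25


class TestNormalize:
    def test_population_zscore(self):
        import pandas as pd

        m = pd.DataFrame({"x": [1.0, 3.0]})
        z, stats = normalize(m)
        assert list(z["x"]) == [-1.0, 1.0]

    def test_constant_column_zeroed_and_flagged(self):
        import pandas as pd

        m = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": [5.0, 5.0, 5.0]})
        z, stats = normalize(m)
        assert stats.zero_variance == ["c"]
        assert (z["c"] == 0).all()

    def test_output_standardized(self):
        rng = np.random.default_rng(0)
        import pandas as pd

        m = pd.DataFrame(rng.normal(3, 2, size=(50, 4)))
        z, _ = normalize(m)
        assert np.allclose(z.mean(), 0, atol=1e-12)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-12)


class TestPca:
    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 5))
        proj = fit_pca(X, 5)
        Z = proj.transform(X)
        Xr = Z @ proj.components_ + X.mean(axis=0)
        assert np.allclose(Xr, X, atol=1e-8)

    def test_explained_variance_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6)) * np.arange(1, 7)
        proj = fit_pca(X, 4)
        evr = proj.explained_variance_ratio_
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 25)
        X = np.c_[t, 2 * t] + 1e-6 * np.random.default_rng(3).normal(size=(25, 2))
        proj = fit_pca(X, 2)
        assert proj.explained_variance_ratio_[0] >= 0.999

    def test_components_beyond_rank_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((10, 3)), 4)

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        c1 = fit_pca(X, 3).components_
        c2 = fit_pca(X.copy(), 3).components_
        assert np.allclose(c1, c2)
        for comp in c1:
            assert comp[np.abs(comp).argmax()] > 0


class TestFbeta:
    def test_perfect(self):
        for beta in (0.5, 1.0, 2.0):
            assert fbeta(1.0, 1.0, beta) == 1.0

    def test_balanced_half(self):
        assert fbeta(0.5, 0.5, 1.0) == pytest.approx(0.5)

    def test_precision_weighted(self):
        assert fbeta(1.0, 0.5, 0.5) == pytest.approx(1.25 * 0.5 / 0.75)

    def test_zero_denominator(self):
        assert fbeta(0.0, 0.0, 1.0) == 0.0

    def test_symmetric_only_at_beta_one(self):
        assert fbeta(0.8, 0.4, 1.0) == pytest.approx(fbeta(0.4, 0.8, 1.0))
        assert fbeta(0.8, 0.4, 2.0) != pytest.approx(fbeta(0.4, 0.8, 2.0))

    def test_recall_sensitivity_grows_with_beta(self):
        # dF/dR (finite difference) increases with beta at fixed interior P, R
        p, r, h = 0.6, 0.4, 1e-6
        slopes = [(fbeta(p, r + h, b) - fbeta(p, r - h, b)) / (2 * h)
                  for b in (0.5, 1.0, 2.0)]
        assert slopes[0] < slopes[1] < slopes[2]


class TestBuildTrainingSet:
    def test_simple_spr_only(self):
        spr = [(f"B{i}", True) for i in range(10)] + \
              [(f"N{i}", False) for i in range(10)]
        ts = build_training_set(spr_labels=spr)
        assert len(ts.sequences) == 20 and ts.labels.sum() == 10

    def test_conflict_resolved_to_binder(self):
        ts = build_training_set(spr_labels=[("S", False), ("X", False)],
                                round4_enriched=["S", "P"])
        assert ts.conflict_count == 1
        assert ts.labels[ts.sequences.index("S")] == 1

    def test_seeded_negative_draw_reproducible(self):
        library = [f"L{i}" for i in range(1000)]
        kwargs = dict(spr_labels=[("P", True)],
                      initial_library_sample=library,
                      neg_sample_size=100, seed=5)
        a = build_training_set(**kwargs)
        b = build_training_set(**kwargs)
        assert a.sequences == b.sequences and (a.labels == b.labels).all()
        assert sum(p == "library_background" for p in a.provenance) == 100

    def test_single_class_rejected(self):
        with pytest.raises(ClassImbalanceError):
            build_training_set(spr_labels=[("A", True), ("B", True)])


def _separable_training(n=120, seed=0):
    """Two compositional clusters: positives K/R-rich, negatives L/V-rich."""
    rng = np.random.default_rng(seed)
    seqs, labels = [], []
    for i in range(n):
        pos = i < n // 2
        alpha = list("KRED" if pos else "LVIA")
        seqs.append("".join(rng.choice(alpha, size=30)))
        labels.append(pos)
    return [(s, l) for s, l in zip(seqs, labels)]


class TestTuneKnn:
    def test_separable_fixture_perfect_fbeta(self):
        ts = build_training_set(spr_labels=_separable_training())
        model = tune_knn(ts, grid={"pca_components": (2, 5),
                                   "k_neighbors": (3, 5)}, cv_folds=3, seed=0)
        assert model.best_score == pytest.approx(1.0)

    def test_grid_of_one_point_selected(self):
        ts = build_training_set(spr_labels=_separable_training())
        model = tune_knn(ts, grid={"pca_components": (4,), "k_neighbors": (5,)},
                         cv_folds=3, seed=0)
        assert (model.pca_components, model.k_neighbors) == (4, 5)
        assert len(model.tuning_record) == 1

    def test_permuted_labels_collapse_to_prevalence(self):
        spr = _separable_training(n=120, seed=1)
        seqs = [s for s, _ in spr]
        labels = np.array([l for _, l in spr])
        prevalence = labels.mean()
        rng = np.random.default_rng(0)
        scores = []
        for _ in range(10):
            perm = rng.permutation(labels)
            ts = build_training_set(
                spr_labels=[(s, bool(l)) for s, l in zip(seqs, perm)])
            model = tune_knn(ts, grid={"pca_components": (2,),
                                       "k_neighbors": (3,)},
                             cv_folds=3, seed=0)
            scores.append(model.best_score)
        assert np.mean(scores) == pytest.approx(prevalence, abs=0.15)

    def test_even_k_rejected(self):
        ts = build_training_set(spr_labels=_separable_training())
        with pytest.raises(ValueError, match="odd"):
            tune_knn(ts, grid={"pca_components": (2,), "k_neighbors": (4,)})

    def test_too_few_class_members_stratification_error(self):
        import itertools

        negs = ["LLLL" + "".join(t)
                for t in itertools.product("LVIA", repeat=3)][:20]
        ts = build_training_set(
            spr_labels=[("KKKKK", True)] + [(s, False) for s in negs])
        with pytest.raises(StratificationError):
            tune_knn(ts, cv_folds=5, seed=0)

    def test_model_predicts_held_out(self):
        ts = build_training_set(spr_labels=_separable_training(seed=3))
        model = tune_knn(ts, grid={"pca_components": (2,), "k_neighbors": (3,)},
                         cv_folds=3, seed=0)
        rng = np.random.default_rng(9)
        pos = "".join(rng.choice(list("KRED"), size=30))
        neg = "".join(rng.choice(list("LVIA"), size=30))
        assert list(model.predict([pos, neg])) == [1, 0]
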