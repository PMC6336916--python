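"""Training-set assembly, PCA, network training, clustering, CV."""

import numpy as np
import pytest

from fcdsurf.classify import (ANNConfig, SubjectFeatures, TrainedDetector,
                              assemble_training_set, cross_validate,
                              fit_pca, predict_probability_map,
                              threshold_and_cluster, train_ann,
                              train_detector)
from fcdsurf.features import FeatureBundle
from fcdsurf.surface import (HomotopicCorrespondence, SurfaceScalarMap,
                             VertexLabel)
from fcdsurf.synthetic import icosphere

from conftest import flood_fill_oracle

FEATS = ["f1", "f2", "f3"]


def toy_subject(subject_id, seed, mesh, lesion_center=None, hemi="lh",
                effect=5.0):
    """A subject with standard-normal features and an optional additive
    lesion signature inside a 14 mm geodesic disc."""
    rng = np.random.default_rng(seed)
    n = mesh.n_vertices
    bundles = {}
    lesion = None
    for h in ("lh", "rh"):
        b = FeatureBundle(n_vertices=n)
        for name in FEATS:
            vals = rng.standard_normal(n)
            if lesion_center is not None and h == hemi:
                from fcdsurf.surface import geodesic_neighborhood
                nb = geodesic_neighborhood(mesh, lesion_center, 14.0)
                idx = np.array(sorted(nb))
                vals[idx] += effect
                lesion = VertexLabel(idx, "lesion")
            b.add(SurfaceScalarMap(vals, name))
        bundles[h] = b
    return SubjectFeatures(
        subject_id=subject_id, bundles=bundles,
        corr=HomotopicCorrespondence.identity(n),
        meshes={"lh": mesh, "rh": mesh},
        group="patient" if lesion_center is not None else "control",
        lesion_hemi=hemi if lesion_center is not None else None,
        lesion=lesion)


@pytest.fixture(scope="module")
def mesh30():
    return icosphere(2, 30.0)


class TestAssemble:
    def test_balanced_rows_from_homotopic_sampling(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40)
        df = assemble_training_set([subj], FEATS)
        n_lesion = len(subj.lesion)
        assert (df.label == 1).sum() == n_lesion
        assert (df.label == 0).sum() == n_lesion

    def test_negatives_come_from_contralateral_hemisphere(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40, hemi="lh")
        df = assemble_training_set([subj], FEATS)
        assert set(df[df.label == 0].hemisphere) == {"rh"}
        assert set(df[df.label == 1].hemisphere) == {"lh"}

    def test_dropping_feature_changes_width_not_rows(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40)
        full = assemble_training_set([subj], FEATS)
        narrow = assemble_training_set([subj], FEATS[:2])
        assert len(full) == len(narrow)
        assert full.shape[1] == narrow.shape[1] + 1

    def test_masked_rows_dropped_symmetrically(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40)
        les = subj.lesion.indices
        # mask one lesion vertex on lh and one homotopic partner on rh
        subj.bundles["lh"]["f1"].values[les[0]] = np.nan
        subj.bundles["rh"]["f2"].values[les[1]] = np.nan
        df = assemble_training_set([subj], FEATS)
        assert (df.label == 1).sum() == (df.label == 0).sum() \
            == len(les) - 2

    def test_empty_lesion_skipped_with_warning(self, mesh30):
        good = toy_subject("p0", 0, mesh30, lesion_center=40)
        bad = toy_subject("p1", 1, mesh30, lesion_center=41)
        bad.lesion = VertexLabel([], "lesion")
        with pytest.warns(UserWarning, match="p1"):
            df = assemble_training_set([good, bad], FEATS)
        assert set(df.subject) == {"p0"}


class TestPCA:
    def test_planar_data_recovers_rank_two(self):
        rng = np.random.default_rng(0)
        basis = rng.standard_normal((2, 5))
        X = rng.standard_normal((200, 2)) @ basis + rng.uniform(-1, 1, 5)
        pca = fit_pca(X, retained_variance=0.95)
        assert pca.n_components == 2
        scores = pca.transform(X)
        recon = scores @ pca.components_ + pca.mean_
        np.testing.assert_allclose(recon, X[:, pca.kept_columns],
                                   atol=1e-8)

    def test_full_variance_keeps_rank(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 4))
        assert fit_pca(X, retained_variance=1.0).n_components == 4

    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 6)) + 3
        pca = fit_pca(X, 0.95)
        np.testing.assert_allclose(pca.transform(X.mean(0)[None]), 0.0,
                                   atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((40, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            pca = fit_pca(X, 0.95)
        assert list(pca.kept_columns) == [0, 2]

    def test_orthonormal_basis(self):
        rng = np.random.default_rng(4)
        pca = fit_pca(rng.standard_normal((80, 6)), 0.99)
        G = pca.components_ @ pca.components_.T
        np.testing.assert_allclose(G, np.eye(pca.n_components), atol=1e-8)


class TestANN:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 200
        X0 = rng.standard_normal((n, 2))
        X1 = rng.standard_normal((n, 2)) + 6.0  # 6 sigma separation
        X = np.vstack([X0, X1])
        y = np.r_[np.zeros(n), np.ones(n)]
        return X, y

    def test_separable_blobs_high_test_accuracy(self):
        X, y = self._blobs()
        det = train_ann(X, y, ANNConfig(seed=0, max_epochs=200))
        assert det.metadata["test_accuracy"] >= 0.95

    def test_single_class_rejected(self):
        X, _ = self._blobs()
        with pytest.raises(ValueError, match="single class"):
            train_ann(X, np.zeros(len(X)), ANNConfig())

    def test_row_permutation_invariance(self):
        X, y = self._blobs()
        det1 = train_ann(X, y, ANNConfig(seed=3, max_epochs=100))
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(X))
        det2 = train_ann(X[perm], y[perm], ANNConfig(seed=3, max_epochs=100))
        for W1, W2 in zip(det1.weights, det2.weights):
            np.testing.assert_array_equal(W1, W2)

    def test_forward_matches_sklearn_oracle(self):
        # dual route: our stored-weight forward pass vs MLPClassifier
        from sklearn.neural_network import MLPClassifier
        X, y = self._blobs(1)
        rng = np.random.default_rng(0)
        clf = MLPClassifier(hidden_layer_sizes=(7,), activation="logistic",
                            solver="adam", max_iter=50, random_state=0)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        p = X.shape[1]
        from fcdsurf.classify import PCAModel
        det = TrainedDetector(
            feature_names=["a", "b"],
            pca=PCAModel(np.zeros(p), np.eye(p), np.ones(p) / p,
                         np.arange(p), 1.0),
            weights=[np.asarray(W) for W in clf.coefs_],
            biases=[np.asarray(b).ravel() for b in clf.intercepts_])
        np.testing.assert_allclose(det.predict_proba(X),
                                   clf.predict_proba(X)[:, 1], atol=1e-12)

    def test_save_load_round_trip(self, tmp_path):
        X, y = self._blobs(2)
        det = train_ann(X, y, ANNConfig(seed=1, max_epochs=60),
                        feature_names=["a", "b"])
        path = tmp_path / "det.npz"
        det.save(path)
        back = TrainedDetector.load(path)
        np.testing.assert_allclose(back.predict_proba(X),
                                   det.predict_proba(X), atol=1e-12)
        assert back.feature_names == ["a", "b"]


class TestProbabilityMaps:
    def test_range_and_mask_propagation(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40)
        df = assemble_training_set([subj], FEATS)
        det = train_detector(df[FEATS].to_numpy(), df.label.to_numpy(),
                             FEATS, 0.99, ANNConfig(seed=0, max_epochs=80))
        subj.bundles["lh"]["f1"].values[3] = np.nan
        pmap = predict_probability_map(det, subj.bundles["lh"])
        assert np.isnan(pmap.values[3])
        v = pmap.values[np.isfinite(pmap.values)]
        assert ((v >= 0) & (v <= 1)).all()

    def test_missing_feature_listed(self, mesh30):
        subj = toy_subject("p0", 0, mesh30, lesion_center=40)
        df = assemble_training_set([subj], FEATS)
        det = train_detector(df[FEATS].to_numpy(), df.label.to_numpy(),
                             FEATS, 0.99, ANNConfig(seed=0, max_epochs=40))
        del subj.bundles["lh"].maps["f2"]
        with pytest.raises(KeyError, match="f2"):
            predict_probability_map(det, subj.bundles["lh"])

    def test_lesion_probability_exceeds_background(self, mesh30):
        subjects = [toy_subject(f"p{i}", i, mesh30, lesion_center=30 + i)
                    for i in range(3)]
        df = assemble_training_set(subjects[:2], FEATS)
        det = train_detector(df[FEATS].to_numpy(), df.label.to_numpy(),
                             FEATS, 0.95, ANNConfig(seed=0))
        held = subjects[2]
        pmap = predict_probability_map(det, held.bundles["lh"])
        inside = held.lesion.to_mask(mesh30.n_vertices)
        assert (np.nanmean(pmap.values[inside]) >
                np.nanmean(pmap.values[~inside]))


class TestClustering:
    def test_all_subthreshold_empty(self, mesh30):
        pmap = SurfaceScalarMap(np.full(mesh30.n_vertices, 0.2), "p")
        assert threshold_and_cluster(pmap, mesh30, 0.5) == []

    def test_two_patches_match_flood_fill_oracle(self, mesh30):
        p = np.full(mesh30.n_vertices, 0.1)
        from fcdsurf.surface import geodesic_neighborhood
        patch_a = sorted(geodesic_neighborhood(mesh30, 0, 8.0))
        patch_b = sorted(geodesic_neighborhood(mesh30, 80, 6.0))
        assert not set(patch_a) & set(patch_b)
        p[patch_a] = 0.9
        p[patch_b] = 0.8
        pmap = SurfaceScalarMap(p, "p")
        clusters = threshold_and_cluster(pmap, mesh30, 0.5)
        assert len(clusters) == 2
        oracle = flood_fill_oracle(mesh30, p >= 0.5)
        got = sorted([set(c.vertices.tolist()) for c in clusters],
                     key=lambda s: min(s))
        assert got == sorted(oracle, key=lambda s: min(s))
        # sorted by descending peak probability
        assert clusters[0].peak_probability >= clusters[1].peak_probability
        assert set(clusters[0].vertices.tolist()) == set(patch_a)

    def test_min_area_filters_everything(self, mesh30):
        p = np.full(mesh30.n_vertices, 0.1)
        p[:3] = 0.9
        pmap = SurfaceScalarMap(p, "p")
        big = 10 * mesh30.total_area()
        assert threshold_and_cluster(pmap, mesh30, 0.5, min_area_mm2=big) \
            == []

    def test_invalid_threshold_rejected(self, mesh30):
        pmap = SurfaceScalarMap(np.zeros(mesh30.n_vertices), "p")
        with pytest.raises(ValueError):
            threshold_and_cluster(pmap, mesh30, 1.5)


class TestCrossValidation:
    def _cohort(self, mesh, n_pat=4, n_con=4):
        subs = [toy_subject(f"p{i}", i, mesh, lesion_center=20 + 7 * i)
                for i in range(n_pat)]
        subs += [toy_subject(f"c{i}", 100 + i, mesh) for i in range(n_con)]
        return subs

    def test_every_subject_held_out_once_per_iteration(self, mesh30):
        subs = self._cohort(mesh30)
        cv = cross_validate(subs, k=2, iterations=3, seed=0,
                            feature_names=FEATS,
                            ann_config=ANNConfig(max_epochs=60),
                            min_area_mm2=0.0)
        assert (cv.per_subject.times_held_out == 3).all()

    def test_same_seed_reproduces_everything(self, mesh30):
        subs = self._cohort(mesh30)
        kw = dict(k=2, iterations=2, seed=5, feature_names=FEATS,
                  ann_config=ANNConfig(max_epochs=60), min_area_mm2=0.0)
        cv1 = cross_validate(subs, **kw)
        cv2 = cross_validate(subs, **kw)
        assert cv1.fold_metrics.equals(cv2.fold_metrics)
        assert cv1.per_subject.equals(cv2.per_subject)

    def test_strong_effect_recovers_lesions(self, mesh30):
        subs = self._cohort(mesh30)
        cv = cross_validate(subs, k=2, iterations=2, seed=1,
                            feature_names=FEATS,
                            ann_config=ANNConfig(max_epochs=150),
                            min_area_mm2=0.0)
        assert cv.aggregate["accuracy_mean"] >= 0.8

    def test_too_few_patients_rejected(self, mesh30):
        subs = self._cohort(mesh30, n_pat=2, n_con=4)
        with pytest.raises(ValueError, match="k=5"):
            cross_validate(subs, k=5, iterations=1, feature_names=FEATS)
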