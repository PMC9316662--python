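"""Diagonal-GMM EM, BIC model selection and the recursive subtype tree."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from pansubtypes import clustering
from pansubtypes.clustering import (
    ClusterConfig,
    GmmModel,
    TreeNode,
    build_features,
    dominant_child_fraction,
    fit_gmm,
    label_samples,
    recursive_cluster,
    select_k_by_bic,
)
from pansubtypes.io_profiles import CohortMatrix


def cohort(counts, ctypes=None):
    df = pd.DataFrame(np.asarray(counts),
                      index=[f"S{i}" for i in range(len(counts))],
                      columns=[f"G{j}" for j in range(np.asarray(counts).shape[1])])
    ct = pd.Series(ctypes or ["CT1"] * len(df), index=df.index)
    return CohortMatrix(df, ct)


class TestBuildFeatures:
    def test_representations(self):
        m = cohort([[3, 0], [1, 2]])
        assert build_features(m, ["G0"], "counts").iloc[0, 0] == 3
        assert build_features(m, ["G0"], "binary").iloc[0, 0] == 1
        assert build_features(m, ["G0"], "log1p").iloc[0, 0] == pytest.approx(np.log(4))

    def test_empty_candidate_set_is_error(self):
        with pytest.raises(ValueError):
            build_features(cohort([[1]]), [])

    def test_column_order_follows_candidates(self):
        m = cohort([[1, 2, 3]])
        f = build_features(m, ["G2", "G0"], "counts")
        assert list(f.columns) == ["G2", "G0"]


class TestFitGmm:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(0)
        X = rng.normal(2.0, 1.5, size=(400, 3))
        model = fit_gmm(X, K=1, var_floor=1e-12)
        assert np.allclose(model.means[0], X.mean(axis=0))
        assert np.allclose(model.variances[0], X.var(axis=0))
        manual = stats.norm.logpdf(
            X, loc=X.mean(axis=0), scale=X.std(axis=0)).sum()
        assert model.log_likelihood == pytest.approx(manual, rel=1e-9)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0, 1, 200),
                            rng.normal(20, 1, 200)]).reshape(-1, 1)
        model = fit_gmm(X, K=2, seed=0, var_floor=1e-9)
        means = np.sort(model.means.ravel())
        assert abs(means[0] - 0) < 0.5 and abs(means[1] - 20) < 0.5
        resp = model.responsibilities(X)
        hard = resp.argmax(axis=1)
        truth = np.array([0] * 200 + [1] * 200)
        acc = max((hard == truth).mean(), (hard != truth).mean())
        assert acc >= 0.99

    def test_k_exceeding_samples_is_error(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((5, 2)), K=6)

    def test_em_loglik_is_monotone(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4)) + rng.integers(0, 2, (300, 1)) * 3
        model = fit_gmm(X, K=3, seed=1)
        assert np.all(np.diff(model.ll_trace) >= -1e-6)

    def test_responsibilities_match_brute_force_densities(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        model = fit_gmm(X, K=2, seed=0)
        resp = model.responsibilities(X)
        # direct density evaluation, independent of the model's own code path
        dens = np.stack([
            model.weights[k]
            * np.prod(stats.norm.pdf(X, model.means[k],
                                     np.sqrt(model.variances[k])), axis=1)
            for k in range(2)
        ], axis=1)
        brute = dens / dens.sum(axis=1, keepdims=True)
        assert np.allclose(resp, brute, atol=1e-9)
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-9)

    def test_agrees_with_sklearn_reference(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 1, (150, 3)),
                            rng.normal(6, 1, (150, 3))])
        ours = fit_gmm(X, K=2, seed=0, var_floor=1e-9)
        ref = GaussianMixture(2, covariance_type="diag", n_init=5,
                              random_state=0, reg_covar=1e-9).fit(X)
        assert adjusted_rand_score(ours.predict(X), ref.predict(X)) == 1.0
        assert ours.log_likelihood == pytest.approx(
            ref.score(X) * len(X), rel=1e-4)


class TestSelectK:
    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(500, 1))
        model, trace = select_k_by_bic(X, k_max=5, seed=0)
        assert model.K == 1
        assert set(trace.columns) >= {"K", "bic"}

    def test_three_separated_blobs_select_three(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(c, 1, (150, 2))
                            for c in (0, 10, 20)])
        model, _ = select_k_by_bic(X, k_max=6, seed=0, var_floor=1e-9)
        assert model.K == 3

    def test_exact_bic_tie_prefers_smaller_k(self, monkeypatch):
        def fake_fit(X, K, seed=0, **kw):
            return GmmModel(K, np.ones(K) / K, np.zeros((K, 1)),
                            np.ones((K, 1)), -10.0, -42.0, K)
        monkeypatch.setattr(clustering, "fit_gmm", fake_fit)
        model, _ = select_k_by_bic(np.zeros((50, 1)), k_max=4)
        assert model.K == 1


class TestRecursion:
    def test_planted_hierarchy_recovered(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([
            rng.normal([0, 0], 1, (150, 2)),
            rng.normal([25, 0], 1, (100, 2)),
            rng.normal([25, 12], 1, (100, 2)),
            rng.normal([25, 24], 1, (100, 2)),
        ])
        truth = np.repeat([0, 1, 2, 3], [150, 100, 100, 100])
        feats = pd.DataFrame(X, index=[f"S{i}" for i in range(len(X))])
        tree = recursive_cluster(feats, ClusterConfig(seed=0, var_floor=1e-6))
        labels = label_samples(tree)
        assert adjusted_rand_score(truth, labels) >= 0.9
        assert len(tree.leaves()) == 4

    def test_homogeneous_data_is_single_leaf(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(300, 3)),
                             index=[f"S{i}" for i in range(300)])
        tree = recursive_cluster(feats, ClusterConfig(seed=0))
        labels = label_samples(tree)
        assert set(labels) == {"C1"}

    def test_constructed_97_3_split_is_retained_as_leaf(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(0, 1, 776), rng.normal(60, 1, 24)])
        feats = pd.DataFrame(X.reshape(-1, 1),
                             index=[f"S{i}" for i in range(800)])
        tree = recursive_cluster(feats, ClusterConfig(seed=0, var_floor=1e-6))
        assert len(tree.leaves()) == 1
        assert tree.root.leaf_reason == "dominant_child"

    def test_leaves_partition_the_cohort(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 1, (120, 2)),
                            rng.normal(9, 1, (120, 2))])
        feats = pd.DataFrame(X, index=[f"S{i}" for i in range(240)])
        tree = recursive_cluster(feats, ClusterConfig(seed=0, var_floor=1e-6))
        seen = [s for leaf in tree.leaves() for s in leaf.sample_ids]
        assert sorted(seen) == sorted(feats.index)
        assert len(seen) == len(set(seen))

    def test_labels_are_deterministic_under_seed(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(0, 1, (100, 2)),
                            rng.normal(8, 1, (100, 2))])
        feats = pd.DataFrame(X, index=[f"S{i}" for i in range(200)])
        l1 = label_samples(recursive_cluster(feats, ClusterConfig(seed=7)))
        l2 = label_samples(recursive_cluster(feats, ClusterConfig(seed=7)))
        pd.testing.assert_series_equal(l1, l2)

    def test_depth_first_leaf_labels(self):
        rng = np.random.default_rng(5)
        X = np.concatenate([rng.normal(c, 1, (80, 1)) for c in (0, 10, 20)])
        feats = pd.DataFrame(X, index=[f"S{i}" for i in range(240)])
        tree = recursive_cluster(feats, ClusterConfig(seed=0, var_floor=1e-6))
        assert [leaf.label for leaf in tree.leaves()] == \
            [f"C{i+1}" for i in range(len(tree.leaves()))]

    def test_unfinalized_tree_is_error(self):
        node = TreeNode(id="1", sample_ids=["S0"], depth=0)
        tree = clustering.SubtypeTree(root=node, config=ClusterConfig())
        node.label = None
        with pytest.raises(ValueError):
            label_samples(tree)


def test_dominant_child_fraction():
    assert dominant_child_fraction([97, 3]) == pytest.approx(0.97)
    assert dominant_child_fraction([50, 50]) == pytest.approx(0.5)
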