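"""Fusion-core contracts: kernel formulas checked by hand, diffusion
invariants, spectral clustering and eigengap against block-graph oracles,
and label propagation behavior."""

import numpy as np
import pytest

from omicsfuse.core import AffinityMatrix, ClusterAssignment, ContractError, SNFHyperparams
from omicsfuse.snf import (
    affinity_matrix,
    eigengap_select,
    fuse_layers,
    propagate_labels,
    snf_fuse,
    spectral_cluster,
    standard_normalize,
)

from conftest import gaussian_layer


def block_affinity(sizes, strong=1.0, weak=1e-4, rng=None):
    """Block-diagonal affinity with optional jitter (still symmetric)."""
    n = sum(sizes)
    w = np.full((n, n), weak)
    start = 0
    labels = np.empty(n, dtype=int)
    for b, size in enumerate(sizes):
        w[start : start + size, start : start + size] = strong
        labels[start : start + size] = b + 1
        start += size
    if rng is not None:
        jitter = rng.uniform(0, 0.01 * strong, size=(n, n))
        w += (jitter + jitter.T) / 2
    np.fill_diagonal(w, strong)
    return AffinityMatrix([f"s{i}" for i in range(n)], w, SNFHyperparams(k=5), "raw"), labels


class TestNormalize:
    def test_rows_zero_mean_unit_sd_and_constant_rows_zeroed(self):
        rng = np.random.default_rng(0)
        values = rng.normal(2, 3, size=(20, 30))
        values[4] = 7.0
        out = standard_normalize(gaussian_layer(values))
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10
        sds = out.values.std(axis=1)
        assert np.abs(sds[sds > 0] - 1).max() < 1e-10
        assert np.all(out.values[4] == 0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        layer = gaussian_layer(rng.normal(size=(10, 15)))
        once = standard_normalize(layer)
        twice = standard_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)


class TestAffinity:
    def test_hand_computed_three_point_example(self):
        # samples at 0, 1, 10 on a line; k=1, mu=0.5
        layer = gaussian_layer(np.array([[0.0, 1.0, 10.0]]))
        aff = affinity_matrix(layer, SNFHyperparams(mu=0.5, k=1))
        w = aff.W
        # pair (0,1): eps = (1 + 1 + 1)/3 = 1 -> W = exp(-1/0.5) = e^-2
        assert w[0, 1] == pytest.approx(np.exp(-2.0), rel=1e-12)
        # pair (1,10): d=9, eps=(1+9+9)/3=19/3 -> exp(-81/(0.5*19/3))
        assert w[1, 2] == pytest.approx(np.exp(-81.0 / (0.5 * 19.0 / 3.0)), rel=1e-12)
        # pair (0,10): d=10, eps=(1+9+10)/3=20/3 -> exp(-100/(0.5*20/3))
        assert w[0, 2] == pytest.approx(np.exp(-100.0 / (0.5 * 20.0 / 3.0)), rel=1e-12)
        assert np.all(np.diag(w) == 1.0)

    def test_duplicate_samples_have_affinity_one(self):
        layer = gaussian_layer(np.array([[0.0, 0.0, 5.0], [1.0, 1.0, -2.0]]))
        aff = affinity_matrix(layer, SNFHyperparams(mu=0.5, k=1))
        assert aff.W[0, 1] == pytest.approx(1.0)

    def test_entries_in_unit_interval_and_monotone_in_distance(self):
        rng = np.random.default_rng(2)
        layer = gaussian_layer(rng.normal(size=(8, 25)))
        aff = affinity_matrix(layer, SNFHyperparams(mu=0.5, k=5))
        assert np.all(aff.W > 0) and np.all(aff.W <= 1)

    def test_k_too_large_rejected(self):
        layer = gaussian_layer(np.random.default_rng(0).normal(size=(4, 5)))
        with pytest.raises(ContractError):
            affinity_matrix(layer, SNFHyperparams(mu=0.5, k=5))


class TestFusion:
    def make_views(self, seed=3, n=40):
        rng = np.random.default_rng(seed)
        centers = np.array([0.0, 6.0])
        labels = np.array([0] * (n // 2) + [1] * (n // 2))
        views = []
        for _ in range(3):
            x = centers[labels][None, :] + rng.normal(size=(12, n))
            views.append(standard_normalize(gaussian_layer(x)))
        return views, labels + 1

    def test_identical_views_match_single_view_clustering(self):
        views, truth = self.make_views()
        params = SNFHyperparams(mu=0.5, k=8)
        affs = [affinity_matrix(views[0], params) for _ in range(3)]
        fused = snf_fuse(affs, params)
        from sklearn.metrics import adjusted_rand_score

        labels = spectral_cluster(fused, 2, 0).labels
        single = spectral_cluster(affs[0], 2, 0).labels
        assert adjusted_rand_score(labels, single) == 1.0
        assert adjusted_rand_score(labels, truth) == 1.0

    def test_fused_matrix_is_symmetric_nonnegative_near_row_stochastic(self):
        views, _ = self.make_views(seed=4)
        params = SNFHyperparams(mu=0.5, k=8)
        fused = snf_fuse([affinity_matrix(v, params) for v in views], params)
        assert np.max(np.abs(fused.W - fused.W.T)) < 1e-8
        assert np.all(fused.W >= 0)
        # each view's kernel is exactly row-stochastic; the final symmetrization
        # of their mean perturbs row sums only marginally
        np.testing.assert_allclose(fused.W.sum(axis=1), 1.0, atol=0.05)

    def test_view_kernels_stay_row_stochastic_and_identical_views_agree(self):
        views, _ = self.make_views(seed=4)
        params = SNFHyperparams(mu=0.5, k=8)
        from omicsfuse.snf import _global_kernel, _local_kernel

        w = affinity_matrix(views[0], params).W
        p = _global_kernel(w)
        s = _local_kernel(w, params.k)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-12)
        # with all views equal, diffusion keeps the per-view kernels identical
        ps = [p.copy() for _ in range(3)]
        for _ in range(5):
            new = []
            for v in range(3):
                others = sum(ps[u] for u in range(3) if u != v) / 2
                q = s @ others @ s.T
                new.append(_global_kernel((q + q.T) / 2.0))
            ps = new
            np.testing.assert_allclose(ps[0].sum(axis=1), 1.0, atol=1e-8)
        assert np.max(np.abs(ps[0] - ps[1])) < 1e-12

    def test_permutation_equivariance(self):
        views, _ = self.make_views(seed=5, n=20)
        params = SNFHyperparams(mu=0.5, k=5)
        fused = fuse_layers(views, params, normalize=False)
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        ids = views[0].sample_ids
        permuted_views = [v.subset_samples([ids[i] for i in perm]) for v in views]
        fused_p = fuse_layers(permuted_views, params, normalize=False)
        np.testing.assert_allclose(fused_p.W, fused.W[np.ix_(perm, perm)], atol=1e-10)

    def test_single_view_rejected_by_snf_fuse(self):
        views, _ = self.make_views(seed=6, n=20)
        params = SNFHyperparams(mu=0.5, k=5)
        with pytest.raises(ContractError):
            snf_fuse([affinity_matrix(views[0], params)], params)


class TestSpectral:
    def test_perfect_two_block_recovery(self):
        aff, truth = block_affinity([12, 8])
        out = spectral_cluster(aff, 2, 0)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(out.labels, truth) == 1.0
        assert set(out.labels) == {1, 2}
        # labels renumbered by descending size: cluster 1 is the 12-block
        assert (out.labels == 1).sum() == 12

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        aff, _ = block_affinity([10, 10, 10], rng=rng)
        a = spectral_cluster(aff, 3, 1).labels
        scaled = AffinityMatrix(aff.sample_ids, 7.3 * aff.W, aff.hyperparams, "raw")
        b = spectral_cluster(scaled, 3, 1).labels
        assert np.array_equal(a, b)

    def test_planted_four_cluster_recovery(self, processed_layers):
        layers, bundle, _ = processed_layers
        params = SNFHyperparams(mu=0.5, k=20)
        fused = fuse_layers(layers, params)
        out = spectral_cluster(fused, 4, 0)
        truth = bundle.true_clusters.loc[out.sample_ids].to_numpy()
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(out.labels, truth) >= 0.9


class TestEigengap:
    def brute_force_eigengap(self, aff, c_min=2, c_max=10):
        w = aff.W
        d = w.sum(axis=1)
        lam = np.sort(np.linalg.eigvals(np.eye(len(d)) - w / d[:, None]).real)
        gaps = [lam[c] - lam[c - 1] for c in range(c_min, c_max + 1)]
        return c_min + int(np.argmax(gaps))

    @pytest.mark.parametrize("sizes,expected", [([10, 10, 10, 10], 4), ([15, 15], 2)])
    def test_disconnected_blocks(self, sizes, expected):
        aff, _ = block_affinity(sizes, weak=0.0)
        assert eigengap_select(aff, 2, min(10, sum(sizes) - 1)) == expected

    def test_uniform_affinity_returns_c_min(self):
        n = 20
        aff = AffinityMatrix(
            [f"s{i}" for i in range(n)], np.ones((n, n)), SNFHyperparams(k=5), "raw"
        )
        assert eigengap_select(aff, 2, 10) == 2

    def test_agrees_with_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            sizes = rng.integers(5, 12, size=rng.integers(2, 5)).tolist()
            aff, _ = block_affinity(sizes, weak=1e-3, rng=rng)
            c_max = min(10, aff.n_samples - 1)
            assert eigengap_select(aff, 2, c_max) == self.brute_force_eigengap(aff, 2, c_max)


class TestPropagation:
    def test_duplicated_train_sample_gets_its_label(self):
        rng = np.random.default_rng(9)
        centers = np.array([0.0, 8.0])
        labels = np.array([1] * 10 + [2] * 10)
        x = centers[labels - 1][None, :] + rng.normal(size=(6, 20))
        train = gaussian_layer(x, prefix="f")
        test_vals = x[:, [0, 12]].copy()
        from omicsfuse.core import OmicsLayer

        test = OmicsLayer("protein", train.analyte_ids, ["t0", "t1"], test_vals, "log")
        assign = ClusterAssignment(train.sample_ids, labels, 2, "spectral")
        out = propagate_labels([train], [test], assign, SNFHyperparams(mu=0.5, k=5))
        got = dict(zip(out.sample_ids, out.labels))
        assert got["t0"] == 1 and got["t1"] == 2
        # train labels unchanged
        for s, l in zip(train.sample_ids, labels):
            assert got[s] == l
        assert out.source == "propagated"

    def test_holdout_agreement_on_separated_cohort(self, processed_layers):
        layers, bundle, _ = processed_layers
        params = SNFHyperparams(mu=0.5, k=20)
        full = spectral_cluster(fuse_layers(layers, params), 4, 0)
        ids = layers[0].sample_ids
        rng = np.random.default_rng(10)
        perm = rng.permutation(len(ids))
        n_tr = int(0.8 * len(ids))
        tr = [ids[i] for i in sorted(perm[:n_tr])]
        te = [ids[i] for i in sorted(perm[n_tr:])]
        tr_layers = [l.subset_samples(tr) for l in layers]
        te_layers = [l.subset_samples(te) for l in layers]
        tr_assign = spectral_cluster(fuse_layers(tr_layers, params), 4, 0)
        prop = propagate_labels(tr_layers, te_layers, tr_assign, params)
        from omicsfuse.predict import match_cluster_labels

        matched = match_cluster_labels(prop, full.restrict(tr))
        got = dict(zip(matched.sample_ids, matched.labels))
        ref = dict(zip(full.sample_ids, full.labels))
        agreement = np.mean([got[s] == ref[s] for s in te])
        assert agreement >= 0.9
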