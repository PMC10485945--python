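"""Strict-inequality filter boundaries, transform properties, PCA outlier
detection, LOD imputation, batch adjustment and variance-filter correctness."""

import numpy as np
import pytest

from omicsfuse.core import ContractError, OmicsLayer
from omicsfuse.preprocess import (
    batch_adjust,
    detect_pca_outliers,
    filter_low_expression,
    lod_filter_impute,
    normalize_transform,
    preprocess_bundle,
    top_variance_filter,
)

from conftest import gaussian_layer, trivial_sheet


def count_layer(rows, datatype="rna", ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"g{i}" for i in range(rows.shape[0])]
    return OmicsLayer(datatype, ids, [f"s{j}" for j in range(rows.shape[1])], rows, "count")


class TestCountFilters:
    def test_rna_total_count_boundary_is_strict(self):
        # 10 samples: totals 499 (dropped) and 500 (kept)
        layer = count_layer([[499] + [0] * 9, [500] + [0] * 9, [50] * 10])
        out, report = filter_low_expression(layer)
        # rows 0 and 1 both have 90% zeros -> also dropped; isolate totals:
        layer = count_layer([[49, 50, 50, 50, 50, 50, 50, 50, 50, 50],
                             [50] * 10])
        out, report = filter_low_expression(layer)
        assert out.analyte_ids == ["g1"]
        assert report.removed_analytes() == ["g0"]

    def test_rna_zero_fraction_boundary_is_strict(self):
        base = [100] * 100
        exactly_80 = [0] * 80 + [100] * 20  # total 2000, 80% zeros -> kept
        over_80 = [0] * 81 + [100] * 19  # 81% zeros -> dropped
        layer = count_layer([base, exactly_80, over_80])
        out, _ = filter_low_expression(layer)
        assert out.analyte_ids == ["g0", "g1"]

    def test_rna_exclusion_list_removed(self):
        layer = count_layer([[100] * 10, [100] * 10], ids=["XIST", "keepme"])
        out, _ = filter_low_expression(layer, exclusion_list={"XIST", "TSIX"})
        assert out.analyte_ids == ["keepme"]

    def test_mirna_mean_boundary_is_strict(self):
        layer = count_layer(
            [[9] * 9 + [18], [10] * 10, [9] * 10], datatype="mirna"
        )  # means 9.9, 10, 9
        out, _ = filter_low_expression(layer)
        assert out.analyte_ids == ["g1"]

    def test_non_count_layer_rejected(self):
        layer = gaussian_layer(np.ones((2, 4)), datatype="rna", scale="log")
        with pytest.raises(ContractError):
            filter_low_expression(layer)


class TestNormalizeTransform:
    def test_identical_samples_give_unit_size_factors(self):
        col = np.array([[4.0], [8.0], [0.0]])
        layer = count_layer(np.hstack([col] * 5))
        out = normalize_transform(layer)
        np.testing.assert_allclose(out.values, np.log2(np.hstack([col] * 5) + 1))
        assert out.values[2, 0] == 0.0  # count 0 -> exactly 0

    def test_doubled_sample_gets_doubled_size_factor(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(200, 6)).astype(float) + 1
        doubled = np.hstack([counts, 2 * counts[:, :1]])
        layer = count_layer(doubled)
        out = normalize_transform(layer)
        np.testing.assert_allclose(out.values[:, 6], out.values[:, 0], atol=0.05)

    def test_all_zero_sample_rejected(self):
        layer = count_layer([[1, 0], [2, 0]])
        with pytest.raises(ContractError, match="s1"):
            normalize_transform(layer)


class TestPCAOutliers:
    def test_homogeneous_data_flags_almost_nothing(self):
        rng = np.random.default_rng(1)
        layer = gaussian_layer(rng.normal(size=(50, 100)))
        assert len(detect_pca_outliers(layer)) <= 1

    def test_displaced_sample_is_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 60))
        direction = rng.normal(size=40)
        direction /= np.linalg.norm(direction)
        x[:, 7] += 10 * np.sqrt(40) * direction  # ~10 pooled SDs along one axis
        layer = gaussian_layer(x)
        assert detect_pca_outliers(layer) == {"s7"}

    def test_invariant_to_sign_flip_of_data(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 50))
        x[:, 3] += 3.0
        a = detect_pca_outliers(gaussian_layer(x))
        b = detect_pca_outliers(gaussian_layer(-x))
        assert a == b


class TestLODFilterImpute:
    def make_layer(self, frac_below, datatype="metabolite", n=100):
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 10, size=(len(frac_below), n))
        flags = np.zeros_like(values, dtype=bool)
        for i, f in enumerate(frac_below):
            flags[i, : int(round(f * n))] = True
        return OmicsLayer(
            datatype,
            [f"m{i}" for i in range(len(frac_below))],
            [f"s{j}" for j in range(n)],
            values,
            "linear" if datatype == "metabolite" else "log",
            lod_flags=flags,
        )

    def test_50_percent_boundary_is_strict(self):
        layer = self.make_layer([0.51, 0.50, 0.10])
        out, report = lod_filter_impute(layer)
        assert out.analyte_ids == ["m1", "m2"]
        assert report.removed_analytes() == ["m0"]

    def test_metabolite_imputed_to_minimum_measured(self):
        values = np.array([[1.0, 2.0, 5.0]])
        flags = np.array([[True, False, False]])
        layer = OmicsLayer("metabolite", ["m0"], ["s0", "s1", "s2"], values, "linear", flags)
        out, _ = lod_filter_impute(layer)
        np.testing.assert_allclose(out.values, [[2.0, 2.0, 5.0]])

    def test_protein_below_lod_used_as_is(self):
        values = np.array([[0.7, 2.0, 5.0]])
        flags = np.array([[True, False, False]])
        layer = OmicsLayer("protein", ["p0"], ["s0", "s1", "s2"], values, "log", flags)
        out, _ = lod_filter_impute(layer)
        np.testing.assert_allclose(out.values, values)


class TestBatchAdjust:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(4)
        layer = gaussian_layer(rng.normal(size=(30, 20)))
        sheet = trivial_sheet(layer.sample_ids)
        out = batch_adjust(layer, sheet)
        np.testing.assert_allclose(out.values, layer.values, atol=1e-8)

    def test_pure_shift_between_batches_removed(self):
        rng = np.random.default_rng(5)
        delta = 8.0
        x = rng.normal(size=(50, 200))
        x[:, 100:] += delta
        layer = gaussian_layer(x)
        sheet = trivial_sheet(layer.sample_ids, batch=["B1"] * 100 + ["B2"] * 100)
        out = batch_adjust(layer, sheet)
        diff = out.values[:, :100].mean(axis=1) - out.values[:, 100:].mean(axis=1)
        assert np.abs(diff).max() < 0.05 * delta

    def test_preserved_covariate_signal_survives(self):
        rng = np.random.default_rng(6)
        n = 60
        group = np.array(["control"] * 30 + ["severe_PE"] * 30)
        x = rng.normal(size=(80, n))
        effect = rng.normal(0, 1.5, size=80)
        x[:, group == "severe_PE"] += effect[:, None]
        batches = np.where(rng.random(n) < 0.5, "B1", "B2")
        x[:, batches == "B2"] += 2.0
        layer = gaussian_layer(x)
        sheet = trivial_sheet(layer.sample_ids, batch=list(batches), disease_group=list(group))
        out = batch_adjust(layer, sheet, preserve=["disease_group"])
        def group_diff(v):
            return v[:, group == "severe_PE"].mean(axis=1) - v[:, group == "control"].mean(axis=1)
        r = np.corrcoef(group_diff(layer.values), group_diff(out.values))[0, 1]
        assert r > 0.95

    def test_singleton_batch_rejected(self):
        rng = np.random.default_rng(7)
        layer = gaussian_layer(rng.normal(size=(10, 5)))
        sheet = trivial_sheet(layer.sample_ids, batch=["B1"] * 4 + ["B2"])
        with pytest.raises(ContractError, match="B2"):
            batch_adjust(layer, sheet)


class TestVarianceFilter:
    def test_quartile_count_is_exact(self):
        rng = np.random.default_rng(8)
        layer = gaussian_layer(rng.normal(size=(100, 30)) * rng.uniform(0.1, 3, (100, 1)))
        out = top_variance_filter(layer, 0.25)
        assert out.n_analytes == 25

    def test_matches_independent_sort_oracle(self):
        rng = np.random.default_rng(9)
        layer = gaussian_layer(rng.normal(size=(100, 30)) * rng.uniform(0.1, 3, (100, 1)))
        out = top_variance_filter(layer, 0.25)
        variances = layer.values.var(axis=1, ddof=1)
        oracle = set(
            sorted(layer.analyte_ids, key=lambda a: (-variances[layer.analyte_ids.index(a)], a))[
                :25
            ]
        )
        assert set(out.analyte_ids) == oracle

    def test_constant_analyte_never_beats_varying_one(self):
        values = np.vstack([np.zeros(10), np.random.default_rng(0).normal(size=(3, 10))])
        layer = gaussian_layer(values)
        out = top_variance_filter(layer, 0.25)  # keeps ceil(1) = 1
        assert "a0" not in out.analyte_ids

    def test_bad_quantile_rejected(self):
        layer = gaussian_layer(np.random.default_rng(0).normal(size=(4, 6)))
        with pytest.raises(ContractError):
            top_variance_filter(layer, 0.0)


class TestPipelineProperties:
    def test_order_equivariance_of_count_filter(self):
        rng = np.random.default_rng(10)
        counts = rng.poisson(40, size=(30, 12)).astype(float)
        counts[5] = 0  # will be dropped
        layer = count_layer(counts)
        out, _ = filter_low_expression(layer)
        perm = rng.permutation(30)
        permuted = OmicsLayer(
            "rna", [layer.analyte_ids[i] for i in perm], layer.sample_ids, counts[perm], "count"
        )
        out_p, _ = filter_low_expression(permuted)
        assert set(out_p.analyte_ids) == set(out.analyte_ids)

    def test_preprocess_bundle_is_pure(self, separated_cohort):
        _, bundle = separated_cohort
        kwargs = dict(preserve=["disease_group", "gestational_age"])
        a, _ = preprocess_bundle(bundle.layers, bundle.sheet, **kwargs)
        b, _ = preprocess_bundle(bundle.layers, bundle.sheet, **kwargs)
        for dt in a:
            np.testing.assert_array_equal(a[dt].values, b[dt].values)
            assert a[dt].analyte_ids == b[dt].analyte_ids

    def test_report_accounting_is_consistent(self, separated_cohort):
        _, bundle = separated_cohort
        layers, report = preprocess_bundle(
            bundle.layers, bundle.sheet, preserve=["disease_group", "gestational_age"]
        )
        removed = set(report.removed_analytes())
        for dt, layer in layers.items():
            assert removed.isdisjoint(layer.analyte_ids)
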