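"""GEM I/O and preprocessing: log2, KS outlier screen, quantile norm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from csgcn.gem import GEM, read_gem, write_gem
from csgcn.preprocess import (ks_outlier_flags, log2_transform,
                              preprocess_pipeline, quantile_normalize)


def _gem(mat, genes=None, samples=None, **kw):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return GEM(values=pd.DataFrame(mat, index=genes, columns=samples), **kw)


class TestIO:
    def test_round_trip_preserves_values(self, tmp_path):
        gem = _gem(np.random.default_rng(0).uniform(0, 100, (5, 4)))
        path = tmp_path / "gem.tsv"
        write_gem(gem, path)
        back = read_gem(path)
        assert back.gene_ids == gem.gene_ids
        assert back.sample_ids == gem.sample_ids
        np.testing.assert_allclose(back.matrix(), gem.matrix(), rtol=1e-9)

    def test_toy_tsv_parses(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text("gene_id\ts1\ts2\ngA\t1.5\t2\ngB\t3\t\n")
        gem = read_gem(path)
        assert gem.gene_ids == ["gA", "gB"]
        assert np.isnan(gem.values.loc["gB", "s2"])

    def test_duplicate_gene_id_errors_with_name(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene_id\ts1\ngA\t1\ngA\t2\n")
        with pytest.raises(ValueError, match="gA"):
            read_gem(path)

    def test_non_numeric_cell_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene_id\ts1\ngA\toops\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_gem(path)


class TestLog2:
    def test_known_values(self):
        gem = _gem([[8.0, 1.0], [0.5, 0.0]])
        out = log2_transform(gem).matrix()
        assert out[0, 0] == 3.0
        assert out[0, 1] == 0.0
        assert out[1, 0] == -1.0          # negatives retained
        assert np.isnan(out[1, 1])        # zero becomes missing

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_transform(_gem([[-1.0, 2.0]]))

    def test_strictly_monotone_on_positive_values(self, rng):
        vals = np.sort(rng.uniform(0.01, 50, 30))
        out = log2_transform(_gem(vals[:, None])).matrix().ravel()
        assert (np.diff(out) > 0).all()


class TestKS:
    def test_identical_distributions_not_flagged(self, rng):
        for seed in range(5):
            mat = np.random.default_rng(seed).normal(0, 1, (400, 10))
            report = ks_outlier_flags(_gem(mat))
            assert report.removed_samples == []

    def test_disjoint_support_sample_flagged_with_dval_one(self, rng):
        mat = rng.normal(0, 1, (200, 20))
        mat[:, 0] += 100  # shifted beyond the pooled range
        report = ks_outlier_flags(_gem(mat))
        assert report.dvals["s0"] == pytest.approx(1.0)
        assert report.removed_samples == ["s0"]

    def test_threshold_is_strictly_greater(self):
        mat = np.random.default_rng(1).normal(0, 1, (300, 5))
        report = ks_outlier_flags(_gem(mat))
        dmax = max(report.dvals.values())
        # flagging at threshold exactly equal to a sample's Dval must
        # leave that sample in (rule is Dval > threshold)
        report2 = ks_outlier_flags(_gem(mat), dval_threshold=dmax)
        assert report2.removed_samples == []

    def test_sample_with_too_few_values_errors(self):
        mat = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError, match="fewer than 2"):
            ks_outlier_flags(_gem(mat))


class TestQuantileNormalize:
    def test_hand_computed_two_columns(self):
        out = quantile_normalize(_gem([[1, 4], [2, 5], [3, 6]])).matrix()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        mat = np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]])
        out = quantile_normalize(_gem(mat)).matrix()
        np.testing.assert_allclose(out, mat, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(arrays(float, (6, 4), unique=True,
                  elements=st.floats(0, 100, allow_nan=False, width=32)))
    def test_sorted_columns_identical_and_idempotent(self, mat):
        # tie-free input: with ties the per-column sorted vectors may
        # legitimately differ (ties receive mean target quantiles)
        gem = _gem(np.asarray(mat, dtype=float))
        out = quantile_normalize(gem)
        m = out.matrix()
        ref = np.sort(m[:, 0])
        for j in range(1, m.shape[1]):
            np.testing.assert_allclose(np.sort(m[:, j]), ref, atol=1e-9)
        twice = quantile_normalize(out).matrix()
        np.testing.assert_allclose(twice, m, atol=1e-9)

    def test_rank_order_preserved_within_samples(self, rng):
        mat = rng.uniform(0, 10, (50, 5))
        out = quantile_normalize(_gem(mat)).matrix()
        for j in range(5):
            assert (np.argsort(out[:, j]) == np.argsort(mat[:, j])).all()

    def test_missing_entries_stay_missing(self, rng):
        mat = rng.uniform(0, 10, (20, 4))
        mat[3, 1] = np.nan
        out = quantile_normalize(_gem(mat)).matrix()
        assert np.isnan(out[3, 1])
        assert np.isfinite(np.delete(out.ravel(), 3 * 4 + 1)).all()


def test_pipeline_order_and_report(rng):
    mat = rng.lognormal(2, 1, (100, 8))
    mat[:, 2] *= 1e6  # gross outlier sample
    gem = _gem(mat)
    out, report = preprocess_pipeline(gem)
    assert report.steps_applied[0] == "log2"
    assert report.steps_applied[-1] == "quantile_normalize"
    assert "s2" in report.removed_samples
    assert "s2" not in out.sample_ids
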