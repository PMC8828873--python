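"""Normalization, probe collapsing, batch adjustment, signature intersection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sig32.errors import CoverageError, InputError
from sig32.preprocess import (
    batch_adjust,
    collapse_probes,
    intersect_signature,
    log2_quantile_normalize,
    quantile_normalize,
)


class TestQuantileNormalize:
    def test_hand_computed_3x2_oracle(self):
        probes = pd.DataFrame({"s1": [2.0, 4.0, 8.0], "s2": [8.0, 16.0, 32.0]})
        out = log2_quantile_normalize(probes)
        expected = pd.DataFrame({"s1": [2.0, 3.0, 4.0], "s2": [2.0, 3.0, 4.0]})
        pd.testing.assert_frame_equal(out, expected)

    def test_identical_columns_reduce_to_log2(self):
        col = [3.0, 1.5, 12.0, 7.0]
        probes = pd.DataFrame({"a": col, "b": col, "c": col})
        out = log2_quantile_normalize(probes)
        assert np.allclose(out.to_numpy(), np.log2(probes.to_numpy()))

    def test_columns_share_sorted_multiset(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.gamma(2.0, 50.0, size=(40, 6)))
        out = log2_quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 6):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(8, 2, size=(30, 5)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_ties_get_mean_of_tied_reference_values(self):
        # column a has a 3-way tie spanning ranks 1..3
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0, 9.0], "b": [1.0, 2.0, 3.0, 4.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert np.allclose(out["a"].to_numpy()[:3], ref[:3].mean())

    def test_non_positive_values_rejected_with_location(self):
        probes = pd.DataFrame({"s1": [2.0, -1.0]})
        with pytest.raises(InputError, match=r"\(1, 0\)"):
            log2_quantile_normalize(probes)

    def test_pseudocount_allows_zero(self):
        probes = pd.DataFrame({"s1": [0.0, 3.0], "s2": [1.0, 7.0]})
        out = log2_quantile_normalize(probes, pseudocount=1.0)
        assert np.isfinite(out.to_numpy()).all()

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 12), st.integers(2, 5), st.integers(0, 10_000))
    def test_multiset_property_random(self, n, m, seed):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(rng.normal(size=(n, m)))
        out = quantile_normalize(df)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, m):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref, atol=1e-12)


class TestCollapseProbes:
    def test_one_probe_per_gene_relabel(self):
        probes = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["p1", "p2"],
                              columns=["s1", "s2"])
        out = collapse_probes(probes, {"p1": "GA", "p2": "GB"})
        assert list(out.index) == ["GA", "GB"]
        assert np.allclose(out.to_numpy(), probes.to_numpy())

    def test_probe_mean(self):
        probes = pd.DataFrame([[1.0], [3.0]], index=["p1", "p2"], columns=["s1"])
        out = collapse_probes(probes, {"p1": "G", "p2": "G"})
        assert out.loc["G", "s1"] == 2.0

    def test_gene_with_missing_probe_dropped(self):
        probes = pd.DataFrame([[1.0, np.nan], [3.0, 4.0], [5.0, 6.0]],
                              index=["p1", "p2", "p3"], columns=["s1", "s2"])
        out = collapse_probes(probes, {"p1": "G1", "p2": "G1", "p3": "G2"})
        assert list(out.index) == ["G2"]
        assert not out.isna().any().any()

    def test_unmapped_probes_warn(self):
        probes = pd.DataFrame([[1.0], [2.0]], index=["p1", "px"], columns=["s"])
        with pytest.warns(UserWarning, match="unmapped"):
            out = collapse_probes(probes, {"p1": "G"})
        assert list(out.index) == ["G"]

    def test_empty_mapping_rejected(self):
        probes = pd.DataFrame([[1.0]], index=["p1"], columns=["s"])
        with pytest.raises(InputError):
            collapse_probes(probes, {})

    def test_collapse_commutes_with_subsetting(self):
        rng = np.random.default_rng(2)
        probes = pd.DataFrame(rng.normal(size=(6, 4)),
                              index=[f"p{i}" for i in range(6)])
        mapping = {f"p{i}": f"G{i // 2}" for i in range(6)}
        full = collapse_probes(probes, mapping).loc[["G0"]]
        sub = collapse_probes(probes.loc[["p0", "p1"]], {"p0": "G0", "p1": "G0"})
        pd.testing.assert_frame_equal(full, sub)


class TestBatchAdjust:
    @staticmethod
    def _cohorts(shift=0.0, scale=1.0, n=200, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(25)]
        a = pd.DataFrame(rng.normal(8, 1, size=(25, n)), index=genes,
                         columns=[f"a{i}" for i in range(n)])
        b = pd.DataFrame(shift + rng.normal(8, scale, size=(25, n)), index=genes,
                         columns=[f"b{i}" for i in range(n)])
        return a, b

    def test_single_batch_passthrough(self):
        a, _ = self._cohorts()
        out = batch_adjust([a], ["one"])
        corr = [np.corrcoef(out.loc[g], a.loc[g])[0, 1] for g in a.index]
        assert min(corr) > 0.999

    def test_mean_shift_removed(self):
        a, b = self._cohorts(shift=2.0, seed=1)
        out = batch_adjust([a, b], ["A", "B"])
        gap = out.loc[:, a.columns].mean(axis=1) - out.loc[:, b.columns].mean(axis=1)
        assert abs(gap.mean()) < 0.05

    def test_variance_ratio_removed(self):
        a, b = self._cohorts(scale=2.0, seed=2)
        out = batch_adjust([a, b], ["A", "B"])
        ratio = (out.loc[:, b.columns].var(axis=1) / out.loc[:, a.columns].var(axis=1)).mean()
        assert 0.8 < ratio < 1.25

    def test_grand_mean_preserved(self):
        a, b = self._cohorts(shift=1.0, seed=3)
        combined = pd.concat([a, b], axis=1)
        out = batch_adjust([a, b], ["A", "B"])
        assert np.allclose(out.mean(axis=1), combined.mean(axis=1), atol=1e-6)

    def test_singleton_batch_rejected(self):
        a, b = self._cohorts()
        with pytest.raises(InputError, match="fewer than 2"):
            batch_adjust([a, b.iloc[:, :1]], ["A", "B"])


class TestIntersectSignature:
    def test_all_present_in_signature_order(self):
        genes = [f"g{i}" for i in range(32)]
        df = pd.DataFrame(np.ones((32, 4)), index=list(reversed(genes)))
        out, missing = intersect_signature(df, genes)
        assert list(out.index) == genes and missing == []

    def test_partial_with_floor(self):
        df = pd.DataFrame(np.ones((1, 2)), index=["g2"])
        with pytest.warns(UserWarning):
            out, missing = intersect_signature(df, ["g1", "g2"], coverage_floor=0.5)
        assert list(out.index) == ["g2"] and missing == ["g1"]

    def test_coverage_floor_thresholds(self):
        genes = [f"g{i}" for i in range(32)]
        df31 = pd.DataFrame(np.ones((31, 2)), index=genes[:31])
        with pytest.warns(UserWarning):
            out, _ = intersect_signature(df31, genes, coverage_floor=0.8)
        assert out.shape[0] == 31  # 96.9% coverage passes
        df25 = pd.DataFrame(np.ones((25, 2)), index=genes[:25])
        with pytest.raises(CoverageError):
            intersect_signature(df25, genes, coverage_floor=0.8)
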