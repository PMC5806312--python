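"""Fold changes, the exact DE stand-in test, BH adjustment and the
threshold screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from rgene_evoscan.expression import (
    DEGRecord,
    bh_adjust,
    cross_pathogen_overlap,
    de_screen,
    heatmap_matrix,
    log_fold_change,
    screen_degs,
    simple_de_test,
)

from _oracles import bh_step_up


class TestLogFoldChange:
    def setup_method(self):
        self.m = pd.DataFrame(
            {"a1": [10, 0, 8], "a2": [10, 0, 8], "b1": [10, 15, 2],
             "b2": [10, 15, 2]},
            index=["flat", "up", "down"],
        )

    def test_equal_means_zero(self):
        lfc = log_fold_change(self.m, ["a1", "a2"], ["b1", "b2"])
        assert lfc["flat"] == 0.0

    def test_pseudocount_arithmetic(self):
        lfc = log_fold_change(self.m, ["a1", "a2"], ["b1", "b2"])
        assert lfc["up"] == pytest.approx(np.log2(16.0 / 1.0))

    def test_antisymmetry(self):
        fwd = log_fold_change(self.m, ["a1", "a2"], ["b1", "b2"])
        rev = log_fold_change(self.m, ["b1", "b2"], ["a1", "a2"])
        assert np.allclose(fwd, -rev)

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            log_fold_change(self.m, [], ["b1"])


class TestSimpleDeTest:
    def test_identical_counts_p_one(self):
        m = pd.DataFrame({"a": [5], "b": [5]}, index=["g"])
        p = simple_de_test(m, ["a"], ["b"])
        assert p["g"] == pytest.approx(1.0)

    def test_extreme_contrast_tiny_p(self):
        m = pd.DataFrame(
            {"a1": [0, 50], "a2": [0, 50], "a3": [0, 50],
             "b1": [100, 50], "b2": [100, 50], "b3": [100, 50]},
            index=["de", "bal"],
        )
        p = simple_de_test(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert p["de"] < 1e-6

    def test_null_p_values_super_uniform(self):
        rng = np.random.default_rng(17)
        counts = pd.DataFrame(
            rng.poisson(50, size=(400, 6)),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        p = simple_de_test(counts, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        # one-sided KS: the empirical CDF should not exceed the uniform
        d_plus = (
            np.arange(1, len(p) + 1) / len(p) - np.sort(p.to_numpy())
        ).max()
        assert d_plus < 1.63 / np.sqrt(len(p))  # ~alpha 0.01 critical value

    def test_zero_library_is_error(self):
        m = pd.DataFrame({"a": [0], "b": [5]}, index=["g"])
        with pytest.raises(ValueError):
            simple_de_test(m, ["a"], ["b"])


class TestBhAdjust:
    def test_hand_computed_vector(self):
        fdr = bh_adjust([0.01, 0.02, 0.04, 0.8])
        assert fdr == pytest.approx([0.04, 0.04, 0.0533333333, 0.8])

    def test_equal_p_unchanged(self):
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.07]) == pytest.approx([0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    def test_matches_textbook_step_up(self, pvals):
        assert bh_adjust(pvals) == pytest.approx(bh_step_up(pvals), abs=1e-12)


class TestScreen:
    def _series(self, lfc, fdr):
        idx = ["g"]
        return pd.Series([lfc], index=idx), pd.Series([fdr], index=idx)

    @pytest.mark.parametrize(
        "lfc,fdr,kept",
        [
            (2.0, 0.05, True),   # inclusive boundaries
            (1.9, 0.001, False),
            (-3.0, 0.01, True),
            (4.0, 0.051, False),
        ],
    )
    def test_threshold_boundaries(self, lfc, fdr, kept):
        out = screen_degs(*self._series(lfc, fdr))
        assert bool(out) is kept
        if kept and lfc < 0:
            assert out[0].direction == "down"

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(3)
        lfc = pd.Series(rng.normal(0, 3, 100))
        fdr = pd.Series(rng.uniform(0, 1, 100))
        strict = {d.gene_id for d in screen_degs(lfc, fdr, lfc_threshold=3,
                                                 fdr_threshold=0.01)}
        loose = {d.gene_id for d in screen_degs(lfc, fdr, lfc_threshold=2,
                                                fdr_threshold=0.05)}
        assert strict <= loose


class TestHeatmap:
    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(
            rng.poisson(30, (5, 4)).astype(float),
            index=[f"g{i}" for i in range(5)],
            columns=list("abcd"),
        )
        m.loc["g3"] = m.loc["g0"]
        ordered = heatmap_matrix(m, list(m.index))
        pos = {g: i for i, g in enumerate(ordered.index)}
        assert abs(pos["g0"] - pos["g3"]) == 1

    def test_contains_exactly_deg_rows(self):
        m = pd.DataFrame(
            np.arange(12).reshape(4, 3).astype(float),
            index=list("wxyz"), columns=list("abc"),
        )
        ordered = heatmap_matrix(m, ["x", "z"])
        assert sorted(ordered.index) == ["x", "z"]

    def test_empty_deg_set_warns(self):
        m = pd.DataFrame({"a": [1.0]}, index=["g"])
        with pytest.warns(UserWarning):
            out = heatmap_matrix(m, [])
        assert out.empty

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.poisson(30, (8, 5)).astype(float),
            index=[f"g{i}" for i in range(8)],
            columns=list("abcde"),
        )
        o1 = heatmap_matrix(m, list(m.index))
        o2 = heatmap_matrix(m, list(m.index))
        assert list(o1.index) == list(o2.index)


class TestOverlap:
    def _rec(self, gene, direction):
        return DEGRecord(gene, "c", 3.0 if direction == "up" else -3.0,
                         0.001, 0.01, direction)

    def test_disjoint_sets_empty(self):
        out = cross_pathogen_overlap(
            {"e1": [self._rec("a", "up")], "e2": [self._rec("b", "up")]}
        )
        assert out["up"] == set()

    def test_identical_sets_full(self):
        recs = [self._rec("a", "up"), self._rec("b", "down")]
        out = cross_pathogen_overlap({"e1": recs, "e2": list(recs)})
        assert out["up"] == {"a"} and out["down"] == {"b"}

    def test_planted_shared_genes_recovered(self):
        e1 = [self._rec(g, "up") for g in ("shared1", "shared2", "only1")]
        e2 = [self._rec(g, "up") for g in ("shared1", "shared2", "only2")]
        out = cross_pathogen_overlap({"e1": e1, "e2": e2})
        assert out["up"] == {"shared1", "shared2"}


def test_full_screen_composition():
    rng = np.random.default_rng(23)
    base = rng.lognormal(4, 0.5, 50)
    counts = pd.DataFrame(
        {
            "a1": rng.poisson(base),
            "a2": rng.poisson(base),
            "b1": rng.poisson(base),
            "b2": rng.poisson(base),
        },
        index=[f"g{i}" for i in range(50)],
    )
    counts.loc["g0", ["b1", "b2"]] = (base[0] * 20).astype(int)
    table, degs = de_screen(counts, ["a1", "a2"], ["b1", "b2"])
    assert "g0" in {d.gene_id for d in degs}
    assert all(abs(d.log_fc) >= 2 and d.fdr <= 0.05 for d in degs)
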