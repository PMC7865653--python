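"""Wilcoxon-Mann-Whitney, ROC with Youden cut-off, and BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from lesionrad.univariate import (
    fdr_adjust,
    roc_with_youden,
    univariate_table,
    wilcoxon_mw,
)

from oracles import wilcoxon_exact_brute, youden_brute


class TestWilcoxon:
    def test_separated_triples_exact(self):
        """A={1,2,3} vs B={4,5,6}: U=0 and the enumeration over C(6,3)=20
        assignments gives two-sided p = 2/20 = 0.1."""
        res = wilcoxon_mw([1, 2, 3], [4, 5, 6])
        assert res.u == 0
        assert res.exact
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_p_one(self):
        res = wilcoxon_mw([1, 2, 2, 3], [1, 2, 2, 3])
        assert res.p_value == 1.0

    def test_all_tied_p_one(self):
        assert wilcoxon_mw([5, 5, 5], [5, 5]).p_value == 1.0

    def test_large_shift_tiny_p(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(6, 1, 200)
        assert wilcoxon_mw(a, b).p_value < 1e-6

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_small_samples_match_enumeration_oracle(self, seed):
        """With ties and uneven group sizes, the exact path must agree with
        an independent enumeration."""
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 6))
        n_b = int(rng.integers(2, 7))
        a = rng.integers(0, 4, n_a).astype(float)
        b = rng.integers(0, 4, n_b).astype(float)
        res = wilcoxon_mw(a, b)
        assert res.exact
        assert res.p_value == pytest.approx(wilcoxon_exact_brute(a, b), abs=1e-12)


class TestRocYouden:
    def test_perfect_separation(self):
        s = roc_with_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert s.auc == 1.0
        assert s.sensitivity == 1.0 and s.specificity == 1.0 and s.accuracy == 1.0
        assert 3 < s.cutoff <= 10

    def test_four_point_hand_roc(self):
        """values {1,2,3,4}, labels {0,0,1,1}: AUC = 1 and the cut-off is
        the smallest observed value with J maximal, i.e. 3 (positives are
        called at value >= cutoff)."""
        s = roc_with_youden([1, 2, 3, 4], [0, 0, 1, 1])
        assert s.auc == 1.0
        assert s.cutoff == 3
        assert s.sensitivity == 1.0 and s.specificity == 1.0

    def test_null_auc_near_half(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.integers(0, 2, 2000)
        s = roc_with_youden(x, y)
        assert s.auc == pytest.approx(0.5, abs=0.05)

    def test_auc_equals_mann_whitney_u(self, rng):
        """Trapezoid AUC with midranks is U/(nA*nB) to 1e-12."""
        for _ in range(20):
            n1, n0 = rng.integers(5, 30, 2)
            x = np.r_[rng.normal(1, 1, n1), rng.normal(0, 1, n0)]
            x = np.round(x, 1)  # induce ties
            y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            res = wilcoxon_mw(x[y == 1], x[y == 0])
            auc_u = res.u / (n1 * n0)
            auc_u = max(auc_u, 1 - auc_u)  # summary is orientation-corrected
            s = roc_with_youden(x, y)
            assert s.auc == pytest.approx(auc_u, abs=1e-12)

    def test_youden_cutoff_matches_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 16))
            x = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            s = roc_with_youden(x, y)
            xo = x if s.orientation == "high" else -x
            j_best, spec_best, _ = youden_brute(xo, y)
            assert s.sensitivity + s.specificity - 1 == pytest.approx(j_best, abs=1e-12)
            assert s.specificity == pytest.approx(spec_best, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_with_youden([1, 2, 3], [1, 1, 1])

    def test_orientation_recorded_for_low_marker(self):
        s = roc_with_youden([4, 3, 2, 1], [0, 0, 1, 1])
        assert s.orientation == "low"
        assert s.auc == 1.0

    def test_bootstrap_ci_available(self, rng):
        x = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 30)]
        y = np.r_[np.ones(30, int), np.zeros(30, int)]
        s = roc_with_youden(x, y, ci_method="bootstrap", n_boot=200,
                            rng=np.random.default_rng(1))
        assert 0 <= s.auc_ci[0] <= s.auc <= s.auc_ci[1] <= 1


class TestFdr:
    def test_hand_example(self):
        adj = fdr_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(fdr_adjust([1.0, 1.0, 1.0]), [1, 1, 1])

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.random(50)
        adj = fdr_adjust(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)

    def test_monotone_in_raw_order(self, rng):
        p = rng.random(30)
        adj = fdr_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestUnivariateTable:
    def test_schema_and_flags(self, rng):
        n = 60
        idx = [f"P{i}" for i in range(n)]
        y = pd.Series(rng.integers(0, 2, n), index=idx)
        feats = pd.DataFrame(
            {
                "signal": y.to_numpy() * 2.0 + rng.normal(0, 0.5, n),
                "noise": rng.normal(0, 1, n),
            },
            index=idx,
        )
        tab = univariate_table(feats, y)
        assert set(tab.columns) >= {
            "auc", "auc_ci_low", "auc_ci_high", "cutoff", "sen", "spec",
            "ppv", "npv", "acc", "p_value", "p_adjusted", "significant",
        }
        assert tab.loc["signal", "significant"]
        assert tab.loc["signal", "auc"] > 0.9
        assert (tab["p_adjusted"] >= tab["p_value"] - 1e-15).all()
        assert ((tab["p_adjusted"] < 0.05) == tab["significant"]).all()
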