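import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cowas.io import ExpressionTable, PairSpec
from cowas.preprocess import (
    PreprocessError,
    QtlResult,
    ZeroVarianceError,
    adjust_pair,
    blom_transform,
    cis_window,
    hwe_pvalue,
    map_pqtls,
    qc_variants,
    screen_variants,
)
from tests.conftest import make_panel


class TestQcVariants:
    def test_common_variant_survives_maf_filter(self):
        # f = mean/2 = 0.375 -> MAF 0.375 >= 0.01
        panel = make_panel(np.array([[0], [0], [1], [2]], dtype=float))
        kept, report = qc_variants(panel, min_mac=0, min_maf=0.01)
        assert kept.variant_ids == ["rs0"]
        assert report.removed["maf"] == 0

    def test_palindromic_variant_removed(self):
        panel = make_panel(np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=float))
        object.__setattr__(panel.variants[1], "a1", "A")
        object.__setattr__(panel.variants[1], "a2", "T")
        kept, report = qc_variants(panel, min_mac=0, min_maf=0.0, hwe_p_min=0.0)
        assert report.removed["palindromic"] == 1
        assert kept.variant_ids == ["rs0"]

    def test_missingness_filter(self):
        col = np.ones((10, 1))
        col[:3, 0] = np.nan  # 30% missing > 10%
        panel = make_panel(np.hstack([col, np.tile([[0], [1]], (5, 1))]))
        kept, report = qc_variants(panel, min_mac=0, min_maf=0.0, hwe_p_min=0.0,
                                   drop_palindromic=False)
        assert report.removed["missingness"] == 1
        assert "rs0" not in kept.variant_ids

    def test_report_counts_reconcile(self):
        rng = np.random.default_rng(0)
        dosages = rng.binomial(2, rng.uniform(0.01, 0.5, 30), size=(200, 30)).astype(float)
        dosages[rng.random(dosages.shape) < 0.05] = np.nan
        panel = make_panel(dosages)
        _, report = qc_variants(panel, min_mac=10, min_maf=0.05)
        assert sum(report.removed.values()) + len(report.surviving_ids) == 30

    def test_fractional_dosages_skip_hwe(self):
        panel = make_panel(np.array([[0.5], [1.0], [1.5], [0.7]]))
        _, report = qc_variants(panel, min_mac=0, min_maf=0.0)
        assert report.hwe_skipped
        assert report.removed["hwe"] == 0


class TestHwe:
    @pytest.mark.parametrize(
        "counts, stat, p, tol",
        [
            ((25, 50, 25), 0.0, 1.0, 1e-12),
            ((30, 40, 30), 4.0, 0.0455002638963586, 1e-10),
            ((10, 0, 10), 20.0, 7.744216431e-06, 1e-12),
        ],
    )
    def test_known_values(self, counts, stat, p, tol):
        from scipy import stats

        assert hwe_pvalue(*counts) == pytest.approx(p, abs=tol)
        # back out the implied statistic to confirm the closed form
        implied = stats.chi2.isf(max(hwe_pvalue(*counts), 1e-300), 1)
        if stat > 0:
            assert implied == pytest.approx(stat, rel=1e-6)

    def test_monomorphic_returns_one(self):
        assert hwe_pvalue(10, 0, 0) == 1.0


class TestBlomTransform:
    def test_median_maps_to_zero_and_tail_value(self):
        out = blom_transform(np.array([5.0, 1.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[1] == pytest.approx(-0.8694237732888861, abs=1e-12)
        assert out[2] == pytest.approx(0.8694237732888861, abs=1e-12)

    def test_ties_averaged(self):
        np.testing.assert_allclose(blom_transform(np.array([2.0, 2.0])), 0.0, atol=1e-12)

    def test_missing_stays_missing(self):
        out = blom_transform(np.array([1.0, np.nan, 3.0, 2.0]))
        assert np.isnan(out[1])
        assert np.argsort(out[[0, 2, 3]]).tolist() == [0, 2, 1]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_ranks(self, values):
        arr = np.array(values)
        out = blom_transform(arr)
        np.testing.assert_array_equal(np.argsort(out), np.argsort(arr))

    def test_large_sample_mean_and_variance(self):
        x = np.random.default_rng(3).normal(size=10_000)
        out = blom_transform(x)
        assert abs(out.mean()) < 0.01
        assert out.std(ddof=1) == pytest.approx(1.0, abs=0.02)


class TestAdjustPair:
    def _pair(self):
        return PairSpec("pa", "pb", ("1", 100, 200), ("1", 300, 400))

    def test_orthogonal_covariates_are_noop(self):
        rng = np.random.default_rng(0)
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        expr = ExpressionTable([f"s{i}" for i in range(n)], ["pa", "pb"],
                               np.column_stack([a, b]))
        cov_raw = rng.normal(size=(n, 2))
        # orthogonalize covariates against the Blom-transformed phenotypes
        from cowas.preprocess import blom_transform as bt
        basis = np.column_stack([np.ones(n), bt(a), bt(b)])
        proj = basis @ np.linalg.lstsq(basis, cov_raw, rcond=None)[0]
        cov = pd.DataFrame(cov_raw - proj, index=expr.sample_ids, columns=["c1", "c2"])
        a_adj, b_adj, subset = adjust_pair(expr, cov, self._pair())
        bare_a, bare_b, _ = adjust_pair(expr, None, self._pair())
        np.testing.assert_allclose(a_adj, bare_a, atol=1e-10)
        np.testing.assert_allclose(b_adj, bare_b, atol=1e-10)

    def test_sample_missing_one_protein_excluded_from_both(self):
        vals = np.array([[1.0, 2.0], [2.0, np.nan], [3.0, 1.0], [0.5, 0.1],
                         [1.5, 2.5], [2.5, 0.4], [0.1, 1.1], [0.9, 3.0],
                         [1.1, 0.2], [2.2, 1.9], [0.3, 2.8]])
        expr = ExpressionTable([f"s{i}" for i in range(11)], ["pa", "pb"], vals)
        a_adj, b_adj, subset = adjust_pair(expr, None, self._pair())
        assert "s1" not in subset
        assert len(a_adj) == len(b_adj) == 10

    def test_covariate_equal_to_phenotype_flags_zero_variance(self):
        rng = np.random.default_rng(1)
        n = 100
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        expr = ExpressionTable([f"s{i}" for i in range(n)], ["pa", "pb"],
                               np.column_stack([a, b]))
        from cowas.preprocess import blom_transform as bt
        cov = pd.DataFrame({"c": bt(a)}, index=expr.sample_ids)
        with pytest.raises(ZeroVarianceError):
            adjust_pair(expr, cov, self._pair())

    def test_too_few_samples_errors(self):
        expr = ExpressionTable(["s0", "s1", "s2"], ["pa", "pb"],
                               np.arange(6, dtype=float).reshape(3, 2))
        with pytest.raises(PreprocessError, match="complete samples"):
            adjust_pair(expr, None, self._pair())


class TestMapPqtls:
    def test_beta_equals_pearson_correlation(self):
        rng = np.random.default_rng(2)
        panel = make_panel(rng.binomial(2, 0.3, size=(300, 10)).astype(float))
        y = rng.normal(size=300)
        y = (y - y.mean()) / y.std(ddof=1)
        qtl = map_pqtls(panel, y)
        from cowas.preprocess import standardize_dosages
        Xs, _ = standardize_dosages(panel.dosages)
        expected = np.array([np.corrcoef(Xs[:, j], y)[0, 1] for j in range(10)])
        np.testing.assert_allclose(qtl.table["beta"].to_numpy(), expected, atol=1e-10)

    def test_perfect_association(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(2, 0.4, size=200).astype(float)
        panel = make_panel(x[:, None])
        from cowas.preprocess import standardize_dosages
        y = standardize_dosages(x[:, None])[0][:, 0]
        qtl = map_pqtls(panel, y)
        assert qtl.table["beta"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        assert qtl.table["p"].iloc[0] < 1e-100

    def test_null_calibration(self):
        rng = np.random.default_rng(4)
        panel = make_panel(rng.binomial(2, 0.3, size=(400, 1000)).astype(float))
        y = rng.normal(size=400)
        qtl = map_pqtls(panel, (y - y.mean()) / y.std(ddof=1))
        frac = (qtl.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_zero_variance_variant_flagged(self):
        panel = make_panel(np.column_stack([np.ones(50), np.tile([0.0, 1.0], 25)]))
        y = np.random.default_rng(5).normal(size=50)
        qtl = map_pqtls(panel, y)
        assert bool(qtl.table["excluded"].iloc[0])
        assert np.isnan(qtl.table["beta"].iloc[0])


class TestCisWindowAndScreening:
    def test_window_arithmetic_and_clamp(self):
        assert cis_window(("chr1", 1_200_000, 1_250_000)) == ("chr1", 700_000, 1_750_000)
        assert cis_window(("chr2", 100_000, 200_000))[1] == 1

    def _qtl(self, rows):
        table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "beta", "se", "p"])
        table["excluded"] = False
        return QtlResult("prot", table)

    def test_pvalue_ranking_and_k(self):
        qtl = self._qtl([("v1", "1", 10, 0.1, 0.1, 0.5),
                         ("v2", "1", 20, 0.1, 0.1, 0.01),
                         ("v3", "1", 30, 0.1, 0.1, 0.2)])
        assert screen_variants(qtl, "pvalue", k=2) == ["v2", "v3"]

    def test_effect_ranking_uses_absolute_value(self):
        qtl = self._qtl([("v1", "1", 10, 0.1, 0.1, 0.5),
                         ("v2", "1", 20, -0.4, 0.1, 0.5),
                         ("v3", "1", 30, 0.2, 0.1, 0.5)])
        assert screen_variants(qtl, "effect", k=1) == ["v2"]

    def test_tie_break_by_position_and_row_order_invariance(self):
        rows = [("vB", "1", 50, 0.1, 0.1, 0.2), ("vA", "1", 10, 0.1, 0.1, 0.2)]
        qtl_fwd = self._qtl(rows)
        qtl_rev = self._qtl(rows[::-1])
        assert screen_variants(qtl_fwd, "pvalue", k=2) == ["vA", "vB"]
        assert screen_variants(qtl_fwd, "pvalue", k=2) == screen_variants(qtl_rev, "pvalue", k=2)

    def test_cis_boundary_inclusive_and_empty_window_errors(self):
        qtl = self._qtl([("v1", "chr1", 700_000, 0.1, 0.1, 0.5)])
        win = cis_window(("chr1", 1_200_000, 1_250_000))
        assert screen_variants(qtl, "pvalue", cis_only=True, window=win) == ["v1"]
        far = cis_window(("chr2", 1_200_000, 1_250_000))
        with pytest.raises(PreprocessError, match="chr2"):
            screen_variants(qtl, "pvalue", cis_only=True, window=far)
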