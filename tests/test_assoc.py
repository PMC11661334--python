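import numpy as np
import pandas as pd
import pytest

from cowas import SimConfig, simulate_dataset
from cowas.assoc import (
    AssociationError,
    LdMatrix,
    bonferroni,
    compute_ld,
    global_f_from_rss,
    harmonize,
    pwas_summary,
    stage2_individual,
    stage2_summary,
    wald_pvalue,
    z_to_beta,
)
from cowas.io import GwasSummary, VariantInfo, WeightSet
from tests.conftest import make_panel


def _gwas(rows):
    return GwasSummary(pd.DataFrame(rows, columns=["id", "a1", "a2", "z", "n"]))


class TestHarmonize:
    def _panel_variants(self):
        return [VariantInfo("rs1", "1", 100, "A", "G")]

    def test_identity_orientation_keeps_z(self):
        z, n, kept = harmonize(_gwas([("rs1", "A", "G", -1.3, 100)]), self._panel_variants())
        assert z[0] == -1.3 and kept == ["rs1"]

    def test_swapped_alleles_negate_z(self):
        z, _, _ = harmonize(_gwas([("rs1", "G", "A", 2.0, 100)]), self._panel_variants())
        assert z[0] == -2.0

    def test_strand_complement_matches(self):
        # panel A/G; GWAS reports T/C = complement of A/G -> same orientation
        z, _, _ = harmonize(_gwas([("rs1", "T", "C", 1.5, 100)]), self._panel_variants())
        assert z[0] == 1.5

    def test_incompatible_alleles_dropped(self):
        variants = [VariantInfo("rs1", "1", 100, "A", "C"),
                    VariantInfo("rs2", "1", 110, "A", "G")]
        gwas = _gwas([("rs1", "A", "G", 1.0, 100), ("rs2", "A", "G", 0.5, 100)])
        z, _, kept = harmonize(gwas, variants)
        assert kept == ["rs2"]

    def test_complement_of_swapped_orientation_flips(self):
        # panel A/C; GWAS G/T is the strand complement of the swapped pair C/A
        variants = [VariantInfo("rs1", "1", 100, "A", "C")]
        z, _, kept = harmonize(_gwas([("rs1", "G", "T", 1.0, 100)]), variants)
        assert kept == ["rs1"] and z[0] == -1.0

    def test_double_flip_is_involution(self):
        rng = np.random.default_rng(0)
        variants = [VariantInfo(f"rs{j}", "1", 100 + j, "A", "G") for j in range(20)]
        z0 = rng.normal(size=20)
        fwd = _gwas([(v.id, "G", "A", z, 200) for v, z in zip(variants, z0)])
        z1, _, _ = harmonize(fwd, variants)
        back = _gwas([(v.id, "G", "A", z, 200) for v, z in zip(variants, z1)])
        z2, _, _ = harmonize(back, variants)
        np.testing.assert_array_equal(z2, z0)


class TestComputeLd:
    def test_duplicated_variant_column_gives_unit_correlation(self):
        col = np.array([0.0, 1, 2, 1, 0, 2, 1, 0])
        panel = make_panel(np.column_stack([col, col]))
        ld = compute_ld(panel)
        assert ld.matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_independent_variants_have_small_correlations(self):
        rng = np.random.default_rng(1)
        panel = make_panel(rng.binomial(2, 0.3, size=(10_000, 20)).astype(float))
        ld = compute_ld(panel)
        off = ld.matrix[~np.eye(20, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_two_samples_give_degenerate_unit_correlation(self):
        panel = make_panel(np.array([[0.0, 1.0], [2.0, 0.0]]))
        ld = compute_ld(panel)
        assert abs(ld.matrix[0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_variant_errors_by_name(self):
        panel = make_panel(np.column_stack([np.ones(10), np.tile([0.0, 1], 5)]))
        with pytest.raises(AssociationError, match="rs0"):
            compute_ld(panel)


class TestScalarHelpers:
    def test_z_to_beta_values(self):
        assert z_to_beta(0.0, 100) == 0.0
        assert z_to_beta(3.0, 102) == pytest.approx(0.2873478855663454, abs=1e-12)
        with pytest.raises(AssociationError):
            z_to_beta(1.0, 2)

    def test_z_to_beta_round_trip_through_ols(self):
        rng = np.random.default_rng(2)
        n = 500
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        y = (y - y.mean()) / y.std(ddof=1)
        r = float(x @ y / (n - 1))
        z = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
        assert z_to_beta(z, n) == pytest.approx(r, abs=1e-10)

    def test_wald_pvalues(self):
        assert wald_pvalue(0.0, 1.0) == 1.0
        assert wald_pvalue(1.959964, 1.0) == pytest.approx(0.05, abs=1e-4)
        assert wald_pvalue(10.0, 1.0) < 1e-22
        with pytest.raises(AssociationError):
            wald_pvalue(1.0, 0.0)

    def test_global_f_closed_form(self):
        assert global_f_from_rss(103.0, 51.5, 104) == pytest.approx(100 / 3, rel=1e-12)


def _simulated_weights(ds):
    """Arbitrary nonzero weights over the simulated panel's variants."""
    rng = np.random.default_rng(99)
    p = ds.panel2.n_variants
    W = np.zeros((p, 3))
    W[rng.choice(p, 5, replace=False), 0] = rng.normal(size=5)
    W[rng.choice(p, 5, replace=False), 1] = rng.normal(size=5)
    W[rng.choice(p, 8, replace=False), 2] = rng.normal(size=8)
    return WeightSet("PROT_A__PROT_B", list(ds.panel2.variants), W[:, 0], W[:, 1], W[:, 2])


class TestStage2:
    def test_null_summary_input_gives_null_result(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        gwas = GwasSummary(ds.gwas.table.assign(z=0.0))
        ld = compute_ld(ds.panel2, ws.union_variant_ids)
        res = stage2_summary(gwas, ld, ws)
        assert res.theta_a == res.theta_b == res.theta_co == 0.0
        assert res.f_stat == 0.0
        assert res.p_global == 1.0

    def test_summary_matches_individual_on_in_sample_ld(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        ld = compute_ld(ds.panel2, ws.union_variant_ids)
        res_s = stage2_summary(ds.gwas, ld, ws)
        res_i = stage2_individual(ds.panel2, ds.y, ws)
        assert res_s.theta_a == pytest.approx(res_i.theta_a, abs=1e-6)
        assert res_s.theta_b == pytest.approx(res_i.theta_b, abs=1e-6)
        assert res_s.theta_co == pytest.approx(res_i.theta_co, abs=1e-6)
        assert res_s.p_global == pytest.approx(res_i.p_global, abs=1e-4)
        assert res_s.p_co == pytest.approx(res_i.p_co, abs=1e-4)

    def test_constant_coexpression_predictor_is_collinear(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        ws.w_co[:] = 0.0
        res = stage2_individual(ds.panel2, ds.y, ws)
        assert res.status == "collinear"
        assert np.isnan(res.theta_co)

    def test_scale_invariance_of_tests(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        ld = compute_ld(ds.panel2, ws.union_variant_ids)
        base = stage2_summary(ds.gwas, ld, ws)
        scaled = WeightSet(ws.pair_id, ws.union_variants, ws.w_a, ws.w_b, ws.w_co * 7.5)
        res = stage2_summary(ds.gwas, ld, scaled)
        assert res.theta_co == pytest.approx(base.theta_co / 7.5, rel=1e-10)
        assert res.p_co == pytest.approx(base.p_co, rel=1e-10)
        assert res.p_global == pytest.approx(base.p_global, rel=1e-10)

    def test_training_overlap_warns(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        with pytest.warns(UserWarning, match="overlap"):
            stage2_individual(ds.panel2, ds.y, ws,
                              training_sample_ids=ds.panel2.sample_ids[:5])


class TestPwas:
    def test_single_variant_identity(self):
        panel = make_panel(
            np.random.default_rng(0).binomial(2, 0.4, size=(500, 1)).astype(float)
        )
        ld = compute_ld(panel)
        b = 0.1
        n = 10_000
        z = b * np.sqrt(n - 2) / np.sqrt(1 - b**2)  # invert z_to_beta
        gwas = _gwas([("rs0", panel.variants[0].a1, panel.variants[0].a2, z, n)])
        res = pwas_summary(gwas, ld, np.array([1.0]), panel.variants, "prot")
        assert res.theta == pytest.approx(0.1, abs=1e-10)

    def test_matches_three_column_machinery_with_columns_removed(self, small_dataset):
        ds = small_dataset
        ws = _simulated_weights(ds)
        ld = compute_ld(ds.panel2, ws.union_variant_ids)
        res = pwas_summary(ds.gwas, ld, ws.w_a, ws.union_variants, "PROT_A")
        # independent one-column computation from the same ingredients
        from cowas.assoc import harmonize as _harm, z_to_beta as _z2b
        z, n_vec, kept = _harm(ds.gwas, ws.union_variants)
        keep = [i for i, v in enumerate(ws.union_variants) if v.id in set(kept)]
        w = ws.w_a[keep]
        sigma = ld.subset(kept).matrix
        b = _z2b(z, n_vec)
        s = float(w @ sigma @ w)
        theta = float(w @ b) / s
        assert res.theta == pytest.approx(theta, abs=1e-12)

    def test_all_zero_weights_fail(self, small_dataset):
        ds = small_dataset
        ld = compute_ld(ds.panel2)
        res = pwas_summary(ds.gwas, ld, np.zeros(ds.panel2.n_variants),
                           list(ds.panel2.variants), "prot")
        assert res.status == "failed"


class TestBonferroni:
    def test_threshold_for_613_pairs(self):
        flags, threshold = bonferroni(np.full(613, 0.5), alpha=0.05)
        assert threshold == pytest.approx(8.157e-5, rel=1e-3)
        assert not flags.any()

    def test_single_test_threshold_is_alpha(self):
        flags, threshold = bonferroni(np.array([0.04]), alpha=0.05)
        assert threshold == 0.05
        assert flags[0]

    def test_failed_entries_excluded_from_family_size(self):
        p = np.array([0.02, np.nan, np.nan, np.nan])
        flags, threshold = bonferroni(p, alpha=0.05)
        assert threshold == 0.05
        assert flags.tolist() == [True, False, False, False]


def test_ld_matrix_validation_rejects_asymmetry():
    with pytest.raises(AssociationError, match="symmetric"):
        LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
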