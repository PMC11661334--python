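"""Stage 2: joint association testing of direct and co-expression effects.

Given stage-1 weights, the three genetically imputed predictors
A_hat = Z w_A, B_hat = Z w_B, C_hat = Z w_co are regressed against the trait.
This can be done on individual-level data (OLS) or reconstructed from GWAS
summary statistics plus an LD reference: with W the p x 3 padded weight
matrix, Sigma the variant correlation matrix, and b the standardized
marginal effect vector, theta_hat = (W' Sigma W)^-1 W' b. The two routes are
algebraically identical when Sigma and b come from the GWAS sample itself.

Primary tests: the interaction Wald test of theta_co (chi-square, 1 df) and
the global F test of all three coefficients against an intercept-only model,
F ~ F(3, n2 - 4) under the null. Per-coefficient tests for theta_A and
theta_B are reported as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel, GwasSummary, VariantInfo, WeightSet
from .preprocess import standardize_dosages

__all__ = [
    "LdMatrix",
    "CowasResult",
    "PwasResult",
    "harmonize",
    "compute_ld",
    "stage2_individual",
    "stage2_summary",
    "z_to_beta",
    "wald_pvalue",
    "global_f_from_rss",
    "pwas_summary",
    "bonferroni",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_COND_MAX = 1e8


class AssociationError(ValueError):
    pass


@dataclass
class LdMatrix:
    """Pairwise variant correlation matrix from a reference panel."""

    variant_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        p = len(self.variant_ids)
        if self.matrix.shape != (p, p):
            raise AssociationError(f"LD matrix shape {self.matrix.shape} != ({p}, {p})")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise AssociationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-12):
            raise AssociationError("LD matrix diagonal must be 1")
        eigmin = float(np.linalg.eigvalsh(self.matrix).min())
        if eigmin < -1e-8:
            raise AssociationError(f"LD matrix has negative eigenvalue {eigmin:.3g}")

    def subset(self, ids: list[str]) -> "LdMatrix":
        index = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in ids if v not in index]
        if missing:
            raise AssociationError(f"variant {missing[0]!r} absent from LD matrix")
        idx = np.array([index[v] for v in ids])
        return LdMatrix(list(ids), self.matrix[np.ix_(idx, idx)])


@dataclass
class CowasResult:
    pair_id: str
    theta_a: float = float("nan")
    theta_b: float = float("nan")
    theta_co: float = float("nan")
    se_a: float = float("nan")
    se_b: float = float("nan")
    se_co: float = float("nan")
    p_a: float = float("nan")
    p_b: float = float("nan")
    p_co: float = float("nan")
    f_stat: float = float("nan")
    p_global: float = float("nan")
    r2: float = float("nan")
    n2: int = 0
    mode: str = "residual"
    status: str = "ok"

    def to_dict(self) -> dict:
        return {
            "pair_id": self.pair_id,
            "theta_a": self.theta_a, "se_a": self.se_a, "p_a": self.p_a,
            "theta_b": self.theta_b, "se_b": self.se_b, "p_b": self.p_b,
            "theta_co": self.theta_co, "se_co": self.se_co, "p_co": self.p_co,
            "f_stat": self.f_stat, "p_global": self.p_global,
            "r2": self.r2, "n2": self.n2, "mode": self.mode, "status": self.status,
        }


@dataclass
class PwasResult:
    protein_id: str
    theta: float = float("nan")
    se: float = float("nan")
    p: float = float("nan")
    n2: int = 0
    status: str = "ok"


def harmonize(
    gwas: GwasSummary, panel_variants: list[VariantInfo]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align GWAS Z scores to the panel's effect alleles.

    Matching (a1, a2) keeps Z; swapped alleles negate it; strand complements
    of either orientation match that orientation (palindromic variants are
    assumed removed upstream). Anything else is dropped. Returns the aligned
    Z vector, per-variant N, and the kept panel variant ids, in panel order.
    """
    if gwas.table.empty or not panel_variants:
        raise AssociationError("harmonize requires non-empty GWAS and panel variants")
    records = gwas.table.set_index("id")
    z_out, n_out, kept = [], [], []
    for v in panel_variants:
        if v.id not in records.index:
            continue
        rec = records.loc[v.id]
        g1, g2 = str(rec["a1"]).upper(), str(rec["a2"]).upper()
        c1, c2 = _COMPLEMENT.get(g1), _COMPLEMENT.get(g2)
        if (g1, g2) == (v.a1, v.a2) or (c1, c2) == (v.a1, v.a2):
            sign = 1.0
        elif (g1, g2) == (v.a2, v.a1) or (c1, c2) == (v.a2, v.a1):
            sign = -1.0
        else:
            continue
        z_out.append(sign * float(rec["z"]))
        n_out.append(int(rec["n"]))
        kept.append(v.id)
    if not kept:
        raise AssociationError("no variants left after GWAS/panel harmonization")
    return np.array(z_out), np.array(n_out), kept


def compute_ld(panel: GenotypePanel, variant_ids: list[str] | None = None) -> LdMatrix:
    """Pearson correlations of mean-imputed, standardized dosage columns;
    symmetrized with a unit diagonal."""
    if panel.n_samples < 2:
        raise AssociationError("LD computation needs at least 2 samples")
    sub = panel if variant_ids is None else panel.subset(variant_ids=variant_ids)
    Xs, degenerate = standardize_dosages(sub.dosages)
    if degenerate.any():
        vid = sub.variants[int(np.flatnonzero(degenerate)[0])].id
        raise AssociationError(f"zero-variance variant {vid!r} in LD panel")
    R = Xs.T @ Xs / (sub.n_samples - 1)
    R = np.clip((R + R.T) / 2, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return LdMatrix(sub.variant_ids, R)


def z_to_beta(z: np.ndarray | float, n: np.ndarray | int) -> np.ndarray | float:
    """Standardized marginal effect from a Z score: b = z / sqrt(n - 2 + z^2),
    the exact inversion of the simple-regression t statistic when both the
    trait and the dosage are standardized."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise AssociationError("z_to_beta requires n > 2")
    out = z / np.sqrt(n - 2 + z**2)
    return float(out) if out.ndim == 0 else out


def wald_pvalue(theta: float, se: float) -> float:
    """Upper chi-square(1) tail at (theta/se)^2."""
    if not se > 0:
        raise AssociationError(f"standard error must be positive, got {se}")
    return float(stats.chi2.sf((theta / se) ** 2, df=1))


def global_f_from_rss(rss_null: float, rss: float, n2: int, k: int = 3) -> float:
    """F statistic comparing the k-predictor model against intercept-only:
    F = ((n2 - k - 1)/k) * (rss_null - rss) / rss."""
    return ((n2 - k - 1) / k) * (rss_null - rss) / rss


def stage2_individual(
    panel2: GenotypePanel,
    y: np.ndarray,
    weights: WeightSet,
    training_sample_ids: list[str] | None = None,
) -> CowasResult:
    """Individual-level stage 2: OLS of the standardized trait on the three
    imputed predictors plus an intercept, with chi-square(1) Wald tests per
    coefficient and the global F test against an intercept-only model."""
    y = np.asarray(y, dtype=float)
    n2 = panel2.n_samples
    if len(y) != n2:
        raise AssociationError("trait length does not match panel sample count")
    if training_sample_ids is not None:
        overlap = set(training_sample_ids) & set(panel2.sample_ids)
        if overlap:
            warnings.warn(
                f"{len(overlap)} samples appear in both training and GWAS panels; "
                "overlap biases two-sample estimates",
                stacklevel=2,
            )
    sub = panel2.subset(variant_ids=weights.union_variant_ids)
    Zs, _ = standardize_dosages(sub.dosages)
    ys = (y - y.mean()) / y.std(ddof=1)
    P = Zs @ weights.weight_matrix()
    X = np.column_stack([np.ones(n2), P])
    result = CowasResult(pair_id=weights.pair_id, n2=n2, mode=weights.mode)
    if np.linalg.matrix_rank(X) < 4:
        result.status = "collinear"
        return result
    coef, _, _, _ = np.linalg.lstsq(X, ys, rcond=None)
    resid = ys - X @ coef
    rss = float(resid @ resid)
    rss_null = float(n2 - 1)  # standardized trait, ddof=1
    sigma2 = rss / (n2 - 4)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov)[1:])
    theta = coef[1:]
    result.theta_a, result.theta_b, result.theta_co = map(float, theta)
    result.se_a, result.se_b, result.se_co = map(float, se)
    result.p_a = wald_pvalue(theta[0], se[0])
    result.p_b = wald_pvalue(theta[1], se[1])
    result.p_co = wald_pvalue(theta[2], se[2])
    result.f_stat = float(global_f_from_rss(rss_null, rss, n2))
    result.p_global = float(stats.f.sf(result.f_stat, 3, n2 - 4))
    result.r2 = float(1 - rss / rss_null)
    return result


def _joint_summary_fit(
    W: np.ndarray, b: np.ndarray, sigma: np.ndarray, n2: int
) -> tuple[np.ndarray, np.ndarray, float, str]:
    """Core summary-level estimator shared by the pair and single-protein
    tests. Returns (theta, se, r2, status)."""
    k = W.shape[1]
    S = W.T @ sigma @ W
    v = W.T @ b
    status = "ok"
    if np.linalg.cond(S) > _COND_MAX:
        S = S + (1e-6 * np.trace(S) / k) * np.eye(k)
        status = "regularized"
        if np.linalg.cond(S) > _COND_MAX:
            return np.full(k, np.nan), np.full(k, np.nan), float("nan"), "failed"
    S_inv = np.linalg.inv(S)
    theta = S_inv @ v
    r2 = float(theta @ v)
    if r2 < 0 or r2 > 0.999:
        r2 = float(np.clip(r2, 0.0, 0.999))
        if status == "ok":
            status = "r2_clipped"
    var = ((1 - r2) / (n2 - k - 1)) * S_inv
    se = np.sqrt(np.diag(var))
    return theta, se, r2, status


def stage2_summary(
    gwas: GwasSummary,
    ld: LdMatrix,
    weights: WeightSet,
    n2: int | None = None,
) -> CowasResult:
    """Summary-level stage 2 from GWAS Z scores and an LD reference.

    The GWAS is harmonized to the weight set's union variants; the LD matrix
    must cover those variants. Marginal Z scores are converted to
    standardized effects, and theta_hat = (W' Sigma W)^-1 W' b with variance
    ((1 - R^2)/(n2 - 4)) (W' Sigma W)^-1, R^2 = theta_hat' W' b. The global
    F statistic ((n2 - 4)/3) R^2/(1 - R^2) is algebraically the RSS-based F
    with RSS_null = n2 - 1, RSS = (n2 - 1)(1 - R^2). When per-variant N
    varies, n2 defaults to the median over kept variants.
    """
    z, n_vec, kept = harmonize(gwas, weights.union_variants)
    if len(kept) < len(weights.union_variants):
        keep_set = set(kept)
        idx = [i for i, v in enumerate(weights.union_variants) if v.id in keep_set]
        W = weights.weight_matrix()[idx]
    else:
        W = weights.weight_matrix()
    ld_sub = ld.subset(kept)
    if n2 is None:
        n2 = int(np.median(n_vec))
    b = z_to_beta(z, n_vec)
    theta, se, r2, status = _joint_summary_fit(W, b, ld_sub.matrix, n2)
    result = CowasResult(pair_id=weights.pair_id, n2=n2, mode=weights.mode, status=status)
    if status == "failed":
        return result
    result.theta_a, result.theta_b, result.theta_co = map(float, theta)
    result.se_a, result.se_b, result.se_co = map(float, se)
    result.p_a = wald_pvalue(theta[0], se[0])
    result.p_b = wald_pvalue(theta[1], se[1])
    result.p_co = wald_pvalue(theta[2], se[2])
    result.r2 = r2
    result.f_stat = float(((n2 - 4) / 3) * r2 / (1 - r2))
    result.p_global = float(stats.f.sf(result.f_stat, 3, n2 - 4))
    return result


def pwas_summary(
    gwas: GwasSummary,
    ld: LdMatrix,
    single_weights: np.ndarray,
    variants: list[VariantInfo],
    protein_id: str,
    n2: int | None = None,
) -> PwasResult:
    """Standard single-protein association from summary data: the
    one-exposure special case of the joint estimator, with residual df
    n2 - 2."""
    w = np.asarray(single_weights, dtype=float)
    nonzero = w != 0
    if not nonzero.any():
        return PwasResult(protein_id, status="failed")
    gw = GwasSummary(gwas.table, gwas.trait, gwas.n_dropped)
    sub_variants = [v for v, nz in zip(variants, nonzero) if nz]
    z, n_vec, kept = harmonize(gw, sub_variants)
    keep_set = set(kept)
    w_kept = np.array([wv for v, wv in zip(sub_variants, w[nonzero]) if v.id in keep_set])
    ld_sub = ld.subset(kept)
    if n2 is None:
        n2 = int(np.median(n_vec))
    b = z_to_beta(z, n_vec)
    W = w_kept[:, None]
    denom = (W.T @ ld_sub.matrix @ W).item()
    if denom <= 0:
        return PwasResult(protein_id, n2=n2, status="failed")
    theta, se, r2, status = _joint_summary_fit(W, b, ld_sub.matrix, n2)
    return PwasResult(
        protein_id=protein_id,
        theta=float(theta[0]),
        se=float(se[0]),
        p=wald_pvalue(theta[0], se[0]),
        n2=n2,
        status=status,
    )


def bonferroni(pvalues: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Family-wise correction over tested (non-NaN) entries only; returns the
    significance flags and the per-test threshold alpha / m."""
    p = np.asarray(pvalues, dtype=float)
    tested = np.isfinite(p)
    m = int(tested.sum())
    if m < 1:
        raise AssociationError("bonferroni requires at least one tested p-value")
    threshold = alpha / m
    flags = np.zeros(p.shape, dtype=bool)
    flags[tested] = p[tested] <= threshold
    return flags, threshold
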