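"""Variant QC, phenotype normalization, marginal pQTL mapping, and screening.

Quality-control thresholds default to the conventional biobank settings:
missingness < 10%, minor allele count >= 100, minor allele frequency >= 1%,
Hardy-Weinberg equilibrium P >= 1e-15, and removal of palindromic (A/T, C/G)
variants. Filters run in that order and a variant removed by one filter is
never re-counted by a later one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel, ExpressionTable, PairSpec

__all__ = [
    "QcReport",
    "QtlResult",
    "qc_variants",
    "hwe_pvalue",
    "blom_transform",
    "adjust_pair",
    "map_pqtls",
    "cis_window",
    "screen_variants",
    "greedy_ld_prune",
    "standardize_dosages",
]

FILTER_ORDER = ["missingness", "mac", "maf", "hwe", "palindromic", "no_id"]


class PreprocessError(ValueError):
    pass


class ZeroVarianceError(PreprocessError):
    """Adjusted phenotype (or a covariate) has no variance left."""


@dataclass
class QcReport:
    n_input: int
    removed: dict[str, int]
    surviving_ids: list[str]
    hwe_skipped: bool = False

    def __post_init__(self) -> None:
        total = sum(self.removed.values()) + len(self.surviving_ids)
        if total != self.n_input:
            raise AssertionError("QC counts do not reconcile with input size")

    def to_frame(self) -> pd.DataFrame:
        rows = [(f, self.removed.get(f, 0)) for f in FILTER_ORDER]
        rows.append(("surviving", len(self.surviving_ids)))
        rows.append(("input", self.n_input))
        rows.append(("hwe_skipped", int(self.hwe_skipped)))
        return pd.DataFrame(rows, columns=["filter", "count"])


@dataclass
class QtlResult:
    """Marginal single-variant association results for one protein.

    ``table`` columns: id, chrom, pos, beta, se, p, excluded. Betas are on
    the standardized scale (phenotype and dosage both unit variance), so
    beta equals the Pearson correlation. Variants whose dosage has zero
    variance after mean imputation carry excluded=True and NaN estimates.
    """

    protein_id: str
    table: pd.DataFrame


def hwe_pvalue(n_aa: int, n_ab: int, n_bb: int) -> float:
    """One-df chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Expected genotype counts come from the estimated allele frequency;
    monomorphic input returns 1.
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise PreprocessError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise PreprocessError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(stat, df=1))


def qc_variants(
    panel: GenotypePanel,
    max_missing: float = 0.10,
    min_mac: int = 100,
    min_maf: float = 0.01,
    hwe_p_min: float = 1e-15,
    drop_palindromic: bool = True,
) -> tuple[GenotypePanel, QcReport]:
    """Apply per-variant filters in the fixed order
    missingness -> MAC -> MAF -> HWE -> palindromic -> no-id.

    MAF is computed from mean dosage over non-missing samples as
    min(f, 1 - f) with f = mean / 2. The HWE test requires hard calls; if
    any non-missing dosage is fractional the HWE filter is skipped and
    noted in the report.
    """
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise PreprocessError("cannot run QC on an empty genotype panel")
    X = panel.dosages
    n = panel.n_samples
    alive = np.ones(panel.n_variants, dtype=bool)
    removed = {f: 0 for f in FILTER_ORDER}

    n_missing = np.isnan(X).sum(axis=0)
    n_obs = n - n_missing
    fail = alive & ((n_obs == 0) | (n_missing / n > max_missing))
    removed["missingness"] = int(fail.sum())
    alive &= ~fail

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    alt_count = mean * n_obs
    mac = np.minimum(alt_count, 2 * n_obs - alt_count)
    fail = alive & (mac < min_mac)
    removed["mac"] = int(fail.sum())
    alive &= ~fail

    f = mean / 2.0
    maf = np.minimum(f, 1 - f)
    fail = alive & (maf < min_maf)
    removed["maf"] = int(fail.sum())
    alive &= ~fail

    obs = X[:, alive] if alive.any() else X[:, :0]
    hard_called = bool(np.all(np.isclose(np.mod(obs[~np.isnan(obs)], 1.0), 0.0)))
    hwe_skipped = not hard_called
    if hard_called:
        fail = np.zeros_like(alive)
        for j in np.flatnonzero(alive):
            col = X[:, j]
            col = col[~np.isnan(col)]
            counts = np.bincount(col.astype(int), minlength=3)
            if hwe_pvalue(counts[0], counts[1], counts[2]) < hwe_p_min:
                fail[j] = True
        removed["hwe"] = int(fail.sum())
        alive &= ~fail

    if drop_palindromic:
        pal = np.array([v.is_palindromic for v in panel.variants])
        fail = alive & pal
        removed["palindromic"] = int(fail.sum())
        alive &= ~fail

    no_id = np.array([v.id in ("", ".") for v in panel.variants])
    fail = alive & no_id
    removed["no_id"] = int(fail.sum())
    alive &= ~fail

    surviving = [panel.variants[j].id for j in np.flatnonzero(alive)]
    report = QcReport(panel.n_variants, removed, surviving, hwe_skipped=hwe_skipped)
    return panel.subset(variant_ids=surviving), report


def blom_transform(values: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal (Blom) transform with tie-averaged ranks.

    output_i = Phi^-1((rank_i - offset) / (n + 1 - 2*offset)), computed over
    non-missing entries only; missing entries stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.full_like(values, np.nan)
    mask = ~np.isnan(values)
    n = int(mask.sum())
    if n < 2:
        raise PreprocessError("blom_transform requires at least 2 non-missing values")
    ranks = stats.rankdata(values[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    return out


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ZeroVarianceError("zero-variance column in covariate matrix")
    return (M - mean) / sd


def adjust_pair(
    expr: ExpressionTable,
    covariates: pd.DataFrame | None,
    pair: PairSpec,
    min_extra_samples: int = 10,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Normalize and covariate-adjust both proteins of a pair.

    Rather than imputing missing expression, the pair is restricted to the
    intersection of samples non-missing for BOTH proteins. On that subset
    each protein is Blom-transformed, then regressed on the standardized
    covariates plus an intercept; the residuals are centered and scaled to
    unit variance (ddof=1).
    """
    a_raw = expr.column(pair.protein_a)
    b_raw = expr.column(pair.protein_b)
    keep = ~np.isnan(a_raw) & ~np.isnan(b_raw)
    subset = [s for s, k in zip(expr.sample_ids, keep) if k]
    n_cov = 0 if covariates is None else covariates.shape[1]
    if len(subset) < n_cov + min_extra_samples:
        raise PreprocessError(
            f"pair {pair.pair_id}: only {len(subset)} complete samples for "
            f"{n_cov} covariates (need >= {n_cov + min_extra_samples})"
        )
    a = blom_transform(a_raw[keep])
    b = blom_transform(b_raw[keep])

    if covariates is not None:
        missing = [s for s in subset if s not in covariates.index]
        if missing:
            raise PreprocessError(f"sample {missing[0]!r} missing from covariates")
        C = _standardize_columns(covariates.loc[subset].to_numpy(dtype=float))
        X = np.column_stack([np.ones(len(subset)), C])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise PreprocessError("covariate matrix is rank-deficient on the pair subset")
        for name, y in (("a", a), ("b", b)):
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            if resid.std(ddof=1) < 1e-10:
                raise ZeroVarianceError(
                    f"pair {pair.pair_id}: protein {name} has no variance after adjustment"
                )
            if name == "a":
                a = resid
            else:
                b = resid

    a = (a - a.mean()) / a.std(ddof=1)
    b = (b - b.mean()) / b.std(ddof=1)
    return a, b, subset


def standardize_dosages(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per variant, then standardize (ddof=1).

    Returns the standardized matrix and a boolean mask of zero-variance
    variants (their columns are set to 0).
    """
    X = np.asarray(X, dtype=float).copy()
    mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mean, idx[1])
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    sd_safe = np.where(degenerate, 1.0, sd)
    Xs = (X - mu) / sd_safe
    Xs[:, degenerate] = 0.0
    return Xs, degenerate


def map_pqtls(panel: GenotypePanel, y_adj: np.ndarray, protein_id: str = "") -> QtlResult:
    """Marginal pQTL scan: simple regression of the adjusted phenotype on
    each standardized dosage column (missing dosages mean-imputed).

    With both sides standardized, beta equals the Pearson correlation;
    two-sided p-values use the t distribution with n - 2 df. Zero-variance
    variants are flagged excluded.
    """
    y = np.asarray(y_adj, dtype=float)
    n = len(y)
    if n != panel.n_samples:
        raise PreprocessError("phenotype length does not match panel samples")
    if n < 3:
        raise PreprocessError("need at least 3 samples for pQTL mapping")
    Xs, degenerate = standardize_dosages(panel.dosages)
    ys = (y - y.mean()) / y.std(ddof=1)
    r = Xs.T @ ys / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(1 - r**2, 0.0) / (n - 2))
        t = np.where(se > 0, r / se, np.inf * np.sign(r))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    table = pd.DataFrame(
        {
            "id": panel.variant_ids,
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            "beta": np.where(degenerate, np.nan, r),
            "se": np.where(degenerate, np.nan, se),
            "p": np.where(degenerate, np.nan, p),
            "excluded": degenerate,
        }
    )
    return QtlResult(protein_id=protein_id, table=table)


def cis_window(
    gene_window: tuple[str, int, int], flank: int = 500_000
) -> tuple[str, int, int]:
    """Cis region: gene start - flank to gene end + flank, closed interval,
    clamped to position 1."""
    chrom, start, end = gene_window
    if start > end:
        raise PreprocessError(f"gene window start > end: {gene_window}")
    return chrom, max(1, start - flank), end + flank


def screen_variants(
    qtl: QtlResult,
    mode: str = "pvalue",
    k: int = 100,
    cis_only: bool = False,
    window: tuple[str, int, int] | None = None,
) -> list[str]:
    """Sure Independence Screening: keep the top-k variants ranked by
    marginal P value (ascending) or |effect size| (descending).

    Ties break deterministically by (chrom, pos, id), so the output is
    invariant to input row order. ``window`` is the cis region (already
    flanked) used when ``cis_only`` is set.
    """
    if mode not in ("pvalue", "effect"):
        raise PreprocessError(f"unknown screening mode {mode!r}")
    df = qtl.table.loc[~qtl.table["excluded"]].copy()
    if cis_only:
        if window is None:
            raise PreprocessError("cis_only screening requires a window")
        chrom, lo, hi = window
        df = df[(df["chrom"] == chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)]
        if df.empty:
            raise PreprocessError(
                f"no variants in cis window {chrom}:{lo}-{hi} for {qtl.protein_id!r}"
            )
    if df.empty:
        raise PreprocessError(f"no usable variants to screen for {qtl.protein_id!r}")
    if mode == "pvalue":
        df = df.assign(_key=df["p"])
        ascending = [True, True, True, True]
    else:
        df = df.assign(_key=-df["beta"].abs())
        ascending = [True, True, True, True]
    df = df.sort_values(["_key", "chrom", "pos", "id"], ascending=ascending, kind="mergesort")
    return df["id"].head(k).tolist()


def greedy_ld_prune(
    panel: GenotypePanel,
    r2_max: float = 0.8,
    window: int = 1000,
    step: int = 100,
    units: str = "count",
) -> list[str]:
    """Greedy LD pruning over a sliding window.

    ``units='count'`` interprets window/step as variant counts (the common
    tool convention for this flag form); ``units='bp'`` interprets them as
    base pairs. Within each window, later variants correlated at r^2 >=
    ``r2_max`` with an earlier kept variant are dropped.
    """
    if units not in ("count", "bp"):
        raise PreprocessError(f"unknown pruning units {units!r}")
    Xs, degenerate = standardize_dosages(panel.dosages)
    n = panel.n_samples
    order = sorted(
        range(panel.n_variants),
        key=lambda j: (panel.variants[j].chrom, panel.variants[j].pos, panel.variants[j].id),
    )
    dropped: set[int] = set(np.flatnonzero(degenerate))
    pos = [panel.variants[j].pos for j in order]
    start = 0
    while start < len(order):
        if units == "count":
            members = order[start : start + window]
            advance = step
        else:
            lo = pos[start]
            members = [order[i] for i in range(start, len(order)) if pos[i] <= lo + window]
            advance = max(1, sum(1 for i in range(start, len(order)) if pos[i] < lo + step))
        kept_local: list[int] = []
        for j in members:
            if j in dropped:
                continue
            ok = True
            for kj in kept_local:
                r = float(Xs[:, j] @ Xs[:, kj] / (n - 1))
                if r * r >= r2_max:
                    dropped.add(j)
                    ok = False
                    break
            if ok:
                kept_local.append(j)
        start += advance
        if advance <= 0:
            break
    return [panel.variants[j].id for j in range(panel.n_variants) if j not in dropped]
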