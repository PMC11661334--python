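"""Stage 1: genetic imputation models for a protein pair and its co-expression.

Three penalized linear models are trained per pair: one for each protein's
expression on its screened pQTL set, and one for the co-expression target on
the union of the two screened sets. In residual mode the co-expression target
is the elementwise product of the two expression residuals (measured minus
imputed); in product mode it is the product of the adjusted expression values
themselves. Out-of-sample performance is assessed with an 80/20 split and
pairs must reach a correlation above a threshold (default 0.03) in all three
models to count as well imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.linear_model import enet_path

from .io import GenotypePanel, PairSpec, VariantInfo, WeightSet
from .preprocess import QtlResult, cis_window, screen_variants, standardize_dosages

__all__ = [
    "PenalizedModel",
    "PairMetrics",
    "TrainConfig",
    "fit_penalized",
    "build_coexpression_target",
    "train_pair",
    "evaluate_pair",
    "train_and_evaluate_pair",
    "metrics_frame",
]

ALPHA_BY_PENALTY = {"enet": 0.5, "lasso": 1.0, "ridge": 0.0}


class TrainingError(ValueError):
    pass


@dataclass
class PenalizedModel:
    """A fitted linear model y ~ intercept + X w with an elastic-net family
    penalty; weights are on the scale of the (standardized) input columns."""

    variant_ids: list[str]
    weights: np.ndarray
    intercept: float
    penalty: str
    lambda_selected: float
    cv_errors: np.ndarray | None = None
    lambdas: np.ndarray | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


@dataclass
class PairMetrics:
    """Out-of-sample performance of the three models for one pair."""

    pair_id: str
    r_a: float
    r_b: float
    r_co: float
    n_train: int
    n_test: int
    min_corr: float = 0.03
    reason: str = ""

    @property
    def r2_a(self) -> float:
        return self.r_a**2

    @property
    def r2_b(self) -> float:
        return self.r_b**2

    @property
    def r2_co(self) -> float:
        return self.r_co**2

    @property
    def passed(self) -> bool:
        rs = (self.r_a, self.r_b, self.r_co)
        if any(not np.isfinite(r) for r in rs):
            return False
        return all(r > self.min_corr for r in rs)


@dataclass
class TrainConfig:
    """Tunables for stage-1 training; defaults follow the standard protocol
    (top-100 screening, 10-fold CV, 0.03 correlation filter, 80/20 split)."""

    penalty: str = "lasso"
    screen: str = "effect"
    top_k: int = 100
    cis_only: bool = False
    cis_flank: int = 500_000
    mode: str = "residual"
    min_corr: float = 0.03
    split: float = 0.8
    n_folds: int = 10
    n_lambdas: int = 100
    min_test: int = 30
    seed: int = 0


def _lambda_path(X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int) -> np.ndarray:
    """Log-spaced path from lambda_max (all-zero weights for alpha > 0) down
    to 1e-3 * lambda_max; for ridge the same grid anchored at the alpha=0.001
    convention is used."""
    n = len(y)
    yc = y - y.mean()
    lmax = float(np.max(np.abs(X.T @ yc)) / (n * max(alpha, 1e-3)))
    lmax = max(lmax, 1e-12)
    return np.geomspace(lmax, 1e-3 * lmax, n_lambdas)


def _ridge_path_fit(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Closed-form ridge solutions for (1/2n)||y - Xw||^2 + (lambda/2)||w||^2
    across the whole path via one SVD. Returns (p, n_lambdas)."""
    n = Xc.shape[0]
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    uy = U.T @ yc
    # w(lambda) = V diag(s / (s^2 + n*lambda)) U^T y
    factors = s[:, None] / (s[:, None] ** 2 + n * lambdas[None, :])
    return Vt.T @ (factors * uy[:, None])


def _path_fit(Xc: np.ndarray, yc: np.ndarray, alpha: float, lambdas: np.ndarray) -> np.ndarray:
    """Coefficient path (p, n_lambdas) for centered data, no intercept."""
    if alpha == 0.0:
        return _ridge_path_fit(Xc, yc, lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, coefs, _ = enet_path(Xc, yc, l1_ratio=alpha, alphas=lambdas)
    return coefs


def _cv_folds(n: int, n_folds: int, seed: int) -> list[np.ndarray]:
    perm = np.random.default_rng(seed).permutation(n)
    return np.array_split(perm, n_folds)


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    penalty: str = "lasso",
    n_folds: int = 10,
    seed: int = 0,
    lambdas: np.ndarray | None = None,
    n_lambdas: int = 100,
) -> PenalizedModel:
    """Fit y ~ X with an elastic-net objective
    (1/2n)||y - Xw - c||^2 + lambda*(alpha*||w||_1 + (1-alpha)/2*||w||^2),
    choosing lambda by minimum mean 10-fold CV error on a descending path.

    Columns of X are expected standardized; y may be on any scale (it is
    centered internally, never rescaled). Fold assignment is a deterministic
    seeded shuffle, so the CV curve and the selected lambda are reproducible
    and invariant to feature order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if penalty not in ALPHA_BY_PENALTY:
        raise TrainingError(f"unknown penalty {penalty!r}")
    if X.ndim != 2 or X.shape[1] < 1:
        raise TrainingError("X must be a 2-d matrix with at least one column")
    n = len(y)
    if y.std(ddof=1) == 0:
        raise TrainingError("response has zero variance")
    alpha = ALPHA_BY_PENALTY[penalty]

    if lambdas is not None and len(lambdas) == 1 and lambdas[0] == 0.0:
        # unpenalized limit, used for testing against OLS
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w, *_ = np.linalg.lstsq(Xc, yc, rcond=None)
        intercept = float(y.mean() - X.mean(axis=0) @ w)
        return PenalizedModel(list(map(str, range(X.shape[1]))), w, intercept, penalty, 0.0)

    if n < 2 * n_folds:
        raise TrainingError(f"need n >= {2 * n_folds} samples for {n_folds}-fold CV")
    if lambdas is None:
        lambdas = _lambda_path(X, y, alpha, n_lambdas)
    lambdas = np.asarray(lambdas, dtype=float)

    folds = _cv_folds(n, n_folds, seed)
    cv_err = np.zeros(len(lambdas))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        Xtr, ytr = X[mask], y[mask]
        mu_x, mu_y = Xtr.mean(axis=0), ytr.mean()
        coefs = _path_fit(Xtr - mu_x, ytr - mu_y, alpha, lambdas)
        preds = (X[fold] - mu_x) @ coefs + mu_y
        cv_err += np.mean((y[fold][:, None] - preds) ** 2, axis=0) * len(fold)
    cv_err /= n
    best = int(np.argmin(cv_err))  # first minimum on a descending path = largest lambda

    mu_x, mu_y = X.mean(axis=0), y.mean()
    coefs = _path_fit(X - mu_x, y - mu_y, alpha, lambdas)
    w = coefs[:, best]
    intercept = float(mu_y - mu_x @ w)
    return PenalizedModel(
        variant_ids=list(map(str, range(X.shape[1]))),
        weights=w,
        intercept=intercept,
        penalty=penalty,
        lambda_selected=float(lambdas[best]),
        cv_errors=cv_err,
        lambdas=lambdas,
    )


def build_coexpression_target(
    a_adj: np.ndarray,
    b_adj: np.ndarray,
    a_hat: np.ndarray,
    b_hat: np.ndarray,
    mode: str = "residual",
) -> np.ndarray:
    """Co-expression target: (a - a_hat) * (b - b_hat) in residual mode, or
    a * b in product mode (adjusted expression is already centered)."""
    arrays = [np.asarray(v, dtype=float) for v in (a_adj, b_adj, a_hat, b_hat)]
    if len({a.shape for a in arrays}) != 1:
        raise TrainingError("co-expression target inputs have mismatched lengths")
    a_adj, b_adj, a_hat, b_hat = arrays
    if mode == "residual":
        return (a_adj - a_hat) * (b_adj - b_hat)
    if mode == "product":
        return a_adj * b_adj
    raise TrainingError(f"unknown co-expression mode {mode!r}")


def _screened_sets(
    pair: PairSpec, qtl_a: QtlResult, qtl_b: QtlResult, config: TrainConfig
) -> tuple[list[str], list[str], list[str]]:
    win_a = cis_window(pair.gene_a_window, config.cis_flank) if config.cis_only else None
    win_b = cis_window(pair.gene_b_window, config.cis_flank) if config.cis_only else None
    set_a = screen_variants(qtl_a, config.screen, config.top_k, config.cis_only, win_a)
    set_b = screen_variants(qtl_b, config.screen, config.top_k, config.cis_only, win_b)
    union = list(set_a) + [v for v in set_b if v not in set(set_a)]
    return set_a, set_b, union


def _pad(weights: np.ndarray, ids: list[str], union: list[str]) -> np.ndarray:
    out = np.zeros(len(union))
    index = {v: i for i, v in enumerate(union)}
    for w, vid in zip(weights, ids):
        out[index[vid]] = w
    return out


def _fit_three_models(
    Z_union: np.ndarray,
    union: list[str],
    set_a: list[str],
    set_b: list[str],
    a_adj: np.ndarray,
    b_adj: np.ndarray,
    config: TrainConfig,
    seed: int,
) -> tuple[PenalizedModel, PenalizedModel, PenalizedModel]:
    """Fit exposure models on their screened columns of the union matrix and
    the co-expression model on the full union matrix."""
    col = {v: i for i, v in enumerate(union)}
    ia = [col[v] for v in set_a]
    ib = [col[v] for v in set_b]
    m_a = fit_penalized(
        Z_union[:, ia], a_adj, config.penalty, config.n_folds, seed, n_lambdas=config.n_lambdas
    )
    m_a.variant_ids = list(set_a)
    m_b = fit_penalized(
        Z_union[:, ib], b_adj, config.penalty, config.n_folds, seed + 1, n_lambdas=config.n_lambdas
    )
    m_b.variant_ids = list(set_b)
    a_hat = m_a.predict(Z_union[:, ia])
    b_hat = m_b.predict(Z_union[:, ib])
    target = build_coexpression_target(a_adj, b_adj, a_hat, b_hat, config.mode)
    if target.std(ddof=1) == 0:
        raise TrainingError("co-expression target has zero variance")
    m_co = fit_penalized(
        Z_union, target, config.penalty, config.n_folds, seed + 2, n_lambdas=config.n_lambdas
    )
    m_co.variant_ids = list(union)
    return m_a, m_b, m_co


def train_pair(
    panel: GenotypePanel,
    pair: PairSpec,
    a_adj: np.ndarray,
    b_adj: np.ndarray,
    qtl_a: QtlResult,
    qtl_b: QtlResult,
    config: TrainConfig | None = None,
) -> WeightSet:
    """Train the three imputation models on all samples of ``panel`` and
    embed them into the union variant order with zero padding.

    ``panel`` must already be restricted to the pair's sample subset and
    ``a_adj``/``b_adj`` standardized (see ``adjust_pair``). A pair whose
    three models include an all-zero weight vector is flagged non-imputable
    (``status='zero_variance_prediction'``).
    """
    config = config or TrainConfig()
    set_a, set_b, union = _screened_sets(pair, qtl_a, qtl_b, config)
    sub = panel.subset(variant_ids=union)
    Z, _ = standardize_dosages(sub.dosages)
    m_a, m_b, m_co = _fit_three_models(
        Z, union, set_a, set_b, a_adj, b_adj, config, config.seed
    )
    w_a = _pad(m_a.weights, set_a, union)
    w_b = _pad(m_b.weights, set_b, union)
    w_co = _pad(m_co.weights, list(union), union)
    status = "ok"
    if not w_a.any() or not w_b.any() or not w_co.any():
        status = "zero_variance_prediction"
    return WeightSet(
        pair_id=pair.pair_id,
        union_variants=list(sub.variants),
        w_a=w_a,
        w_b=w_b,
        w_co=w_co,
        mode=config.mode,
        status=status,
    )


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def evaluate_pair(
    panel: GenotypePanel,
    pair: PairSpec,
    a_adj: np.ndarray,
    b_adj: np.ndarray,
    qtl_a: QtlResult,
    qtl_b: QtlResult,
    config: TrainConfig | None = None,
) -> PairMetrics:
    """Out-of-sample evaluation with a deterministic seeded 80/20 split.

    r_a and r_b correlate measured with imputed expression on the test
    split. The co-expression correlation r_co compares the test-split
    prediction of the co-expression model trained on the 80% split against
    the residual target computed on the test split with single-protein
    models trained on ALL samples (in product mode the test target is the
    observed product of adjusted expression).
    """
    config = config or TrainConfig()
    n = panel.n_samples
    set_a, set_b, union = _screened_sets(pair, qtl_a, qtl_b, config)
    sub = panel.subset(variant_ids=union)
    Z, _ = standardize_dosages(sub.dosages)

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(config.split * n))
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    if len(test_idx) < config.min_test:
        raise TrainingError(
            f"test split has {len(test_idx)} samples (< {config.min_test})"
        )

    col = {v: i for i, v in enumerate(union)}
    ia = [col[v] for v in set_a]
    ib = [col[v] for v in set_b]
    try:
        m_a80, m_b80, m_co80 = _fit_three_models(
            Z[train_idx], union, set_a, set_b, a_adj[train_idx], b_adj[train_idx],
            config, config.seed + 10,
        )
    except TrainingError as exc:
        return PairMetrics(pair.pair_id, float("nan"), float("nan"), float("nan"),
                           len(train_idx), len(test_idx), config.min_corr, str(exc))

    r_a = _safe_corr(a_adj[test_idx], m_a80.predict(Z[test_idx][:, ia]))
    r_b = _safe_corr(b_adj[test_idx], m_b80.predict(Z[test_idx][:, ib]))

    c_hat_test = m_co80.predict(Z[test_idx])
    if config.mode == "product":
        target_test = a_adj[test_idx] * b_adj[test_idx]
    else:
        # residual target on the test split, with full-data exposure models
        m_a_full, m_b_full, _ = _fit_three_models(
            Z, union, set_a, set_b, a_adj, b_adj, config, config.seed
        )
        target_test = build_coexpression_target(
            a_adj[test_idx],
            b_adj[test_idx],
            m_a_full.predict(Z[test_idx][:, ia]),
            m_b_full.predict(Z[test_idx][:, ib]),
            "residual",
        )
    r_co = _safe_corr(c_hat_test, target_test)

    reason = ""
    if any(np.isnan(r) for r in (r_a, r_b, r_co)):
        reason = "zero-variance prediction on test split"
    return PairMetrics(
        pair_id=pair.pair_id,
        r_a=r_a,
        r_b=r_b,
        r_co=r_co,
        n_train=len(train_idx),
        n_test=len(test_idx),
        min_corr=config.min_corr,
        reason=reason,
    )


def train_and_evaluate_pair(
    panel: GenotypePanel,
    pair: PairSpec,
    a_adj: np.ndarray,
    b_adj: np.ndarray,
    qtl_a: QtlResult,
    qtl_b: QtlResult,
    config: TrainConfig | None = None,
) -> WeightSet:
    """Evaluate with the 80/20 protocol, then re-train all three models on
    the full dataset; the returned WeightSet carries the PairMetrics."""
    config = config or TrainConfig()
    metrics = evaluate_pair(panel, pair, a_adj, b_adj, qtl_a, qtl_b, config)
    ws = train_pair(panel, pair, a_adj, b_adj, qtl_a, qtl_b, config)
    ws.metrics = metrics
    return ws


def metrics_frame(weightsets: list[WeightSet]) -> pd.DataFrame:
    rows = []
    for ws in weightsets:
        m: PairMetrics = ws.metrics
        rows.append(
            (
                ws.pair_id, m.r_a, m.r_b, m.r_co, m.r2_a, m.r2_b, m.r2_co,
                m.n_train, m.n_test, m.passed, ws.status, m.reason,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "pair_id", "r_a", "r_b", "r_co", "r2_a", "r2_b", "r2_co",
            "n_train", "n_test", "passed", "status", "reason",
        ],
    )
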