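"""Synthetic two-sample datasets with known pQTL, coQTL, and trait architecture.

The generator embodies the generative model the association machinery
assumes: two protein abundances with sparse additive genetic control,
residuals whose correlation is itself genotype-dependent (the coQTL effect,
linked through tanh so it stays in (-1, 1) while remaining locally linear),
and a downstream quantitative trait driven by the genetically regulated
expression of both proteins plus their genetically regulated co-expression.
A second, non-overlapping sample provides the trait and its marginal GWAS
summary statistics. Everything is a pure function of the config, including
the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import stats

from .io import (
    ExpressionTable,
    GenotypePanel,
    GwasSummary,
    PairSpec,
    VariantInfo,
)

import pandas as pd

__all__ = [
    "SimConfig",
    "SimDataset",
    "simulate_genotypes",
    "simulate_expression_pair",
    "simulate_outcome_and_gwas",
    "simulate_dataset",
    "simulate_study",
    "PRESETS",
]

_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]  # never palindromic

PRESETS = {
    "null": (0.0, 0.0, 0.0),
    "direct-only": (0.1, -0.1, 0.0),
    "coqtl-only": (0.0, 0.0, 0.2),
    "full": (0.1, -0.1, 0.2),
}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated protein pair.

    Defaults describe a sparse cis architecture: 50 variants of which 5
    regulate each protein (standardized-dosage effect size 0.3 each, about
    30% heritability), 5 modulate the residual correlation with the same
    per-variant strength, and the trait carries direct effects (0.1, -0.1)
    and a co-expression effect of 0.2 on top of unit-variance noise.
    """

    n1: int = 1000
    n2: int = 5000
    p: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    k_a: int = 5
    k_b: int = 5
    k_co: int = 5
    beta_scale_a: float = 0.3
    beta_scale_b: float = 0.3
    eta0: float = 0.0
    eta_scale: float = 0.3
    theta: tuple[float, float, float] = (0.1, -0.1, 0.2)
    noise_sd: float = 1.0
    h2_a: float | None = None
    h2_b: float | None = None
    ld_phi: float = 0.0
    n_covariates: int = 0
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError(f"invalid MAF range {self.maf_range}")
        if max(self.k_a, self.k_b, self.k_co) > self.p:
            raise SimulationError("causal-variant counts exceed variant count")
        for h2 in (self.h2_a, self.h2_b):
            if h2 is not None and h2 >= 1:
                raise SimulationError(f"requested heritability {h2} must be < 1")
        if not (0 <= self.ld_phi < 1):
            raise SimulationError("AR(1) parameter must be in [0, 1)")


@dataclass
class SimDataset:
    """A complete two-sample dataset plus the latent truth record."""

    config: SimConfig
    panel1: GenotypePanel
    panel2: GenotypePanel
    expression: ExpressionTable
    covariates: pd.DataFrame | None
    pair: PairSpec
    y: np.ndarray
    gwas: GwasSummary
    truth: dict

    def truth_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        payload = {"config": asdict(self.config), **self.truth}
        return json.dumps(payload, default=default, indent=2)


def _standardized(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def simulate_genotypes(
    n: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    phi: float = 0.0,
    sample_prefix: str = "s",
    variant_prefix: str = "rsim",
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 1000,
    mafs: np.ndarray | None = None,
) -> GenotypePanel:
    """Hard-call dosages with per-variant MAF ~ Uniform(maf_range).

    With ``phi`` = 0 variants are independent Binomial(2, MAF). A positive
    ``phi`` induces AR(1)-correlated haplotypes via a latent Gaussian
    threshold model, exercising LD-aware code paths.
    """
    if n < 1 or p < 1:
        raise SimulationError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    if mafs is None:
        mafs = rng.uniform(maf_range[0], maf_range[1], size=p)
    if phi == 0.0:
        dosages = rng.binomial(2, mafs[None, :], size=(n, p)).astype(float)
    else:
        thresh = stats.norm.ppf(mafs)
        haps = np.zeros((2, n, p))
        for h in range(2):
            latent = np.empty((n, p))
            latent[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, p - 1)) * np.sqrt(1 - phi**2)
            for j in range(1, p):
                latent[:, j] = phi * latent[:, j - 1] + innov[:, j - 1]
            haps[h] = (latent < thresh[None, :]).astype(float)
        dosages = haps.sum(axis=0)
    variants = []
    for j in range(p):
        a1, a2 = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        variants.append(
            VariantInfo(f"{variant_prefix}{j}", chrom, pos_start + j * pos_step, a1, a2)
        )
    sample_ids = [f"{sample_prefix}{i:06d}" for i in range(n)]
    panel = GenotypePanel(sample_ids, variants, dosages)
    panel._mafs = mafs  # retained so the GWAS panel can reuse the same frequencies
    return panel


def _draw_effects(rng: np.random.Generator, p: int, k: int, scale: float) -> tuple[np.ndarray, np.ndarray]:
    idx = np.sort(rng.choice(p, size=k, replace=False))
    beta = np.zeros(p)
    beta[idx] = scale * rng.choice([-1.0, 1.0], size=k)
    return idx, beta


def simulate_expression_pair(
    panel: GenotypePanel, cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Simulate the two abundances on ``panel`` and return the truth record.

    A = Zs beta_A + eps_A and B = Zs beta_B + eps_B on standardized dosages,
    with (eps_A, eps_B) bivariate normal, unit variances, and per-sample
    correlation rho_i = tanh(eta0 + Zs_i' eta). Causal sets are drawn without
    replacement; the coQTL set may overlap the pQTL sets.
    """
    cfg.validate()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    p = panel.n_variants
    Zs = _standardized(panel.dosages)

    scale_a, scale_b = cfg.beta_scale_a, cfg.beta_scale_b
    if cfg.h2_a is not None:
        scale_a = np.sqrt(cfg.h2_a / (cfg.k_a * (1 - cfg.h2_a)))
    if cfg.h2_b is not None:
        scale_b = np.sqrt(cfg.h2_b / (cfg.k_b * (1 - cfg.h2_b)))
    idx_a, beta_a = _draw_effects(rng, p, cfg.k_a, scale_a)
    idx_b, beta_b = _draw_effects(rng, p, cfg.k_b, scale_b)
    idx_co, eta = _draw_effects(rng, p, cfg.k_co, cfg.eta_scale)

    rho = np.tanh(cfg.eta0 + Zs @ eta)
    eps_a = rng.standard_normal(panel.n_samples)
    xi = rng.standard_normal(panel.n_samples)
    eps_b = rho * eps_a + np.sqrt(1 - rho**2) * xi
    A = Zs @ beta_a + eps_a
    B = Zs @ beta_b + eps_b
    truth = {
        "idx_a": idx_a, "idx_b": idx_b, "idx_co": idx_co,
        "beta_a": beta_a, "beta_b": beta_b, "eta": eta, "eta0": cfg.eta0,
        "rho": rho, "eps_a": eps_a, "eps_b": eps_b,
        "genetic_a": Zs @ beta_a, "genetic_b": Zs @ beta_b,
    }
    return A, B, truth


def simulate_outcome_and_gwas(
    panel2: GenotypePanel,
    cfg: SimConfig,
    truth: dict,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, GwasSummary]:
    """Trait and marginal GWAS on the second, non-overlapping sample.

    y_i = theta_A g_A(Z_i) + theta_B g_B(Z_i) + theta_co rho(Z_i) + e_i with
    the same latent parameters applied to the GWAS panel's standardized
    dosages; the standardized trait is regressed on each standardized
    dosage column and Z = beta/se recorded with n = n2.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    Zs = _standardized(panel2.dosages)
    g_a = Zs @ truth["beta_a"]
    g_b = Zs @ truth["beta_b"]
    rho = np.tanh(truth["eta0"] + Zs @ truth["eta"])
    th_a, th_b, th_co = cfg.theta
    e = rng.standard_normal(panel2.n_samples) * cfg.noise_sd
    y = th_a * g_a + th_b * g_b + th_co * rho + e
    y = (y - y.mean()) / y.std(ddof=1)

    n2 = panel2.n_samples
    r = Zs.T @ y / (n2 - 1)
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt(n2 - 2) / np.sqrt(1 - r**2)
    table = pd.DataFrame(
        {
            "id": panel2.variant_ids,
            "a1": [v.a1 for v in panel2.variants],
            "a2": [v.a2 for v in panel2.variants],
            "z": z,
            "n": n2,
        }
    )
    return y, GwasSummary(table, trait="simulated")


def simulate_dataset(cfg: SimConfig) -> SimDataset:
    """Full two-sample dataset for one pair; pure function of the config."""
    cfg.validate()
    base = np.random.default_rng(cfg.seed)
    maf_seed, geno1_seed, geno2_seed = base.integers(0, 2**31 - 1, size=3)
    mafs = np.random.default_rng(maf_seed).uniform(*cfg.maf_range, size=cfg.p)
    panel1 = simulate_genotypes(
        cfg.n1, cfg.p, cfg.maf_range, seed=int(geno1_seed), phi=cfg.ld_phi,
        sample_prefix="train", mafs=mafs,
    )
    panel2 = simulate_genotypes(
        cfg.n2, cfg.p, cfg.maf_range, seed=int(geno2_seed), phi=cfg.ld_phi,
        sample_prefix="gwas", mafs=mafs,
    )
    rng1 = np.random.default_rng(cfg.seed + 1)
    A, B, truth = simulate_expression_pair(panel1, cfg, rng1)

    covariates = None
    if cfg.n_covariates > 0:
        C = rng1.standard_normal((cfg.n1, cfg.n_covariates))
        loadings = rng1.uniform(-0.5, 0.5, size=(cfg.n_covariates, 2))
        A = A + C @ loadings[:, 0]
        B = B + C @ loadings[:, 1]
        truth["covariate_loadings"] = loadings
        covariates = pd.DataFrame(
            C,
            index=panel1.sample_ids,
            columns=[f"cov{j}" for j in range(cfg.n_covariates)],
        )

    y, gwas = simulate_outcome_and_gwas(panel2, cfg, truth)
    first = panel1.variants[0].pos
    last = panel1.variants[-1].pos
    pair = PairSpec(
        "PROT_A", "PROT_B",
        (panel1.variants[0].chrom, first, last),
        (panel1.variants[0].chrom, first, last),
    )
    expression = ExpressionTable(panel1.sample_ids, ["PROT_A", "PROT_B"], np.column_stack([A, B]))
    truth["theta"] = np.array(cfg.theta)
    return SimDataset(cfg, panel1, panel2, expression, covariates, pair, y, gwas, truth)


def simulate_study(cfg: SimConfig, n_pairs: int) -> SimDataset:
    """Several independent pairs sharing one pair of sample panels.

    Each pair gets its own block of ``cfg.p`` variants and its own protein
    columns; the trait sums the contributions of every pair (plus one noise
    term), so marginal GWAS statistics cover all blocks jointly.
    """
    cfg.validate()
    if n_pairs < 1:
        raise SimulationError("n_pairs must be >= 1")
    base = np.random.default_rng(cfg.seed)
    panels1, panels2, exprs, pairs, truths = [], [], [], [], []
    signal = np.zeros(cfg.n2)
    th_a, th_b, th_co = cfg.theta
    for k in range(n_pairs):
        sub_seed = int(base.integers(0, 2**31 - 1))
        sub_cfg = replace(cfg, seed=sub_seed)
        mafs = np.random.default_rng(sub_seed).uniform(*cfg.maf_range, size=cfg.p)
        p1 = simulate_genotypes(
            cfg.n1, cfg.p, cfg.maf_range, seed=sub_seed + 1, phi=cfg.ld_phi,
            sample_prefix="train", variant_prefix=f"rsim{k}_",
            pos_start=1_000_000 + k * cfg.p * 1000, mafs=mafs,
        )
        p2 = simulate_genotypes(
            cfg.n2, cfg.p, cfg.maf_range, seed=sub_seed + 2, phi=cfg.ld_phi,
            sample_prefix="gwas", variant_prefix=f"rsim{k}_",
            pos_start=1_000_000 + k * cfg.p * 1000, mafs=mafs,
        )
        A, B, truth = simulate_expression_pair(p1, sub_cfg, np.random.default_rng(sub_seed + 3))
        Zs2 = _standardized(p2.dosages)
        signal += (
            th_a * Zs2 @ truth["beta_a"]
            + th_b * Zs2 @ truth["beta_b"]
            + th_co * np.tanh(truth["eta0"] + Zs2 @ truth["eta"])
        )
        first, last = p1.variants[0].pos, p1.variants[-1].pos
        pairs.append(
            PairSpec(
                f"PROT_A{k}", f"PROT_B{k}",
                (p1.variants[0].chrom, first, last),
                (p1.variants[0].chrom, first, last),
            )
        )
        panels1.append(p1)
        panels2.append(p2)
        exprs.append((A, B))
        truths.append(truth)

    panel1 = GenotypePanel(
        panels1[0].sample_ids,
        [v for p in panels1 for v in p.variants],
        np.hstack([p.dosages for p in panels1]),
    )
    panel2 = GenotypePanel(
        panels2[0].sample_ids,
        [v for p in panels2 for v in p.variants],
        np.hstack([p.dosages for p in panels2]),
    )
    e = np.random.default_rng(cfg.seed + 7).standard_normal(cfg.n2) * cfg.noise_sd
    y = signal + e
    y = (y - y.mean()) / y.std(ddof=1)
    Zs2 = _standardized(panel2.dosages)
    r = np.clip(Zs2.T @ y / (cfg.n2 - 1), -0.999999, 0.999999)
    z = r * np.sqrt(cfg.n2 - 2) / np.sqrt(1 - r**2)
    gwas = GwasSummary(
        pd.DataFrame(
            {
                "id": panel2.variant_ids,
                "a1": [v.a1 for v in panel2.variants],
                "a2": [v.a2 for v in panel2.variants],
                "z": z,
                "n": cfg.n2,
            }
        ),
        trait="simulated",
    )
    protein_ids = [pid for pr in pairs for pid in (pr.protein_a, pr.protein_b)]
    values = np.column_stack([col for A, B in exprs for col in (A, B)])
    expression = ExpressionTable(panel1.sample_ids, protein_ids, values)
    truth = {"pairs": [p.pair_id for p in pairs], "per_pair": truths, "theta": np.array(cfg.theta)}
    ds = SimDataset(cfg, panel1, panel2, expression, None, pairs[0], y, gwas, truth)
    ds.pairs = pairs
    return ds
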