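"""End-to-end orchestration: simulate -> preprocess -> train -> test.

Pairs are processed independently and results are written sorted by pair id,
so output is identical regardless of processing order. The run manifest
(config + seed + library versions, no timestamps) is sufficient to reproduce
a run exactly; re-running with the same config yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import CowasResult, bonferroni, compute_ld, pwas_summary, stage2_summary
from .io import (
    GenotypePanel,
    GwasSummary,
    read_covariates,
    read_expression_table,
    read_genotype_panel,
    read_gwas_summary,
    read_pairs,
    write_covariates,
    write_expression_table,
    write_genotype_panel,
    write_gwas_summary,
    write_pairs,
    write_weightset,
)
from .preprocess import PreprocessError, adjust_pair, map_pqtls, qc_variants
from .simulate import PRESETS, SimConfig, simulate_study
from .train import TrainConfig, TrainingError, metrics_frame, train_and_evaluate_pair

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("cowas")
if not logger.handlers:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("stage=%(stage)s pair=%(pair)s event=%(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def _log(stage: str, pair: str, message: str) -> None:
    logger.info(message, extra={"stage": stage, "pair": pair})


@dataclass
class RunConfig:
    """Every tunable of the pipeline in one place; defaults are the standard
    protocol settings (top-100 screening, 500 kb cis flank, 0.03 correlation
    filter, 80/20 split, Bonferroni at alpha 0.05)."""

    out_dir: str = "cowas_run"
    # input paths (ignored when simulating)
    genotypes: str = ""
    variant_meta: str = ""
    gwas_genotypes: str = ""
    gwas_variant_meta: str = ""
    expression: str = ""
    covariates: str = ""
    pairs: str = ""
    gwas: str = ""
    # simulation
    simulate: bool = False
    preset: str = "full"
    n_pairs: int = 1
    sim_n1: int = 1000
    sim_n2: int = 5000
    sim_p: int = 50
    # QC thresholds
    max_missing: float = 0.10
    min_mac: int = 100
    min_maf: float = 0.01
    hwe_p_min: float = 1e-15
    drop_palindromic: bool = True
    run_qc: bool = True
    # training
    penalty: str = "lasso"
    screen: str = "effect"
    top_k: int = 100
    cis_only: bool = False
    cis_flank: int = 500_000
    mode: str = "residual"
    min_corr: float = 0.03
    split: float = 0.8
    # testing
    alpha: float = 0.05
    correction: str = "bonferroni"
    n2_override: int = 0
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            penalty=self.penalty,
            screen=self.screen,
            top_k=self.top_k,
            cis_only=self.cis_only,
            cis_flank=self.cis_flank,
            mode=self.mode,
            min_corr=self.min_corr,
            split=self.split,
            seed=self.seed,
        )

    def to_file(self, path) -> None:
        lines = [f"{k}={v}" for k, v in dataclasses.asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        values = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(defaults, key)
            if isinstance(current, bool):
                values[key] = raw.lower() in ("1", "true", "yes")
            elif isinstance(current, int):
                values[key] = int(raw)
            elif isinstance(current, float):
                values[key] = float(raw)
            else:
                values[key] = raw
        return cls(**values)


def _load_inputs(config: RunConfig, input_dir: Path):
    """Either simulate a study (and persist it as the canonical TSV inputs)
    or read the user-supplied files."""
    if config.simulate:
        theta = PRESETS[config.preset]
        sim_cfg = SimConfig(
            n1=config.sim_n1, n2=config.sim_n2, p=config.sim_p,
            theta=theta, seed=config.seed,
        )
        ds = simulate_study(sim_cfg, config.n_pairs)
        input_dir.mkdir(parents=True, exist_ok=True)
        write_genotype_panel(ds.panel1, input_dir / "genotypes.tsv", input_dir / "variants.tsv")
        write_genotype_panel(
            ds.panel2, input_dir / "gwas_genotypes.tsv", input_dir / "gwas_variants.tsv"
        )
        write_expression_table(ds.expression, input_dir / "expression.tsv")
        write_pairs(ds.pairs, input_dir / "pairs.tsv")
        write_gwas_summary(ds.gwas, input_dir / "gwas.tsv")
        (input_dir / "truth.json").write_text(ds.truth_json())
        return ds.panel1, ds.panel2, ds.expression, None, ds.pairs, ds.gwas
    panel1 = read_genotype_panel(config.genotypes, config.variant_meta)
    panel2 = read_genotype_panel(config.gwas_genotypes, config.gwas_variant_meta)
    expression = read_expression_table(config.expression)
    covariates = read_covariates(config.covariates) if config.covariates else None
    pairs = read_pairs(config.pairs)
    gwas = read_gwas_summary(config.gwas)
    return panel1, panel2, expression, covariates, pairs, gwas


_RESULT_COLUMNS = [
    "pair_id", "theta_a", "se_a", "p_a", "theta_b", "se_b", "p_b",
    "theta_co", "se_co", "p_co", "f_stat", "p_global", "r2", "n2",
    "mode", "status", "sig_interaction", "sig_global",
]


def run_pipeline(config: RunConfig) -> Path:
    """Run the full workflow and return the results directory.

    Outputs: weight TSVs, pair metrics, pair association results, PWAS
    results, a significant-pair edge list, the QC report, and a manifest.
    Exit is successful even when zero pairs pass the imputation filter.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        return _run(config, out)
    except (PreprocessError, TrainingError, ValueError) as exc:
        failed_marker.write_text(f"{exc}\n")
        raise


def _run(config: RunConfig, out: Path) -> Path:
    panel1, panel2, expression, covariates, pairs, gwas = _load_inputs(
        config, out / "inputs"
    )
    _log("load", "-", f"loaded n1={panel1.n_samples} n2={panel2.n_samples} "
         f"variants={panel1.n_variants} pairs={len(pairs)}")

    if config.run_qc:
        panel1, report = qc_variants(
            panel1, config.max_missing, config.min_mac, config.min_maf,
            config.hwe_p_min, config.drop_palindromic,
        )
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        _log("qc", "-", f"surviving={len(report.surviving_ids)}")
        keep2 = [v for v in report.surviving_ids if v in set(panel2.variant_ids)]
        panel2 = panel2.subset(variant_ids=keep2)

    tc = config.train_config()
    weightsets = []
    results: list[CowasResult] = []
    pwas_rows = []
    pwas_seen: set[str] = set()
    weight_dir = out / "weights"
    weight_dir.mkdir(exist_ok=True)
    for pair in sorted(pairs, key=lambda p: p.pair_id):
        try:
            a_adj, b_adj, subset = adjust_pair(expression, covariates, pair)
            sub_panel = panel1.subset(samples=subset)
            qtl_a = map_pqtls(sub_panel, a_adj, pair.protein_a)
            qtl_b = map_pqtls(sub_panel, b_adj, pair.protein_b)
            ws = train_and_evaluate_pair(sub_panel, pair, a_adj, b_adj, qtl_a, qtl_b, tc)
        except (PreprocessError, TrainingError) as exc:
            _log("train", pair.pair_id, f"skipped: {exc}")
            continue
        weightsets.append(ws)
        write_weightset(ws, weight_dir / f"{pair.pair_id}.weights.tsv")
        _log("train", pair.pair_id,
             f"r_a={ws.metrics.r_a:.4f} r_b={ws.metrics.r_b:.4f} "
             f"r_co={ws.metrics.r_co:.4f} passed={ws.metrics.passed}")
        if not ws.metrics.passed or ws.status != "ok":
            continue
        ld = compute_ld(panel2, ws.union_variant_ids)
        n2 = config.n2_override or None
        res = stage2_summary(gwas, ld, ws, n2=n2)
        results.append(res)
        _log("test", pair.pair_id, f"p_co={res.p_co:.3g} p_global={res.p_global:.3g}")
        for protein, w in ((pair.protein_a, ws.w_a), (pair.protein_b, ws.w_b)):
            if protein in pwas_seen:
                continue
            pwas_seen.add(protein)
            pw = pwas_summary(gwas, ld, w, ws.union_variants, protein, n2=n2)
            pwas_rows.append((pw.protein_id, pw.theta, pw.se, pw.p, pw.n2, pw.status))

    if weightsets:
        metrics_frame(weightsets).to_csv(
            out / "pair_metrics.tsv", sep="\t", index=False, float_format="%.6g"
        )
    else:
        pd.DataFrame(columns=metrics_frame([]).columns).to_csv(
            out / "pair_metrics.tsv", sep="\t", index=False
        )

    res_df = pd.DataFrame([r.to_dict() for r in results])
    if len(res_df):
        flags_int, thr_int = bonferroni(res_df["p_co"].to_numpy(), config.alpha)
        flags_glob, thr_glob = bonferroni(res_df["p_global"].to_numpy(), config.alpha)
        res_df["sig_interaction"] = flags_int
        res_df["sig_global"] = flags_glob
        res_df = res_df.sort_values("pair_id")
    else:
        res_df = pd.DataFrame(columns=_RESULT_COLUMNS)
        thr_int = thr_glob = float("nan")
    res_df.to_csv(out / "cowas_results.tsv", sep="\t", index=False, float_format="%.6g")

    pwas_df = pd.DataFrame(
        pwas_rows, columns=["protein_id", "theta", "se", "p", "n2", "status"]
    ).sort_values("protein_id") if pwas_rows else pd.DataFrame(
        columns=["protein_id", "theta", "se", "p", "n2", "status"]
    )
    if len(pwas_df):
        flags, _ = bonferroni(pwas_df["p"].to_numpy(), config.alpha)
        pwas_df["significant"] = flags
    pwas_df.to_csv(out / "pwas_results.tsv", sep="\t", index=False, float_format="%.6g")

    edges = res_df.loc[
        res_df.get("sig_interaction", pd.Series(dtype=bool)).astype(bool)
        | res_df.get("sig_global", pd.Series(dtype=bool)).astype(bool),
        "pair_id",
    ] if len(res_df) else pd.Series(dtype=str)
    (out / "significant_pairs.txt").write_text(
        "".join(f"{e}\n" for e in edges.tolist())
    )

    manifest = {
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "versions": {
            "cowas": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_pairs_trained": len(weightsets),
        "n_pairs_tested": len(results),
        "bonferroni_threshold_interaction": thr_int,
        "bonferroni_threshold_global": thr_glob,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    config.to_file(out / "run_config.txt")
    _log("done", "-", f"trained={len(weightsets)} tested={len(results)} "
         f"significant={len(edges) if len(res_df) else 0}")
    return out
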