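"""Data model and TSV readers/writers shared by every stage.

All on-disk artifacts are plain UTF-8 tab-delimited text with a header row.
Missing dosages and missing expression values are encoded as ``NA``.
Genomic coordinates are 1-based, closed intervals throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantInfo",
    "GenotypePanel",
    "ExpressionTable",
    "PairSpec",
    "GwasSummary",
    "WeightSet",
    "read_genotype_panel",
    "write_genotype_panel",
    "read_expression_table",
    "write_expression_table",
    "read_covariates",
    "write_covariates",
    "read_pairs",
    "write_pairs",
    "read_gwas_summary",
    "write_gwas_summary",
    "read_weightset",
    "write_weightset",
]

_VALID_ALLELES = frozenset("ACGT")


class DataFormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass(frozen=True)
class VariantInfo:
    """A biallelic variant: ``a1`` is the effect (dosage-counted) allele."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise DataFormatError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.a1 == self.a2:
            raise DataFormatError(f"variant {self.id}: identical alleles {self.a1!r}")
        for allele in (self.a1, self.a2):
            if allele not in _VALID_ALLELES:
                raise DataFormatError(
                    f"variant {self.id}: allele {allele!r} not one of A/C/G/T"
                )

    @property
    def is_palindromic(self) -> bool:
        """Strand-ambiguous allele pair: A/T or C/G."""
        return {self.a1, self.a2} in ({"A", "T"}, {"C", "G"})


@dataclass
class GenotypePanel:
    """Samples-by-variants matrix of alternate-allele dosages in [0, 2].

    ``dosages[i, j]`` is the dosage of ``variants[j].a1`` in ``sample_ids[i]``;
    missing entries are NaN.
    """

    sample_ids: list[str]
    variants: list[VariantInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, p = self.dosages.shape
        if n != len(self.sample_ids):
            raise DataFormatError(
                f"dosage rows ({n}) != number of samples ({len(self.sample_ids)})"
            )
        if p != len(self.variants):
            raise DataFormatError(
                f"dosage columns ({p}) != number of variants ({len(self.variants)})"
            )
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise DataFormatError(f"duplicate variant id {dup.index[0]!r}")
        bad = np.argwhere((self.dosages < 0) | (self.dosages > 2))
        if bad.size:
            i, j = bad[0]
            raise DataFormatError(
                f"dosage {self.dosages[i, j]!r} out of [0, 2] at sample "
                f"{self.sample_ids[i]!r}, variant {self.variants[j].id!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v.id: j for j, v in enumerate(self.variants)}
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"variant {missing[0]!r} not present in panel")
        return np.array([lookup[i] for i in ids], dtype=int)

    def subset(
        self,
        samples: Sequence[str] | None = None,
        variant_ids: Sequence[str] | None = None,
    ) -> "GenotypePanel":
        """Subset preserving the requested order; never silently reorders."""
        rows = np.arange(self.n_samples)
        sample_ids = list(self.sample_ids)
        if samples is not None:
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in samples if s not in lookup]
            if missing:
                raise KeyError(f"sample {missing[0]!r} not present in panel")
            rows = np.array([lookup[s] for s in samples], dtype=int)
            sample_ids = list(samples)
        cols = np.arange(self.n_variants)
        variants = list(self.variants)
        if variant_ids is not None:
            cols = self.variant_index(variant_ids)
            variants = [self.variants[j] for j in cols]
        return GenotypePanel(sample_ids, variants, self.dosages[np.ix_(rows, cols)])


@dataclass
class ExpressionTable:
    """Samples-by-proteins abundance matrix; missing entries are NaN."""

    sample_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.protein_ids)):
            raise DataFormatError(
                f"expression shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.protein_ids)} proteins"
            )
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise DataFormatError("duplicate protein ids in expression table")

    def column(self, protein_id: str) -> np.ndarray:
        try:
            j = self.protein_ids.index(protein_id)
        except ValueError:
            raise KeyError(f"protein {protein_id!r} not in expression table") from None
        return self.values[:, j]


@dataclass(frozen=True)
class PairSpec:
    """A protein pair with the genomic windows of the coding genes."""

    protein_a: str
    protein_b: str
    gene_a_window: tuple[str, int, int]
    gene_b_window: tuple[str, int, int]

    def __post_init__(self) -> None:
        if self.protein_a == self.protein_b:
            raise DataFormatError(f"pair proteins must be distinct: {self.protein_a!r}")
        for win in (self.gene_a_window, self.gene_b_window):
            if win[1] > win[2]:
                raise DataFormatError(f"gene window start > end: {win}")

    @property
    def pair_id(self) -> str:
        return f"{self.protein_a}__{self.protein_b}"


@dataclass
class GwasSummary:
    """Harmonizable per-variant GWAS summary records.

    ``table`` has columns id, a1, a2, z, n. ``n_dropped`` tallies records
    discarded while reading (missing fields or non-positive standard errors).
    """

    table: pd.DataFrame
    trait: str = "trait"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        required = ["id", "a1", "a2", "z", "n"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataFormatError(f"GWAS table missing columns {missing}")
        self.table = self.table[required].reset_index(drop=True)
        if self.table["id"].duplicated().any():
            dup = self.table.loc[self.table["id"].duplicated(), "id"].iloc[0]
            raise DataFormatError(f"duplicate GWAS variant id {dup!r}")
        if not np.all(np.isfinite(self.table["z"].to_numpy(dtype=float))):
            raise DataFormatError("non-finite Z score in GWAS table")
        if (self.table["n"] < 5).any():
            bad = self.table.loc[self.table["n"] < 5, "id"].iloc[0]
            raise DataFormatError(f"per-variant N < 5 at {bad!r}")


@dataclass
class WeightSet:
    """Fitted variant weights for one pair on the union variant list.

    The three weight vectors share the same length and variant order; a
    weight is zero wherever a variant was not in that model's feature set.
    Weights are on the standardized-dosage scale.
    """

    pair_id: str
    union_variants: list[VariantInfo]
    w_a: np.ndarray
    w_b: np.ndarray
    w_co: np.ndarray
    mode: str = "residual"
    metrics: object | None = None
    status: str = "ok"

    def __post_init__(self) -> None:
        p = len(self.union_variants)
        for name in ("w_a", "w_b", "w_co"):
            w = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, w)
            if w.shape != (p,):
                raise DataFormatError(
                    f"{name} has shape {w.shape}, expected ({p},) to match the union list"
                )
        if self.mode not in ("residual", "product"):
            raise DataFormatError(f"unknown co-expression mode {self.mode!r}")

    @property
    def union_variant_ids(self) -> list[str]:
        return [v.id for v in self.union_variants]

    def weight_matrix(self) -> np.ndarray:
        """p x 3 matrix with columns (w_a, w_b, w_co)."""
        return np.column_stack([self.w_a, self.w_b, self.w_co])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)


def read_genotype_panel(dosage_path, variant_meta_path) -> GenotypePanel:
    """Read a dosage matrix plus its variant metadata sidecar.

    The dosage file has a ``sample_id`` first column and one column per
    variant; the metadata file has columns id, chrom, pos, a1, a2 and fixes
    the variant order of the returned panel.
    """
    meta = _read_tsv(variant_meta_path)
    required = ["id", "chrom", "pos", "a1", "a2"]
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise DataFormatError(f"variant metadata missing columns {missing}")
    dos = pd.read_csv(dosage_path, sep="\t", na_values=["NA"], keep_default_na=False)
    if dos.columns[0] != "sample_id":
        raise DataFormatError("dosage file must start with a 'sample_id' column")
    dosage_ids = list(dos.columns[1:])
    meta_ids = meta["id"].tolist()
    extra = sorted(set(dosage_ids) - set(meta_ids))
    if extra:
        raise DataFormatError(f"variant {extra[0]!r} in dosage file but not in metadata")
    absent = [i for i in meta_ids if i not in set(dosage_ids)]
    if absent:
        raise DataFormatError(f"variant {absent[0]!r} in metadata but not in dosage file")
    variants = [
        VariantInfo(r.id, str(r.chrom), int(r.pos), r.a1, r.a2)
        for r in meta.itertuples(index=False)
    ]
    values = dos[meta_ids].to_numpy(dtype=float)
    return GenotypePanel(dos["sample_id"].astype(str).tolist(), variants, values)


def write_genotype_panel(panel: GenotypePanel, dosage_path, variant_meta_path) -> None:
    dos = pd.DataFrame(panel.dosages, columns=panel.variant_ids)
    dos.insert(0, "sample_id", panel.sample_ids)
    dos.to_csv(dosage_path, sep="\t", index=False, na_rep="NA", float_format="%.17g")
    meta = pd.DataFrame(
        [(v.id, v.chrom, v.pos, v.a1, v.a2) for v in panel.variants],
        columns=["id", "chrom", "pos", "a1", "a2"],
    )
    meta.to_csv(variant_meta_path, sep="\t", index=False)


def _read_matrix_table(path) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if df.columns[0] != "sample_id":
        raise DataFormatError(f"{path}: first column must be 'sample_id'")
    ids = df["sample_id"].astype(str).tolist()
    cols = list(df.columns[1:])
    return ids, cols, df[cols].to_numpy(dtype=float)


def read_expression_table(path) -> ExpressionTable:
    sample_ids, protein_ids, values = _read_matrix_table(path)
    return ExpressionTable(sample_ids, protein_ids, values)


def write_expression_table(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(table.values, columns=table.protein_ids)
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def read_covariates(path) -> pd.DataFrame:
    """Covariate matrix indexed by sample id, one column per covariate."""
    sample_ids, names, values = _read_matrix_table(path)
    return pd.DataFrame(values, index=sample_ids, columns=names)


def write_covariates(cov: pd.DataFrame, path) -> None:
    out = cov.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


_PAIR_COLUMNS = [
    "protein_a", "protein_b",
    "chrom_a", "start_a", "end_a",
    "chrom_b", "start_b", "end_b",
]


def read_pairs(path) -> list[PairSpec]:
    df = _read_tsv(path)
    missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"pair list missing columns {missing}")
    return [
        PairSpec(
            r.protein_a,
            r.protein_b,
            (str(r.chrom_a), int(r.start_a), int(r.end_a)),
            (str(r.chrom_b), int(r.start_b), int(r.end_b)),
        )
        for r in df.itertuples(index=False)
    ]


def write_pairs(pairs: Sequence[PairSpec], path) -> None:
    rows = [
        (p.protein_a, p.protein_b, *p.gene_a_window, *p.gene_b_window) for p in pairs
    ]
    pd.DataFrame(rows, columns=_PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gwas_summary(path, z_mode: str = "auto", trait: str = "trait") -> GwasSummary:
    """Read GWAS summary statistics with either a ``z`` column or ``beta``+``se``.

    When effect sizes are given, Z = beta / se. Records with missing fields
    or se <= 0 are dropped and counted in the returned ``n_dropped`` tally.
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("id", "a1", "a2", "n"):
        if col not in df.columns:
            raise DataFormatError(f"GWAS file missing column {col!r}")
    has_z = "z" in df.columns
    has_beta = "beta" in df.columns and "se" in df.columns
    if not has_z and not has_beta:
        raise DataFormatError("GWAS file must provide either z or beta+se")
    if z_mode == "auto":
        z_mode = "z" if has_z else "beta_se"
    if z_mode == "z" and not has_z:
        raise DataFormatError("GWAS file has no 'z' column")
    if z_mode == "beta_se" and not has_beta:
        raise DataFormatError("GWAS file has no 'beta' and 'se' columns")

    n_input = len(df)
    if z_mode == "z":
        df["z"] = pd.to_numeric(df["z"], errors="coerce")
        keep = df["z"].notna()
    else:
        beta = pd.to_numeric(df["beta"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        keep = beta.notna() & se.notna() & (se > 0)
        df["z"] = beta / se
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    keep &= df["n"].notna() & df[["id", "a1", "a2"]].notna().all(axis=1)
    df = df.loc[keep].copy()
    df["id"] = df["id"].astype(str)
    df["n"] = df["n"].astype(int)
    return GwasSummary(
        table=df[["id", "a1", "a2", "z", "n"]],
        trait=trait,
        n_dropped=n_input - len(df),
    )


def write_gwas_summary(gwas: GwasSummary, path) -> None:
    gwas.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


_MODEL_LABELS = {"A": "w_a", "B": "w_b", "co": "w_co"}


def write_weightset(ws: WeightSet, path, metrics_path=None) -> None:
    """Long-format TSV: pair_id, model in {A, B, co}, variant_id, a1, weight."""
    rows = []
    for label, attr in _MODEL_LABELS.items():
        w = getattr(ws, attr)
        for v, weight in zip(ws.union_variants, w):
            rows.append((ws.pair_id, label, v.id, v.chrom, v.pos, v.a1, v.a2, ws.mode, weight))
    df = pd.DataFrame(
        rows,
        columns=["pair_id", "model", "variant_id", "chrom", "pos", "a1", "a2", "mode", "weight"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    if metrics_path is not None and ws.metrics is not None:
        from .train import metrics_frame  # local import: avoids module cycle

        metrics_frame([ws]).to_csv(metrics_path, sep="\t", index=False, float_format="%.17g")


def read_weightset(path) -> WeightSet:
    df = pd.read_csv(path, sep="\t")
    unknown = set(df["model"].unique()) - set(_MODEL_LABELS)
    if unknown:
        raise DataFormatError(f"unknown model label {sorted(unknown)[0]!r} in weight file")
    pair_ids = df["pair_id"].unique()
    if len(pair_ids) != 1:
        raise DataFormatError("weight file must contain exactly one pair")
    modes = df["mode"].unique()
    if len(modes) != 1:
        raise DataFormatError("inconsistent mode labels in weight file")
    first = df[df["model"] == "A"]
    variants = [
        VariantInfo(str(r.variant_id), str(r.chrom), int(r.pos), r.a1, r.a2)
        for r in first.itertuples(index=False)
    ]
    order = [v.id for v in variants]
    weights = {}
    for label, attr in _MODEL_LABELS.items():
        sub = df[df["model"] == label].set_index("variant_id")
        if sorted(sub.index) != sorted(order):
            raise DataFormatError(f"model {label} variant list differs from model A")
        weights[attr] = sub.loc[order, "weight"].to_numpy(dtype=float)
    return WeightSet(pair_id=str(pair_ids[0]), union_variants=variants, mode=str(modes[0]), **weights)
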