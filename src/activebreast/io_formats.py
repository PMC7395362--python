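"""Readers, writers and validated domain types for every table the pipeline touches.

Canonical dialects: tab-separated with a header for expression matrices
(first column = gene identifiers), comma-separated for covariate, variant
and hotspot tables, standard GMT for gene-set collections. Lines starting
with ``#`` are treated as provenance comments and skipped on read. Readers
never rescale or otherwise mutate numeric values; gene and sample
identifiers are matched case-sensitively by exact string equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SignatureDefinition",
    "GeneSetCollection",
    "ValidationError",
    "COVARIATE_COLUMNS",
    "VARIANT_COLUMNS",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_signature_table",
    "write_signature_table",
    "read_covariates",
    "write_covariates",
    "read_variants",
    "write_variants",
]


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


# --------------------------------------------------------------------------
# Expression matrices
# --------------------------------------------------------------------------

#: Allowed values of :attr:`ExpressionMatrix.scale`.
SCALES = ("tpm", "log2_median_centered")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix with per-sample batch labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
        Non-negative TPM when ``scale == "tpm"``; real-valued after
        log2/median-centre normalisation.
    batch
        Series mapping each sample identifier to its batch label
        (e.g. ``"F"`` for the formalin-fixed batch, ``"P"`` for PAXgene).
    scale
        Either ``"tpm"`` or ``"log2_median_centered"``.
    """

    values: pd.DataFrame
    batch: pd.Series
    scale: str = "tpm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene identifiers: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample identifiers: {dups[:5]}")
        self.batch = pd.Series(self.batch)
        missing = [s for s in self.values.columns if s not in self.batch.index]
        if missing:
            raise ValidationError(f"samples missing from batch map: {missing[:5]}")
        self.batch = self.batch.reindex(self.values.columns)
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.scale == "tpm" and (self.values.to_numpy() < 0).any():
            raise ValidationError("negative value in TPM-scale expression matrix")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def batches(self) -> list[str]:
        """Distinct batch labels, in order of first appearance."""
        return list(dict.fromkeys(self.batch))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.batch.loc[list(samples)], self.scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy(), self.scale)


def read_expression(
    path: str | Path,
    batch_map: Mapping[str, str],
    scale: str = "tpm",
) -> ExpressionMatrix:
    """Read a tab-separated gene x sample expression table.

    The first column carries gene identifiers, the header row sample
    identifiers. ``batch_map`` must cover every sample. Rows whose values
    are all missing are rejected (dropped with no imputation); any other
    missing or negative value is a validation error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    all_missing = df.isna().all(axis=1)
    df = df.loc[~all_missing]
    return ExpressionMatrix(df, pd.Series(dict(batch_map)), scale=scale)


def write_expression(m: ExpressionMatrix, path: str | Path, header_comment: str | None = None) -> None:
    """Write the matrix as TSV; optional ``#``-prefixed provenance header."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        m.values.to_csv(fh, sep="\t", index_label="gene")


# --------------------------------------------------------------------------
# Signatures
# --------------------------------------------------------------------------

SIGNATURE_METHODS = ("sign_corrected_average", "mean_log2_up")


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene-expression signature with up/down gene membership.

    ``method == "sign_corrected_average"`` scores a sample as the
    sign-corrected average of log2(TPM+1) over up- minus down-regulated
    genes; ``"mean_log2_up"`` is the plain mean over the up set, for
    signatures with no down component.
    """

    name: str
    up: frozenset = field(default_factory=frozenset)
    down: frozenset = field(default_factory=frozenset)
    method: str = "sign_corrected_average"

    def __post_init__(self) -> None:
        object.__setattr__(self, "up", frozenset(self.up))
        object.__setattr__(self, "down", frozenset(self.down))
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(
                f"signature {self.name!r}: genes in both up and down sets: {sorted(overlap)[:5]}"
            )
        if len(self.up) + len(self.down) < 1:
            raise ValidationError(f"signature {self.name!r} is empty")
        if self.method not in SIGNATURE_METHODS:
            raise ValidationError(f"signature {self.name!r}: unknown method {self.method!r}")


def read_signature_table(path: str | Path) -> list[SignatureDefinition]:
    """Read a signature membership table (TSV or CSV by extension).

    Expected columns: ``signature``, ``gene``, ``direction`` (up/down) and
    optionally ``method``; one row per (signature, gene).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    required = {"signature", "gene", "direction"}
    if not required.issubset(df.columns):
        raise ValidationError(f"signature table must have columns {sorted(required)}")
    out: list[SignatureDefinition] = []
    for name, grp in df.groupby("signature", sort=False):
        direction = grp["direction"].str.lower()
        bad = set(direction) - {"up", "down"}
        if bad:
            raise ValidationError(f"signature {name!r}: unknown direction values {sorted(bad)}")
        up = set(grp.loc[direction == "up", "gene"])
        down = set(grp.loc[direction == "down", "gene"])
        method = "sign_corrected_average"
        if "method" in grp.columns and grp["method"].notna().any():
            methods = set(grp["method"].dropna())
            if len(methods) > 1:
                raise ValidationError(f"signature {name!r}: conflicting methods {sorted(methods)}")
            method = methods.pop()
        out.append(SignatureDefinition(str(name), frozenset(up), frozenset(down), method))
    return out


def write_signature_table(sigs: Iterable[SignatureDefinition], path: str | Path) -> None:
    rows = []
    for sig in sigs:
        for g in sorted(sig.up):
            rows.append({"signature": sig.name, "gene": g, "direction": "up", "method": sig.method})
        for g in sorted(sig.down):
            rows.append({"signature": sig.name, "gene": g, "direction": "down", "method": sig.method})
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Gene-set collections (GMT)
# --------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets, as carried by GMT files. Names are case-preserved."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated gene ids."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{path}:{lineno}: GMT line has no genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not genes:
                raise ValidationError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# --------------------------------------------------------------------------
# Covariate tables
# --------------------------------------------------------------------------

#: Canonical covariate column names. ``sample_id`` and ``batch`` are required;
#: the rest may be absent or hold missing values (carried as NaN; association
#: operations use pairwise-complete deletion).
COVARIATE_COLUMNS = (
    "sample_id",
    "batch",
    "age",
    "bmi",
    "gail_score",
    "parity",
    "family_history",
    "pct_adipocyte",
    "pct_stromal",
    "pct_epithelial",
    "tdlu_count",
    "adipocyte_area",
    "phenotype",
)

_PCT_COLUMNS = ("pct_adipocyte", "pct_stromal", "pct_epithelial")


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in df.columns:
        raise ValidationError("covariate table must have a sample_id column")
    if df["sample_id"].duplicated().any():
        raise ValidationError("duplicated sample_id in covariate table")
    for col in _PCT_COLUMNS:
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < 0) | (vals > 100)).any():
                raise ValidationError(f"{col} outside [0, 100]")
    return df


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Read a per-sample covariate CSV; missing cells stay NaN."""
    df = pd.read_csv(path, comment="#")
    return validate_covariates(df)


def write_covariates(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    validate_covariates(df)
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# Variant-call tables
# --------------------------------------------------------------------------

#: Columns of an expressed-variant call table, one row per call.
VARIANT_COLUMNS = (
    "sample_id",
    "batch",
    "gene",
    "contig",
    "position",
    "ref",
    "alt",
    "likelihood",
    "ref_depth",
    "alt_depth",
    "af",
    "aa_change",
    "consequence",
)


def validate_variants(df: pd.DataFrame, af_tolerance: float = 0.05) -> pd.DataFrame:
    """Validate a variant table; adds an ``af_consistent`` flag column.

    Depth fields must be non-negative integers and AF within [0, 1].
    Where total depth > 0, AF is cross-checked against AD/(AD+ref depth);
    inconsistent rows are flagged, not dropped.
    """
    missing = [c for c in ("sample_id", "gene", "likelihood", "ref_depth", "alt_depth", "af") if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    if (df["alt_depth"].dropna() < 0).any() or (df["ref_depth"].dropna() < 0).any():
        raise ValidationError("negative read depth in variant table")
    af = df["af"].dropna()
    if ((af < 0) | (af > 1)).any():
        raise ValidationError("AF outside [0, 1] in variant table")
    total = df["ref_depth"] + df["alt_depth"]
    with np.errstate(invalid="ignore", divide="ignore"):
        implied = np.where(total > 0, df["alt_depth"] / total, np.nan)
    consistent = np.where(np.isnan(implied), True, np.abs(df["af"] - implied) <= af_tolerance)
    df = df.copy()
    df["af_consistent"] = consistent.astype(bool)
    return df


def read_variants(path: str | Path) -> pd.DataFrame:
    return validate_variants(pd.read_csv(path, comment="#"))


def write_variants(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
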