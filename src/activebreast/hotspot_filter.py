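"""Filtering of RNA-expressed cancer-gene hotspot variant calls and
per-sample mutation-burden statistics.

A call survives only if it clears every threshold — mutation likelihood
score >= 5, variant allele frequency 0.02 <= AF <= 0.40, variant allele
read depth AD >= 2, a predicted non-silent amino-acid change — and is
present in every supplied curated hotspot list (intersection, matching the
requirement that calls appear in both the MSK-IMPACT and GTEx-expressed
hotspot databases). All bounds are inclusive exactly as printed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .io_formats import ValidationError

__all__ = [
    "FilterThresholds",
    "HotspotList",
    "classify_silent",
    "filter_variants",
    "burden_per_sample",
    "burden_association",
    "SILENT_KEYWORDS",
    "NONSILENT_KEYWORDS",
]

#: Consequence-string keywords classed as silent (no predicted protein change).
SILENT_KEYWORDS = (
    "synonymous",
    "silent",
    "no_protein_change",
    "noncoding",
    "non_coding",
    "intron",
    "utr",
)

#: Consequence-string keywords classed as protein-altering.
NONSILENT_KEYWORDS = (
    "missense",
    "nonsense",
    "stop_gained",
    "stop_lost",
    "frameshift",
    "splice",
    "start_lost",
    "inframe",
)


def classify_silent(consequence: str) -> bool:
    """True if the consequence string denotes a silent (non-protein-altering) call.

    Unrecognised strings are conservatively classed as silent so that only
    calls with an affirmative protein-altering annotation pass the filter.
    """
    c = str(consequence).lower()
    if any(k in c for k in NONSILENT_KEYWORDS):
        return False
    return True


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive hotspot-filter bounds; defaults are the published heuristics."""

    likelihood_min: float = 5.0
    af_min: float = 0.02
    af_max: float = 0.40
    ad_min: int = 2

    def __post_init__(self) -> None:
        if self.af_min > self.af_max:
            raise ValidationError(f"AF lower bound {self.af_min} exceeds upper bound {self.af_max}")
        if not (0.0 <= self.af_min <= 1.0 and 0.0 <= self.af_max <= 1.0):
            raise ValidationError("AF bounds must lie in [0, 1]")
        if self.ad_min < 0:
            raise ValidationError("AD threshold must be non-negative")


@dataclass
class HotspotList:
    """A curated hotspot list keyed by (gene, AA change) and/or (gene, locus, ref, alt)."""

    name: str
    aa_keys: set = field(default_factory=set)  # {(gene, aa_change)}
    locus_keys: set = field(default_factory=set)  # {(gene, contig, position, ref, alt)}

    @classmethod
    def from_frame(cls, name: str, df: pd.DataFrame) -> "HotspotList":
        """Build from a CSV-derived frame with gene + aa_change and/or locus columns."""
        aa_keys: set = set()
        locus_keys: set = set()
        if {"gene", "aa_change"}.issubset(df.columns):
            sub = df.dropna(subset=["gene", "aa_change"])
            aa_keys = set(zip(sub["gene"].astype(str), sub["aa_change"].astype(str)))
        if {"gene", "contig", "position", "ref", "alt"}.issubset(df.columns):
            sub = df.dropna(subset=["contig", "position", "ref", "alt"])
            locus_keys = set(
                zip(
                    sub["gene"].astype(str),
                    sub["contig"].astype(str),
                    sub["position"].astype(int),
                    sub["ref"].astype(str),
                    sub["alt"].astype(str),
                )
            )
        if not aa_keys and not locus_keys:
            raise ValidationError(f"hotspot list {name!r} has no usable keys")
        return cls(name, aa_keys, locus_keys)

    def contains(self, row: pd.Series) -> bool:
        """Membership of one variant call; prefers the (gene, AA) key, falls back to locus."""
        gene = str(row.get("gene"))
        aa = row.get("aa_change")
        if self.aa_keys and aa is not None and not pd.isna(aa):
            if (gene, str(aa)) in self.aa_keys:
                return True
        if self.locus_keys:
            try:
                key = (gene, str(row["contig"]), int(row["position"]), str(row["ref"]), str(row["alt"]))
            except (KeyError, TypeError, ValueError):
                return False
            return key in self.locus_keys
        return False


def filter_variants(
    calls: pd.DataFrame,
    hotspot_lists: list[HotspotList] | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Return exactly the calls passing every threshold and every hotspot list.

    Input row order is preserved; the empty input yields an empty output.
    A precomputed boolean ``silent`` column is honoured; otherwise silence
    is derived from the ``consequence`` string via :func:`classify_silent`.
    """
    if calls.empty:
        return calls.copy()
    if "silent" in calls.columns:
        silent = calls["silent"].astype(bool)
    elif "consequence" in calls.columns:
        silent = calls["consequence"].map(classify_silent)
    else:
        raise ValidationError("variant table needs a 'silent' or 'consequence' column")
    keep = (
        (calls["likelihood"] >= thresholds.likelihood_min)
        & (calls["af"] >= thresholds.af_min)
        & (calls["af"] <= thresholds.af_max)
        & (calls["alt_depth"] >= thresholds.ad_min)
        & ~silent
    )
    if hotspot_lists:
        for hl in hotspot_lists:
            keep &= calls.apply(hl.contains, axis=1)
    return calls.loc[keep].copy()


def burden_per_sample(filtered: pd.DataFrame, all_samples: list[str]) -> pd.Series:
    """Surviving-call count per sample; samples with no calls get 0."""
    counts = pd.Series(0, index=pd.Index(all_samples, name="sample_id"), dtype=int)
    if not filtered.empty:
        observed = filtered["sample_id"].value_counts()
        counts = counts.add(observed.reindex(counts.index, fill_value=0), fill_value=0).astype(int)
    return counts


def burden_association(
    burden: pd.Series,
    covariates: pd.DataFrame,
    attribute: str,
) -> tuple[float, float]:
    """Spearman correlation of per-sample burden with a covariate.

    Uses pairwise-complete records only; returns (rho, two-sided p). A
    constant burden or attribute has undefined rank correlation and returns
    (nan, nan) explicitly rather than raising.
    """
    cov = covariates.set_index("sample_id")
    common = [s for s in burden.index if s in cov.index]
    pairs = pd.DataFrame({"burden": burden.loc[common], "attr": cov.loc[common, attribute]}).dropna()
    if len(pairs) < 3:
        raise ValidationError(f"burden_association needs >= 3 complete pairs (got {len(pairs)})")
    if pairs["burden"].nunique() == 1 or pairs["attr"].nunique() == 1:
        return float("nan"), float("nan")
    rho, p = spearmanr(pairs["burden"], pairs["attr"])
    return float(rho), float(p)
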