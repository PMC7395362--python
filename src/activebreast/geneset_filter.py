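"""Post-processing of gene set enrichment analysis (GSEA) report tables.

Adipose-associated gene sets are identified purely by name: keep any set
name containing "fat", "adip" or "lip" (case-insensitive) and then drop
names containing exclusion terms such as "sulfate"/"sulfation" (which
match "lip" via glycolipid sulfation pathways but are not adipose
biology). Enrichment is summarised at an FDR q threshold, by default 10%.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .io_formats import ValidationError

__all__ = [
    "EnrichmentSummary",
    "DEFAULT_INCLUDE",
    "DEFAULT_EXCLUDE",
    "select_adipose_sets",
    "summarize_enrichment",
    "adipose_overrepresentation_p",
    "read_gsea_report",
]

DEFAULT_INCLUDE = ("fat", "adip", "lip")
DEFAULT_EXCLUDE = ("sulfate", "sulfation")


def select_adipose_sets(
    names: list[str],
    include: tuple[str, ...] = DEFAULT_INCLUDE,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> list[str]:
    """Names containing >=1 include substring and no exclude substring.

    Matching is case-insensitive on the raw set name; input order is
    preserved. The exclusion list is user-extensible (the published list is
    illustrative, not exhaustive).
    """
    inc = tuple(t.lower() for t in include)
    exc = tuple(t.lower() for t in exclude)
    out = []
    for name in names:
        low = name.lower()
        if any(t in low for t in inc) and not any(t in low for t in exc):
            out.append(name)
    return out


@dataclass(frozen=True)
class EnrichmentSummary:
    """Counts of enriched sets overall and within the adipose-name subset."""

    n_records: int
    n_enriched: int
    n_adipose: int
    n_adipose_enriched: int
    q_threshold: float

    @property
    def pct_enriched(self) -> float:
        """Enriched sets as a percent of all records, one decimal."""
        return round(100.0 * self.n_enriched / self.n_records, 1) if self.n_records else 0.0

    @property
    def pct_adipose_of_enriched(self) -> float:
        """Adipose-named sets as a percent of enriched sets, one decimal."""
        return round(100.0 * self.n_adipose_enriched / self.n_enriched, 1) if self.n_enriched else 0.0

    @property
    def pct_adipose_background(self) -> float:
        """Adipose-named sets as a percent of all records, one decimal."""
        return round(100.0 * self.n_adipose / self.n_records, 1) if self.n_records else 0.0


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    required = {"name", "q"}
    if records.empty:
        return records
    if not required.issubset(records.columns):
        raise ValidationError(f"enrichment table needs columns {sorted(required)}")
    q = records["q"].dropna()
    if ((q < 0) | (q > 1)).any():
        raise ValidationError("FDR q outside [0, 1]")
    if "p" in records.columns:
        p = records["p"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("nominal p outside [0, 1]")
    if "size" in records.columns and (records["size"].dropna() < 1).any():
        raise ValidationError("gene set size < 1")
    return records


def summarize_enrichment(
    records: pd.DataFrame,
    q_threshold: float = 0.10,
    include: tuple[str, ...] = DEFAULT_INCLUDE,
    exclude: tuple[str, ...] = DEFAULT_EXCLUDE,
) -> EnrichmentSummary:
    """Count records with q <= threshold, overall and among adipose-named sets."""
    records = _validate_records(records)
    if records.empty:
        return EnrichmentSummary(0, 0, 0, 0, q_threshold)
    adipose = set(select_adipose_sets(records["name"].tolist(), include, exclude))
    enriched = records["q"] <= q_threshold
    is_adipose = records["name"].isin(adipose)
    return EnrichmentSummary(
        n_records=len(records),
        n_enriched=int(enriched.sum()),
        n_adipose=int(is_adipose.sum()),
        n_adipose_enriched=int((enriched & is_adipose).sum()),
        q_threshold=q_threshold,
    )


def adipose_overrepresentation_p(summary: EnrichmentSummary) -> float:
    """Hypergeometric upper-tail p for adipose sets among the enriched ones.

    Convenience statistic comparing the adipose fraction among enriched
    sets against the background adipose fraction (drawing ``n_enriched``
    sets without replacement from ``n_records`` of which ``n_adipose`` are
    adipose-named).
    """
    if summary.n_enriched == 0:
        return 1.0
    return float(
        hypergeom.sf(
            summary.n_adipose_enriched - 1,
            summary.n_records,
            summary.n_adipose,
            summary.n_enriched,
        )
    )


def read_gsea_report(path: str | Path) -> pd.DataFrame:
    """Read a GSEA report TSV into the canonical enrichment-record frame.

    Accepts both the standard GSEA column headers (NAME, NES, ``NOM p-val``,
    ``FDR q-val``, SIZE) and already-canonical lower-case names
    (name, nes, p, q, size, direction).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    renames = {
        "NAME": "name",
        "NES": "nes",
        "NOM p-val": "p",
        "FDR q-val": "q",
        "SIZE": "size",
        "DIRECTION": "direction",
    }
    df = df.rename(columns={k: v for k, v in renames.items() if k in df.columns})
    return _validate_records(df)
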