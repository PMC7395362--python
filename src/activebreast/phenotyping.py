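"""Transcriptome phenotyping: normalisation, variable-gene selection,
hierarchical clustering into Active/Inactive, signature scoring and
differential-gene counting.

The workflow mirrors the batch-specific classification of histologically
normal breast transcriptomes: log2(TPM+1) values are median-centred per
gene, samples are clustered (average linkage on 1 - Pearson correlation)
on variably expressed classifier genes (IQR > 0.8), the tree is cut into
two groups, and the group with the higher mean sign-corrected signature
score is labelled *Active*. The signature score of sample s is

    Ss = [ sum_{g in U} log2(Tg + 1) - sum_{g in D} log2(Tg + 1) ] / (|U| + |D|)

with U/D the up-/down-regulated signature genes actually present in the
matrix and Tg the TPM of gene g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, SignatureDefinition, ValidationError

__all__ = [
    "PhenotypeAssignment",
    "normalize_log2_median_center",
    "select_variable_genes",
    "cluster_phenotypes",
    "signature_score",
    "score_samples",
    "assign_labels",
    "diff_genes",
    "plot_heatmap",
]

ACTIVE = "Active"
INACTIVE = "Inactive"


@dataclass(frozen=True)
class PhenotypeAssignment:
    """Per-sample phenotype call with its numeric signature score."""

    sample_id: str
    batch: str
    label: str  # "Active" | "Inactive"
    score: float
    cluster: int


def normalize_log2_median_center(m: ExpressionMatrix, per_batch: bool = False) -> ExpressionMatrix:
    """log2(TPM+1)-transform and median-centre each gene.

    With ``per_batch=True`` the per-gene median is taken within each batch
    (used when batches are phenotyped independently); otherwise across all
    samples. Every gene's output median is exactly 0.
    """
    if m.scale != "tpm":
        raise ValidationError("normalize_log2_median_center expects a TPM-scale matrix")
    if m.n_genes == 0 or m.n_samples == 0:
        raise ValidationError("cannot normalise an empty expression matrix")
    log2 = np.log2(m.values + 1.0)
    if per_batch:
        centered = log2.copy()
        for b in m.batches():
            cols = m.batch.index[m.batch == b]
            sub = log2[cols]
            centered[cols] = sub.sub(sub.median(axis=1), axis=0)
    else:
        centered = log2.sub(log2.median(axis=1), axis=0)
    return ExpressionMatrix(centered, m.batch.copy(), scale="log2_median_centered")


def select_variable_genes(
    m: ExpressionMatrix,
    classifier_genes: set | frozenset | list,
    iqr_threshold: float = 0.8,
) -> list[str]:
    """Return classifier genes whose normalised IQR strictly exceeds the threshold.

    IQR uses linear interpolation between order statistics (numpy's default
    quantile rule). Output preserves the matrix's gene order. The default
    threshold of 0.8 is the variability gate used to pick the classifying
    gene panel.
    """
    if m.scale != "log2_median_centered":
        raise ValidationError("select_variable_genes expects a normalised matrix")
    classifier_genes = set(classifier_genes)
    present = [g for g in m.genes if g in classifier_genes]
    if not present:
        raise ValidationError(
            f"no classifier genes found in matrix ({len(classifier_genes)} requested, 0 matched)"
        )
    sub = m.values.loc[present]
    q75 = sub.quantile(0.75, axis=1)
    q25 = sub.quantile(0.25, axis=1)
    iqr = q75 - q25
    return [g for g in present if iqr[g] > iqr_threshold]


def _sample_distance(values: pd.DataFrame, metric: str) -> np.ndarray:
    """Condensed sample-sample distance matrix for clustering."""
    x = values.to_numpy().T  # samples x genes
    if metric == "correlation":
        # 1 - Pearson correlation between sample profiles; constant profiles
        # have undefined correlation -> treated as maximally distant from
        # everything but themselves.
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(x)
        dist = 1.0 - corr
        dist[np.isnan(dist)] = 2.0
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
        return squareform(dist, checks=False)
    if metric == "euclidean":
        from scipy.spatial.distance import pdist

        return pdist(x, metric="euclidean")
    raise ValidationError(f"unknown clustering metric {metric!r}")


def cluster_phenotypes(
    m: ExpressionMatrix,
    genes: list[str],
    metric: str = "correlation",
    method: str = "average",
) -> tuple[list[str], list[str]]:
    """Agglomerative clustering of samples into two groups on selected genes.

    Samples are sorted canonically before linkage so the bipartition is
    invariant to the input column order. Returns the two clusters as lists
    of sample ids, each ordered as in the input matrix.
    """
    genes = list(genes)
    if m.n_samples < 4:
        raise ValidationError("clustering requires at least 4 samples")
    if len(genes) < 2:
        raise ValidationError("clustering requires at least 2 selected genes")
    missing = [g for g in genes if g not in m.values.index]
    if missing:
        raise ValidationError(f"selected genes absent from matrix: {missing[:5]}")
    order = sorted(m.samples)
    sub = m.values.loc[genes, order]
    d = _sample_distance(sub, metric)
    if np.allclose(d, 0.0):
        raise ValidationError("degenerate clustering: all sample profiles identical")
    z = linkage(d, method=method)
    assignment = fcluster(z, t=2, criterion="maxclust")
    if len(set(assignment)) != 2:
        raise ValidationError("degenerate clustering: tree cut did not yield two clusters")
    member = dict(zip(order, assignment))
    c1 = [s for s in m.samples if member[s] == 1]
    c2 = [s for s in m.samples if member[s] == 2]
    return c1, c2


def signature_score(tpm: pd.Series | dict, sig: SignatureDefinition) -> float:
    """Sign-corrected average signature score of one sample.

    ``tpm`` maps gene id -> TPM (non-negative). Signature genes absent from
    the input are dropped from both the sums and the denominator counts, so
    the score stays a mean over observed genes. With
    ``method == "mean_log2_up"`` the score is the plain mean of log2(TPM+1)
    over the up set.
    """
    tpm = pd.Series(tpm)
    up = [g for g in sig.up if g in tpm.index]
    down = [g for g in sig.down if g in tpm.index]
    if sig.method == "mean_log2_up":
        if not up:
            raise ValidationError(f"signature {sig.name!r}: no up-genes present in sample")
        return float(np.mean(np.log2(tpm[up].to_numpy() + 1.0)))
    if not up and not down:
        raise ValidationError(f"signature {sig.name!r}: no signature gene present in sample")
    vals = tpm[up + down].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValidationError("signature_score expects non-negative TPM values")
    log2 = np.log2(vals + 1.0)
    total = log2[: len(up)].sum() - log2[len(up):].sum()
    return float(total / (len(up) + len(down)))


def score_samples(m: ExpressionMatrix, sig: SignatureDefinition) -> pd.Series:
    """Vectorised :func:`signature_score` over every sample of a TPM matrix."""
    if m.scale != "tpm":
        raise ValidationError("score_samples expects a TPM-scale matrix")
    up = [g for g in m.genes if g in sig.up]
    down = [g for g in m.genes if g in sig.down]
    if sig.method == "mean_log2_up":
        if not up:
            raise ValidationError(f"signature {sig.name!r}: no up-genes present in matrix")
        return np.log2(m.values.loc[up] + 1.0).mean(axis=0)
    if not up and not down:
        raise ValidationError(f"signature {sig.name!r}: no signature gene present in matrix")
    log2 = np.log2(m.values + 1.0)
    num = log2.loc[up].sum(axis=0) - log2.loc[down].sum(axis=0)
    return num / (len(up) + len(down))


def assign_labels(
    clusters: tuple[list[str], list[str]],
    m: ExpressionMatrix,
    classifier: SignatureDefinition,
) -> list[PhenotypeAssignment]:
    """Label the cluster with the higher mean signature score *Active*.

    The classifier signature carries Active-upregulated genes as U and
    Inactive-upregulated genes as D, so a higher sign-corrected score means
    a more Active-like transcriptome. Tied cluster means raise rather than
    resolving silently.
    """
    if len(clusters) != 2:
        raise ValidationError("assign_labels expects exactly two clusters")
    c1, c2 = (list(c) for c in clusters)
    if not c1 or not c2:
        raise ValidationError("assign_labels: empty cluster")
    scores = score_samples(m, classifier)
    m1, m2 = float(scores[c1].mean()), float(scores[c2].mean())
    if m1 == m2:
        raise ValidationError(
            "tied cluster mean signature scores; labelling requires an explicit ordering policy"
        )
    active, inactive = (c1, c2) if m1 > m2 else (c2, c1)
    active_set = set(active)
    out = []
    for s in m.samples:
        if s not in active_set and s not in set(inactive):
            continue
        out.append(
            PhenotypeAssignment(
                sample_id=s,
                batch=str(m.batch[s]),
                label=ACTIVE if s in active_set else INACTIVE,
                score=float(scores[s]),
                cluster=1 if s in set(c1) else 2,
            )
        )
    return out


def assignments_to_frame(assignments: list[PhenotypeAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"sample_id": a.sample_id, "batch": a.batch, "label": a.label, "score": a.score, "cluster": a.cluster}
            for a in assignments
        ]
    )


def phenotype_batch(
    m: ExpressionMatrix,
    classifier: SignatureDefinition,
    iqr_threshold: float = 0.8,
    metric: str = "correlation",
    method: str = "average",
) -> list[PhenotypeAssignment]:
    """Full within-batch phenotyping: normalise, select, cluster, label."""
    norm = normalize_log2_median_center(m)
    genes = select_variable_genes(norm, classifier.up | classifier.down, iqr_threshold)
    if len(genes) < 2:
        raise ValidationError(
            f"only {len(genes)} classifier genes exceed IQR {iqr_threshold}; cannot cluster"
        )
    clusters = cluster_phenotypes(norm, genes, metric=metric, method=method)
    return assign_labels(clusters, m, classifier)


def phenotype_cohort(
    m: ExpressionMatrix,
    classifier: SignatureDefinition,
    iqr_threshold: float = 0.8,
    metric: str = "correlation",
    method: str = "average",
) -> list[PhenotypeAssignment]:
    """Phenotype each batch independently and concatenate the assignments."""
    out: list[PhenotypeAssignment] = []
    for b in m.batches():
        cols = [s for s in m.samples if m.batch[s] == b]
        out.extend(phenotype_batch(m.subset_samples(cols), classifier, iqr_threshold, metric, method))
    return out


def diff_genes(m: ExpressionMatrix, labels: Mapping[str, str], fdr: float = 0.05) -> list[str]:
    """Genes differentially expressed between Active and Inactive samples.

    Per-gene two-sided Wilcoxon rank-sum (Mann-Whitney U) on expression
    values, Benjamini-Hochberg adjustment, genes with adjusted p < ``fdr``
    returned in matrix gene order.
    """
    labels = dict(labels)
    active = [s for s in m.samples if labels.get(s) == ACTIVE]
    inactive = [s for s in m.samples if labels.get(s) == INACTIVE]
    if len(active) < 3 or len(inactive) < 3:
        raise ValidationError(
            f"diff_genes needs >= 3 samples per group (got {len(active)} Active, {len(inactive)} Inactive)"
        )
    a = m.values[active].to_numpy()
    b = m.values[inactive].to_numpy()
    pvals = np.ones(m.n_genes)
    for i in range(m.n_genes):
        if np.ptp(np.concatenate([a[i], b[i]])) == 0.0:
            continue  # constant gene: no evidence of difference
        pvals[i] = mannwhitneyu(a[i], b[i], alternative="two-sided").pvalue
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [g for g, r in zip(m.genes, reject) if r]


def plot_heatmap(
    m: ExpressionMatrix,
    genes: list[str],
    assignments: list[PhenotypeAssignment],
    path: str,
) -> None:
    """Cluster-ordered sample x classifier-gene heat map written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = assignments_to_frame(assignments).sort_values(["label", "score"])
    order = [s for s in frame["sample_id"] if s in set(m.samples)]
    sub = m.values.loc[genes, order]
    fig, ax = plt.subplots(figsize=(max(6, len(order) * 0.08), max(4, len(genes) * 0.02)))
    vmax = np.nanpercentile(np.abs(sub.to_numpy()), 98) or 1.0
    ax.imshow(sub.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    n_active = int((frame["label"] == ACTIVE).sum())
    ax.axvline(len(order) - n_active - 0.5, color="black", lw=1)
    ax.set_xlabel("samples (Inactive | Active)")
    ax.set_ylabel(f"{len(genes)} classifier genes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
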