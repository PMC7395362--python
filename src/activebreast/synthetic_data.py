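"""Synthetic normal-breast cohort generator.

Emulates the statistical structure the pipeline assumes so every stage is
testable without any download: two latent transcriptome phenotypes
(*Active*/*Inactive*) shifting up-/down-regulated signature genes by ±δ
log2 units, two processing batches (F: 96 formalin-fixed samples, P: 55
PAXgene samples) with a per-gene monotone affine distortion and distinct
zero-inflation applied to one batch, phenotype-skewed tissue composition
(Active samples adipocyte-rich), covariate shifts (Active: higher Gail
score, larger adipocytes), and an expressed-variant table whose per-sample
burden rises with adipocyte fraction. Expression is generated per gene in
log2 space (Gaussian) and back-transformed to TPM; the batch distortion is
affine in log2 space, hence monotone in TPM, so per-gene quantile mapping
can in principle remove it exactly.

All outputs are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hotspot_filter import HotspotList
from .io_formats import ExpressionMatrix, SignatureDefinition, ValidationError

__all__ = [
    "CohortSpec",
    "generate_cohort",
    "generate_variant_fixture",
    "generate_enrichment_fixture",
    "classifier_signature",
    "default_hotspot_lists",
    "HOTSPOT_CATALOG",
]

#: Fixed catalogue of (gene, amino-acid change) hotspots the generator draws
#: from. TP53 entries are most numerous, mirroring its dominance among
#: expressed hotspots in normal tissue.
HOTSPOT_CATALOG: tuple[tuple[str, str], ...] = (
    ("TP53", "p.R175H"),
    ("TP53", "p.R248Q"),
    ("TP53", "p.R273H"),
    ("TP53", "p.R282W"),
    ("TP53", "p.G245S"),
    ("PIK3CA", "p.H1047R"),
    ("PIK3CA", "p.E545K"),
    ("EGFR", "p.L858R"),
    ("KRAS", "p.G12D"),
    ("AKT1", "p.E17K"),
    ("IDH1", "p.R132H"),
    ("ERBB2", "p.V777L"),
)

#: Hotspots present in the first curated list only (used to exercise the
#: both-lists intersection requirement).
_MSK_ONLY: tuple[tuple[str, str], ...] = (
    ("BRAF", "p.V600E"),
    ("NRAS", "p.Q61R"),
)


def default_hotspot_lists() -> list[HotspotList]:
    """The two curated hotspot lists matching :data:`HOTSPOT_CATALOG`."""
    msk = HotspotList("MSK-IMPACT", aa_keys=set(HOTSPOT_CATALOG) | set(_MSK_ONLY))
    gtex = HotspotList("GTEx-expressed", aa_keys=set(HOTSPOT_CATALOG))
    return [msk, gtex]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort; defaults mirror the study conditions.

    ``delta`` is the mean log2-unit expression shift of up-signature genes
    in Active samples (down-genes shift by −δ). ``active_fraction`` follows
    the observed per-batch Active rates (47/96 and 31/55). Composition is
    Dirichlet over (adipocyte, stromal, epithelial) nuclei fractions, with
    Active concentrated on adipocytes (~78% mean vs ~50%). Variant burden
    is Poisson with rate ``burden_base + burden_slope * adipocyte_fraction``.
    """

    n_per_batch: tuple[tuple[str, int], ...] = (("F", 96), ("P", 55))
    active_fraction: tuple[tuple[str, float], ...] = (("F", 47 / 96), ("P", 31 / 55))
    n_signature_up: int = 50
    n_signature_down: int = 50
    n_background: int = 900
    delta: float = 2.0
    # batch distortion: log2 value x -> scale*x + shift for the distorted batch
    distorted_batch: str = "P"
    distortion_scale_range: tuple[float, float] = (0.7, 1.3)
    distortion_shift_range: tuple[float, float] = (-1.0, 1.0)
    zero_inflation: tuple[tuple[str, float], ...] = (("F", 0.05), ("P", 0.10))
    # expression model (log2 space)
    baseline_mean_range: tuple[float, float] = (1.0, 6.0)
    gene_sd_range: tuple[float, float] = (0.5, 0.9)
    # tissue composition Dirichlet concentrations (adipocyte, stromal, epithelial)
    active_alpha: tuple[float, float, float] = (12.0, 1.5, 1.5)
    inactive_alpha: tuple[float, float, float] = (7.5, 3.75, 3.75)
    # covariate model
    gail_mean_inactive: float = 1.18
    gail_mean_active: float = 1.46
    gail_sd: float = 0.5
    age_mean: float = 46.0
    age_sd: float = 9.0
    age_shift_active: float = 2.0
    bmi_mean: float = 27.0
    bmi_sd: float = 5.0
    # variant model
    burden_base: float = 0.5
    burden_slope: float = 5.0
    fail_rate: float = 1.0  # Poisson rate of non-passing calls per sample
    af_beta: tuple[float, float] = (2.0, 28.0)
    ad_poisson_mean: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, n in self.n_per_batch:
            if n <= 0:
                raise ValidationError("n_per_batch entries must be positive")
        for _, f in self.active_fraction:
            if not (0.0 < f < 1.0):
                raise ValidationError("active_fraction must lie in (0, 1)")
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if min(self.n_signature_up, self.n_signature_down) < 1 or self.n_background < 0:
            raise ValidationError("gene counts must be positive")
        for _, z in self.zero_inflation:
            if not (0.0 <= z < 1.0):
                raise ValidationError("zero_inflation must lie in [0, 1)")

    @property
    def batches(self) -> dict[str, int]:
        return dict(self.n_per_batch)

    @property
    def active_fractions(self) -> dict[str, float]:
        return dict(self.active_fraction)

    @property
    def zero_rates(self) -> dict[str, float]:
        return dict(self.zero_inflation)


def classifier_signature(spec: CohortSpec) -> SignatureDefinition:
    """The planted Active/Inactive classifier signature for a spec's genes."""
    up = frozenset(f"SIGUP{i:04d}" for i in range(spec.n_signature_up))
    down = frozenset(f"SIGDN{i:04d}" for i in range(spec.n_signature_down))
    return SignatureDefinition("ActiveInactive", up, down, "sign_corrected_average")


def _gene_names(spec: CohortSpec) -> list[str]:
    return (
        [f"SIGUP{i:04d}" for i in range(spec.n_signature_up)]
        + [f"SIGDN{i:04d}" for i in range(spec.n_signature_down)]
        + [f"BG{i:04d}" for i in range(spec.n_background)]
    )


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one full synthetic cohort.

    Returns ``(expression, covariates, variants, truth)`` where ``truth``
    holds the latent per-sample phenotype (kept separate from the data
    tables) plus the adipocyte fraction used by the variant model, and the
    variant table carries ground-truth ``truth_pass`` filter flags.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec)
    n_genes = len(genes)
    n_up, n_down = spec.n_signature_up, spec.n_signature_down

    samples: list[str] = []
    batches: list[str] = []
    phenos: list[str] = []
    for b, n in spec.n_per_batch:
        n_active = int(round(spec.active_fractions[b] * n))
        labels = np.array(["Active"] * n_active + ["Inactive"] * (n - n_active))
        rng.shuffle(labels)
        for i in range(n):
            samples.append(f"{b}{i + 1:03d}")
            batches.append(b)
            phenos.append(labels[i])
    n_samples = len(samples)
    is_active = np.array([p == "Active" for p in phenos])

    # ---- expression in log2 space ------------------------------------
    mu = rng.uniform(*spec.baseline_mean_range, size=n_genes)
    sd = rng.uniform(*spec.gene_sd_range, size=n_genes)
    shift = np.zeros(n_genes)
    shift[:n_up] = spec.delta
    shift[n_up : n_up + n_down] = -spec.delta
    log2 = rng.normal(mu[:, None], sd[:, None], size=(n_genes, n_samples))
    log2 += shift[:, None] * is_active[None, :]

    # monotone per-gene affine distortion of one batch
    a = rng.uniform(*spec.distortion_scale_range, size=n_genes)
    b_ = rng.uniform(*spec.distortion_shift_range, size=n_genes)
    in_distorted = np.array([bt == spec.distorted_batch for bt in batches])
    log2[:, in_distorted] = a[:, None] * log2[:, in_distorted] + b_[:, None]

    tpm = np.maximum(np.exp2(log2) - 1.0, 0.0)
    for bt, z in spec.zero_inflation:
        cols = np.array([x == bt for x in batches])
        mask = rng.random(size=(n_genes, int(cols.sum()))) < z
        block = tpm[:, cols]
        block[mask] = 0.0
        tpm[:, cols] = block

    expr = ExpressionMatrix(
        pd.DataFrame(tpm, index=genes, columns=samples),
        pd.Series(batches, index=samples),
        scale="tpm",
    )

    # ---- tissue composition and covariates ---------------------------
    comp = np.empty((n_samples, 3))
    comp[is_active] = rng.dirichlet(spec.active_alpha, size=int(is_active.sum()))
    comp[~is_active] = rng.dirichlet(spec.inactive_alpha, size=int((~is_active).sum()))

    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n_samples) + spec.age_shift_active * is_active, 27, 66)
    gail_mean = np.where(is_active, spec.gail_mean_active, spec.gail_mean_inactive)
    gail = np.clip(rng.normal(gail_mean, spec.gail_sd), 0.1, None)
    gail = np.where(age < 35, np.nan, gail)  # risk score not computable for young donors
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, n_samples), 17, 45)
    parity = rng.poisson(2.0, n_samples)
    family_history = rng.random(n_samples) < 0.15
    tdlu = rng.poisson(5.0 + 45.0 * comp[:, 2])
    adipocyte_area = np.clip(
        rng.normal(2400.0, 350.0, n_samples) + 250.0 * is_active, 500.0, None
    )

    covariates = pd.DataFrame(
        {
            "sample_id": samples,
            "batch": batches,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "gail_score": np.round(gail, 3),
            "parity": parity,
            "family_history": family_history,
            "pct_adipocyte": np.round(100 * comp[:, 0], 2),
            "pct_stromal": np.round(100 * comp[:, 1], 2),
            "pct_epithelial": np.round(100 * comp[:, 2], 2),
            "tdlu_count": tdlu,
            "adipocyte_area": np.round(adipocyte_area, 1),
        }
    )

    # ---- expressed-variant calls -------------------------------------
    variants = _generate_variants(rng, spec, samples, batches, comp[:, 0])

    truth = pd.DataFrame(
        {
            "sample_id": samples,
            "batch": batches,
            "phenotype": phenos,
            "adipocyte_fraction": comp[:, 0],
        }
    )
    return expr, covariates, variants, truth


def _passing_call(rng: np.random.Generator, spec: CohortSpec, sample: str, batch: str) -> dict:
    gene, aa = HOTSPOT_CATALOG[rng.integers(len(HOTSPOT_CATALOG))]
    while True:  # truncate AF into the passing window
        af = rng.beta(*spec.af_beta)
        if 0.02 <= af <= 0.40:
            break
    ad = max(2, int(rng.poisson(spec.ad_poisson_mean)))
    ref_depth = max(0, int(round(ad * (1.0 - af) / af)))
    af_obs = ad / (ad + ref_depth) if ad + ref_depth else af
    return {
        "sample_id": sample,
        "batch": batch,
        "gene": gene,
        "contig": "chr17" if gene == "TP53" else "chr3",
        "position": int(rng.integers(1_000_000, 90_000_000)),
        "ref": "C",
        "alt": "T",
        "likelihood": round(5.0 + float(rng.exponential(8.0)), 2),
        "ref_depth": ref_depth,
        "alt_depth": ad,
        "af": round(float(af_obs), 4),
        "aa_change": aa,
        "consequence": "missense",
        "truth_pass": True,
        "fail_reason": "",
    }


_FAIL_MODES = ("likelihood", "af_low", "af_high", "ad", "silent", "not_in_list")


def _failing_call(rng: np.random.Generator, spec: CohortSpec, sample: str, batch: str, mode: str) -> dict:
    rec = _passing_call(rng, spec, sample, batch)
    if mode == "likelihood":
        rec["likelihood"] = round(float(rng.uniform(0.0, 4.99)), 2)
    elif mode == "af_low":
        rec["af"] = round(float(rng.uniform(0.001, 0.019)), 4)
        rec["ref_depth"] = int(round(rec["alt_depth"] * (1 - rec["af"]) / rec["af"]))
    elif mode == "af_high":
        rec["af"] = round(float(rng.uniform(0.41, 0.95)), 4)
        rec["ref_depth"] = int(round(rec["alt_depth"] * (1 - rec["af"]) / rec["af"]))
    elif mode == "ad":
        rec["alt_depth"] = int(rng.integers(0, 2))
        rec["ref_depth"] = max(1, int(round(rec["alt_depth"] * (1 - rec["af"]) / rec["af"]))) if rec["af"] > 0 else 50
        rec["af"] = round(rec["alt_depth"] / (rec["alt_depth"] + rec["ref_depth"]), 4) if rec["alt_depth"] + rec["ref_depth"] else 0.1
        if not (0.02 <= rec["af"] <= 0.40):
            rec["af"] = 0.05
            rec["ref_depth"] = int(round(rec["alt_depth"] * 19)) if rec["alt_depth"] else 50
    elif mode == "silent":
        rec["consequence"] = "synonymous"
    elif mode == "not_in_list":
        gene, aa = _MSK_ONLY[rng.integers(len(_MSK_ONLY))]
        rec["gene"], rec["aa_change"] = gene, aa  # in MSK list but absent from GTEx list
    rec["truth_pass"] = False
    rec["fail_reason"] = mode
    return rec


def _generate_variants(
    rng: np.random.Generator,
    spec: CohortSpec,
    samples: list[str],
    batches: list[str],
    adipocyte_fraction: np.ndarray,
) -> pd.DataFrame:
    rows: list[dict] = []
    for s, b, adip in zip(samples, batches, adipocyte_fraction):
        n_pass = rng.poisson(spec.burden_base + spec.burden_slope * adip)
        for _ in range(n_pass):
            rows.append(_passing_call(rng, spec, s, b))
        for _ in range(rng.poisson(spec.fail_rate)):
            mode = _FAIL_MODES[rng.integers(len(_FAIL_MODES))]
            rows.append(_failing_call(rng, spec, s, b, mode))
    if not rows:
        return pd.DataFrame(columns=list(_passing_call(rng, spec, "x", "F").keys()))
    return pd.DataFrame(rows)


def generate_variant_fixture(
    n_records: int,
    spec: CohortSpec = CohortSpec(),
    seed: int | None = None,
) -> pd.DataFrame:
    """A controlled variant table with ground-truth filter flags.

    Records cycle through one clean (passing) call, four boundary passing
    calls (likelihood exactly 5, AF exactly 0.02 and 0.40, AD exactly 2 —
    all bounds inclusive) and one call violating each single criterion, so
    a downstream filter can be checked record by record against the
    ``truth_pass`` column.
    """
    if n_records < 0:
        raise ValidationError("n_records must be >= 0")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    boundary_edits = [
        {"likelihood": 5.0},
        {"af": 0.02},
        {"af": 0.40},
        {"alt_depth": 2},
    ]
    cycle_len = 1 + len(boundary_edits) + len(_FAIL_MODES)
    rows: list[dict] = []
    for i in range(n_records):
        sample = f"S{i % 24 + 1:03d}"
        batch = "F" if i % 2 == 0 else "P"
        k = i % cycle_len
        if k == 0:
            rows.append(_passing_call(rng, spec, sample, batch))
        elif k <= len(boundary_edits):
            rec = _passing_call(rng, spec, sample, batch)
            rec.update(boundary_edits[k - 1])
            if "af" in boundary_edits[k - 1]:
                rec["ref_depth"] = int(round(rec["alt_depth"] * (1 - rec["af"]) / rec["af"]))
            rec["fail_reason"] = "boundary"
            rows.append(rec)
        else:
            mode = _FAIL_MODES[k - 1 - len(boundary_edits)]
            rows.append(_failing_call(rng, spec, sample, batch, mode))
    if not rows:
        return pd.DataFrame(
            columns=list(_passing_call(np.random.default_rng(0), spec, "x", "F").keys())
        )
    return pd.DataFrame(rows)


def generate_enrichment_fixture(
    n_sets: int = 400,
    adipose_fraction: float = 0.03,
    enriched_fraction: float = 0.05,
    adipose_enrichment_boost: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """A synthetic GSEA-style result table with adipose-name structure.

    Adipose-named sets (fraction ``adipose_fraction`` of all sets) draw
    their FDR q from a distribution ``adipose_enrichment_boost`` times more
    likely to clear q <= 0.10 than background sets, emulating the observed
    over-representation of fat/adipocyte pathways among Active-upregulated
    sets. A few sulfation-named decoys that match "lip" are included.
    """
    rng = np.random.default_rng(seed)
    n_adipose = max(1, int(round(adipose_fraction * n_sets)))
    stems = ("FAT_METABOLISM", "ADIPOGENESIS", "LIPOLYSIS", "ADIPOCYTE_DIFFERENTIATION", "LIPID_STORAGE")
    names = [f"{stems[i % len(stems)]}_{i:03d}" for i in range(n_adipose)]
    n_decoy = max(1, n_sets // 100)
    names += [f"GLYCOLIPID_SULFATION_{i:03d}" for i in range(n_decoy)]
    names += [f"PATHWAY_{i:04d}" for i in range(n_sets - len(names))]
    is_adipose = np.array([n < n_adipose for n in range(len(names))])
    p_enr = np.where(
        is_adipose, min(1.0, enriched_fraction * adipose_enrichment_boost), enriched_fraction
    )
    enriched = rng.random(len(names)) < p_enr
    q = np.where(enriched, rng.uniform(0.0, 0.10, len(names)), rng.uniform(0.10001, 1.0, len(names)))
    return pd.DataFrame(
        {
            "name": names,
            "nes": np.round(np.where(enriched, rng.uniform(1.5, 3.0, len(names)), rng.normal(0, 1, len(names))), 3),
            "p": np.round(np.clip(q * rng.uniform(0.2, 1.0, len(names)), 0, 1), 5),
            "q": np.round(q, 5),
            "size": rng.integers(15, 500, len(names)),
            "direction": "Active-up",
        }
    )
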