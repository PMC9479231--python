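"""Replicate reproducibility and variant-precision statistics.

Reproducibility between replicate libraries of the same specimen is
summarized per gene by the maximum absolute difference (MAD) of log2
expression across the replicates. The replicate false-positive rate is
the fraction of genes whose MAD exceeds a log-fold-change cutoff:

    FPR = N(MAD > lfc) / N_total

optionally restricted to expressed genes (TPM > 4), since
low-expression genes dominate MAD noise. Variant precision is the
fraction of RNA-seq SNP calls confirmed by matched DNA exome calls,
stratified into the six pyrimidine-reference substitution categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

MUTATION_CATEGORIES = ("C>T", "C>G", "C>A", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ReplicateComparison:
    """FPR of one replicate group at one lfc cutoff."""

    replicate_group: str
    lfc_cutoff: float
    n_total: int
    n_exceed: int
    fpr: float
    mad_per_gene: pd.Series = field(repr=False)
    expression_filter: str | None = None


def mad_per_gene(expr: ExpressionMatrix, group_samples) -> pd.Series:
    """Per-gene maximum absolute pairwise difference across replicates.

    For each gene, the largest |difference| of expression between any
    two samples of the group (equivalently max - min); for a pair this
    is simply the absolute difference.
    """
    group_samples = list(group_samples)
    if len(group_samples) < 2:
        raise ValueError("a replicate group needs at least 2 samples")
    sub = expr.subset_samples(group_samples).values.to_numpy(dtype=float)
    mad = sub.max(axis=1) - sub.min(axis=1)
    return pd.Series(mad, index=expr.gene_ids, name="mad")


def fpr(
    mad: pd.Series,
    lfc: float,
    gene_filter: pd.Series | None = None,
    replicate_group: str = "",
) -> ReplicateComparison:
    """Replicate false-positive rate: fraction of genes with MAD
    strictly above the log-fold-change cutoff.

    ``gene_filter`` (boolean per gene, e.g. TPM > 4 in all replicates)
    restricts both numerator and denominator.
    """
    if lfc <= 0:
        raise ValueError("lfc cutoff must be positive")
    mad = pd.Series(mad)
    if gene_filter is not None:
        gene_filter = pd.Series(gene_filter).reindex(mad.index)
        if gene_filter.isna().any():
            raise ValueError("gene_filter does not cover all genes in mad")
        mad = mad[gene_filter.astype(bool)]
    n_total = int(mad.size)
    if n_total == 0:
        raise ValueError("FPR undefined: no genes pass the expression filter")
    n_exceed = int((mad > lfc).sum())
    return ReplicateComparison(
        replicate_group=replicate_group,
        lfc_cutoff=float(lfc),
        n_total=n_total,
        n_exceed=n_exceed,
        fpr=n_exceed / n_total,
        mad_per_gene=mad,
        expression_filter=None if gene_filter is None else "filtered",
    )


def expression_filter(
    tpm: ExpressionMatrix,
    group_samples,
    cutoff: float = 4.0,
    mode: str = "all",
) -> pd.Series:
    """Boolean per-gene filter: TPM > cutoff in all (or any) replicates
    of the group."""
    if tpm.layer != "TPM":
        raise ValueError(f"expected TPM layer, got {tpm.layer!r}")
    if mode not in ("all", "any"):
        raise ValueError("mode must be 'all' or 'any'")
    sub = tpm.subset_samples(list(group_samples)).values > cutoff
    return sub.all(axis=1) if mode == "all" else sub.any(axis=1)


def replicate_fpr_table(
    expr: ExpressionMatrix,
    groups: dict,
    lfc_grid=(0.5, 1.0, 1.5, 2.0),
    tpm: ExpressionMatrix | None = None,
    tpm_cutoff: float = 4.0,
    filter_mode: str = "all",
) -> pd.DataFrame:
    """FPR for every replicate group over an lfc grid, unfiltered and
    (when a TPM layer is given) TPM-filtered."""
    rows = []
    for group, samples in groups.items():
        mad = mad_per_gene(expr, samples)
        filt = (
            expression_filter(tpm, samples, tpm_cutoff, filter_mode)
            if tpm is not None
            else None
        )
        for lfc in lfc_grid:
            res = fpr(mad, lfc, replicate_group=str(group))
            rows.append((group, lfc, "none", res.n_total, res.n_exceed, res.fpr))
            if filt is not None:
                resf = fpr(mad, lfc, gene_filter=filt, replicate_group=str(group))
                rows.append(
                    (group, lfc, f"tpm>{tpm_cutoff:g}", resf.n_total, resf.n_exceed, resf.fpr)
                )
    return pd.DataFrame(
        rows, columns=["replicate_group", "lfc", "filter", "n_total", "n_exceed", "fpr"]
    )


def mutation_category(ref: str, alt: str) -> str:
    """Collapse a substitution to its pyrimidine-reference category
    (e.g. G>A is counted as C>T)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _COMPLEMENT or alt not in _COMPLEMENT or ref == alt:
        raise ValueError(f"not a single-nucleotide substitution: {ref}>{alt}")
    if ref in ("G", "A"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def snp_confirmation_rate(snp_rna, snp_dna) -> pd.DataFrame:
    """Precision of RNA-seq SNP calls against matched DNA calls.

    Variants are (chrom, pos, ref, alt) tuples (1-based positions,
    normalized alleles); duplicates and ordering are irrelevant. The
    rate is |RNA ∩ DNA| / |RNA| per substitution category and overall;
    categories with no RNA calls report NaN.
    """
    rna = {tuple(v) for v in snp_rna}
    dna = {tuple(v) for v in snp_dna}
    rows = []
    for cat in MUTATION_CATEGORIES:
        in_cat = {v for v in rna if mutation_category(v[2], v[3]) == cat}
        n_rna = len(in_cat)
        n_conf = len(in_cat & dna)
        rate = n_conf / n_rna if n_rna else np.nan
        rows.append((cat, n_rna, n_conf, rate))
    n_rna_all = len(rna)
    n_conf_all = len(rna & dna)
    rows.append(
        ("overall", n_rna_all, n_conf_all, n_conf_all / n_rna_all if n_rna_all else np.nan)
    )
    return pd.DataFrame(
        rows, columns=["category", "n_rna", "n_confirmed", "confirmation_rate"]
    ).set_index("category")


def mad_feature_association(
    mad: pd.Series, feature: pd.Series, n_bins: int = 5
) -> tuple[float, pd.DataFrame]:
    """Spearman correlation of per-gene MAD with a gene feature (length
    or GC fraction), plus per-quantile-bin median MAD.

    Returns NaN correlation with a warning when either input is
    constant (ties make the rank correlation undefined).
    """
    mad = pd.Series(mad)
    feature = pd.Series(feature).reindex(mad.index)
    if feature.isna().any():
        raise ValueError("feature does not cover all genes in mad")
    if feature.nunique() <= 1:
        raise ValueError("constant feature: correlation undefined")
    if mad.nunique() <= 1:
        warnings.warn("constant MAD: correlation undefined, returning NaN", stacklevel=2)
        rho = np.nan
    else:
        rho = float(stats.spearmanr(mad.to_numpy(), feature.to_numpy()).statistic)
    bins = pd.qcut(feature, q=n_bins, duplicates="drop")
    table = (
        pd.DataFrame({"mad": mad, "bin": bins})
        .groupby("bin", observed=True)["mad"]
        .agg(median_mad="median", n="size")
        .reset_index()
    )
    return rho, table
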