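"""Expression normalization: FPKM, TPM and TMM-scaled log2 CPM.

FPKM divides counts by exonic length (kb) and library size (millions).
TPM renormalizes FPKM so every sample sums to one million, which makes
the per-sample values comparable as transcript fractions. The TMM
(trimmed mean of M-values) factor corrects for composition bias between
libraries: for each sample a scaling factor is computed from the
doubly-trimmed, precision-weighted mean of gene-wise log ratios against
a reference sample, and CPM are computed on the resulting effective
library sizes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import DegenerateSampleError, ExpressionMatrix


def _check_positive_lengths(lengths: pd.Series, gene_ids: pd.Index) -> pd.Series:
    lengths = pd.Series(lengths)
    missing = gene_ids.difference(lengths.index)
    if len(missing) > 0:
        raise ValueError(f"missing gene lengths for {len(missing)} genes, e.g. {list(missing[:3])}")
    lengths = lengths.loc[gene_ids].astype(float)
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0].tolist()
        raise ValueError(f"non-positive gene lengths: {bad[:5]}")
    return lengths


def compute_fpkm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Fragments per kilobase of exon per million mapped reads.

    ``FPKM_gs = count_gs / (length_g / 1e3) / (libsize_s / 1e6)``.

    Parameters
    ----------
    counts
        Counts-layer matrix.
    lengths
        Exonic length in bp per gene id (Series indexed by gene id).
    """
    if counts.layer != "counts":
        raise ValueError(f"expected counts layer, got {counts.layer!r}")
    lengths = _check_positive_lengths(lengths, counts.gene_ids)
    libsize = counts.values.sum(axis=0)
    zero = libsize.index[libsize == 0].tolist()
    if zero:
        raise DegenerateSampleError(f"samples with zero total counts: {zero}")
    vals = counts.values.div(lengths / 1e3, axis=0).div(libsize / 1e6, axis=1)
    return ExpressionMatrix(vals, "FPKM")


def compute_tpm(fpkm: ExpressionMatrix) -> ExpressionMatrix:
    """Transcripts per million: per-sample FPKM rescaled to sum to 1e6."""
    if fpkm.layer != "FPKM":
        raise ValueError(f"expected FPKM layer, got {fpkm.layer!r}")
    colsum = fpkm.values.sum(axis=0)
    zero = colsum.index[colsum <= 0].tolist()
    if zero:
        raise DegenerateSampleError(f"samples with zero total FPKM: {zero}")
    return ExpressionMatrix(fpkm.values.div(colsum, axis=1) * 1e6, "TPM")


def counts_to_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convenience: counts -> FPKM -> TPM."""
    return compute_tpm(compute_fpkm(counts, lengths))


def _choose_reference(values: np.ndarray, libsize: np.ndarray) -> int:
    # sample whose 75th count-fraction percentile is closest to the mean
    uq = np.array(
        [np.quantile(values[:, j] / libsize[j], 0.75) for j in range(values.shape[1])]
    )
    return int(np.argmin(np.abs(uq - uq.mean())))


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    keep = (obs > 0) & (ref > 0)
    if keep.sum() == 0:
        return 1.0
    p_obs = obs[keep] / n_obs
    p_ref = ref[keep] / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M, used as inverse weight
    w = (n_obs - obs[keep]) / (n_obs * obs[keep]) + (n_ref - ref[keep]) / (n_ref * ref[keep])
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if sel.sum() == 0 or w[sel].sum() == 0:
        return 1.0
    return float(2 ** (np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])))


def tmm_factors(
    counts: ExpressionMatrix,
    ref_sample: str | None = None,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    normalize: bool = True,
) -> pd.Series:
    """Per-sample TMM scaling factors.

    The reference is the sample whose upper-quartile count fraction is
    closest to the cohort mean (deterministic; override with
    ``ref_sample``). Genes with zero counts in either member of a pair
    are excluded before trimming. With ``normalize=True`` the factor
    vector is divided by its geometric mean so it multiplies to 1.
    """
    if counts.layer != "counts":
        raise ValueError(f"expected counts layer, got {counts.layer!r}")
    if counts.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    values = counts.values.to_numpy(dtype=float)
    libsize = values.sum(axis=0)
    zero = counts.sample_ids[libsize == 0].tolist()
    if zero:
        raise DegenerateSampleError(f"samples with zero total counts: {zero}")
    if ref_sample is None:
        ref_idx = _choose_reference(values, libsize)
    else:
        if ref_sample not in counts.sample_ids:
            raise KeyError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = int(counts.sample_ids.get_loc(ref_sample))
    ref = values[:, ref_idx]
    n_ref = libsize[ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(values[:, j], ref, libsize[j], n_ref, logratio_trim, sum_trim)
            for j in range(values.shape[1])
        ]
    )
    if normalize:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


def tmm_log2cpm(
    counts: ExpressionMatrix,
    pseudocount: float = 1.0,
    ref_sample: str | None = None,
) -> ExpressionMatrix:
    """log2(CPM + pseudocount) on TMM effective library sizes.

    Effective library size is ``libsize * factor``; the pseudocount
    (default 1.0 on the CPM scale) keeps zeros finite.
    """
    factors = tmm_factors(counts, ref_sample=ref_sample)
    libsize = counts.values.sum(axis=0)
    eff = libsize * factors
    cpm = counts.values.div(eff / 1e6, axis=1)
    return ExpressionMatrix(np.log2(cpm + pseudocount), "logCPM")
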