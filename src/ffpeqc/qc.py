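"""Sample-level QC metrics and pass/fail flagging.

Three metrics summarize each library after quantification:

* ``median_cor_expr`` — the sample's median Spearman correlation of
  gene expression with every other sample in the cohort. Degraded
  libraries decorrelate from the cohort consensus.
* ``gene_reads`` — total reads assigned to genic regions.
* ``gene_tpm4`` — number of detected genes, operationalized as genes
  with TPM strictly greater than 4.

A sample fails QC when any metric falls strictly below its threshold
(defaults 0.75 / 25 million / 11,400; boundary values pass). Because a
technical control is sequenced in every batch, a failing control
condemns its whole batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

LOW_CORRELATION = "LOW_CORRELATION"
LOW_GENE_READS = "LOW_GENE_READS"
LOW_GENE_TPM4 = "LOW_GENE_TPM4"
BATCH_CONTROL_FAIL = "BATCH_CONTROL_FAIL"

FAIL_REASONS = (LOW_CORRELATION, LOW_GENE_READS, LOW_GENE_TPM4, BATCH_CONTROL_FAIL)


@dataclass(frozen=True)
class QCThresholds:
    """QC cutoffs; a metric strictly below its cutoff fails."""

    cor_min: float = 0.75
    reads_min: int = 25_000_000
    tpm4_min: int = 11_400

    def __post_init__(self) -> None:
        if not -1.0 <= self.cor_min <= 1.0:
            raise ValueError("cor_min must be in [-1, 1]")
        if self.reads_min <= 0 or self.tpm4_min <= 0:
            raise ValueError("reads_min and tpm4_min must be positive")


def pairwise_spearman(expr: ExpressionMatrix) -> pd.DataFrame:
    """Samples x samples Spearman rank correlation matrix.

    Ties receive average ranks. A constant sample (zero rank variance)
    has undefined correlations; its off-diagonal entries are NaN and a
    warning names it.
    """
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples for pairwise correlation")
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes for rank correlation")
    values = expr.values.to_numpy(dtype=float)
    constant = expr.sample_ids[np.ptp(values, axis=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant-expression samples (correlation undefined): {constant}",
            stacklevel=2,
        )
    # rank (average ties) then Pearson; constant columns yield NaN pairs
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rho = np.corrcoef(ranks, rowvar=False)
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=expr.sample_ids, columns=expr.sample_ids)


def median_cor_expr(corr: pd.DataFrame) -> pd.Series:
    """Per-sample median correlation with the rest of the cohort.

    The diagonal is excluded; undefined (NaN) pairs are dropped from
    each sample's median. Even counts use the midpoint median.
    """
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if corr.shape[0] < 2:
        raise ValueError("median_cor_expr undefined for a cohort of 1")
    arr = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(arr, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(arr, axis=1)
    if np.isnan(med).any():
        bad = corr.index[np.isnan(med)].tolist()
        warnings.warn(f"median correlation undefined for samples: {bad}", stacklevel=2)
    return pd.Series(med, index=corr.index, name="median_cor_expr")


def gene_level_metrics(counts: ExpressionMatrix, tpm: ExpressionMatrix) -> pd.DataFrame:
    """Per-sample ``gene_reads`` (count column sums) and ``gene_tpm4``
    (genes with TPM strictly > 4)."""
    if counts.layer != "counts":
        raise ValueError(f"expected counts layer, got {counts.layer!r}")
    if tpm.layer != "TPM":
        raise ValueError(f"expected TPM layer, got {tpm.layer!r}")
    if set(counts.sample_ids) != set(tpm.sample_ids):
        raise ValueError("counts and TPM matrices cover different sample sets")
    gene_reads = counts.values.sum(axis=0).astype(np.int64)
    gene_tpm4 = (tpm.values > 4).sum(axis=0).reindex(counts.sample_ids).astype(np.int64)
    return pd.DataFrame({"gene_reads": gene_reads, "gene_tpm4": gene_tpm4})


def compute_qc_metrics(
    counts: ExpressionMatrix,
    tpm: ExpressionMatrix,
    logcpm: ExpressionMatrix,
) -> pd.DataFrame:
    """All three QC metrics in one table (one row per sample)."""
    corr = pairwise_spearman(logcpm)
    med = median_cor_expr(corr)
    gl = gene_level_metrics(counts, tpm)
    out = gl.copy()
    out.insert(0, "median_cor_expr", med.reindex(out.index))
    return out


def flag_samples(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Assign PASS/FAIL status from the three metrics.

    A sample fails iff ``median_cor_expr < cor_min`` or
    ``gene_reads < reads_min`` or ``gene_tpm4 < tpm4_min`` (strict
    inequalities: boundary values pass). ``fail_reasons`` lists every
    violated criterion.
    """
    thresholds = thresholds or QCThresholds()
    required = ("median_cor_expr", "gene_reads", "gene_tpm4")
    for col in required:
        if col not in metrics.columns:
            raise ValueError(f"missing metric column {col!r}")
        nan = metrics.index[metrics[col].isna()].tolist()
        if nan:
            raise ValueError(f"metric {col!r} missing for samples: {nan}")
    out = metrics.copy()
    reasons = []
    for sid, row in metrics.iterrows():
        r = []
        if row["median_cor_expr"] < thresholds.cor_min:
            r.append(LOW_CORRELATION)
        if row["gene_reads"] < thresholds.reads_min:
            r.append(LOW_GENE_READS)
        if row["gene_tpm4"] < thresholds.tpm4_min:
            r.append(LOW_GENE_TPM4)
        reasons.append(tuple(r))
    out["fail_reasons"] = reasons
    out["status"] = ["FAIL" if r else "PASS" for r in reasons]
    return out


def propagate_batch_failure(flagged: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Fail every sample in a batch whose technical control failed.

    ``design`` must carry ``batch_id`` and ``is_technical_control``
    indexed by sample id. Batches with no control are left untouched
    with a warning.
    """
    for col in ("batch_id", "is_technical_control"):
        if col not in design.columns:
            raise ValueError(f"design table missing column {col!r}")
    missing = flagged.index.difference(design.index).tolist()
    if missing:
        raise ValueError(f"samples without batch assignment: {missing}")
    design = design.loc[flagged.index]
    out = flagged.copy()
    no_control = []
    for batch, members in design.groupby("batch_id").groups.items():
        controls = design.loc[members]
        controls = controls.index[controls["is_technical_control"].astype(bool)]
        if len(controls) == 0:
            no_control.append(batch)
            continue
        if (out.loc[controls, "status"] == "FAIL").any():
            for sid in members:
                out.at[sid, "status"] = "FAIL"
                prev = out.at[sid, "fail_reasons"]
                if BATCH_CONTROL_FAIL not in prev:
                    out.at[sid, "fail_reasons"] = tuple(prev) + (BATCH_CONTROL_FAIL,)
    if no_control:
        warnings.warn(f"batches with no technical control: {no_control}", stacklevel=2)
    return out
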