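"""Compute the three post-sequencing QC metrics and flag samples.

The metrics: per-sample median Spearman correlation with the rest of
the cohort (median_cor_expr), total gene-mapped reads (gene_reads) and
detected genes with TPM > 4 (gene_tpm4). A failing technical control
condemns its whole batch. Thresholds here are scaled to this small
synthetic cohort; on a real cohort the defaults are 0.75 / 25 million
/ 11,400.
"""

import ffpeqc
from ffpeqc import simulate as sim
from ffpeqc.qc import QCThresholds, compute_qc_metrics, flag_samples, propagate_batch_failure

bundle = sim.simulate_cohort(
    sim.SimulationParams(n_genes=1000, n_samples=24, n_batches=3, seed=1)
)
counts = bundle["counts"]
tpm = ffpeqc.counts_to_tpm(counts, bundle["catalog"]["length_bp"])
logcpm = ffpeqc.tmm_log2cpm(counts)

metrics = compute_qc_metrics(counts, tpm, logcpm)
flagged = flag_samples(metrics, QCThresholds(cor_min=0.75, reads_min=1_200_000, tpm4_min=400))
flagged = propagate_batch_failure(flagged, bundle["truth"])

print(flagged[["median_cor_expr", "gene_reads", "gene_tpm4", "status"]].round(3).to_string())
n_fail = (flagged["status"] == "FAIL").sum()
print(f"\n{len(flagged) - n_fail} PASS / {n_fail} FAIL")
# Samples with low latent quality decorrelate from the cohort, lose
# read depth and detect fewer genes, so they trip one or more criteria.
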