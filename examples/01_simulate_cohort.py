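"""Generate a synthetic FFPE RNA-seq cohort and look at its design.

Builds a 24-sample cohort in 3 sequencing batches, each carrying a
technical-control replicate, with latent per-sample quality driving
both the degradation of the count matrix and the pre-sequencing lab
metrics.
"""

from ffpeqc import simulate as sim

params = sim.SimulationParams(
    n_genes=1000, n_samples=24, n_batches=3, n_replicate_groups=3, seed=1
)
bundle = sim.simulate_cohort(params)

truth = bundle["truth"]
lab = bundle["lab_metrics"]
print(bundle["counts"])
print(f"batches: {truth['batch_id'].nunique()}, "
      f"controls: {int(truth['is_technical_control'].sum())}, "
      f"replicate groups: {truth['replicate_group'].nunique()}")
print(f"latent quality range: {truth['quality'].min():.2f} - {truth['quality'].max():.2f}")
for status, grp in lab.groupby("true_status"):
    print(f"{status:>4}: median RNA {grp['rna_qubit'].median():5.1f} ng/ul, "
          f"median library {grp['library_qubit'].median():4.2f} ng/ul  (n={len(grp)})")
# Degraded (FAIL) samples have visibly lower RNA and library
# concentrations -- the association the QC predictor will exploit.
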