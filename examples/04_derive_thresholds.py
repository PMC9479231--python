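"""Derive the three QC cutoffs from planted cohort relationships.

Three smoothed relationships determine the cutoffs: the knee of the
replicate-FPR vs median-correlation curve, the correlation cutoff
mapped through the correlation vs detected-genes relation, and the
depth at 85% of the detected-genes saturation plateau. The synthetic
structures are planted at (0.75, 11400, 25 million) so the derivation
can be checked against known truth.
"""

from ffpeqc import simulate as sim
from ffpeqc.thresholds import derive_thresholds

out = derive_thresholds(
    sim.planted_fpr_knee(seed=0),
    sim.planted_cor_tpm4(seed=0),
    sim.planted_saturation(seed=0),
)
print(f"correlation cutoff (knee of FPR curve):   {out['cor_min']:.3f}")
print(f"detected-gene cutoff (mapped at knee):    {out['tpm4_min']:.0f} genes")
print(f"read-depth cutoff (85% of saturation):    {out['reads_min'] / 1e6:.1f} million reads")
print(f"saturation plateau:                       {out['saturation_plateau']:.0f} genes")
# The derived triple lands on the planted (0.75, 11400, ~25e6) values
# within smoothing noise.
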