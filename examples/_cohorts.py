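"""Shared helper for the examples: a replicate pair at a given quality."""

import pandas as pd

from ffpeqc import simulate as sim


def replicate_pair(quality: float, seed: int, n_genes: int = 2000):
    params = sim.SimulationParams(n_genes=n_genes, seed=seed)
    catalog = sim.generate_gene_catalog(n_genes, seed)
    truth = pd.DataFrame(
        {
            "quality": [quality, quality],
            "batch_id": ["b1", "b2"],
            "replicate_group": ["g", "g"],
            "is_technical_control": [False, False],
            "true_status": ["PASS", "PASS"],
        },
        index=pd.Index(["A", "B"], name="sample_id"),
    )
    return catalog, sim.simulate_counts(catalog, truth, params)
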