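"""Gene x sample expression container with an explicit layer tag."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LAYERS = ("counts", "FPKM", "TPM", "logCPM")


class DegenerateSampleError(ValueError):
    """A sample column is unusable (e.g. zero total counts)."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample.
    layer
        One of ``counts``, ``FPKM``, ``TPM``, ``logCPM``. The counts
        layer must hold non-negative integers; TPM columns each sum to
        1e6.
    """

    values: pd.DataFrame
    layer: str

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if self.layer == "counts":
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts layer must hold integers")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.layer)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix(layer={self.layer!r}, "
            f"{self.n_genes} genes x {self.n_samples} samples)"
        )
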