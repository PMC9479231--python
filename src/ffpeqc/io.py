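"""Reading and writing the interchange formats.

The canonical count format is TSV: first column gene ids, header row of
sample ids. MatrixMarket (MTX) is accepted for sparse inputs with
``<stem>_rows.txt`` / ``<stem>_cols.txt`` sidecars holding gene and
sample names. SNP tables are TSV with columns chrom, pos (1-based),
ref, alt; a VCF adapter reading only the fixed columns is provided.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import ExpressionMatrix


def read_counts(path) -> ExpressionMatrix:
    """Read a count matrix from TSV or MTX (+name sidecars)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"counts file not found: {path}")
    if path.suffix == ".mtx":
        mat = spio.mmread(path)
        rows = _read_names(path.with_name(path.stem + "_rows.txt"))
        cols = _read_names(path.with_name(path.stem + "_cols.txt"))
        values = pd.DataFrame(
            np.asarray(mat.todense() if sparse.issparse(mat) else mat),
            index=rows,
            columns=cols,
        )
    else:
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            dups = sorted({h for h in header if header.count(h) > 1})
            raise ValueError(f"duplicate sample columns in {path.name}: {dups[:5]}")
        values = pd.read_csv(path, sep="\t", index_col=0)
        bad = values.columns[~values.dtypes.map(lambda d: np.issubdtype(d, np.number))]
        if len(bad) > 0:
            col = bad[0]
            rows = values.index[pd.to_numeric(values[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric counts in column {col!r}, e.g. rows {rows[:3].tolist()}"
            )
    if (values.to_numpy() < 0).any():
        raise ValueError("negative counts in input")
    return ExpressionMatrix(values, "counts")


def _read_names(path: Path) -> list:
    if not path.exists():
        raise FileNotFoundError(f"MTX sidecar name file not found: {path}")
    return path.read_text().split()


def write_matrix(expr: ExpressionMatrix, path, fmt: str = "tsv") -> None:
    """Write a matrix layer as TSV, or counts as MTX with sidecars."""
    path = Path(path)
    if fmt == "tsv":
        expr.values.to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(str(path.with_suffix("")), sparse.csr_matrix(expr.values.to_numpy()))
        path.with_name(path.stem + "_rows.txt").write_text("\n".join(map(str, expr.gene_ids)) + "\n")
        path.with_name(path.stem + "_cols.txt").write_text("\n".join(map(str, expr.sample_ids)) + "\n")
    else:
        raise ValueError("fmt must be 'tsv' or 'mtx'")


def read_gene_annotation(path) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, length_bp, gc_frac."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    annot = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("length_bp",):
        if col not in annot.columns:
            raise ValueError(f"annotation missing column {col!r}")
    if annot.index.has_duplicates:
        raise ValueError("duplicate gene ids in annotation")
    return annot


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata CSV indexed by sample_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    meta = pd.read_csv(path, index_col=0)
    if meta.index.has_duplicates:
        dups = meta.index[meta.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dups[:5]}")
    return meta


def read_snp_table(path) -> set:
    """SNP TSV (chrom, pos, ref, alt) -> set of variant keys."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"SNP table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    for col in ("chrom", "pos", "ref", "alt"):
        if col not in df.columns:
            raise ValueError(f"SNP table missing column {col!r}")
    return {
        (str(r.chrom), int(r.pos), str(r.ref).upper(), str(r.alt).upper())
        for r in df.itertuples()
    }


def read_vcf_variants(path) -> set:
    """Minimal VCF adapter: fixed columns of an uncompressed VCF only.

    Multi-allelic records are split; positions stay 1-based as in VCF.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"VCF not found: {path}")
    out = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"malformed VCF line: {line[:80]!r}")
            chrom, pos, _, ref, alts = fields[:5]
            for alt in alts.split(","):
                out.add((chrom, int(pos), ref.upper(), alt.upper()))
    return out
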