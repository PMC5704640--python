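"""Expression-matrix containers and I/O.

A gene-by-sample matrix of non-negative expression values is the input to
every stage of the pipeline.  Values may be raw counts, RPKM/FPKM, microarray
intensities, or unit-less synthetic numbers; downstream rank-based analyses
never care which, but the unit is carried along so that count-specific
operations (RPKM conversion) can refuse inappropriate input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

UNITS = ("counts", "RPKM", "FPKM", "intensity", "arbitrary")


class MatrixValidationError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with a declared unit.

    Parameters
    ----------
    data:
        Dense gene (rows) by sample (columns) table.  Gene and sample
        identifiers must be unique; values must be finite and non-negative.
    unit:
        One of :data:`UNITS`.
    """

    data: pd.DataFrame
    unit: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise MatrixValidationError(
                f"unknown unit {self.unit!r}; expected one of {UNITS}"
            )
        df = self.data
        if not isinstance(df, pd.DataFrame):
            raise MatrixValidationError("data must be a pandas DataFrame")
        dup = df.index[df.index.duplicated()].unique().tolist()
        if dup:
            raise MatrixValidationError(f"duplicate gene ids: {dup}")
        dup_s = df.columns[df.columns.duplicated()].unique().tolist()
        if dup_s:
            raise MatrixValidationError(f"duplicate sample ids: {dup_s}")
        df = df.astype(np.float64, copy=False)
        values = df.to_numpy()
        bad = ~np.isfinite(values)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise MatrixValidationError(
                f"non-finite value for gene {df.index[g]!r} in sample "
                f"{df.columns[s]!r}; encode missing measurements explicitly"
            )
        neg = values < 0
        if neg.any():
            g, s = np.argwhere(neg)[0]
            raise MatrixValidationError(
                f"negative value {values[g, s]} for gene {df.index[g]!r} "
                f"in sample {df.columns[s]!r}"
            )
        self.data = df

    # -- basic accessors ---------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        """Return one sample's profile as a gene-indexed Series."""
        return self.data[sample_id]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(genes)], unit=self.unit)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], unit=self.unit)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path,
    format: str = "delimited",
    sep: str = "\t",
    unit: str = "arbitrary",
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene-by-sample expression matrix.

    ``delimited``: genes as rows, first column = gene id, first row = sample
    ids (tab-separated by default, ``sep=','`` for CSV).
    ``sparse-matrix-market``: an MTX triplet file with companion one-id-per-
    line gene and sample lists (defaults: ``<path>.genes.txt`` and
    ``<path>.samples.txt``).

    Duplicate gene rows are an error, never silently collapsed.
    """
    path = Path(path)
    if format == "delimited":
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
    elif format == "sparse-matrix-market":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(
            path.suffix + ".genes.txt"
        )
        samples_path = Path(samples_path) if samples_path else path.with_suffix(
            path.suffix + ".samples.txt"
        )
        mat = mmread(str(path))
        if sparse.issparse(mat):
            mat = mat.toarray()
        genes = [ln.strip() for ln in Path(genes_path).read_text().splitlines() if ln.strip()]
        samples = [ln.strip() for ln in Path(samples_path).read_text().splitlines() if ln.strip()]
        df = pd.DataFrame(np.asarray(mat, dtype=np.float64), index=genes, columns=samples)
    else:
        raise ValueError(f"unknown format {format!r}")
    return ExpressionMatrix(df, unit=unit)


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    format: str = "delimited",
    sep: str = "\t",
) -> None:
    """Write a matrix; delimited output round-trips values to full precision."""
    path = Path(path)
    if format == "delimited":
        df = matrix.data.copy()
        df.insert(0, "gene_id", df.index)
        # repr is the shortest representation that round-trips a double
        df.to_csv(path, sep=sep, index=False,
                  float_format=lambda x: repr(float(x)))
    elif format == "sparse-matrix-market":
        mmwrite(str(path), sparse.csr_matrix(matrix.values))
        Path(str(path) + ".genes.txt").write_text("\n".join(matrix.gene_ids) + "\n")
        Path(str(path) + ".samples.txt").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_lengths(path: str | Path, sep: str = "\t") -> pd.Series:
    """Two-column table (gene id, exon length in bp) -> Series of lengths."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 2:
        raise ValueError("gene-length table needs two columns: gene id, length")
    ser = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str))
    bad = ser[(~np.isfinite(ser)) | (ser < 1)]
    if len(bad):
        raise ValueError(f"exon lengths must be >= 1 bp; offending genes: "
                         f"{bad.index.tolist()[:5]}")
    return ser


META_COLUMNS = ("sample_id", "condition", "input_mass_pg", "replicate_index")


def read_sample_metadata(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Sample metadata table.

    Required columns: sample_id, condition, input_mass_pg, replicate_index.
    Optional: paired_high_sample_ids (semicolon-separated list), protocol
    (single-end / paired-end).
    """
    meta = pd.read_csv(path, sep=sep)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing columns: {missing}")
    meta["sample_id"] = meta["sample_id"].astype(str)
    if (meta["input_mass_pg"] <= 0).any():
        bad = meta.loc[meta["input_mass_pg"] <= 0, "sample_id"].tolist()
        raise ValueError(f"input_mass_pg must be positive; offending samples: {bad}")
    dup = meta["sample_id"][meta["sample_id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate sample ids in metadata: {dup}")
    return meta


def apply_gene_mapping(
    matrix: ExpressionMatrix, mapping: Mapping[str, str] | pd.Series
) -> ExpressionMatrix:
    """Rename gene ids through a two-column mapping (old id -> new id).

    Genes absent from the mapping are dropped; a mapping that collapses two
    input genes onto one output id is an error (no silent aggregation).
    """
    mapping = dict(mapping.items() if isinstance(mapping, pd.Series) else mapping.items())
    keep = [g for g in matrix.gene_ids if g in mapping]
    df = matrix.data.loc[keep].rename(index=mapping)
    return ExpressionMatrix(df, unit=matrix.unit)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def compute_rpkm(
    counts: ExpressionMatrix,
    gene_lengths: Mapping[str, float] | pd.Series,
    total_mapped: Mapping[str, float] | pd.Series | None = None,
    paired_end: bool = False,
) -> ExpressionMatrix:
    """Reads/fragments per kilobase of exon model per million mapped reads.

    R = 1e9 * C / (N * L), with C the mapped reads on the gene's exons, N the
    per-sample total mapped reads and L the exon length in bp.  For paired-end
    data each fragment yields two reads, so the FPKM value is half the RPKM
    value and the output unit is FPKM.

    ``total_mapped`` defaults to the per-sample column sums.
    """
    if counts.unit not in ("counts", "arbitrary"):
        raise ValueError(f"compute_rpkm expects counts, got unit {counts.unit!r}")
    lengths = pd.Series(gene_lengths, dtype=float) if not isinstance(
        gene_lengths, pd.Series
    ) else gene_lengths.astype(float)
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"no exon length for genes: {missing[:5]}")
    L = lengths.reindex(counts.gene_ids).to_numpy()
    if (L < 1).any():
        raise ValueError("exon lengths must be >= 1 bp")
    if total_mapped is None:
        N = counts.values.sum(axis=0)
    else:
        N = pd.Series(total_mapped).reindex(counts.sample_ids).to_numpy(dtype=float)
    if np.any(~np.isfinite(N)) or np.any(N < 1):
        raise ValueError("total mapped reads must be >= 1 for every sample")
    vals = 1e9 * counts.values / (N[None, :] * L[:, None])
    unit = "RPKM"
    if paired_end:
        vals = vals / 2.0
        unit = "FPKM"
    return ExpressionMatrix(
        pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        unit=unit,
    )


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the shared gene universe.

    The output gene order follows the first matrix.  Mirrors the platform
    restriction step in which a signature's pair universe shrinks to the genes
    a given platform actually measures.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two matrices to intersect")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("gene universes have an empty intersection")
    order = [g for g in matrices[0].gene_ids if g in common]
    return [m.subset_genes(order) for m in matrices]
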