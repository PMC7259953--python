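"""UMI count-matrix container and readers/writers for 10x-style triplet files.

The core container is :class:`CountMatrix`: an integer genes x cells matrix of
UMI counts together with gene identifiers, cell barcodes, a sample label and a
per-gene mitochondrial flag. The matrix is always held genes x cells
internally; readers transpose as needed so that no caller ever has to reason
about on-disk orientation.

On disk, counts travel as a Matrix Market coordinate-integer file
(``matrix.mtx``) plus one-entry-per-line ``barcodes.tsv`` and ``features.tsv``
companions (the feature file may carry 1-3 tab-separated columns; the first is
the gene id). Bulk RNA-seq profiles are two-column (gene id, fpkm) TSV tables
with an optional header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .exceptions import FormatError

#: Default prefix identifying mitochondrial genes. Yeast mitochondrial ORFs
#: carry systematic names starting with "Q0" (e.g. Q0045 = COX1).
DEFAULT_MITO_PREFIX = "Q0"


@dataclass
class CountMatrix:
    """Genes x cells integer UMI count matrix with companion metadata.

    Parameters
    ----------
    counts
        Non-negative integer array, shape ``(n_genes, n_cells)``.
    gene_ids
        Unique gene identifiers, one per row.
    barcodes
        Unique cell barcodes, one per column.
    sample_label
        Free-text sample name (e.g. ``"glucose-12h"``).
    mito_flags
        Boolean per gene marking mitochondrial-genome genes.
    """

    counts: np.ndarray
    gene_ids: list[str]
    barcodes: list[str]
    sample_label: str = ""
    mito_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D genes x cells matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                raise FormatError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise FormatError("counts must be non-negative")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.barcodes = [str(b) for b in self.barcodes]
        if len(self.gene_ids) != self.counts.shape[0]:
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {self.counts.shape[0]} rows"
            )
        if len(self.barcodes) != self.counts.shape[1]:
            raise FormatError(
                f"{len(self.barcodes)} barcodes for {self.counts.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise FormatError("duplicate barcodes")
        if self.mito_flags is None:
            self.mito_flags = np.array(
                [g.startswith(DEFAULT_MITO_PREFIX) for g in self.gene_ids], dtype=bool
            )
        else:
            self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.mito_flags.shape != (self.counts.shape[0],):
            raise FormatError("mito_flags must have one entry per gene")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene_id: str) -> int:
        """Row index of ``gene_id`` (exact, case-sensitive match)."""
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(gene_id) from None

    def subset_cells(self, keep: np.ndarray | list) -> "CountMatrix":
        """Return a new CountMatrix restricted to the given column selection."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return CountMatrix(
            counts=self.counts[:, keep],
            gene_ids=list(self.gene_ids),
            barcodes=[self.barcodes[i] for i in keep],
            sample_label=self.sample_label,
            mito_flags=self.mito_flags.copy(),
        )


@dataclass
class BulkProfile:
    """Bulk RNA-seq expression profile: gene ids with fpkm values."""

    gene_ids: list[str]
    fpkm: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        if len(self.gene_ids) != self.fpkm.shape[0]:
            raise FormatError("gene_ids and fpkm length mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in bulk profile")
        if (self.fpkm < 0).any():
            raise ValueError("fpkm values must be non-negative")

    def as_series(self) -> pd.Series:
        return pd.Series(self.fpkm, index=self.gene_ids, name="fpkm")


def _read_single_column(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_mtx_triplet(
    matrix_path: str | os.PathLike,
    barcodes_path: str | os.PathLike,
    features_path: str | os.PathLike,
    sample_label: str = "",
    mito_prefix: str | tuple[str, ...] = DEFAULT_MITO_PREFIX,
) -> CountMatrix:
    """Read a 10x-style MTX triplet (matrix + barcodes + features).

    The Matrix Market file must be coordinate integer with genes as rows
    (1-based indices). ``mito_prefix`` configures the gene-id prefix rule used
    to set the mitochondrial flags; pass a tuple to allow several prefixes.
    """
    try:
        mat = scipy.io.mmread(os.fspath(matrix_path))
    except ValueError as exc:
        raise FormatError(f"cannot parse Matrix Market file: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    dense = np.asarray(mat.todense())
    if not np.issubdtype(dense.dtype, np.integer):
        if not np.allclose(dense, np.round(dense)):
            raise FormatError("matrix entries must be integers")
        dense = np.round(dense).astype(np.int64)
    if (dense < 0).any():
        raise FormatError("matrix entries must be non-negative")
    gene_ids = _read_single_column(features_path)
    barcodes = _read_single_column(barcodes_path)
    if dense.shape != (len(gene_ids), len(barcodes)):
        raise FormatError(
            f"matrix is {dense.shape} but companions give "
            f"{len(gene_ids)} features x {len(barcodes)} barcodes"
        )
    prefixes = (mito_prefix,) if isinstance(mito_prefix, str) else tuple(mito_prefix)
    mito = np.array([g.startswith(prefixes) for g in gene_ids], dtype=bool)
    return CountMatrix(dense.astype(np.int64), gene_ids, barcodes, sample_label, mito)


def write_mtx_triplet(cm: CountMatrix, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write ``matrix.mtx``, ``barcodes.tsv`` and ``features.tsv`` under out_dir.

    Returns a mapping of logical name to written path. The output round-trips
    exactly through :func:`read_mtx_triplet`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "barcodes": os.path.join(out_dir, "barcodes.tsv"),
        "features": os.path.join(out_dir, "features.tsv"),
    }
    sparse = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(paths["matrix"], sparse, field="integer")
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(b + "\n" for b in cm.barcodes)
    with open(paths["features"], "w") as fh:
        fh.writelines(g + "\n" for g in cm.gene_ids)
    return paths


def read_mtx_dir(
    directory: str | os.PathLike, sample_label: str = "", **kwargs
) -> CountMatrix:
    """Read a triplet set from a directory laid out by :func:`write_mtx_triplet`."""
    d = os.fspath(directory)
    return read_mtx_triplet(
        os.path.join(d, "matrix.mtx"),
        os.path.join(d, "barcodes.tsv"),
        os.path.join(d, "features.tsv"),
        sample_label=sample_label,
        **kwargs,
    )


def read_bulk_table(path: str | os.PathLike) -> BulkProfile:
    """Read a two-column (gene id, fpkm) TSV, with header auto-detection.

    The first row is treated as a header when its second field is not
    numeric. Duplicate gene ids and negative fpkm values are rejected.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"line {lineno}: expected 2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    if not rows:
        raise FormatError("empty bulk table")
    # header detection: non-numeric second field on row 1
    try:
        float(rows[0][1])
    except ValueError:
        rows = rows[1:]
    gene_ids = [r[0] for r in rows]
    try:
        fpkm = np.array([float(r[1]) for r in rows])
    except ValueError as exc:
        raise FormatError(f"non-numeric fpkm value: {exc}") from exc
    if len(set(gene_ids)) != len(gene_ids):
        raise FormatError("duplicate gene id in bulk table")
    if (fpkm < 0).any():
        raise ValueError("negative fpkm in bulk table")
    return BulkProfile(gene_ids, fpkm)


def write_bulk_table(bp: BulkProfile, path: str | os.PathLike) -> None:
    """Write a bulk profile as a headered two-column TSV."""
    df = pd.DataFrame({"gene_id": bp.gene_ids, "fpkm": bp.fpkm})
    df.to_csv(path, sep="\t", index=False)
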