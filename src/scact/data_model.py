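"""Containers and on-disk formats for single-cell omics matrices.

The two modalities handled throughout the package are a cell-by-gene RNA
expression matrix and a cell-by-peak chromatin-accessibility matrix.  Both are
carried in an :class:`OmicsMatrix`, which bundles the numeric matrix (dense or
sparse) with cell barcodes, feature identifiers, per-cell metadata (cell type,
batch, sequencing depth, doublet flag) and, for ATAC features, genomic peak
coordinates.  On disk, matrices live in a 10x-style directory: a Matrix Market
triplet file plus TSV barcode/feature tables, with per-cell metadata in an
optional sidecar TSV.  Dense TSV files are accepted for toy inputs.

Genomic coordinates are 0-based, half-open ``[start, end)``, matching BED and
the ``chrom:start-end`` peak-name convention.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

RNA = "RNA"
ATAC = "ATAC"

_PEAK_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


class FormatError(ValueError):
    """Raised when on-disk files disagree with each other or the contract."""


class AnnotationError(ValueError):
    """Raised when feature names cannot be parsed into genomic intervals."""


@dataclass(frozen=True)
class PeakAnnotation:
    """A genomic interval (0-based, half-open) attached to one feature."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self):
        if not self.chrom:
            raise AnnotationError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_peak_name(name: str) -> PeakAnnotation:
    """Parse a ``chrom:start-end`` feature id into a :class:`PeakAnnotation`."""
    m = _PEAK_RE.match(name)
    if m is None:
        raise AnnotationError(f"unparseable peak name: {name!r}")
    return PeakAnnotation(m.group(1), int(m.group(2)), int(m.group(3)))


@dataclass
class OmicsMatrix:
    """A cells × features matrix with metadata, for one modality.

    ``values`` may be dense ``ndarray`` or ``scipy.sparse`` (CSR is used
    internally); the numeric contract is identical either way.
    """

    values: object
    modality: str
    cell_ids: list
    feature_ids: list
    cell_meta: Optional[pd.DataFrame] = None
    feature_meta: Optional[list] = None  # list[PeakAnnotation] or None

    def __post_init__(self):
        if self.modality not in (RNA, ATAC):
            raise ValueError(f"unknown modality {self.modality!r}")
        self.cell_ids = list(self.cell_ids)
        self.feature_ids = list(self.feature_ids)
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise FormatError(
                f"{n} matrix rows but {len(self.cell_ids)} cell ids")
        if p != len(self.feature_ids):
            raise FormatError(
                f"{p} matrix columns but {len(self.feature_ids)} feature ids")
        if len(set(self.cell_ids)) != n:
            raise FormatError("duplicate cell ids")
        if len(set(self.feature_ids)) != p:
            raise FormatError("duplicate feature ids")
        if self.feature_meta is not None and len(self.feature_meta) != p:
            raise FormatError("feature_meta length mismatch")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids,
                                                         name="cell_id"))
        else:
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)
            self.cell_meta.index.name = "cell_id"
        if sp.issparse(self.values):
            self.values = self.values.tocsr()

    # ---- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dense(self) -> np.ndarray:
        if sp.issparse(self.values):
            return np.asarray(self.values.todense())
        return np.asarray(self.values)

    def subset_cells(self, index) -> "OmicsMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return OmicsMatrix(
            values=self.values[index],
            modality=self.modality,
            cell_ids=[self.cell_ids[i] for i in index],
            feature_ids=self.feature_ids,
            cell_meta=self.cell_meta.iloc[index],
            feature_meta=self.feature_meta,
        )

    def subset_features(self, index) -> "OmicsMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        vals = self.values[:, index] if not sp.issparse(self.values) \
            else self.values.tocsc()[:, index].tocsr()
        return OmicsMatrix(
            values=vals,
            modality=self.modality,
            cell_ids=self.cell_ids,
            feature_ids=[self.feature_ids[i] for i in index],
            cell_meta=self.cell_meta,
            feature_meta=None if self.feature_meta is None
            else [self.feature_meta[i] for i in index],
        )

    def copy(self) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            feature_ids=list(self.feature_ids),
            cell_meta=self.cell_meta.copy(),
            feature_meta=None if self.feature_meta is None
            else list(self.feature_meta),
        )


@dataclass
class Embedding:
    """A cells × k latent matrix tied to its source modality.

    ``mapped`` is True once the embedding has been pushed through one of the
    cross-modality mapping MLPs.
    """

    values: np.ndarray
    source_modality: str
    cell_ids: list
    mapped: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in embedding")
        if self.values.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows != cell ids")

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MTX = "matrix.mtx"
_BARCODES = "barcodes.tsv"
_FEATURES = "features.tsv"
_CELL_META = "cell_meta.tsv"
_DENSE = "dense.tsv"


def _parse_atac_features(feature_ids: Sequence[str]):
    anns, bad = [], []
    for fid in feature_ids:
        try:
            anns.append(parse_peak_name(fid))
        except AnnotationError:
            bad.append(fid)
    if bad:
        raise AnnotationError(
            f"unparseable ATAC feature names: {bad[:10]}"
            + ("..." if len(bad) > 10 else ""))
    return anns


def read_matrix_dir(path: str, modality: str) -> OmicsMatrix:
    """Read an OmicsMatrix from a 10x-style directory or a dense TSV dir.

    The Matrix Market file is stored features × cells (10x convention) and
    transposed on read.  ATAC feature ids of the form ``chrom:start-end`` are
    parsed into :class:`PeakAnnotation` objects.
    """
    mtx = os.path.join(path, _MTX)
    dense = os.path.join(path, _DENSE)
    if os.path.exists(mtx):
        for fname in (_BARCODES, _FEATURES):
            if not os.path.exists(os.path.join(path, fname)):
                raise FileNotFoundError(
                    f"missing {fname} in matrix directory {path}")
        values = sp.csr_matrix(scipy.io.mmread(mtx).T)
        cell_ids = _read_id_column(os.path.join(path, _BARCODES))
        feature_ids = _read_id_column(os.path.join(path, _FEATURES))
    elif os.path.exists(dense):
        df = pd.read_csv(dense, sep="\t", index_col=0)
        values = df.to_numpy(dtype=np.float64)
        cell_ids = [str(c) for c in df.index]
        feature_ids = [str(c) for c in df.columns]
    else:
        raise FileNotFoundError(
            f"neither {_MTX} nor {_DENSE} found in {path}")
    if values.shape[0] != len(cell_ids) or values.shape[1] != len(feature_ids):
        raise FormatError(
            f"matrix shape {values.shape} does not match id tables "
            f"({len(cell_ids)} barcodes, {len(feature_ids)} features)")
    meta_path = os.path.join(path, _CELL_META)
    cell_meta = None
    if os.path.exists(meta_path):
        cell_meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        cell_meta.index = cell_meta.index.astype(str)
    feature_meta = _parse_atac_features(feature_ids) if modality == ATAC else None
    return OmicsMatrix(values=values, modality=modality, cell_ids=cell_ids,
                       feature_ids=feature_ids, cell_meta=cell_meta,
                       feature_meta=feature_meta)


def _read_id_column(path: str) -> list:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0]
                for line in fh if line.strip()]


def write_matrix_dir(m: OmicsMatrix, path: str) -> None:
    """Write in the 10x-style directory layout readable by read_matrix_dir.

    Values round-trip exactly: integer matrices use the integer Matrix Market
    field; floats are written with 17 significant digits.
    """
    os.makedirs(path, exist_ok=True)
    vals = m.values if sp.issparse(m.values) else sp.csr_matrix(m.values)
    data = vals.data
    is_int = data.size == 0 or np.all(data == np.round(data))
    out = vals.T.tocoo()
    if is_int:
        out = out.astype(np.int64)
        scipy.io.mmwrite(os.path.join(path, _MTX), out, field="integer")
    else:
        scipy.io.mmwrite(os.path.join(path, _MTX), out, field="real",
                         precision=17)
    with open(os.path.join(path, _BARCODES), "w") as fh:
        fh.writelines(f"{c}\n" for c in m.cell_ids)
    with open(os.path.join(path, _FEATURES), "w") as fh:
        fh.writelines(f"{f}\n" for f in m.feature_ids)
    if m.cell_meta is not None and m.cell_meta.shape[1] > 0:
        m.cell_meta.to_csv(os.path.join(path, _CELL_META), sep="\t")


def align_metadata(m: OmicsMatrix, meta_table: pd.DataFrame) -> OmicsMatrix:
    """Attach per-cell metadata keyed by cell id; order of cells preserved.

    Cells absent from ``meta_table`` receive nulls.  Duplicate keys are an
    error (ambiguous assignment).
    """
    if meta_table.index.has_duplicates:
        dups = meta_table.index[meta_table.index.duplicated()].unique()
        raise FormatError(f"duplicate cell ids in metadata: {list(dups)[:10]}")
    out = m.copy()
    out.cell_meta = meta_table.reindex(m.cell_ids)
    out.cell_meta.index.name = "cell_id"
    return out


def write_bed(annotations: Sequence[PeakAnnotation], path: str,
              scores: Optional[Sequence[float]] = None,
              names: Optional[Sequence[str]] = None) -> None:
    """Export peak intervals as BED, with optional scores in column 5."""
    with open(path, "w") as fh:
        for i, a in enumerate(annotations):
            name = names[i] if names is not None else a.name
            score = 0.0 if scores is None else float(scores[i])
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{name}\t{score:.6g}\n")
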