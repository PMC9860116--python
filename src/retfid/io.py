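"""Core data model and I/O for sparse count matrices and cell annotations.

The in-memory containers are deliberately light: an :class:`ExpressionMatrix`
wraps a ``scipy.sparse`` matrix (genes x cells) together with gene / cell
identifier indexes and a layer tag, and a cell annotation is a plain
:class:`pandas.DataFrame` with a fixed set of required columns.  Conversion
to :class:`anndata.AnnData` is provided for interoperability with the wider
single-cell ecosystem.
"""

from __future__ import annotations

import gzip
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ._exceptions import FormatError, UsageError, VocabularyError

logger = logging.getLogger(__name__)

#: Canonical major retinal cell types.
CANONICAL_TYPES = (
    "RGC",
    "amacrine",
    "bipolar",
    "horizontal",
    "muller_glia",
    "rod",
    "cone",
)

#: Required columns of a cell-annotation table.
ANNOTATION_COLUMNS = ("cell_id", "cell_type", "dataset", "batch", "source")

#: Valid values of the ``source`` column.
SOURCES = ("tissue_mature", "tissue_fetal", "organoid")


@dataclass
class ExpressionMatrix:
    """A genes x cells expression matrix with identifier indexes.

    Parameters
    ----------
    values
        Sparse matrix of shape ``(n_genes, n_cells)`` holding non-negative
        counts or log-normalized values.
    genes, cells
        Unique, ordered gene / cell identifiers.
    layer
        ``"counts"`` (non-negative integers) or ``"lognorm"``.
    """

    values: sp.spmatrix
    genes: pd.Index
    cells: pd.Index
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.genes = pd.Index(self.genes, name="gene")
        self.cells = pd.Index(self.cells, name="cell")
        if self.layer not in ("counts", "lognorm"):
            raise UsageError(f"unknown layer {self.layer!r}")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            raise FormatError("duplicate gene identifiers")
        if not self.cells.is_unique:
            raise FormatError("duplicate cell identifiers")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("negative expression values")
        if self.layer == "counts" and self.values.nnz:
            if np.any(self.values.data != np.round(self.values.data)):
                raise FormatError("counts layer contains non-integer entries")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset_cells(self, cell_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.cells.get_indexer(pd.Index(cell_ids))
        if (idx < 0).any():
            raise UsageError("unknown cell identifiers in subset")
        return replace(self, values=self.values[:, idx],
                       cells=self.cells[idx])

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if (idx < 0).any():
            raise UsageError("unknown gene identifiers in subset")
        return replace(self, values=self.values[idx, :],
                       genes=self.genes[idx])

    def to_anndata(self):
        """Return an :class:`anndata.AnnData` (cells x genes) view."""
        import anndata as ad

        return ad.AnnData(
            X=self.values.T.tocsr(),
            obs=pd.DataFrame(index=self.cells.astype(str)),
            var=pd.DataFrame(index=self.genes.astype(str)),
        )


def _dedup(ids: pd.Index, what: str) -> pd.Index:
    """De-duplicate identifiers by '-1', '-2' suffixing (10x convention)."""
    if ids.is_unique:
        return ids
    counts: dict[str, int] = {}
    out = []
    for x in ids:
        n = counts.get(x, 0)
        out.append(x if n == 0 else f"{x}-{n}")
        counts[x] = n + 1
    dups = ids[ids.duplicated()].unique().tolist()
    logger.warning("de-duplicated %d %s identifiers by suffixing: %s",
                   len(dups), what, dups[:5])
    warnings.warn(f"duplicate {what} identifiers de-duplicated by suffixing")
    return pd.Index(out)


def _read_ids(path: str | Path) -> pd.Index:
    """Read newline-delimited TSV identifiers; first column is the id."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return pd.Index(df.iloc[:, 0].to_numpy())


def read_counts(matrix_path: str | Path,
                genes_path: str | Path,
                cells_path: str | Path) -> ExpressionMatrix:
    """Read a Matrix-Market count matrix with gene / cell identifier files.

    Supports 10x-style triplet MTX (optionally gzipped) with two-column (v2)
    or three-column (v3) feature files; the first column always provides the
    identifier.  Duplicate gene identifiers are de-duplicated by suffixing.
    """
    matrix_path = Path(matrix_path)
    opener = gzip.open if matrix_path.suffix == ".gz" else open
    try:
        with opener(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - re-raise as format error
        raise FormatError(f"cannot parse Matrix-Market file: {exc}") from exc
    mat = sp.csr_matrix(mat)
    genes = _dedup(_read_ids(genes_path), "gene")
    cells = _read_ids(cells_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"matrix header declares {mat.shape} but identifier files have "
            f"{len(genes)} genes and {len(cells)} cells"
        )
    if mat.nnz and (mat.data < 0).any():
        raise FormatError("negative entries in count matrix")
    if mat.nnz and np.any(mat.data != np.round(mat.data)):
        raise FormatError("non-integer entries in count matrix")
    return ExpressionMatrix(mat, genes, cells, layer="counts")


def write_counts(m: ExpressionMatrix, out_dir: str | Path,
                 prefix: str = "") -> None:
    """Write matrix.mtx / genes.tsv / barcodes.tsv into *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / f"{prefix}matrix.mtx"), m.values)
    pd.Series(m.genes).to_csv(out / f"{prefix}genes.tsv", sep="\t",
                              header=False, index=False)
    pd.Series(m.cells).to_csv(out / f"{prefix}barcodes.tsv", sep="\t",
                              header=False, index=False)


def log_normalize(m: ExpressionMatrix,
                  scale: float = 10_000.0) -> ExpressionMatrix:
    """Library-size normalize each cell to *scale* counts, then ln(1+x).

    Cells with zero total counts are dropped with a warning.
    """
    if m.layer != "counts":
        raise UsageError("matrix is already log-normalized")
    if scale <= 0:
        raise UsageError("scale must be positive")
    totals = np.asarray(m.values.sum(axis=0)).ravel()
    keep = totals > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} cells with zero counts")
    if not keep.any():
        raise UsageError("no cells remain after dropping zero-count cells")
    vals = m.values[:, keep].tocsc().astype(float)
    inv = scale / totals[keep]
    vals = vals @ sp.diags(inv)
    vals.data = np.log1p(vals.data)
    return ExpressionMatrix(vals.tocsr(), m.genes, m.cells[keep],
                            layer="lognorm")


@dataclass
class CellTypeVocabulary:
    """Canonical cell-type names and a raw-label -> canonical synonym map."""

    canonical: tuple[str, ...] = CANONICAL_TYPES
    synonyms: Mapping[str, str] = field(default_factory=dict)

    def lookup(self, raw: str) -> str | None:
        if raw in self.canonical:
            return raw
        if raw in self.synonyms:
            return self.synonyms[raw]
        key = raw.strip().lower()
        for k, v in self.synonyms.items():
            if k.lower() == key:
                return v
        for c in self.canonical:
            if c.lower() == key:
                return c
        return None


DEFAULT_SYNONYMS: dict[str, str] = {
    "MG": "muller_glia",
    "Muller glia": "muller_glia",
    "Muller glial": "muller_glia",
    "Mueller glia": "muller_glia",
    "muller": "muller_glia",
    "retinal ganglion cell": "RGC",
    "ganglion": "RGC",
    "RGCs": "RGC",
    "Rods": "rod",
    "Rod photoreceptor": "rod",
    "Cones": "cone",
    "Cone photoreceptor": "cone",
    "AC": "amacrine",
    "Amacrine cell": "amacrine",
    "BC": "bipolar",
    "Bipolar cell": "bipolar",
    "HC": "horizontal",
    "Horizontal cell": "horizontal",
    "other": "other",
}


def default_vocabulary() -> CellTypeVocabulary:
    return CellTypeVocabulary(CANONICAL_TYPES, dict(DEFAULT_SYNONYMS))


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Check the contract of a cell-annotation table and return it."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation is missing columns {missing}")
    if ann["cell_id"].duplicated().any():
        raise FormatError("duplicate cell_id in annotation")
    bad = set(ann["source"]) - set(SOURCES)
    if bad:
        raise FormatError(f"unknown source values {sorted(bad)}")
    fetal = ann["source"] == "tissue_fetal"
    if "age_dpc" not in ann.columns:
        if fetal.any():
            raise FormatError("tissue_fetal cells require age_dpc")
    elif ann.loc[fetal, "age_dpc"].isna().any():
        raise FormatError("tissue_fetal cells require non-null age_dpc")
    return ann


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, dtype={"cell_id": str, "batch": str,
                                   "dataset": str})
    return validate_annotation(ann)


def harmonize_cell_types(ann: pd.DataFrame,
                         vocab: CellTypeVocabulary | None = None,
                         strict: bool = True) -> pd.DataFrame:
    """Map raw cell-type labels onto the canonical vocabulary.

    Unmapped labels raise in strict mode; otherwise they become ``"other"``.
    Idempotent: canonical labels map to themselves.
    """
    vocab = vocab or default_vocabulary()
    mapped = {}
    unmapped = []
    for raw in pd.unique(ann["cell_type"]):
        hit = vocab.lookup(str(raw))
        if hit is None:
            unmapped.append(str(raw))
            mapped[raw] = "other"
        else:
            mapped[raw] = hit
    if unmapped:
        if strict:
            raise VocabularyError(
                f"unmapped cell-type labels: {sorted(unmapped)}")
        logger.info("mapping unmapped labels to 'other': %s", sorted(unmapped))
    out = ann.copy()
    out["cell_type"] = ann["cell_type"].map(mapped)
    logger.info("harmonized %d raw labels", len(mapped))
    return out


def write_report(report, out_dir: str | Path) -> dict[str, Path]:
    """Write a fidelity report as per-metric CSV, ranking CSV and JSON.

    *report* is a :class:`retfid.fidelity.FidelityReport`; the function only
    relies on its ``to_frames`` / ``to_dict`` surface.
    """
    if report.raw.empty:
        raise UsageError("nothing to write: empty report")
    metrics, ranking = report.to_frames()
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "metrics": out / "metrics.csv",
            "ranking": out / "ranking.csv",
            "report": out / "report.json",
        }
        metrics.to_csv(paths["metrics"], index=False)
        ranking.to_csv(paths["ranking"], index=False)
        with open(paths["report"], "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    except OSError as exc:
        raise OSError(f"cannot write report to {out}: {exc}") from exc
    return paths
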