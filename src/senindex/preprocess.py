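"""Expression-matrix ingestion, QC filters and the log-TPM transform.

The working container is a genes x cells matrix carrying a layer tag
(``counts``, ``tpm`` or ``log_tpm``); QC thresholds are defined on specific
layers.  The filters implemented here mirror a standard single-cell QC
recipe for droplet/plate data:

* drop cells with fewer than 1000 detected genes,
* drop cells whose mean expression over a housekeeping panel is at or below
  log2(TPM+1) = 2.5 (equivalently TPM = 2^2.5 - 1 on the linear layer),
* drop mitochondrial genes (symbol prefix ``MT-``) from the gene axis.

"Mitochondrial removal" here means removing the mitochondrial *genes*, not
filtering cells on mitochondrial fraction: downstream rank-based scoring
should not see the mitochondrial compartment at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

LAYERS = ("counts", "tpm", "log_tpm")

#: Required cell-metadata columns.
META_REQUIRED = ("cell_id", "patient_id", "cell_type", "response")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with identifiers and a layer tag."""

    values: np.ndarray | sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    layer: str = "counts"

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        n_g, n_c = self.values.shape
        if n_g != len(self.gene_ids) or n_c != len(self.cell_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        if self.min() < 0:
            raise ValueError("expression values must be non-negative")

    # ---- helpers -------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def min(self) -> float:
        v = self.values
        if sp.issparse(v):
            return float(v.min()) if v.shape[0] and v.shape[1] else 0.0
        arr = np.asarray(v)
        return float(arr.min()) if arr.size else 0.0

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)

    def subset_cells(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(mask)
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx]
        return ExpressionMatrix(vals, self.gene_ids,
                                [self.cell_ids[i] for i in idx], self.layer)

    def subset_genes(self, mask: np.ndarray) -> "ExpressionMatrix":
        idx = np.flatnonzero(mask)
        vals = self.values[idx, :] if not sp.issparse(self.values) else self.values.tocsr()[idx, :]
        return ExpressionMatrix(vals, [self.gene_ids[i] for i in idx],
                                self.cell_ids, self.layer)


@dataclass
class QCReport:
    """Bookkeeping for a sequence of QC filters."""

    n_cells_in: int
    n_cells_kept: int
    removals: dict[str, int] = field(default_factory=dict)
    thresholds: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_cells_kept + sum(self.removals.values()) != self.n_cells_in:
            raise ValueError("QCReport counts are inconsistent")


# --------------------------------------------------------------------------
# IO
# --------------------------------------------------------------------------

def read_mtx(mtx_path: str | Path, genes_path: str | Path,
             barcodes_path: str | Path, layer: str = "counts") -> ExpressionMatrix:
    """Read MatrixMarket matrix + gene/barcode TSVs (genes as rows)."""
    values = scipy.io.mmread(str(mtx_path)).tocsr()
    genes = pd.read_csv(genes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    cells = pd.read_csv(barcodes_path, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
    return ExpressionMatrix(values, genes, cells, layer)


def read_dense(path: str | Path, layer: str = "counts", sep: str | None = None) -> ExpressionMatrix:
    """Read a dense TSV/CSV with genes as rows and cells as columns."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), df.index.astype(str).tolist(),
                            df.columns.astype(str).tolist(), layer)


def write_mtx(m: ExpressionMatrix, mtx_path: str | Path, genes_path: str | Path,
              barcodes_path: str | Path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(m.values))
    Path(genes_path).write_text("\n".join(m.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(m.cell_ids) + "\n")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV; validates required columns."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_REQUIRED if c not in meta.columns]
    if missing:
        raise ValueError(f"cell metadata missing columns: {missing}")
    bad = set(meta["response"].dropna()) - {"R", "NR"}
    if bad:
        raise ValueError(f"response labels must be R/NR, got {sorted(bad)}")
    return meta


# --------------------------------------------------------------------------
# Filters and transforms
# --------------------------------------------------------------------------

def detected_genes_per_cell(m: ExpressionMatrix) -> np.ndarray:
    v = m.values
    if sp.issparse(v):
        return np.asarray((v > 0).sum(axis=0)).ravel()
    return (np.asarray(v) > 0).sum(axis=0)


def filter_min_genes(m: ExpressionMatrix, min_genes: int = 1000
                     ) -> tuple[ExpressionMatrix, QCReport]:
    """Remove cells with fewer than ``min_genes`` detected (nonzero) genes.

    A cell with exactly ``min_genes`` detected genes is retained (the rule
    is strict "< min_genes").
    """
    if m.n_cells == 0 or m.n_genes == 0:
        raise ValueError("empty expression matrix")
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    if min_genes > m.n_genes:
        logger.warning("min_genes=%d exceeds gene count %d; all cells may be removed",
                       min_genes, m.n_genes)
    detected = detected_genes_per_cell(m)
    keep = detected >= min_genes
    out = m.subset_cells(keep)
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_kept=out.n_cells,
        removals={"min_genes": int((~keep).sum())},
        thresholds={"min_genes": float(min_genes)},
    )
    return out, report


def to_log_tpm(m: ExpressionMatrix,
               gene_lengths_kb: dict[str, float] | None = None
               ) -> ExpressionMatrix:
    """Counts -> TPM -> log2(TPM + 1).

    With gene lengths (kb), TPM_g = (c_g / L_g) / sum_g(c_g / L_g) * 1e6 per
    cell.  Without lengths the per-cell scaling degrades to counts-per-million
    (every cell summed to 1e6), appropriate for UMI/droplet counts and for
    data already length-normalized upstream; a warning records the surrogate.
    Zero-total cells come out all-zero with a warning.
    """
    if m.layer != "counts":
        raise ValueError(f"to_log_tpm expects counts, got layer {m.layer!r}")
    dense = m.dense().astype(float)
    if gene_lengths_kb is not None:
        lengths = np.array([gene_lengths_kb.get(g, np.nan) for g in m.gene_ids])
        if np.isnan(lengths).any():
            missing = [g for g, l in zip(m.gene_ids, lengths) if np.isnan(l)]
            raise ValueError(f"missing gene lengths for {missing[:5]}...")
        if (lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        rate = dense / lengths[:, None]
    else:
        logger.warning("no gene lengths supplied; TPM computed as counts-per-million")
        rate = dense
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("%d zero-total cells emitted as all-zero", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(zero[None, :], 0.0, rate / np.where(zero, 1.0, totals)[None, :] * 1e6)
    return ExpressionMatrix(np.log2(tpm + 1.0), m.gene_ids, m.cell_ids, "log_tpm")


def housekeeping_filter(m: ExpressionMatrix, hk, threshold_log: float = 2.5
                        ) -> tuple[ExpressionMatrix, QCReport]:
    """Keep cells whose mean housekeeping expression strictly exceeds the cut.

    On the ``log_tpm`` layer the cut is ``threshold_log`` (default 2.5, i.e.
    mean log2(TPM+1) > 2.5); on the ``tpm`` layer the equivalent linear cut
    ``2**threshold_log - 1`` is used.  Cells exactly at the threshold are
    removed (strict ``>`` for retention).
    """
    hk_genes = set(hk.genes if hasattr(hk, "genes") else hk)
    present = [i for i, g in enumerate(m.gene_ids) if g in hk_genes]
    if not present:
        raise ValueError("no housekeeping genes present in the matrix")
    if m.layer == "log_tpm":
        cut = threshold_log
    elif m.layer == "tpm":
        cut = 2.0 ** threshold_log - 1.0
    else:
        raise ValueError(f"housekeeping_filter expects tpm/log_tpm, got {m.layer!r}")
    dense = m.dense()
    means = dense[present, :].mean(axis=0)
    keep = means > cut
    out = m.subset_cells(keep)
    report = QCReport(
        n_cells_in=m.n_cells,
        n_cells_kept=out.n_cells,
        removals={"housekeeping": int((~keep).sum())},
        thresholds={"housekeeping_threshold": float(cut)},
        notes=[f"{len(present)}/{len(hk_genes)} housekeeping genes present"],
    )
    return out, report


def remove_mito(m: ExpressionMatrix, mito_prefix: str = "MT-"
                ) -> tuple[ExpressionMatrix, QCReport]:
    """Drop genes whose symbol starts with the mitochondrial prefix."""
    prefix = mito_prefix.upper()
    is_mito = np.array([g.upper().startswith(prefix) for g in m.gene_ids])
    if not is_mito.any():
        logger.info("no genes matched mito prefix %r", mito_prefix)
    out = m.subset_genes(~is_mito)
    report = QCReport(
        n_cells_in=m.n_cells, n_cells_kept=m.n_cells,
        removals={}, thresholds={},
        notes=[f"removed {int(is_mito.sum())} mitochondrial genes"],
    )
    return out, report
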