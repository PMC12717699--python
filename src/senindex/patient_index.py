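"""Per-patient senescence index from percentile-classified cells.

Within a cell-type stratum, two percentile cutoffs over the pooled senescence
scores (all patients together) split cells into high (score >= upper cutoff),
low (score <= lower cutoff) and intermediate.  The per-patient index is then

    index = ((H/T) + ps) / ((L/T) + ps)        ps = 0.01

with H, L, T the high/low/total cell counts and ps a pseudocount so the
ratio is defined when a patient has no low-senescence cells.  index = 1 when
H = L; it grows toward (1 + ps)/ps = 101 when every cell is high.  Patients
contribute only when they have strictly more than ``min_cells`` cells in the
stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PS = 0.01


@dataclass(frozen=True)
class ThresholdPair:
    """Upper/lower percentile thresholds defining high/low senescence."""

    upper_pct: float
    lower_pct: float

    def __post_init__(self) -> None:
        if not (55 <= self.upper_pct <= 95):
            raise ValueError("upper_pct must be in [55, 95]")
        if not (5 <= self.lower_pct <= 45):
            raise ValueError("lower_pct must be in [5, 45]")
        if self.lower_pct >= self.upper_pct:
            raise ValueError("lower_pct must be < upper_pct")


@dataclass(frozen=True)
class PatientIndexRecord:
    """High/low/total cell counts and senescence index for patient x cell type."""

    patient_id: str
    cell_type: str
    H: int
    L: int
    T: int
    index: float
    ps: float = DEFAULT_PS
    response: str | None = None


def classify_cells(scores: pd.Series, tp: ThresholdPair) -> pd.Series:
    """Label each cell high/low/intermediate by pooled percentile cutoffs.

    Cutoffs use linear-interpolation percentiles of the pooled stratum
    scores; high iff score >= upper cutoff, low iff score <= lower cutoff.
    A degenerate stratum (all scores identical) makes every cell satisfy
    both rules and is resolved as all-intermediate with a warning.
    """
    if len(scores) < 2:
        raise ValueError("stratum must contain at least 2 cells")
    vals = scores.to_numpy(dtype=float)
    upper = np.percentile(vals, tp.upper_pct, method="linear")
    lower = np.percentile(vals, tp.lower_pct, method="linear")
    labels = pd.Series("intermediate", index=scores.index, name="sen_class")
    if upper <= lower:  # only possible when scores are (near) constant
        logger.warning("degenerate stratum: percentile cutoffs collapse; "
                       "all cells labelled intermediate")
        return labels
    labels[vals >= upper] = "high"
    labels[vals <= lower] = "low"
    return labels


def compute_index(H: int, L: int, T: int, ps: float = DEFAULT_PS) -> float:
    """((H/T) + ps) / ((L/T) + ps): strictly increasing in H, decreasing in L."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if H < 0 or L < 0 or H + L > T:
        raise ValueError("need 0 <= H, 0 <= L, H + L <= T")
    if ps <= 0:
        raise ValueError("pseudocount must be positive")
    return (H / T + ps) / (L / T + ps)


def cohort_indices(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    tp: ThresholdPair,
    sen_col: str = "senescence",
    min_cells: int = 10,
    ps: float = DEFAULT_PS,
) -> tuple[list[PatientIndexRecord], dict]:
    """Index per (patient, cell type) with strictly more than ``min_cells`` cells.

    Percentile cutoffs are pooled across patients within each cell type;
    a per-patient cutoff would make the index scale-free and useless for
    between-patient discrimination.  Returns records plus a report of the
    patients omitted for insufficient cells.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    meta = meta.loc[scores.index]
    records: list[PatientIndexRecord] = []
    omitted: list[dict] = []
    for ct, ct_idx in meta.groupby("cell_type").groups.items():
        sub_scores = scores.loc[ct_idx, sen_col]
        if len(sub_scores) < 2:
            logger.warning("cell type %r has < 2 cells; skipped", ct)
            continue
        labels = classify_cells(sub_scores, tp)
        sub_meta = meta.loc[ct_idx]
        for pid, p_idx in sub_meta.groupby("patient_id").groups.items():
            T = len(p_idx)
            if T <= min_cells:
                omitted.append({"patient_id": str(pid), "cell_type": str(ct), "T": T})
                continue
            lab = labels.loc[p_idx]
            H = int((lab == "high").sum())
            L = int((lab == "low").sum())
            resp = sub_meta.loc[p_idx, "response"].iloc[0] if "response" in sub_meta else None
            records.append(PatientIndexRecord(
                patient_id=str(pid), cell_type=str(ct), H=H, L=L, T=T,
                index=compute_index(H, L, T, ps), ps=ps, response=resp,
            ))
    if not records:
        logger.warning("no patient passed the min_cells=%d filter", min_cells)
    return records, {"min_cells": min_cells, "omitted": omitted}


def records_frame(records: list[PatientIndexRecord]) -> pd.DataFrame:
    """Tabulate index records (patient_id, cell_type, H, L, T, index, response)."""
    return pd.DataFrame([{
        "patient_id": r.patient_id, "cell_type": r.cell_type,
        "H": r.H, "L": r.L, "T": r.T, "index": r.index, "response": r.response,
    } for r in records])
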