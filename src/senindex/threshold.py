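"""Threshold-pair grid search with ROC/AUC selection and Youden cutoff.

Every (upper, lower) percentile pair defines high/low senescence classes,
hence a per-patient index, hence an ROC curve for discriminating
non-responders (NR, the positive class: higher senescence index predicts
non-response) from responders (R).  The default grid spans upper percentiles
55..95 and lower percentiles 5..45 in steps of 5 (81 pairs); the selected
pair maximizes AUC, with ties broken toward the pair retaining the larger
fraction of classified cells, then more patients, then lexicographically.
At the selected pair a Youden-optimal index cutoff (max sensitivity +
specificity - 1) is derived.

The search is in-sample model selection over 81 correlated candidates; the
reported best AUC carries selection optimism, so the number of pairs
searched is always part of the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .patient_index import DEFAULT_PS, ThresholdPair

logger = logging.getLogger(__name__)

DEFAULT_UPPER = tuple(range(55, 100, 5))  # 55..95
DEFAULT_LOWER = tuple(range(5, 50, 5))    # 5..45


class YoudenResult(NamedTuple):
    cutoff: float
    j: float
    sensitivity: float
    specificity: float


@dataclass
class GridResult:
    """All per-pair AUCs plus the selected optimum and its Youden cutoff."""

    records: pd.DataFrame          # upper, lower, auc, n_patients, retained_cell_fraction
    best_pair: ThresholdPair
    best_auc: float
    youden: YoudenResult
    n_pairs_searched: int
    cell_type: str | None = None
    diagnostics: dict = field(default_factory=dict)


def _as_binary(labels: Sequence[str], positive: str = "NR") -> np.ndarray:
    y = np.asarray(labels)
    classes = set(np.unique(y).tolist())
    if not classes <= {"R", "NR"}:
        raise ValueError(f"labels must be R/NR, got {sorted(classes)}")
    return (y == positive).astype(bool)


def roc_auc(indices: Sequence[float], labels: Sequence[str], positive: str = "NR") -> float:
    """AUC as the Mann-Whitney probability P(index_pos > index_neg) + ties/2.

    Computed from pooled average ranks; exactly equals pair counting with
    half-credit for ties.
    """
    x = np.asarray(indices, dtype=float)
    pos = _as_binary(labels, positive)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(x, method="average")
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def youden_cutoff(indices: Sequence[float], labels: Sequence[str],
                  positive: str = "NR") -> YoudenResult:
    """Exhaustive Youden scan over midpoints between distinct sorted values.

    Classification rule: predict positive (NR) iff index >= cutoff.
    Candidates are the midpoints between consecutive distinct values plus
    -inf and +inf.  Ties in J break toward higher specificity, then the
    smaller cutoff.
    """
    x = np.asarray(indices, dtype=float)
    pos = _as_binary(labels, positive)
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present")
    distinct = np.unique(x)
    candidates = [-np.inf]
    candidates += [(a + b) / 2.0 for a, b in zip(distinct[:-1], distinct[1:])]
    candidates += [np.inf]
    if len(distinct) == 1:
        logger.warning("all index values tied; Youden cutoff is degenerate")
    best: YoudenResult | None = None
    for c in candidates:
        pred = x >= c
        sens = float(pred[pos].mean())
        spec = float((~pred[~pos]).mean())
        j = sens + spec - 1.0
        cand = YoudenResult(float(c), j, sens, spec)
        if best is None or (cand.j, cand.specificity, -cand.cutoff) > (
                best.j, best.specificity, -best.cutoff):
            best = cand
    assert best is not None
    return best


def _stratum_arrays(scores: pd.DataFrame, meta: pd.DataFrame, sen_col: str
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Align scores/metadata into flat arrays for the fast grid path."""
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    meta = meta.loc[scores.index]
    s = scores[sen_col].to_numpy(dtype=float)
    patients, codes = np.unique(meta["patient_id"].to_numpy(), return_inverse=True)
    resp = np.array([
        meta.loc[meta["patient_id"] == p, "response"].iloc[0] for p in patients
    ])
    return s, codes, patients, resp


def evaluate_pair(s: np.ndarray, codes: np.ndarray, resp: np.ndarray,
                  upper_pct: float, lower_pct: float,
                  min_cells: int = 10, ps: float = DEFAULT_PS) -> dict:
    """Per-pair AUC, patient count and retained-cell fraction (numpy fast path)."""
    n_patients = resp.shape[0]
    upper = np.percentile(s, upper_pct, method="linear")
    lower = np.percentile(s, lower_pct, method="linear")
    T = np.bincount(codes, minlength=n_patients)
    if upper <= lower:
        H = np.zeros(n_patients, dtype=int)
        L = np.zeros(n_patients, dtype=int)
    else:
        H = np.bincount(codes[s >= upper], minlength=n_patients)
        L = np.bincount(codes[s <= lower], minlength=n_patients)
    ok = T > min_cells
    out = {"upper": upper_pct, "lower": lower_pct, "auc": np.nan,
           "n_patients": int(ok.sum()), "retained_cell_fraction": np.nan,
           "indices": None, "ok": ok, "H": H, "L": L, "T": T}
    if ok.sum() == 0:
        return out
    idx = (H[ok] / T[ok] + ps) / (L[ok] / T[ok] + ps)
    out["indices"] = idx
    out["retained_cell_fraction"] = float((H[ok] + L[ok]).sum() / T[ok].sum())
    r = resp[ok]
    if len(set(r)) == 2:
        out["auc"] = roc_auc(idx, r)
    return out


def grid_search(
    scores: pd.DataFrame,
    meta: pd.DataFrame,
    sen_col: str = "senescence",
    upper_range: Sequence[float] = DEFAULT_UPPER,
    lower_range: Sequence[float] = DEFAULT_LOWER,
    min_cells: int = 10,
    ps: float = DEFAULT_PS,
    cell_type: str | None = None,
) -> GridResult:
    """Evaluate every (upper, lower) pair and select the AUC-maximizing one.

    Operates within one cell-type stratum: pass ``cell_type`` to subset, or
    supply data containing a single cell type.  Pairs that leave only one
    response class are recorded with AUC = NaN and excluded from selection;
    if every pair is degenerate an error carries the per-pair diagnostics.
    """
    meta = meta.set_index("cell_id") if "cell_id" in meta.columns else meta
    meta = meta.loc[scores.index]
    if cell_type is not None:
        mask = meta["cell_type"] == cell_type
        if not mask.any():
            raise ValueError(f"no cells of type {cell_type!r}")
        scores, meta = scores.loc[mask.to_numpy()], meta.loc[mask.to_numpy()]
    elif meta["cell_type"].nunique() > 1:
        raise ValueError("multiple cell types present; pass cell_type=")

    s, codes, patients, resp = _stratum_arrays(scores, meta, sen_col)
    rows = []
    per_pair = {}
    for up in upper_range:
        for lo in lower_range:
            if lo >= up:
                continue
            res = evaluate_pair(s, codes, resp, up, lo, min_cells, ps)
            rows.append({k: res[k] for k in
                         ("upper", "lower", "auc", "n_patients", "retained_cell_fraction")})
            per_pair[(up, lo)] = res
    records = pd.DataFrame(rows)
    valid = records.dropna(subset=["auc"])
    if valid.empty:
        raise ValueError(
            "every threshold pair left a single response class; "
            f"diagnostics: {records.to_dict('records')}"
        )
    # argmax AUC; ties -> larger retained fraction, more patients, lexicographic
    order = valid.sort_values(
        by=["auc", "retained_cell_fraction", "n_patients", "upper", "lower"],
        ascending=[False, False, False, True, True],
    )
    top = order.iloc[0]
    best_pair = ThresholdPair(float(top["upper"]), float(top["lower"]))
    best = per_pair[(top["upper"], top["lower"])]
    yr = youden_cutoff(best["indices"], resp[best["ok"]], positive="NR")
    return GridResult(
        records=records,
        best_pair=best_pair,
        best_auc=float(top["auc"]),
        youden=yr,
        n_pairs_searched=len(records),
        cell_type=cell_type,
        diagnostics={"n_patients_total": len(patients)},
    )


def bootstrap_auc_ci(indices: Sequence[float], labels: Sequence[str],
                     n_boot: int = 1000, seed: int = 0,
                     alpha: float = 0.05) -> tuple[float, float]:
    """Patient-level bootstrap percentile CI for the AUC (reporting aid)."""
    rng = np.random.default_rng(seed)
    x = np.asarray(indices, dtype=float)
    y = np.asarray(labels)
    aucs = []
    n = len(x)
    for _ in range(n_boot):
        take = rng.integers(0, n, size=n)
        if len(set(y[take])) < 2:
            continue
        aucs.append(roc_auc(x[take], y[take]))
    lo, hi = np.percentile(aucs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def save_grid(result: GridResult, records_path, summary_path) -> None:
    """Write the grid TSV and the selected-optimum summary JSON."""
    import json

    result.records.to_csv(records_path, sep="\t", index=False)
    summary = {
        "cell_type": result.cell_type,
        "best_upper_pct": result.best_pair.upper_pct,
        "best_lower_pct": result.best_pair.lower_pct,
        "best_auc": result.best_auc,
        "youden_cutoff": result.youden.cutoff,
        "youden_j": result.youden.j,
        "sensitivity": result.youden.sensitivity,
        "specificity": result.youden.specificity,
        "n_pairs_searched": result.n_pairs_searched,
    }
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2)
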