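"""Dysfunctional-cell filtering: exhausted/low-senescence removal and state labels.

T-cell exhaustion and senescence are distinct dysfunctional states that can
coexist in the same compartment.  Before a senescence index is computed, cells
that look exhausted-but-not-senescent are removed so they do not inflate the
low-senescence denominator:

* the joint percentile filter drops cells that are simultaneously below the
  20th percentile of senescence and above the 80th percentile of exhaustion
  (both strict, per cell-type stratum);
* the cluster exclusion drops whole clusters whose median senescence is low
  and median exhaustion is high relative to the cell type;
* state labelling assigns each cell a mutually exclusive dysfunction label
  for reporting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MIN_STRATUM = 5


def _percentile(a: np.ndarray, q: float) -> float:
    """Linear-interpolation percentile (the common statistical default)."""
    return float(np.percentile(a, q, method="linear"))


def joint_percentile_filter(
    scores: pd.DataFrame,
    sen_col: str = "senescence",
    exh_col: str = "exhaustion",
    p_low: float = 20.0,
    p_high: float = 80.0,
    stratify_by: pd.Series | None = None,
) -> tuple[pd.Index, dict]:
    """Remove cells with sen < P_low(sen) AND exh > P_high(exh), per stratum.

    Percentiles are computed within each stratum (default: one global
    stratum when ``stratify_by`` is None).  Strata with fewer than 5 cells
    are skipped with a warning.  Returns the kept cell index and a report.
    """
    if not (0 < p_low < 100 and 0 < p_high < 100):
        raise ValueError("percentiles must be in (0, 100)")
    for col in (sen_col, exh_col):
        if col not in scores.columns:
            raise ValueError(f"missing score column {col!r}")
    if stratify_by is None:
        strata = pd.Series("all", index=scores.index)
    else:
        strata = stratify_by.reindex(scores.index)
    keep = pd.Series(True, index=scores.index)
    report: dict = {"p_low": p_low, "p_high": p_high, "strata": {}}
    for name, idx in scores.groupby(strata).groups.items():
        sub = scores.loc[idx]
        if len(sub) < MIN_STRATUM:
            logger.warning("stratum %r has %d < %d cells; joint filter skipped",
                           name, len(sub), MIN_STRATUM)
            report["strata"][str(name)] = {"n": len(sub), "removed": 0, "skipped": True}
            continue
        sen_cut = _percentile(sub[sen_col].to_numpy(), p_low)
        exh_cut = _percentile(sub[exh_col].to_numpy(), p_high)
        bad = (sub[sen_col] < sen_cut) & (sub[exh_col] > exh_cut)
        keep.loc[idx[bad.to_numpy()]] = False
        report["strata"][str(name)] = {
            "n": len(sub), "removed": int(bad.sum()), "skipped": False,
            "sen_cut": sen_cut, "exh_cut": exh_cut,
        }
    return scores.index[keep], report


def exclude_clusters(
    scores: pd.DataFrame,
    cluster_labels: pd.Series,
    sen_col: str = "senescence",
    exh_col: str = "exhaustion",
    low_q: float = 25.0,
    high_q: float = 75.0,
) -> tuple[pd.Index, list]:
    """Exclude clusters with low median senescence and high median exhaustion.

    A cluster is excluded iff its median senescence is below the ``low_q``
    percentile of all cells' senescence AND its median exhaustion is above
    the ``high_q`` percentile of all cells' exhaustion (within the cell type
    the caller passes).  Returns kept cells and the excluded cluster list.
    """
    labels = cluster_labels.reindex(scores.index)
    if labels.isna().all() or len(labels) == 0:
        raise ValueError("no cluster labels provided")
    uniq = labels.dropna().unique()
    if len(uniq) < 2:
        logger.warning("single cluster; no exclusion possible")
        return scores.index, []
    sen_ref = _percentile(scores[sen_col].to_numpy(), low_q)
    exh_ref = _percentile(scores[exh_col].to_numpy(), high_q)
    excluded = []
    for cl in uniq:
        sub = scores.loc[labels == cl]
        if sub[sen_col].median() < sen_ref and sub[exh_col].median() > exh_ref:
            excluded.append(cl)
    keep = ~labels.isin(excluded)
    return scores.index[keep], excluded


#: score column -> emitted state label
STATE_OF_COLUMN = {
    "senescence": "senescent-enriched",
    "exhaustion": "exhausted",
    "anergy": "anergic",
    "proliferation": "proliferative-reference",
}


def state_labels(
    scores: pd.DataFrame,
    columns: dict[str, str] | None = None,
    high_pct: float = 80.0,
) -> pd.Series:
    """Mutually exclusive per-cell state labels.

    A cell is labelled by the state whose score has the highest percentile
    rank among the available state columns; if none of its scores exceeds
    that column's ``high_pct`` percentile the cell is labelled ``other``.
    """
    columns = columns or {c: STATE_OF_COLUMN[c] for c in scores.columns
                          if c in STATE_OF_COLUMN}
    if not columns:
        raise ValueError("no recognised state score columns")
    cols = list(columns)
    pct_ranks = scores[cols].rank(pct=True) * 100.0
    cuts = {c: _percentile(scores[c].to_numpy(), high_pct) for c in cols}
    exceeds = pd.DataFrame({c: scores[c] > cuts[c] for c in cols})
    best = pct_ranks.idxmax(axis=1)
    labels = best.map(columns)
    labels[~exceeds.any(axis=1)] = "other"
    return labels.rename("state")
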