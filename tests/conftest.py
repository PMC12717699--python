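"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's vectorized code paths: ranks
are computed by pair counting, AUC by explicit pair enumeration, Youden by
exhaustive midpoint scan, GSEA by a position-by-position running sum.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest


# --------------------------------------------------------------------------
# Oracles
# --------------------------------------------------------------------------

def rank_desc_average_ties(expr: np.ndarray) -> np.ndarray:
    """Rank by decreasing value, average ties, via explicit pair counting."""
    n = len(expr)
    ranks = np.empty(n)
    for i in range(n):
        greater = sum(1 for j in range(n) if expr[j] > expr[i])
        equal = sum(1 for j in range(n) if j != i and expr[j] == expr[i])
        ranks[i] = 1 + greater + equal / 2.0
    return ranks


def ucell_oracle(matrix: np.ndarray, gene_ids: list[str], up: list[str],
                 down: list[str], max_rank: int) -> np.ndarray:
    """Per-cell directional rank score computed cell by cell, gene by gene."""
    pos = {g: i for i, g in enumerate(gene_ids)}
    out = np.zeros(matrix.shape[1])
    for c in range(matrix.shape[1]):
        ranks = rank_desc_average_ties(matrix[:, c])
        ranks = np.where(ranks > max_rank, max_rank + 1, ranks)

        def direction(genes):
            idx = [pos[g] for g in genes if g in pos]
            if not idx:
                return None
            r = sorted(ranks[i] for i in idx)
            n = len(r)
            u = sum(r) - n * (n + 1) / 2.0
            return 1.0 - u / (n * max_rank)

        s_up = direction(up)
        s_dn = direction(down)
        out[c] = (s_up or 0.0) - (s_dn or 0.0)
    return out


def auc_pair_counting(pos_vals, neg_vals) -> float:
    """AUC by explicit (positive, negative) pair enumeration."""
    wins = ties = 0
    for p in pos_vals:
        for q in neg_vals:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos_vals) * len(neg_vals))


def youden_scan_oracle(values, labels, positive="NR"):
    """Best (cutoff, J, sens, spec) by scanning every midpoint candidate."""
    x = np.asarray(values, dtype=float)
    pos = np.asarray(labels) == positive
    distinct = np.unique(x)
    candidates = [-np.inf] + [
        (a + b) / 2 for a, b in zip(distinct[:-1], distinct[1:])
    ] + [np.inf]
    best = None
    for c in candidates:
        pred = x >= c
        sens = pred[pos].mean()
        spec = (~pred[~pos]).mean()
        j = sens + spec - 1
        key = (j, spec, -c)
        if best is None or key > best[0]:
            best = (key, (c, j, sens, spec))
    return best[1]


def wilcoxon_enumeration_p(x, y, alternative="two-sided") -> float:
    """Exact rank-sum p-value by enumerating all rank assignments (no ties)."""
    x, y = list(x), list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n, m = len(x), len(y)
    rank_of = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank_of[v] for v in x)
    ws = [sum(combo) for combo in itertools.combinations(range(1, n + m + 1), n)]
    total = len(ws)
    p_less = sum(w <= w_obs for w in ws) / total
    p_greater = sum(w >= w_obs for w in ws) / total
    if alternative == "less":
        return p_less
    if alternative == "greater":
        return p_greater
    return min(1.0, 2 * min(p_less, p_greater))


def gsea_positional_oracle(metric: pd.Series, gene_set, weight: float) -> float:
    """ES by evaluating the running sum explicitly at every position."""
    ordered = metric.sort_values(ascending=False, kind="stable")
    hits = [g in set(gene_set) for g in ordered.index]
    n = len(ordered)
    n_hit = sum(hits)
    denom = sum(abs(ordered.iloc[i]) ** weight for i in range(n) if hits[i])
    running, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            running += (abs(ordered.iloc[i]) ** weight) / denom if denom else 1 / n_hit
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


# --------------------------------------------------------------------------
# Fixtures
# --------------------------------------------------------------------------

@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """10 genes x 3 cells with fixed integer values (frozen fixture)."""
    from senindex.preprocess import ExpressionMatrix

    values = np.array([
        [9, 0, 4], [7, 1, 4], [5, 2, 4], [3, 3, 4], [1, 4, 4],
        [0, 5, 2], [2, 6, 2], [4, 7, 2], [6, 8, 0], [8, 9, 0],
    ], dtype=float)
    genes = [f"G{i}" for i in range(10)]
    return ExpressionMatrix(values, genes, ["c1", "c2", "c3"], "log_tpm")


@pytest.fixture
def toy_cohort_meta():
    """Small deterministic cohort: 4 patients x 1 cell type, 12 cells each."""
    rows = []
    rng = np.random.default_rng(7)
    for p, resp in [("P1", "R"), ("P2", "R"), ("P3", "NR"), ("P4", "NR")]:
        for i in range(12):
            rows.append({"cell_id": f"{p}_c{i}", "patient_id": p,
                         "cell_type": "CD8T", "response": resp})
    meta = pd.DataFrame(rows)
    base = rng.uniform(0, 1, len(meta))
    nr = meta["response"].to_numpy() == "NR"
    scores = pd.DataFrame(
        {"senescence": np.where(nr, base * 0.5 + 0.5, base * 0.5),
         "exhaustion": rng.uniform(0, 1, len(meta))},
        index=pd.Index(meta["cell_id"], name="cell_id"))
    return scores, meta
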