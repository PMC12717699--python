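"""Functional-module discovery in a binary gene x term association matrix.

The input is a matrix with genes as rows, significantly enriched functional
terms (GO/pathway) as columns and entries 1 when the gene is annotated to
the term.  PCA retains the smallest leading component set explaining > 90%
of total variance; k-means (seeded restarts) over a k range picks k by
silhouette; Ward hierarchical clustering of the same reduced matrix is
returned for inspection.  Genes whose annotations straddle clusters are
re-assigned to the cluster where they carry the highest cumulative
enrichment score (term-level scores if supplied, otherwise binary counts),
ties broken by cluster size then index.  Term retrieval itself is out of
scope: the matrix is an input file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)


@dataclass
class GeneFunctionMatrix:
    """Binary gene x term matrix with optional per-association scores."""

    binary: pd.DataFrame
    scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.binary.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("association matrix entries must be 0/1")
        zero_rows = vals.sum(axis=1) == 0
        if zero_rows.any():
            raise ValueError(
                f"all-zero gene rows: {list(self.binary.index[zero_rows])}"
            )
        if self.scores is not None:
            if not self.scores.index.equals(self.binary.index) or \
               not self.scores.columns.equals(self.binary.columns):
                raise ValueError("score matrix must align with the binary matrix")

    @classmethod
    def from_tsv(cls, path) -> "GeneFunctionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.astype(int))


@dataclass
class ClusterResult:
    assignment: pd.Series           # gene -> cluster id
    chosen_k: int
    silhouette_by_k: dict[int, float]
    inertia_by_k: dict[int, float]  # elbow curve, emitted for inspection
    n_components: int
    explained_variance: float
    ward_linkage: np.ndarray
    reassigned: list[str] = field(default_factory=list)


def _reduce(gfm: GeneFunctionMatrix, var_target: float = 0.90
            ) -> tuple[np.ndarray, int, float]:
    x = gfm.binary.to_numpy(dtype=float)
    pca = PCA(svd_solver="full")
    z = pca.fit_transform(x)
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_keep = int(np.searchsorted(cum, var_target) + 1)
    n_keep = min(n_keep, z.shape[1])
    return z[:, :n_keep], n_keep, float(cum[n_keep - 1])


def reduce_and_cluster(
    gfm: GeneFunctionMatrix,
    k_range: range | list[int] = range(2, 9),
    seed: int = 0,
    var_target: float = 0.90,
) -> ClusterResult:
    """PCA (> 90% variance) then silhouette-selected k-means + Ward dendrogram."""
    k_range = [k for k in k_range if 2 <= k <= len(gfm.binary) - 1]
    if not k_range:
        raise ValueError("k_range is empty after bounds check")
    z, n_comp, expl = _reduce(gfm, var_target)
    if np.allclose(z, z[0]):
        raise ValueError("constant matrix after reduction; nothing to cluster")

    sil: dict[int, float] = {}
    inertia: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        lab = km.fit_predict(z)
        fits[k] = km
        inertia[k] = float(km.inertia_)
        sil[k] = float(silhouette_score(z, lab)) if len(set(lab)) > 1 else -1.0
    chosen_k = max(sil, key=lambda k: (sil[k], -k))
    labels = pd.Series(fits[chosen_k].labels_, index=gfm.binary.index, name="cluster")

    ward = linkage(z, method="ward")
    assignment, reassigned = _resolve_multi_membership(gfm, labels)
    return ClusterResult(
        assignment=assignment, chosen_k=chosen_k, silhouette_by_k=sil,
        inertia_by_k=inertia, n_components=n_comp, explained_variance=expl,
        ward_linkage=ward, reassigned=reassigned,
    )


def _resolve_multi_membership(gfm: GeneFunctionMatrix, labels: pd.Series
                              ) -> tuple[pd.Series, list[str]]:
    """Re-assign genes annotated across clusters by cumulative enrichment score.

    Each term is attributed to the cluster where most of its annotated genes
    sit; a gene's cumulative score per cluster is the sum of its association
    scores over that cluster's terms.  Genes with positive weight in more
    than one cluster move to the argmax (ties: larger cluster, lower id).
    """
    binary = gfm.binary
    weights = gfm.scores if gfm.scores is not None else binary.astype(float)
    clusters = sorted(labels.unique())
    sizes = labels.value_counts()
    # term -> cluster by majority of annotated genes
    term_cluster = {}
    for term in binary.columns:
        members = labels[binary[term] == 1]
        term_cluster[term] = members.value_counts().idxmax() if len(members) else None
    assignment = labels.copy()
    reassigned = []
    for gene in binary.index:
        cum = {c: 0.0 for c in clusters}
        for term in binary.columns[binary.loc[gene] == 1]:
            c = term_cluster[term]
            if c is not None:
                cum[c] += float(weights.loc[gene, term])
        positive = [c for c in clusters if cum[c] > 0]
        if len(positive) <= 1:
            continue
        best = max(positive, key=lambda c: (cum[c], sizes.get(c, 0), -c))
        if best != assignment.loc[gene]:
            reassigned.append(gene)
            assignment.loc[gene] = best
    return assignment, reassigned


def linkage_to_newick(z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string (for the dendrogram)."""
    n = len(leaf_names)

    def build(node: int) -> str:
        if node < n:
            return leaf_names[node]
        left, right, dist, _ = z[node - n]
        return f"({build(int(left))},{build(int(right))}):{dist:.4g}"

    return build(2 * n - 2) + ";"
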