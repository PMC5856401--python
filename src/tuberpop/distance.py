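"""Nei (1972) standard genetic distance, Ward dendrograms, partition tools.

Distances can be computed among individuals (within-individual allele
frequencies, dosage/ploidy — the convention of polyploid-aware distance
tools) or among populations (pooled allele frequencies). Missing data are
handled pairwise-complete: a locus missing in either member of a pair is
dropped for that pair only, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .panel import GenotypePanel, allele_frequency

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "nei_distance",
    "ward_cluster",
    "to_newick",
    "cut_tree",
    "cluster_agreement",
]

# Nei identity I = 0 (disjoint fixation) would give D = -ln I = inf; capping
# at I = NEI_EPS keeps Ward arithmetic finite.
NEI_EPS = 1e-10
NEI_D_CAP = -np.log(NEI_EPS)


@dataclass
class DistanceMatrix:
    ids: list
    matrix: np.ndarray  # symmetric, zero diagonal
    metric: str
    capped: np.ndarray | None = None  # boolean mask of capped entries

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("distance matrix must be square and symmetric")
        self.matrix = m

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence in scipy linkage form."""

    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix
    leaf_ids: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def _frequency_profiles(panel: GenotypePanel, level: str, grouping=None):
    if level == "individual":
        freqs = panel.dosage / panel.ploidy[:, None]
        ids = list(panel.sample_ids)
    elif level == "population":
        if grouping is None:
            grouping = panel.group
        if grouping is None:
            raise ValueError("population-level distance needs a grouping")
        grouping = np.asarray(grouping)
        ids = []
        rows = []
        for g in dict.fromkeys(grouping.tolist()):
            idx = np.flatnonzero(grouping == g)
            rows.append(allele_frequency(panel, idx))
            ids.append(g)
        freqs = np.vstack(rows)
    else:
        raise ValueError(f"unknown level {level!r}")
    return ids, freqs


def nei_distance(
    panel: GenotypePanel, level: str = "individual", grouping=None
) -> DistanceMatrix:
    """Nei standard genetic distance D = -ln I between frequency profiles.

    For biallelic loci with frequencies x = (p, 1-p) and y = (q, 1-q):
    Jxy = mean over shared loci of (p q + (1-p)(1-q)), Jx and Jy the
    analogous self-identities, I = Jxy / sqrt(Jx Jy). Loci missing in
    either entity are excluded pairwise; identities of zero are capped so
    D stays finite (the ``capped`` mask flags those pairs).
    """
    ids, P = _frequency_profiles(panel, level, grouping)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 entities")
    D = np.zeros((n, n))
    capped = np.zeros((n, n), dtype=bool)
    present = ~np.isnan(P)
    for i in range(n):
        for j in range(i + 1, n):
            shared = present[i] & present[j]
            if not shared.any():
                raise ValueError(
                    f"entities {ids[i]!r} and {ids[j]!r} share no scored loci"
                )
            p, q = P[i, shared], P[j, shared]
            jxy = np.mean(p * q + (1 - p) * (1 - q))
            jx = np.mean(p * p + (1 - p) * (1 - p))
            jy = np.mean(q * q + (1 - q) * (1 - q))
            I = jxy / np.sqrt(jx * jy)
            if I < NEI_EPS:
                D[i, j] = D[j, i] = NEI_D_CAP
                capped[i, j] = capped[j, i] = True
            else:
                # floating point can push I a hair above 1 for identical rows
                D[i, j] = D[j, i] = max(-np.log(min(I, 1.0)), 0.0)
    return DistanceMatrix(ids=ids, matrix=D, metric="nei1972", capped=capped)


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Ward minimum-variance agglomeration of a precomputed distance matrix.

    Uses the Lance-Williams recurrence on squared distances; merge heights
    are non-decreasing.
    """
    Z = hierarchy.linkage(squareform(dist.matrix, checks=True), method="ward")
    return Dendrogram(linkage=Z, leaf_ids=list(dist.ids))


def to_newick(tree: Dendrogram) -> str:
    """Newick text for a dendrogram; leaf depth is half the merge height.

    Two leaves merged at height h render as ``(a:h/2,b:h/2);`` — the
    ultrametric convention where the merge height is the full tip-to-tip
    path through the node.
    """
    root = hierarchy.to_tree(tree.linkage)
    names = [str(s) for s in tree.leaf_ids]

    def walk(node, parent_half: float) -> str:
        half = node.dist / 2.0
        length = parent_half - half
        if node.is_leaf():
            return f"{names[node.id]}:{length:.10g}"
        left = walk(node.left, half)
        right = walk(node.right, half)
        return f"({left},{right}):{length:.10g}"

    half = root.dist / 2.0
    return f"({walk(root.left, half)},{walk(root.right, half)});"


def cut_tree(tree: Dendrogram, k: int) -> dict:
    """Partition into k clusters by removing the k-1 highest merges."""
    n = len(tree.leaf_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    labels = hierarchy.cut_tree(tree.linkage, n_clusters=k).ravel() + 1
    return dict(zip(tree.leaf_ids, labels.tolist()))


def cluster_agreement(a, b) -> float:
    """Percent agreement between two labelings under the best label matching.

    Maximises, over bijections between the two label sets (rectangular
    assignment on the confusion matrix), the fraction of entities with
    identical assignment; returns a percentage.
    """
    from scipy.optimize import linear_sum_assignment

    if isinstance(a, dict) or isinstance(b, dict):
        if not (isinstance(a, dict) and isinstance(b, dict)):
            raise ValueError("pass two dicts or two aligned sequences")
        if set(a) != set(b):
            raise ValueError("labelings cover different entity sets")
        keys = sorted(a, key=str)
        a = [a[k] for k in keys]
        b = [b[k] for k in keys]
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings cover different entity sets")
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    confusion = np.zeros((len(ua), len(ub)))
    np.add.at(confusion, (ia, ib), 1)
    rows, cols = linear_sum_assignment(confusion, maximize=True)
    return 100.0 * confusion[rows, cols].sum() / len(a)
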