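"""Disease-similarity analysis: Jaccard distances between gene sets,
complete-linkage hierarchical clustering, and the Mantel test.

Diseases are compared at two levels: by their DEG sets and by their top-k
(default 100) predicted targets. A significant Mantel correlation between
the two distance matrices indicates that similar expression signatures
lead to similar target predictions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Set

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "jaccard_distance",
    "build_distance_matrix",
    "hierarchical_cluster",
    "merges_to_newick",
    "mantel_test",
    "top_k_sets",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("Jaccard distances must lie in [0,1]")
        self.values = v

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


def jaccard_distance(a: Set, b: Set) -> float:
    """1 - |a ∩ b| / |a ∪ b|; undefined (error) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard distance of two empty sets is undefined")
    return 1.0 - len(a & b) / union


def build_distance_matrix(sets: Mapping[str, Set]) -> DistanceMatrix:
    """Pairwise Jaccard distance matrix over named gene sets."""
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least two diseases")
    for name, s in sets.items():
        if len(s) == 0:
            raise ValueError(f"empty gene set for disease {name!r}")
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jaccard_distance(sets[labels[i]], sets[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, values=mat)


def top_k_sets(predictions: Mapping[str, pd.DataFrame], k: int = 100
               ) -> dict[str, set]:
    """Top-k node sets per disease from ranked prediction lists."""
    out = {}
    for disease, pred in predictions.items():
        top = pred.sort_values("rank").head(k)
        out[disease] = set(top.index)
    return out


def hierarchical_cluster(d: DistanceMatrix, linkage: str = "complete"
                         ) -> list[tuple]:
    """Agglomerative clustering with complete linkage and a deterministic
    tie-break by label order.

    Returns the merge list: tuples ``(left, right, height)`` where left and
    right are either label strings or earlier merge tuples. Complete
    linkage sets the distance between clusters to the maximum pairwise
    distance; among equidistant candidate pairs the one whose earliest
    member label comes first in ``d.labels`` merges first.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    order = {lab: i for i, lab in enumerate(d.labels)}
    # each active cluster: (min label index, member indices, tree)
    clusters: list[tuple[int, list[int], object]] = [
        (order[lab], [i], lab) for i, lab in enumerate(d.labels)]
    dist = d.values.copy()
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                height = max(dist[i, j] for i in clusters[a][1]
                             for j in clusters[b][1])
                key = (height, clusters[a][0], clusters[b][0])
                if best is None or key < best[0]:
                    best = (key, a, b)
        (height, _, _), a, b = best
        ca, cb = clusters[b], clusters[a]  # pop order: b first
        clusters.pop(b)
        clusters.pop(a)
        left, right = sorted((ca, cb), key=lambda c: c[0])
        merged = (min(left[0], right[0]), left[1] + right[1],
                  (left[2], right[2], height))
        clusters.append(merged)
        clusters.sort(key=lambda c: c[0])
    tree = clusters[0][2]
    return _collect_merges(tree)


def _collect_merges(tree) -> list[tuple]:
    merges = []

    def walk(node):
        if isinstance(node, tuple):
            walk(node[0])
            walk(node[1])
            merges.append(node)

    walk(tree)
    return merges


def merges_to_newick(merges: Sequence[tuple]) -> str:
    """Render the final merge of a merge list as a Newick string with
    merge heights as internal branch annotations."""
    if not merges:
        raise ValueError("empty merge list")

    def render(node) -> str:
        if not isinstance(node, tuple):
            return str(node)
        left, right, height = node
        return f"({render(left)},{render(right)}):{height:g}"

    return render(merges[-1]) + ";"


def mantel_test(d1: DistanceMatrix, d2: DistanceMatrix, n_perm: int = 1000,
                seed: int = 0) -> MantelResult:
    """One-sided (greater) Mantel test between two distance matrices.

    r is the Pearson correlation of the strictly-upper-triangle entries;
    the p-value is the add-one permutation estimate
    (1 + #{r_perm >= r_obs}) / (n_perm + 1), permuting rows and columns of
    the second matrix jointly.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d1.labels)
    x = d1.upper_triangle()
    if np.std(x) == 0 or np.std(d2.upper_triangle()) == 0:
        raise ValueError("zero variance in a distance matrix triangle")
    iu = np.triu_indices(n, k=1)

    def corr(mat2: np.ndarray) -> float:
        y = mat2[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(d2.values)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(d2.values[np.ix_(perm, perm)]) >= r_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm)
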