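"""Modularity of ligand production vs promiscuity of ligand binding.

The production network is clustered hierarchically on Jaccard distances
between the cells' produced-ligand sets, with the module count chosen by
mean silhouette width.  The binding network is co-clustered with the Dhillon
bipartite spectral algorithm (degree-normalized SVD embedding + k-means).
The two structures are compared through the inter-module shared-ligand
vectors S (production) and T (binding) with a two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    assignment: pd.Series  # cell -> module id
    silhouette: pd.Series  # per-cell silhouette width on the Jaccard metric
    mean_silhouette_per_k: pd.DataFrame  # columns: k, mean_silhouette
    k: int

    @property
    def modules(self) -> dict[int, set[str]]:
        return {
            int(m): set(self.assignment.index[self.assignment == m])
            for m in sorted(self.assignment.unique())
        }


@dataclass
class CoclusterResult:
    row_assignment: pd.Series  # ligand -> co-cluster
    col_assignment: pd.Series  # cell -> co-cluster
    k: int
    singular_values_used: list[float]
    singular_values: list[float]

    def is_separable(self, rtol: float = 0.05) -> bool:
        """False when the informative singular values are nearly equal to the rest.

        In the degenerate case (e.g. an all-ones matrix) the second and later
        singular values collapse to a near-equal level far below the leading
        one, and the embedding carries no block structure.
        """
        s = np.asarray(self.singular_values)
        if len(s) < 2:
            return False
        used = np.asarray(self.singular_values_used)
        rest_max = s[1 + len(used):].max() if len(s) > 1 + len(used) else 0.0
        return bool(used.min() - rest_max > rtol * s[0])


def jaccard_distance_matrix(A: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between the binary rows of A.

    Pairs of all-zero rows (cells producing no ligand) get distance 0 with a
    warning: their produced-ligand sets are identically empty.
    """
    X = (A.to_numpy() > 0)
    empty = ~X.any(axis=1)
    if empty.any():
        logger.warning(
            "cells with empty ligand sets (pairwise distance set to 0): %s",
            list(A.index[empty]),
        )
    with np.errstate(invalid="ignore"):
        d = pdist(X, metric="jaccard")
    d = np.nan_to_num(d, nan=0.0)  # scipy leaves 0/0 pairs undefined
    return pd.DataFrame(squareform(d), index=A.index, columns=A.index)


def cluster_production(
    A: pd.DataFrame, k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
) -> ModulePartition:
    """Ward clustering of cells on Jaccard distances; k chosen by mean silhouette."""
    n = len(A)
    if n < 3:
        raise ValueError("need at least 3 cells to cluster")
    D = jaccard_distance_matrix(A)
    condensed = squareform(D.to_numpy(), checks=False)
    Z = hierarchy.linkage(condensed, method="ward")

    rows, best, fallback = [], None, None
    for k in sorted(k_range):
        if not 2 <= k <= n - 1:
            continue
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            # tied merge heights can make a k-cluster cut unreachable
            logger.warning("dendrogram cut at k=%d yields a single cluster", k)
            rows.append({"k": k, "mean_silhouette": float("nan")})
            if fallback is None:
                fallback = (k, labels)
            continue
        sil = silhouette_samples(D.to_numpy(), labels, metric="precomputed")
        mean_sil = float(np.mean(sil))
        rows.append({"k": k, "mean_silhouette": mean_sil})
        if best is None or mean_sil > best[0] + 1e-12:
            best = (mean_sil, k, labels, sil)
    if best is None and fallback is not None:
        k, labels = fallback
        best = (float("nan"), k, labels, np.zeros(n))
    if best is None:
        raise ValueError(f"no valid module count in k_range={k_range} for n={n}")
    _, k, labels, sil = best
    return ModulePartition(
        assignment=pd.Series(labels, index=A.index, name="module"),
        silhouette=pd.Series(sil, index=A.index, name="silhouette"),
        mean_silhouette_per_k=pd.DataFrame(rows),
        k=int(k),
    )


def bootstrap_cluster_confidence(
    A: pd.DataFrame, k: int, n_boot: int = 200, seed: int = 0
) -> pd.Series:
    """Fraction of ligand-column bootstrap replicates reproducing each module."""
    rng = np.random.default_rng(seed)
    base = cluster_production(A, k_range=(k,))
    target = {frozenset(m) for m in base.modules.values()}
    found = {m: 0 for m in target}
    for _ in range(n_boot):
        cols = rng.choice(A.columns, size=A.shape[1], replace=True)
        try:
            part = cluster_production(A[cols], k_range=(k,))
        except ValueError:
            continue
        boot = {frozenset(m) for m in part.modules.values()}
        for m in target:
            if m in boot:
                found[m] += 1
    return pd.Series(
        {" + ".join(sorted(m)): found[m] / n_boot for m in target}, name="bootstrap_support"
    )


# -- Dhillon bipartite spectral co-clustering ----------------------------

def cocluster_binding(
    B: pd.DataFrame, k: int, seed: int = 0, n_init: int = 10
) -> CoclusterResult:
    """Spectral co-clustering of the weighted ligand x cell binding matrix.

    Rows and columns are embedded with the singular vectors 2..ceil(log2 k)+1
    of the degree-normalized matrix D_r^{-1/2} B D_c^{-1/2}, then jointly
    k-means-partitioned into k co-clusters (fixed seed for reproducibility).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    M = B.to_numpy(dtype=float)
    zero_rows = B.index[M.sum(axis=1) == 0].tolist()
    zero_cols = B.columns[M.sum(axis=0) == 0].tolist()
    if zero_rows or zero_cols:
        raise ValueError(
            f"zero-degree nodes: rows {zero_rows[:5]}, columns {zero_cols[:5]}"
        )
    r = 1.0 / np.sqrt(M.sum(axis=1))
    c = 1.0 / np.sqrt(M.sum(axis=0))
    An = M * r[:, None] * c[None, :]
    U, s, Vt = np.linalg.svd(An, full_matrices=False)
    n_vec = int(np.ceil(np.log2(k)))
    use = slice(1, 1 + n_vec)
    Z = np.vstack([r[:, None] * U[:, use], c[:, None] * Vt.T[:, use]])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Z)
    labels = km.labels_
    return CoclusterResult(
        row_assignment=pd.Series(labels[: M.shape[0]], index=B.index, name="cocluster"),
        col_assignment=pd.Series(labels[M.shape[0]:], index=B.columns, name="cocluster"),
        k=k,
        singular_values_used=[float(x) for x in s[use]],
        singular_values=[float(x) for x in s],
    )


# -- production vs binding comparison ------------------------------------

def module_ligand_sets(matrix: pd.DataFrame, assignment: pd.Series) -> dict[int, set[str]]:
    """Per module, the union of ligands its cells interact with.

    ``matrix`` is cells x ligands (production) or ligands x cells (binding
    — pass transposed).
    """
    out: dict[int, set[str]] = {}
    for m in sorted(assignment.unique()):
        cells = assignment.index[assignment == m]
        block = matrix.loc[cells]
        out[int(m)] = set(block.columns[(block > 0).any(axis=0)])
    return out


def overlap_vector(ligand_sets: dict[int, set[str]]) -> list[int]:
    """Pairwise inter-module shared-ligand counts, modules in id order."""
    if len(ligand_sets) < 2:
        raise ValueError("need at least 2 modules to form inter-module pairs")
    mods = sorted(ligand_sets)
    return [
        len(ligand_sets[a] & ligand_sets[b])
        for i, a in enumerate(mods)
        for b in mods[i + 1:]
    ]


@dataclass
class OverlapComparison:
    S: list[int]  # production-side inter-module overlaps
    T: list[int]  # binding-side inter-module overlaps
    t: float
    p: float
    variant: str


def overlap_ttest(S, T, variant: str = "welch") -> OverlapComparison:
    """Two-sample two-sided t-test comparing the overlap vectors S and T."""
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    res = stats.ttest_ind(S, T, equal_var=(variant == "pooled"))
    return OverlapComparison(list(S), list(T), float(res.statistic), float(res.pvalue), variant)


def compare_module_overlap(
    prod_sets: dict[int, set[str]],
    bind_sets: dict[int, set[str]],
    variant: str = "welch",
) -> OverlapComparison:
    """Compare production-module vs binding-module ligand sharing."""
    return overlap_ttest(overlap_vector(prod_sets), overlap_vector(bind_sets), variant)


def write_partition(partition: ModulePartition, path) -> None:
    df = pd.DataFrame(
        {"cell": partition.assignment.index, "module": partition.assignment.to_numpy()}
    )
    df.to_csv(path, sep="\t", index=False)
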