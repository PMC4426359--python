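"""Ras-target transcript selection and the two-cluster permutation analysis.

Genes responding to perturbation of the Ras/PKA pathway are selected from
mutant/reference expression ratios: a gene qualifies when its ratio shows
more than a 30% change — ratio >= 1.3 or <= 1/1.3 on the linear scale by
default — in *all* mutants (the intersection across the three Ras-pathway
mutants). The selected genes are then clustered on their expression across
natural isolates (agglomerative, Euclidean distance, average linkage, tree
cut at k = 2); the strength of the two-way split is the mean silhouette
width. Its significance is assessed by re-running the clustering on random
gene subsets of the same size drawn from the full expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score


@dataclass(frozen=True)
class ResponsiveGeneSet:
    gene_ids: tuple[str, ...]
    ratios: pd.DataFrame  # retained genes x mutants


@dataclass(frozen=True)
class ClusterSplit:
    labels: pd.Series  # gene -> {1, 2}
    sizes: tuple[int, int]
    statistic: float  # mean silhouette width at k = 2
    p: float = float("nan")


def select_responsive_genes(
    ratio_matrix: pd.DataFrame,
    threshold: float = 0.30,
    *,
    scale: str = "linear",
) -> ResponsiveGeneSet:
    """Genes changed by more than ``threshold`` in every mutant column.

    On the linear scale a gene passes in a mutant when its ratio is
    >= 1 + threshold or <= 1 / (1 + threshold) (symmetric on the ratio
    scale); ``scale="log"`` applies |log2 ratio| >= log2(1 + threshold)
    instead (the two rules are equivalent for the symmetric bound).
    """
    if (ratio_matrix <= 0).any().any():
        raise ValueError("expression ratios must be positive")
    if scale == "linear":
        up = ratio_matrix >= 1.0 + threshold
        down = ratio_matrix <= 1.0 / (1.0 + threshold)
    elif scale == "log":
        lg = np.abs(np.log2(ratio_matrix))
        up = down = lg >= np.log2(1.0 + threshold)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    passes = (up | down).all(axis=1)
    keep = ratio_matrix.index[passes]
    return ResponsiveGeneSet(tuple(map(str, keep)), ratio_matrix.loc[keep])


def _split_statistic(matrix: np.ndarray) -> tuple[np.ndarray, float]:
    model = AgglomerativeClustering(n_clusters=2, metric="euclidean", linkage="average")
    labels = model.fit_predict(matrix)
    if len(set(labels)) < 2:  # pragma: no cover - k=2 always yields 2 labels
        return labels, float("nan")
    return labels, float(silhouette_score(matrix, labels, metric="euclidean"))


def cluster_two_groups(expression: pd.DataFrame) -> ClusterSplit:
    """Two-way agglomerative split of genes by their expression profiles."""
    if expression.shape[0] < 4 or expression.shape[1] < 2:
        raise ValueError("need at least 4 genes and 2 strains")
    X = expression.to_numpy(dtype=float)
    if np.allclose(X, X.flat[0]):
        raise ValueError("constant expression matrix: split undefined")
    labels, stat = _split_statistic(X)
    labels = pd.Series(labels + 1, index=expression.index, name="cluster")
    sizes = (int((labels == 1).sum()), int((labels == 2).sum()))
    return ClusterSplit(labels, sizes, stat)


def cluster_permutation_pvalue(
    full_expression: pd.DataFrame,
    k_genes: int,
    observed_statistic: float,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p for the split strength of a selected gene set.

    Draws ``n_perm`` random subsets of ``k_genes`` genes from the full
    matrix, reclusters each, and reports the +1-corrected fraction of
    subsets whose split statistic reaches the observed one.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    if k_genes > full_expression.shape[0]:
        raise ValueError("k_genes exceeds the gene panel")
    rng = np.random.default_rng(seed)
    X = full_expression.to_numpy(dtype=float)
    n_hit = 0
    for _ in range(n_perm):
        idx = rng.choice(X.shape[0], size=k_genes, replace=False)
        _, stat = _split_statistic(X[idx])
        if stat >= observed_statistic:
            n_hit += 1
    return (1.0 + n_hit) / (n_perm + 1.0)


def transcript_pipeline(
    ratio_matrix: pd.DataFrame,
    expression: pd.DataFrame,
    *,
    threshold: float = 0.30,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[ResponsiveGeneSet, ClusterSplit]:
    """Selection, clustering and the permutation test in one call."""
    selected = select_responsive_genes(ratio_matrix, threshold)
    sub = expression.loc[list(selected.gene_ids)]
    split = cluster_two_groups(sub)
    p = cluster_permutation_pvalue(
        expression, len(selected.gene_ids), split.statistic, n_perm, seed
    )
    return selected, ClusterSplit(split.labels, split.sizes, split.statistic, p)
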