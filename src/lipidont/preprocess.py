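"""Dataset preprocessing: normalization, imputation, scaling, clustering.

These are the standard steps applied to a lipid abundance matrix (rows =
lipid names, columns = samples, missing values as NaN) before enrichment
analysis: fraction-of-total normalization per sample, half-minimum
imputation of missing values, per-lipid z-scoring for heat-map style
clustering, and complete-linkage hierarchical clustering on Euclidean
distances.  The cluster workflow runs target-list enrichment of every
cluster against all matched lipids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .enrichment import EnrichmentOptions, EnrichmentReport, fisher_enrichment
from .nomenclature import match_names
from .ontology import Ontology

__all__ = [
    "ClusterAssignment",
    "normalize_fraction_of_total",
    "impute_half_minimum",
    "zscore_rows",
    "hierarchical_clusters",
    "cluster_enrichment_workflow",
]


def normalize_fraction_of_total(matrix: pd.DataFrame) -> pd.DataFrame:
    """Express every lipid as a fraction of the summed intensity per sample.

    Missing entries stay missing and are excluded from the column sums.
    """
    sums = matrix.sum(axis=0, skipna=True)
    dead = sums.index[(sums <= 0) | matrix.isna().all(axis=0)]
    if len(dead):
        raise ValueError(f"columns without positive intensity: {list(dead)}")
    return matrix / sums


def impute_half_minimum(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing values by half the minimum positive value of the
    original matrix (a detection-limit style imputation)."""
    values = matrix.to_numpy(float)
    positive = values[np.isfinite(values) & (values > 0)]
    if positive.size == 0:
        raise ValueError("matrix contains no positive values")
    return matrix.fillna(0.5 * float(positive.min()))


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale every lipid to mean 0 and standard deviation 1 (sample SD,
    ddof=1).  Constant rows cannot be scaled; they are dropped with a
    warning."""
    means = matrix.mean(axis=1)
    sds = matrix.std(axis=1, ddof=1)
    constant = sds.index[(sds == 0) | sds.isna()]
    if len(constant):
        warnings.warn(
            f"dropping {len(constant)} constant lipid rows: "
            f"{list(constant[:5])}...",
            stacklevel=2,
        )
    keep = matrix.index.difference(constant, sort=False)
    scaled = matrix.loc[keep].sub(means[keep], axis=0).div(sds[keep], axis=0)
    return scaled


@dataclass
class ClusterAssignment:
    """Cluster labels (1..k) per lipid plus the agglomerative linkage tree."""

    labels: pd.Series
    linkage_tree: np.ndarray
    k: int

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def hierarchical_clusters(matrix: pd.DataFrame, k: int) -> ClusterAssignment:
    """Complete-linkage hierarchical clustering of lipid rows on Euclidean
    distance, cut into ``k`` clusters.

    Deterministic given the input row order; ties in merge heights are
    resolved by scipy's ordering of the condensed distance matrix.
    """
    n = len(matrix)
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    tree = linkage(matrix.to_numpy(float), method="complete", metric="euclidean")
    raw = fcluster(tree, t=k, criterion="maxclust")
    # Relabel clusters 1..k in order of first appearance for reproducibility.
    relabel: dict[int, int] = {}
    labels = []
    for c in raw:
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        labels.append(relabel[c])
    return ClusterAssignment(pd.Series(labels, index=matrix.index), tree, k)


def cluster_enrichment_workflow(
    matrix: pd.DataFrame,
    k: int,
    ontology: Ontology,
    options: EnrichmentOptions | None = None,
) -> tuple[ClusterAssignment, dict[int, EnrichmentReport]]:
    """The full heat-map style workflow: impute missing values, normalize to
    fraction of total, z-score, cluster into ``k`` groups, then run a
    target-list (Fisher) enrichment of every cluster against all matched
    lipids.

    Group statistics are not involved: clustering operates on the scaled
    matrix, and each cluster's members form the target list while the whole
    matched dataset forms the universe.
    """
    imputed = impute_half_minimum(matrix)
    normalized = normalize_fraction_of_total(imputed)
    scaled = zscore_rows(normalized)

    mapping, report = match_names(list(scaled.index), ontology)
    matched = scaled.loc[[r for r in scaled.index if r in mapping]].copy()
    matched.index = [mapping[r] for r in matched.index]
    matched = matched.groupby(level=0).mean()

    assignment = hierarchical_clusters(matched, k)
    universe = set(matched.index)
    reports: dict[int, EnrichmentReport] = {}
    for cluster in range(1, k + 1):
        members = set(assignment.members(cluster))
        if not members:
            continue
        reports[cluster] = fisher_enrichment(
            members, universe, ontology, options, match_report=report
        )
    return assignment, reports
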