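"""Gene partitioning and k-means++ trend clustering.

Intersecting genes from the two datasets are stacked (early integration:
one row per gene per dataset over the shared conditions) and clustered
jointly, so both of a gene's labels live in one shared label space.
Non-intersecting genes are clustered separately per dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from trendtide.matrix import AbundanceMatrix

K_MIN, K_MAX = 2, 10


@dataclass(frozen=True)
class GenePartition:
    """Set-algebra split of two datasets' gene universes by shared ID."""

    intersecting: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


@dataclass
class TrendAssignment:
    """Result of one k-means run on profile rows.

    ``labels`` is indexed by the input table's index — ``(gene, dataset)``
    tuples for joint clustering, bare gene IDs for per-dataset runs.
    Labels are canonically ordered: trend 0 has the highest centroid value
    at the first condition (ties broken by later conditions).
    """

    k: int
    labels: pd.Series
    centroids: np.ndarray
    inertia: float
    conditions: tuple[str, ...]

    def label_of(self, key) -> int:
        return int(self.labels.loc[key])


def partition_genes(a: AbundanceMatrix, b: AbundanceMatrix) -> GenePartition:
    """Split genes by presence in the two datasets (exact ID match).

    The datasets must agree on condition names and order.
    """
    if a.conditions != b.conditions:
        diff = sorted(set(a.conditions) ^ set(b.conditions)) or list(
            f"{x} != {y}" for x, y in zip(a.conditions, b.conditions) if x != y
        )
        raise ValueError(
            f"condition mismatch between {a.dataset_id!r} and {b.dataset_id!r}: {diff}"
        )
    ga, gb = set(a.genes), set(b.genes)
    return GenePartition(
        intersecting=frozenset(ga & gb),
        only_a=frozenset(ga - gb),
        only_b=frozenset(gb - ga),
    )


def stack_intersecting(
    a: AbundanceMatrix, b: AbundanceMatrix, partition: GenePartition
) -> pd.DataFrame:
    """Stack the intersecting genes' z-scored profiles from both datasets.

    Returns a 2*|intersecting| x n_conditions table whose MultiIndex rows
    are (gene, dataset_id), sorted by gene then dataset for determinism.
    """
    if a.state != "zscored" or b.state != "zscored":
        raise ValueError("stack_intersecting requires z-scored matrices")
    if not partition.intersecting:
        raise ValueError("nothing to compare: the gene intersection is empty")
    genes = sorted(partition.intersecting)
    frames = []
    for m in sorted((a, b), key=lambda m: m.dataset_id):
        sub = m.data.loc[genes].copy()
        sub.index = pd.MultiIndex.from_product(
            [genes, [m.dataset_id]], names=["gene", "dataset"]
        )
        frames.append(sub)
    stacked = pd.concat(frames).sort_index()
    return stacked


def _canonicalize(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by descending centroid value at the first condition,
    ties broken by subsequent conditions."""
    order = sorted(range(len(centroids)), key=lambda i: tuple(-centroids[i]))
    remap = np.empty(len(centroids), dtype=int)
    for new, old in enumerate(order):
        remap[old] = new
    return remap[labels], centroids[order]


def kmeans_pp(
    rows: pd.DataFrame, k: int, seed: int, n_init: int = 10
) -> TrendAssignment:
    """Cluster profile rows with k-means++ seeding and Lloyd iterations.

    Squared-Euclidean distance on the profile vectors; `n_init` restarts
    keep the lowest-inertia solution; a fixed seed yields identical labels.
    k must lie in [2, 10] and not exceed the number of rows.
    """
    if not (K_MIN <= k <= K_MAX):
        raise ValueError(f"k must lie in [{K_MIN}, {K_MAX}], got {k}")
    if k > len(rows):
        raise ValueError(f"k={k} exceeds the number of rows ({len(rows)})")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_init,
        max_iter=300,
        tol=1e-6,
        random_state=int(seed) % (2**32),
    )
    raw_labels = km.fit_predict(rows.to_numpy())
    labels, centroids = _canonicalize(raw_labels, km.cluster_centers_)
    return TrendAssignment(
        k=k,
        labels=pd.Series(labels, index=rows.index, name="trend"),
        centroids=centroids,
        inertia=float(km.inertia_),
        conditions=tuple(rows.columns),
    )


def _derive_seeds(seed: int, n: int = 3) -> list[int]:
    """Deterministically derive independent child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def cluster_pair(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    k: int,
    seed: int,
    n_init: int = 10,
    partition: GenePartition | None = None,
) -> tuple[TrendAssignment, TrendAssignment | None, TrendAssignment | None]:
    """Joint clustering of intersecting genes + per-dataset clustering of the rest.

    Returns (joint, non_a, non_b).  The joint assignment labels every
    intersecting gene twice — once per dataset — in one shared label space.
    A non-intersecting set with fewer than k members is left unclustered
    (None).  All three runs derive their seeds from the single `seed`.
    """
    if a.state != "zscored" or b.state != "zscored":
        raise ValueError("cluster_pair requires z-scored matrices")
    if partition is None:
        partition = partition_genes(a, b)
    seed_joint, seed_a, seed_b = _derive_seeds(seed, 3)
    stacked = stack_intersecting(a, b, partition)
    joint = kmeans_pp(stacked, k, seed_joint, n_init=n_init)

    def _side(matrix: AbundanceMatrix, genes: frozenset[str], child_seed: int):
        if len(genes) < k:
            return None
        rows = matrix.data.loc[sorted(genes)]
        return kmeans_pp(rows, k, child_seed, n_init=n_init)

    non_a = _side(a, partition.only_a, seed_a)
    non_b = _side(b, partition.only_b, seed_b)
    return joint, non_a, non_b
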