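"""Per-gene statistics, percentile-range filtering and z-score normalization.

Variance and median abundance (and their percentile ranks) are computed on
raw values, before z-scoring, so that abundance/variance filters retain
their meaning after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from trendtide.matrix import AbundanceMatrix

METRICS = ("variance", "median_abundance")
SCOPES = ("both_datasets", "single_dataset")


@dataclass(frozen=True)
class FilterSpec:
    """A percentile-range filter on one per-gene metric.

    A gene passes iff its metric percentile rank lies in ``[lo, hi]``; with
    ``scope="both_datasets"`` it must pass in both matrices of a pair.
    """

    metric: str
    lo: float
    hi: float
    scope: str = "both_datasets"

    def __post_init__(self):
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}, got {self.scope!r}")
        if not (0 <= self.lo <= 100 and 0 <= self.hi <= 100):
            raise ValueError("lo and hi must lie in [0, 100]")
        if self.lo > self.hi:
            raise ValueError(f"lo ({self.lo}) > hi ({self.hi})")


def percentile_ranks(values: np.ndarray) -> np.ndarray:
    """Rank each value on a 0..100 scale.

    rank = 100 * (number of strictly smaller values) / (n - 1), with ties
    midpoint-averaged; n == 1 is undefined and raises.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("percentile ranks are undefined for fewer than 2 genes")
    return 100.0 * (rankdata(values, method="average") - 1.0) / (n - 1.0)


def compute_gene_stats(matrix: AbundanceMatrix) -> pd.DataFrame:
    """Variance, median abundance and their percentile ranks per gene.

    Returns a DataFrame indexed by gene with columns ``variance``,
    ``median_abundance``, ``variance_pct``, ``median_abundance_pct``.
    Requires raw values (state == "raw").
    """
    if matrix.state != "raw":
        raise ValueError("gene stats must be computed on raw values")
    if matrix.n_genes < 2:
        raise ValueError("percentile ranks are undefined for a single-gene matrix")
    x = matrix.values
    var = x.var(axis=1, ddof=0)
    med = np.median(x, axis=1)
    return pd.DataFrame(
        {
            "variance": var,
            "median_abundance": med,
            "variance_pct": percentile_ranks(var),
            "median_abundance_pct": percentile_ranks(med),
        },
        index=pd.Index(matrix.genes, name="gene"),
    )


def filter_by_percentile(
    matrices: AbundanceMatrix | Sequence[AbundanceMatrix],
    spec: FilterSpec,
    stats: pd.DataFrame | Sequence[pd.DataFrame] | None = None,
) -> set[str]:
    """Return the gene IDs whose metric percentile rank falls in [lo, hi].

    For ``scope="both_datasets"`` two matrices must be given and a gene is
    retained only if it satisfies the range in both (evaluated on each
    dataset's own percentile ranks).  Precomputed `stats` (as returned by
    :func:`compute_gene_stats`) can be passed to avoid recomputation.
    """
    if isinstance(matrices, AbundanceMatrix):
        matrices = [matrices]
    matrices = list(matrices)
    if spec.scope == "both_datasets" and len(matrices) != 2:
        raise ValueError("scope='both_datasets' requires exactly two matrices")
    if stats is None:
        stats = [compute_gene_stats(m) for m in matrices]
    elif isinstance(stats, pd.DataFrame):
        stats = [stats]
    else:
        stats = list(stats)
    col = f"{spec.metric}_pct"
    survivor_sets = []
    for st in stats:
        pct = st[col]
        survivor_sets.append(set(st.index[(pct >= spec.lo) & (pct <= spec.hi)]))
    if spec.scope == "both_datasets":
        return survivor_sets[0] & survivor_sets[1]
    return set().union(*survivor_sets)


def zscore(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Standardize each gene's profile to mean 0, population sd 1.

    Zero-variance genes map to the all-zero profile and are recorded in the
    result's ``flat_genes``; they can be removed with the variance filter.
    """
    if matrix.state != "raw":
        raise ValueError(f"matrix {matrix.dataset_id!r} is already z-scored")
    x = matrix.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    flat = sd[:, 0] == 0.0
    safe_sd = np.where(sd == 0.0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[flat, :] = 0.0
    return AbundanceMatrix(
        dataset_id=matrix.dataset_id,
        data=pd.DataFrame(z, index=matrix.data.index, columns=matrix.data.columns),
        state="zscored",
        dropped=matrix.dropped,
        flat_genes=tuple(np.asarray(matrix.genes)[flat]),
    )
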