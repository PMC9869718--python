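"""End-to-end pair analysis: the load -> filter -> z-score -> cluster ->
compare chain shared by the CLI, tests and scripted use."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from trendtide import cluster as _cluster
from trendtide import compare as _compare
from trendtide import preprocess as _pre
from trendtide.matrix import AbundanceMatrix


@dataclass
class PairAnalysis:
    """Everything produced for one dataset pair."""

    partition: _cluster.GenePartition
    result: _compare.ComparisonResult
    sankey: _compare.SankeyModel
    zscored_a: AbundanceMatrix
    zscored_b: AbundanceMatrix
    stats_a: pd.DataFrame
    stats_b: pd.DataFrame


def run_pair(
    a: AbundanceMatrix,
    b: AbundanceMatrix,
    k: int,
    seed: int,
    prefilter: _pre.FilterSpec | None = None,
    n_init: int = 10,
) -> PairAnalysis:
    """Analyze one raw dataset pair.

    An optional pre-clustering percentile filter (variance or median
    abundance) removes genes before z-scoring; unlike the dynamic
    first-level filters it therefore changes the clustering itself.
    """
    if a.state != "raw" or b.state != "raw":
        raise ValueError("run_pair expects raw matrices")
    stats_a = _pre.compute_gene_stats(a)
    stats_b = _pre.compute_gene_stats(b)
    if prefilter is not None:
        # the pre-clustering filter screens each dataset on its own ranks
        single = _pre.FilterSpec(prefilter.metric, prefilter.lo, prefilter.hi,
                                 "single_dataset")
        keep_a = _pre.filter_by_percentile(a, single, stats=stats_a)
        keep_b = _pre.filter_by_percentile(b, single, stats=stats_b)
        a = a.subset([g for g in a.genes if g in keep_a])
        b = b.subset([g for g in b.genes if g in keep_b])
        stats_a = _pre.compute_gene_stats(a)
        stats_b = _pre.compute_gene_stats(b)
    za, zb = _pre.zscore(a), _pre.zscore(b)
    partition = _cluster.partition_genes(za, zb)
    joint, non_a, non_b = _cluster.cluster_pair(za, zb, k=k, seed=seed,
                                                n_init=n_init, partition=partition)
    result = _compare.build_comparison(joint, non_a, non_b,
                                       stats_a=stats_a, stats_b=stats_b)
    sankey = _compare.build_sankey(result)
    return PairAnalysis(
        partition=partition,
        result=result,
        sankey=sankey,
        zscored_a=za,
        zscored_b=zb,
        stats_a=stats_a,
        stats_b=stats_b,
    )
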