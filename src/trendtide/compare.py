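"""Concordance classification, Sankey intersection model, filters, selection.

Each intersecting gene carries two trend labels in one shared label space
(one per dataset).  Equal labels => concordant, unequal => discordant.  The
Sankey model groups genes into nodes (dataset x trend) and links
(trend_a x trend_b intersections); at most k^2 links can exist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trendtide.cluster import GenePartition, TrendAssignment
from trendtide.preprocess import FilterSpec


@dataclass
class ComparisonResult:
    """Trend labels and concordance for one dataset pair."""

    dataset_a: str
    dataset_b: str
    k: int
    labels_a: dict[str, int]  # intersecting genes, shared label space
    labels_b: dict[str, int]
    centroids: np.ndarray  # (k, n_conditions), z-score units
    conditions: tuple[str, ...]
    only_a_labels: dict[str, int] = field(default_factory=dict)
    only_b_labels: dict[str, int] = field(default_factory=dict)
    stats_a: pd.DataFrame | None = None  # raw-value gene stats for dynamic filters
    stats_b: pd.DataFrame | None = None

    @property
    def genes(self) -> list[str]:
        return sorted(self.labels_a)

    def is_concordant(self, gene: str) -> bool:
        return self.labels_a[gene] == self.labels_b[gene]

    @property
    def n_concordant(self) -> int:
        return sum(self.labels_a[g] == self.labels_b[g] for g in self.labels_a)

    @property
    def n_discordant(self) -> int:
        return len(self.labels_a) - self.n_concordant

    def to_table(self) -> pd.DataFrame:
        """Long gene<->trend assignment table (intersecting + non-intersecting)."""
        rows = [
            {
                "gene": g,
                f"trend_{self.dataset_a}": self.labels_a[g],
                f"trend_{self.dataset_b}": self.labels_b[g],
                "concordant": self.labels_a[g] == self.labels_b[g],
            }
            for g in self.genes
        ]
        return pd.DataFrame(rows, columns=[
            "gene", f"trend_{self.dataset_a}", f"trend_{self.dataset_b}", "concordant",
        ])

    def to_dict(self) -> dict:
        return {
            "dataset_a": self.dataset_a,
            "dataset_b": self.dataset_b,
            "k": self.k,
            "conditions": list(self.conditions),
            "centroids": self.centroids.tolist(),
            "labels_a": self.labels_a,
            "labels_b": self.labels_b,
            "only_a_labels": self.only_a_labels,
            "only_b_labels": self.only_b_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComparisonResult":
        return cls(
            dataset_a=d["dataset_a"],
            dataset_b=d["dataset_b"],
            k=int(d["k"]),
            labels_a={g: int(v) for g, v in d["labels_a"].items()},
            labels_b={g: int(v) for g, v in d["labels_b"].items()},
            centroids=np.asarray(d["centroids"], dtype=float),
            conditions=tuple(d["conditions"]),
            only_a_labels={g: int(v) for g, v in d.get("only_a_labels", {}).items()},
            only_b_labels={g: int(v) for g, v in d.get("only_b_labels", {}).items()},
        )


@dataclass(frozen=True)
class SankeyNode:
    dataset: str
    trend: int
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def id(self) -> str:
        return f"node:{self.dataset}:{self.trend}"


@dataclass(frozen=True)
class SankeyLink:
    trend_a: int
    trend_b: int
    genes: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def id(self) -> str:
        return f"link:{self.trend_a}:{self.trend_b}"


@dataclass
class SankeyModel:
    """Nodes (dataset x trend), links (trend intersections), summary counts."""

    dataset_a: str
    dataset_b: str
    k: int
    nodes: list[SankeyNode]
    links: list[SankeyLink]

    @property
    def n_intersecting(self) -> int:
        return sum(l.size for l in self.links)

    @property
    def summary(self) -> dict:
        conc = sum(l.size for l in self.links if l.trend_a == l.trend_b)
        total = self.n_intersecting
        disc = total - conc
        return {
            "concordant": conc,
            "discordant": disc,
            "pct_concordant": 100.0 * conc / total if total else 0.0,
            "pct_discordant": 100.0 * disc / total if total else 0.0,
        }

    def node(self, dataset: str, trend: int) -> SankeyNode:
        for n in self.nodes:
            if n.dataset == dataset and n.trend == trend:
                return n
        raise KeyError(f"no node {dataset}:{trend}")

    def link(self, trend_a: int, trend_b: int) -> SankeyLink:
        for l in self.links:
            if l.trend_a == trend_a and l.trend_b == trend_b:
                return l
        raise KeyError(f"no link {trend_a}->{trend_b}")

    def to_dict(self) -> dict:
        return {
            "dataset_a": self.dataset_a,
            "dataset_b": self.dataset_b,
            "k": self.k,
            "nodes": [
                {"dataset": n.dataset, "trend": n.trend, "size": n.size,
                 "genes": sorted(n.genes)}
                for n in self.nodes
            ],
            "links": [
                {"trend_a": l.trend_a, "trend_b": l.trend_b, "size": l.size,
                 "genes": sorted(l.genes)}
                for l in self.links
            ],
            "summary": self.summary,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SankeyModel":
        return cls(
            dataset_a=d["dataset_a"],
            dataset_b=d["dataset_b"],
            k=int(d["k"]),
            nodes=[
                SankeyNode(n["dataset"], int(n["trend"]), frozenset(n["genes"]))
                for n in d["nodes"]
            ],
            links=[
                SankeyLink(int(l["trend_a"]), int(l["trend_b"]), frozenset(l["genes"]))
                for l in d["links"]
            ],
        )

    def link_table(self) -> pd.DataFrame:
        total = self.n_intersecting
        rows = [
            {
                "trend_a": l.trend_a,
                "trend_b": l.trend_b,
                "size": l.size,
                "pct_of_intersecting": 100.0 * l.size / total if total else 0.0,
            }
            for l in self.links
        ]
        return pd.DataFrame(rows, columns=["trend_a", "trend_b", "size", "pct_of_intersecting"])


def build_comparison(
    joint: TrendAssignment,
    non_a: TrendAssignment | None = None,
    non_b: TrendAssignment | None = None,
    stats_a: pd.DataFrame | None = None,
    stats_b: pd.DataFrame | None = None,
) -> ComparisonResult:
    """Turn a joint trend assignment into per-gene (label_a, label_b) pairs.

    The joint assignment's index must be (gene, dataset) with exactly two
    datasets and every gene labeled in both; a gene labeled on one side
    only indicates a corrupt assignment and raises.
    """
    idx = joint.labels.index
    if not isinstance(idx, pd.MultiIndex) or idx.nlevels != 2:
        raise ValueError("joint assignment must be indexed by (gene, dataset)")
    datasets = sorted(idx.get_level_values("dataset").unique())
    if len(datasets) != 2:
        raise ValueError(f"expected 2 datasets in joint assignment, found {datasets}")
    ds_a, ds_b = datasets
    per_ds = {ds: joint.labels.xs(ds, level="dataset") for ds in datasets}
    missing = set(per_ds[ds_a].index) ^ set(per_ds[ds_b].index)
    if missing:
        raise ValueError(
            f"corrupt assignment: genes labeled in only one dataset: {sorted(missing)}"
        )
    return ComparisonResult(
        dataset_a=ds_a,
        dataset_b=ds_b,
        k=joint.k,
        labels_a={g: int(v) for g, v in per_ds[ds_a].items()},
        labels_b={g: int(v) for g, v in per_ds[ds_b].items()},
        centroids=joint.centroids,
        conditions=joint.conditions,
        only_a_labels=(
            {g: int(v) for g, v in non_a.labels.items()} if non_a is not None else {}
        ),
        only_b_labels=(
            {g: int(v) for g, v in non_b.labels.items()} if non_b is not None else {}
        ),
        stats_a=stats_a,
        stats_b=stats_b,
    )


def build_sankey(result: ComparisonResult) -> SankeyModel:
    """Group genes into (dataset, trend) nodes and (trend_a, trend_b) links.

    Only populated nodes/links are materialized; with k trends there are at
    most k^2 links.
    """
    if not result.labels_a:
        raise ValueError("no intersecting genes to build a Sankey model from")
    node_members: dict[tuple[str, int], set[str]] = {}
    link_members: dict[tuple[int, int], set[str]] = {}
    for g in result.labels_a:
        ta, tb = result.labels_a[g], result.labels_b[g]
        node_members.setdefault((result.dataset_a, ta), set()).add(g)
        node_members.setdefault((result.dataset_b, tb), set()).add(g)
        link_members.setdefault((ta, tb), set()).add(g)
    nodes = [
        SankeyNode(ds, t, frozenset(members))
        for (ds, t), members in sorted(node_members.items())
    ]
    links = [
        SankeyLink(ta, tb, frozenset(members))
        for (ta, tb), members in sorted(link_members.items())
    ]
    return SankeyModel(result.dataset_a, result.dataset_b, result.k, nodes, links)


def overview(
    pairs: list[tuple[ComparisonResult, GenePartition]]
) -> pd.DataFrame:
    """One row of concordant/discordant/non-intersecting counts per pair."""
    if not pairs:
        raise ValueError("overview requires at least one comparison")
    rows = []
    for result, partition in pairs:
        rows.append(
            {
                "dataset_a": result.dataset_a,
                "dataset_b": result.dataset_b,
                "n_concordant": result.n_concordant,
                "n_discordant": result.n_discordant,
                "n_intersecting": len(result.labels_a),
                "n_only_a": len(partition.only_a),
                "n_only_b": len(partition.only_b),
            }
        )
    return pd.DataFrame(rows)


def apply_filters(
    model: SankeyModel,
    result: ComparisonResult,
    specs: list[FilterSpec] | None = None,
    min_link_size: int = 0,
) -> SankeyModel:
    """Subset the Sankey model by percentile filters and link size.

    Genes failing any FilterSpec (evaluated on the raw-value gene stats
    stored in `result`) are removed from node and link member sets; links
    smaller than `min_link_size` are dropped.  Trend labels are never
    recomputed — filtering subsets an existing clustering.
    """
    if min_link_size < 0:
        raise ValueError("min_link_size must be >= 0")
    specs = specs or []
    keep = set(result.labels_a)
    for spec in specs:
        if result.stats_a is None or result.stats_b is None:
            raise ValueError("dynamic filters need gene stats on the comparison result")
        col = f"{spec.metric}_pct"
        sa, sb = result.stats_a[col], result.stats_b[col]
        pass_a = {g for g in keep if spec.lo <= sa[g] <= spec.hi}
        pass_b = {g for g in keep if spec.lo <= sb[g] <= spec.hi}
        if spec.scope == "both_datasets":
            keep &= pass_a & pass_b
        else:
            keep &= pass_a | pass_b
    links = []
    for l in model.links:
        members = l.genes & keep
        if members and len(members) >= min_link_size:
            links.append(SankeyLink(l.trend_a, l.trend_b, frozenset(members)))
    surviving = set().union(*(l.genes for l in links)) if links else set()
    nodes = []
    for n in model.nodes:
        members = n.genes & surviving
        if members:
            nodes.append(SankeyNode(n.dataset, n.trend, frozenset(members)))
    return SankeyModel(model.dataset_a, model.dataset_b, model.k, nodes, links)


def highlight(model: SankeyModel, query: set[str]) -> dict[str, tuple[int, int] | str]:
    """Resolve query gene IDs to their (trend_a, trend_b) link coordinates.

    IDs not present in any link map to the string ``"absent"``.
    """
    coords: dict[str, tuple[int, int]] = {}
    for l in model.links:
        for g in l.genes:
            coords[g] = (l.trend_a, l.trend_b)
    return {q: coords.get(q, "absent") for q in query}


def select(model: SankeyModel, picks: list[str]) -> tuple[set[str], pd.DataFrame]:
    """Extract the union of gene sets behind node/link picks.

    Picks are identifiers of the form ``"node:<dataset>:<trend>"`` or
    ``"link:<trend_a>:<trend_b>"``.  Returns (gene set, per-pick table with
    counts and percentage of all intersecting genes).
    """
    total = model.n_intersecting
    known = {n.id: n for n in model.nodes}
    known.update({l.id: l for l in model.links})
    rows, union = [], set()
    for pick in picks:
        if pick not in known:
            raise KeyError(f"unknown pick {pick!r}; valid ids look like "
                           f"'node:<dataset>:<trend>' or 'link:<ta>:<tb>'")
        item = known[pick]
        union |= item.genes
        if isinstance(item, SankeyLink):
            source = f"{model.dataset_a}:{item.trend_a}"
            target = f"{model.dataset_b}:{item.trend_b}"
        else:
            source = target = f"{item.dataset}:{item.trend}"
        rows.append(
            {
                "pick": pick,
                "source": source,
                "target": target,
                "n_genes": item.size,
                "pct_of_intersecting": 100.0 * item.size / total if total else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=["pick", "source", "target", "n_genes",
                                        "pct_of_intersecting"])
    return union, table
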