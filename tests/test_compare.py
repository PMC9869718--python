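import numpy as np
import pandas as pd
import pytest

from trendtide import compare, preprocess, synth
from trendtide.cluster import GenePartition, TrendAssignment
from trendtide.pipeline import run_pair
from trendtide.preprocess import FilterSpec


def _joint(pairs, k=3, conds=("c1", "c2")):
    """Build a joint TrendAssignment from {gene: (label_a, label_b)}."""
    idx = pd.MultiIndex.from_tuples(
        [(g, ds) for g in sorted(pairs) for ds in ("A", "B")],
        names=["gene", "dataset"],
    )
    labels = pd.Series(
        [pairs[g][0] if ds == "A" else pairs[g][1] for g, ds in idx], index=idx
    )
    return TrendAssignment(k=k, labels=labels, centroids=np.zeros((k, len(conds))),
                           inertia=0.0, conditions=conds)


class TestBuildComparison:
    def test_equal_labels_concordant(self):
        r = compare.build_comparison(_joint({"g": (1, 1)}))
        assert r.is_concordant("g")

    def test_unequal_labels_discordant(self):
        r = compare.build_comparison(_joint({"g": (1, 2)}))
        assert not r.is_concordant("g")

    def test_summary_percentages(self):
        pairs = {f"g{i}": ((0, 0) if i < 6 else (0, 1)) for i in range(10)}
        r = compare.build_comparison(_joint(pairs))
        model = compare.build_sankey(r)
        assert model.summary["pct_concordant"] == pytest.approx(60.0)
        assert model.summary["pct_discordant"] == pytest.approx(40.0)

    def test_one_sided_gene_is_corrupt(self):
        idx = pd.MultiIndex.from_tuples(
            [("g1", "A"), ("g1", "B"), ("g2", "A")], names=["gene", "dataset"]
        )
        joint = TrendAssignment(
            k=2, labels=pd.Series([0, 0, 1], index=idx),
            centroids=np.zeros((2, 2)), inertia=0.0, conditions=("c1", "c2"),
        )
        with pytest.raises(ValueError, match="g2"):
            compare.build_comparison(joint)


class TestBuildSankey:
    def test_all_cells_populated_k4_gives_16_links(self):
        pairs = {}
        i = 0
        for ta in range(4):
            for tb in range(4):
                for _ in range(2):
                    pairs[f"g{i:03d}"] = (ta, tb)
                    i += 1
        model = compare.build_sankey(compare.build_comparison(_joint(pairs, k=4)))
        assert len(model.links) == 16

    def test_all_concordant_diagonal_only(self):
        pairs = {f"g{i}": (i % 3, i % 3) for i in range(9)}
        model = compare.build_sankey(compare.build_comparison(_joint(pairs)))
        assert len(model.links) == 3
        assert all(l.trend_a == l.trend_b for l in model.links)

    def test_link_sizes_sum_to_intersecting(self, planted_analysis):
        analysis, truth = planted_analysis
        assert analysis.sankey.n_intersecting == len(truth.intersecting)

    def test_node_conservation(self, planted_analysis):
        analysis, _ = planted_analysis
        model = analysis.sankey
        for node in model.nodes:
            if node.dataset == model.dataset_a:
                incident = [l for l in model.links if l.trend_a == node.trend]
            else:
                incident = [l for l in model.links if l.trend_b == node.trend]
            assert node.size == sum(l.size for l in incident)

    def test_diagonal_identity(self, planted_analysis):
        analysis, _ = planted_analysis
        model = analysis.sankey
        diag = sum(l.size for l in model.links if l.trend_a == l.trend_b)
        assert model.summary["concordant"] == diag


class TestOverview:
    def test_four_datasets_six_rows(self):
        rows = []
        for i in range(6):
            pairs = {"g1": (0, 0), "g2": (0, 1)}
            r = compare.build_comparison(_joint(pairs))
            p = GenePartition(frozenset(pairs), frozenset(), frozenset())
            rows.append((r, p))
        table = compare.overview(rows)
        assert len(table) == 6

    def test_identical_datasets_fully_concordant(self):
        rng = np.random.default_rng(0)
        from trendtide.matrix import AbundanceMatrix

        data = rng.normal(size=(40, 5))
        a = AbundanceMatrix("A", pd.DataFrame(
            data, index=[f"g{i}" for i in range(40)],
            columns=[f"c{j}" for j in range(5)]))
        b = AbundanceMatrix("B", a.data.copy())
        analysis = run_pair(a, b, k=3, seed=1)
        s = analysis.sankey.summary
        assert s["pct_concordant"] == pytest.approx(100.0)
        assert len(analysis.partition.only_a) == 0
        table = compare.overview([(analysis.result, analysis.partition)])
        assert table.loc[0, "n_only_b"] == 0

    def test_counts_add_up(self, planted_analysis):
        analysis, _ = planted_analysis
        table = compare.overview([(analysis.result, analysis.partition)])
        row = table.iloc[0]
        assert row["n_concordant"] + row["n_discordant"] == row["n_intersecting"]


class TestApplyFilters:
    def test_identity(self, planted_analysis):
        analysis, _ = planted_analysis
        out = compare.apply_filters(analysis.sankey, analysis.result, [], 0)
        assert out.to_dict() == analysis.sankey.to_dict()

    def test_min_link_size_boundary(self, planted_analysis):
        analysis, _ = planted_analysis
        biggest = max(l.size for l in analysis.sankey.links)
        out = compare.apply_filters(analysis.sankey, analysis.result, [],
                                    min_link_size=biggest + 1)
        assert out.links == []

    def test_negative_min_link_size(self, planted_analysis):
        analysis, _ = planted_analysis
        with pytest.raises(ValueError, match="min_link_size"):
            compare.apply_filters(analysis.sankey, analysis.result, [], -1)

    def test_variance_filter_matches_brute_force(self, planted_analysis):
        analysis, _ = planted_analysis
        spec = FilterSpec("variance", 80, 100, "both_datasets")
        out = compare.apply_filters(analysis.sankey, analysis.result, [spec], 0)
        kept = set().union(*(l.genes for l in out.links)) if out.links else set()
        # brute-force oracle: intersect the per-dataset percentile survivors
        sa = analysis.result.stats_a["variance_pct"]
        sb = analysis.result.stats_b["variance_pct"]
        genes = set(analysis.result.labels_a)
        expect = {g for g in genes if sa[g] >= 80} & {g for g in genes if sb[g] >= 80}
        assert kept == expect

    def test_contractive(self, planted_analysis):
        analysis, _ = planted_analysis
        spec = FilterSpec("median_abundance", 20, 90, "both_datasets")
        out = compare.apply_filters(analysis.sankey, analysis.result, [spec], 2)
        for l in out.links:
            assert l.genes <= analysis.sankey.link(l.trend_a, l.trend_b).genes


class TestHighlightSelect:
    def test_highlight_coordinates(self, planted_analysis):
        analysis, truth = planted_analysis
        g = truth.intersecting[0]
        hits = compare.highlight(analysis.sankey, {g, "nope"})
        assert hits[g] == (analysis.result.labels_a[g], analysis.result.labels_b[g])
        assert hits["nope"] == "absent"

    def test_highlight_all_reconstructs_links(self, planted_analysis):
        analysis, _ = planted_analysis
        model = analysis.sankey
        hits = compare.highlight(model, set(analysis.result.labels_a))
        recon = {}
        for g, coord in hits.items():
            recon.setdefault(coord, set()).add(g)
        for l in model.links:
            assert recon[(l.trend_a, l.trend_b)] == set(l.genes)

    def test_select_link(self, planted_analysis):
        analysis, _ = planted_analysis
        link = analysis.sankey.links[0]
        genes, table = compare.select(analysis.sankey, [link.id])
        assert genes == set(link.genes)
        assert table.loc[0, "pct_of_intersecting"] == pytest.approx(
            100.0 * link.size / analysis.sankey.n_intersecting
        )

    def test_node_pick_equals_union_of_incident_links(self, planted_analysis):
        analysis, _ = planted_analysis
        model = analysis.sankey
        node = model.nodes[0]
        genes, _ = compare.select(model, [node.id])
        incident = set().union(
            *(l.genes for l in model.links
              if (l.trend_a if node.dataset == model.dataset_a else l.trend_b) == node.trend)
        )
        assert genes == incident

    def test_two_nodes_same_dataset_disjoint(self, planted_analysis):
        analysis, _ = planted_analysis
        model = analysis.sankey
        same_ds = [n for n in model.nodes if n.dataset == model.dataset_a]
        g1, _ = compare.select(model, [same_ds[0].id])
        g2, _ = compare.select(model, [same_ds[1].id])
        assert g1 & g2 == set()  # trends partition a dataset

    def test_unknown_pick_errors(self, planted_analysis):
        analysis, _ = planted_analysis
        with pytest.raises(KeyError, match="unknown pick"):
            compare.select(analysis.sankey, ["link:99:99"])
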