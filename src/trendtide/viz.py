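"""Static renderings of every view: trend diagrams, Sankey, overview bars,
enrichment bars.  Figures are pure views of the data model — every rendered
number equals the corresponding number in the exported tables."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Rectangle, Polygon

from trendtide.compare import ComparisonResult, SankeyModel
from trendtide.matrix import AbundanceMatrix

# colorblind-safe categorical set of 10 (max k)
DEFAULT_PALETTE = (
    "#0173b2", "#de8f05", "#029e73", "#d55e00", "#cc78bc",
    "#ca9161", "#fbafe4", "#949494", "#ece133", "#56b4e9",
)

TREND_MODES = ("centroid", "profiles", "box")
FORMATS = ("png", "pdf", "svg")


@dataclass
class PlotStyle:
    palette: tuple[str, ...] = DEFAULT_PALETTE
    highlight_color: str = "black"
    figsize: tuple[float, float] = (8.0, 5.0)
    format: str = "png"
    dpi: int = 150

    def color(self, trend: int) -> str:
        return self.palette[trend % len(self.palette)]


def _save(fig, path, style: PlotStyle) -> Path:
    path = Path(path)
    if path.suffix.lstrip(".") not in FORMATS:
        path = path.with_suffix(f".{style.format}")
    fig.savefig(path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_trends(
    result: ComparisonResult,
    zscored: dict[str, AbundanceMatrix],
    path,
    mode: str = "centroid",
    highlight: set[str] | None = None,
    style: PlotStyle | None = None,
) -> Path:
    """Per-trend, per-dataset panels of z-scored profiles.

    centroid: mean line with a +-sd band; profiles: one line per gene;
    box: per-condition distribution boxes.  Highlighted genes are drawn in
    black on top (absent IDs produce a warning, not an error).
    """
    if mode not in TREND_MODES:
        raise ValueError(f"mode must be one of {TREND_MODES}")
    style = style or PlotStyle()
    highlight = highlight or set()
    datasets = [result.dataset_a, result.dataset_b]
    labels = {result.dataset_a: result.labels_a, result.dataset_b: result.labels_b}
    trends = sorted({t for lab in labels.values() for t in lab.values()})
    conds = list(result.conditions)
    xs = np.arange(len(conds))
    fig, axes = plt.subplots(
        len(datasets), len(trends),
        figsize=(3.0 * len(trends), 2.4 * len(datasets)),
        sharey=True, squeeze=False,
    )
    for r, ds in enumerate(datasets):
        matrix = zscored[ds]
        for c, trend in enumerate(trends):
            ax = axes[r][c]
            genes = [g for g, t in labels[ds].items() if t == trend and g in matrix.data.index]
            prof = matrix.data.loc[genes].to_numpy() if genes else np.empty((0, len(conds)))
            color = style.color(trend)
            if mode == "centroid" and len(prof):
                mean, sd = prof.mean(axis=0), prof.std(axis=0, ddof=0)
                ax.fill_between(xs, mean - sd, mean + sd, color=color, alpha=0.3)
                ax.plot(xs, mean, color=color, lw=2)
            elif mode == "profiles":
                for row in prof:
                    ax.plot(xs, row, color=color, alpha=0.35, lw=0.7)
            elif mode == "box" and len(prof):
                bp = ax.boxplot(prof, positions=xs, widths=0.6, patch_artist=True,
                                showfliers=False)
                for patch in bp["boxes"]:
                    patch.set_facecolor(color)
            for g in sorted(highlight & set(genes)):
                ax.plot(xs, matrix.data.loc[g].to_numpy(),
                        color=style.highlight_color, lw=1.2, zorder=5)
            ax.set_xticks(xs)
            ax.set_xticklabels(conds, rotation=45, fontsize=7)
            if r == 0:
                ax.set_title(f"trend {trend} (n={len(genes)})", fontsize=9)
            if c == 0:
                ax.set_ylabel(f"{ds}\nz-score", fontsize=8)
    fig.tight_layout()
    return _save(fig, path, style)


def plot_sankey(model: SankeyModel, path, style: PlotStyle | None = None) -> Path:
    """Two node columns with bands whose thickness encodes link size.

    Band color gradients are inverted: the left end shows the right node's
    color and vice versa, so flows into a node are easy to trace back.
    """
    style = style or PlotStyle()
    if not model.links:
        raise ValueError("model has no links")
    total = model.n_intersecting
    gap = 0.02 * total

    def layout(dataset: str, trend_of) -> dict[int, tuple[float, float]]:
        spans, y = {}, 0.0
        for n in sorted((n for n in model.nodes if n.dataset == dataset),
                        key=lambda n: n.trend):
            spans[n.trend] = (y, y + n.size)
            y += n.size + gap
        return spans

    left = layout(model.dataset_a, None)
    right = layout(model.dataset_b, None)
    fig, ax = plt.subplots(figsize=style.figsize)
    node_w = 0.04
    for trend, (y0, y1) in left.items():
        ax.add_patch(Rectangle((0.0, y0), node_w, y1 - y0,
                               color=style.color(trend), lw=0))
    for trend, (y0, y1) in right.items():
        ax.add_patch(Rectangle((1.0 - node_w, y0), node_w, y1 - y0,
                               color=style.color(trend), lw=0))
    # stack link attachment points down each node
    off_l = {t: y0 for t, (y0, _) in left.items()}
    off_r = {t: y0 for t, (y0, _) in right.items()}
    n_strips = 24
    xs = np.linspace(node_w, 1.0 - node_w, n_strips + 1)
    for link in sorted(model.links, key=lambda l: (l.trend_a, l.trend_b)):
        h = link.size
        y_l, y_r = off_l[link.trend_a], off_r[link.trend_b]
        off_l[link.trend_a] += h
        off_r[link.trend_b] += h
        c_left = np.array(matplotlib.colors.to_rgb(style.color(link.trend_b)))
        c_right = np.array(matplotlib.colors.to_rgb(style.color(link.trend_a)))
        # smoothstep vertical interpolation between the two attachment points
        t = np.linspace(0, 1, n_strips + 1)
        s = t * t * (3 - 2 * t)
        y_lo = y_l + (y_r - y_l) * s
        for i in range(n_strips):
            frac = (i + 0.5) / n_strips
            color = (1 - frac) * c_left + frac * c_right
            ax.add_patch(Polygon(
                [(xs[i], y_lo[i]), (xs[i + 1], y_lo[i + 1]),
                 (xs[i + 1], y_lo[i + 1] + h), (xs[i], y_lo[i] + h)],
                closed=True, facecolor=color, lw=0, alpha=0.6,
            ))
    s = model.summary
    ax.set_title(
        f"{model.dataset_a} vs {model.dataset_b} — "
        f"concordant {s['concordant']} ({s['pct_concordant']:.1f}%), "
        f"discordant {s['discordant']} ({s['pct_discordant']:.1f}%)",
        fontsize=10,
    )
    ax.set_xlim(-0.02, 1.02)
    top = max(max(y1 for _, y1 in left.values()), max(y1 for _, y1 in right.values()))
    ax.set_ylim(top, -gap)  # flows read top-down
    ax.axis("off")
    ax.text(0.0, -2 * gap, model.dataset_a, ha="left", fontsize=9)
    ax.text(1.0, -2 * gap, model.dataset_b, ha="right", fontsize=9)
    return _save(fig, path, style)


def plot_overview(counts: pd.DataFrame, path, style: PlotStyle | None = None) -> Path:
    """One horizontal stacked bar per dataset pair: concordant, discordant,
    only-in-A, only-in-B counts."""
    style = style or PlotStyle()
    if counts.empty:
        raise ValueError("overview table is empty")
    segments = ["n_concordant", "n_discordant", "n_only_a", "n_only_b"]
    seg_labels = ["concordant", "discordant", "only in A", "only in B"]
    seg_colors = ["#2166ac", "#b2182b", "#bdbdbd", "#636363"]
    fig, ax = plt.subplots(figsize=(style.figsize[0], 0.6 * len(counts) + 1.2))
    ys = np.arange(len(counts))
    lefts = np.zeros(len(counts))
    for seg, lab, col in zip(segments, seg_labels, seg_colors):
        vals = counts[seg].to_numpy(dtype=float)
        ax.barh(ys, vals, left=lefts, color=col, label=lab, height=0.6)
        lefts += vals
    ax.set_yticks(ys)
    ax.set_yticklabels([f"{r.dataset_a} vs {r.dataset_b}" for r in counts.itertuples()],
                       fontsize=8)
    ax.invert_yaxis()
    ax.set_xlabel("genes")
    ax.legend(fontsize=8, ncol=4, loc="upper center", bbox_to_anchor=(0.5, -0.18))
    fig.tight_layout()
    return _save(fig, path, style)


def plot_enrichment(
    table: pd.DataFrame, path,
    only_significant: bool = True,
    style: PlotStyle | None = None,
) -> Path:
    """Horizontal bars of -log10(FDR), sorted ascending by FDR, colored by
    over/under direction.  FDR 0 is clamped to the float tiny value for the
    log only."""
    style = style or PlotStyle()
    if table.empty:
        raise ValueError("enrichment table is empty")
    sub = table[table["significant"]] if only_significant else table
    fig, ax = plt.subplots(figsize=(style.figsize[0], 0.4 * max(len(sub), 1) + 1.0))
    if sub.empty:
        import warnings
        warnings.warn("no significant terms to plot", stacklevel=2)
    else:
        sub = sub.sort_values("fdr", kind="stable")
        fdr = sub["fdr"].to_numpy(dtype=float)
        fdr = np.where(fdr <= 0.0, np.finfo(float).tiny, fdr)
        lengths = -np.log10(fdr)
        colors = ["#b2182b" if d == "over" else "#2166ac" for d in sub["direction"]]
        ys = np.arange(len(sub))
        ax.barh(ys, lengths, color=colors, height=0.6)
        ax.set_yticks(ys)
        ax.set_yticklabels(
            [f"{r.term_id} {r.term_name}" for r in sub.itertuples()], fontsize=8
        )
        ax.invert_yaxis()  # smallest FDR at top
    ax.set_xlabel(r"$-\log_{10}$(FDR)")
    fig.tight_layout()
    return _save(fig, path, style)
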