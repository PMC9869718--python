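"""Local GO-term enrichment: Fisher's exact test + Benjamini-Hochberg FDR.

Replaces the original remote enrichment service with a fully local test
against a user-supplied annotation.  For every term a 2x2 contingency table
(selected / not-selected x in-term / not-in-term) is evaluated with the
two-sided Fisher's exact test; BH correction is applied within each GO
category separately (a flag switches to global correction).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from trendtide.io import Annotation, GO_CATEGORIES

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "category",
    "n_selected_in_term", "n_selected", "n_background_in_term", "n_background",
    "expected", "direction", "p_value", "fdr", "significant",
]


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped to 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich(
    selection: set[str],
    annotation: Iterable[Annotation],
    background: set[str] | None = None,
    alpha: float = 0.05,
    per_category_fdr: bool = True,
) -> pd.DataFrame:
    """Test each annotation term for over/under-representation in `selection`.

    Parameters
    ----------
    selection
        Gene IDs of interest.  Genes absent from the background are dropped
        (with a warning recorded in the log).
    annotation
        Annotation records (term + member genes).
    background
        The gene universe to test against.  ``None`` uses the union of all
        annotated genes ("whole annotation"); pass the first-level gene set
        to restrict the universe to the genes of the current analysis.
    alpha
        FDR significance threshold for the ``significant`` flag.
    per_category_fdr
        Correct within each GO category separately (default) or globally.

    Returns an EnrichmentTable DataFrame sorted by (category, p_value).
    """
    annotation = list(annotation)
    if not annotation:
        raise ValueError("annotation is empty")
    if background is None:
        background = set().union(*(a.genes for a in annotation))
    background = set(background)
    inside = set(selection) & background
    if not inside:
        raise ValueError("selection is empty after intersecting with the background")
    if len(background) < len(inside):
        raise ValueError("background smaller than selection")

    n_sel, n_bg = len(inside), len(background)
    rows = []
    for term in annotation:
        in_term = term.genes & background
        if not in_term:
            continue
        a = len(inside & in_term)            # selected, in term
        b = n_sel - a                        # selected, not in term
        c = len(in_term) - a                 # not selected, in term
        d = (n_bg - n_sel) - c               # not selected, not in term
        expected = n_sel * len(in_term) / n_bg
        _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "term_id": term.term_id,
                "term_name": term.term_name,
                "category": term.category,
                "n_selected_in_term": a,
                "n_selected": n_sel,
                "n_background_in_term": len(in_term),
                "n_background": n_bg,
                "expected": expected,
                "direction": "over" if a > expected else "under",
                "p_value": float(p),
            }
        )
    if not rows:
        raise ValueError("no annotation term overlaps the background")
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    if per_category_fdr:
        for cat in table["category"].unique():
            mask = table["category"] == cat
            table.loc[mask, "fdr"] = bh_fdr(table.loc[mask, "p_value"].to_numpy())
    else:
        table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < alpha
    table = table.sort_values(["category", "p_value", "term_id"], kind="stable")
    return table.reset_index(drop=True)[ENRICHMENT_COLUMNS]
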