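"""Synthetic paired datasets with planted trend structure.

Every (trend_a, trend_b) cell of a k x k grid receives a configurable
number of genes; a gene's profile in dataset A follows shape `trend_a`
plus Gaussian noise (in shape space), then an affine per-dataset transform
maps it to raw abundance units.  Because noise is added before the
transform, z-scoring approximately inverts the transform, making planted
trends recoverable by the normalization + clustering chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trendtide.io import Annotation, GO_CATEGORIES
from trendtide.matrix import AbundanceMatrix


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    return (x - mean) / sd


def default_shapes(n_trends: int, n_conditions: int) -> np.ndarray:
    """Piecewise-linear trend prototypes (increasing, decreasing, peak, dip,
    and shifted-apex variants), each standardized to mean 0 / sd 1."""
    if not 2 <= n_trends <= 10:
        raise ValueError("n_trends must lie in [2, 10]")
    if n_conditions < 3:
        raise ValueError("need at least 3 conditions for distinct shapes")
    x = np.linspace(0.0, 1.0, n_conditions)

    def tri(apex: float, up: bool) -> np.ndarray:
        y = np.where(x <= apex, x / max(apex, 1e-9), (1 - x) / max(1 - apex, 1e-9))
        return y if up else -y

    candidates = [
        x,                 # increasing
        -x,                # decreasing
        tri(0.5, True),    # central peak
        tri(0.5, False),   # central dip
        tri(0.25, True),   # early peak
        tri(0.75, True),   # late peak
        tri(0.25, False),  # early dip
        tri(0.75, False),  # late dip
        np.cos(3 * np.pi * x),   # down-up-down oscillation
        -np.cos(3 * np.pi * x),  # up-down-up oscillation
    ]
    return _standardize_rows(np.array(candidates[:n_trends], dtype=float))


@dataclass
class SyntheticSpec:
    """Recipe for one planted dataset pair.

    `genes_per_cell` is either a scalar (every (trend_a, trend_b) cell gets
    that many intersecting genes) or a k x k integer array of per-cell
    counts, which allows planting an arbitrary concordant fraction
    (diagonal mass / total mass).  `frac_only_a`/`frac_only_b` add
    non-intersecting genes, expressed as a fraction of the intersecting
    count.  `scale_a`/`scale_b` are (multiplier, offset) affine transforms
    into raw abundance units.
    """

    n_trends: int = 4
    n_conditions: int = 5
    genes_per_cell: int | np.ndarray = 20
    noise_sd: float = 0.2
    frac_only_a: float = 0.0
    frac_only_b: float = 0.0
    scale_a: tuple[float, float] = (1.0, 0.0)
    scale_b: tuple[float, float] = (1.0, 0.0)
    shapes: np.ndarray | None = None
    seed: int = 0

    def resolved_shapes(self) -> np.ndarray:
        shapes = (
            default_shapes(self.n_trends, self.n_conditions)
            if self.shapes is None
            else np.asarray(self.shapes, dtype=float)
        )
        if shapes.shape != (self.n_trends, self.n_conditions):
            raise ValueError(
                f"shapes must be ({self.n_trends}, {self.n_conditions}), got {shapes.shape}"
            )
        # separability guarantee: shapes must stand clear of the noise floor
        for i in range(len(shapes)):
            for j in range(i + 1, len(shapes)):
                d = float(np.linalg.norm(shapes[i] - shapes[j]))
                if d <= 4.0 * self.noise_sd:
                    raise ValueError(
                        f"shapes {i} and {j} are inseparable at noise_sd={self.noise_sd}"
                        f" (distance {d:.3f} <= {4.0 * self.noise_sd:.3f})"
                    )
        return shapes

    def cell_counts(self) -> np.ndarray:
        k = self.n_trends
        if np.isscalar(self.genes_per_cell):
            if self.genes_per_cell < 1:
                raise ValueError("genes_per_cell must be >= 1")
            return np.full((k, k), int(self.genes_per_cell), dtype=int)
        counts = np.asarray(self.genes_per_cell, dtype=int)
        if counts.shape != (k, k):
            raise ValueError(f"genes_per_cell array must be {k}x{k}")
        if counts.min() < 0 or counts.sum() == 0:
            raise ValueError("cell counts must be >= 0 with a positive total")
        return counts


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside a generated pair."""

    labels_a: dict[str, int]  # every gene in A, planted trend
    labels_b: dict[str, int]
    intersecting: tuple[str, ...]
    concordant_fraction: float
    cell_counts: np.ndarray

    def to_table(self) -> pd.DataFrame:
        rows = []
        for g in self.intersecting:
            rows.append({"gene": g, "trend_a": self.labels_a[g], "trend_b": self.labels_b[g]})
        return pd.DataFrame(rows, columns=["gene", "trend_a", "trend_b"])


def cell_counts_for_concordance(
    n_trends: int, n_genes: int, concordant_fraction: float
) -> np.ndarray:
    """A k x k count matrix whose diagonal mass approximates the target
    concordant fraction while spreading genes as evenly as possible."""
    if not 0.0 <= concordant_fraction <= 1.0:
        raise ValueError("concordant_fraction must lie in [0, 1]")
    k = n_trends
    n_diag = int(round(n_genes * concordant_fraction))
    n_off = n_genes - n_diag
    counts = np.zeros((k, k), dtype=int)
    diag_base, diag_extra = divmod(n_diag, k)
    for i in range(k):
        counts[i, i] = diag_base + (1 if i < diag_extra else 0)
    off_cells = [(i, j) for i in range(k) for j in range(k) if i != j]
    off_base, off_extra = divmod(n_off, len(off_cells))
    for idx, (i, j) in enumerate(off_cells):
        counts[i, j] = off_base + (1 if idx < off_extra else 0)
    return counts


def generate_pair(
    spec: SyntheticSpec,
) -> tuple[AbundanceMatrix, AbundanceMatrix, PlantedTruth]:
    """Generate two raw abundance matrices with planted trends plus truth.

    Intersecting genes are laid out cell by cell; profile in A is
    ``scale_a(shape[trend_a] + noise)`` and in B ``scale_b(shape[trend_b] +
    noise)`` with independent noise draws.  Non-intersecting genes follow a
    randomly chosen trend in their single dataset.  A fixed seed makes the
    output bit-identical across calls.
    """
    shapes = spec.resolved_shapes()
    counts = spec.cell_counts()
    rng = np.random.default_rng(spec.seed)
    conditions = [f"c{i + 1}" for i in range(spec.n_conditions)]

    genes, labels_a, labels_b = [], {}, {}
    rows_a, rows_b = [], []
    mult_a, off_a = spec.scale_a
    mult_b, off_b = spec.scale_b
    idx = 0
    for ta in range(spec.n_trends):
        for tb in range(spec.n_trends):
            for _ in range(counts[ta, tb]):
                g = f"g{idx:05d}"
                idx += 1
                genes.append(g)
                labels_a[g] = ta
                labels_b[g] = tb
                noise_a = rng.normal(0.0, spec.noise_sd, spec.n_conditions)
                noise_b = rng.normal(0.0, spec.noise_sd, spec.n_conditions)
                rows_a.append(mult_a * (shapes[ta] + noise_a) + off_a)
                rows_b.append(mult_b * (shapes[tb] + noise_b) + off_b)

    n_int = len(genes)
    n_only_a = int(round(spec.frac_only_a * n_int))
    n_only_b = int(round(spec.frac_only_b * n_int))
    only_a_genes, only_b_genes = [], []
    for i in range(n_only_a):
        g = f"a{i:05d}"
        t = int(rng.integers(spec.n_trends))
        only_a_genes.append(g)
        labels_a[g] = t
        rows_a.append(mult_a * (shapes[t] + rng.normal(0.0, spec.noise_sd, spec.n_conditions)) + off_a)
    for i in range(n_only_b):
        g = f"b{i:05d}"
        t = int(rng.integers(spec.n_trends))
        only_b_genes.append(g)
        labels_b[g] = t
        rows_b.append(mult_b * (shapes[t] + rng.normal(0.0, spec.noise_sd, spec.n_conditions)) + off_b)

    a = AbundanceMatrix(
        dataset_id="A",
        data=pd.DataFrame(np.array(rows_a), index=genes + only_a_genes, columns=conditions),
    )
    b = AbundanceMatrix(
        dataset_id="B",
        data=pd.DataFrame(np.array(rows_b), index=genes + only_b_genes, columns=conditions),
    )
    diag = int(sum(counts[i, i] for i in range(spec.n_trends)))
    truth = PlantedTruth(
        labels_a=labels_a,
        labels_b=labels_b,
        intersecting=tuple(genes),
        concordant_fraction=diag / n_int,
        cell_counts=counts,
    )
    return a, b, truth


def generate_annotation(
    truth: PlantedTruth,
    n_terms: int = 20,
    enriched_cell: tuple[int, int] | None = None,
    fold: float = 5.0,
    base_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[Annotation], str | None]:
    """Random annotation over the intersecting genes, optionally with one
    planted term whose membership rate is `fold` x higher inside one
    (trend_a, trend_b) cell.

    Returns (annotation records, planted term id or None).
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.intersecting)
    records: list[Annotation] = []
    planted_id = None
    if enriched_cell is not None:
        if fold <= 1.0:
            raise ValueError("fold must be > 1")
        ta, tb = enriched_cell
        cell_genes = {
            g for g in genes
            if truth.labels_a[g] == ta and truth.labels_b[g] == tb
        }
        if not cell_genes:
            raise ValueError(f"enriched cell {enriched_cell} is not populated")
        p_in = min(1.0, fold * base_rate)
        members = {
            g for g in genes
            if rng.random() < (p_in if g in cell_genes else base_rate)
        }
        if not members:  # pathological tiny draw; force one member
            members = {next(iter(cell_genes))}
        planted_id = "T_PLANTED"
        records.append(
            Annotation(planted_id, "planted term", "biological process", frozenset(members))
        )
    n_random = n_terms - len(records)
    for i in range(n_random):
        members = {g for g in genes if rng.random() < base_rate}
        if not members:
            members = {genes[int(rng.integers(len(genes)))]}
        cat = GO_CATEGORIES[i % len(GO_CATEGORIES)] if enriched_cell is None else "biological process"
        records.append(Annotation(f"T{i:04d}", f"random term {i}", cat, frozenset(members)))
    return records, planted_id
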