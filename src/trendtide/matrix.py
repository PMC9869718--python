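"""Core in-memory representation of one abundance dataset."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: normalization states an :class:`AbundanceMatrix` can be in
STATES = ("raw", "zscored")


@dataclass
class AbundanceMatrix:
    """One dataset: genes (rows) x ordered conditions (columns).

    Parameters
    ----------
    dataset_id
        Short label identifying the dataset within a session.
    data
        DataFrame indexed by gene ID with one float column per condition.
        No missing values are allowed; the loader drops incomplete genes.
    state
        ``"raw"`` for values as loaded (arbitrary normalized units such as
        FPKM or log2-LFQ) or ``"zscored"`` after per-gene standardization.
    dropped
        Gene IDs removed at load time because of missing/non-numeric cells.
    flat_genes
        Genes whose raw profile had zero variance (all-zero after z-scoring).
    """

    dataset_id: str
    data: pd.DataFrame
    state: str = "raw"
    dropped: tuple[str, ...] = ()
    flat_genes: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown state {self.state!r}; expected one of {STATES}")
        if self.data.index.has_duplicates:
            dups = sorted(self.data.index[self.data.index.duplicated()].unique())
            raise ValueError(f"duplicate gene IDs in {self.dataset_id!r}: {dups}")
        if self.data.shape[1] < 2:
            raise ValueError(
                f"dataset {self.dataset_id!r} has {self.data.shape[1]} conditions; need >= 2"
            )
        if self.data.isna().any().any():
            raise ValueError(f"dataset {self.dataset_id!r} contains missing values")
        self.data = self.data.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = [str(c) for c in self.data.columns]

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def profile(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy()

    def subset(self, genes) -> "AbundanceMatrix":
        """Row-subset preserving state and metadata; order follows `genes`."""
        idx = [g for g in genes if g in self.data.index]
        return AbundanceMatrix(
            dataset_id=self.dataset_id,
            data=self.data.loc[idx].copy(),
            state=self.state,
            dropped=self.dropped,
            flat_genes=tuple(g for g in self.flat_genes if g in idx),
        )
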