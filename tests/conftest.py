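import numpy as np
import pandas as pd
import pytest

from trendtide.matrix import AbundanceMatrix
from trendtide import synth


@pytest.fixture
def tiny_matrix():
    """3 genes x 3 conditions, raw."""
    return AbundanceMatrix(
        dataset_id="A",
        data=pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [2.0, 4.0, 6.0]],
            index=["g1", "g2", "g3"],
            columns=["c1", "c2", "c3"],
        ),
    )


@pytest.fixture
def abundance_tsv(tmp_path):
    p = tmp_path / "abund.tsv"
    p.write_text(
        "gene\tc1\tc2\n"
        "g1\t1.0\t2.0\n"
        "g2\t3.0\t4.0\n"
        "g3\t5.0\t6.0\n"
    )
    return p


@pytest.fixture
def planted_pair():
    """Default 4-trend pair, all 16 cells populated, 20 genes/cell."""
    spec = synth.SyntheticSpec(n_trends=4, genes_per_cell=20, noise_sd=0.2, seed=7)
    return synth.generate_pair(spec)


@pytest.fixture
def planted_analysis(planted_pair):
    from trendtide.pipeline import run_pair

    a, b, truth = planted_pair
    return run_pair(a, b, k=4, seed=7), truth
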