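import numpy as np
import pandas as pd
import pytest

from mirpipe.io_formats import ExpressionMatrix
from mirpipe.seedmatch import MatureMiRNA


@pytest.fixture
def let7():
    """A let-7a-like mature miRNA with known seed motifs."""
    return MatureMiRNA(mirna_id="mir-let7a", sequence="UGAGGUAGUAGGUUGUAUAGUU")


@pytest.fixture
def count_matrix():
    """3 features x 2 samples raw count matrix."""
    df = pd.DataFrame(
        {"s1": [100.0, 900.0, 0.0], "s2": [10.0, 80.0, 10.0]},
        index=["f1", "f2", "f3"],
    )
    return ExpressionMatrix(df, "raw_count")


@pytest.fixture
def two_group_counts():
    """Deterministic 50-feature, 5+5-sample count matrix and group map."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(10)]
    latent = rng.normal(7, 0.8, size=(50, 10))
    df = pd.DataFrame(
        np.round(2.0**latent), index=[f"f{i:02d}" for i in range(50)], columns=samples
    )
    groups = {s: ("a" if i < 5 else "b") for i, s in enumerate(samples)}
    return ExpressionMatrix(df, "raw_count"), groups
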