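import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def seg_frame(rows):
    """Segment table from (sample, chrom, start, end, mean_cn) tuples."""
    df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "mean_cn"])
    df["n_markers"] = np.maximum(1, (df["end"] - df["start"]) // 1000)
    return df[["sample", "chrom", "start", "end", "n_markers", "mean_cn"]]
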