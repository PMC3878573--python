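import numpy as np
import pandas as pd
import pytest

from gatatriad.io import PeakRecord, PeakSet, ExpressionMatrix


@pytest.fixture
def small_peakset():
    recs = [
        PeakRecord("chr1", 100, 300, 150, 40, "X", "p1"),
        PeakRecord("chr1", 900, 1200, 1000, 25, "X", "p2"),
        PeakRecord("chr2", 50, 250, 120, 60, "X", "p3"),
    ]
    return PeakSet("X", recs)


@pytest.fixture
def expr_matrix():
    rng = np.random.default_rng(0)
    tp = [0.0, 2.0, 8.0, 24.0]
    vals = rng.uniform(1, 10, size=(6, 4))
    df = pd.DataFrame(vals, index=[f"g{i}" for i in range(6)], columns=tp)
    return ExpressionMatrix(values=df, lineage="erythroid")


def peakset_from_summits(summits, experiment_id="X", chrom="chr1", halfwidth=100, tags=10):
    recs = [
        PeakRecord(chrom, s - halfwidth, s + halfwidth, s, tags, experiment_id, f"p{i}")
        for i, s in enumerate(summits)
    ]
    return PeakSet(experiment_id, recs)
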