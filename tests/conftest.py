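import numpy as np
import pandas as pd
import pytest

from trzmir.screen import CONTROL, TREATED, NormalizedMatrix, SampleMeta

FOUR_LINES = (
    ("SKBR3", "positive"),
    ("BT474", "positive"),
    ("MCF7", "negative"),
    ("MDA-MB-231", "negative"),
)


def make_normalized(log2_values: dict[str, dict[str, float]] | pd.DataFrame,
                    lines=FOUR_LINES) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from per-sample log2 values.

    Columns must be named '<line>_treated' / '<line>_control'.
    """
    df = pd.DataFrame(log2_values) if not isinstance(log2_values, pd.DataFrame) else log2_values
    status = dict(lines)
    samples = []
    for col in df.columns:
        line, treatment = col.rsplit("_", 1)
        assert treatment in (TREATED, CONTROL)
        samples.append(
            SampleMeta(sample_id=col, cell_line=line, her2_status=status[line],
                       treatment=treatment)
        )
    return NormalizedMatrix(values=df, samples=samples, quantile_normalized=True)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
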