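import numpy as np
import pandas as pd
import pytest

from line1meth.expression import ExpressionMatrix
from line1meth.simulate import PatternCounts


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 cases vs 3 controls, 4 genes, one clear shift, one missing-heavy row."""
    values = pd.DataFrame(
        {
            "c1": [1.0, 5.0, np.nan, 2.0],
            "c2": [1.1, 5.2, np.nan, 2.1],
            "c3": [0.9, 5.1, 1.0, np.nan],
            "k1": [1.0, 1.0, np.nan, 2.0],
            "k2": [1.05, 1.2, 2.0, 2.2],
            "k3": [0.95, 1.1, np.nan, 1.9],
        },
        index=["flat", "shifted", "sparse", "noisy"],
    )
    groups = pd.Series(
        {"c1": "ASD", "c2": "ASD", "c3": "ASD", "k1": "CTRL", "k2": "CTRL", "k3": "CTRL"}
    )
    return ExpressionMatrix(values=values, groups=groups)


def random_counts(rng: np.random.Generator) -> PatternCounts:
    """A random feasible lane: non-negative counts with positive total."""
    counts = rng.integers(0, 50, size=4)
    if counts.sum() == 0:
        counts[rng.integers(0, 4)] = 1
    return PatternCounts(*[float(c) for c in counts])
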