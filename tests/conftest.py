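import numpy as np
import pandas as pd
import pytest

from discrimint import DataMatrix, OutcomeVector, Pattern


@pytest.fixture
def nine_by_four():
    """Hand-built 9x4 categorical matrix with a numerical outcome.

    The pattern y1=a & y2=x covers rows {0, 1, 2} (outcomes 2, 2.5, 3);
    the interval [2, 3.5] additionally contains row 7 (outcome 3.5), giving
    contingency counts (9, 3, 4, 3).
    """
    frame = pd.DataFrame(
        {
            "y1": ["a", "a", "a", "b", "b", "c", "a", "c", "b"],
            "y2": ["x", "x", "x", "x", "y", "y", "y", "x", "y"],
            "y3": ["m", "n", "m", "n", "m", "n", "m", "n", "m"],
            "y4": ["p", "p", "q", "q", "p", "p", "q", "q", "p"],
        }
    )
    outcome = OutcomeVector(
        "numerical", np.array([2.0, 2.5, 3.0, 10.0, 11.0, 12.0, 13.0, 3.5, 14.0])
    )
    matrix = DataMatrix(frame, outcome)
    pattern = Pattern(descriptor=(("y1", "a"), ("y2", "x")), label="ax")
    return matrix, pattern


def random_matrix(rng, n_rows=None, n_cols=None):
    """Random categorical matrix + numerical outcome for oracle fuzzing."""
    n_rows = n_rows or int(rng.integers(3, 25))
    n_cols = n_cols or int(rng.integers(2, 5))
    cats = ["a", "b", "c"]
    frame = pd.DataFrame(
        {f"y{j}": rng.choice(cats, size=n_rows) for j in range(n_cols)}
    )
    outcome = OutcomeVector("numerical", rng.normal(size=n_rows))
    return DataMatrix(frame, outcome)
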