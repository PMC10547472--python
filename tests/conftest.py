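import numpy as np
import pandas as pd
import pytest

from facscomplexity import AUMatrix, EventLog


def make_matrix(patterns, contexts, au_labels, species="sim", interaction="i1"):
    """Build a small AUMatrix from explicit row patterns.

    ``patterns`` is a list of 0/1 tuples; ``contexts`` a parallel list
    of context labels (or one label for all rows).
    """
    if isinstance(contexts, str):
        contexts = [contexts] * len(patterns)
    # one interaction per context keeps metadata consistent
    df = pd.DataFrame(
        {
            "interaction_id": [f"{interaction}-{c}" for c in contexts],
            "subject_id": "s1",
            "species": species,
            "context": contexts,
        }
    )
    df = pd.concat([df, pd.DataFrame(np.array(patterns), columns=au_labels)], axis=1)
    return AUMatrix(df)


@pytest.fixture
def tiny_matrix():
    """4 rows, 3 AUs, two contexts."""
    return make_matrix(
        [(1, 0, 0), (1, 1, 0), (0, 0, 1), (1, 0, 0)],
        ["affiliative", "affiliative", "aggressive", "aggressive"],
        ["AU10", "AU12", "AU18"],
    )


def make_event_log(rows):
    """rows: list of dicts; missing fields get defaults."""
    defaults = {
        "interaction_id": "i1",
        "subject_id": "s1",
        "species": "sim",
        "context": "affiliative",
        "au": "",
        "start_s": np.nan,
        "stop_s": np.nan,
        "duration_s": 1.0,
    }
    return EventLog(pd.DataFrame([{**defaults, **r} for r in rows]))
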