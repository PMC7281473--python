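import numpy as np
import pandas as pd
import pytest

from retinomimic.counts_de import CountMatrix
from retinomimic.dose_response import DoseResponseAssay

DOSES = np.array([0.001, 0.01, 0.1, 1.0, 10.0])


def make_assay(name, mean_inhibition, n_replicates=3, doses=DOSES):
    """Assay with exact per-dose mean inhibition (replicates identical)."""
    inh = np.asarray(mean_inhibition, dtype=float)
    viab = np.tile((1.0 - inh)[:, None], (1, n_replicates))
    return DoseResponseAssay(name, doses, viab)


def make_count_matrix(counts, lines=None, conditions=None, subtypes=None):
    """CountMatrix from a raw array with a minimal consistent sample sheet."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    if conditions is None:
        conditions = ["DMSO" if j < n // 2 else "ATRA" for j in range(n)]
    if lines is None:
        lines = [f"L{j % max(n // 2, 1):02d}" for j in range(n)]
    if subtypes is None:
        subtypes = ["luminal"] * n
    samples = pd.DataFrame(
        {
            "cell_line": lines,
            "condition": conditions,
            "replicate": list(range(1, n + 1)),
            "subtype": subtypes,
        },
        index=[f"S{j}" for j in range(n)],
    )
    frame = pd.DataFrame(
        counts, index=[f"G{i}" for i in range(counts.shape[0])], columns=samples.index
    )
    return CountMatrix(frame, samples)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
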