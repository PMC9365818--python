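import math

import numpy as np
import pytest

from abfescreen.constants import Constants
from abfescreen.datasets import load_bace1_tier1


@pytest.fixture(scope="session")
def constants() -> Constants:
    return Constants()


@pytest.fixture(scope="session")
def tier1_df():
    return load_bace1_tier1()


def brute_force_auc(scores, labels) -> float:
    """Exhaustive Mann-Whitney pairwise comparison (ascending = better)."""
    actives = [s for s, l in zip(scores, labels) if l == "active"]
    decoys = [s for s, l in zip(scores, labels) if l == "decoy"]
    total = 0.0
    for a in actives:
        for d in decoys:
            if a < d:
                total += 1.0
            elif a == d:
                total += 0.5
    return total / (len(actives) * len(decoys))


def hanley_mcneil_se(auc: float, n_a: int, n_d: int) -> float:
    """Standard error of an empirical AUC (Hanley & McNeil 1982)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_a - 1) * (q1 - auc**2)
        + (n_d - 1) * (q2 - auc**2)
    ) / (n_a * n_d)
    return math.sqrt(max(var, 0.0))
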