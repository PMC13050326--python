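import numpy as np
import pytest
from hypothesis import settings

from saroc import ScoredCohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")

# 4 positives scoring {0.9, 0.8, 0.7, 0.4}, 4 negatives {0.6, 0.3, 0.2, 0.1}:
# small enough to check every derived quantity by hand or exhaustive scan.
TOY_SCORES = [0.9, 0.8, 0.7, 0.4, 0.6, 0.3, 0.2, 0.1]
TOY_LABELS = [1, 1, 1, 1, 0, 0, 0, 0]


def make_toy_cohort(reader_calls=None):
    ids = [f"case{i}" for i in range(8)]
    return ScoredCohort(ids, TOY_SCORES, TOY_LABELS, reader_calls)


@pytest.fixture
def toy_cohort():
    return make_toy_cohort()


def random_cohort(rng, n_min=8, n_max=50, ties=True, prevalence_range=(0.15, 0.85)):
    """Random two-class cohort, optionally with heavy score ties."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        prev = rng.uniform(*prevalence_range)
        labels = (rng.random(n) < prev).astype(int)
        if 0 < labels.sum() < n:
            break
    kind = rng.integers(0, 3) if ties else 0
    if kind == 0:
        scores = rng.random(n)
        scores = np.where(labels == 1, scores ** 0.5, scores ** 1.5)
    elif kind == 1:
        scores = np.round(rng.random(n), 1)  # heavy ties
    else:
        scores = np.clip(rng.beta(2 + 3 * labels, 5 - 3 * labels), 0, 1)
    ids = [f"r{i}" for i in range(n)]
    return ScoredCohort(ids, scores, labels.astype(np.int8))
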