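import math

import numpy as np
import pytest

from psorelapse.cohort import score_cohort
from psorelapse.meta import Z95, StudyEffect
from psorelapse.score import canonical_table
from psorelapse.simulate import GeneratorConfig, generate


@pytest.fixture(scope="session")
def canonical():
    return canonical_table()


@pytest.fixture
def make_study():
    """Factory: StudyEffect from a log-effect and its variance."""

    def _make(y, v, factor="smoking", study_id="s1", effect_type="RR", **kw):
        se = math.sqrt(v)
        return StudyEffect(
            study_id=study_id, factor_id=factor, effect_type=effect_type,
            estimate=math.exp(y), ci_low=math.exp(y - Z95 * se),
            ci_high=math.exp(y + Z95 * se), n=100, **kw)

    return _make


@pytest.fixture(scope="session")
def default_cohort_5000():
    """One large synthetic cohort under the generator's default settings."""
    return generate(GeneratorConfig(n=5000, seed=1))


@pytest.fixture(scope="session")
def scored_5000(default_cohort_5000, canonical):
    return score_cohort(default_cohort_5000, canonical)


def brute_force_auc(scores, outcomes):
    """Pairwise concordance with ties counted 1/2 — the AUC oracle."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    cases, controls = s[y], s[~y]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))
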