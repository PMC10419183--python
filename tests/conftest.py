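import numpy as np
import pandas as pd
import pytest

from metscreen.cohort import default_config, generate_cohort
from metscreen.indices import ParticipantRecord, panel_frame
from metscreen.mets import diagnose_cohort


@pytest.fixture(scope="session")
def cohort10k():
    """Default synthetic cohort at n=10000 (shared across calibration tests)."""
    cohort, _ = generate_cohort(default_config(n=10000, seed=7))
    return cohort


@pytest.fixture(scope="session")
def diagnosed10k(cohort10k):
    panels = panel_frame(cohort10k)
    flags, prevalence = diagnose_cohort(cohort10k)
    return panels, flags, prevalence


@pytest.fixture
def reference_record():
    """The worked-example participant used throughout the unit tests."""
    return ParticipantRecord(
        id="ref",
        sex="male",
        age=60.0,
        height=1.70,
        weight=70.0,
        wc=90.0,
        tg=1.7,
        hdl=1.2,
        fpg=5.0,
        sbp=125.0,
        dbp=80.0,
    )


def random_scores_labels(rng, n_max=50):
    """A random ROC instance with both classes present."""
    n = int(rng.integers(4, n_max + 1))
    # mix continuous and tied scores
    if rng.random() < 0.5:
        scores = rng.normal(size=n)
    else:
        scores = rng.integers(0, 6, size=n).astype(float)
    labels = rng.random(n) < rng.uniform(0.2, 0.8)
    if labels.all() or not labels.any():
        labels[rng.integers(n)] = not labels[rng.integers(n)]
        labels[0] = True
        labels[-1] = False
    return scores, labels
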