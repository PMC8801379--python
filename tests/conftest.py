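"""Shared fixtures: compact generator configs and a trained control-panel model.

Event counts are reduced from the production default (10,000) to 2,000 per
sample so the whole suite runs on a laptop; the generator invariant
(>= 1,000 events) still holds and gating fractions stay stable to ~1%.
"""

from __future__ import annotations

import pytest

from crbflow.fva_quantify import quantify_sample_pair, results_to_frame
from crbflow.pipeline import subject_mean_features
from crbflow.rcs_model import fit_rcs_model
from crbflow.synthetic_data import (
    GeneratorConfig,
    SampleSpec,
    generate_control_cohort,
    simulate_sample_pair,
)

TEST_EVENTS = 2000


def subject_features(subjects, config, day=1, cell_type="PBMC"):
    """Quantify one replicate per subject -> tidy feature table."""
    rows = []
    for s in subjects:
        ch, un = simulate_sample_pair(
            s, SampleSpec(s.subject_id, cell_type=cell_type, day=day), config
        )
        rows.append(
            quantify_sample_pair(
                ch, un, subject_id=s.subject_id, cell_type=cell_type, day=day
            )
        )
    return subject_mean_features(results_to_frame(rows))


@pytest.fixture(scope="session")
def gen_config():
    return GeneratorConfig(events_per_sample=TEST_EVENTS, rng_seed=7)


@pytest.fixture(scope="session")
def control_panel():
    """A 22-carrier / 14-relative training panel and its fitted RCS model."""
    config = GeneratorConfig(events_per_sample=TEST_EVENTS, rng_seed=0)
    subjects = generate_control_cohort(config, 22, 14, "train")
    features = subject_features(subjects, config)
    labels = [
        "pathogenic-like" if s.group == 1 else "benign-like" for s in subjects
    ]
    model = fit_rcs_model(features, labels, seed=0)
    return {
        "config": config,
        "subjects": subjects,
        "features": features,
        "model": model,
    }
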