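"""Shared fixtures: bundled campaign tables and reusable trained models.

The expensive artifacts (a PWM-trained generative model and its sampled
output) are session-scoped so that behavioural unit tests and the
acceptance suite exercise one and the same training run.
"""

from __future__ import annotations

import numpy as np
import pytest

from vhhmine import campaign
from vhhmine.generative import (
    GenerativeConfig,
    sample_sequences,
    train_generative_model,
)
from vhhmine.repertoire import AA_ALPHABET, AnnotatedVHH


@pytest.fixture(scope="session")
def campaign_counts():
    return campaign.cluster_reads()


@pytest.fixture(scope="session")
def campaign_candidates():
    return campaign.candidates_as_vhh()


def make_pwm(rng: np.random.Generator, length: int = 20) -> np.ndarray:
    """CDR-like PWM: every third position variable (0.5/0.3/0.2), rest fixed."""
    pwm = np.zeros((length, len(AA_ALPHABET)))
    for pos in range(length):
        if pos % 3 == 0:
            idx = rng.choice(20, size=3, replace=False)
            pwm[pos, idx] = [0.5, 0.3, 0.2]
        else:
            pwm[pos, rng.integers(20)] = 1.0
    return pwm


def draw_from_pwm(pwm: np.ndarray, n: int, rng: np.random.Generator) -> list[str]:
    length = pwm.shape[0]
    return [
        "".join(AA_ALPHABET[rng.choice(20, p=pwm[p])] for p in range(length))
        for _ in range(n)
    ]


def as_triplet(seq: str) -> tuple[str, str, str]:
    # fixed CDR1/CDR2/CDR3 split used across the PWM fixtures
    return (seq[:7], seq[7:13], seq[13:])


@pytest.fixture(scope="session")
def pwm_fixture():
    """Known-generator training data: (pwm, unique AnnotatedVHHs, draw fn)."""
    rng = np.random.default_rng(20240917)
    pwm = make_pwm(rng)
    seqs = draw_from_pwm(pwm, 1000, rng)
    unique: dict[tuple[str, str, str], AnnotatedVHH] = {}
    for i, s in enumerate(seqs):
        t = as_triplet(s)
        if t in unique:
            unique[t].counts[2] += 1
        else:
            unique[t] = AnnotatedVHH(
                seq_id=f"pwm_{i}", cdr1=t[0], cdr2=t[1], cdr3=t[2], counts={2: 1}
            )
    held_out = draw_from_pwm(pwm, 500, rng)
    return pwm, list(unique.values()), held_out


@pytest.fixture(scope="session")
def reduced_config():
    """The reduced-scale training configuration used for model checks."""
    return GenerativeConfig(hidden_units=32, max_epochs=30, cv_folds=5, seed=5)


@pytest.fixture(scope="session")
def pwm_model(pwm_fixture, reduced_config):
    _, training, _ = pwm_fixture
    return train_generative_model(training, reduced_config)


@pytest.fixture(scope="session")
def pwm_samples(pwm_model):
    samples, shortfall = sample_sequences(pwm_model, n=2000, seed=3)
    return samples, shortfall
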