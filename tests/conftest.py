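"""Shared fixtures: synthetic records and cohort feature tables.

Cohort fixtures are session-scoped because feature extraction over a
hundred records is the expensive part of the suite; every test that needs
a labeled feature table shares the same deterministic cohorts.
"""

import numpy as np
import pytest

import korosound as ks

GLOBAL_SEED = 1


@pytest.fixture(scope="session")
def seeds():
    return ks.stage_seeds(GLOBAL_SEED)


@pytest.fixture()
def config():
    return ks.RunConfig()


@pytest.fixture(scope="session")
def healthy_record():
    """One synthetic healthy-template record with its ground-truth beats."""
    record, truth = ks.generate_record(ks.healthy_spec(), seed=42)
    return record, truth


@pytest.fixture(scope="session")
def contrast_features(seeds):
    """Feature table of a 50+50 cohort with strong programmed class contrast."""
    records, _ = ks.generate_cohorts(50, ks.healthy_spec(), ks.chf_spec(),
                                     seed=seeds["simulate"])
    return ks.features_table(records)


@pytest.fixture(scope="session")
def null_features(seeds):
    """Feature table of a 100+100 cohort whose labels carry no signal."""
    spec = ks.healthy_spec()
    records, _ = ks.generate_cohorts(100, spec, spec, seed=seeds["simulate"])
    return ks.features_table(records)


def match_anchors(anchor_times, truth_times, tol=0.050):
    """Greedy one-to-one matching; returns (recall, precision)."""
    anchor_times = np.asarray(anchor_times)
    used = set()
    tp = 0
    for t in truth_times:
        if anchor_times.size == 0:
            break
        d = np.abs(anchor_times - t)
        order = np.argsort(d)
        for i in order:
            if d[i] > tol:
                break
            if i not in used:
                used.add(i)
                tp += 1
                break
    recall = tp / len(truth_times)
    precision = tp / len(anchor_times) if len(anchor_times) else 0.0
    return recall, precision
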