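"""Shared fixtures: planted synthetic SSNs and fitted detectors."""

from __future__ import annotations

import warnings

import pytest

from acdc_ssn.estimators import ACDCCommunityDetector
from acdc_ssn.synthetic import GeneratorConfig, SplitInjection, generate


@pytest.fixture(scope="session")
def clean_ssn():
    """Separable 3-family planted SSN (transition band populated)."""
    return generate(GeneratorConfig(seed=11, family_sizes=(12, 12, 12)))


@pytest.fixture(scope="session")
def split_ssn():
    """3-family SSN with one family severed into bridge-joined halves."""
    return generate(
        GeneratorConfig(
            seed=7,
            family_sizes=(12, 12, 12),
            transition_fraction=0.0,
            split_injection=SplitInjection(),
        )
    )


@pytest.fixture(scope="session")
def fitted_detector(clean_ssn):
    """Detector fitted on the clean SSN (shared; treat as read-only)."""
    det = ACDCCommunityDetector(random_state=0, kmeans_replicas=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        det.fit(clean_ssn.links)
    return det


@pytest.fixture(scope="session")
def fitted_split_detector(split_ssn):
    det = ACDCCommunityDetector(random_state=0, kmeans_replicas=30)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        det.fit(split_ssn.links)
    return det
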