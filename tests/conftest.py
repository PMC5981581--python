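"""Shared fixtures: synthetic datasets and segmented ROIs.

The heavyweight fixtures (the 300-image dataset and its segmented ROIs)
are session-scoped so the end-to-end and CNN-training tests share one
segmentation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from irispad import synth
from irispad.pipeline import PipelineConfig, compute_rois


@pytest.fixture(scope="session")
def default_params() -> synth.SynthParams:
    return synth.SynthParams()


@pytest.fixture(scope="session")
def eye_and_truth(default_params):
    return synth.generate_eye(default_params, seed=3)


@pytest.fixture(scope="session")
def dataset300(default_params):
    """150 bona-fide + 150 attack eyes: 200 train / 100 test_known."""
    images, records, truths = synth.generate_dataset(
        default_params, 150, 150, seed=11
    )
    return images, records, truths


@pytest.fixture(scope="session")
def rois300(dataset300):
    """Segmented ROIs with a 200-train / 100-test protocol split.

    Per class: the first 100 eyes train, the remaining 50 test.
    """
    images, records, _ = dataset300
    rois = compute_rois(images, PipelineConfig().seg)
    labels = np.array([1 if r.label == "attack" else 0 for r in records])
    splits = np.empty(len(records), dtype="<U10")
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        splits[idx[:100]] = "train"
        splits[idx[100:]] = "test_known"
    return rois, labels, splits
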