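import logging

import numpy as np
import pytest

from connanomaly.atlas import default_atlas, make_atlas
from connanomaly.normative import ConnectivityMatrix, Modality

logging.getLogger("connanomaly").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def atlas379():
    return default_atlas()


@pytest.fixture
def toy_atlas():
    """4 cortical regions: 2 left / 2 right, two lobes, two networks."""
    return make_atlas([
        ("L_a", "left", "cortical", "none", "frontal", "DMN"),
        ("L_b", "left", "cortical", "none", "parietal", "CEN"),
        ("R_a", "right", "cortical", "none", "frontal", "DMN"),
        ("R_b", "right", "cortical", "none", "parietal", "CEN"),
    ])


@pytest.fixture
def mixed_atlas():
    """Toy atlas with cortical, subcortical and midline regions of every
    subcortical class the edge classifier distinguishes."""
    return make_atlas([
        ("L_ctx1", "left", "cortical", "none", "frontal", "DMN"),
        ("L_ctx2", "left", "cortical", "none", "temporal", "DMN"),
        ("R_ctx1", "right", "cortical", "none", "frontal", "CEN"),
        ("L_caud", "left", "subcortical", "basal_ganglia", "subcortical", "Basal ganglia"),
        ("R_thal", "right", "subcortical", "thalamus", "subcortical", "Thalamus"),
        ("L_hip", "left", "subcortical", "hippocampus", "subcortical", "Limbic"),
        ("R_cereb", "right", "subcortical", "cerebellum", "subcortical", "Cerebellum"),
        ("R_acc", "right", "subcortical", "accumbens", "subcortical", "Basal ganglia"),
        ("Brain stem", "midline", "subcortical", "brainstem", "subcortical", "Brainstem"),
    ])


def structural_matrix(subject_id, values):
    return ConnectivityMatrix(subject_id, Modality.STRUCTURAL, np.asarray(values, float))


def functional_matrix(subject_id, values):
    return ConnectivityMatrix(subject_id, Modality.FUNCTIONAL, np.asarray(values, float))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
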