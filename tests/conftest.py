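"""Shared fixtures: small synthetic brains and the reference phantom run.

The reference phantom and its pipeline run are session-scoped because the
96-cubed end-to-end computation is the most expensive thing in the suite and
many tests only inspect its (immutable) outputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from lacunaflow import (
    BinaryMask,
    ImageVolume,
    PipelineConfig,
    build_subject_masks,
    build_template_masks,
    default_phantom_spec,
    generate_pair,
    segment_incident_lacunes,
)

PHANTOM_SEED = 7


@pytest.fixture(scope="session")
def phantom_data():
    """The reference 96^3 phantom (3 incident, 1 extension, 2 confounders)."""
    return generate_pair(default_phantom_spec(seed=PHANTOM_SEED))


@pytest.fixture(scope="session")
def phantom_masks(phantom_data):
    tset = build_template_masks(
        phantom_data.wm_mask, phantom_data.ventricles, phantom_data.basal_ganglia
    )
    sset = build_subject_masks(
        phantom_data.followup, phantom_data.brain_mask, seed=PHANTOM_SEED
    )
    return tset, sset


@pytest.fixture(scope="session")
def phantom_result(phantom_data, phantom_masks):
    tset, sset = phantom_masks
    cfg = PipelineConfig(kmeans_seed=PHANTOM_SEED)
    return segment_incident_lacunes(
        phantom_data.baseline,
        phantom_data.followup,
        sset,
        tset,
        phantom_data.baseline_lacunes,
        cfg,
    )


def make_volume(data, spacing=(1.0, 1.0, 1.0)) -> ImageVolume:
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def make_mask(data, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    return BinaryMask(data=np.asarray(data).astype(np.uint8), spacing=spacing)


@pytest.fixture
def tiny_brain():
    """12^3 three-tier brain: CSF=10 shell gap, GM=60, WM=100 core."""
    shape = (12, 12, 12)
    t1 = np.zeros(shape)
    brain = np.zeros(shape, dtype=bool)
    cx = np.array([5.5, 5.5, 5.5])
    coords = np.indices(shape).reshape(3, -1).T
    dist = np.linalg.norm(coords - cx, axis=1).reshape(shape)
    brain[dist <= 5.5] = True
    t1[brain] = 10.0  # CSF rim
    t1[dist <= 4.0] = 60.0  # GM
    t1[dist <= 2.5] = 100.0  # WM
    return make_volume(t1), make_mask(brain), dist
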