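"""Shared fixtures.

``phantom_study`` is the expensive session fixture: a full end-to-end run
(38 phantom controls + 6 lesioned patients at half resolution, normative
model, patch dataset, CNN trained for 2000 iterations).  Everything that
needs a trained model shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

import ctinfarct as ci
from ctinfarct import pipeline
from ctinfarct.nn import predict_classes
from ctinfarct.normative import TScoreMap
from ctinfarct.volume import BinaryMask


def make_tmap(t: np.ndarray, mask: np.ndarray | None = None) -> TScoreMap:
    """Wrap a raw 3-D array as a t-score map (all-true mask by default)."""
    t = np.asarray(t, dtype=np.float64)
    m = np.ones(t.shape, bool) if mask is None else np.asarray(mask, bool)
    return TScoreMap(t=t, mask=BinaryMask(m), n_used=38)


@pytest.fixture(scope="session")
def phantom_study():
    """End-to-end phantom run: cohort, normative model, dataset, trained CNN."""
    seed = 1
    spec = ci.PhantomSpec(seed=seed)
    lesions = ci.LesionSpec(seed=seed + 1)
    controls = [ci.generate_control(spec, 1000 + i) for i in range(38)]
    patients = [ci.generate_patient(spec, lesions, 2000 + i) for i in range(6)]
    normative = pipeline.build_model_from_controls(controls)
    tmaps = [pipeline.patient_tscore_map(vol, normative) for vol, _ in patients]
    masks = [mask for _, mask in patients]
    dataset = pipeline.build_patch_dataset(tmaps, masks, seed=seed)
    cnn = ci.build_cnn(ci.CNNConfig(seed=seed))
    history = ci.train_cnn(cnn, dataset,
                           ci.TrainConfig(max_iterations=2000, seed=seed))
    x_val, y_val = dataset.arrays("validation")
    val_accuracy = float((predict_classes(cnn, x_val) == y_val).mean())
    return {
        "seed": seed, "spec": spec, "lesions": lesions,
        "controls": controls, "patients": patients,
        "normative": normative, "tmaps": tmaps, "masks": masks,
        "dataset": dataset, "cnn": cnn, "history": history,
        "val_accuracy": val_accuracy,
    }
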