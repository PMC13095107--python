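"""Shared fixtures.

The two expensive end-to-end cross-validation runs (separable-class data
and identical-profile null data) are session-scoped so every test that
inspects them shares one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from eegstage.evaluate import run_kfold
from eegstage.imaging import segment, to_image
from eegstage.io import Recording
from eegstage.model import ModelConfig, TrainConfig, build_model, predict, train
from eegstage.preprocess import downsample, swt_denoise
from eegstage.synth import SynthSpec, generate_dataset, null_profiles

# Training settings for the end-to-end runs: small batches so a short run
# still performs enough gradient updates on the scaled-down dataset.
E2E_TRAIN = TrainConfig(batch_size=12, max_epochs=3, learning_rate=1e-3, seed=0)
E2E_DATA_SEED = 1
E2E_KFOLD_SEED = 0


def make_recording(n_samples=2560, fs=256, label="HS", subject_id="s1", seed=0, scale=10.0):
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_samples, 19)) * scale
    return Recording(subject_id=subject_id, label=label, fs=fs, data=data)


@pytest.fixture
def recording():
    return make_recording()


def preprocess_to_images(recordings):
    """Full preprocessing chain: 256 Hz → denoise → 5 s windows → 8-bit images."""
    images, labels, subjects = [], [], []
    for rec in recordings:
        den = swt_denoise(downsample(rec))
        for seg in segment(den):
            images.append(to_image(seg).pixels)
            labels.append(seg.label)
            subjects.append(seg.subject_id)
    return np.stack(images), np.array(labels), np.array(subjects)


def cnn_fit_predict(train_cfg=E2E_TRAIN, model_cfg=None):
    arch = build_model(model_cfg or ModelConfig())

    def fit_predict(xtr, ytr, xte):
        trained = train(arch, xtr, ytr, train_cfg)
        fit_predict.last_epochs_run = trained.epochs_run
        return predict(trained, xte)

    return fit_predict


@pytest.fixture(scope="session")
def easy_kfold_run():
    """10-fold CNN run on separable-class synthetic data (12 subj/class, 60 s)."""
    spec = SynthSpec(n_per_class=12, duration_s=60.0, seed=E2E_DATA_SEED)
    _, recordings = generate_dataset(spec)
    X, y, subjects = preprocess_to_images(recordings)
    reports, summary = run_kfold(X, y, cnn_fit_predict(), k=10, seed=E2E_KFOLD_SEED)
    return {"reports": reports, "summary": summary, "n": len(y)}


@pytest.fixture(scope="session")
def null_kfold_run():
    """Same pipeline and training settings on identical-profile (null) data.

    Shorter recordings (30 s) keep the run affordable; chance-level
    behaviour does not depend on recording length.
    """
    spec = SynthSpec(
        n_per_class=12, duration_s=30.0, profiles=null_profiles(), seed=E2E_DATA_SEED
    )
    _, recordings = generate_dataset(spec)
    X, y, subjects = preprocess_to_images(recordings)
    reports, summary = run_kfold(X, y, cnn_fit_predict(), k=10, seed=E2E_KFOLD_SEED)
    return {"reports": reports, "summary": summary, "n": len(y)}
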