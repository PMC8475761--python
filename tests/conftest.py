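import numpy as np
import pytest

import eegid as eg
from eegid.preprocess import EpochArray
from eegid.spectral_features import concat_tensors


@pytest.fixture(scope="session")
def small_spec():
    """3 subjects, 2 runs, both conditions, 60 s — a fast full-design cohort."""
    return eg.make_cohort_spec(3, 2, seed=11, overrides={"duration_s": 60.0})


@pytest.fixture(scope="session")
def small_epochs(small_spec):
    rec = eg.synthesize_recording(small_spec, "S01", "RUN1", "REO")
    return eg.preprocess_recording(rec)


def random_epochs(n_epochs=20, n_channels=4, n_samples=100, fs=100.0, seed=0):
    rng = np.random.default_rng(seed)
    labels = tuple(f"ch{i}" for i in range(n_channels))
    return EpochArray(
        subject_id="S01",
        run_id="RUN1",
        condition="REO",
        fs=fs,
        channel_labels=labels,
        epochs=rng.standard_normal((n_epochs, n_channels, n_samples)),
    )


def cohort_psd_tensor(spec, runs=None, condition="REO", block=5):
    """Transformed, block-averaged PSD tensor over a cohort's recordings."""
    runs = runs or spec.run_ids
    tensors = []
    for sid in spec.subject_ids:
        for rid in runs:
            rec = eg.synthesize_recording(spec, sid, rid, condition)
            tensors.append(eg.welch_psd(eg.preprocess_recording(rec)))
    t = concat_tensors(tensors)
    return eg.block_average(eg.transform_features(t), block)
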