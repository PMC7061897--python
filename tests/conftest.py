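import numpy as np
import pytest

from eegfactors import (
    MixingModel,
    Recording,
    SourceSpec,
    SyntheticDatasetConfig,
    generate_sources,
    make_labeled_dataset,
    mix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_recording(rng):
    return Recording(
        subject_id="s01",
        trial_id="t01",
        channel_labels=[f"ch{i:02d}" for i in range(8)],
        fs=128.0,
        data=rng.standard_normal((8, 1024)),
    )


@pytest.fixture(scope="session")
def laplace_mixture():
    """Noiseless 8-channel mixture of 3 independent heavy-tailed sources,
    plus the ground truth; the shared fixture behind the source-recovery and
    subspace-projection oracle tests."""
    rng = np.random.default_rng(42)
    M = rng.standard_normal((8, 3))
    model = MixingModel(
        M=M,
        source_specs=[SourceSpec("laplace_iid")] * 3,
        noise_sd=0.0,
        fs=128.0,
    )
    S = generate_sources(model, 6000, seed=7)
    rec = mix(S, model, seed=8)
    return model, S, rec


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two-subject synthetic dataset used by decoder training tests."""
    cfg = SyntheticDatasetConfig(
        n_subjects=2, trials_per_subject=6, trial_seconds=10, master_seed=11
    )
    return make_labeled_dataset(cfg)


@pytest.fixture(scope="session")
def pooled_samples(tiny_dataset):
    from eegfactors import zscore_per_subject

    normed = zscore_per_subject(tiny_dataset.recordings)
    return np.concatenate([r.data.T for r in normed], axis=0), normed
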