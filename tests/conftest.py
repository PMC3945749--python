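import numpy as np
import pytest

import mimicrank as mr

RATE = 48000


@pytest.fixture(scope="session")
def tone_clip():
    """Pure 937.5 Hz tone, 1 s: lands exactly on spectrogram bin 5."""
    t = np.arange(RATE) / RATE
    return mr.AudioClip(samples=0.9 * np.sin(2 * np.pi * 937.5 * t), rate=RATE, id="tone")


@pytest.fixture(scope="session")
def identity_library():
    """Small library whose mimics are bit-identical copies of their models."""
    return mr.build_library(
        mr.LibrarySpec(
            n_mimic=6,
            n_model=6,
            n_other=4,
            n_conspecific=4,
            perturbation=mr.IDENTITY_PERTURBATION,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def study_library():
    """82-file library at the study composition and perturbation level."""
    return mr.build_library(mr.LibrarySpec(seed=5))
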