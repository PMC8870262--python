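"""Shared fixtures.

The heavier session-scope fixtures define the desk-scale study: a
two-site paired-modality "human-like" pretraining cohort and a six-site
"macaque-like" target cohort of 64^3 volumes, with a grid-64 ResTLU network
of reduced channel widths so the whole two-stage protocol runs on one CPU.
"""

import numpy as np
import pytest

from restlu import network as net
from restlu import phantom as ph
from restlu import training as tr

# desk-scale study conditions (shared by the end-to-end and transfer suites)
DESK_CHANNELS = (8, 16, 32, 48, 64)
DESK_GRID = 64
HUMAN_SEED = 101
MACAQUE_SEED = 202
PRETRAIN_EPOCHS = 10
FINETUNE_EPOCHS = 12


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_spec():
    """A minimal architecture for fast structural tests."""
    return net.ArchSpec(variant="restlu", encoder_channels=(4, 6, 8, 10, 12),
                        grid=(32, 32))


@pytest.fixture(scope="session")
def desk_spec():
    return net.ArchSpec(variant="restlu", encoder_channels=DESK_CHANNELS,
                        grid=(DESK_GRID, DESK_GRID))


@pytest.fixture(scope="session")
def human_cohort():
    """2 source-domain sites x 3 subjects, paired T1w/T2w, 64x64x48."""
    return ph.generate_cohort(ph.human_profiles(2, 3), ph.human_base_spec(),
                              seed=HUMAN_SEED)


@pytest.fixture(scope="session")
def macaque_cohort():
    """6 target-domain sites x 2 subjects, all 64^3, site-varying contrast,
    noise and bias."""
    profiles = ph.macaque_profiles(6, 2)
    for p in profiles:
        p.shape = (64, 64, 64)
    base = ph.macaque_base_spec((64, 64, 64))
    return ph.generate_cohort(profiles, base, seed=MACAQUE_SEED)


@pytest.fixture(scope="session")
def pretrained(desk_spec, human_cohort):
    """Stage-one checkpoint: 10 epochs on the paired human-like cohort."""
    cfg = tr.TrainConfig.pretrain_defaults(epochs=PRETRAIN_EPOCHS, seed=11,
                                           slice_step=2)
    state, record = tr.pretrain(human_cohort[:4], cfg, desk_spec,
                                val_dataset=human_cohort[4:])
    return state, record
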