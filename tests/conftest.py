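import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from nodphon.kinematics import NormalizedTrajectory
from nodphon.synthetic import SessionConfig, simulate_session


def make_trajectory(y, fps=50.0):
    y = np.asarray(y, dtype=float)
    return NormalizedTrajectory(t=np.arange(len(y)) / fps, y=y, fps=fps)


@pytest.fixture(scope="session")
def noiseless_session():
    """Small synthetic corpus with zero jitter and no dropped frames."""
    cfg = SessionConfig(
        seed=123, n_signers=6, nods_per_signer=15,
        jitter_sd=0.0, dropped_frame_rate=0.0, low_confidence_rate=0.0,
    )
    return simulate_session(cfg)


@pytest.fixture(scope="session")
def noisy_session():
    """Small synthetic corpus at the default noise operating point."""
    return simulate_session(SessionConfig(seed=7, n_signers=4, nods_per_signer=12))
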