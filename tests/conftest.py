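import numpy as np
import pandas as pd
import pytest

from smokesense.config import CohortConfig, MotifSpec
from smokesense.io import CHANNELS
from smokesense.pipeline import LabeledDataset
from smokesense.synthetic import generate_participant


@pytest.fixture(scope="session")
def tiny_bundle():
    """One participant, 2 days per phase, moderate event rates."""
    cfg = CohortConfig(n_participants=1, phase1_days=2, phase2_days=2,
                       smokes_per_day=12.0, craving_rate=4.0, lapse_rate=7.0,
                       motif_amplitude=1.0, missing_prob=0.02, seed=11)
    return generate_participant(cfg, MotifSpec(), "p01")


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(n_participants=1, phase1_days=2, phase2_days=2,
                        smokes_per_day=12.0, craving_rate=4.0, lapse_rate=7.0,
                        motif_amplitude=1.0, missing_prob=0.02, seed=11)


def make_dataset(X: np.ndarray, y: np.ndarray, kinds=None, levels=None,
                 hours=None, participant="p01", phase=1,
                 channels=CHANNELS) -> LabeledDataset:
    """Assemble a LabeledDataset directly from arrays (test helper)."""
    n = len(y)
    start = pd.Timestamp("2024-01-01")
    meta = pd.DataFrame({
        "participant_id": participant,
        "phase": phase,
        "start_time": [start + pd.Timedelta(minutes=5 * i) for i in range(n)],
        "event_kind": kinds if kinds is not None else
        np.where(np.asarray(y) == 1, "smoke", "none"),
        "craving_level": levels if levels is not None else np.full(n, np.nan),
        "hour_of_day": hours if hours is not None
        else [(i // 12) % 24 for i in range(n)],
    })
    return LabeledDataset(np.asarray(X, dtype=float), np.asarray(y, dtype=int),
                          meta, tuple(channels))
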