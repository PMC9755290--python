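import warnings

import numpy as np
import pytest

from eegmarkers.montage import PairClassification
from eegmarkers.pipeline import preprocess_record
from eegmarkers.records import EEGRecord
from eegmarkers.synth import CohortConfig, generate_recording

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def pairs() -> PairClassification:
    return PairClassification()


@pytest.fixture(scope="session")
def as_pair():
    """Matched AS-like wake/sleep pair (same participant seed), raw."""
    cfg = CohortConfig(regime="AS_like", fs=125.0, duration_s=60.0, seed=3,
                       mask_fraction=0.0)
    wake = generate_recording(cfg, "p0", "wake", 77)
    sleep = generate_recording(cfg, "p0", "nrem", 77)
    return cfg, wake, sleep


@pytest.fixture(scope="session")
def as_pair_preprocessed(as_pair):
    cfg, wake, sleep = as_pair
    return cfg, preprocess_record(wake)[0], preprocess_record(sleep)[0]


def make_record(data: np.ndarray, fs: float = 125.0,
                mask: np.ndarray | None = None, state: str = "wake",
                labels=None) -> EEGRecord:
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if labels is None:
        from eegmarkers.montage import CANONICAL_ORDER
        labels = CANONICAL_ORDER[: data.shape[0]]
    if mask is None:
        mask = np.ones(data.shape[1], dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return EEGRecord(
            data=data, fs=fs, channel_labels=tuple(labels),
            artifact_mask=mask, participant_id="p0", cohort="AS_like",
            state=state,
        )
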