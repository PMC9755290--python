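"""In-memory EEG container and file I/O (internal fixture format, EDF).

An :class:`EEGRecord` is a channels x samples float array in microvolts with
a sampling rate, canonical channel labels, a per-sample artifact mask
(``True`` = usable) and participant/cohort/state metadata.  The internal
fixture format stores the array as a ``.npy`` file next to a JSON sidecar
with the metadata; EDF files are read through MNE when available.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .montage import CANONICAL_ORDER, canonical_label

#: Sampling rates seen in the cohorts this pipeline targets.  Other positive
#: rates are accepted with a warning.
STANDARD_RATES = (125.0, 200.0, 250.0, 256.0, 500.0, 512.0)

WAKE = "wake"
NREM = "nrem"
STATES = (WAKE, NREM)


@dataclass
class EEGRecord:
    """Multichannel EEG segment with artifact mask and study metadata."""

    data: np.ndarray              # (n_channels, n_samples), microvolts
    fs: float                     # Hz
    channel_labels: tuple[str, ...]
    artifact_mask: np.ndarray     # (n_samples,) bool, True = usable
    participant_id: str
    cohort: str
    state: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if float(self.fs) not in STANDARD_RATES:
            warnings.warn(
                f"non-standard sampling rate {self.fs} Hz accepted",
                stacklevel=2,
            )
        if self.artifact_mask is None:
            self.artifact_mask = np.ones(self.data.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.data.shape[1],):
            raise ValueError("artifact mask length must equal sample count")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.state not in STATES:
            raise ValueError(f"state must be one of {STATES}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def usable_s(self) -> float:
        return float(self.artifact_mask.sum()) / self.fs

    @property
    def recording_id(self) -> str:
        return f"{self.participant_id}_{self.state}"

    def copy_with(self, **kwargs) -> "EEGRecord":
        out = replace(self, **kwargs)
        return out


def mask_from_intervals(
    n_samples: int, bad_intervals: list[tuple[int, int]]
) -> np.ndarray:
    """Build a usability mask from half-open [start, stop) bad intervals."""
    mask = np.ones(n_samples, dtype=bool)
    for start, stop in bad_intervals:
        mask[max(start, 0):min(stop, n_samples)] = False
    return mask


# ---------------------------------------------------------------------------
# internal fixture format: <stem>.npy + <stem>.json
# ---------------------------------------------------------------------------

def write_fixture(record: EEGRecord, path: str | Path) -> Path:
    """Write a record in the internal fixture format; returns the .npy path."""
    path = Path(path)
    if path.suffix == ".npy":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), record.data)
    sidecar = {
        "fs": record.fs,
        "channel_labels": list(record.channel_labels),
        "participant_id": record.participant_id,
        "cohort": record.cohort,
        "state": record.state,
        "bad_intervals": _mask_to_intervals(record.artifact_mask),
        "meta": record.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path.with_suffix(".npy")


def read_fixture(path: str | Path) -> EEGRecord:
    path = Path(path)
    if path.suffix == ".json":
        path = path.with_suffix("")
    data = np.load(path.with_suffix(".npy"))
    try:
        sidecar = json.loads(path.with_suffix(".json").read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(
            f"malformed fixture sidecar {path.with_suffix('.json')}: "
            f"error at offset {exc.pos}"
        ) from exc
    mask = mask_from_intervals(
        data.shape[1], [tuple(iv) for iv in sidecar["bad_intervals"]]
    )
    return EEGRecord(
        data=data,
        fs=float(sidecar["fs"]),
        channel_labels=tuple(sidecar["channel_labels"]),
        artifact_mask=mask,
        participant_id=sidecar["participant_id"],
        cohort=sidecar["cohort"],
        state=sidecar["state"],
        meta=sidecar.get("meta", {}),
    )


def _mask_to_intervals(mask: np.ndarray) -> list[list[int]]:
    """Half-open [start, stop) intervals of *unusable* samples."""
    bad = ~np.asarray(mask, dtype=bool)
    if not bad.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
    return [[int(s), int(e)] for s, e in zip(edges[::2], edges[1::2])]


# ---------------------------------------------------------------------------
# EDF reading (MNE); fixture fallback
# ---------------------------------------------------------------------------

def read_edf(
    path: str | Path,
    participant_id: str | None = None,
    cohort: str = "unknown",
    state: str = WAKE,
) -> EEGRecord:
    """Read a 19-channel 10-20 EDF recording into canonical channel order.

    Channels whose labels cannot be mapped onto the 10-20 montage are
    dropped; units are converted to microvolts.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF files requires the 'mne' package") from exc
    path = Path(path)
    if path.suffix.lower() != ".edf":
        raise ValueError(f"expected an .edf file, got {path.name!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    mapping: dict[str, str] = {}
    for name in raw.ch_names:
        try:
            mapping[name] = canonical_label(name)
        except KeyError:
            continue
    present = [c for c in CANONICAL_ORDER if c in mapping.values()]
    inverse = {v: k for k, v in mapping.items()}
    data = np.stack([raw.get_data(picks=[inverse[c]])[0] for c in present])
    data = data * 1e6  # MNE loads volts
    return EEGRecord(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(present),
        artifact_mask=np.ones(data.shape[1], dtype=bool),
        participant_id=participant_id or path.stem,
        cohort=cohort,
        state=state,
    )


def read_recording(path: str | Path, fmt: str | None = None) -> EEGRecord:
    """Read a recording, dispatching on format ('edf' or 'fixture')."""
    path = Path(path)
    if fmt is None:
        fmt = "edf" if path.suffix.lower() == ".edf" else "fixture"
    if fmt == "edf":
        return read_edf(path)
    if fmt == "fixture":
        return read_fixture(path)
    raise ValueError(f"unknown recording format {fmt!r}")
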