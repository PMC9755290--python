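"""Canonical EEG feature set and per-recording extraction.

42 features in five categories:

========== =====================================================
category   features
========== =====================================================
scEntropy  mMSE, LZ, CTW, PermEn8/16/32/64/128
fcEntropy  SRwSMI8..128, LRwSMI8..128
scSpectralA absolute band power: sA, delta1A, delta2A, thetaA,
           alphasigmaA, betaA
scSpectralR the corresponding relative powers (suffix R)
fcSpectral SRdwPLI / LRdwPLI in the six bands
========== =====================================================

Single-channel (SC) measures are later averaged across channels and
functional-connectivity (FC) measures across short-range and long-range
channel pairs; this module emits the per-channel / per-pair-class values
in tidy long format, one row per (recording, feature, channel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import entropy as ent
from .montage import PairClassification
from .preprocess import downsample
from .records import EEGRecord
from .spectral import BandSet, WaveletGrid, band_power, dwpli, morlet_psd

BAND_KEYS = ("s", "delta1", "delta2", "theta", "alphasigma", "beta")
TAU_KEYS = (8, 16, 32, 64, 128)


def canonical_features() -> dict[str, str]:
    """Mapping feature name -> category for the 42 canonical features."""
    feats: dict[str, str] = {}
    for name in ("mMSE", "LZ", "CTW"):
        feats[name] = "scEntropy"
    for tau in TAU_KEYS:
        feats[f"PermEn{tau}"] = "scEntropy"
    for rng in ("SR", "LR"):
        for tau in TAU_KEYS:
            feats[f"{rng}wSMI{tau}"] = "fcEntropy"
    for b in BAND_KEYS:
        feats[f"{b}A"] = "scSpectralA"
    for b in BAND_KEYS:
        feats[f"{b}R"] = "scSpectralR"
    for rng in ("SR", "LR"):
        for b in BAND_KEYS:
            feats[f"{rng}dwPLI_{b}"] = "fcSpectral"
    return feats


FEATURE_CATEGORIES = canonical_features()
CATEGORIES = ("scEntropy", "fcEntropy", "scSpectralA", "scSpectralR",
              "fcSpectral")


@dataclass(frozen=True)
class FeatureProfile:
    """Problem-size controls for feature extraction.

    The default profile computes every feature on every channel and pair.
    The reduced profile limits the costliest estimators to channel subsets
    and subsamples connectivity pairs; single-channel EEG features show low
    spatial variability, so subset means remain good estimates of the
    all-channel mean.
    """

    permen_fs: float = 125.0
    slow_fs: float = 200.0           # analysis rate for mMSE/LZ/CTW
    mmse_channels: tuple[str, ...] | None = None
    mmse_max_segments: int | None = None
    mmse_scales: tuple[int, ...] | None = None
    lzctw_channels: tuple[str, ...] | None = None
    pair_subsample: tuple[int, int] | None = None   # (n_short, n_long)
    pair_seed: int = 12345
    mmse: bool = True
    compute_dwpli: bool = True


REDUCED_PROFILE = FeatureProfile(
    mmse_channels=("Cz",),
    mmse_max_segments=1,
    mmse_scales=tuple(range(1, 11)),
    lzctw_channels=("Fp1", "F4", "Cz", "T5", "O1"),
    pair_subsample=(18, 18),
)


def _channel_indices(record: EEGRecord, subset: tuple[str, ...] | None) -> list[int]:
    if subset is None:
        return list(range(record.n_channels))
    have = {lab: i for i, lab in enumerate(record.channel_labels)}
    return [have[lab] for lab in subset if lab in have]


def extract_features(
    record: EEGRecord,
    pairs: PairClassification,
    profile: FeatureProfile = FeatureProfile(),
    grid: WaveletGrid = WaveletGrid(),
    bands: BandSet = BandSet(),
) -> pd.DataFrame:
    """Compute all canonical features of one (preprocessed) recording.

    Returns a tidy frame with columns ``recording_id, participant_id,
    cohort, state, feature, category, unit, value`` where ``unit`` is a
    channel label for SC features and ``"SR"``/``"LR"`` placeholders are
    already class-averaged for FC features.
    """
    rows: list[dict] = []

    def emit(feature: str, unit: str, value: float) -> None:
        rows.append({
            "recording_id": record.recording_id,
            "participant_id": record.participant_id,
            "cohort": record.cohort,
            "state": record.state,
            "feature": feature,
            "category": FEATURE_CATEGORIES[feature],
            "unit": unit,
            "value": value,
        })

    use_pairs = pairs
    if profile.pair_subsample is not None:
        use_pairs = pairs.subsample(*profile.pair_subsample, profile.pair_seed)

    # --- symbolic measures at 125 Hz -------------------------------------
    rec125 = (record if record.fs == profile.permen_fs
              else downsample(record, profile.permen_fs))
    for tau_ms in TAU_KEYS:
        tau = int(round(tau_ms * rec125.fs / 1000.0))
        if tau < 1 or rec125.n_samples <= 2 * tau:
            for c in record.channel_labels:
                emit(f"PermEn{tau_ms}", c, float("nan"))
            emit(f"SRwSMI{tau_ms}", "SR", float("nan"))
            emit(f"LRwSMI{tau_ms}", "LR", float("nan"))
            continue
        codes = ent.symbolize_batch(rec125.data, 3, tau)
        pe = ent.perm_entropy_windows(
            codes, tau, rec125.fs, rec125.artifact_mask
        )
        for ci, lab in enumerate(rec125.channel_labels):
            emit(f"PermEn{tau_ms}", lab, float(pe[ci]))
        for rng_name, plist in (("SR", use_pairs.short_pairs),
                                ("LR", use_pairs.long_pairs)):
            vals = ent.wsmi_pairs_windows(
                codes, list(plist), tau, rec125.fs, rec125.artifact_mask
            )
            emit(f"{rng_name}wSMI{tau_ms}", rng_name,
                 float(np.nanmean(vals)) if len(vals) else float("nan"))

    # --- slow-rate complexity measures ------------------------------------
    slow_fs = min(profile.slow_fs, record.fs)
    rec_slow = record if record.fs == slow_fs else downsample(record, slow_fs)
    lz_cfg = ent.LZCTWConfig(fs=slow_fs)
    for ci in _channel_indices(rec_slow, profile.lzctw_channels):
        lab = rec_slow.channel_labels[ci]
        x = rec_slow.data[ci]
        emit("LZ", lab, ent.lz76(x, slow_fs, lz_cfg, rec_slow.artifact_mask))
        emit("CTW", lab,
             ent.ctw_entropy_rate(x, slow_fs, lz_cfg, rec_slow.artifact_mask))
    if profile.mmse:
        mmse_cfg = ent.MMSEConfig(fs=slow_fs)
        if profile.mmse_scales is not None:
            mmse_cfg = ent.MMSEConfig(fs=slow_fs,
                                      scales=profile.mmse_scales)
        for ci in _channel_indices(rec_slow, profile.mmse_channels):
            lab = rec_slow.channel_labels[ci]
            x = rec_slow.data[ci]
            m_mask = rec_slow.artifact_mask
            if profile.mmse_max_segments is not None:
                lim = int(profile.mmse_max_segments
                          * mmse_cfg.segment_s * slow_fs)
                x = x[:lim]
                m_mask = m_mask[:lim]
            emit("mMSE", lab, ent.mmse(x, slow_fs, mmse_cfg, m_mask))

    # --- spectral power ----------------------------------------------------
    psd = morlet_psd(record, grid)
    absolute = band_power(psd, grid, bands, relative=False)
    with np.errstate(invalid="ignore"):
        relative = band_power(psd, grid, bands, relative=True) \
            if np.all(np.nansum(absolute, axis=-1) > 0) \
            else np.full_like(absolute, np.nan)
    for ci, lab in enumerate(record.channel_labels):
        for bi, b in enumerate(BAND_KEYS):
            emit(f"{b}A", lab, float(absolute[ci, bi]))
            emit(f"{b}R", lab, float(relative[ci, bi]))

    # --- dwPLI ---------------------------------------------------------------
    if profile.compute_dwpli:
        conn = dwpli(record, use_pairs, grid, bands)
        for bi, b in enumerate(BAND_KEYS):
            emit(f"SRdwPLI_{b}", "SR", float(conn["short"][bi]))
            emit(f"LRdwPLI_{b}", "LR", float(conn["long"][bi]))
    else:
        for b in BAND_KEYS:
            emit(f"SRdwPLI_{b}", "SR", float("nan"))
            emit(f"LRdwPLI_{b}", "LR", float("nan"))

    df = pd.DataFrame(rows)
    df["usable_length_s"] = record.usable_s
    return df
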