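"""Canonical 19-channel 10-20 montage and channel-pair geometry.

The package ships a fixed adult-template set of 3D electrode coordinates
(millimetres) so that channel-pair classification into short-range and
long-range pairs is reproducible across machines and input files.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

#: Canonical channel order for the 19-channel international 10-20 montage,
#: using classic clinical temporal labels (T3/T4/T5/T6).
CANONICAL_ORDER: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Case-insensitive aliases mapping modern/variant labels onto the canonical
#: names (modified combinatorial nomenclature T7 == classic T3, etc.).
LABEL_ALIASES: dict[str, str] = {
    "t7": "T3", "t8": "T4", "p7": "T5", "p8": "T6",
    "fpz1": "Fp1",  # rare vendor quirk
}


def canonical_label(label: str) -> str:
    """Map an electrode label onto the canonical 10-20 name.

    Matching is case-insensitive and strips common reference suffixes such
    as ``-REF`` or ``EEG `` prefixes found in clinical EDF exports.
    """
    lab = label.strip()
    for prefix in ("EEG ", "eeg "):
        if lab.startswith(prefix):
            lab = lab[len(prefix):]
    lab = lab.split("-")[0].strip().lower()
    if lab in LABEL_ALIASES:
        return LABEL_ALIASES[lab]
    for name in CANONICAL_ORDER:
        if lab == name.lower():
            return name
    raise KeyError(f"unrecognized 10-20 channel label: {label!r}")


def template_coordinates() -> pd.DataFrame:
    """Return the shipped adult-template electrode coordinates in mm.

    Indexed by canonical label, columns ``x_mm, y_mm, z_mm`` (RAS-like:
    +x right, +y anterior, +z superior).
    """
    with importlib.resources.files("eegmarkers.data").joinpath(
        "montage_1020.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("label").loc[list(CANONICAL_ORDER)]


@dataclass(frozen=True)
class PairClassification:
    """Partition of unordered channel pairs by scalp Euclidean distance.

    Pairs closer than ``short_min_mm`` are excluded from connectivity
    averages (dominated by volume conduction); pairs in
    ``[short_min_mm, long_min_mm)`` are short-range; pairs at
    ``>= long_min_mm`` are long-range.
    """

    short_min_mm: float = 80.0
    long_min_mm: float = 130.0
    labels: tuple[str, ...] = CANONICAL_ORDER
    short_pairs: tuple[tuple[int, int], ...] = field(init=False)
    long_pairs: tuple[tuple[int, int], ...] = field(init=False)
    excluded_pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        coords = template_coordinates()
        xyz = coords.loc[list(self.labels), ["x_mm", "y_mm", "z_mm"]].to_numpy()
        short, long_, excl = [], [], []
        for i, j in combinations(range(len(self.labels)), 2):
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d < self.short_min_mm:
                excl.append((i, j))
            elif d < self.long_min_mm:
                short.append((i, j))
            else:
                long_.append((i, j))
        object.__setattr__(self, "short_pairs", tuple(short))
        object.__setattr__(self, "long_pairs", tuple(long_))
        object.__setattr__(self, "excluded_pairs", tuple(excl))

    @property
    def n_pairs(self) -> int:
        return len(self.short_pairs) + len(self.long_pairs) + len(self.excluded_pairs)

    def subsample(
        self, n_short: int, n_long: int, seed: int
    ) -> "PairClassification":
        """Return a copy whose short/long pair lists are random subsets.

        Used by reduced analysis profiles to bound the cost of
        connectivity estimation; the excluded class is left intact.
        """
        rng = np.random.default_rng(seed)
        short = self.short_pairs
        long_ = self.long_pairs
        if n_short < len(short):
            idx = rng.choice(len(short), size=n_short, replace=False)
            short = tuple(short[i] for i in sorted(idx))
        if n_long < len(long_):
            idx = rng.choice(len(long_), size=n_long, replace=False)
            long_ = tuple(long_[i] for i in sorted(idx))
        out = object.__new__(PairClassification)
        object.__setattr__(out, "short_min_mm", self.short_min_mm)
        object.__setattr__(out, "long_min_mm", self.long_min_mm)
        object.__setattr__(out, "labels", self.labels)
        object.__setattr__(out, "short_pairs", short)
        object.__setattr__(out, "long_pairs", long_)
        object.__setattr__(out, "excluded_pairs", self.excluded_pairs)
        return out
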