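"""Electrode-array geometry: the 32-channel skull-surface grid.

The packaged default layout emulates a flat 32-electrode grid implanted on
the rodent skull (4 columns x 8 rows, anterior-posterior and medio-lateral
coordinates in mm relative to bregma).  All connectivity analyses key off
pairwise Euclidean distances between electrodes: pairs are split into
"short" and "long" groups at mm thresholds, and channels are grouped into
six regions (left/right x rostral/middle/caudal) for regional averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

N_CHANNELS = 32
N_PAIRS = N_CHANNELS * (N_CHANNELS - 1) // 2  # 496

HEMISPHERES = ("left", "right", "midline")
REGION_CLASSES = ("rostral", "middle", "caudal")

#: channel used for single-channel spectral / SWD analysis (right
#: somatosensory, medial column, middle row of the packaged grid)
DEFAULT_ANALYSIS_CHANNEL = 18

_REQUIRED_COLUMNS = ["id", "label", "ap_mm", "ml_mm", "hemisphere", "region_class"]


@dataclass(frozen=True)
class ElectrodeArray:
    """Validated 32-channel electrode layout.

    ``table`` holds one row per channel with columns
    ``id, label, ap_mm, ml_mm, hemisphere, region_class``, sorted by id.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ValueError(f"layout table missing columns: {missing}")
        if len(t) != N_CHANNELS:
            raise ValueError(f"wrong row count: expected {N_CHANNELS}, got {len(t)}")
        if t["id"].duplicated().any():
            raise ValueError("duplicate channel ids")
        if t[["ap_mm", "ml_mm"]].isna().any().any():
            raise ValueError("missing coordinates")
        if t[["ap_mm", "ml_mm"]].duplicated().any():
            raise ValueError("duplicate coordinate pairs")
        bad_h = set(t["hemisphere"]) - set(HEMISPHERES)
        if bad_h:
            raise ValueError(f"unknown hemisphere labels: {bad_h}")
        bad_r = set(t["region_class"]) - set(REGION_CLASSES)
        if bad_r:
            raise ValueError(f"unknown region classes: {bad_r}")
        object.__setattr__(
            self, "table", t.sort_values("id").reset_index(drop=True)
        )

    @property
    def channel_ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    @property
    def coordinates(self) -> np.ndarray:
        """(32, 2) array of (ap_mm, ml_mm) sorted by channel id."""
        return self.table[["ap_mm", "ml_mm"]].to_numpy(float)

    def region_of(self, channel_id: int) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == channel_id]
        if row.empty:
            raise KeyError(f"unknown channel id {channel_id}")
        return str(row["hemisphere"].iloc[0]), str(row["region_class"].iloc[0])

    def region_groups(self) -> dict[tuple[str, str], list[int]]:
        """Map (hemisphere, region_class) -> sorted channel ids."""
        groups: dict[tuple[str, str], list[int]] = {}
        for _, row in self.table.iterrows():
            groups.setdefault(
                (row["hemisphere"], row["region_class"]), []
            ).append(int(row["id"]))
        return groups


@dataclass(frozen=True)
class PairSet:
    """Unordered channel pairs on one side of a distance threshold.

    Pairs at exactly the threshold distance belong to the short set, so
    short(t) and long(t) always partition the 496 pairs.
    """

    threshold_mm: float
    side: str  # "short" | "long"
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.side not in ("short", "long"):
            raise ValueError("side must be 'short' or 'long'")
        if self.threshold_mm <= 0:
            raise ValueError("threshold must be positive")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(sorted(self.pairs))


def load_array(source=None) -> ElectrodeArray:
    """Load and validate an electrode layout.

    Parameters
    ----------
    source
        CSV path, file-like, or DataFrame with columns
        ``id,label,ap_mm,ml_mm,hemisphere,region_class``.  ``None`` loads
        the packaged default 32-channel grid.
    """
    if source is None:
        with resources.files("eegconn.data").joinpath(
            "default_layout.csv"
        ).open() as fh:
            table = pd.read_csv(fh)
    elif isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source)
    return ElectrodeArray(table)


def pairwise_distances(array: ElectrodeArray) -> np.ndarray:
    """Symmetric 32x32 matrix of Euclidean distances in mm, indexed by id."""
    return squareform(pdist(array.coordinates))


def all_pairs() -> list[tuple[int, int]]:
    """All 496 unordered channel-id pairs, canonical (low, high) order."""
    return list(itertools.combinations(range(N_CHANNELS), 2))


def pairs_by_threshold(
    array: ElectrodeArray, threshold_mm: float, side: str
) -> PairSet:
    """Channel pairs strictly shorter ('short') or longer ('long') than
    ``threshold_mm`` (ties go to short)."""
    if not 1.0 <= threshold_mm <= 14.0:
        raise ValueError(
            f"threshold {threshold_mm} mm outside physical range [1, 14] mm"
        )
    dmat = pairwise_distances(array)
    pairs = []
    for i, j in all_pairs():
        d = dmat[i, j]
        if (d <= threshold_mm) == (side == "short"):
            pairs.append((i, j))
    # side validation happens in PairSet
    return PairSet(threshold_mm, side, frozenset(pairs))


def region_pairs(array: ElectrodeArray) -> list[tuple[tuple[str, str], tuple[str, str]]]:
    """All 15 unordered pairs of distinct (hemisphere, region) groups."""
    groups = array.region_groups()
    expected = [
        (h, r) for h in ("left", "right") for r in REGION_CLASSES
    ]
    empty = [g for g in expected if not groups.get(g)]
    if empty:
        raise ValueError(f"empty region groups: {empty}")
    return list(itertools.combinations(expected, 2))
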