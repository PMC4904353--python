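"""End-to-end composition: recordings → windowed wells → feature tables.

These helpers wire the stages together the way a full study analysis runs:
window each recording to its last 15 minutes, compute the 12-feature vector
per well, stack into a long table keyed by (plate_id, well_id, div), and
aggregate to plate level.  They accept any iterable of
:class:`~meao.spikeio.PlateRecording`, including the lazy generator from
:func:`meao.synth.iter_study`, so a full 62-recording study never needs to be
resident in memory at once.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from meao.features import FEATURE_NAMES, FeatureConfig, plate_features, well_features
from meao.spikeio import PlateRecording, window_last

__all__ = ["well_feature_table", "plate_feature_table", "extract_features"]


def well_feature_table(
    recordings: Iterable[PlateRecording],
    config: FeatureConfig = FeatureConfig(),
    window: float | None = 900.0,
) -> pd.DataFrame:
    """Well-level feature table over an iterable of plate recordings.

    Each recording is first restricted to its last *window* seconds
    (``window=None`` skips windowing).  Returns one row per well with columns
    ``plate_id, well_id, div`` plus the 12 features; missing values are NaN.
    """
    rows = []
    for plate in recordings:
        if window is not None:
            plate = window_last(plate, window)
        for wid in sorted(plate.wells):
            vec = well_features(plate.wells[wid], config)
            rows.append({"plate_id": plate.plate_id, "well_id": wid,
                         "div": plate.div, **vec.to_dict()})
    df = pd.DataFrame(rows, columns=["plate_id", "well_id", "div", *FEATURE_NAMES])
    return df


def plate_feature_table(well_table: pd.DataFrame) -> pd.DataFrame:
    """Plate-level table: per-feature median of nonzero, non-missing well values."""
    return plate_features(well_table)


def extract_features(
    recordings: Iterable[PlateRecording],
    config: FeatureConfig = FeatureConfig(),
    window: float | None = 900.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (well_table, plate_table) in one pass."""
    wt = well_feature_table(recordings, config, window)
    return wt, plate_feature_table(wt)
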