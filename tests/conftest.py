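"""Shared fixtures: hand-built recordings and a small synthetic study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from meao.features import prepare_for_classification
from meao.pipeline import plate_feature_table, well_feature_table
from meao.spikeio import PlateRecording, SpikeTrain, WellRecording
from meao.synth import StudyDesign, iter_study


def make_train(times, interval=(0.0, 60.0)) -> SpikeTrain:
    return SpikeTrain(np.asarray(times, dtype=float), interval)


def make_well(electrode_times: dict[int, list[float]], interval=(0.0, 60.0),
              plate_id="P01", well_id="A1", div=9) -> WellRecording:
    electrodes = {idx: make_train(t, interval) for idx, t in electrode_times.items()}
    return WellRecording(plate_id, well_id, div, electrodes, interval)


def make_plate(wells: dict[str, dict[int, list[float]]], interval=(0.0, 60.0),
               plate_id="P01", div=9) -> PlateRecording:
    return PlateRecording(
        plate_id, div,
        {wid: make_well(elecs, interval, plate_id, wid, div) for wid, elecs in wells.items()},
    )


@pytest.fixture(scope="session")
def mini_study_design() -> StudyDesign:
    """A reduced study: 3 plates × 12 wells × 4 ages, one recording dropped."""
    return StudyDesign(n_plates=3, wells_per_plate=12,
                       dropped_recordings=(("P02", 7),))


@pytest.fixture(scope="session")
def mini_study_tables(mini_study_design):
    """(well_table, plate_table, classification-ready table) of the mini study."""
    well_table = well_feature_table(iter_study(mini_study_design, master_seed=42),
                                    window=None)
    plate_table = plate_feature_table(well_table)
    kept, _, _ = prepare_for_classification(well_table)
    return well_table, plate_table, kept


@pytest.fixture(scope="session")
def gaussian_table() -> pd.DataFrame:
    """Balanced 4-class table with well-separated Gaussian feature clusters."""
    rng = np.random.default_rng(12345)
    rows = []
    for i, div in enumerate((5, 7, 9, 12)):
        X = rng.normal(loc=5.0 * i, scale=0.5, size=(60, 4))
        for x in X:
            rows.append({"div": div, **{f"f{j}": v for j, v in enumerate(x)}})
    return pd.DataFrame(rows)
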