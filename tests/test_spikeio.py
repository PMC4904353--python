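"""Data model, file round-trips, windowing and plate screening."""

from __future__ import annotations

import math

import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meao.spikeio import (
    PlateRecording,
    SpikeDataError,
    SpikeTrain,
    active_electrodes,
    electrode_index,
    electrode_label,
    exclude_outlier_plates,
    load_recording,
    parse_channel_name,
    window_last,
    write_recording,
)
from tests.conftest import make_plate, make_train, make_well


class TestSpikeTrain:
    def test_invariants_enforced(self):
        with pytest.raises(SpikeDataError):
            SpikeTrain(np.array([1.0, 0.5]), (0, 10))  # not increasing
        with pytest.raises(SpikeDataError):
            SpikeTrain(np.array([1.0, 1.0]), (0, 10))  # not strictly increasing
        with pytest.raises(SpikeDataError):
            SpikeTrain(np.array([10.0]), (0, 10))  # outside half-open interval
        with pytest.raises(SpikeDataError):
            SpikeTrain(np.array([]), (5, 5))  # empty interval

    def test_firing_rate(self):
        assert make_train([1, 2, 3], (0, 60)).firing_rate == pytest.approx(0.05)


class TestChannelNames:
    @pytest.mark.parametrize("idx", range(1, 17))
    def test_label_roundtrip(self, idx):
        assert electrode_index(electrode_label(idx)) == idx

    def test_parse(self):
        assert parse_channel_name("A1_11") == ("A1", 1)
        assert parse_channel_name("F8_44") == ("F8", 16)
        with pytest.raises(SpikeDataError):
            parse_channel_name("A1")


class TestRoundTrip:
    @pytest.mark.parametrize("fmt,ext", [("hdf5", "h5"), ("csv", "csv")])
    def test_write_then_load_identical(self, tmp_path, fmt, ext):
        plate = make_plate(
            {"A1": {1: [0.5, 1.0, 2.5], 5: [3.0]}, "B2": {16: [0.1, 59.0]}},
            interval=(0.0, 60.0), plate_id="P07", div=12,
        )
        path = tmp_path / f"plate.{ext}"
        write_recording(plate, path, format=fmt)
        loaded = load_recording(path, format=fmt,
                                **({"interval": (0.0, 60.0)} if fmt == "csv" else {}))
        assert loaded.plate_id == "P07" and loaded.div == 12
        assert set(loaded.wells) == set(plate.wells)
        for wid, well in plate.wells.items():
            assert set(loaded.wells[wid].electrodes) == set(well.electrodes)
            for idx, train in well.electrodes.items():
                np.testing.assert_array_equal(loaded.wells[wid].electrodes[idx].times,
                                              train.times)

    def test_single_channel_hdf5(self, tmp_path):
        path = tmp_path / "one.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=[0.1, 0.2, 0.3])
            f.create_dataset("sCount", data=[3])
            f.create_dataset("names", data=np.array(["A1_11"], dtype=h5py.string_dtype()))
            f.attrs.update(plate_id="P01", div=7, t0=0.0, t1=1.0)
        plate = load_recording(path)
        assert len(plate.wells) == 1
        assert plate.wells["A1"].electrodes[1].n_spikes == 3

    def test_unsorted_csv_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "plate_id,div,well,electrode,time_s\nP01,5,A1,1,2.0\nP01,5,A1,1,1.0\n"
        )
        with pytest.raises(SpikeDataError, match="not strictly increasing"):
            load_recording(path, format="csv")

    def test_malformed_hdf5_names_missing(self, tmp_path):
        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=[0.1])
            f.create_dataset("sCount", data=[1])
        with pytest.raises(SpikeDataError, match="names"):
            load_recording(path)


class TestWindowLast:
    def _plate(self, times, interval=(0.0, 1800.0)):
        return make_plate({"A1": {1: times}}, interval=interval)

    def test_only_last_spikes_survive(self):
        plate = self._plate([100.0, 1000.0])
        out = window_last(plate, 900.0)
        np.testing.assert_allclose(out.wells["A1"].electrodes[1].times, [100.0])  # 1000-900
        assert out.interval == (0.0, 900.0)

    def test_retained_spikes_were_late(self):
        times = np.linspace(1.0, 1799.0, 100)
        out = window_last(self._plate(list(times)), 900.0)
        shifted = out.wells["A1"].electrodes[1].times + 900.0
        assert np.all(shifted >= 900.0)
        np.testing.assert_allclose(shifted, times[times >= 900.0])

    def test_exact_window_is_identity_on_counts(self):
        plate = self._plate([1.0, 500.0, 899.0], interval=(0.0, 900.0))
        out = window_last(plate, 900.0)
        assert out.n_spikes == plate.n_spikes

    def test_duration_longer_than_recording_warns_and_keeps_all(self):
        plate = self._plate([1.0, 500.0], interval=(0.0, 600.0))
        with pytest.warns(UserWarning, match="exceeds recording length"):
            out = window_last(plate, 900.0)
        assert out.n_spikes == 2
        assert out.interval == (0.0, 600.0)

    @given(st.lists(st.floats(min_value=0.0, max_value=1799.0), max_size=40),
           st.floats(min_value=10.0, max_value=1800.0))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_contractive(self, raw, duration):
        times = np.unique(np.round(np.asarray(raw), 6))
        plate = self._plate(list(times), interval=(0.0, 1800.0))
        once = window_last(plate, duration)
        twice = window_last(once, duration)
        assert once.n_spikes <= plate.n_spikes
        np.testing.assert_array_equal(
            once.wells["A1"].electrodes[1].times, twice.wells["A1"].electrodes[1].times
        )


class TestActiveElectrodes:
    def test_threshold(self):
        well = make_well({1: [], 2: [], 3: [1.0, 2.0, 3.0, 4.0, 5.0]})
        assert active_electrodes(well) == {3}
        assert active_electrodes(well, min_spikes=10) == set()
        well9 = make_well({1: list(np.arange(1, 10, dtype=float))})
        assert active_electrodes(well9, min_spikes=10) == set()
        assert active_electrodes(well9, min_spikes=9) == {1}

    def test_silent_well_empty(self):
        assert active_electrodes(make_well({1: [], 2: []})) == set()


class TestOutlierScreen:
    def _plates(self, n, div=7):
        return [make_plate({"A1": {1: [1.0]}}, plate_id=f"P{i:02d}", div=div)
                for i in range(n)]

    def test_high_mfr_plate_excluded(self):
        plates = self._plates(4)
        mfr = {(p.plate_id, p.div): r for p, r in zip(plates, [0.5, 0.6, 0.7, 3.0])}
        screen = exclude_outlier_plates(plates, k=2.0, mfr=mfr)
        assert [p.plate_id for p in screen.excluded] == ["P03"]  # 3.0 > 0.6 + 2*0.1
        assert len(screen.kept) == 3
        assert ("P03", 7) in screen.reasons

    def test_identical_mfrs_none_excluded(self):
        plates = self._plates(4)
        mfr = {(p.plate_id, p.div): 0.5 for p in plates}
        screen = exclude_outlier_plates(plates, mfr=mfr)
        assert not screen.excluded

    def test_infinite_k_none_excluded(self):
        plates = self._plates(4)
        mfr = {(p.plate_id, p.div): r for p, r in zip(plates, [0.5, 0.6, 0.7, 3.0])}
        screen = exclude_outlier_plates(plates, k=math.inf, mfr=mfr)
        assert not screen.excluded

    def test_small_group_skipped_with_warning(self):
        plates = self._plates(2)
        mfr = {(p.plate_id, p.div): r for p, r in zip(plates, [0.1, 100.0])}
        with pytest.warns(UserWarning, match="outlier screen skipped"):
            screen = exclude_outlier_plates(plates, mfr=mfr)
        assert not screen.excluded and len(screen.kept) == 2
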