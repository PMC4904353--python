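"""Data model and I/O for multiwell MEA spike-time recordings.

The hierarchy is plate → well → electrode.  A plate carries up to 48 wells
(named ``A1`` … ``F8``), each with up to 16 electrodes.  Electrodes are
indexed 1..16 and also carry an Axion-style row-column label ``11`` … ``44``
(row-major: electrode ``e`` ↦ label ``f"{(e-1)//4+1}{(e-1)%4+1}"``), so a
channel is written ``"A1_11"``.

All times are seconds (float64) and every recording interval is half-open
``[t0, t1)``.  Missing statistics elsewhere in the package are encoded as NaN.

On-disk formats
---------------
HDF5 dialect (one plate recording per file):
    ``/spikes``  concatenated per-channel spike times (seconds)
    ``/sCount``  spikes per channel (same channel order as ``/names``)
    ``/names``   channel name strings ``"<well>_<electrode-label>"``
    root attributes ``plate_id`` (str), ``div`` (int), ``t0``, ``t1`` (float)

CSV long format: columns ``plate_id, div, well, electrode, time_s`` with one
row per spike; ``electrode`` is the 1..16 index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "WellRecording",
    "PlateRecording",
    "WELL_IDS",
    "electrode_label",
    "electrode_index",
    "parse_channel_name",
    "load_recording",
    "write_recording",
    "window_last",
    "active_electrodes",
    "exclude_outlier_plates",
    "plate_mean_firing_rate",
]

#: The 48 well names of a 6-row × 8-column plate, row-major.
WELL_IDS: tuple[str, ...] = tuple(f"{r}{c}" for r in "ABCDEF" for c in range(1, 9))


class SpikeDataError(ValueError):
    """Raised when a file or object violates the spike-data contracts."""


def electrode_label(index: int) -> str:
    """Axion-style row-column label for electrode *index* (1..16)."""
    if not 1 <= index <= 16:
        raise ValueError(f"electrode index must be in 1..16, got {index}")
    r, c = divmod(index - 1, 4)
    return f"{r + 1}{c + 1}"


def electrode_index(label: str) -> int:
    """Inverse of :func:`electrode_label`; also accepts a plain 1..16 integer string."""
    if len(label) == 2 and label.isdigit() and "1" <= label[0] <= "4" and "1" <= label[1] <= "4":
        return (int(label[0]) - 1) * 4 + int(label[1])
    idx = int(label)
    if not 1 <= idx <= 16:
        raise SpikeDataError(f"cannot parse electrode label {label!r}")
    return idx


def parse_channel_name(name: str) -> tuple[str, int]:
    """Split ``"A1_11"`` into ``("A1", 1)``."""
    try:
        well, elec = name.rsplit("_", 1)
    except ValueError as exc:
        raise SpikeDataError(f"channel name {name!r} is not '<well>_<electrode>'") from exc
    return well, electrode_index(elec)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (s) on one electrode within a half-open interval."""

    times: np.ndarray
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        t0, t1 = self.interval
        if not t1 > t0:
            raise SpikeDataError(f"interval must satisfy t1 > t0, got [{t0}, {t1})")
        if times.ndim != 1:
            raise SpikeDataError("spike times must be a 1-d array")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise SpikeDataError("spike times must be strictly increasing")
            if times[0] < t0 or times[-1] >= t1:
                raise SpikeDataError(
                    f"spike times must lie in [{t0}, {t1}); "
                    f"got range [{times[0]}, {times[-1]}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def firing_rate(self) -> float:
        """Mean firing rate in Hz over the recording interval."""
        return self.n_spikes / self.duration


@dataclass(frozen=True)
class WellRecording:
    """All electrodes of one well at one recording age (DIV)."""

    plate_id: str
    well_id: str
    div: int
    electrodes: Mapping[int, SpikeTrain]
    interval: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.electrodes) > 16:
            raise SpikeDataError(f"well {self.well_id}: more than 16 electrodes")
        for idx, train in self.electrodes.items():
            if not 1 <= idx <= 16:
                raise SpikeDataError(f"well {self.well_id}: electrode index {idx} out of 1..16")
            if train.interval != self.interval:
                raise SpikeDataError(
                    f"well {self.well_id} electrode {idx}: interval {train.interval} "
                    f"differs from well interval {self.interval}"
                )

    @property
    def duration(self) -> float:
        return self.interval[1] - self.interval[0]

    @property
    def n_spikes(self) -> int:
        return sum(t.n_spikes for t in self.electrodes.values())


@dataclass(frozen=True)
class PlateRecording:
    """One plate at one recording age: a mapping well_id → WellRecording."""

    plate_id: str
    div: int
    wells: Mapping[str, WellRecording]

    def __post_init__(self) -> None:
        if len(self.wells) > 48:
            raise SpikeDataError(f"plate {self.plate_id}: more than 48 wells")
        intervals = {w.interval for w in self.wells.values()}
        if len(intervals) > 1:
            raise SpikeDataError(f"plate {self.plate_id}: wells disagree on interval")
        for wid, well in self.wells.items():
            if well.div != self.div:
                raise SpikeDataError(f"plate {self.plate_id} well {wid}: div mismatch")

    @property
    def interval(self) -> tuple[float, float]:
        if not self.wells:
            raise SpikeDataError(f"plate {self.plate_id} has no wells")
        return next(iter(self.wells.values())).interval

    @property
    def n_spikes(self) -> int:
        return sum(w.n_spikes for w in self.wells.values())

    def channels(self) -> Iterable[tuple[str, int, SpikeTrain]]:
        """Yield (well_id, electrode_index, train) in deterministic order."""
        for wid in sorted(self.wells):
            well = self.wells[wid]
            for idx in sorted(well.electrodes):
                yield wid, idx, well.electrodes[idx]


# ---------------------------------------------------------------------------
# readers / writers


def _assemble_plate(
    plate_id: str,
    div: int,
    interval: tuple[float, float],
    channels: Mapping[tuple[str, int], np.ndarray],
) -> PlateRecording:
    by_well: dict[str, dict[int, SpikeTrain]] = {}
    for (well_id, elec), times in channels.items():
        by_well.setdefault(well_id, {})[elec] = SpikeTrain(times, interval)
    wells = {
        wid: WellRecording(plate_id, wid, div, elecs, interval)
        for wid, elecs in by_well.items()
    }
    return PlateRecording(plate_id, div, wells)


def write_recording(plate: PlateRecording, path: str | Path, format: str = "hdf5") -> None:
    """Write a plate recording in the HDF5 dialect or the long CSV format."""
    path = Path(path)
    if format == "hdf5":
        names, counts, chunks = [], [], []
        for wid, idx, train in plate.channels():
            names.append(f"{wid}_{electrode_label(idx)}")
            counts.append(train.n_spikes)
            chunks.append(train.times)
        spikes = np.concatenate(chunks) if chunks else np.empty(0)
        t0, t1 = plate.interval
        with h5py.File(path, "w") as f:
            f.create_dataset("spikes", data=spikes)
            f.create_dataset("sCount", data=np.asarray(counts, dtype=np.int64))
            f.create_dataset("names", data=np.array(names, dtype=h5py.string_dtype()))
            f.attrs["plate_id"] = plate.plate_id
            f.attrs["div"] = int(plate.div)
            f.attrs["t0"] = float(t0)
            f.attrs["t1"] = float(t1)
    elif format == "csv":
        rows = []
        for wid, idx, train in plate.channels():
            for t in train.times:
                rows.append((plate.plate_id, plate.div, wid, idx, t))
        df = pd.DataFrame(rows, columns=["plate_id", "div", "well", "electrode", "time_s"])
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def load_recording(
    path: str | Path,
    format: str = "hdf5",
    interval: tuple[float, float] | None = None,
) -> PlateRecording:
    """Load a plate recording.

    ``format="hdf5"`` reads the documented dialect; missing ``t0``/``t1``
    attributes (as in externally produced files) fall back to
    ``[0, ceil(max spike time))``.  ``format="csv"`` reads the long table; the
    *interval* argument overrides the inferred window.  Unsorted spike times
    raise :class:`SpikeDataError` naming the offending channel.
    """
    path = Path(path)
    if format == "hdf5":
        return _load_hdf5(path)
    if format == "csv":
        return _load_csv(path, interval)
    raise ValueError(f"unknown format {format!r}")


def _load_hdf5(path: Path) -> PlateRecording:
    with h5py.File(path, "r") as f:
        for key in ("spikes", "sCount", "names"):
            if key not in f:
                raise SpikeDataError(f"{path}: missing required dataset '/{key}'")
        spikes = np.asarray(f["spikes"], dtype=float).ravel()
        counts = np.asarray(f["sCount"], dtype=np.int64).ravel()
        raw_names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["names"][()]]
        attrs = dict(f.attrs)
    if counts.sum() != spikes.size:
        raise SpikeDataError(f"{path}: sCount sums to {counts.sum()} but /spikes has {spikes.size}")
    if len(raw_names) != counts.size:
        raise SpikeDataError(f"{path}: {len(raw_names)} names for {counts.size} counts")
    plate_id = str(attrs.get("plate_id", path.stem))
    div = int(attrs.get("div", 0))
    t0 = float(attrs.get("t0", 0.0))
    if "t1" in attrs:
        t1 = float(attrs["t1"])
    else:
        t1 = float(np.ceil(spikes.max())) + 1.0 if spikes.size else 1.0
    channels: dict[tuple[str, int], np.ndarray] = {}
    offsets = np.concatenate([[0], np.cumsum(counts)])
    for i, name in enumerate(raw_names):
        well, elec = parse_channel_name(name)
        times = spikes[offsets[i]: offsets[i + 1]]
        if times.size and np.any(np.diff(times) <= 0):
            raise SpikeDataError(f"{path}: channel {name}: spike times not strictly increasing")
        channels[(well, elec)] = times
    return _assemble_plate(plate_id, div, (t0, t1), channels)


def _load_csv(path: Path, interval: tuple[float, float] | None) -> PlateRecording:
    df = pd.read_csv(path)
    required = {"plate_id", "div", "well", "electrode", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise SpikeDataError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise SpikeDataError(f"{path}: no spike rows")
    plate_ids = df["plate_id"].unique()
    divs = df["div"].unique()
    if len(plate_ids) > 1 or len(divs) > 1:
        raise SpikeDataError(f"{path}: expected a single (plate_id, div); got {plate_ids}, {divs}")
    if interval is None:
        tmax = float(df["time_s"].max())
        interval = (0.0, float(np.ceil(tmax)) + 1.0)
    channels: dict[tuple[str, int], np.ndarray] = {}
    for (well, elec), grp in df.groupby(["well", "electrode"], sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise SpikeDataError(
                f"{path}: well {well} electrode {elec}: spike times not strictly increasing"
            )
        channels[(str(well), int(elec))] = times
    return _assemble_plate(str(plate_ids[0]), int(divs[0]), interval, channels)


# ---------------------------------------------------------------------------
# windowing and screening


def _window_train(train: SpikeTrain, start: float, duration: float) -> SpikeTrain:
    keep = train.times[(train.times >= start) & (train.times < start + duration)]
    return SpikeTrain(keep - start, (0.0, duration))


def window_last(plate: PlateRecording, duration: float = 900.0) -> PlateRecording:
    """Restrict to the last *duration* seconds and re-zero time.

    The new interval is ``[t1 - duration, t1)`` expressed as ``[0, duration)``.
    If the recording is shorter than *duration* the full recording is kept
    (re-zeroed to ``[0, original length)``) and a warning is emitted.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t0, t1 = plate.interval
    if duration > t1 - t0:
        warnings.warn(
            f"plate {plate.plate_id}: requested window {duration} s exceeds recording "
            f"length {t1 - t0} s; keeping the full recording",
            stacklevel=2,
        )
        duration = t1 - t0
    start = t1 - duration
    wells = {
        wid: WellRecording(
            plate.plate_id,
            wid,
            plate.div,
            {idx: _window_train(tr, start, duration) for idx, tr in well.electrodes.items()},
            (0.0, duration),
        )
        for wid, well in plate.wells.items()
    }
    return PlateRecording(plate.plate_id, plate.div, wells)


def active_electrodes(well: WellRecording, min_spikes: int = 1) -> set[int]:
    """Electrode indices with at least *min_spikes* spikes in the window.

    "Active" has no universal definition for developing cultures; the default
    (≥1 spike over the window) imposes no activity threshold.  A common
    stricter alternative is ≥5 spikes/min, i.e. ``min_spikes=75`` for a
    15-minute window.
    """
    return {idx for idx, tr in well.electrodes.items() if tr.n_spikes >= min_spikes}


def plate_mean_firing_rate(plate: PlateRecording) -> float:
    """Plate MFR in Hz: mean of per-electrode firing rates over all electrodes."""
    rates = [tr.firing_rate for _, _, tr in plate.channels()]
    return float(np.mean(rates)) if rates else 0.0


@dataclass(frozen=True)
class OutlierScreen:
    """Result of the per-DIV plate MFR outlier screen."""

    kept: list[PlateRecording]
    excluded: list[PlateRecording]
    reasons: dict[tuple[str, int], str] = field(default_factory=dict)


def exclude_outlier_plates(
    recordings: Sequence[PlateRecording],
    k: float = 2.0,
    mfr: Mapping[tuple[str, int], float] | None = None,
) -> OutlierScreen:
    """Screen plate recordings whose MFR is an outlier within their DIV group.

    Within each DIV group, a recording is excluded when its plate MFR exceeds
    ``mean + k·SD`` of the *other* recordings in the group (leave-one-out
    baseline, strict ``>``).  Groups with fewer than three recordings are not
    screened (a warning is emitted).  Precomputed MFRs may be supplied as a
    mapping ``(plate_id, div) → Hz``.
    """
    rates = {
        (p.plate_id, p.div): (mfr[(p.plate_id, p.div)] if mfr is not None else plate_mean_firing_rate(p))
        for p in recordings
    }
    by_div: dict[int, list[PlateRecording]] = {}
    for p in recordings:
        by_div.setdefault(p.div, []).append(p)

    kept: list[PlateRecording] = []
    excluded: list[PlateRecording] = []
    reasons: dict[tuple[str, int], str] = {}
    for div, group in sorted(by_div.items()):
        if len(group) < 3:
            warnings.warn(f"DIV {div}: only {len(group)} recording(s); outlier screen skipped",
                          stacklevel=2)
            kept.extend(group)
            continue
        for p in group:
            others = [rates[(q.plate_id, q.div)] for q in group if q is not p]
            mu = float(np.mean(others))
            sd = float(np.std(others, ddof=1))
            r = rates[(p.plate_id, p.div)]
            if np.isfinite(sd) and r > mu + k * sd:
                excluded.append(p)
                reasons[(p.plate_id, p.div)] = (
                    f"MFR {r:.3g} Hz > {mu:.3g} + {k:g}·{sd:.3g} Hz of other DIV {div} plates"
                )
            else:
                kept.append(p)
    return OutlierScreen(kept=kept, excluded=excluded, reasons=reasons)
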