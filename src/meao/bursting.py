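"""MaxInterval burst detection and per-electrode burst statistics.

The detector is the three-phase MaxInterval scheme popularised by
Neuroexplorer.  Phase 1 scans interspike intervals (ISIs): a candidate burst
opens at spike *i* when ISI(i, i+1) ≤ ``max_begin_isi`` and extends while the
following ISIs stay ≤ ``max_isi``.  Phase 2 merges consecutive candidates
whose gap (last spike of one to first spike of the next) is < ``min_ibi``.
Phase 3 discards candidates shorter than ``min_duration`` or with fewer than
``min_spikes`` spikes.  The default parameters are the values conventional
for developing cortical cultures: 0.25 s max ISI, 0.1 s max beginning ISI,
0.8 s min IBI, 0.05 s min duration, 6 spikes minimum.

``merge_order`` selects whether Phase 2 runs before Phase 3
(``"merge_then_filter"``, the Neuroexplorer convention and the default) or
after (``"filter_then_merge"``).

Statistics use the sample SD (n−1 denominator) in all coefficients of
variation; undefined statistics are NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from meao.spikeio import SpikeTrain

__all__ = [
    "BurstParams",
    "Burst",
    "ElectrodeBurstStats",
    "detect_bursts",
    "burst_statistics",
    "is_bursting_electrode",
]


@dataclass(frozen=True)
class BurstParams:
    """MaxInterval thresholds (all times in seconds)."""

    max_isi: float = 0.25
    max_begin_isi: float = 0.1
    min_ibi: float = 0.8
    min_duration: float = 0.05
    min_spikes: int = 6
    merge_order: Literal["merge_then_filter", "filter_then_merge"] = "merge_then_filter"

    def __post_init__(self) -> None:
        if min(self.max_isi, self.max_begin_isi, self.min_ibi, self.min_duration) <= 0:
            raise ValueError("all burst time parameters must be positive")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be ≥ 1")
        if self.max_begin_isi > self.max_isi:
            raise ValueError("max_begin_isi must be ≤ max_isi")


@dataclass(frozen=True)
class Burst:
    """A detected burst: spike-index range [first, last] (inclusive) into the train."""

    start: float
    end: float
    n_spikes: int
    spike_index_range: tuple[int, int]

    @property
    def duration(self) -> float:
        return self.end - self.start


def _candidate_bursts(times: np.ndarray, params: BurstParams) -> list[tuple[int, int]]:
    """Phase 1: candidate (first, last) spike-index pairs, in order.

    A candidate opens at the left spike of the first ISI ≤ max_begin_isi not
    already inside a candidate, and runs while ISIs stay ≤ max_isi.  Within a
    maximal run of ISIs ≤ max_isi this yields one candidate, spanning from the
    first qualifying beginning ISI to the end of the run.
    """
    isi = np.diff(times)
    ext = isi <= params.max_isi
    beg = isi <= params.max_begin_isi
    candidates: list[tuple[int, int]] = []
    if not ext.any():
        return candidates
    # boundaries of maximal True-runs in ext
    padded = np.concatenate([[False], ext, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # one past last True
    for s, e in zip(starts, ends):
        open_at = np.flatnonzero(beg[s:e])
        if open_at.size:
            first = int(s + open_at[0])
            candidates.append((first, int(e)))  # spikes first..e inclusive
    return candidates


def _merge(cands: list[tuple[int, int]], times: np.ndarray, min_ibi: float) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for first, last in cands:
        if merged and times[first] - times[merged[-1][1]] < min_ibi:
            merged[-1] = (merged[-1][0], last)
        else:
            merged.append((first, last))
    return merged


def _filter(cands: list[tuple[int, int]], times: np.ndarray, params: BurstParams) -> list[tuple[int, int]]:
    return [
        (f, l)
        for f, l in cands
        if (l - f + 1) >= params.min_spikes and (times[l] - times[f]) >= params.min_duration
    ]


def detect_bursts(train: SpikeTrain, params: BurstParams = BurstParams()) -> list[Burst]:
    """Detect bursts on one electrode with the three-phase MaxInterval scheme.

    Returns disjoint bursts in temporal order; fewer than two spikes yield an
    empty list.  After merging, internal gaps may exceed ``max_isi`` but are
    always < ``min_ibi``.
    """
    times = train.times
    if times.size < 2:
        return []
    cands = _candidate_bursts(times, params)
    if params.merge_order == "merge_then_filter":
        cands = _filter(_merge(cands, times, params.min_ibi), times, params)
    elif params.merge_order == "filter_then_merge":
        cands = _merge(_filter(cands, times, params), times, params.min_ibi)
    else:
        raise ValueError(f"unknown merge_order {params.merge_order!r}")
    return [
        Burst(start=float(times[f]), end=float(times[l]), n_spikes=l - f + 1,
              spike_index_range=(f, l))
        for f, l in cands
    ]


@dataclass(frozen=True)
class ElectrodeBurstStats:
    """Per-electrode burst statistics; undefined values are NaN.

    ``burst_rate`` bursts/min; ``mean_duration`` s; ``within_burst_fr`` Hz
    (mean over bursts of spike count / duration); ``pct_spikes_in_bursts`` %;
    ``cv_ibi`` and ``cv_within_isi`` dimensionless sample-SD/mean ratios.
    """

    burst_rate: float
    mean_duration: float
    within_burst_fr: float
    pct_spikes_in_bursts: float
    cv_ibi: float
    cv_within_isi: float


def _cv(values: np.ndarray) -> float:
    """Sample coefficient of variation; NaN when fewer than two values or zero mean."""
    if values.size < 2:
        return math.nan
    mean = float(np.mean(values))
    if mean == 0:
        return math.nan
    return float(np.std(values, ddof=1) / mean)


def burst_statistics(train: SpikeTrain, bursts: Sequence[Burst]) -> ElectrodeBurstStats:
    """Summarise the bursts of one electrode.

    ``burst_rate`` is always defined.  Duration and within-burst rate need at
    least one burst; the IBI CV needs ≥2 gaps (i.e. ≥3 bursts); the
    within-burst ISI CV needs ≥2 within-burst ISIs.  ``pct_spikes_in_bursts``
    is defined whenever the train has spikes.
    """
    minutes = train.duration / 60.0
    n = len(bursts)
    burst_rate = n / minutes

    if n:
        durations = np.array([b.duration for b in bursts])
        mean_duration = float(durations.mean())
        within_burst_fr = float(np.mean([b.n_spikes / b.duration for b in bursts]))
    else:
        mean_duration = math.nan
        within_burst_fr = math.nan

    if train.n_spikes:
        in_bursts = sum(b.n_spikes for b in bursts)
        pct = 100.0 * in_bursts / train.n_spikes
    else:
        pct = math.nan

    gaps = np.array([bursts[i + 1].start - bursts[i].end for i in range(n - 1)]) if n >= 2 else np.empty(0)
    cv_ibi = _cv(gaps)

    within_isis: list[np.ndarray] = []
    for b in bursts:
        f, l = b.spike_index_range
        within_isis.append(np.diff(train.times[f:l + 1]))
    cv_within = _cv(np.concatenate(within_isis)) if within_isis else math.nan

    return ElectrodeBurstStats(
        burst_rate=burst_rate,
        mean_duration=mean_duration,
        within_burst_fr=within_burst_fr,
        pct_spikes_in_bursts=pct,
        cv_ibi=cv_ibi,
        cv_within_isi=cv_within,
    )


def is_bursting_electrode(stats: ElectrodeBurstStats, threshold: float = 1.0) -> bool:
    """True when the electrode bursts at least *threshold* times per minute (inclusive)."""
    return stats.burst_rate >= threshold
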