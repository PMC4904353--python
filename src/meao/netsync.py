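"""Network-spike detection and the spike-time tiling coefficient (STTC).

Network spikes are brief epochs in which many electrodes of a well fire
together: the window is divided into small half-open bins (default 3 ms,
anchored at the window start) and each bin counted for the number of distinct
electrodes with ≥1 spike; a network spike is a maximal run of consecutive
bins whose count reaches a threshold (default 5 electrodes, inclusive by
default; ``strict_gt=True`` requires counts strictly above the threshold).

The STTC of two trains A, B on interval [t0, t1) with half-width Δt is

    STTC = ½ [ (P_A − T_B) / (1 − P_A·T_B) + (P_B − T_A) / (1 − P_B·T_A) ]

where P_A is the proportion of A's spikes lying within ±Δt of a spike of B,
and T_A is the fraction of [t0, t1) covered by the union of ±Δt windows
around A's spikes (clipped at the interval boundaries).  A degenerate
denominator (P·T = 1) contributes 0 for that term.  The coefficient is
symmetric, lies in [−1, 1], and is insensitive to firing rate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from meao.spikeio import SpikeTrain, WellRecording, active_electrodes

__all__ = [
    "NetworkSpike",
    "SttcConfig",
    "detect_network_spikes",
    "network_spike_features",
    "sttc",
    "mean_pairwise_sttc",
    "tiling_fraction",
]


@dataclass(frozen=True)
class NetworkSpike:
    """A maximal run of supra-threshold bins: [onset, offset) with peak electrode count."""

    onset: float
    offset: float
    peak_electrodes: int

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def detect_network_spikes(
    well: WellRecording,
    bin_width: float = 0.003,
    threshold: int = 5,
    strict_gt: bool = False,
) -> list[NetworkSpike]:
    """Detect network spikes in one well.

    Bins are ``[t0 + k·w, t0 + (k+1)·w)``; a spike on a bin edge belongs to
    the right bin.  Counts are distinct electrodes per bin.  Runs of bins with
    count ≥ *threshold* (or > with ``strict_gt``) become events; onset/offset
    are the run's outer bin edges and the peak is the maximum per-bin count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if threshold < 1:
        raise ValueError("threshold must be ≥ 1")
    t0, t1 = well.interval
    n_bins = int(math.ceil((t1 - t0) / bin_width))
    if not well.electrodes or n_bins == 0:
        return []

    # distinct (electrode, bin) pairs → per-bin electrode counts
    keys: list[np.ndarray] = []
    for idx, train in well.electrodes.items():
        if train.n_spikes == 0:
            continue
        bins = np.unique(((train.times - t0) / bin_width).astype(np.int64))
        bins = bins[bins < n_bins]  # guard float edge at t1
        keys.append(bins)
    if not keys:
        return []
    counts = np.zeros(n_bins, dtype=np.int32)
    for bins in keys:
        counts[bins] += 1

    supra = counts > threshold if strict_gt else counts >= threshold
    if not supra.any():
        return []
    padded = np.concatenate([[False], supra, [False]])
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])
    return [
        NetworkSpike(
            onset=t0 + s * bin_width,
            offset=t0 + e * bin_width,
            peak_electrodes=int(counts[s:e].max()),
        )
        for s, e in zip(starts, ends)
    ]


def network_spike_features(
    events: list[NetworkSpike], window_minutes: float
) -> tuple[float, float, float]:
    """(rate per minute, median duration s, median peak count).

    The rate is 0 when there are no events; the medians are then NaN.
    """
    if window_minutes <= 0:
        raise ValueError("window_minutes must be positive")
    if not events:
        return 0.0, math.nan, math.nan
    rate = len(events) / window_minutes
    durations = np.array([e.duration for e in events])
    peaks = np.array([e.peak_electrodes for e in events])
    return float(rate), float(np.median(durations)), float(np.median(peaks))


@dataclass(frozen=True)
class SttcConfig:
    """STTC configuration: half-width ``dt`` (s) and the recording interval."""

    dt: float = 0.05
    interval: tuple[float, float] = (0.0, 900.0)

    def __post_init__(self) -> None:
        t0, t1 = self.interval
        if not 0 < self.dt < (t1 - t0) / 2:
            raise ValueError(f"dt must satisfy 0 < dt < (t1−t0)/2, got {self.dt}")


def tiling_fraction(times: np.ndarray, dt: float, interval: tuple[float, float]) -> float:
    """Fraction of [t0, t1) covered by the union of ±dt windows around *times*.

    Overlapping windows are counted once and windows are clipped at the
    interval boundaries.
    """
    if times.size == 0:
        return 0.0
    t0, t1 = interval
    lo = np.clip(times - dt, t0, t1)
    hi = np.clip(times + dt, t0, t1)
    # sorted times ⇒ union length = Σ (hi_i − max(lo_i, hi_{i−1}))
    lo[1:] = np.maximum(lo[1:], hi[:-1])
    return float(np.sum(hi - lo) / (t1 - t0))


def _proportion_near(a: np.ndarray, b: np.ndarray, dt: float) -> float:
    """Proportion of spikes in *a* lying within ±dt of some spike in *b*."""
    left = np.searchsorted(b, a - dt, side="left")
    right = np.searchsorted(b, a + dt, side="right")
    return float(np.mean(right > left))


def sttc(a: SpikeTrain, b: SpikeTrain, cfg: SttcConfig) -> float:
    """Spike-time tiling coefficient of two trains; NaN if either is empty."""
    if a.n_spikes == 0 or b.n_spikes == 0:
        return math.nan
    dt = cfg.dt
    pa = _proportion_near(a.times, b.times, dt)
    pb = _proportion_near(b.times, a.times, dt)
    ta = tiling_fraction(a.times, dt, cfg.interval)
    tb = tiling_fraction(b.times, dt, cfg.interval)

    def term(p: float, t: float) -> float:
        denom = 1.0 - p * t
        return (p - t) / denom if denom != 0.0 else 0.0

    return 0.5 * (term(pa, tb) + term(pb, ta))


def mean_pairwise_sttc(
    well: WellRecording,
    cfg: SttcConfig | None = None,
    min_spikes: int = 1,
) -> float:
    """Mean STTC over all unordered pairs of active electrodes in a well.

    Pairs with an undefined STTC are skipped; NaN when fewer than two active
    electrodes or when every pair is undefined.
    """
    if cfg is None:
        cfg = SttcConfig(interval=well.interval)
    active = sorted(active_electrodes(well, min_spikes=min_spikes))
    if len(active) < 2:
        return math.nan
    values = [
        sttc(well.electrodes[i], well.electrodes[j], cfg)
        for i, j in itertools.combinations(active, 2)
    ]
    values = [v for v in values if not math.isnan(v)]
    return float(np.mean(values)) if values else math.nan
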