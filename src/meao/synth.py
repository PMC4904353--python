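"""Synthetic multiwell MEA spike-train generator with age-dependent structure.

The generator emulates the statistical shape of a developmental study on
48-well plates: 16 plates, 48 wells of 16 electrodes, recorded at DIV 5, 7,
9 and 12 over a 15-minute window, with two recordings dropped so the default
study yields 62 plate recordings and 2976 well recordings.

Each electrode superposes three point processes:

* tonic firing — homogeneous Poisson at ``electrode_rate``;
* bursting — a renewal process of burst onsets with gamma-distributed
  inter-burst intervals (CV ``ibi_cv``), each burst emitting roughly
  ``burst_n_spikes`` spikes at ``within_burst_isi`` spacing with
  multiplicative jitter (gamma ISIs with CV ``within_burst_isi_jitter``);
* network events — well-level Poisson events at ``network_event_rate``; each
  event recruits a random subset of the well's live electrodes (binomial with
  success probability ``network_participation``); a recruited electrode fires
  a first spike at a short exponential latency (mean 2 ms) after the event
  onset — the tight alignment characteristic of network spikes — plus
  0–few extra spikes spread over a 10 ms envelope.

Rates are modulated by hierarchical log-normal multipliers: one per plate
(SD ``plate_heterogeneity`` on the log scale, shared across the plate's four
ages — plates are repeated measures) and one per well (SD
``well_heterogeneity``, persistent across ages of the same well).  Each
electrode is dead/silent with probability ``p_silent_electrode``.

The per-age default parameters rise monotonically with DIV in firing rate,
burst rate and organisation, network-event rate and recruitment, and ISI/IBI
dispersion, which qualitatively reproduces the developmental trajectories of
such cultures; early ages are sparse enough that many DIV-5 wells lack
bursts or network events, so downstream missing-value handling is exercised.
The magnitudes are generator choices, documented in the methods note.

``effect_scale`` interpolates every parameter between its across-age mean
(0: no age effect, classification should fall to chance) and the defaults
(1).  All randomness is driven by ``numpy`` ``SeedSequence``s derived from a
single master seed, so output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterator, Mapping

import numpy as np

from meao.spikeio import WELL_IDS, PlateRecording, SpikeTrain, WellRecording

__all__ = [
    "AgeParams",
    "StudyDesign",
    "DEFAULT_AGE_PARAMS",
    "default_age_params",
    "scaled_age_params",
    "synth_well",
    "synth_study",
    "iter_study",
]

#: Minimum separation between retained spikes (s); closer duplicates are dropped.
DEDUP_TOL = 1e-6

#: Length of the within-event envelope (s) for network-event spikes.
EVENT_ENVELOPE = 0.010
#: Mean first-spike latency (s) of a recruited electrode after event onset.
EVENT_LATENCY = 0.002


@dataclass(frozen=True)
class AgeParams:
    """Generator parameters for one age class (DIV)."""

    div: int
    electrode_rate: float  # Hz, tonic Poisson
    burst_rate: float  # bursts/min per electrode
    burst_n_spikes: float  # mean spikes per burst
    within_burst_isi: float  # s, mean within-burst ISI
    within_burst_isi_jitter: float  # CV of within-burst ISIs
    ibi_cv: float  # CV of inter-burst intervals
    network_event_rate: float  # events/min per well
    network_participation: float  # fraction of electrodes recruited per event
    well_heterogeneity: float = 0.3  # SD of per-well log rate multiplier
    plate_heterogeneity: float = 0.15  # SD of per-plate log rate multiplier
    p_silent_electrode: float = 0.1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name != "div" and v < 0:
                raise ValueError(f"{f.name} must be ≥ 0, got {v}")
        for name in ("network_participation", "p_silent_electrode"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


#: Default per-age parameters; every age-sensitive parameter is monotone in DIV.
DEFAULT_AGE_PARAMS: dict[int, AgeParams] = {
    5: AgeParams(div=5, electrode_rate=0.15, burst_rate=0.6, burst_n_spikes=7,
                 within_burst_isi=0.045, within_burst_isi_jitter=0.25, ibi_cv=0.30,
                 network_event_rate=0.08, network_participation=0.35,
                 p_silent_electrode=0.45),
    7: AgeParams(div=7, electrode_rate=0.35, burst_rate=2.0, burst_n_spikes=9,
                 within_burst_isi=0.040, within_burst_isi_jitter=0.40, ibi_cv=0.55,
                 network_event_rate=0.6, network_participation=0.45,
                 p_silent_electrode=0.25),
    9: AgeParams(div=9, electrode_rate=0.60, burst_rate=3.5, burst_n_spikes=11,
                 within_burst_isi=0.035, within_burst_isi_jitter=0.55, ibi_cv=0.80,
                 network_event_rate=2.0, network_participation=0.60,
                 p_silent_electrode=0.12),
    12: AgeParams(div=12, electrode_rate=0.90, burst_rate=5.5, burst_n_spikes=14,
                  within_burst_isi=0.030, within_burst_isi_jitter=0.70, ibi_cv=1.05,
                  network_event_rate=4.5, network_participation=0.75,
                  p_silent_electrode=0.05),
}


def default_age_params(div: int) -> AgeParams:
    """The default generator parameters for one of the study ages (5, 7, 9, 12)."""
    try:
        return DEFAULT_AGE_PARAMS[div]
    except KeyError:
        raise ValueError(f"no default parameters for DIV {div}; "
                         f"known ages: {sorted(DEFAULT_AGE_PARAMS)}") from None


_SCALABLE = [f.name for f in fields(AgeParams) if f.name != "div"]


def scaled_age_params(effect_scale: float,
                      base: Mapping[int, AgeParams] | None = None) -> dict[int, AgeParams]:
    """Interpolate the inter-age parameter differences.

    Every parameter becomes ``mean + effect_scale · (value − mean)`` where the
    mean is across the four ages; ``effect_scale=0`` makes all ages
    statistically identical, ``1`` returns the defaults.  Fractions are
    clipped to [0, 1].
    """
    base = dict(base or DEFAULT_AGE_PARAMS)
    means = {name: float(np.mean([getattr(p, name) for p in base.values()]))
             for name in _SCALABLE}
    out = {}
    for div, p in base.items():
        updates = {}
        for name in _SCALABLE:
            v = means[name] + effect_scale * (getattr(p, name) - means[name])
            if name in ("network_participation", "p_silent_electrode"):
                v = min(max(v, 0.0), 1.0)
            updates[name] = max(v, 0.0)
        out[div] = replace(p, **updates)
    return out


@dataclass(frozen=True)
class StudyDesign:
    """Shape of the synthetic study."""

    n_plates: int = 16
    wells_per_plate: int = 48
    electrodes_per_well: int = 16
    divs: tuple[int, ...] = (5, 7, 9, 12)
    window: float = 900.0
    #: (plate_id, div) recordings absent from the study; the default drops one
    #: DIV 12 and one DIV 7 recording, leaving 62 recordings / 2976 wells.
    dropped_recordings: tuple[tuple[str, int], ...] = (("P04", 7), ("P11", 12))

    def __post_init__(self) -> None:
        if min(self.n_plates, self.wells_per_plate, self.electrodes_per_well) < 1:
            raise ValueError("counts must be positive")
        if not self.divs:
            raise ValueError("divs must be nonempty")
        if self.wells_per_plate > len(WELL_IDS):
            raise ValueError(f"at most {len(WELL_IDS)} wells per plate")
        if self.window <= 0:
            raise ValueError("window must be positive")

    @property
    def plate_ids(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1:02d}" for i in range(self.n_plates))

    @property
    def well_ids(self) -> tuple[str, ...]:
        return WELL_IDS[: self.wells_per_plate]


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, key)]))


def _gamma_from_cv(rng: np.random.Generator, mean: float, cv: float, size: int) -> np.ndarray:
    """Gamma draws with the given mean and coefficient of variation (cv=0 → constant)."""
    if cv <= 0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, size=size)


def _burst_train(rng: np.random.Generator, params: AgeParams, rate_mult: float,
                 window: float) -> np.ndarray:
    """Spike times of the renewal burst process on one electrode."""
    rate = params.burst_rate * rate_mult / 60.0  # bursts/s
    if rate <= 0:
        return np.empty(0)
    mean_ibi = 1.0 / rate
    # expected bursts + slack; onsets from cumulative gamma IBIs
    n_max = int(window * rate + 10 * math.sqrt(window * rate) + 10)
    ibis = _gamma_from_cv(rng, mean_ibi, params.ibi_cv, n_max)
    onsets = rng.uniform(0, mean_ibi) + np.cumsum(ibis) - ibis[0]
    onsets = onsets[onsets < window]
    spikes = []
    for onset in onsets:
        n = max(2, rng.poisson(params.burst_n_spikes))
        isis = _gamma_from_cv(rng, params.within_burst_isi,
                              params.within_burst_isi_jitter, n - 1)
        spikes.append(onset + np.concatenate([[0.0], np.cumsum(isis)]))
    return np.concatenate(spikes) if spikes else np.empty(0)


def _finalize(times: np.ndarray, window: float) -> np.ndarray:
    """Sort, clip to [0, window) and enforce a minimum ISI of DEDUP_TOL."""
    times = np.sort(times[(times >= 0) & (times < window)])
    if times.size < 2:
        return times
    keep = np.concatenate([[True], np.diff(times) > DEDUP_TOL])
    return times[keep]


def synth_well(
    params: AgeParams,
    seed: int | np.random.SeedSequence = 0,
    plate_id: str = "P01",
    well_id: str = "A1",
    window: float = 900.0,
    n_electrodes: int = 16,
    rate_multiplier: float | None = None,
) -> WellRecording:
    """Simulate one well for one recording age.

    With ``rate_multiplier=None`` a per-well log-normal multiplier with log-SD
    ``params.well_heterogeneity`` is drawn from the seed; the study generator
    passes the persistent plate×well multiplier explicitly.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(int(seed))
    rng = np.random.default_rng(ss)
    if rate_multiplier is None:
        rate_multiplier = float(np.exp(rng.normal(0.0, params.well_heterogeneity)))

    alive = rng.random(n_electrodes) >= params.p_silent_electrode
    per_elec: list[np.ndarray] = []
    for e in range(n_electrodes):
        if not alive[e]:
            per_elec.append(np.empty(0))
            continue
        tonic_rate = params.electrode_rate * rate_multiplier
        n_tonic = rng.poisson(tonic_rate * window)
        tonic = rng.uniform(0, window, n_tonic)
        bursts = _burst_train(rng, params, rate_multiplier, window)
        per_elec.append(np.concatenate([tonic, bursts]))

    # well-level network events recruiting a random electrode subset
    ev_rate = params.network_event_rate * rate_multiplier / 60.0
    n_events = rng.poisson(ev_rate * window)
    event_times = rng.uniform(0, window, n_events)
    live = np.flatnonzero(alive)
    for t in event_times:
        if live.size == 0:
            break
        recruited = live[rng.random(live.size) < params.network_participation]
        for e in recruited:
            first = t + min(rng.exponential(EVENT_LATENCY), EVENT_ENVELOPE)
            n_extra = rng.poisson(1.0)
            extra = t + rng.uniform(0, EVENT_ENVELOPE, n_extra)
            per_elec[e] = np.concatenate([per_elec[e], [first], extra])

    electrodes = {
        e + 1: SpikeTrain(_finalize(per_elec[e], window), (0.0, window))
        for e in range(n_electrodes)
    }
    return WellRecording(plate_id=plate_id, well_id=well_id, div=params.div,
                         electrodes=electrodes, interval=(0.0, window))


def iter_study(
    design: StudyDesign = StudyDesign(),
    params_by_div: Mapping[int, AgeParams] | None = None,
    master_seed: int = 0,
) -> Iterator[PlateRecording]:
    """Yield the study's plate recordings one at a time (memory-friendly).

    Plate and well rate multipliers are drawn once per plate/well and reused
    across that plate's ages, so plates behave as repeated measures.  All
    seeds derive deterministically from *master_seed*.
    """
    if params_by_div is None:
        params_by_div = {d: default_age_params(d) for d in design.divs}
    dropped = set(design.dropped_recordings)
    any_params = next(iter(params_by_div.values()))

    plate_mults = {}
    well_mults = {}
    for pi, pid in enumerate(design.plate_ids):
        rng_p = _rng(master_seed, 1, pi)
        plate_mults[pid] = float(np.exp(rng_p.normal(0.0, any_params.plate_heterogeneity)))
        for wi, wid in enumerate(design.well_ids):
            rng_w = _rng(master_seed, 2, pi, wi)
            well_mults[(pid, wid)] = float(np.exp(rng_w.normal(0.0, any_params.well_heterogeneity)))

    for pi, pid in enumerate(design.plate_ids):
        for di, div in enumerate(design.divs):
            if (pid, div) in dropped:
                continue
            params = params_by_div[div]
            wells = {}
            for wi, wid in enumerate(design.well_ids):
                ss = np.random.SeedSequence([int(master_seed), 3, pi, di, wi])
                wells[wid] = synth_well(
                    params, ss, plate_id=pid, well_id=wid, window=design.window,
                    n_electrodes=design.electrodes_per_well,
                    rate_multiplier=plate_mults[pid] * well_mults[(pid, wid)],
                )
            yield PlateRecording(plate_id=pid, div=div, wells=wells)


def synth_study(
    design: StudyDesign = StudyDesign(),
    params_by_div: Mapping[int, AgeParams] | None = None,
    master_seed: int = 0,
) -> list[PlateRecording]:
    """Materialise the full synthetic study as a list of plate recordings."""
    return list(iter_study(design, params_by_div, master_seed))
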