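"""Assembly of the 12 per-well activity features and their aggregation rules.

The 12 features, in canonical order:

========================  =====================================================
``mfr``                   median firing rate (Hz) over active electrodes
``burst_rate``            median bursts/min over bursting electrodes
``burst_duration``        median mean-burst-duration (s) over bursting electrodes
``frac_bursting_electrodes``  bursting / active electrode count
``within_burst_fr``       median within-burst firing rate (Hz), bursting electrodes
``pct_spikes_in_bursts``  median % of spikes inside bursts, bursting electrodes
``cv_ibi``                median CV of inter-burst intervals, bursting electrodes
``cv_within_isi``         median CV of within-burst ISIs, bursting electrodes
``ns_rate``               network spikes per minute (0 when none)
``ns_duration``           median network-spike duration (s)
``ns_peak``               median network-spike peak electrode count
``mean_correlation``      mean pairwise STTC over active electrodes
========================  =====================================================

An electrode is *active* when it has at least ``active_min_spikes`` spikes in
the analysis window and *bursting* when its burst rate is at least
``bursting_threshold`` per minute.  Undefined values are NaN.  A value is zero
only when its defining count is genuinely zero (e.g. ``ns_rate`` with no
events) — never as a stand-in for "undefined" — because plate-level
aggregation ignores zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from meao.bursting import BurstParams, burst_statistics, detect_bursts, is_bursting_electrode
from meao.netsync import SttcConfig, detect_network_spikes, mean_pairwise_sttc, network_spike_features
from meao.spikeio import WellRecording, active_electrodes

__all__ = [
    "FEATURE_NAMES",
    "FeatureConfig",
    "well_features",
    "plate_features",
    "prepare_for_classification",
    "KEY_COLUMNS",
]

FEATURE_NAMES: tuple[str, ...] = (
    "mfr",
    "burst_rate",
    "burst_duration",
    "frac_bursting_electrodes",
    "within_burst_fr",
    "pct_spikes_in_bursts",
    "cv_ibi",
    "cv_within_isi",
    "ns_rate",
    "ns_duration",
    "ns_peak",
    "mean_correlation",
)

#: Identifier columns of a feature table.
KEY_COLUMNS: tuple[str, ...] = ("plate_id", "well_id", "div")

#: Columns zero-filled for wells with no bursts / no network spikes.
ZERO_FILL_NO_BURSTS = ("within_burst_fr", "burst_duration")
ZERO_FILL_NO_NETWORK_SPIKES = ("ns_duration", "ns_peak")
#: A missing value in these columns excludes the well from classification.
EXCLUDE_IF_MISSING = ("mean_correlation", "cv_ibi", "cv_within_isi")


@dataclass(frozen=True)
class FeatureConfig:
    """All tunable parameters of the feature extraction stage."""

    burst: BurstParams = field(default_factory=BurstParams)
    ns_bin_width: float = 0.003
    ns_threshold: int = 5
    ns_strict_gt: bool = False
    sttc_dt: float = 0.05
    active_min_spikes: int = 1
    bursting_threshold: float = 1.0  # bursts/min


def _median(values: list[float]) -> float:
    finite = [v for v in values if not math.isnan(v)]
    return float(np.median(finite)) if finite else math.nan


def well_features(well: WellRecording, config: FeatureConfig = FeatureConfig()) -> pd.Series:
    """Compute the 12-feature vector for one (windowed) well.

    Electrode statistics are aggregated per the canonical rules: medians over
    active electrodes for the firing rate, medians over bursting electrodes
    for the six burst statistics (NaN when no electrode bursts), counts for
    the network-spike block, the mean pairwise STTC for the correlation.
    """
    minutes = well.duration / 60.0
    active = sorted(active_electrodes(well, min_spikes=config.active_min_spikes))

    values: dict[str, float] = dict.fromkeys(FEATURE_NAMES, math.nan)

    if active:
        values["mfr"] = float(np.median([well.electrodes[i].firing_rate for i in active]))

    stats = {}
    for i in active:
        train = well.electrodes[i]
        stats[i] = burst_statistics(train, detect_bursts(train, config.burst))
    bursting = [i for i in active if is_bursting_electrode(stats[i], config.bursting_threshold)]
    if active:
        values["frac_bursting_electrodes"] = len(bursting) / len(active)
    if bursting:
        values["burst_rate"] = _median([stats[i].burst_rate for i in bursting])
        values["burst_duration"] = _median([stats[i].mean_duration for i in bursting])
        values["within_burst_fr"] = _median([stats[i].within_burst_fr for i in bursting])
        values["pct_spikes_in_bursts"] = _median([stats[i].pct_spikes_in_bursts for i in bursting])
        values["cv_ibi"] = _median([stats[i].cv_ibi for i in bursting])
        values["cv_within_isi"] = _median([stats[i].cv_within_isi for i in bursting])

    events = detect_network_spikes(
        well, bin_width=config.ns_bin_width, threshold=config.ns_threshold,
        strict_gt=config.ns_strict_gt,
    )
    values["ns_rate"], values["ns_duration"], values["ns_peak"] = network_spike_features(
        events, minutes
    )

    values["mean_correlation"] = mean_pairwise_sttc(
        well, SttcConfig(dt=config.sttc_dt, interval=well.interval),
        min_spikes=config.active_min_spikes,
    )
    return pd.Series(values, index=list(FEATURE_NAMES), dtype=float)


def plate_features(well_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a well-level feature table to plate level.

    For each feature and each (plate_id, div), the plate value is the median
    over wells whose value is non-missing **and nonzero** (zeros ignored);
    NaN when no such well exists.
    """
    def nonzero_median(col: pd.Series) -> float:
        vals = col.dropna()
        vals = vals[vals != 0]
        return float(vals.median()) if len(vals) else math.nan

    grouped = well_table.groupby(["plate_id", "div"], sort=True)
    out = grouped[list(FEATURE_NAMES)].agg(nonzero_median)
    return out.reset_index()


def prepare_for_classification(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Apply the classification missing-value policy to a well-level table.

    Wells with no bursts have ``within_burst_fr`` and ``burst_duration`` set
    to zero; wells with no network spikes have ``ns_peak`` and ``ns_duration``
    set to zero.  Wells still missing ``mean_correlation``, ``cv_ibi`` or
    ``cv_within_isi`` (or any residual feature) are excluded.  Zero-fill is
    applied before exclusion, so the fills survive only on rows the exclusion
    rule keeps.

    Returns ``(kept, excluded, excluded_fraction)`` where *excluded* holds the
    dropped rows and the fraction is relative to the input row count.
    """
    if table.empty:
        return table.copy(), table.copy(), 0.0
    out = table.copy()
    no_bursts = out["frac_bursting_electrodes"].isna() | (out["frac_bursting_electrodes"] == 0)
    for col in ZERO_FILL_NO_BURSTS:
        out.loc[no_bursts & out[col].isna(), col] = 0.0
    no_ns = out["ns_rate"].isna() | (out["ns_rate"] == 0)
    for col in ZERO_FILL_NO_NETWORK_SPIKES:
        out.loc[no_ns & out[col].isna(), col] = 0.0

    missing = out[list(FEATURE_NAMES)].isna().any(axis=1)
    kept = out.loc[~missing].copy()
    excluded = out.loc[missing].copy()
    return kept, excluded, float(missing.mean())
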