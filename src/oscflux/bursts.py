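"""Oscillation-burst detection, individual alpha frequency, per-epoch measures.

A burst is a maximal run of consecutive wavelet-power samples at one
frequency that exceed the aperiodic-model threshold and last strictly longer
than the duration threshold (min_cycles / f, 3 cycles by default).  Runs are
found per frequency row; events at adjacent frequencies are deliberately not
merged — the individual alpha frequency (IAF) is selected afterwards as the
in-band frequency with the longest summed burst duration, and all epoch
summaries are computed at that single frequency.

Edge-invalid samples (within half a wavelet of an epoch boundary) and
artefact-masked samples cannot belong to a run, so a burst interrupted by an
artefact counts as two candidate runs, each subject to the duration rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectral import ThresholdProfile, TimeFrequencyPower

logger = logging.getLogger("oscflux.bursts")

ALPHA_BAND = (8.0, 13.0)


@dataclass
class BurstEvent:
    """One supra-threshold oscillatory episode at a single frequency."""

    freq: float
    onset: float          # seconds, epoch-relative, half-open [onset, offset)
    offset: float
    mean_power: float
    channel: str | None = None
    epoch: int | None = None

    @property
    def duration_s(self) -> float:
        return self.offset - self.onset

    @property
    def duration_cycles(self) -> float:
        return self.duration_s * self.freq


@dataclass
class AlphaMeasures:
    """Per-epoch summary of IAF bursts: power, time proportion, duration."""

    iaf: float
    burst_power: float        # nan when no bursts
    burst_proportion: float   # in [0, 1]
    burst_duration: float     # seconds; nan when no bursts
    n_bursts: int


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True in a boolean vector."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, mask.size]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_bursts(tfr: TimeFrequencyPower, thresholds: ThresholdProfile,
                  channel: str | None = None,
                  epoch: int | None = None,
                  boundary_percentile: float | None = 0.5) -> list[BurstEvent]:
    """Detect supra-threshold episodes per frequency.

    A run qualifies as a burst when its duration strictly exceeds
    ``thresholds.duration_threshold`` at that frequency.  Samples flagged
    invalid in the TFR mask are treated as sub-threshold.

    Because a burst's power envelope crosses the high detection threshold
    well inside its true extent, qualifying runs are then grown outward to
    where power falls below a lower boundary threshold (the
    ``boundary_percentile`` quantile of the chi-squared power distribution
    around the aperiodic model; 0.5, i.e. the background median, by
    default) — the dual-threshold convention of envelope-based burst
    detectors.  Pass ``boundary_percentile=None`` to report the raw
    detection-threshold runs.
    """
    if tfr.freqs.shape != thresholds.freqs.shape or \
            not np.allclose(tfr.freqs, thresholds.freqs):
        raise ValueError("TFR and thresholds use different frequency grids")
    fs = tfr.fs
    events: list[BurstEvent] = []
    supra = (tfr.power > thresholds.power_threshold[:, np.newaxis]) & tfr.valid
    if boundary_percentile is not None:
        from scipy.stats import chi2
        ratio = chi2.ppf(boundary_percentile, df=2) / chi2.ppf(
            thresholds.percentile, df=2)
        boundary = thresholds.power_threshold * ratio
        above_boundary = (tfr.power > boundary[:, np.newaxis]) & tfr.valid
    for i, f in enumerate(tfr.freqs):
        spans = []
        for start, stop in _runs(supra[i]):
            duration = (stop - start) / fs
            if duration <= thresholds.duration_threshold[i]:
                continue
            if boundary_percentile is not None:
                row = above_boundary[i]
                while start > 0 and row[start - 1]:
                    start -= 1
                while stop < row.size and row[stop]:
                    stop += 1
            if spans and start <= spans[-1][1]:
                spans[-1] = (spans[-1][0], max(stop, spans[-1][1]))
            else:
                spans.append((start, stop))
        for start, stop in spans:
            events.append(BurstEvent(
                freq=float(f), onset=start / fs, offset=stop / fs,
                mean_power=float(tfr.power[i, start:stop].mean()),
                channel=channel, epoch=epoch))
    return events


def find_iaf(events: list[BurstEvent],
             alpha_band: tuple[float, float] = ALPHA_BAND) -> float:
    """Individual alpha frequency: in-band frequency with the longest summed
    burst duration across all supplied events; ties break toward the lower
    frequency.  Returns nan when no in-band event exists."""
    totals: dict[float, float] = {}
    for ev in events:
        if alpha_band[0] <= ev.freq <= alpha_band[1]:
            totals[ev.freq] = totals.get(ev.freq, 0.0) + ev.duration_s
    if not totals:
        return float("nan")
    best = max(sorted(totals), key=lambda f: (totals[f], -f))
    return float(best)


def epoch_alpha_measures(events: list[BurstEvent], valid_epoch_duration: float,
                         duration_weighted_power: bool = True) -> AlphaMeasures:
    """Summarise the IAF bursts of one epoch.

    burst_power is the duration-weighted mean of per-event mean power (set
    ``duration_weighted_power=False`` for a plain event mean);
    burst_proportion is total burst time over the valid epoch duration;
    burst_duration is the arithmetic mean event duration.
    """
    if valid_epoch_duration <= 0:
        raise ValueError("valid_epoch_duration must be positive")
    if not events:
        return AlphaMeasures(iaf=float("nan"), burst_power=float("nan"),
                             burst_proportion=0.0, burst_duration=float("nan"),
                             n_bursts=0)
    durations = np.array([ev.duration_s for ev in events])
    powers = np.array([ev.mean_power for ev in events])
    if duration_weighted_power:
        burst_power = float(np.average(powers, weights=durations))
    else:
        burst_power = float(powers.mean())
    return AlphaMeasures(
        iaf=float(events[0].freq),
        burst_power=burst_power,
        burst_proportion=float(durations.sum() / valid_epoch_duration),
        burst_duration=float(durations.mean()),
        n_bursts=len(events))


def aggregate_condition_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Average per-epoch alpha measures into participant x channel x condition
    cells.

    ``measures`` must carry columns participant, channel, condition and the
    three measure columns (burst_power, burst_proportion, burst_duration).
    Cells with no epochs simply do not appear; measure columns that are all
    nan within a cell yield nan (missing-flagged) means.
    """
    required = {"participant", "channel", "condition",
                "burst_power", "burst_proportion", "burst_duration"}
    missing = required - set(measures.columns)
    if missing:
        raise ValueError(f"measures table lacks columns: {sorted(missing)}")
    grouped = (measures
               .groupby(["participant", "channel", "condition"], sort=True)
               [["burst_power", "burst_proportion", "burst_duration"]]
               .mean()
               .reset_index())
    return grouped


def events_to_frame(events: list[BurstEvent]) -> pd.DataFrame:
    """Long-format event table (for CSV export)."""
    return pd.DataFrame(
        [{"participant": None, "channel": ev.channel, "epoch": ev.epoch,
          "freq": ev.freq, "onset": ev.onset, "offset": ev.offset,
          "duration_s": ev.duration_s, "mean_power": ev.mean_power}
         for ev in events],
        columns=["participant", "channel", "epoch", "freq", "onset", "offset",
                 "duration_s", "mean_power"])
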