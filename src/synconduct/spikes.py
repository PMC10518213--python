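"""Spike detection, blanking, PSTHs and firing-rate response metrics.

Detection takes the first time-derivative of the recording to remove
slow baseline drift, then thresholds at a multiple (default 3) of the
full-trace derivative standard deviation. Detected spikes can be
"blanked" — the window from 1 ms before to 3 ms after each spike is
replaced by a straight line — before subthreshold noise statistics are
computed. PSTHs use 20-ms bins over multiples of 20 trials, matching
the reporting conventions of the recordings these routines target.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .datamodel import Modality, StimulusSpec, SweepRecord


@dataclass
class SpikeTrain:
    """Detected (or ground-truth) spike times for one sweep, in seconds."""

    spike_times: np.ndarray
    duration: float
    sampling_rate: float
    detection_threshold_sd: float = 3.0
    refractory_floor_ms: float = 1.0

    def __post_init__(self):
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ValueError("spike times must lie within the sweep")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class PSTH:
    """Trial-averaged firing-rate histogram."""

    bin_width_ms: float
    rates_hz: np.ndarray
    n_trials: int
    sd_across_blocks_hz: np.ndarray
    n_per_block: int

    @property
    def n_bins(self) -> int:
        return self.rates_hz.size

    @property
    def bin_edges_s(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width_ms * 1e-3

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ms * 1e-3

    def total_count(self) -> float:
        """Total spike count implied by the histogram (exact conservation)."""
        return float(np.sum(self.rates_hz) * self.n_trials * self.bin_width_ms * 1e-3)


@dataclass
class ResponseWindows:
    """Measurement windows relative to stimulus onset, in seconds.

    The source recordings mark these only graphically, so the defaults
    here are a declared convention: background over the 300 ms
    immediately before stimulus onset, peak as the maximum bin in the
    first 150 ms of the On-phase, sustained as the mean over the last
    250 ms of the On-phase.
    """

    background_s: float = 0.300
    peak_search_s: float = 0.150
    sustained_s: float = 0.250


@dataclass
class ResponseMetrics:
    background_rate_hz: float
    peak_rate_hz: float
    sustained_rate_hz: float
    windows: Dict[str, Tuple[float, float]]


def detect_spikes(sweep: SweepRecord, threshold_sd: float = 3.0) -> SpikeTrain:
    """Derivative-threshold spike detection.

    The first difference of the trace is computed (removing slow
    baseline drift); its standard deviation over the whole trace sets
    the threshold at ``threshold_sd`` x SD. Positive-going threshold
    crossings become spike times at the crossing sample, with a 1-ms
    refractory lockout. A constant trace yields an empty train.
    """
    if sweep.modality is Modality.VOLTAGE_CLAMP:
        raise ValueError("spike detection requires a voltage-modality sweep")
    if sweep.n_samples < 10:
        raise ValueError("trace too short for spike detection (< 10 samples)")
    deriv = np.diff(sweep.signal)
    sd = float(np.std(deriv))
    if sd == 0.0:
        return SpikeTrain(
            np.empty(0), sweep.duration, sweep.sampling_rate, threshold_sd
        )
    thresh = threshold_sd * sd
    above = deriv > thresh
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate([[0], crossings])
    lockout = max(1, int(round(1e-3 * sweep.sampling_rate)))
    times = []
    last = -lockout - 1
    for idx in crossings:
        if idx - last > lockout:
            times.append(idx / sweep.sampling_rate)
            last = idx
    return SpikeTrain(
        np.asarray(times), sweep.duration, sweep.sampling_rate, threshold_sd
    )


def blank_spikes(
    sweep: SweepRecord,
    spikes: SpikeTrain,
    pre_ms: float = 1.0,
    post_ms: float = 3.0,
) -> SweepRecord:
    """Replace a window around each spike with linear interpolation.

    Each window runs from ``pre_ms`` before to ``post_ms`` after the
    spike time; overlapping windows are merged before interpolation so
    the operation is idempotent. Windows clipped by the trace edge are
    anchored at the clipped boundary sample. Samples outside the merged
    windows are untouched.
    """
    if spikes.n_spikes == 0:
        return sweep.replace(signal=sweep.signal.copy())
    fs = sweep.sampling_rate
    n = sweep.n_samples
    starts = np.floor((spikes.spike_times - pre_ms * 1e-3) * fs).astype(int)
    stops = np.ceil((spikes.spike_times + post_ms * 1e-3) * fs).astype(int)
    starts = np.clip(starts, 0, n - 1)
    stops = np.clip(stops, 0, n - 1)
    # merge overlapping windows
    merged = [[starts[0], stops[0]]]
    for a, b in zip(starts[1:], stops[1:]):
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = sweep.signal.copy()
    for a, b in merged:
        if b <= a:
            continue
        out[a : b + 1] = np.linspace(out[a], out[b], b - a + 1)
    return sweep.replace(signal=out)


def compute_psth(
    trains: Sequence[SpikeTrain],
    bin_width_ms: float = 20.0,
    n_per_block: int = 20,
    duration: Optional[float] = None,
) -> PSTH:
    """Trial-averaged PSTH over a multiple of ``n_per_block`` trials.

    Rate per bin is total count / (n_trials x bin width); the SD across
    block-wise PSTHs (blocks of ``n_per_block`` consecutive trials)
    estimates trial-block variability. A trial count that is not a
    positive multiple of the block size is rejected rather than trimmed.
    """
    n_trials = len(trains)
    if n_trials == 0 or n_trials % n_per_block != 0:
        raise ValueError(
            f"number of trials ({n_trials}) must be a positive multiple of "
            f"the block size ({n_per_block})"
        )
    if duration is None:
        duration = max(tr.duration for tr in trains)
    bw_s = bin_width_ms * 1e-3
    n_bins = int(round(duration / bw_s))
    edges = np.arange(n_bins + 1) * bw_s
    counts = np.stack(
        [np.histogram(tr.spike_times, bins=edges)[0] for tr in trains]
    )
    rates = counts.sum(axis=0) / (n_trials * bw_s)
    n_blocks = n_trials // n_per_block
    block_rates = (
        counts.reshape(n_blocks, n_per_block, n_bins).sum(axis=1)
        / (n_per_block * bw_s)
    )
    sd = block_rates.std(axis=0, ddof=1) if n_blocks > 1 else np.zeros(n_bins)
    return PSTH(
        bin_width_ms=bin_width_ms,
        rates_hz=rates,
        n_trials=n_trials,
        sd_across_blocks_hz=sd,
        n_per_block=n_per_block,
    )


def response_metrics(
    psth: PSTH,
    stim: StimulusSpec,
    windows: Optional[ResponseWindows] = None,
) -> ResponseMetrics:
    """Background, peak and sustained firing rates from a PSTH.

    Background is the mean rate over the pre-stimulus window, peak the
    maximum bin within the onset search window after On-phase start and
    sustained the mean over the late-On window (both inside the first
    stimulus cycle). The windows used are recorded in the result.
    """
    w = windows or ResponseWindows()
    t_on = stim.phase_zero
    half_period = 0.5 / stim.frequency
    spans = {
        "background": (max(0.0, t_on - w.background_s), t_on),
        "peak": (t_on, t_on + w.peak_search_s),
        "sustained": (t_on + half_period - w.sustained_s, t_on + half_period),
    }
    edges = psth.bin_edges_s
    total_span = edges[-1]
    for name, (a, b) in spans.items():
        if a < 0 or b > total_span + 1e-9:
            raise ValueError(f"{name} window ({a:.3f}, {b:.3f}) s outside PSTH span")

    def _bins(a: float, b: float) -> np.ndarray:
        centers = psth.bin_centers_s
        return (centers >= a) & (centers < b)

    bg = float(np.mean(psth.rates_hz[_bins(*spans["background"])]))
    peak = float(np.max(psth.rates_hz[_bins(*spans["peak"])]))
    sus = float(np.mean(psth.rates_hz[_bins(*spans["sustained"])]))
    return ResponseMetrics(
        background_rate_hz=bg,
        peak_rate_hz=peak,
        sustained_rate_hz=sus,
        windows=spans,
    )


def percent_change(a: float, b: float) -> int:
    """Percent reduction 100 x (a - b)/a, rounded half-away-from-zero.

    Matches the convention used when reporting drug-induced reductions
    of firing rates or amplitudes (e.g. 11.9 -> 6.1 Hz is a 49%
    reduction). Full precision is available via
    :func:`percent_change_exact`.
    """
    return int(
        math.copysign(
            math.floor(abs(percent_change_exact(a, b)) + 0.5),
            percent_change_exact(a, b),
        )
    )


def percent_change_exact(a: float, b: float) -> float:
    if a <= 0:
        raise ValueError("reference value must be positive")
    return 100.0 * (a - b) / a
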