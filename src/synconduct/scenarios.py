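"""End-to-end simulated-experiment workflows.

Each function runs one complete in-silico experiment on the model
On-ganglion cell — spiking PSTH metrics per pharmacological condition,
voltage-clamp I-V families with conductance decomposition, baseline
noise statistics against the Campbell oracle, spike-detector
performance against ground truth — deriving all per-trial seeds from a
single base seed so every run is reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .conductance import (
    ConductanceTrace,
    build_iv_series,
    decompose_conductances,
    net_light_evoked,
)
from .datamodel import StimulusSpec
from .spikes import ResponseMetrics, SpikeTrain, compute_psth, detect_spikes, response_metrics
from .stats import baseline_stats, campbell_moments
from .synthetic import (
    CellModel,
    MgBlock,
    SynapticDriveSpec,
    build_synaptic_drive,
    default_on_gc_cell,
    default_on_gc_drive,
    default_stimulus,
    make_stimulus,
    shot_noise_conductance,
    simulate_current_clamp,
    simulate_voltage_clamp,
    DriveTraces,
    UnitaryEvent,
)

FS = 10_000.0  # Hz, digitization rate of the emulated recordings

#: Standard decomposition protocol: nine holding potentials spanning
#: -110 to +50 mV in 20-mV steps.
IV_POTENTIALS = np.arange(-110.0, 51.0, 20.0)


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """n reproducible 31-bit seeds derived from one base seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def simulate_condition_metrics(
    condition: str,
    seed: int,
    n_trials: int = 20,
    spec: Optional[SynapticDriveSpec] = None,
    cell: Optional[CellModel] = None,
    stimulus: Optional[StimulusSpec] = None,
) -> ResponseMetrics:
    """PSTH response metrics for one condition over ``n_trials`` sweeps."""
    spec = spec or default_on_gc_drive()
    cell = cell or default_on_gc_cell()
    stimulus = stimulus or default_stimulus()
    intensity = make_stimulus(stimulus, FS)
    seeds = _sub_seeds(seed, n_trials)
    trains = []
    for s in seeds:
        drive = build_synaptic_drive(
            spec, intensity, stimulus.background_intensity, FS, condition, seed=int(s)
        )
        sweep, spike_times = simulate_current_clamp(cell, drive)
        trains.append(SpikeTrain(spike_times, sweep.duration, FS))
    psth = compute_psth(trains, bin_width_ms=20.0, n_per_block=n_trials)
    return response_metrics(psth, stimulus)


def spike_detector_performance(
    seed: int,
    n_runs: int = 100,
    duration_s: float = 1.0,
    tolerance_s: float = 1e-3,
) -> Dict[str, float]:
    """Detector sensitivity and false-discovery rate against ground truth.

    Each run simulates a current-clamp sweep driven by tonic shot noise
    (high signal-to-noise spikes), detects spikes with the 3-SD
    derivative rule, and matches detections to true spike times within
    +/-1 ms.
    """
    cell = default_on_gc_cell()
    unit = UnitaryEvent(0.6, 2.0)
    seeds = _sub_seeds(seed, n_runs)
    tp = fn = fp = 0
    for s in seeds:
        g = shot_noise_conductance(
            np.full(int(duration_s * FS), 1200.0), unit, FS, seed=int(s)
        )
        drive = DriveTraces(g, np.zeros_like(g), np.zeros_like(g), FS, {})
        sweep, truth = simulate_current_clamp(cell, drive)
        det = detect_spikes(sweep).spike_times
        matched = np.zeros(det.size, dtype=bool)
        for t in truth:
            if det.size:
                j = int(np.argmin(np.abs(det - t)))
                if abs(det[j] - t) <= tolerance_s and not matched[j]:
                    matched[j] = True
                    tp += 1
                    continue
            fn += 1
        fp += int((~matched).sum())
    return {
        "sensitivity": tp / max(tp + fn, 1),
        "false_discovery_rate": fp / max(tp + fp, 1),
        "n_true_spikes": tp + fn,
    }


def decomposition_recovery(
    seed: int,
    condition: str = "control",
    n_trials: int = 20,
    stimulus: Optional[StimulusSpec] = None,
    spec: Optional[SynapticDriveSpec] = None,
    potentials: Sequence[float] = tuple(IV_POTENTIALS),
    baseline_window_s: Tuple[float, float] = (0.0, 0.3),
) -> Dict[str, np.ndarray | ConductanceTrace]:
    """Full voltage-clamp pipeline with recovery diagnostics.

    Simulates ``n_trials`` sweeps at each holding potential, forms the
    net light-evoked currents, bins them at 10 ms, decomposes, and
    returns the fitted trace together with the baseline-subtracted,
    binned ground-truth component means for error measurement.
    """
    spec = spec or default_on_gc_drive()
    cell = default_on_gc_cell(spiking=False)
    stimulus = stimulus or default_stimulus(duration=1.3, phase_zero=0.3)
    intensity = make_stimulus(stimulus, FS)
    mg = cell.mg_block
    seeds = iter(_sub_seeds(seed, len(potentials) * n_trials))
    net: Dict[float, np.ndarray] = {}
    gt_sum = None
    for v in potentials:
        sweeps = []
        for _ in range(n_trials):
            drive = build_synaptic_drive(
                spec, intensity, stimulus.background_intensity, FS, condition,
                seed=int(next(seeds)),
            )
            sweeps.append(simulate_voltage_clamp(cell, drive, float(v)))
            gt = np.stack([drive.g_exc_ampa, drive.g_inh, drive.g_nmda_scalefree])
            gt_sum = gt if gt_sum is None else gt_sum + gt
        net[float(v)] = net_light_evoked(sweeps, baseline_window_s)
    gt_mean = gt_sum / (len(potentials) * n_trials)
    iv = build_iv_series(net, FS, bin_width_ms=10.0)
    fitted = decompose_conductances(iv, mg_block=mg, fit_nmda=True)
    # bin and baseline-subtract the ground truth the same way
    spb = int(round(10.0e-3 * FS))
    n_bins = gt_mean.shape[1] // spb
    gtb = gt_mean[:, : n_bins * spb].reshape(3, n_bins, spb).mean(axis=2)
    b0 = int(round(baseline_window_s[0] / 10.0e-3))
    b1 = int(round(baseline_window_s[1] / 10.0e-3))
    gtb = gtb - gtb[:, b0:b1].mean(axis=1, keepdims=True)
    return {
        "fitted": fitted,
        "truth_exc": gtb[0],
        "truth_inh": gtb[1],
        "truth_nmda": gtb[2],
        "iv": iv,
    }


def component_recovery_errors(rec: Dict) -> Dict[str, float]:
    """Per-component RMSE as a fraction of the true peak magnitude."""
    fitted: ConductanceTrace = rec["fitted"]
    out = {}
    for name, est, tru in (
        ("exc", fitted.g_exc_ns, rec["truth_exc"]),
        ("inh", fitted.g_inh_ns, rec["truth_inh"]),
        ("nmda", fitted.g_nmda_ns, rec["truth_nmda"]),
    ):
        rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
        peak = float(np.max(np.abs(tru)))
        out[name] = rmse / peak if peak > 0 else 0.0
    return out


def campbell_agreement(
    seed: int,
    n_repeats: int = 100,
    v_hold: float = -76.0,
    rate_hz: float = 1000.0,
    unit: Optional[UnitaryEvent] = None,
    duration_s: float = 2.0,
) -> Dict[str, float]:
    """Empirical vs Campbell-predicted moments of the tonic current.

    Simulates the tonic shot-noise current at the junction-corrected
    holding potential and compares the across-repeat mean and variance
    to the closed-form prediction, in units of their standard errors.
    The leak is omitted so the comparison isolates the synaptic shot
    noise (a constant leak offset would shift the mean only).
    """
    unit = unit or UnitaryEvent(0.6, 2.0)
    cell = CellModel(g_leak_ns=0.0, spike_mechanism=None)
    seeds = _sub_seeds(seed, n_repeats)
    means, varis = [], []
    for s in seeds:
        g = shot_noise_conductance(
            np.full(int(duration_s * FS), rate_hz), unit, FS, seed=int(s)
        )
        drive = DriveTraces(g, np.zeros_like(g), np.zeros_like(g), FS, {})
        sw = simulate_voltage_clamp(cell, drive, v_hold)
        means.append(sw.signal.mean())
        varis.append(sw.signal.var())
    m_pred, v_pred = campbell_moments(rate_hz, unit, v_hold - cell.e_exc_mv)
    m_emp, v_emp = float(np.mean(means)), float(np.mean(varis))
    se_m = float(np.std(means) / np.sqrt(n_repeats))
    se_v = float(np.std(varis) / np.sqrt(n_repeats))
    return {
        "mean_pred_pa": m_pred,
        "mean_emp_pa": m_emp,
        "mean_z": (m_emp - m_pred) / se_m,
        "var_pred_pa2": v_pred,
        "var_emp_pa2": v_emp,
        "var_z": (v_emp - v_pred) / se_v,
    }


def baseline_drug_effect(
    seed: int,
    n_trials: int = 10,
    v_hold: float = -76.0,
) -> Dict[str, float]:
    """Holding current and baseline current SD, control vs CP-AMPAR block.

    Voltage-clamp sweeps at the corrected holding potential under the
    stimulus protocol; the pre-stimulus window gives the tonic inward
    current (relative to leak) and its SD per condition.
    """
    spec = default_on_gc_drive()
    cell = default_on_gc_cell(spiking=False)
    stimulus = default_stimulus()
    intensity = make_stimulus(stimulus, FS)
    out = {}
    seeds = _sub_seeds(seed, n_trials)
    window = (0.0, stimulus.phase_zero)
    for condition in ("control", "IEM"):
        means, sds = [], []
        for s in seeds:
            drive = build_synaptic_drive(
                spec, intensity, stimulus.background_intensity, FS, condition,
                seed=int(s),
            )
            sw = simulate_voltage_clamp(cell, drive, v_hold)
            bs = baseline_stats(sw, window)
            leak = cell.g_leak_ns * (v_hold - cell.e_leak_mv)
            means.append(bs.mean - leak)  # synaptic (tonic) component only
            sds.append(bs.sd)
        out[f"tonic_current_{condition}_pa"] = float(np.mean(means))
        out[f"baseline_sd_{condition}_pa"] = float(np.mean(sds))
    return out
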