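"""Synthetic ganglion-cell and AII-cell recordings with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a tonic excitatory conductance built from Poisson shot noise
(summation of relatively large unitary EPSCs) whose rate is modulated
up during the On-phase and down during the Off-phase of a square-wave
contrast stimulus; a transient, rectified excitatory component at
On-phase onsets that survives CP-AMPAR blockade; an NMDA-type component
with a sigmoidal Mg-block voltage dependence; and transient inhibition
at On-phase onset. Pharmacological conditions (IEM-1460, D-AP5, MFA,
inhibitory cocktail) are multiplicative factor transforms on these
components, not receptor kinetics.

Sweeps are produced either by an ideal voltage clamp (algebraic, no
series-resistance error) or by a leaky integrate-and-fire neuron with a
stereotyped spike waveform pasted at each spike so the detector sees
realistic input. Every stochastic operation takes an explicit seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.signal import fftconvolve

from .datamodel import Modality, StimulusSpec, SweepRecord


# ---------------------------------------------------------------------------
# NMDA Mg-block nonlinearity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MgBlock:
    """Sigmoidal Mg-block factor B(V) = 1 / (1 + (Mg/c) * exp(-V/k)).

    ``mg_mM`` is the external Mg2+ concentration, ``conc_scale_mM`` (c)
    the concentration scale and ``steepness_mv`` (k) the e-fold voltage.
    Defaults are the standard published constants for this form
    (c = 3.57 mM, k = 16.13 mV) at 1 mM Mg2+; they are configuration,
    recorded in every fit report, not a claim about any particular
    dataset.
    """

    mg_mM: float = 1.0
    steepness_mv: float = 16.13
    conc_scale_mM: float = 3.57

    def __call__(self, v_mv) -> np.ndarray:
        v = np.asarray(v_mv, dtype=float)
        return 1.0 / (1.0 + (self.mg_mM / self.conc_scale_mM) * np.exp(-v / self.steepness_mv))

    def as_record(self) -> dict:
        return {
            "form": "1/(1+(Mg/c)*exp(-V/k))",
            "mg_mM": self.mg_mM,
            "steepness_mv": self.steepness_mv,
            "conc_scale_mM": self.conc_scale_mM,
        }


# ---------------------------------------------------------------------------
# Cell and drive parameterization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeMechanism:
    """Threshold-and-reset spiking with a pasted stereotyped waveform."""

    threshold_mv: float = -52.0
    reset_mv: float = -62.0
    refractory_ms: float = 2.0
    waveform_amplitude_mv: float = 80.0  # peak above threshold
    waveform_width_ms: float = 1.0


@dataclass(frozen=True)
class CellModel:
    """Conductance-based point neuron (single compartment)."""

    capacitance_pf: float = 60.0
    g_leak_ns: float = 4.0
    e_leak_mv: float = -65.0
    e_exc_mv: float = 0.0
    e_inh_mv: float = -70.0
    spike_mechanism: Optional[SpikeMechanism] = None
    mg_block: MgBlock = field(default_factory=MgBlock)

    def __post_init__(self):
        if self.capacitance_pf <= 0:
            raise ValueError("capacitance must be positive")
        if self.g_leak_ns < 0:
            raise ValueError("g_leak must be >= 0")
        if not self.e_inh_mv < self.e_exc_mv:
            raise ValueError("E_inh must be below E_exc")


@dataclass(frozen=True)
class UnitaryEvent:
    """Unitary EPSC conductance kernel: instant rise, exponential decay.

    ``kernel(0) = 1`` scaled by ``amplitude_ns``; closed-form integrals
    are ``integral w = tau`` and ``integral w^2 = tau/2`` (in seconds).
    """

    amplitude_ns: float = 0.6
    tau_ms: float = 2.0

    def kernel(self, sampling_rate: float, n_taus: float = 10.0) -> np.ndarray:
        n = max(2, int(round(n_taus * self.tau_ms * 1e-3 * sampling_rate)))
        t = np.arange(n) / sampling_rate
        return np.exp(-t / (self.tau_ms * 1e-3))


@dataclass(frozen=True)
class TonicExc:
    unit: UnitaryEvent = field(default_factory=UnitaryEvent)
    baseline_rate_hz: float = 1000.0
    light_gain: float = 1.0  # rate modulation per unit Weber contrast


@dataclass(frozen=True)
class TransientExc:
    """Rectified cone-driven transient at On-phase onsets (deterministic)."""

    amplitude_ns: float = 8.0
    latency_ms: float = 5.0
    decay_ms: float = 40.0
    rectification_threshold: float = 0.0  # min contrast step that triggers it


@dataclass(frozen=True)
class TransientInh:
    amplitude_ns: float = 2.0
    latency_ms: float = 10.0
    decay_ms: float = 30.0


#: Default pharmacological factor maps. Missing keys mean "factor 1".
DEFAULT_DRUG_SENSITIVITY: Dict[str, Dict[str, float]] = {
    "control": {},
    "IEM": {"tonic_exc": 0.0},
    "AP5": {"nmda": 0.0},
    "AP5+IEM": {"nmda": 0.0, "tonic_exc": 0.0},
    "inhibitors": {"inhibition": 0.0},
    "inhibitors+IEM": {"inhibition": 0.0, "tonic_exc": 0.0},
    "MFA": {"tonic_exc": 0.0},
    "MFA+IEM": {"tonic_exc": 0.0},
}

_COMPONENTS = ("tonic_exc", "transient_exc", "nmda", "inhibition")


@dataclass(frozen=True)
class SynapticDriveSpec:
    """Generative parameters for the synaptic drive of one model cell."""

    tonic_exc: TonicExc = field(default_factory=TonicExc)
    transient_exc: TransientExc = field(default_factory=TransientExc)
    nmda_fraction: float = 0.2
    inhibition: TransientInh = field(default_factory=TransientInh)
    drug_sensitivity: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DRUG_SENSITIVITY.items()}
    )
    # Multiplicative factors already folded in by apply_condition.
    applied_factors: Dict[str, float] = field(
        default_factory=lambda: {k: 1.0 for k in _COMPONENTS}
    )

    def __post_init__(self):
        if not 0.0 <= self.nmda_fraction < 1.0:
            raise ValueError("nmda_fraction must lie in [0, 1)")
        if any(f < 0 for f in self.applied_factors.values()):
            raise ValueError("drug factors must be >= 0")

    def condition_factors(self, condition: str) -> Dict[str, float]:
        if condition not in self.drug_sensitivity:
            raise KeyError(f"unknown condition {condition!r}")
        fac = {k: 1.0 for k in _COMPONENTS}
        fac.update(self.drug_sensitivity[condition])
        for k in _COMPONENTS:
            fac[k] *= self.applied_factors.get(k, 1.0)
        return fac


def apply_condition(spec: SynapticDriveSpec, condition: str) -> SynapticDriveSpec:
    """Fold a condition's multiplicative factors into the spec.

    Control is the identity. Conditions compose multiplicatively, so two
    conditions that each zero the tonic component occlude each other:
    applying both equals applying either alone to that component.
    """
    fac = spec.condition_factors(condition)
    return replace(spec, applied_factors=fac)


# ---------------------------------------------------------------------------
# Stimulus and conductance generation
# ---------------------------------------------------------------------------

def make_stimulus(spec: StimulusSpec, sampling_rate: float) -> np.ndarray:
    """Square-wave intensity trace (Rh*/rod/s), symmetric about background.

    The first half-cycle after ``phase_zero`` is the On-phase at L_max;
    before ``phase_zero`` the trace sits at the background.
    """
    n = int(round(spec.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    trace = np.full(n, spec.background_intensity)
    active = t >= spec.phase_zero
    phase = (t[active] - spec.phase_zero) * spec.frequency % 1.0
    trace[active] = np.where(phase < 0.5, spec.l_max, spec.l_min)
    return trace


def contrast_signal(intensity: np.ndarray, background: float) -> np.ndarray:
    """Weber contrast (L - L_bg)/L_bg of an intensity trace."""
    if background <= 0:
        raise ValueError("background intensity must be positive")
    return (np.asarray(intensity, dtype=float) - background) / background


def shot_noise_conductance(
    rate_hz: np.ndarray,
    unit: UnitaryEvent,
    sampling_rate: float,
    seed: int,
) -> np.ndarray:
    """Inhomogeneous-Poisson shot-noise conductance trace (nS).

    Exact sampling of the continuous-time process: event counts per
    sample interval are Poisson(rate * dt), each event receives a
    uniform sub-interval time, and the exponentially decaying unitary
    kernel is evaluated at the true event-to-sample lags (a per-event
    weight at the first sample after the event followed by a discrete
    exponential decay). Sample moments are therefore unbiased for the
    Campbell-theorem values. A warm-up pad of 10 decay constants at the
    initial rate makes the returned trace stationary from sample 0.
    Reproducible for a given seed.
    """
    rate = np.asarray(rate_hz, dtype=float)
    if np.any(rate < 0):
        raise ValueError("event rate must be >= 0")
    rng = np.random.default_rng(seed)
    tau_samples = unit.tau_ms * 1e-3 * sampling_rate
    n_pad = int(round(10.0 * tau_samples))
    full_rate = np.concatenate([np.full(n_pad, rate[0] if rate.size else 0.0), rate])
    counts = rng.poisson(full_rate / sampling_rate)
    total = int(counts.sum())
    if total == 0:
        return np.zeros_like(rate)
    # per-event decay from the (uniform) event time to the next sample
    bins = np.repeat(np.arange(full_rate.size), counts)
    u = rng.random(total)  # event position within the interval, in samples
    weights = np.exp(-(1.0 - u) / tau_samples)
    impulses = np.zeros(full_rate.size)
    np.add.at(impulses, bins, weights)
    kernel = unit.kernel(sampling_rate)
    g = fftconvolve(impulses, kernel)[n_pad : n_pad + rate.size]
    return unit.amplitude_ns * g


def _onset_transient(
    contrast: np.ndarray,
    sampling_rate: float,
    amplitude_ns: float,
    latency_ms: float,
    decay_ms: float,
    rectification_threshold: float = 0.0,
) -> np.ndarray:
    """Exponential transient triggered by positive contrast steps only."""
    steps = np.diff(contrast, prepend=contrast[0])
    onsets = np.flatnonzero(steps > rectification_threshold)
    out = np.zeros_like(contrast)
    if amplitude_ns == 0 or onsets.size == 0:
        return out
    lat = int(round(latency_ms * 1e-3 * sampling_rate))
    n_kern = max(2, int(round(8 * decay_ms * 1e-3 * sampling_rate)))
    kern = np.exp(-np.arange(n_kern) / (decay_ms * 1e-3 * sampling_rate))
    for i in onsets:
        start = i + lat
        if start >= contrast.size:
            continue
        stop = min(contrast.size, start + n_kern)
        out[start:stop] += amplitude_ns * kern[: stop - start]
    return out


@dataclass
class DriveTraces:
    """Synaptic conductance traces plus component-level ground truth (nS)."""

    g_exc_ampa: np.ndarray
    g_nmda_scalefree: np.ndarray  # conductance at full Mg unblock
    g_inh: np.ndarray
    sampling_rate: float
    ground_truth: Dict[str, np.ndarray]

    @property
    def n_samples(self) -> int:
        return self.g_exc_ampa.size


def build_synaptic_drive(
    spec: SynapticDriveSpec,
    intensity: np.ndarray,
    background: float,
    sampling_rate: float,
    condition: str = "control",
    seed: int = 0,
) -> DriveTraces:
    """Compose the synaptic conductance drive for one trial.

    The tonic shot-noise rate is modulated multiplicatively by the
    stimulus contrast (up during On, down during Off); the transient
    component fires at On-phase onsets; the NMDA-type conductance
    carries ``nmda_fraction`` of the excitatory drive (scale-free, i.e.
    before Mg block); all components are scaled by the condition's drug
    factors. Component ground truth is returned for recovery tests.
    """
    fac = spec.condition_factors(condition)
    contrast = contrast_signal(intensity, background)

    rate = spec.tonic_exc.baseline_rate_hz * np.clip(
        1.0 + spec.tonic_exc.light_gain * contrast, 0.0, None
    )
    g_tonic = fac["tonic_exc"] * shot_noise_conductance(
        rate, spec.tonic_exc.unit, sampling_rate, seed
    )
    g_transient = fac["transient_exc"] * _onset_transient(
        contrast,
        sampling_rate,
        spec.transient_exc.amplitude_ns,
        spec.transient_exc.latency_ms,
        spec.transient_exc.decay_ms,
        spec.transient_exc.rectification_threshold,
    )
    g_inh = fac["inhibition"] * _onset_transient(
        contrast,
        sampling_rate,
        spec.inhibition.amplitude_ns,
        spec.inhibition.latency_ms,
        spec.inhibition.decay_ms,
    )
    f = spec.nmda_fraction
    g_exc_total = g_tonic + g_transient
    g_ampa = (1.0 - f) * g_exc_total
    g_nmda = fac["nmda"] * f * g_exc_total
    return DriveTraces(
        g_exc_ampa=g_ampa,
        g_nmda_scalefree=g_nmda,
        g_inh=g_inh,
        sampling_rate=sampling_rate,
        ground_truth={
            "tonic": g_tonic,
            "transient": g_transient,
            "nmda": g_nmda,
            "inhibition": g_inh,
            "exc_ampa": g_ampa,
        },
    )


# ---------------------------------------------------------------------------
# Clamp simulations
# ---------------------------------------------------------------------------

def clamp_current_pa(
    cell: CellModel,
    v_mv: float | np.ndarray,
    g_exc: np.ndarray,
    g_inh: np.ndarray,
    g_nmda: np.ndarray,
    include_leak: bool = True,
) -> np.ndarray:
    """Membrane current for given conductances at potential V (pA).

    I = G_exc (V-E_exc) + G_inh (V-E_inh) + G_nmda B(V) (V-E_exc)
        [+ g_leak (V-E_leak)];   nS x mV -> pA, inward negative.
    """
    b = cell.mg_block(v_mv)
    i = (
        g_exc * (v_mv - cell.e_exc_mv)
        + g_inh * (v_mv - cell.e_inh_mv)
        + g_nmda * b * (v_mv - cell.e_exc_mv)
    )
    if include_leak:
        i = i + cell.g_leak_ns * (v_mv - cell.e_leak_mv)
    return i


def simulate_voltage_clamp(
    cell: CellModel,
    drive: DriveTraces,
    v_hold: float,
    cell_id: str = "sim",
    condition: str = "control",
    trial_index: int = 0,
) -> SweepRecord:
    """Ideal voltage clamp: algebraic current at the held potential.

    No series-resistance error is modeled, so the recorded current is an
    exact linear function of each conductance trace. The returned
    holding potential is flagged junction-corrected (the simulation
    works in true membrane potential).
    """
    for g in (drive.g_inh, drive.g_nmda_scalefree):
        if g.shape != drive.g_exc_ampa.shape:
            raise ValueError("conductance traces must share the sampling grid")
    current = clamp_current_pa(
        cell, v_hold, drive.g_exc_ampa, drive.g_inh, drive.g_nmda_scalefree
    )
    return SweepRecord(
        cell_id=cell_id,
        modality=Modality.VOLTAGE_CLAMP,
        sampling_rate=drive.sampling_rate,
        signal=current,
        holding_potential=v_hold,
        ljp_corrected=True,
        condition=condition,
        trial_index=trial_index,
    )


def _spike_waveform(mech: SpikeMechanism, sampling_rate: float) -> np.ndarray:
    """Stereotyped depolarizing transient pasted at each spike (mV, relative)."""
    n = max(3, int(round(mech.waveform_width_ms * 1e-3 * sampling_rate)))
    return mech.waveform_amplitude_mv * np.sin(np.linspace(0.0, np.pi, n))


def simulate_current_clamp(
    cell: CellModel,
    drive: DriveTraces,
    cell_id: str = "sim",
    condition: str = "control",
    trial_index: int = 0,
) -> Tuple[SweepRecord, np.ndarray]:
    """Leaky integrate-and-fire simulation; returns (sweep, true spike times).

    Forward-Euler integration of
    C dV/dt = -[G_exc (V-E_exc) + G_inh (V-E_inh)
               + G_nmda B(V) (V-E_exc) + g_leak (V-E_leak)].
    When V crosses threshold the spike time is recorded, a stereotyped
    spike waveform is pasted onto the voltage trace for detector
    realism, and V is held at reset for the refractory period. Raises
    if the time step exceeds tau_membrane/10.
    """
    mech = cell.spike_mechanism
    if mech is None:
        raise ValueError("spike_mechanism required for current-clamp simulation")
    fs = drive.sampling_rate
    dt_ms = 1e3 / fs
    if cell.g_leak_ns > 0:
        tau_m_ms = cell.capacitance_pf / cell.g_leak_ns
        if dt_ms > tau_m_ms / 10.0:
            raise ValueError(
                f"time step {dt_ms:.3g} ms too coarse for tau_m {tau_m_ms:.3g} ms"
            )
    n = drive.n_samples
    ge, gi, gn = drive.g_exc_ampa, drive.g_inh, drive.g_nmda_scalefree
    v = np.empty(n)
    v[0] = cell.e_leak_mv
    refr_samples = int(round(mech.refractory_ms * 1e-3 * fs))
    spikes = []
    mg = cell.mg_block
    c = cell.capacitance_pf
    hold_until = -1
    vi = cell.e_leak_mv
    for i in range(1, n):
        if i <= hold_until:
            v[i] = mech.reset_mv
            vi = mech.reset_mv
            continue
        i_mem = (
            ge[i - 1] * (vi - cell.e_exc_mv)
            + gi[i - 1] * (vi - cell.e_inh_mv)
            + gn[i - 1] * mg(vi) * (vi - cell.e_exc_mv)
            + cell.g_leak_ns * (vi - cell.e_leak_mv)
        )
        vi = vi - dt_ms * i_mem / c  # pA / pF * ms -> mV
        if vi >= mech.threshold_mv:
            spikes.append(i / fs)
            hold_until = i + refr_samples
            vi = mech.reset_mv
            v[i] = mech.threshold_mv
        else:
            v[i] = vi
    # Paste the stereotyped spike transient after integration so the
    # dynamics are pure LIF but the detector sees realistic events.
    wf = _spike_waveform(mech, fs)
    for t_sp in spikes:
        j = int(round(t_sp * fs))
        stop = min(n, j + wf.size)
        v[j:stop] += wf[: stop - j]
    sweep = SweepRecord(
        cell_id=cell_id,
        modality=Modality.CURRENT_CLAMP,
        sampling_rate=fs,
        signal=v,
        condition=condition,
        trial_index=trial_index,
    )
    return sweep, np.asarray(spikes)


def lif_constant_drive_rate(
    cell: CellModel, g_exc_ns: float, g_inh_ns: float = 0.0
) -> float:
    """Closed-form firing rate (Hz) of the LIF under constant conductances.

    Zero if the steady-state voltage does not reach threshold.
    """
    mech = cell.spike_mechanism
    g_tot = cell.g_leak_ns + g_exc_ns + g_inh_ns
    v_inf = (
        cell.g_leak_ns * cell.e_leak_mv
        + g_exc_ns * cell.e_exc_mv
        + g_inh_ns * cell.e_inh_mv
    ) / g_tot
    if v_inf <= mech.threshold_mv:
        return 0.0
    tau_ms = cell.capacitance_pf / g_tot
    t_isi_ms = mech.refractory_ms + tau_ms * math.log(
        (v_inf - mech.reset_mv) / (v_inf - mech.threshold_mv)
    )
    return 1e3 / t_isi_ms


# ---------------------------------------------------------------------------
# Canonical scenario defaults
# ---------------------------------------------------------------------------

def default_on_gc_cell(spiking: bool = True) -> CellModel:
    """Model On-ganglion cell used by the worked analyses."""
    return CellModel(
        capacitance_pf=60.0,
        g_leak_ns=4.0,
        e_leak_mv=-65.0,
        spike_mechanism=SpikeMechanism() if spiking else None,
    )


def default_on_gc_drive() -> SynapticDriveSpec:
    """Model On-ganglion-cell drive: tonic CP-AMPAR shot noise modulated
    by the stimulus, a large IEM-resistant transient at On-onset, a
    modest NMDA fraction, and transient On-phase inhibition."""
    return SynapticDriveSpec()


def default_stimulus(duration: float = 2.3, phase_zero: float = 0.3) -> StimulusSpec:
    """1 Hz, 80%-contrast square wave on a ~600 Rh*/rod/s background,
    preceded by a pre-stimulus epoch at the background intensity."""
    return StimulusSpec(duration=duration, phase_zero=phase_zero)
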