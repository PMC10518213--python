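"""Shared data model for recorded and simulated sweeps.

Units are fixed package-wide: membrane potential in mV, current in pA,
conductance in nS, time in seconds for sweep-level quantities (sampling
rates in Hz), milliseconds only where a field name says so. Inward
current is negative. Sample 0 sits at t = 0 and bins are half-open
[t, t + dt).
"""
from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np


class Modality(str, enum.Enum):
    """Recording configuration of a sweep."""

    EXTRACELLULAR = "extracellular"
    CURRENT_CLAMP = "current_clamp"
    VOLTAGE_CLAMP = "voltage_clamp"


#: Conditions understood by the drug-sensitivity machinery. ``custom`` is a
#: free-form escape hatch; everything else maps to a factor transform.
KNOWN_CONDITIONS = (
    "control",
    "IEM",
    "AP5",
    "AP5+IEM",
    "inhibitors",
    "inhibitors+IEM",
    "MFA",
    "MFA+IEM",
    "custom",
)


class SchemaError(ValueError):
    """A sweep or dataset violates the data-model schema."""


class StateError(RuntimeError):
    """An operation was applied in an invalid state (e.g. double LJP correction)."""


@dataclass
class SweepRecord:
    """One recorded or simulated trial of a time series.

    ``signal`` holds pA for voltage clamp and mV otherwise.
    ``holding_potential`` is required exactly when the modality is
    voltage clamp.
    """

    cell_id: str
    modality: Modality
    sampling_rate: float
    signal: np.ndarray
    holding_potential: Optional[float] = None
    ljp_corrected: bool = False
    condition: str = "control"
    trial_index: int = 0
    stimulus_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.modality = Modality(self.modality)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 1:
            raise SchemaError("signal must be one-dimensional")
        if not self.sampling_rate > 0:
            raise SchemaError("sampling_rate must be positive")
        if self.trial_index < 0:
            raise SchemaError("trial_index must be >= 0")
        if self.modality is Modality.VOLTAGE_CLAMP:
            if self.holding_potential is None:
                raise SchemaError(
                    "voltage_clamp sweep requires a holding_potential"
                )
        elif self.holding_potential is not None:
            raise SchemaError(
                "holding_potential only applies to voltage_clamp sweeps"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.size

    @property
    def duration(self) -> float:
        """Sweep duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, sample 0 at t = 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def replace(self, **kwargs) -> "SweepRecord":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StimulusSpec:
    """Square-wave contrast-modulated spot stimulus.

    Contrast follows the convention
    ``contrast_percent = 100 * (L_max - L_min) / L_background`` with the
    modulation split symmetrically about the background, so an 80%
    contrast on a 600 Rh*/rod/s background swings between 840 and 360.
    The first half-cycle after ``phase_zero`` is the On-phase.
    """

    background_intensity: float = 600.0  # Rh*/rod/s
    contrast_percent: float = 80.0
    frequency: float = 1.0  # Hz
    spot_diameter: float = 300.0  # um; carried as metadata only
    duration: float = 2.0  # s
    phase_zero: float = 0.0  # s, first On-phase onset

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast_percent <= 100.0:
            raise ValueError(
                "contrast_percent must lie in [0, 100] under the "
                "symmetric-modulation convention (L_min would go negative)"
            )
        if self.background_intensity < 0:
            raise ValueError("background_intensity must be >= 0")

    @property
    def l_max(self) -> float:
        return self.background_intensity * (1.0 + self.contrast_percent / 200.0)

    @property
    def l_min(self) -> float:
        return self.background_intensity * (1.0 - self.contrast_percent / 200.0)


# Preset liquid-junction-potential corrections, in mV (negative by
# convention): the Cs-internal GC recordings, the conductance-analysis
# stage, and the AII-amacrine Cs internal each use a different value, so
# they are carried as metadata rather than hard-coded.
LJP_PRESETS = {
    "cs_internal_gc": -16.0,
    "conductance_analysis": -13.0,
    "aii_cs_internal": -15.0,
}


@dataclass(frozen=True)
class JunctionCorrection:
    """Liquid-junction-potential correction applied to voltage-valued fields."""

    ljp: float
    applies_to: str = "custom"

    @classmethod
    def preset(cls, name: str) -> "JunctionCorrection":
        try:
            return cls(ljp=LJP_PRESETS[name], applies_to=name)
        except KeyError:
            raise KeyError(
                f"unknown LJP preset {name!r}; known: {sorted(LJP_PRESETS)}"
            ) from None


def correct_junction_potential(
    sweep: SweepRecord, corr: JunctionCorrection
) -> SweepRecord:
    """Shift voltage-valued fields of ``sweep`` by the LJP.

    For voltage modalities the signal itself is shifted; for voltage
    clamp only the holding potential moves (the signal is a current and
    is left untouched). Applying a correction twice is a state error.
    """
    if sweep.ljp_corrected:
        raise StateError("sweep is already junction-corrected")
    if sweep.modality is Modality.VOLTAGE_CLAMP:
        return sweep.replace(
            holding_potential=sweep.holding_potential + corr.ljp,
            ljp_corrected=True,
        )
    return sweep.replace(signal=sweep.signal + corr.ljp, ljp_corrected=True)


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix on the log(TPM+1) scale with cluster labels."""

    values: np.ndarray  # (n_cells, n_genes), >= 0
    cluster_labels: Sequence[str]
    gene_ids: Sequence[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cluster_labels = list(self.cluster_labels)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2:
            raise SchemaError("values must be 2-D (cells x genes)")
        if np.any(self.values < 0):
            raise SchemaError("log(TPM+1) values cannot be negative")
        if len(self.cluster_labels) != self.values.shape[0]:
            raise SchemaError("one cluster label required per cell")
        if len(self.gene_ids) != self.values.shape[1]:
            raise SchemaError("one gene id required per gene column")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise SchemaError("gene_ids must be unique")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def cluster_mask(self, cluster: str) -> np.ndarray:
        mask = np.asarray([lbl == cluster for lbl in self.cluster_labels])
        if not mask.any():
            raise KeyError(f"unknown or empty cluster {cluster!r}")
        return mask


def sweep_sort_key(sweep: SweepRecord):
    """Stable ordering used by the dataset loader/saver."""
    return (sweep.cell_id, sweep.condition, sweep.trial_index)


def _asdict(sweep: SweepRecord) -> dict:
    d = dataclasses.asdict(sweep)
    d["modality"] = sweep.modality.value
    d.pop("signal")
    return d
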