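"""Synaptic conductance estimation from voltage-clamp I-V families.

Net light-evoked currents are measured at a family of holding
potentials, binned at 10-ms intervals, and each bin's current-voltage
relation is decomposed by least squares into excitatory, inhibitory and
(optionally) NMDA-type components,

    I(V) = G_exc (V - E_exc) + G_inh (V - E_inh) + G_nmda B(V) (V - E_exc),

with assumed reversal potentials E_exc = 0 mV and E_inh = -70 mV and a
sigmoidal Mg-block factor B(V). Conductances are not constrained to be
non-negative: negative values are meaningful and indicate suppression of
a baseline (pre-stimulus) conductance, because the currents entering the
fit are baseline-subtracted per potential.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import Modality, SweepRecord
from .synthetic import MgBlock

DEFAULT_E_EXC = 0.0
DEFAULT_E_INH = -70.0


class ConditioningWarning(UserWarning):
    """The I-V design matrix is nearly singular for the supplied potentials."""


@dataclass
class IVSeries:
    """Binned current-voltage relations on a common 10-ms grid.

    ``currents_pa`` has shape (n_bins, n_potentials); ``potentials_mv``
    are junction-corrected holding potentials.
    """

    time_grid_ms: np.ndarray  # bin centers
    potentials_mv: np.ndarray
    currents_pa: np.ndarray
    n_sweeps_per_potential: np.ndarray
    bin_width_ms: float = 10.0

    def __post_init__(self):
        self.time_grid_ms = np.asarray(self.time_grid_ms, dtype=float)
        self.potentials_mv = np.asarray(self.potentials_mv, dtype=float)
        self.currents_pa = np.asarray(self.currents_pa, dtype=float)
        if self.currents_pa.shape != (
            self.time_grid_ms.size,
            self.potentials_mv.size,
        ):
            raise ValueError("currents must be (n_bins, n_potentials)")
        if np.unique(self.potentials_mv).size < 2:
            raise ValueError("at least 2 distinct potentials required")


@dataclass
class ConductanceTrace:
    """Time-resolved decomposed synaptic conductances (nS)."""

    time_grid_ms: np.ndarray
    g_exc_ns: np.ndarray
    g_inh_ns: np.ndarray
    g_nmda_ns: np.ndarray  # scale at full Mg unblock; zeros if not fitted
    rmse_pa: np.ndarray
    e_exc_mv: float = DEFAULT_E_EXC
    e_inh_mv: float = DEFAULT_E_INH
    mg_block_record: dict = field(default_factory=dict)
    condition_number: float = np.nan
    nmda_fitted: bool = True

    def __post_init__(self):
        for name in ("g_exc_ns", "g_inh_ns", "g_nmda_ns", "rmse_pa", "time_grid_ms"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.rmse_pa < 0):
            raise ValueError("RMSE must be >= 0")


@dataclass
class LinearIVFit:
    """Least-squares line through (V, I) points: slope in nS, reversal in mV."""

    conductance_ns: float
    reversal_mv: float
    r_squared: float
    n_points: int
    degenerate: bool = False  # reversal undefined (zero slope)


def net_light_evoked(
    sweeps: Sequence[SweepRecord], baseline_window_s: Tuple[float, float] = (0.0, 0.3)
) -> np.ndarray:
    """Trial-averaged current minus its own pre-stimulus baseline mean (pA).

    All sweeps must be voltage clamp at the same junction-corrected
    holding potential; per-potential baseline subtraction removes leak
    and tonic offsets at that potential.
    """
    if not sweeps:
        raise ValueError("no sweeps supplied")
    v0 = sweeps[0].holding_potential
    fs = sweeps[0].sampling_rate
    for sw in sweeps:
        if sw.modality is not Modality.VOLTAGE_CLAMP:
            raise ValueError("net_light_evoked requires voltage-clamp sweeps")
        if sw.holding_potential != v0 or sw.sampling_rate != fs:
            raise ValueError("sweeps must share holding potential and time base")
    mean = np.mean([sw.signal for sw in sweeps], axis=0)
    a = int(round(baseline_window_s[0] * fs))
    b = int(round(baseline_window_s[1] * fs))
    if b <= a or b > mean.size:
        raise ValueError("baseline window outside sweep")
    return mean - mean[a:b].mean()


def build_iv_series(
    net_traces: Dict[float, np.ndarray],
    sampling_rate: float,
    bin_width_ms: float = 10.0,
) -> IVSeries:
    """Average net currents in 10-ms bins to one (V, I) point per bin."""
    if len(net_traces) < 2:
        raise ValueError("at least 2 holding potentials required")
    potentials = np.array(sorted(net_traces))
    n = {len(tr) for tr in net_traces.values()}
    if len(n) != 1:
        raise ValueError("net traces must share a common time base")
    n = n.pop()
    samples_per_bin = int(round(bin_width_ms * 1e-3 * sampling_rate))
    n_bins = n // samples_per_bin
    centers = (np.arange(n_bins) + 0.5) * bin_width_ms
    currents = np.empty((n_bins, potentials.size))
    for j, v in enumerate(potentials):
        tr = np.asarray(net_traces[v], dtype=float)[: n_bins * samples_per_bin]
        currents[:, j] = tr.reshape(n_bins, samples_per_bin).mean(axis=1)
    return IVSeries(
        time_grid_ms=centers,
        potentials_mv=potentials,
        currents_pa=currents,
        n_sweeps_per_potential=np.ones(potentials.size, dtype=int),
        bin_width_ms=bin_width_ms,
    )


def fit_linear_iv(points: Sequence[Tuple[float, float]]) -> LinearIVFit:
    """Least-squares line through (V, I); slope is the conductance in nS.

    The reversal potential is the zero-current crossing -intercept/slope;
    for a zero-slope (flat) relation it is undefined and flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("at least 2 (V, I) points required")
    v, i = pts[:, 0], pts[:, 1]
    if np.unique(v).size < 2:
        raise ValueError("all potentials identical: singular fit")
    res = stats.linregress(v, i)
    slope, intercept = res.slope, res.intercept
    if slope == 0.0:
        return LinearIVFit(0.0, float("nan"), res.rvalue**2, pts.shape[0], True)
    return LinearIVFit(
        conductance_ns=float(slope),
        reversal_mv=float(-intercept / slope),
        r_squared=float(res.rvalue**2),
        n_points=pts.shape[0],
    )


def _design_matrix(
    potentials: np.ndarray,
    e_exc: float,
    e_inh: float,
    mg_block: Optional[MgBlock],
    fit_nmda: bool,
) -> np.ndarray:
    cols = [potentials - e_exc, potentials - e_inh]
    if fit_nmda:
        cols.append(mg_block(potentials) * (potentials - e_exc))
    return np.column_stack(cols)


def decompose_conductances(
    iv: IVSeries,
    mg_block: Optional[MgBlock] = None,
    fit_nmda: bool = True,
    e_exc: float = DEFAULT_E_EXC,
    e_inh: float = DEFAULT_E_INH,
    weights: Optional[np.ndarray] = None,
    condition_threshold: float = 1e6,
) -> ConductanceTrace:
    """Per-bin least-squares decomposition of the I-V relations.

    Each 10-ms bin's (V, I) points are solved for (G_exc, G_inh[,
    G_nmda]) with the reversal potentials fixed by assumption, not
    re-fit. ``fit_nmda`` is a per-cell-type choice (on for cells with
    nonlinear excitatory I-V, off where a linear I-V suffices).
    Non-negativity is NOT imposed: negative conductances are
    interpretable as suppression of baseline input. Equal weights by
    default; per-potential weights (e.g. trial counts) may be supplied.
    """
    if fit_nmda and mg_block is None:
        mg_block = MgBlock()
    n_components = 3 if fit_nmda else 2
    if iv.potentials_mv.size < n_components:
        raise ValueError(
            f"{iv.potentials_mv.size} potentials cannot determine "
            f"{n_components} components"
        )
    X = _design_matrix(iv.potentials_mv, e_exc, e_inh, mg_block, fit_nmda)
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        Xw = X * w[:, None]
        Yw = iv.currents_pa * w[None, :]
    else:
        Xw, Yw = X, iv.currents_pa
    cond = float(np.linalg.cond(Xw))
    if cond > condition_threshold:
        warnings.warn(
            f"I-V design matrix nearly singular (condition number {cond:.3g}); "
            "NMDA and linear components are close to collinear over the "
            "supplied potentials",
            ConditioningWarning,
        )
    coef, *_ = np.linalg.lstsq(Xw, Yw.T, rcond=None)
    fitted = (X @ coef).T
    rmse = np.sqrt(np.mean((iv.currents_pa - fitted) ** 2, axis=1))
    g_nmda = coef[2] if fit_nmda else np.zeros(iv.time_grid_ms.size)
    return ConductanceTrace(
        time_grid_ms=iv.time_grid_ms,
        g_exc_ns=coef[0],
        g_inh_ns=coef[1],
        g_nmda_ns=g_nmda,
        rmse_pa=rmse,
        e_exc_mv=e_exc,
        e_inh_mv=e_inh,
        mg_block_record=mg_block.as_record() if mg_block is not None else {},
        condition_number=cond,
        nmda_fitted=fit_nmda,
    )


def reconstruct_currents(g: ConductanceTrace, v_hold: float) -> np.ndarray:
    """Forward model evaluated at one holding potential (pA per 10-ms bin)."""
    if not (
        np.all(np.isfinite(g.g_exc_ns))
        and np.all(np.isfinite(g.g_inh_ns))
        and np.all(np.isfinite(g.g_nmda_ns))
    ):
        raise ValueError("conductance trace contains non-finite values")
    i = g.g_exc_ns * (v_hold - g.e_exc_mv) + g.g_inh_ns * (v_hold - g.e_inh_mv)
    if g.nmda_fitted and g.mg_block_record:
        mg = MgBlock(
            mg_mM=g.mg_block_record["mg_mM"],
            steepness_mv=g.mg_block_record["steepness_mv"],
            conc_scale_mM=g.mg_block_record["conc_scale_mM"],
        )
        i = i + g.g_nmda_ns * mg(v_hold) * (v_hold - g.e_exc_mv)
    return i


def difference_conductance(
    ctrl: ConductanceTrace, drug: ConductanceTrace
) -> ConductanceTrace:
    """Component-wise control-minus-drug conductance (e.g. the
    CP-AMPAR-antagonist-sensitive component)."""
    if not np.array_equal(ctrl.time_grid_ms, drug.time_grid_ms):
        raise ValueError("time grids differ")
    if ctrl.mg_block_record != drug.mg_block_record:
        raise ValueError("Mg-block records differ between fits")
    return ConductanceTrace(
        time_grid_ms=ctrl.time_grid_ms.copy(),
        g_exc_ns=ctrl.g_exc_ns - drug.g_exc_ns,
        g_inh_ns=ctrl.g_inh_ns - drug.g_inh_ns,
        g_nmda_ns=ctrl.g_nmda_ns - drug.g_nmda_ns,
        rmse_pa=np.zeros_like(ctrl.rmse_pa),
        e_exc_mv=ctrl.e_exc_mv,
        e_inh_mv=ctrl.e_inh_mv,
        mg_block_record=dict(ctrl.mg_block_record),
        nmda_fitted=ctrl.nmda_fitted or drug.nmda_fitted,
    )


def timecourse_similarity(
    g_a: np.ndarray, g_b: np.ndarray
) -> Tuple[float, float]:
    """Best scale factor and Pearson correlation between two time courses.

    ``scale`` minimizes sum (g_a - s * g_b)^2 in closed form
    (sum a*b / sum b^2) — e.g. the factor ~4 relating the antagonist-
    sensitive excitatory components of two cell types. A flat reference
    trace leaves the scale undefined (NaN).
    """
    a = np.asarray(g_a, dtype=float)
    b = np.asarray(g_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("traces must share a common grid")
    denom = float(np.dot(b, b))
    if denom == 0.0:
        return float("nan"), float("nan")
    scale = float(np.dot(a, b) / denom)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        corr = float("nan")
    else:
        corr = float(stats.pearsonr(a, b).statistic)
    return scale, corr
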