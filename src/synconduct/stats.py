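"""Baseline noise statistics, the Campbell-theorem oracle, and group tests.

A tonically depolarized cell receiving many large unitary EPSCs shows a
baseline mean and variance linked by Campbell's theorem for Poisson shot
noise: mean = rate * integral(kernel) and variance = rate *
integral(kernel^2). These closed forms are the independent oracle
against which the simulated tonic current at a fixed holding potential
is checked. Group comparisons follow the reporting pipeline of the
recordings: Shapiro-Wilk normality check (advisory only), paired or
unpaired two-tailed t-test, Bonferroni correction, alpha = 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .datamodel import Modality, SweepRecord
from .spikes import SpikeTrain, blank_spikes, detect_spikes
from .synthetic import UnitaryEvent

ALPHA = 0.05


@dataclass
class BaselineStats:
    """Mean and SD of a signal over a baseline window (mV or pA)."""

    mean: float
    sd: float
    window_s: Tuple[float, float]
    blanked: bool
    modality: Modality

    @property
    def variance(self) -> float:
        return self.sd**2


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    test: str  # "paired_t" | "unpaired_t"
    t_statistic: float
    p_value: float
    normality_p: float
    correction: str
    m_comparisons: int
    p_adjusted: float
    alpha: float = ALPHA
    normality_warning: bool = False
    degenerate: bool = False


def baseline_stats(
    sweep: SweepRecord,
    window_s: Tuple[float, float],
    blank: bool = False,
    spikes: Optional[SpikeTrain] = None,
) -> BaselineStats:
    """Mean and SD of the (optionally spike-blanked) signal over a window.

    For current-clamp voltage noise the spikes must be blanked first so
    the SD mostly reflects subthreshold fluctuations; the blanking is
    run on the whole sweep before windowing. If ``blank`` is set and no
    spike train is supplied, the derivative detector is run first.
    """
    a = int(round(window_s[0] * sweep.sampling_rate))
    b = int(round(window_s[1] * sweep.sampling_rate))
    if a < 0 or b > sweep.n_samples or b <= a:
        raise ValueError("baseline window outside sweep")
    sig_sweep = sweep
    if blank:
        if spikes is None:
            spikes = detect_spikes(sweep)
        sig_sweep = blank_spikes(sweep, spikes)
    seg = sig_sweep.signal[a:b]
    return BaselineStats(
        mean=float(np.mean(seg)),
        sd=float(np.std(seg)),
        window_s=(window_s[0], window_s[1]),
        blanked=blank,
        modality=sweep.modality,
    )


def campbell_moments(
    rate_hz: float, unit: UnitaryEvent, driving_force_mv: float = 1.0
) -> Tuple[float, float]:
    """Shot-noise mean (pA) and variance (pA^2) from Campbell's theorem.

    For an exponential unitary kernel of peak conductance A (nS) and
    decay tau (s), integral(w) = tau and integral(w^2) = tau/2, so with
    event rate nu (Hz) and driving force F (mV):

        mean     = nu * A * F * tau
        variance = nu * (A * F)^2 * tau / 2

    With F = 1 the same formulas give conductance moments (nS, nS^2).
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    tau_s = unit.tau_ms * 1e-3
    amp = unit.amplitude_ns * driving_force_mv
    return rate_hz * amp * tau_s, rate_hz * amp**2 * tau_s / 2.0


def compare_groups(
    a: Sequence[float],
    b: Sequence[float],
    design: str = "paired",
    m_comparisons: int = 1,
) -> GroupComparison:
    """Two-tailed t-test between two groups with Bonferroni adjustment.

    Normality of the analyzed distribution (paired differences for the
    paired design, pooled values otherwise) is checked with Shapiro-Wilk;
    a failure attaches a warning but does not switch tests. When both
    groups are constant and equal the comparison is degenerate and p is
    reported as 1 with a flag.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    if design == "paired":
        if x.size != y.size:
            raise ValueError("paired design requires equal group sizes")
        if x.size < 2:
            raise ValueError("paired design requires n >= 2")
        norm_sample = x - y
    else:
        norm_sample = np.concatenate([x, y])
    if np.ptp(norm_sample) == 0.0 or norm_sample.size < 3:
        normality_p = float("nan")
    else:
        normality_p = float(sps.shapiro(norm_sample).pvalue)
    degenerate = False
    if design == "paired":
        if np.all(x == y):
            t_stat, p = 0.0, 1.0
            degenerate = True
        else:
            res = sps.ttest_rel(x, y)
            t_stat, p = float(res.statistic), float(res.pvalue)
    else:
        if np.std(x) == 0 and np.std(y) == 0 and np.mean(x) == np.mean(y):
            t_stat, p = 0.0, 1.0
            degenerate = True
        else:
            res = sps.ttest_ind(x, y)
            t_stat, p = float(res.statistic), float(res.pvalue)
    correction = "bonferroni" if m_comparisons > 1 else "none"
    p_adj = min(1.0, m_comparisons * p) if correction == "bonferroni" else p
    return GroupComparison(
        mean_a=float(np.mean(x)),
        sd_a=float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        n_a=x.size,
        mean_b=float(np.mean(y)),
        sd_b=float(np.std(y, ddof=1)) if y.size > 1 else 0.0,
        n_b=y.size,
        test=f"{design}_t",
        t_statistic=t_stat,
        p_value=p,
        normality_p=normality_p,
        correction=correction,
        m_comparisons=m_comparisons,
        p_adjusted=p_adj,
        normality_warning=bool(normality_p < ALPHA)
        if np.isfinite(normality_p)
        else False,
        degenerate=degenerate,
    )
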