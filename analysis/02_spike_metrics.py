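#!/usr/bin/env python
"""PSTH response metrics per pharmacological condition.

Simulates 20-trial blocks of current-clamp sweeps for each condition,
detects spikes, builds 20-ms-bin PSTHs and extracts background, peak
and sustained firing rates. Reports the percent reductions relative to
control, and recomputes the printed worked percentages from the
reported group means as a cross-check of the reduction arithmetic.
"""
import pandas as pd

from synconduct.scenarios import simulate_condition_metrics
from synconduct.spikes import percent_change
from _util import RESULTS

SEED = 1
CONDITIONS = ("control", "IEM", "AP5", "MFA", "MFA+IEM", "inhibitors")

rows = []
metrics = {}
for condition in CONDITIONS:
    m = simulate_condition_metrics(condition, seed=SEED)
    metrics[condition] = m
    rows.append(
        {
            "condition": condition,
            "background_hz": round(m.background_rate_hz, 2),
            "peak_hz": round(m.peak_rate_hz, 2),
            "sustained_hz": round(m.sustained_rate_hz, 2),
        }
    )
df = pd.DataFrame(rows)
df.to_csv(RESULTS / "psth_metrics.tsv", sep="\t", index=False)
print(df.to_string(index=False))

ctrl = metrics["control"]
iem = metrics["IEM"]
print(
    "\nCP-AMPAR block: background falls "
    f"{percent_change(ctrl.background_rate_hz, iem.background_rate_hz)}%, "
    f"sustained {percent_change(ctrl.sustained_rate_hz, iem.sustained_rate_hz)}%, "
    f"peak only {percent_change(ctrl.peak_rate_hz, iem.peak_rate_hz)}% — the "
    "tonic pathway carries the sustained signal, the transient survives."
)
print(
    "Occlusion: MFA vs MFA+IEM background "
    f"{metrics['MFA'].background_rate_hz:.2f} vs "
    f"{metrics['MFA+IEM'].background_rate_hz:.2f} Hz (no further effect)."
)
print(
    "\nWorked reductions from the reported group means: "
    f"background 11.9->6.1 Hz = {percent_change(11.9, 6.1)}%, "
    f"peak 86.8->55.5 Hz = {percent_change(86.8, 55.5)}%, "
    f"sustained 18.7->1.2 Hz = {percent_change(18.7, 1.2)}%."
)
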