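#!/usr/bin/env python
"""Simulate a small On-ganglion-cell recording session and save it.

Generates current-clamp sweeps under control and CP-AMPAR-antagonist
(IEM) conditions and voltage-clamp sweeps across the nine-potential I-V
protocol, then writes them in the native sweep-table format so the
downstream scripts (and anyone inspecting the files) can work from a
concrete dataset. Full-size simulations are re-generated in memory by
the later scripts; this file keeps the saved dataset deliberately small.
"""
import numpy as np

import synconduct as sc
from synconduct.scenarios import IV_POTENTIALS
from synconduct.synthetic import (
    build_synaptic_drive,
    default_on_gc_cell,
    default_on_gc_drive,
    default_stimulus,
    make_stimulus,
    simulate_current_clamp,
    simulate_voltage_clamp,
)
from _util import RESULTS

SEED = 1
FS = 2000.0  # demo rate: keeps the saved table small, well inside LIF stability

stim = default_stimulus(duration=0.8, phase_zero=0.3)
intensity = make_stimulus(stim, FS)
spec = default_on_gc_drive()
sweeps = []

for condition in ("control", "IEM"):
    cell = default_on_gc_cell()
    for trial in range(3):
        drive = build_synaptic_drive(
            spec, intensity, stim.background_intensity, FS, condition,
            seed=SEED * 1000 + trial,
        )
        sw, _ = simulate_current_clamp(
            cell, drive, cell_id="gc1", condition=condition, trial_index=trial
        )
        sweeps.append(sw)

passive = default_on_gc_cell(spiking=False)
for j, v in enumerate(IV_POTENTIALS):
    drive = build_synaptic_drive(
        spec, intensity, stim.background_intensity, FS, "control", seed=SEED * 2000 + j
    )
    sweeps.append(
        simulate_voltage_clamp(
            passive, drive, float(v), cell_id="gc1", condition="control", trial_index=j
        )
    )

out = RESULTS / "simulated_sweeps.tsv"
sc.save_dataset(sweeps, out)
back = sc.load_dataset(out)
print(f"wrote {len(sweeps)} sweeps to {out} (round-trip check: {len(back)} loaded)")
print(
    "conditions:",
    sorted({s.condition for s in back}),
    "| modalities:",
    sorted({s.modality.value for s in back}),
)
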