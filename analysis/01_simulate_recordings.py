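#!/usr/bin/env python
"""Generate the synthetic dataset every downstream analysis consumes.

Two genotype scenarios are simulated per modality: a wild-type terminal
(resting calcium ~110 nM, replenishment 80 sites/s) and a calcium-handling
mutant (resting calcium ~265 nM, replenishment halved).  Outputs go to
scratch/simulated/ as plain CSV plus a ground-truth sidecar per trace.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from presynquant.io import train_protocol, write_roi_table, write_trace_table
from presynquant.simulate import (
    ImagingModel,
    PRESET_PROTOCOLS,
    preset,
    render_train_trace,
    simulate_mini_trace,
    simulate_phluorin,
    simulate_train,
)

OUT = Path("scratch/simulated")
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20260930
N_CELLS = 4

rows = []
for genotype, preset_name in (("wt", "wt_rest"), ("e373k", "e373k_rest")):
    for i in range(N_CELLS):
        model = preset(preset_name, seed=SEED + i + (0 if genotype == "wt" else 100))
        trace, events = simulate_mini_trace(model, duration=60.0)
        stem = f"minis_{genotype}_{i}"
        write_trace_table(trace, OUT / f"{stem}.csv")
        events.to_csv(OUT / f"{stem}_truth.csv", index=False, float_format="%.12g")
        rows.append({"file": f"{stem}.csv", "genotype": genotype,
                     "true_rate_hz": model.effective_mini_rate,
                     "n_events": len(events)})

proto = PRESET_PROTOCOLS["depletion_40hz"]
for g_off, (genotype, rate) in enumerate((("wt", 80.0), ("e373k", 40.0))):
    for i in range(N_CELLS):
        model = dataclasses.replace(
            preset("depletion_40hz", seed=SEED + 200 + 1000 * g_off + i),
            replenish_rate=rate, q_mean=10.0,
        )
        amps, truth = simulate_train(model, proto, mode="stochastic")
        trace = render_train_trace(amps, proto, model)
        stem = f"train40hz_{genotype}_{i}"
        write_trace_table(trace, OUT / f"{stem}.csv")
        truth.to_csv(OUT / f"{stem}_truth.csv", index=False, float_format="%.12g")
        rows.append({"file": f"{stem}.csv", "genotype": genotype,
                     "true_rate_hz": None, "n_events": proto.n_stim})

for genotype, tau in (("wt", 12.0), ("e373k", 24.0)):
    imaging = ImagingModel(tau_endo=tau, noise_cv=0.01, seed=SEED + 300)
    roi, truth = simulate_phluorin(
        imaging, probe_times=(10.0, 110.0, 210.0), conditioning=(310.0, 30.0),
        post_probe_times=(440.0,), nh4cl_window=(500.0, 519.0), duration=520.0,
    )
    write_roi_table(roi, OUT / f"syphy_{genotype}.csv")
    rows.append({"file": f"syphy_{genotype}.csv", "genotype": genotype,
                 "true_rate_hz": None, "n_events": None})

manifest = pd.DataFrame(rows)
manifest.to_csv(OUT / "manifest.csv", index=False)
print(f"wrote {len(manifest)} simulated recordings to {OUT}/")
print(manifest.groupby("genotype").size().rename("files").to_string())
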