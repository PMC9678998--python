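#!/usr/bin/env python
"""Short-term depression and recovery kinetics on sustained stimulation.

Simulates 30 s @ 20 Hz trains followed by 0.1 Hz probing for a control and a
replenishment-halved genotype, fits the bi-exponential depression and the
mono-exponential recovery, and tabulates SSC and time constants.  The
replenishment rates here are low enough that the pool cannot refill within
one 10 s probe interval, so the genotype contrast survives into the
recovered steady state.
"""

from pathlib import Path

import pandas as pd

from presynquant.io import train_protocol
from presynquant.simulate import SynapseModel, simulate_train
from presynquant.trains import EvokedResponse, fit_depression, fit_recovery

OUT = Path("results")
proto = train_protocol(20.0, 30.0, probe_freq=0.1, probe_duration=240.0)


def responses(amps, times):
    return [EvokedResponse(stim_t=float(t), baseline=0.0, peak=-float(a),
                           amplitude=float(a), index_in_train=k)
            for k, (t, a) in enumerate(zip(times, amps))]


rows = []
for genotype, rate in (("wt", 4.0), ("e373k", 2.0)):
    model = SynapseModel(N_sites=100, q_mean=10.0, Pr=0.35, replenish_rate=rate)
    amps, _ = simulate_train(model, proto, mode="expected")
    r = responses(amps, proto.stim_times)
    train_r = [x for x in r if x.stim_t < 30.0]
    probe_r = [x for x in r if x.stim_t >= 30.0]
    dep = fit_depression(train_r)
    rec = fit_recovery(probe_r, I1_pre=r[0].amplitude, t_train_end=30.0)
    rows.append({
        "genotype": genotype, "replenish_sites_per_s": rate,
        "depression_SSC": dep.SSC, "tau_fast_s": dep.tau_fast,
        "tau_slow_s": dep.tau_slow, "depression_model": dep.model,
        "recovery_SSC": rec.SSC, "recovery_tau_s": rec.tau,
        "first_post_response": rec.first_post_response,
    })

table = pd.DataFrame(rows)
table.to_csv(OUT / "depression_recovery.csv", index=False, float_format="%.6g")
print(table.round(3).to_string(index=False))
print("\nhalved replenishment lowers the recovered steady state "
      f"({table.recovery_SSC[1]:.2f} vs {table.recovery_SSC[0]:.2f} of pre-train I1)")
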