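"""Simulate a small study and characterize its kinetics.

Builds the two-readout `minimal` scenario (a reference agonist plus one
test ligand carrying a +0.5 log bias toward the second readout), fits
the rise-and-fall model to the reference traces at the top dose, and
prints the recovered rates and half-times.  T1/2 = ln(2)/K1 is the
half-time of the fast (rise) phase.
"""

import numpy as np

from biasquant import fit_rise_fall, make_scenario, simulate_study

scenario = make_scenario("minimal", {"seed": 42})
dataset = simulate_study(scenario)
print(f"simulated {dataset.n_traces()} wells "
      f"({len(scenario.readouts)} readouts x {len(scenario.ligands)} ligands)")

top_dose = scenario.reference.dose_grid[-1]
for trace in dataset.traces():
    if trace.ligand == "REF" and trace.log10_conc == top_dose and trace.replicate == 0:
        fit = fit_rise_fall(trace)
        truth = scenario.reference.kinetic[trace.readout]
        print(f"{trace.readout}: K1={fit.params.k1:.3f}/min (truth {truth.k1})  "
              f"K2={fit.params.k2:.3f}/min (truth {truth.k2})  "
              f"T1/2={fit.t_half:.2f} min")

# the injected ground truth the downstream stages should recover
print("injected ddLogBF(R1,R2) for TEST:",
      scenario.injected_bias("TEST", ("R1", "R2")))
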