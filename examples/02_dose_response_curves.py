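"""Concentration/activity curves, empirical potency, and EC80.

Integrates each well's kinetic trace to its AUC, normalizes by the
reference ligand's maximal response (top dose = 100%), fits a 4PL to
each curve and derives EC50/EC80.  The test ligand is a partial agonist
(plateau below 100%) and much less potent than the reference.
"""

from biasquant import ec_fraction, fit_hill, make_scenario, normalize_to_reference, simulate_study

dataset = simulate_study(make_scenario("minimal", {"seed": 42}))
curves = normalize_to_reference(dataset)  # full 30-min AUC window

for (cell, ligand, readout), curve in sorted(curves.items()):
    fit = fit_hill(curve)
    ec80 = ec_fraction(fit, 0.8)
    print(f"{cell} {ligand:>4} {readout}: Emax={fit.emax:6.1f}%  "
          f"pEC50={-fit.log_ec50:5.2f}  log10 EC80={ec80:6.2f}")

# Emax is % of the reference maximum: ~100 for REF by construction,
# lower for the partial-agonist TEST ligand; pEC50 differences of ~2-3
# log units reflect the low-molecular-weight ligand's weaker potency.
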