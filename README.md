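# biasquant

Ligand-bias quantification for GPCR signaling assays: from raw
time-resolved concentration/response traces to operational-model
transduction coefficients, statistically validated bias factors, and
multivariate comparison of ligand profiles.

## The problem

Biased agonists activate some of a receptor's signaling pathways more
than others relative to a reference agonist — a property central to
dissecting pathway-specific pharmacology (e.g. low-molecular-weight
allosteric agonists of the FSH receptor profiled against FSH on Gαs,
Gαq, Gαi, β-arrestin-2 and cAMP readouts). Quantifying bias from
plate-reader kinetics requires a chain of steps that are easy to get
subtly wrong: integrating kinetic traces to endpoints, normalizing to
the reference maximum, fitting the Black–Leff operational model jointly
across ligands, and testing whether an apparent bias survives
statistical scrutiny or reflects a flat, non-identifiable curve.
`biasquant` implements that chain as a tested library with a synthetic
data generator whose ground truth makes every stage verifiable.

## The model

Responses follow the operational model of agonism, reparameterized in
the transduction coefficient `LogR = log10(τ/Ka)`:

    E = Basal + (Emax − Basal) / (1 + (([L]/10^LogKa + 1)/(10^LogR·[L]))ⁿ)

For a pair of responses, one global maximum-likelihood fit (Gaussian
error, unknown variance per response, concentrated analytically) shares
`Basal`, `Emax`, `LogR` per response across the ligand panel; each test
ligand contributes per-response `LogKa`, a transduction shift `ΔLogR1`,
and the bias factor

    ΔΔLogBF = ΔLogR2 − ΔLogR1,

which enters the model directly as a free parameter. Its 95% CI comes
from the profile likelihood (χ²₁ crossing, bounded in (−5, +5)), and
significance from a likelihood-ratio test against the nested
`ΔΔLogBF = 0` model. Kinetic traces are summarized by the rise-and-fall
model `E(t) = C/(K1−K2)·(e^(−K2·t) − e^(−K1·t))` with `T1/2 = ln2/K1`,
and ligand profiles are compared by centered PCA plus Ward clustering
on the bias matrix (reference row ≡ 0). See `docs/methods.md` for the
full account.

## Worked example

```python
from biasquant import (FitConfig, global_fit_pair, lrt_bias, make_scenario,
                       normalize_to_reference, profile_ci, simulate_study)

scenario = make_scenario("minimal", {"seed": 42})   # injects ΔΔLogBF = +0.5
dataset = simulate_study(scenario)
curves = normalize_to_reference(dataset)            # % of reference max, 30-min AUC

r1 = {lig: c for (cm, lig, ro), c in curves.items() if ro == "R1"}
r2 = {lig: c for (cm, lig, ro), c in curves.items() if ro == "R2"}
fit = global_fit_pair(r1, r2, reference="REF", config=FitConfig(n_starts=24, seed=0))
lo, hi, _ = profile_ci(fit, "TEST")
stat, p = lrt_bias(fit, "TEST")
print(fit.ligands["TEST"].ddlogbf, (lo, hi), p)
```

Output (seed 42):

```
injected ddLogBF : +0.500
estimated ddLogBF: +0.455  95% profile CI [+0.405, +0.504]
LRT vs ddLogBF=0 : chi2(1) stat=106.7, p=5.06e-25
```

The estimate recovers the injected half-log bias toward readout R2, the
profile CI covers the truth, and the LRT rejects the balanced-ligand
null. The `examples/` directory has one short script per capability
(kinetics, dose-response/EC80, bias factors, PCA + clustering), and the
`bias-quant` CLI exposes the same pipeline for shell use
(`bias-quant simulate`, `fit-kinetics`, `dose-response`, `fit-bias`,
`cluster`, `run`, `report`).

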