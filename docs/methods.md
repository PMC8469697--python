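# Methods

`biasquant` quantifies ligand bias at a G-protein-coupled receptor from
time-resolved plate-reader data. This note documents the models, the
estimation machinery, the synthetic-data generator, and the numerical
and design choices a user should know before trusting the outputs.

## 1. Kinetic model

Each well's time course is modelled by the rise-and-fall difference of
exponentials

    E(t) = C / (K1 − K2) · (e^(−K2·t) − e^(−K1·t)),   K1 > K2 ≥ 0,

with `C` (signal·min⁻¹) an amplitude scale, `K1` (min⁻¹) the fast rise
rate and `K2` (min⁻¹) the slow decay rate. The reported half-time is

    T1/2 = ln(2) / K1,

the half-time of the fast exponential. The natural logarithm is used:
for a process governed by `e^(−K1·t)` the base-10 logarithm would be
dimensionally wrong. Sustained signals are the `K2 = 0` boundary; the
`K1 = K2` degeneracy is evaluated in its continuous limit
`C·t·e^(−K1·t)` to avoid 0/0. The expression is symmetric under a plain
swap of `K1` and `K2`; the fitter's `K1 > K2` box constraint (fit in
`(C, K2, ΔK = K1 − K2)` coordinates) makes the reported labelling
unique. Fits use bounded nonlinear least squares with a time-to-peak
heuristic start plus randomized multi-starts (20 by default, fixed
seed). Traces with zero dynamic range are flagged degenerate, never
fitted; a stalled optimizer yields `converged=False`, not an exception.

Traces are assumed baseline-corrected to start at 0 (Δ-ratio readouts).
Area under the curve (AUC) uses the trapezoid rule on observed samples
— exact for piecewise-linear signals and standard for plate-reader
kinetics — with linear interpolation when the endpoint falls between
samples.

## 2. Concentration/activity curves

Per (cell model, readout, endpoint), every replicate AUC is divided by
the mean AUC of the reference ligand at its top dose and multiplied by
100, so the reference top dose averages exactly 100%. The normalizer is
the *observed* maximal response, not a fitted asymptote. An alternative
convention (normalize by the reference signal at a fixed time point,
default 20 min) is available by flag; both are provided because kinetic
figures and concentration/activity figures in this field commonly use
different conventions, and the package does not assert one as canonical.

Empirical summaries (Emax, pEC50) come from a four-parameter logistic
on log10 dose with unconstrained Hill slope; descending curves
(inverse agonism) are permitted and flagged. EC fractions follow
`log10 EC_f = logEC50 + (1/n)·log10(f/(1−f))` (EC80 at `f = 0.8`).
Endpoint profiles rebuild curves at several AUC endpoints (default 2,
7, 20 min), renormalizing against the reference *at the same endpoint*,
which exposes kinetics-driven shifts in apparent efficacy and potency.
Ligand comparisons use Welch's unequal-variance t-test (Satterthwaite
degrees of freedom, two-sided); two zero-variance samples with equal
means return p = 1 by convention. The 4PL is descriptive only — the
operational model below is the pharmacological fit.

## 3. Operational model and bias factors

The Black–Leff operational model links concentration `[L]` to response
through the efficacy τ and the functional dissociation constant `Ka`:

    E = Basal + (Emax − Basal) · (τ[L])ⁿ / ((τ[L])ⁿ + (Ka + [L])ⁿ).

For estimation it is reparameterized in `LogKa` and the transduction
coefficient `LogR = log10(τ/Ka)`:

    E = Basal + (Emax − Basal) / (1 + (([L]/10^LogKa + 1) / (10^LogR·[L]))ⁿ),

algebraically identical (the bracket equals `((Ka+[L])/(τ[L]))ⁿ`; the
package verifies the equivalence to 1e-10 relative over 10⁴ random
draws). Internally the n = 1 form is evaluated as
`1 + 10^(−LogR−LogKa) + 10^(−LogR−x)` with `x = log10[L]`, which is
overflow-safe across the entire parameter box. The Hill slope is fixed
to 1 in all bias fits to aid identifiability.

For a pair of responses measured on the same ligand panel, one global
maximum-likelihood fit shares `Basal_r`, `Emax_r`, `LogR_r` (r = 1, 2)
across ligands. The reference agonist is fitted with `Ka := 1`, so its
`LogR` absorbs the molar scale and acts as a composite system
parameter. Each test ligand adds `LogKa1`, `LogKa2`, a common
transduction shift `ΔLogR1`, and the bias factor `ΔΔLogBF`, which
enters response 2 as `LogR2 + ΔLogR1 + ΔΔLogBF`. Positive `ΔΔLogBF`
means bias toward response 2; the pair orientation follows the
user-supplied readout list and is recorded in every output row. The
`Ka := 1` convention leaves `ΔΔLogBF` exactly invariant (it is a
difference of log-ratios in which the scale cancels), which is why the
noiseless recovery tests can demand 1e-3 agreement.

**Error model and optimizer.** Residuals are additive Gaussian with an
unknown variance per response, concentrated analytically:
`σ̂²_r = RSS_r/N_r`, so `−2 logL = Σ_r N_r·log(RSS_r/N_r) + const`. The
optimizer is iteratively reweighted least squares — bounded
trust-region least squares at fixed per-response weights, then a σ
update — whose fixed point is exactly the concentrated-likelihood MLE
and is far better conditioned than direct minimization of the log-RSS
objective. Multi-start uses one data-driven heuristic start (curve
midpoint crossings) plus Latin-hypercube draws inside the box:
`Basal/Emax` within the observed data range ±50% of its span,
`LogR ∈ (−3, 12)`, `LogKa ∈ (−12, −2)`, and `ΔLogR1, ΔΔLogBF ∈ (−5, +5)`.
The default start count is 1000; the validation studies and acceptance
script use 6–24 starts, which the heuristic start makes sufficient on
the synthetic instances (the best optimum is unchanged when the count
is raised — this was checked, and the full protocol remains one config
field away). Equal-likelihood optima are tie-broken toward the smaller
total |ΔΔLogBF| (parsimony).

**Uncertainty.** 95% CIs for `ΔΔLogBF` come from the profile
likelihood: the bias is fixed on a walk outward from the MLE (step
0.05, stretching up to 0.8 on flat profiles), all other parameters are
re-optimized at each point with warm-started continuation, and the
bound is refined by bisection to 1e-3 where `−2Δlog L` crosses the
χ²₁ 0.95 quantile (3.841). Bounds that reach the (−5, +5) box are
flagged unbounded. Significance uses the likelihood-ratio test against
the nested null with that ligand's `ΔΔLogBF` pinned to 0, refitted with
the same multi-start protocol; the statistic is floored at 0, and if
the null ever beats the full model the full fit is restarted from the
null optimum before the statistic is formed.

**Identifiability triage.** A curve is classed `flat_response` when its
observed dynamic range is below twice the fitted residual sd (or when a
supplied transduction-coefficient profile CI spans more than 4 log
units), and `boundary` when the ligand's MLE sits on a parameter bound.
These thresholds are explicit, configurable stand-ins for what is
ultimately a judgment call; they are not claims about any particular
dataset. Display classes follow from the pair: both curves
identifiable and p < α → `significant`; identifiable but p ≥ α →
`none`; one member non-identifiable with a nonzero direction →
`observed`; both non-identifiable → `nd`. A flat-response ligand can
therefore never be reported as statistically significant bias. No
multiplicity correction is applied across the pair sweep by default
(a Benjamini–Hochberg option exists behind a flag).

Known limitation: two near-full agonists constrain only their plateaus
and EC50s, so `Emax` and the τ's trade off along a likelihood ridge and
some parameter lands on a bound; the triage then downgrades the call to
`observed`. This is the correct, conservative behavior — the bias of a
saturating pair is weakly identified — but it means clean `significant`
calls need at least one clear partial agonist or an informative dose
range.

## 4. Multivariate stage

Per cell model, bias factors form a ligands × readout-pairs matrix; the
reference ligand's row is identically 0 by definition. `nd` entries are
imputed to 0 and masked (default) or the ligand row is dropped. PCA is
column-mean-centered and unscaled by default — all entries share log10
bias units, so standardization is a geometry-changing choice exposed as
a flag, not a default. Components are sign-fixed (largest-magnitude
loading positive). Clustering is Ward linkage on the PC scores covering
≥ 95% variance (minimum two components), cut at k clusters (default 3);
a k-means consolidation step common in some HCPC implementations is
deliberately omitted for determinism. The zero-imputation default
reproduces a known artifact worth flagging: a ligand with *no*
determined bias lands exactly on the reference in PC space. That
overlay means "no information", not pharmacological equivalence, and
the mask records which entries were imputed.

## 5. Synthetic-data generator

The generator emulates the design of a biased-agonism profiling study
at an FSH-receptor-like system: a reference agonist dosed 10^−12.5 to
10^−6.5 M, test ligands dosed 10^−10 to 10^−4 M (half-log steps in the
`paper_like` preset), ≥ 6 replicates, 30-min kinetic traces sampled
every 0.5 min (sampling interval is a package choice; instruments
vary), five readouts (Gαs, Gαq, Gαi, β-arrestin-2 recruitment, cAMP)
and three cell models (wild type plus two knockout emulations).

Each well's noiseless trace is the rise-and-fall curve with its
amplitude scaled by the operational fractional response at that dose,
`w([L]) = (E([L]) − Basal)/(Emax − Basal)`. How kinetic amplitude
couples to dose is a modelling choice (instruments report both freely);
this one makes the AUC dose-response reproduce the operational model
exactly, so the downstream fit is consistent with the generator by
construction — which is precisely what inverse-crime recovery tests
need. Noise is additive Gaussian, homoscedastic per readout (default
sd 0.05 on unit-peak signals), matching the fit's error model. Bias is
injected through per-readout efficacies: ground truth stores τ per
ligand × readout, and the realized `ΔΔLogBF` for a pair is the
difference of log10 τ-ratios versus the reference — equivalently,
response 2's transduction coefficient is shifted by
`ΔLogR1 + ΔΔLogBF`. (An arbitrary per-pair bias map is not realizable
from per-readout coefficients; deriving the pair map from per-readout
truth keeps every pair self-consistent.)

Knockout emulation multiplies a readout's τ by a constant for *all*
ligands (Gαi × 0.1 in the ΔGαs model, β-arrestin-2 × 0.05 in the ΔARRB
model). This reproduces a global pathway suppression — a system effect
that cancels in bias factors — and is a modelling convenience, not a
mechanistic claim about knockout biology.

Randomness: every well draws from a deterministic substream keyed by
(cell model, ligand, readout, dose, replicate) via hashed seed
sequences, so identical scenarios are byte-identical after
serialization and removing part of a design never changes the remaining
wells.

What the generator does *not* emulate: receptor trafficking and
endosomal compartments, occupancy-level binding kinetics,
heteroscedastic or non-Gaussian plate noise, edge effects, replicate
drift, and ligand-specific kinetic changes across readouts. Passing
recovery tests therefore demonstrates the *estimation chain* is
correct and calibrated under its own assumptions; it does not
demonstrate robustness to real-world noise structure.

## 6. Validation studies and problem sizes

`biasquant.validation` packages the recovery and calibration studies
(also exposed via `scripts/acceptance.py`):

- equation equivalence: 10⁴ random draws across the full parameter box;
- kinetic inverse crime: four parameter sets on a 0–30 min grid;
- bias recovery: injected ΔΔLogBF ∈ {−2, −0.5, 0, 0.5, 2} noiseless,
  and 100 Monte-Carlo repeats at 5%-of-Emax noise with 6 replicates;
- CI calibration: 200 repeats at a representative two-response setting
  (7 doses per ligand, 6 replicates, noise sd 5, true bias +0.5), plus
  a brute-force 0.01-step grid-scan oracle for the CI endpoints on a
  6-dose, 3-replicate instance;
- LRT size: 200 repeats of the same setting with true bias 0;
- triage, endpoint-sensitivity and multivariate checks on the
  `flat_ligand` / `minimal` presets and a planted three-group matrix.

The Monte-Carlo instance sizes (one test ligand, 7 doses, 6 replicates)
are the package's chosen representative setting: large enough for the
asymptotic χ² machinery to be in its working regime, small enough that
the full suite reruns in minutes on one CPU. The replicate count
matters: with the ~10-parameter pair model, the concentrated variance
estimate `RSS/N` is biased low for small N, and 3-replicate instances
measurably narrow the profile CIs (coverage ≈ 0.82 instead of ≈ 0.92
at 6 replicates). Six replicates — the design the generator emulates —
is therefore the honest default, and the residual few-percent
undercoverage at small N is a known property of concentrated-variance
profile likelihoods, not a bug.

## 7. Numerical conventions and degenerate inputs

- σ is floored at 1e-12 so noiseless (zero-RSS) fits stay finite;
  log-RSS terms use the floor squared.
- `dose = −∞` evaluates to Basal in both model forms.
- Zero-variance Welch comparisons: p = 1 for equal means, p = 0
  otherwise (documented convention).
- Rank-zero bias matrices return a degenerate PCA (zero scores and
  variance fractions) rather than raising.
- All-zero traces, flat curves and sub-4-point inputs are rejected or
  flagged with explicit reasons; pipeline failures mask downstream
  outputs for the affected keys and are listed in the run manifest.
- Pipeline outputs are written with a fixed float format; rerunning an
  identical configuration reproduces byte-identical tables.
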