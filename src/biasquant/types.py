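"""Core domain containers shared across the pipeline.

Conventions used throughout the package:

* ligand concentrations are expressed as ``log10`` molar (so ``-7`` means
  100 nM); positive concentration columns are rejected at I/O time,
* times are minutes, signals are in arbitrary plate-reader units until
  normalization expresses them as percent of the reference-ligand maximum,
* the transduction coefficient is ``R = tau / Ka`` and all bias quantities
  (``ΔLogR``, ``ΔΔLogBF``) are log10 differences of transduction
  coefficients relative to the reference agonist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "KineticParams",
    "OperationalParams",
    "LigandSpec",
    "Scenario",
    "KineticTrace",
    "KineticFit",
    "DoseResponseCurve",
    "HillFit",
    "FitConfig",
    "LigandBiasParams",
    "GlobalFitResult",
    "BiasEstimate",
    "BiasMatrix",
    "PCAResult",
]


@dataclass(frozen=True)
class KineticParams:
    """Rise-and-fall kinetic parameters.

    The time course of a well is modelled as
    ``E(t) = C/(K1 - K2) * (exp(-K2*t) - exp(-K1*t))`` with the fast rate
    ``K1`` strictly greater than the slow rate ``K2 >= 0``.  ``C`` carries
    units of signal/min.
    """

    c: float
    k1: float
    k2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c) and math.isfinite(self.k1) and math.isfinite(self.k2)):
            raise ValueError("kinetic parameters must be finite")
        if not (self.k1 > self.k2 >= 0.0):
            raise ValueError(f"require K1 > K2 >= 0, got K1={self.k1}, K2={self.k2}")

    @property
    def t_half(self) -> float:
        """Half-time of the fast phase, ln(2)/K1 (natural log)."""
        return math.log(2.0) / self.k1


@dataclass(frozen=True)
class OperationalParams:
    """Operational-model (Black–Leff) parameters for one ligand x readout.

    ``log_r`` is log10 of the transduction coefficient R = tau/Ka, so the
    efficacy is ``tau = 10**(log_r + log_ka)``.
    """

    basal: float
    emax: float
    log_ka: float
    log_r: float
    hill_n: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.basal, self.emax, self.log_ka, self.log_r, self.hill_n)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("operational parameters must be finite")
        if self.hill_n <= 0:
            raise ValueError("hill_n must be > 0")

    @property
    def log_tau(self) -> float:
        return self.log_r + self.log_ka

    @property
    def tau(self) -> float:
        return 10.0 ** self.log_tau


@dataclass
class LigandSpec:
    """One ligand in a simulated study, with per-readout ground truth."""

    name: str
    role: str  # "reference" | "test"
    dose_grid: np.ndarray  # log10 M, strictly increasing, >= 6 points
    operational: dict[str, OperationalParams]  # readout -> params
    kinetic: dict[str, KineticParams]  # readout -> params

    def __post_init__(self) -> None:
        self.dose_grid = np.asarray(self.dose_grid, dtype=float)
        if self.role not in ("reference", "test"):
            raise ValueError(f"role must be 'reference' or 'test', got {self.role!r}")
        if self.dose_grid.size < 6:
            raise ValueError("dose_grid needs at least 6 concentrations")
        if not np.all(np.diff(self.dose_grid) > 0):
            raise ValueError("dose_grid must be strictly increasing")


@dataclass
class Scenario:
    """Full design of a simulated study (the generator's ground truth)."""

    name: str
    cell_models: list[str]
    readouts: list[str]
    ligands: list[LigandSpec]
    noise_sd: dict[str, float]  # readout -> sd in signal units
    n_replicates: int
    time_grid: np.ndarray  # minutes
    seed: int
    # (cell_model, readout) -> multiplicative factor on tau, emulating
    # knockout-induced global suppression of a pathway (applied to every
    # ligand, so it is a system effect that cancels in bias factors).
    tau_scale: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_grid = np.asarray(self.time_grid, dtype=float)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.time_grid[0] != 0 or not np.all(np.diff(self.time_grid) > 0):
            raise ValueError("time_grid must start at 0 and be strictly increasing")
        if self.time_grid[-1] < 20.0:
            raise ValueError("time_grid must span at least 20 minutes")
        refs = [l.name for l in self.ligands if l.role == "reference"]
        if len(refs) != 1:
            raise ValueError(f"exactly one reference ligand required, got {refs}")
        for lig in self.ligands:
            missing = [r for r in self.readouts if r not in lig.operational or r not in lig.kinetic]
            if missing:
                raise ValueError(f"ligand {lig.name} lacks ground truth for readouts {missing}")
        missing_sd = [r for r in self.readouts if r not in self.noise_sd]
        if missing_sd:
            raise ValueError(f"noise_sd missing for readouts {missing_sd}")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")

    @property
    def reference(self) -> LigandSpec:
        return next(l for l in self.ligands if l.role == "reference")

    def injected_bias(self, ligand: str, pair: tuple[str, str]) -> float:
        """Ground-truth ΔΔLogBF of ``ligand`` for the ordered readout pair.

        Positive values mean bias toward the second readout of the pair.
        The reference ligand is identically 0 by definition.
        """
        lig = next(l for l in self.ligands if l.name == ligand)
        if lig.role == "reference":
            return 0.0
        ref = self.reference
        r1, r2 = pair
        d1 = lig.operational[r1].log_tau - ref.operational[r1].log_tau
        d2 = lig.operational[r2].log_tau - ref.operational[r2].log_tau
        return d2 - d1

    def with_overrides(self, **kwargs) -> "Scenario":
        return replace(self, **kwargs)


@dataclass
class KineticTrace:
    """One well's time series."""

    cell_model: str
    ligand: str
    readout: str
    log10_conc: float
    replicate: int
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals must have identical shape")

    @property
    def key(self) -> tuple:
        return (self.cell_model, self.ligand, self.readout, self.log10_conc, self.replicate)


@dataclass
class KineticFit:
    """Result of fitting the rise-and-fall model to one trace."""

    params: Optional[KineticParams]
    t_half: Optional[float]
    rss: float
    converged: bool
    degenerate: bool
    n_points: int
    message: str = ""


@dataclass
class DoseResponseCurve:
    """Normalized concentration/activity curve for one ligand x readout.

    ``responses`` has shape (n_doses, n_replicates) and is expressed as
    percent of the reference ligand's observed maximal response.
    """

    cell_model: str
    ligand: str
    readout: str
    endpoint_min: float
    doses: np.ndarray  # log10 M, strictly increasing
    responses: np.ndarray  # (n_doses, n_reps), % of reference max
    reference_ligand: str

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if not np.all(np.diff(self.doses) > 0):
            raise ValueError("doses must be strictly increasing")
        if self.responses.shape[0] != self.doses.size:
            raise ValueError("responses must have one row per dose")

    @property
    def dose_means(self) -> np.ndarray:
        return np.nanmean(self.responses, axis=1)

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Long-form (dose, response) pairs with NaN replicates dropped."""
        x = np.repeat(self.doses, self.responses.shape[1])
        y = self.responses.ravel()
        ok = np.isfinite(y)
        return x[ok], y[ok]


@dataclass
class HillFit:
    """Empirical four-parameter logistic fit on log10 dose."""

    basal: float
    emax: float
    log_ec50: float
    hill_n: float
    se: dict[str, float]
    rss: float
    degenerate: bool = False
    descending: bool = False
    extrapolated: bool = False
    message: str = ""


@dataclass
class FitConfig:
    """Settings for the global operational-model fit.

    ``n_starts`` counts multi-start initializations (one data-driven
    heuristic start plus Latin-hypercube draws within the parameter box).
    Bias-type parameters (ΔLogR1, ΔΔLogBF) live in the (-5, +5) box.
    """

    n_starts: int = 1000
    seed: int = 0
    log_r_bounds: tuple[float, float] = (-3.0, 12.0)
    log_ka_bounds: tuple[float, float] = (-12.0, -2.0)
    delta_bounds: tuple[float, float] = (-5.0, 5.0)
    basal_emax_expand: float = 0.5
    sigma_floor: float = 1e-12
    polish_top: int = 3
    alpha: float = 0.05
    profile_step: float = 0.05
    profile_tol: float = 1e-3
    compute_ci: bool = True
    compute_lrt: bool = True


@dataclass
class LigandBiasParams:
    """Per-test-ligand parameters of the global fit."""

    log_ka1: float
    log_ka2: float
    delta_log_r1: float
    ddlogbf: float


@dataclass
class GlobalFitResult:
    """Outcome of the shared operational-model fit for one readout pair."""

    responses: tuple[str, str]
    reference: str
    basal: tuple[float, float]
    emax: tuple[float, float]
    log_r: tuple[float, float]
    ligands: dict[str, LigandBiasParams]
    sigma: tuple[float, float]
    loglik: float
    n_starts: int
    n_converged: int
    converged: bool
    theta: np.ndarray = field(repr=False, default=None)
    # retained so profile/LRT refits can reuse the exact same data + layout
    _engine: object = field(repr=False, default=None)


@dataclass
class BiasEstimate:
    """ΔΔLogBF for one (ligand, readout pair), with its uncertainty."""

    ligand: str
    pair: tuple[str, str]
    value: float
    ci95: tuple[float, float]
    ci_bounded: tuple[bool, bool]
    p_lrt: float
    lrt_stat: float
    identifiability: str  # identifiable | flat_response | boundary
    display: str  # significant | observed | none | nd

    def __post_init__(self) -> None:
        if self.display == "significant":
            assert self.identifiability == "identifiable" and self.p_lrt < 0.05


@dataclass
class BiasMatrix:
    """Ligands x readout-pairs matrix of ΔΔLogBF for one cell model."""

    cell_model: str
    ligands: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray  # (n_ligands, n_pairs)
    mask: np.ndarray  # True where the entry was imputed / not determined
    reference: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class PCAResult:
    """Principal components of a bias matrix."""

    ligands: list[str]
    scores: np.ndarray  # (n_ligands, n_components)
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    degenerate: bool = False
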