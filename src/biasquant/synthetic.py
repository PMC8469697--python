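"""Study-shaped synthetic data with known ground truth.

The generator emulates a biased-agonism profiling study at a Gs-coupled
receptor: a reference agonist (an FSH-like hormone dosed 10^-12.5 to
10^-6.5 M) and several low-molecular-weight test ligands (dosed 10^-10 to
10^-4 M) are profiled on multiple recruitment / second-messenger readouts
in several cell models, with 30-minute kinetic traces per well.

Each well's noiseless trace is a rise-and-fall curve whose amplitude is
scaled by the operational-model fractional response at that dose,

    signal(t, L) = rise_fall(t; C * w(L), K1, K2),
    w(L) = (E(L) - Basal) / (Emax - Basal),

so integrating traces to AUC reproduces an operational concentration/
activity curve exactly.  Ligand bias is injected through per-readout
efficacies tau: the ground-truth bias factor for a readout pair (r1, r2)
is the difference of log10 tau-ratios versus the reference, which is also
what the downstream global fit estimates (ΔLogR2 = ΔLogR1 + ΔΔLogBF).

Additive Gaussian noise (homoscedastic per readout) matches the error
model assumed by the bias engine, keeping parameter-recovery experiments
well-posed.  Every well draws from its own deterministic random substream
keyed by (cell model, ligand, readout, dose, replicate), so subsetting a
design never changes the remaining traces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .bias_engine import eval_operational
from .kinetics import amplitude_to_c, eval_rise_fall
from .types import KineticParams, KineticTrace, LigandSpec, OperationalParams, Scenario

__all__ = [
    "PRESETS",
    "make_scenario",
    "simulate_kinetic_trace",
    "simulate_study",
    "StudyDataset",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

SCHEMA_VERSION = 1
CSV_COLUMNS = ["cell_model", "ligand", "readout", "log10_conc_M", "time_min", "replicate", "signal"]

PRESETS = ("paper_like", "minimal", "flat_ligand", "null_bias")

# -- preset construction -----------------------------------------------------

_REF_DOSES = np.arange(-12.5, -6.49, 0.5)  # 13 half-log steps, 10^-12.5..10^-6.5 M
_TEST_DOSES = np.arange(-10.0, -3.99, 0.5)  # 10^-10..10^-4 M

# reference agonist: molar-scale functional Ka with per-readout efficacy tau.
_REF_LOG_KA = -9.0
_REF_TAU = {"Gs": 50.0, "Gq": 30.0, "Gi": 20.0, "barr2": 3.0, "cAMP": 200.0}

# test-ligand ground truth: (log_ka, tau per readout). Efficacies span weak
# partial agonism to super-agonist-like behavior on arrestin recruitment.
_TEST_TRUTH = {
    "B1": (-5.5, {"Gs": 2.0, "Gq": 0.10, "Gi": 0.03, "barr2": 0.10, "cAMP": 1.0}),
    "B2": (-6.0, {"Gs": 8.0, "Gq": 0.60, "Gi": 0.40, "barr2": 0.25, "cAMP": 6.0}),
    "B3": (-6.3, {"Gs": 40.0, "Gq": 15.0, "Gi": 25.0, "barr2": 35.0, "cAMP": 15.0}),
    "T1": (-6.0, {"Gs": 25.0, "Gq": 8.0, "Gi": 15.0, "barr2": 6.0, "cAMP": 8.0}),
}

# kinetic profiles (peak amplitude, fast rate K1, slow rate K2): the
# reference is intermediate; test ligands are transient, slow-sustained,
# fast, or reference-like.
_KINETICS = {
    "FSH": (1.0, 0.20, 0.020),
    "B1": (0.5, 0.35, 0.120),
    "B2": (0.9, 0.08, 0.010),
    "B3": (1.1, 0.50, 0.040),
    "T1": (1.0, 0.15, 0.020),
}


def _kin(name: str, readouts: Iterable[str]) -> dict[str, KineticParams]:
    peak, k1, k2 = _KINETICS[name]
    kp = KineticParams(c=amplitude_to_c(peak, k1, k2), k1=k1, k2=k2)
    return {r: kp for r in readouts}


def _ops(log_ka: float, tau: dict[str, float], readouts: Iterable[str]) -> dict[str, OperationalParams]:
    return {
        r: OperationalParams(basal=0.0, emax=1.0, log_ka=log_ka,
                             log_r=float(np.log10(tau[r]) - log_ka))
        for r in readouts
    }


def _paper_like(seed: int) -> Scenario:
    readouts = ["Gs", "Gq", "Gi", "barr2", "cAMP"]
    ligands = [
        LigandSpec("FSH", "reference", _REF_DOSES.copy(),
                   _ops(_REF_LOG_KA, _REF_TAU, readouts), _kin("FSH", readouts))
    ]
    for name, (log_ka, tau) in _TEST_TRUTH.items():
        ligands.append(LigandSpec(name, "test", _TEST_DOSES.copy(),
                                  _ops(log_ka, tau, readouts), _kin(name, readouts)))
    # knockout emulation: global pathway suppression applied to all ligands
    tau_scale = {("dGas", "Gi"): 0.1, ("dARRB", "barr2"): 0.05}
    return Scenario(
        name="paper_like",
        cell_models=["WT", "dGas", "dARRB"],
        readouts=readouts,
        ligands=ligands,
        noise_sd={r: 0.05 for r in readouts},
        n_replicates=6,
        time_grid=np.arange(0.0, 30.01, 0.5),
        seed=seed,
        tau_scale=tau_scale,
    )


def _two_readout(seed: int, name: str, test_bias: float, extra_flat: bool = False) -> Scenario:
    readouts = ["R1", "R2"]
    ref_tau = {"R1": 50.0, "R2": 50.0}
    # clear partial agonist: near-full test agonists trade Emax against tau
    # along a likelihood ridge and defeat the point of a clean testbed
    test_tau = {"R1": 2.0, "R2": 2.0 * 10.0 ** test_bias}
    ligands = [
        LigandSpec("REF", "reference", np.arange(-12.5, -6.49, 1.0),
                   _ops(_REF_LOG_KA, ref_tau, readouts), _kin("FSH", readouts)),
        LigandSpec("TEST", "test", np.arange(-10.0, -3.99, 1.0),
                   _ops(-6.0, test_tau, readouts), _kin("T1", readouts)),
    ]
    if extra_flat:
        # tau ~ 0 on R1: a flat concentration/activity profile whose
        # transduction coefficient is not identifiable (the triage testbed)
        ligands.append(LigandSpec("FLAT", "test", np.arange(-10.0, -3.99, 1.0),
                                  _ops(-6.0, {"R1": 1e-7, "R2": 10.0}, readouts),
                                  _kin("B1", readouts)))
    return Scenario(
        name=name,
        cell_models=["WT"],
        readouts=readouts,
        ligands=ligands,
        noise_sd={r: 0.05 for r in readouts},
        n_replicates=3,
        time_grid=np.arange(0.0, 30.01, 1.0),
        seed=seed,
    )


def make_scenario(preset: str, overrides: dict | None = None) -> Scenario:
    """Build one of the named study designs, optionally overriding fields.

    Presets: ``paper_like`` (3 cell models x 5 readouts x 1 reference + 4
    test ligands x 6 replicates), ``minimal`` (one readout pair, one test
    ligand with a +0.5 injected bias), ``flat_ligand`` (minimal plus a
    non-identifiable flat ligand), ``null_bias`` (all injected bias = 0).
    Override keys must be Scenario fields (scalar ``noise_sd`` broadcasts
    over readouts).
    """
    overrides = dict(overrides or {})
    seed = int(overrides.pop("seed", 0))
    if preset == "paper_like":
        sc = _paper_like(seed)
    elif preset == "minimal":
        sc = _two_readout(seed, "minimal", 0.5)
    elif preset == "flat_ligand":
        sc = _two_readout(seed, "flat_ligand", 0.5, extra_flat=True)
    elif preset == "null_bias":
        sc = _two_readout(seed, "null_bias", 0.0)
    else:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    if overrides:
        valid = {f.name for f in dataclasses.fields(Scenario)}
        bad = set(overrides) - valid
        if bad:
            raise ValueError(f"override keys not in Scenario schema: {sorted(bad)}")
        if "noise_sd" in overrides and np.isscalar(overrides["noise_sd"]):
            overrides["noise_sd"] = {r: float(overrides["noise_sd"]) for r in sc.readouts}
        sc = sc.with_overrides(**overrides)
    return sc


# -- simulation --------------------------------------------------------------

def _trace_rng(scenario_seed: int, key: tuple) -> np.random.Generator:
    """Deterministic per-well substream keyed by the well identity."""
    digest = hashlib.blake2s(repr(key).encode(), digest_size=16).digest()
    words = np.frombuffer(digest, dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(scenario_seed) & 0x7FFFFFFF, *words.tolist()]))


def fractional_response(op: OperationalParams, dose: float) -> float:
    """Operational fractional response w = (E - Basal)/(Emax - Basal)."""
    if op.emax == op.basal:
        raise ValueError("degenerate operational params: Emax == Basal")
    e = eval_operational(op, dose)
    return (e - op.basal) / (op.emax - op.basal)


def simulate_kinetic_trace(lig: LigandSpec, readout: str, dose: float,
                           kp: KineticParams, op: OperationalParams,
                           noise_sd: float, rng: np.random.Generator,
                           time_grid: np.ndarray, *, cell_model: str = "WT",
                           replicate: int = 0, tau_scale: float = 1.0) -> KineticTrace:
    """Simulate one well: dose-scaled rise-and-fall plus Gaussian noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if tau_scale != 1.0:
        op = dataclasses.replace(op, log_r=op.log_r + float(np.log10(tau_scale)))
    w = fractional_response(op, dose)
    clean = eval_rise_fall((kp.c * w, kp.k1, kp.k2), np.asarray(time_grid, dtype=float))
    noisy = clean + rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else clean
    return KineticTrace(cell_model=cell_model, ligand=lig.name, readout=readout,
                        log10_conc=float(dose), replicate=replicate,
                        times=np.asarray(time_grid, dtype=float), signals=noisy)


class StudyDataset:
    """Long-format collection of kinetic traces plus provenance.

    ``df`` columns: cell_model, ligand, readout, log10_conc_M, time_min,
    replicate, signal.  ``provenance`` is the generating :class:`Scenario`
    or the string ``"imported"``.
    """

    def __init__(self, df: pd.DataFrame, provenance: Scenario | str = "imported"):
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        self.schema_version = SCHEMA_VERSION

    # -- access ---------------------------------------------------------
    def well_keys(self) -> pd.DataFrame:
        return self.df[["cell_model", "ligand", "readout", "log10_conc_M", "replicate"]].drop_duplicates()

    def traces(self) -> Iterable[KineticTrace]:
        group_cols = ["cell_model", "ligand", "readout", "log10_conc_M", "replicate"]
        for key, sub in self.df.groupby(group_cols, sort=True):
            sub = sub.sort_values("time_min")
            yield KineticTrace(cell_model=key[0], ligand=key[1], readout=key[2],
                               log10_conc=key[3], replicate=int(key[4]),
                               times=sub["time_min"].to_numpy(),
                               signals=sub["signal"].to_numpy())

    def n_traces(self) -> int:
        return len(self.well_keys())

    # -- serialization --------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False, float_format="%.10g")

    def ground_truth_sidecar(self, path) -> None:
        """Write the generating scenario's ground truth as JSON."""
        if not isinstance(self.provenance, Scenario):
            raise ValueError("imported datasets carry no ground truth")
        sc = self.provenance
        pairs = [(a, b) for i, a in enumerate(sc.readouts) for b in sc.readouts[i + 1:]]
        truth = {
            "schema_version": self.schema_version,
            "scenario": sc.name,
            "seed": sc.seed,
            "ligands": {
                lig.name: {
                    "role": lig.role,
                    "operational": {r: dataclasses.asdict(lig.operational[r]) for r in sc.readouts},
                    "kinetic": {r: dataclasses.asdict(lig.kinetic[r]) for r in sc.readouts},
                    "injected_bias": {f"{a}|{b}": sc.injected_bias(lig.name, (a, b)) for a, b in pairs},
                }
                for lig in sc.ligands
            },
        }
        with open(path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)


def simulate_study(sc: Scenario) -> StudyDataset:
    """Simulate every (cell model, ligand, readout, dose, replicate) well."""
    frames = []
    nt = sc.time_grid.size
    for cell in sc.cell_models:
        for lig in sc.ligands:
            for readout in sc.readouts:
                kp = lig.kinetic[readout]
                op = lig.operational[readout]
                scale = sc.tau_scale.get((cell, readout), 1.0)
                sd = sc.noise_sd[readout]
                for dose in lig.dose_grid:
                    for rep in range(sc.n_replicates):
                        key = (cell, lig.name, readout, round(float(dose), 6), rep)
                        rng = _trace_rng(sc.seed, key)
                        try:
                            tr = simulate_kinetic_trace(lig, readout, float(dose), kp, op, sd, rng,
                                                        sc.time_grid, cell_model=cell,
                                                        replicate=rep, tau_scale=scale)
                        except ValueError as exc:
                            raise ValueError(f"simulation failed for well {key}: {exc}") from exc
                        frames.append(pd.DataFrame({
                            "cell_model": cell, "ligand": lig.name, "readout": readout,
                            "log10_conc_M": float(dose), "time_min": tr.times,
                            "replicate": rep, "signal": tr.signals,
                        }, index=range(nt)))
    df = pd.concat(frames, ignore_index=True)
    return StudyDataset(df, provenance=sc)


# -- scenario (de)serialization ---------------------------------------------

def scenario_to_yaml(sc: Scenario, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": sc.name,
        "cell_models": list(sc.cell_models),
        "readouts": list(sc.readouts),
        "noise_sd": {k: float(v) for k, v in sc.noise_sd.items()},
        "n_replicates": int(sc.n_replicates),
        "time_grid": [float(v) for v in sc.time_grid],
        "seed": int(sc.seed),
        "tau_scale": [{"cell_model": c, "readout": r, "factor": float(f)}
                      for (c, r), f in sc.tau_scale.items()],
        "ligands": [
            {
                "name": lig.name,
                "role": lig.role,
                "dose_grid": [float(d) for d in lig.dose_grid],
                "operational": {r: dataclasses.asdict(lig.operational[r]) for r in sc.readouts},
                "kinetic": {r: dataclasses.asdict(lig.kinetic[r]) for r in sc.readouts},
            }
            for lig in sc.ligands
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    ligands = [
        LigandSpec(
            name=d["name"], role=d["role"], dose_grid=np.asarray(d["dose_grid"], dtype=float),
            operational={r: OperationalParams(**p) for r, p in d["operational"].items()},
            kinetic={r: KineticParams(**p) for r, p in d["kinetic"].items()},
        )
        for d in doc["ligands"]
    ]
    return Scenario(
        name=doc["name"], cell_models=list(doc["cell_models"]), readouts=list(doc["readouts"]),
        ligands=ligands, noise_sd={k: float(v) for k, v in doc["noise_sd"].items()},
        n_replicates=int(doc["n_replicates"]), time_grid=np.asarray(doc["time_grid"], dtype=float),
        seed=int(doc["seed"]),
        tau_scale={(e["cell_model"], e["readout"]): float(e["factor"]) for e in doc.get("tau_scale", [])},
    )
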