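"""Parameter-recovery and calibration studies.

Self-contained simulation studies that exercise the whole estimation
chain against known ground truth: algebraic equivalence of the two
operational-model forms, inverse-crime recovery of kinetic and bias
parameters, profile-likelihood CI calibration and a brute-force grid
oracle, likelihood-ratio-test type-I error, non-identifiability triage,
endpoint sensitivity of relative efficacy, and multivariate sanity of
the PCA/clustering stage.  Problem sizes are chosen for desk-scale
reruns (see docs/methods.md); every study is deterministic given its
seed.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .bias_engine import (
    _PairEngine,
    eval_operational,
    global_fit_pair,
    lrt_bias,
    profile_ci,
)
from .dose_response import endpoint_profiles
from .kinetics import eval_rise_fall, fit_rise_fall
from .multivariate import build_bias_matrix, cluster_pca, run_pca
from .synthetic import make_scenario, simulate_study
from .types import DoseResponseCurve, FitConfig, KineticTrace, OperationalParams

__all__ = [
    "equation_equivalence",
    "kinetic_recovery",
    "make_pair_curves",
    "bias_recovery_noiseless",
    "bias_recovery_noisy",
    "ci_calibration",
    "ci_grid_oracle_check",
    "lrt_type1_error",
    "flat_ligand_triage",
    "endpoint_sensitivity",
    "multivariate_sanity",
]

_REF_DOSES = np.linspace(-12.5, -6.5, 7)
_TEST_DOSES = np.linspace(-10.0, -4.0, 7)
# ground truth of the representative two-response instance (Ka := 1
# reference convention, responses in % of reference max)
_TRUTH = dict(log_r=(9.3, 9.0), test_log_ka=-7.0, delta_log_r1=-1.8, emax=100.0)


def equation_equivalence(n_draws: int = 10_000, seed: int = 0) -> float:
    """Max relative disagreement between canonical and LogR model forms."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_draws):
        p = OperationalParams(
            basal=rng.uniform(1.0, 50.0),
            emax=rng.uniform(60.0, 250.0),
            log_ka=rng.uniform(-12.0, -2.0),
            log_r=rng.uniform(-3.0, 12.0),
            hill_n=rng.uniform(0.5, 2.0),
        )
        dose = rng.uniform(-12.5, -4.0)
        a = eval_operational(p, dose, form="canonical")
        b = eval_operational(p, dose, form="reparameterized")
        worst = max(worst, abs(a - b) / max(abs(a), abs(b), 1e-300))
    return worst


def kinetic_recovery(seed: int = 0) -> dict:
    """Noiseless rise-and-fall inverse crime over several parameter sets."""
    t = np.arange(0.0, 30.01, 0.5)
    cases = [(1.0, 0.2, 0.05), (0.5, 0.5, 0.04), (2.0, 0.08, 0.01), (1.0, 0.2, 0.0)]
    worst = 0.0
    t_half_dev = 0.0
    for c, k1, k2 in cases:
        y = eval_rise_fall((c, k1, k2), t)
        tr = KineticTrace("WT", "X", "R", -7.0, 0, t, y)
        kf = fit_rise_fall(tr, seed=seed)
        assert kf.params is not None
        for true, est in ((c, kf.params.c), (k1, kf.params.k1)):
            worst = max(worst, abs(est - true) / abs(true))
        worst = max(worst, abs(kf.params.k2 - k2) / max(abs(k2), 1.0))
        t_half_dev = max(t_half_dev, abs(kf.t_half - math.log(2.0) / kf.params.k1))
    return {"max_rel_err": worst, "t_half_identity_dev": t_half_dev}


# ---------------------------------------------------------------------------
# bias-recovery instance (forward model = the fit's own equations)
# ---------------------------------------------------------------------------

def _curve(lig: str, readout: str, doses: np.ndarray, op: OperationalParams,
           noise: float, n_reps: int, rng: np.random.Generator) -> DoseResponseCurve:
    clean = eval_operational(op, doses)
    resp = np.tile(clean[:, None], (1, n_reps))
    if noise > 0:
        resp = resp + rng.normal(0.0, noise, size=resp.shape)
    return DoseResponseCurve(cell_model="WT", ligand=lig, readout=readout,
                             endpoint_min=30.0, doses=doses, responses=resp,
                             reference_ligand="REF")


def make_pair_curves(ddlogbf: float, noise: float = 0.0, n_reps: int = 6,
                     seed: int = 0, ref_doses: np.ndarray | None = None,
                     test_doses: np.ndarray | None = None):
    """Two-response instance with one test ligand and a known bias factor."""
    rng = np.random.default_rng(seed)
    rd = _REF_DOSES if ref_doses is None else ref_doses
    td = _TEST_DOSES if test_doses is None else test_doses
    lr1, lr2 = _TRUTH["log_r"]
    lka, dlr = _TRUTH["test_log_ka"], _TRUTH["delta_log_r1"]
    emax = _TRUTH["emax"]
    ops = {
        ("REF", 0): OperationalParams(0.0, emax, 0.0, lr1),
        ("REF", 1): OperationalParams(0.0, emax, 0.0, lr2),
        ("TEST", 0): OperationalParams(0.0, emax, lka, lr1 + dlr),
        ("TEST", 1): OperationalParams(0.0, emax, lka, lr2 + dlr + ddlogbf),
    }
    curves1, curves2 = {}, {}
    for (lig, r), op in ops.items():
        doses = rd if lig == "REF" else td
        c = _curve(lig, f"E{r + 1}", doses, op, noise, n_reps, rng)
        (curves1 if r == 0 else curves2)[lig] = c
    return curves1, curves2


def _fit_config(seed: int, n_starts: int = 12) -> FitConfig:
    return FitConfig(n_starts=n_starts, seed=seed, polish_top=2)


def bias_recovery_noiseless(biases=(-2.0, -0.5, 0.0, 0.5, 2.0), seed: int = 0) -> dict:
    """Inverse-crime recovery of injected ΔΔLogBF from noiseless curves."""
    errs = {}
    for b in biases:
        c1, c2 = make_pair_curves(b, noise=0.0, n_reps=1, seed=seed)
        fit = global_fit_pair(c1, c2, "REF", _fit_config(seed))
        errs[b] = abs(fit.ligands["TEST"].ddlogbf - b)
    return {"errors": errs, "max_abs_err": max(errs.values())}


def bias_recovery_noisy(n_seeds: int = 100, ddlogbf: float = 0.5, noise: float = 5.0,
                        n_reps: int = 6, seed: int = 0) -> dict:
    """Monte-Carlo recovery with 5%-of-Emax noise; reports the median error."""
    errs = []
    for i in range(n_seeds):
        c1, c2 = make_pair_curves(ddlogbf, noise=noise, n_reps=n_reps, seed=(seed * 100_003 + i) % 2**31)
        fit = global_fit_pair(c1, c2, "REF", _fit_config((seed + i) % 2**31, n_starts=8))
        errs.append(abs(fit.ligands["TEST"].ddlogbf - ddlogbf))
    return {"median_abs_err": float(np.median(errs)), "errors": errs}


def ci_calibration(n_sims: int = 200, ddlogbf: float = 0.5, noise: float = 5.0,
                   n_reps: int = 6, seed: int = 0) -> dict:
    """Coverage of the 95% profile-likelihood CI at a representative setting."""
    hits = 0
    for i in range(n_sims):
        c1, c2 = make_pair_curves(ddlogbf, noise=noise, n_reps=n_reps, seed=(seed * 200_003 + i) % 2**31)
        fit = global_fit_pair(c1, c2, "REF", _fit_config((seed + i) % 2**31, n_starts=6))
        lo, hi, _ = profile_ci(fit, "TEST")
        hits += lo - 1e-12 <= ddlogbf <= hi + 1e-12
    return {"coverage": hits / n_sims, "n_sims": n_sims}


def ci_grid_oracle_check(seed: int = 0, step: float = 0.01) -> dict:
    """Profile CI endpoints versus a dense grid-scan oracle.

    The oracle fixes ΔΔLogBF on a regular grid, re-optimizes all other
    parameters at every grid point, and reads the 95% bounds off the
    -2 log-likelihood-ratio curve by linear interpolation.
    """
    from scipy import stats as st

    c1, c2 = make_pair_curves(0.5, noise=5.0, n_reps=3, seed=seed,
                              ref_doses=np.linspace(-12.5, -6.5, 6),
                              test_doses=np.linspace(-10.0, -4.0, 6))
    fit = global_fit_pair(c1, c2, "REF", _fit_config(seed))
    lo, hi, _ = profile_ci(fit, "TEST")

    engine: _PairEngine = fit._engine
    idx = engine.ddbf_index("TEST")
    free = np.ones(engine.n_params, dtype=bool)
    free[idx] = False
    b_hat = fit.theta[idx]
    m2_hat = -2.0 * fit.loglik
    thresh = float(st.chi2.ppf(0.95, 1))
    grid = np.arange(b_hat - 1.5, b_hat + 1.5 + step / 2, step)
    prof = np.empty_like(grid)
    warm = fit.theta.copy()
    order = np.argsort(np.abs(grid - b_hat))  # scan outward from the MLE
    for j in order:
        theta0 = warm.copy()
        theta0[idx] = grid[j]
        theta, _, m2, _ = engine.irls(theta0, free, max_rounds=4)
        prof[j] = max(m2 - m2_hat, 0.0)
        warm = theta

    def _cross(side: int) -> float:
        sel = grid <= b_hat if side < 0 else grid >= b_hat
        g, p = grid[sel], prof[sel]
        if side < 0:
            g, p = g[::-1], p[::-1]
        above = np.nonzero(p >= thresh)[0]
        if above.size == 0:
            return -5.0 if side < 0 else 5.0
        k = above[0]
        g0, g1, p0, p1 = g[k - 1], g[k], p[k - 1], p[k]
        return float(g0 + (thresh - p0) * (g1 - g0) / (p1 - p0))

    oracle_lo, oracle_hi = _cross(-1), _cross(+1)
    return {
        "ci": (lo, hi), "oracle": (oracle_lo, oracle_hi),
        "max_endpoint_dev": max(abs(lo - oracle_lo), abs(hi - oracle_hi)),
    }


def lrt_type1_error(n_sims: int = 200, noise: float = 5.0, n_reps: int = 6,
                    alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the bias LRT when the true ΔΔLogBF is 0."""
    rejections = 0
    for i in range(n_sims):
        c1, c2 = make_pair_curves(0.0, noise=noise, n_reps=n_reps, seed=(seed * 300_007 + i) % 2**31)
        fit = global_fit_pair(c1, c2, "REF", _fit_config((seed + i) % 2**31, n_starts=6))
        _, p = lrt_bias(fit, "TEST")
        rejections += p < alpha
    return {"rejection_rate": rejections / n_sims, "n_sims": n_sims}


def flat_ligand_triage(seed: int = 0) -> dict:
    """Non-identifiability triage of a tau -> 0 flat-response ligand."""
    from .bias_engine import all_pairs_bias

    sc = make_scenario("flat_ligand", {"seed": seed})
    ds = simulate_study(sc)
    table = all_pairs_bias(ds, sc.readouts, "WT", config=_fit_config(seed, n_starts=8))
    row = table[table["ligand"] == "FLAT"].iloc[0]
    return {
        "identifiability_flat_readout": row["identifiability1"],
        "display": row["display"],
        "ci_unbounded": not (row["lo_bounded"] and row["hi_bounded"]),
        "flat_always_flagged": float(row["identifiability1"] == "flat_response"
                                     and row["display"] in ("observed", "nd")),
    }


def endpoint_sensitivity(seed: int = 0) -> dict:
    """Relative Emax of a slow test ligand across AUC endpoints 2/7/20 min.

    The test ligand's rise rate K1 is half the reference's, so early
    endpoints integrate proportionally less of its response; relative
    Emax must increase strictly from 2 to 7 to 20 min (noiseless).
    """
    sc = make_scenario("minimal", {"seed": seed, "noise_sd": 0.0})
    slow = []
    for lig in sc.ligands:
        if lig.role == "test":
            kin = {r: dataclasses.replace(kp, k1=0.10, k2=0.02)
                   for r, kp in lig.kinetic.items()}  # reference K1 is 0.20
            lig = dataclasses.replace(lig, kinetic=kin)
        slow.append(lig)
    sc = sc.with_overrides(ligands=slow)
    ds = simulate_study(sc)
    prof = endpoint_profiles(ds, [2.0, 7.0, 20.0])
    sub = prof[(prof["ligand"] == "TEST") & (prof["readout"] == "R1")].sort_values("endpoint_min")
    emax = dict(zip(sub["endpoint_min"], sub["emax"]))
    vals = [emax[2.0], emax[7.0], emax[20.0]]
    return {"emax_by_endpoint": emax,
            "strictly_increasing": float(vals[0] < vals[1] < vals[2])}


def multivariate_sanity(seed: int = 0) -> dict:
    """Planted-group recovery and degeneracy behavior of PCA/clustering."""
    rng = np.random.default_rng(seed)
    pairs = [("A", "B"), ("A", "C"), ("B", "C"), ("A", "D")]
    centers = {1: np.zeros(4), 2: np.array([2.0, 2.0, 2.0, 2.0]),
               3: np.array([-2.0, 2.0, -2.0, 2.0])}
    group_of = {"L1": 1, "L2": 1, "L3": 2, "L4": 2, "L5": 3, "L6": 3}
    rows = []
    for lig, g in group_of.items():
        vec = centers[g] + rng.normal(0.0, 0.02, size=4)  # gap ~10x spread
        for (r1, r2), v in zip(pairs, vec):
            rows.append(dict(cell_model="WT", ligand=lig, response1=r1, response2=r2,
                             ddlogbf=v, display="significant"))
    table = pd.DataFrame(rows)
    bm = build_bias_matrix(table, "WT", reference="REF")
    pca = run_pca(bm)
    labels, _, _ = cluster_pca(pca, k=3)
    truth = [1] + [group_of[l] for l in bm.ligands[1:]]  # reference sits in group 1
    ari = adjusted_rand_score(truth, labels)

    # FSH/B1-style overlay: an all-nd ligand row is imputed to zero and
    # must land exactly on the reference in PC space and co-cluster with it
    nd_rows = [dict(cell_model="WT", ligand="ND", response1=r1, response2=r2,
                    ddlogbf=math.nan, display="nd") for r1, r2 in pairs]
    table2 = pd.concat([table, pd.DataFrame(nd_rows)], ignore_index=True)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the all-nd overlay is intentional here
        bm2 = build_bias_matrix(table2, "WT", reference="REF")
        pca2 = run_pca(bm2)
    i_ref, i_nd = bm2.ligands.index("REF"), bm2.ligands.index("ND")
    overlay = float(np.allclose(pca2.scores[i_ref], pca2.scores[i_nd], atol=1e-10))
    labels2, _, _ = cluster_pca(pca2, k=3)
    co_cluster = float(labels2[i_ref] == labels2[i_nd])
    return {
        "planted_group_ari": float(ari),
        "variance_fraction_sum": float(pca.explained_variance_ratio.sum()),
        "identical_rows_identical_scores": overlay,
        "identical_rows_co_cluster": co_cluster,
    }
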