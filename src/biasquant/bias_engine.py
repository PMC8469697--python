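"""Operational-model bias quantification.

The Black–Leff operational model links ligand concentration [L] to a
response through the efficacy tau and the functional dissociation
constant Ka,

    E = Basal + (Emax - Basal) (tau [L])^n / ((tau [L])^n + (Ka + [L])^n).

For transduction-coefficient estimation the model is reparameterized in
LogKa and LogR = log10(tau/Ka),

    E = Basal + (Emax - Basal) / (1 + (([L]/10^LogKa + 1) / (10^LogR [L]))^n),

which is algebraically identical (the bracket equals ((Ka+[L])/(tau [L]))^n)
but exposes LogR directly.  For a pair of responses the reference agonist
is fitted with Ka := 1 (its LogR then absorbs the molar scale; bias
differences are invariant to this convention) and each test ligand gets
per-response LogKa, a shared transduction shift ΔLogR1, and the bias
factor ΔΔLogBF which enters response 2 as LogR2 + ΔLogR1 + ΔΔLogBF.
All curves of both responses are fitted jointly by maximum likelihood
under additive Gaussian noise with unknown per-response variance; the
variance is concentrated out analytically (sigma_r^2 = RSS_r / N_r), so
the optimizer minimizes sum_r N_r log(RSS_r / N_r) via iteratively
reweighted least squares, whose fixed point is the same MLE.

Uncertainty on ΔΔLogBF comes from the profile likelihood (re-optimizing
all nuisance parameters at each fixed bias value, 95% bounds where the
-2 log-likelihood ratio crosses the chi-square(1) quantile 3.841, inside
the (-5, +5) box) and significance from a likelihood-ratio test against
the nested model with the ligand's bias pinned to 0.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .types import (
    BiasEstimate,
    DoseResponseCurve,
    FitConfig,
    GlobalFitResult,
    LigandBiasParams,
    OperationalParams,
)

__all__ = [
    "eval_operational",
    "global_fit_pair",
    "profile_ci",
    "lrt_bias",
    "classify_curve",
    "all_pairs_bias",
    "CHI2_95_1DF",
]

CHI2_95_1DF = float(stats.chi2.ppf(0.95, 1))  # 3.841...
_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------

def eval_operational(params: OperationalParams, dose, form: str = "reparameterized"):
    """Operational-model response at log10-molar ``dose`` (scalar or array).

    ``form="canonical"`` evaluates the tau/Ka expression directly;
    ``form="reparameterized"`` uses the LogR form.  Both are algebraically
    identical; ``dose = -inf`` returns Basal in either form.
    """
    x = np.asarray(dose, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(np.isnan(x)):
        raise ValueError("non-finite dose")
    span = params.emax - params.basal
    n = params.hill_n
    with np.errstate(over="ignore", divide="ignore"):
        if form == "canonical":
            L = 10.0 ** x
            tau = 10.0 ** (params.log_r + params.log_ka)
            ka = 10.0 ** params.log_ka
            tl = (tau * L) ** n
            out = params.basal + span * tl / (tl + (ka + L) ** n)
        elif form == "reparameterized":
            # ((L/Ka + 1)/(R L))^n == (10^-(logR+logKa) + 10^-(logR+x))^n
            a = 10.0 ** (-(params.log_r + params.log_ka)) + 10.0 ** (-(params.log_r + x))
            out = params.basal + span / (1.0 + a ** n)
        else:
            raise ValueError(f"unknown form {form!r}")
    out = np.where(np.isneginf(x), params.basal, out)
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# joint fit machinery
# ---------------------------------------------------------------------------

class _PairEngine:
    """Data layout, parameter packing and likelihood for one readout pair.

    theta = [basal1, emax1, logR1, basal2, emax2, logR2,
             then per test ligand: logKa1, logKa2, dLogR1, ddLogBF].
    """

    def __init__(self, curves1: dict[str, DoseResponseCurve],
                 curves2: dict[str, DoseResponseCurve],
                 reference: str, config: FitConfig):
        if reference not in curves1 or reference not in curves2:
            raise ValueError(f"reference ligand {reference!r} missing from one response")
        if set(curves1) != set(curves2):
            raise ValueError("the two responses cover different ligand sets")
        self.reference = reference
        self.test_ligands = [l for l in curves1 if l != reference]
        if not self.test_ligands:
            raise ValueError("need at least one test ligand")
        self.config = config
        self.curves = (curves1, curves2)
        self.x: list[dict[str, np.ndarray]] = [{}, {}]
        self.y: list[dict[str, np.ndarray]] = [{}, {}]
        for r, cs in enumerate(self.curves):
            for lig, c in cs.items():
                if c.doses.size < 4:
                    raise ValueError(f"curve {lig}/{c.readout}: need >= 4 doses")
                x, y = c.flat()
                self.x[r][lig], self.y[r][lig] = x, y
        self.n_r = [sum(v.size for v in self.y[r].values()) for r in (0, 1)]
        self.n_params = 6 + 4 * len(self.test_ligands)
        self._bounds()

    # -- layout helpers -------------------------------------------------
    def lig_slice(self, lig: str) -> slice:
        i = self.test_ligands.index(lig)
        return slice(6 + 4 * i, 10 + 4 * i)

    def ddbf_index(self, lig: str) -> int:
        return 6 + 4 * self.test_ligands.index(lig) + 3

    def _bounds(self) -> None:
        cfg = self.config
        lo = np.empty(self.n_params)
        hi = np.empty(self.n_params)
        for r in (0, 1):
            yall = np.concatenate(list(self.y[r].values()))
            ymin, ymax = float(np.min(yall)), float(np.max(yall))
            rng = max(ymax - ymin, 1.0)
            lo[3 * r], hi[3 * r] = ymin - cfg.basal_emax_expand * rng, ymax + cfg.basal_emax_expand * rng
            lo[3 * r + 1], hi[3 * r + 1] = lo[3 * r], hi[3 * r]
            lo[3 * r + 2], hi[3 * r + 2] = cfg.log_r_bounds
        for i in range(len(self.test_ligands)):
            s = 6 + 4 * i
            lo[s], hi[s] = cfg.log_ka_bounds
            lo[s + 1], hi[s + 1] = cfg.log_ka_bounds
            lo[s + 2], hi[s + 2] = cfg.delta_bounds
            lo[s + 3], hi[s + 3] = cfg.delta_bounds
        self.lb, self.ub = lo, hi

    # -- model ----------------------------------------------------------
    def predict(self, theta: np.ndarray, r: int, lig: str) -> np.ndarray:
        basal, emax, log_r = theta[3 * r], theta[3 * r + 1], theta[3 * r + 2]
        x = self.x[r][lig]
        if lig == self.reference:
            log_ka = 0.0
            lr = log_r
        else:
            s = self.lig_slice(lig)
            log_ka = theta[s.start + r]
            lr = log_r + theta[s.start + 2] + (theta[s.start + 3] if r == 1 else 0.0)
        with np.errstate(over="ignore"):
            denom = 1.0 + 10.0 ** (-(lr + log_ka)) + 10.0 ** (-(lr + x))
        return basal + (emax - basal) / denom

    def residuals(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        out = []
        for r in (0, 1):
            res = [self.predict(theta, r, lig) - self.y[r][lig] for lig in self.y[r]]
            out.append(np.concatenate(res))
        return out[0], out[1]

    def rss(self, theta: np.ndarray) -> tuple[float, float]:
        r0, r1 = self.residuals(theta)
        return float(r0 @ r0), float(r1 @ r1)

    def m2ll(self, theta: np.ndarray) -> float:
        """Concentrated -2 log-likelihood (per-response unknown variance)."""
        floor2 = self.config.sigma_floor ** 2
        total = 0.0
        for n, ssq in zip(self.n_r, self.rss(theta)):
            total += n * (math.log(max(ssq / n, floor2)) + _LOG2PI + 1.0)
        return total

    # -- optimization ---------------------------------------------------
    def _solve(self, theta0: np.ndarray, free: np.ndarray, sigma: np.ndarray,
               ftol: float, max_nfev: int | None):
        """One weighted least-squares pass over the free parameters."""
        theta_full = theta0.copy()
        w = 1.0 / np.concatenate([np.full(self.n_r[0], sigma[0]), np.full(self.n_r[1], sigma[1])])

        def fun(p: np.ndarray) -> np.ndarray:
            theta_full[free] = p
            r0, r1 = self.residuals(theta_full)
            return np.concatenate([r0, r1]) * w

        sol = least_squares(fun, theta0[free], bounds=(self.lb[free], self.ub[free]),
                            xtol=ftol, ftol=ftol, gtol=1e-12, max_nfev=max_nfev)
        theta_full[free] = sol.x
        return theta_full, sol

    def irls(self, theta0: np.ndarray, free: np.ndarray | None = None,
             ftol: float = 1e-13, max_rounds: int = 8):
        """Iteratively reweighted LS converging to the concentrated MLE."""
        if free is None:
            free = np.ones(self.n_params, dtype=bool)
        floor = self.config.sigma_floor
        theta = np.clip(theta0, self.lb, self.ub)
        sigma = np.array([1.0, 1.0])
        ok = False
        for _ in range(max_rounds):
            theta, sol = self._solve(theta, free, sigma, ftol, None)
            ssq = self.rss(theta)
            new_sigma = np.array([max(math.sqrt(s / n), floor) for s, n in zip(ssq, self.n_r)])
            ok = bool(sol.success)
            if np.all(np.abs(new_sigma - sigma) <= 1e-9 * sigma + 1e-15):
                sigma = new_sigma
                break
            sigma = new_sigma
        return theta, sigma, self.m2ll(theta), ok

    def heuristic_start(self) -> np.ndarray:
        theta = np.empty(self.n_params)
        lr_ref = [0.0, 0.0]
        for r in (0, 1):
            ref_c = self.curves[r][self.reference]
            means = ref_c.dose_means
            yall = np.concatenate(list(self.y[r].values()))
            theta[3 * r] = float(np.min(yall))
            theta[3 * r + 1] = float(np.max(yall))
            lr_ref[r] = -_half_cross(ref_c.doses, means)
            theta[3 * r + 2] = lr_ref[r]
        for i, lig in enumerate(self.test_ligands):
            s = 6 + 4 * i
            dlr = [0.0, 0.0]
            for r in (0, 1):
                c = self.curves[r][lig]
                theta[s + r] = float(np.median(c.doses))
                dlr[r] = -_half_cross(c.doses, c.dose_means) - lr_ref[r]
            theta[s + 2] = dlr[0]
            theta[s + 3] = dlr[1] - dlr[0]
        return np.clip(theta, self.lb, self.ub)

    def multistart(self, free: np.ndarray | None = None,
                   extra_starts: list[np.ndarray] | None = None,
                   fixed_ref: np.ndarray | None = None):
        """Full multi-start protocol: heuristic + Latin-hypercube starts,
        coarse screening, then tight IRLS polish of the best candidates.
        Parameters masked out of ``free`` are pinned at ``fixed_ref``."""
        cfg = self.config
        if free is None:
            free = np.ones(self.n_params, dtype=bool)
        if not free.all() and fixed_ref is None:
            raise ValueError("fixed_ref required when parameters are pinned")
        starts = [self.heuristic_start()]
        if extra_starts:
            starts.extend(np.clip(s, self.lb, self.ub) for s in extra_starts)
        n_lhs = max(cfg.n_starts - len(starts), 0)
        if n_lhs:
            sampler = qmc.LatinHypercube(d=self.n_params, seed=cfg.seed)
            unit = sampler.random(n_lhs)
            starts.extend(self.lb + unit * (self.ub - self.lb))
        if not free.all():
            pinned = ~free
            starts = [s.copy() for s in starts]
            for s in starts:
                s[pinned] = fixed_ref[pinned]
        coarse = []
        n_ok = 0
        for x0 in starts:
            theta, sol = self._solve(x0, free, np.array([1.0, 1.0]), 1e-8, 60 * self.n_params)
            n_ok += bool(sol.success)
            coarse.append((2.0 * sol.cost, theta))
        coarse.sort(key=lambda t: t[0])
        best = None
        for _, theta0 in coarse[: max(cfg.polish_top, 1)]:
            theta, sigma, m2, ok = self.irls(theta0, free)
            if best is None or m2 < best[2] - 1e-12 or (
                    abs(m2 - best[2]) <= 1e-12
                    and _total_abs_bias(self, theta) < _total_abs_bias(self, best[0])):
                best = (theta, sigma, m2, ok)
        theta, sigma, m2, ok = best
        return theta, sigma, m2, ok, len(starts), n_ok


def _total_abs_bias(engine: _PairEngine, theta: np.ndarray) -> float:
    # parsimony tie-break between equal-likelihood optima
    return sum(abs(theta[engine.ddbf_index(l)]) for l in engine.test_ligands)


def _half_cross(doses: np.ndarray, means: np.ndarray) -> float:
    """Dose at which a curve crosses the midpoint of its own range."""
    lo, hi = float(np.min(means)), float(np.max(means))
    if hi - lo <= 0:
        return float(np.median(doses))
    half = 0.5 * (lo + hi)
    above = means >= half
    idx = np.argmax(above) if above.any() else None
    if idx is None or idx == 0:
        return float(doses[0]) if above.all() else float(np.median(doses))
    x0, x1 = doses[idx - 1], doses[idx]
    y0, y1 = means[idx - 1], means[idx]
    if y1 == y0:
        return float(x1)
    return float(x0 + (half - y0) * (x1 - x0) / (y1 - y0))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def global_fit_pair(curves1: dict[str, DoseResponseCurve],
                    curves2: dict[str, DoseResponseCurve],
                    reference: str,
                    config: FitConfig | None = None) -> GlobalFitResult:
    """Joint operational-model fit of two responses across all ligands.

    ``curves1``/``curves2`` map ligand name to its normalized curve on
    response 1 / response 2.  The Hill slope is fixed to 1.  Returns the
    best multi-start optimum; ``ΔΔLogBF > 0`` means bias toward response 2.
    """
    config = config or FitConfig()
    engine = _PairEngine(curves1, curves2, reference, config)
    theta, sigma, m2, ok, n_started, n_conv = engine.multistart()
    resp_names = (next(iter(curves1.values())).readout, next(iter(curves2.values())).readout)
    ligs = {
        lig: LigandBiasParams(
            log_ka1=float(theta[engine.lig_slice(lig).start]),
            log_ka2=float(theta[engine.lig_slice(lig).start + 1]),
            delta_log_r1=float(theta[engine.lig_slice(lig).start + 2]),
            ddlogbf=float(theta[engine.ddbf_index(lig)]),
        )
        for lig in engine.test_ligands
    }
    return GlobalFitResult(
        responses=resp_names, reference=reference,
        basal=(float(theta[0]), float(theta[3])),
        emax=(float(theta[1]), float(theta[4])),
        log_r=(float(theta[2]), float(theta[5])),
        ligands=ligs, sigma=(float(sigma[0]), float(sigma[1])),
        loglik=-0.5 * m2, n_starts=n_started, n_converged=n_conv,
        converged=ok, theta=theta, _engine=engine,
    )


def _profile_m2ll(engine: _PairEngine, idx: int, value: float,
                  warm: np.ndarray) -> tuple[float, np.ndarray]:
    free = np.ones(engine.n_params, dtype=bool)
    free[idx] = False
    theta0 = warm.copy()
    theta0[idx] = value
    theta, _, m2, _ = engine.irls(theta0, free, max_rounds=5)
    return m2, theta


def profile_ci(fit: GlobalFitResult, ligand: str, level: float = 0.95):
    """Profile-likelihood CI for a ligand's ΔΔLogBF.

    Walks outward from the MLE re-optimizing all other parameters at each
    fixed bias value (warm-started continuation), then refines each bound
    by bisection on the -2 log-likelihood-ratio crossing.  Bounds clipped
    at the (-5, +5) box are flagged unbounded.
    Returns ``(lo, hi, (lo_bounded, hi_bounded))``.
    """
    if not fit.converged:
        raise ValueError("cannot profile a non-converged fit")
    engine: _PairEngine = fit._engine
    cfg = engine.config
    idx = engine.ddbf_index(ligand)
    thresh = float(stats.chi2.ppf(level, 1))
    m2_hat = -2.0 * fit.loglik
    b_hat = float(fit.theta[idx])
    box_lo, box_hi = cfg.delta_bounds

    def delta(b: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        m2, theta = _profile_m2ll(engine, idx, b, warm)
        return max(m2 - m2_hat, 0.0), theta

    results = {}
    for sign, box in ((+1.0, box_hi), (-1.0, box_lo)):
        step = cfg.profile_step
        b_prev, d_prev, warm = b_hat, 0.0, fit.theta.copy()
        bound, bounded = box, False
        while True:
            b = b_prev + sign * step
            if (sign > 0 and b >= box) or (sign < 0 and b <= box):
                b = box
            d, warm = delta(b, warm)
            if d >= thresh:
                # refine crossing in (b_prev, b) by bisection with warm starts
                lo_b, hi_b = (b_prev, b) if sign > 0 else (b, b_prev)
                d_lo, d_hi = (d_prev, d) if sign > 0 else (d, d_prev)
                while hi_b - lo_b > cfg.profile_tol:
                    mid = 0.5 * (lo_b + hi_b)
                    dm, warm = delta(mid, warm)
                    crossing_side = dm >= thresh
                    if (crossing_side and sign > 0) or (not crossing_side and sign < 0):
                        hi_b = mid
                    else:
                        lo_b = mid
                bound, bounded = 0.5 * (lo_b + hi_b), True
                break
            if b == box:
                bound, bounded = box, False
                break
            # adaptive step-out on flat profiles
            if d - d_prev < 0.1:
                step = min(step * 1.6, 0.8)
            b_prev, d_prev = b, d
        results[sign] = (bound, bounded)
    lo, lo_bounded = results[-1.0]
    hi, hi_bounded = results[+1.0]
    return float(lo), float(hi), (bool(lo_bounded), bool(hi_bounded))


def lrt_bias(fit: GlobalFitResult, ligand: str) -> tuple[float, float]:
    """Likelihood-ratio test of ΔΔLogBF = 0 for one ligand.

    Refits the nested null model (same equations, this ligand's bias
    pinned to 0, everything else free) with the same multi-start
    protocol; the statistic 2(logL_full - logL_null) is floored at 0 and
    compared with chi-square(1).  If the null ever beats the full model
    the full fit is restarted from the null optimum (likelihood sanity).
    """
    if not fit.converged:
        raise ValueError("cannot test a non-converged fit")
    engine: _PairEngine = fit._engine
    idx = engine.ddbf_index(ligand)
    free = np.ones(engine.n_params, dtype=bool)
    free[idx] = False
    warm = fit.theta.copy()
    warm[idx] = 0.0
    theta_null, _, m2_null, _, _, _ = engine.multistart(free=free, extra_starts=[warm],
                                                        fixed_ref=warm)
    m2_full = -2.0 * fit.loglik
    if m2_null < m2_full - 1e-9:
        # null found a better optimum: restart the full fit from it
        theta, sigma, m2, ok = engine.irls(theta_null)
        if m2 < m2_full:
            fit.theta = theta
            fit.loglik = -0.5 * m2
            fit.sigma = (float(sigma[0]), float(sigma[1]))
            for lig in engine.test_ligands:
                s = engine.lig_slice(lig).start
                fit.ligands[lig] = LigandBiasParams(*map(float, theta[s:s + 4]))
            m2_full = m2
    stat = max(m2_null - m2_full, 0.0)
    p = float(stats.chi2.sf(stat, 1))
    return float(stat), p


def classify_curve(curve: DoseResponseCurve, resid_sd: float,
                   at_boundary: bool = False,
                   log_r_ci_span: float | None = None) -> str:
    """Identifiability triage for one concentration/activity curve.

    ``flat_response``: observed dynamic range below twice the residual sd
    (or a transduction-coefficient profile CI wider than 4 log units /
    pinned at both box bounds, when supplied); ``boundary``: an MLE sitting
    on a parameter bound; ``identifiable`` otherwise.
    """
    dyn = float(np.ptp(curve.dose_means))
    if dyn < 2.0 * resid_sd:
        return "flat_response"
    if log_r_ci_span is not None and log_r_ci_span > 4.0:
        return "flat_response"
    if at_boundary:
        return "boundary"
    return "identifiable"


def _at_bound(value: float, bounds: tuple[float, float], tol: float = 1e-6) -> bool:
    return value <= bounds[0] + tol or value >= bounds[1] - tol


def _display_class(id1: str, id2: str, value: float, p: float, alpha: float) -> str:
    non1, non2 = id1 != "identifiable", id2 != "identifiable"
    if non1 and non2:
        return "nd"
    if non1 or non2:
        return "observed" if np.isfinite(value) and value != 0.0 else "nd"
    return "significant" if p < alpha else "none"


BIAS_TABLE_COLUMNS = [
    "cell_model", "ligand", "response1", "response2", "ddlogbf",
    "ci_lo", "ci_hi", "lo_bounded", "hi_bounded", "lrt_stat", "p_lrt",
    "identifiability1", "identifiability2", "identifiability", "display",
]


def all_pairs_bias(ds, readouts: list[str], cell_model: str,
                   reference: str | None = None,
                   config: FitConfig | None = None,
                   endpoint: float | None = None) -> pd.DataFrame:
    """Bias sweep over all unordered readout pairs of one cell model.

    Runs the global fit, profile CI, LRT and identifiability triage for
    each pair; positive ΔΔLogBF means bias toward ``response2`` (pair
    orientation follows the supplied readout list).  Per-pair failures
    are recorded as ``nd`` rows, never abort the sweep.
    """
    from .dose_response import normalize_to_reference

    config = config or FitConfig()
    if len(readouts) < 2:
        raise ValueError("need at least 2 readouts")
    curves = normalize_to_reference(ds, endpoint=endpoint, reference=reference)
    ref = reference
    if ref is None:
        ref = next(iter({c.reference_ligand for c in curves.values()}))
    rows = []
    for r1, r2 in itertools.combinations(readouts, 2):
        c1 = {lig: c for (cm, lig, ro), c in curves.items() if cm == cell_model and ro == r1}
        c2 = {lig: c for (cm, lig, ro), c in curves.items() if cm == cell_model and ro == r2}
        try:
            fit = global_fit_pair(c1, c2, ref, config)
        except Exception as exc:  # record and continue the sweep
            for lig in set(c1) - {ref}:
                rows.append(_nd_row(cell_model, lig, r1, r2, f"fit failed: {exc}"))
            continue
        for lig, lp in fit.ligands.items():
            try:
                if config.compute_ci:
                    lo, hi, (lb, hb) = profile_ci(fit, lig)
                else:
                    lo = hi = math.nan
                    lb = hb = False
                stat, p = (lrt_bias(fit, lig) if config.compute_lrt else (math.nan, math.nan))
                lp = fit.ligands[lig]  # lrt_bias may refresh the MLE
                bnd = (_at_bound(lp.ddlogbf, config.delta_bounds)
                       or _at_bound(lp.delta_log_r1, config.delta_bounds))
                id1 = classify_curve(c1[lig], fit.sigma[0],
                                     at_boundary=bnd or _at_bound(lp.log_ka1, config.log_ka_bounds))
                id2 = classify_curve(c2[lig], fit.sigma[1],
                                     at_boundary=bnd or _at_bound(lp.log_ka2, config.log_ka_bounds))
                overall = "identifiable" if id1 == id2 == "identifiable" else (
                    "flat_response" if "flat_response" in (id1, id2) else "boundary")
                disp = _display_class(id1, id2, lp.ddlogbf,
                                      p if math.isfinite(p) else 1.0, config.alpha)
                rows.append(dict(cell_model=cell_model, ligand=lig, response1=r1, response2=r2,
                                 ddlogbf=lp.ddlogbf, ci_lo=lo, ci_hi=hi,
                                 lo_bounded=lb, hi_bounded=hb, lrt_stat=stat, p_lrt=p,
                                 identifiability1=id1, identifiability2=id2,
                                 identifiability=overall, display=disp))
            except Exception as exc:
                rows.append(_nd_row(cell_model, lig, r1, r2, f"post-fit failed: {exc}"))
    return pd.DataFrame(rows, columns=BIAS_TABLE_COLUMNS)


def _nd_row(cell_model: str, lig: str, r1: str, r2: str, msg: str) -> dict:
    return dict(cell_model=cell_model, ligand=lig, response1=r1, response2=r2,
                ddlogbf=math.nan, ci_lo=math.nan, ci_hi=math.nan,
                lo_bounded=False, hi_bounded=False, lrt_stat=math.nan, p_lrt=math.nan,
                identifiability1="flat_response", identifiability2="flat_response",
                identifiability="flat_response", display="nd")


def bias_estimates(table: pd.DataFrame) -> list[BiasEstimate]:
    """Convert a bias table to :class:`BiasEstimate` records."""
    out = []
    for _, row in table.iterrows():
        out.append(BiasEstimate(
            ligand=row["ligand"], pair=(row["response1"], row["response2"]),
            value=row["ddlogbf"], ci95=(row["ci_lo"], row["ci_hi"]),
            ci_bounded=(bool(row["lo_bounded"]), bool(row["hi_bounded"])),
            p_lrt=row["p_lrt"], lrt_stat=row["lrt_stat"],
            identifiability=row["identifiability"], display=row["display"],
        ))
    return out
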