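"""Concentration/activity curves from kinetic AUCs.

Kinetic traces are integrated to the area under the curve (AUC) at a
chosen endpoint and expressed as percent of the reference agonist's
observed maximal response: every replicate AUC is divided by the mean
AUC of the reference ligand at its top dose (per cell model, readout and
endpoint) and multiplied by 100, so the reference top dose maps to a
mean of exactly 100.  An alternative convention normalizes by the
reference signal at a fixed time point instead of the full-window AUC.

Empirical potency/efficacy summaries come from a four-parameter logistic
(4PL) fit on log10 dose; the operational model in :mod:`bias_engine`
remains the authoritative pharmacological fit.  Endpoint profiles rebuild
the curves at several AUC endpoints (e.g. 2, 7, 20 min) to expose
kinetics-induced shifts in relative Emax and potency, and ligand
comparisons use Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .kinetics import trace_auc
from .types import DoseResponseCurve, HillFit

__all__ = [
    "normalize_to_reference",
    "fit_hill",
    "ec_fraction",
    "endpoint_profiles",
    "welch_compare",
    "hill_response",
]


def _auc_table(ds, endpoint: float | None) -> pd.DataFrame:
    rows = [
        dict(cell_model=tr.cell_model, ligand=tr.ligand, readout=tr.readout,
             log10_conc_M=tr.log10_conc, replicate=tr.replicate,
             auc=trace_auc(tr, endpoint))
        for tr in ds.traces()
    ]
    return pd.DataFrame(rows)


def normalize_to_reference(ds, endpoint: float | None = None,
                           reference: str | None = None,
                           convention: str = "auc",
                           norm_time: float = 20.0) -> dict[tuple, DoseResponseCurve]:
    """Build normalized curves, keyed by (cell_model, ligand, readout).

    ``convention="auc"`` (default) normalizes replicate AUCs by the mean
    reference top-dose AUC; ``convention="timepoint"`` divides instead by
    the mean reference top-dose signal at ``norm_time`` minutes.  Readouts
    whose reference maximum is not positive are withheld (flagged in the
    raised error if nothing remains).
    """
    if isinstance(ds.provenance, str):
        ref = reference
    else:
        ref = reference or ds.provenance.reference.name
    if ref is None:
        raise ValueError("reference ligand must be given for imported data")
    if convention not in ("auc", "timepoint"):
        raise ValueError(f"unknown normalization convention {convention!r}")

    if convention == "auc":
        tab = _auc_table(ds, endpoint)
        value_col = "auc"
    else:
        df = ds.df
        i = (df["time_min"] - norm_time).abs().groupby(
            [df["cell_model"], df["ligand"], df["readout"],
             df["log10_conc_M"], df["replicate"]]).idxmin()
        tab = df.loc[i.values, ["cell_model", "ligand", "readout",
                                "log10_conc_M", "replicate", "signal"]].copy()
        value_col = "signal"

    curves: dict[tuple, DoseResponseCurve] = {}
    withheld = []
    for (cell, readout), sub in tab.groupby(["cell_model", "readout"], sort=True):
        ref_sub = sub[sub["ligand"] == ref]
        if ref_sub.empty:
            raise ValueError(f"reference ligand {ref!r} missing for ({cell}, {readout})")
        top = ref_sub["log10_conc_M"].max()
        ref_max = ref_sub.loc[ref_sub["log10_conc_M"] == top, value_col].mean()
        if not (ref_max > 0):
            withheld.append((cell, readout))
            continue
        for lig, lsub in sub.groupby("ligand", sort=True):
            piv = lsub.pivot_table(index="log10_conc_M", columns="replicate",
                                   values=value_col, aggfunc="mean")
            doses = piv.index.to_numpy(dtype=float)
            resp = 100.0 * piv.to_numpy(dtype=float) / ref_max
            ep = endpoint if endpoint is not None else float(ds.df["time_min"].max())
            curves[(cell, lig, readout)] = DoseResponseCurve(
                cell_model=cell, ligand=lig, readout=readout, endpoint_min=ep,
                doses=doses, responses=resp, reference_ligand=ref)
    if not curves:
        raise ValueError(f"all readouts withheld (non-positive reference max): {withheld}")
    return curves


# ---------------------------------------------------------------------------
# empirical 4PL fitting
# ---------------------------------------------------------------------------

def hill_response(x, basal: float, emax: float, log_ec50: float, hill_n: float):
    """Four-parameter logistic on log10 dose."""
    return basal + (emax - basal) / (1.0 + 10.0 ** ((log_ec50 - np.asarray(x, dtype=float)) * hill_n))


def fit_hill(curve: DoseResponseCurve, fix_n: float | None = None,
             flat_tol: float = 1e-9) -> HillFit:
    """Least-squares 4PL fit of a normalized curve.

    ``fix_n`` pins the Hill slope.  Flat curves (no dynamic range) return
    a degenerate flag instead of parameters; a fitted EC50 more than two
    log units outside the dosed range is flagged ``extrapolated``.
    """
    x, y = curve.flat()
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct doses for a 4PL fit")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite responses")
    means = curve.dose_means
    span = float(np.ptp(means))
    scale = max(np.max(np.abs(y)), 1.0)
    if span <= flat_tol * scale:
        return HillFit(math.nan, math.nan, math.nan, math.nan, {}, rss=float(np.var(y) * y.size),
                       degenerate=True, message="flat curve, no dynamic range")

    descending = means[-1] < means[0]
    x_lo, x_hi = float(x.min()), float(x.max())

    def resid(theta):
        b, e, lec, n = theta
        if fix_n is not None:
            n = fix_n
        return hill_response(x, b, e, lec, n) - y

    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    pad = max(y_hi - y_lo, 1.0)
    b0 = means[-1] if descending else means[0]
    e0 = means[0] if descending else means[-1]
    from .bias_engine import _half_cross  # midpoint-crossing heuristic
    lec0 = _half_cross(curve.doses, means if not descending else -means)
    lb = [y_lo - pad, y_lo - pad, x_lo - 4.0, 0.05]
    ub = [y_hi + pad, y_hi + pad, x_hi + 4.0, 10.0]
    best = None
    for n0 in ((fix_n,) if fix_n is not None else (0.7, 1.0, 2.0)):
        x0 = np.clip([b0, e0, lec0, n0], lb, ub)
        sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-15, ftol=1e-15, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    b, e, lec, n = best.x
    if fix_n is not None:
        n = fix_n
    # standard errors from the Gauss-Newton covariance
    se: dict[str, float] = {}
    dof = y.size - best.x.size
    if dof > 0 and best.cost > 0:
        try:
            jtj = best.jac.T @ best.jac
            cov = np.linalg.pinv(jtj) * (2.0 * best.cost / dof)
            for name, v in zip(("basal", "emax", "log_ec50", "hill_n"), np.diag(cov)):
                se[name] = float(np.sqrt(max(v, 0.0)))
        except np.linalg.LinAlgError:
            pass
    return HillFit(basal=float(b), emax=float(e), log_ec50=float(lec), hill_n=float(n),
                   se=se, rss=float(2.0 * best.cost),
                   descending=bool(e < b),
                   extrapolated=not (x_lo - 2.0 <= lec <= x_hi + 2.0))


def ec_fraction(fit: HillFit, f: float) -> float:
    """log10 concentration producing fraction ``f`` of the fitted span.

    ``log10 EC_f = log_ec50 + (1/n) log10(f/(1-f))``; ``f=0.5`` returns
    the EC50 itself, ``f=0.8`` the EC80 used for sub-maximal stimulation.
    """
    if fit.degenerate:
        raise ValueError("cannot derive EC fractions from a degenerate fit")
    if not (0.0 < f < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    return fit.log_ec50 + math.log10(f / (1.0 - f)) / fit.hill_n


def endpoint_profiles(ds, endpoints: Sequence[float],
                      reference: str | None = None,
                      fix_n: float | None = None) -> pd.DataFrame:
    """Relative Emax and pEC50 per (endpoint, cell model, ligand, readout).

    For each AUC endpoint the curves are renormalized against the
    reference at that same endpoint and refitted, exposing how apparent
    efficacy and potency depend on the stimulation time considered.
    """
    t_max = float(ds.df["time_min"].max())
    bad = [e for e in endpoints if not (0 < e <= t_max + 1e-9)]
    if bad:
        raise ValueError(f"endpoints outside recorded window (0, {t_max}]: {bad}")
    rows = []
    for ep in endpoints:
        curves = normalize_to_reference(ds, endpoint=float(ep), reference=reference)
        for (cell, lig, readout), curve in curves.items():
            try:
                fit = fit_hill(curve, fix_n=fix_n)
            except ValueError as exc:
                rows.append(dict(endpoint_min=float(ep), cell_model=cell, ligand=lig,
                                 readout=readout, emax=math.nan, p_ec50=math.nan,
                                 degenerate=True, note=str(exc)))
                continue
            rows.append(dict(
                endpoint_min=float(ep), cell_model=cell, ligand=lig, readout=readout,
                emax=fit.emax, p_ec50=(-fit.log_ec50 if not fit.degenerate else math.nan),
                degenerate=fit.degenerate, note=""))
    return pd.DataFrame(rows)


def welch_compare(a, b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: returns (t, Satterthwaite df, p).

    Two-sided.  If both samples have zero variance and equal means the
    comparison is vacuous and (0, df, 1) is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in samples")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
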