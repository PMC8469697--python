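"""Operational-model global fit, profile CIs, LRT, identifiability triage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biasquant import (
    FitConfig,
    OperationalParams,
    all_pairs_bias,
    bias_estimates,
    classify_curve,
    eval_operational,
    global_fit_pair,
    lrt_bias,
    make_scenario,
    profile_ci,
    simulate_study,
)
from biasquant.validation import make_pair_curves


class TestEvalOperational:
    def test_zero_ligand_limit_returns_basal(self):
        p = OperationalParams(basal=7.0, emax=100.0, log_ka=-7.0, log_r=7.0)
        assert eval_operational(p, -np.inf) == 7.0
        assert eval_operational(p, -np.inf, form="canonical") == 7.0

    def test_unit_tau_plateau_is_half_span(self):
        # tau = 10^(log_r + log_ka) = 1 -> saturating response (Basal+Emax)/2
        p = OperationalParams(basal=0.0, emax=100.0, log_ka=-6.0, log_r=6.0)
        assert eval_operational(p, 2.0) == pytest.approx(50.0, rel=1e-4)

    def test_reference_value_at_ka_dose(self):
        p = OperationalParams(basal=0.0, emax=100.0, log_ka=-7.0, log_r=7.5)
        assert eval_operational(p, -7.0) == pytest.approx(61.257, abs=1e-3)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(basal=st.floats(0, 50), span=st.floats(1, 200), log_ka=st.floats(-12, -2),
           log_r=st.floats(-3, 12), n=st.floats(0.5, 2), dose=st.floats(-12.5, -4))
    def test_canonical_and_reparameterized_forms_agree(self, basal, span, log_ka, log_r, n, dose):
        p = OperationalParams(basal=basal, emax=basal + span, log_ka=log_ka, log_r=log_r, hill_n=n)
        a = eval_operational(p, dose, form="canonical")
        b = eval_operational(p, dose, form="reparameterized")
        assert a == pytest.approx(b, rel=1e-10, abs=1e-12)

    def test_unknown_form_rejected(self):
        p = OperationalParams(0.0, 100.0, -7.0, 7.0)
        with pytest.raises(ValueError, match="unknown form"):
            eval_operational(p, -7.0, form="banana")


class TestGlobalFit:
    def test_noiseless_null_bias_recovered_to_machine_precision(self):
        c1, c2 = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        assert abs(fit.ligands["TEST"].ddlogbf) < 1e-6

    def test_noiseless_strong_bias_recovered(self):
        c1, c2 = make_pair_curves(1.5, noise=0.0, n_reps=1, seed=0)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        assert fit.ligands["TEST"].ddlogbf == pytest.approx(1.5, abs=1e-3)

    def test_reference_dose_shift_leaves_bias_invariant(self):
        c1, c2 = make_pair_curves(0.8, noise=0.0, n_reps=1, seed=0)
        fit0 = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        for cs in (c1, c2):
            for c in cs.values():
                c.doses = c.doses + 1.0
        fit1 = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        assert fit1.ligands["TEST"].ddlogbf == pytest.approx(
            fit0.ligands["TEST"].ddlogbf, abs=1e-5)
        # the shared transduction coefficients absorb the unit change
        assert fit1.log_r[0] == pytest.approx(fit0.log_r[0] - 1.0, abs=1e-4)

    def test_missing_reference_rejected(self):
        c1, c2 = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        c1.pop("REF")
        with pytest.raises(ValueError, match="different ligand sets|reference"):
            global_fit_pair(c1, c2, "REF", FitConfig(n_starts=4, seed=0))

    def test_sigma_estimates_match_injected_noise(self):
        c1, c2 = make_pair_curves(0.5, noise=5.0, n_reps=6, seed=1)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        assert fit.sigma[0] == pytest.approx(5.0, rel=0.35)
        assert fit.sigma[1] == pytest.approx(5.0, rel=0.35)


class TestProfileAndLrt:
    def test_noiseless_null_ci_is_tight_around_zero(self):
        c1, c2 = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        lo, hi, (bl, bh) = profile_ci(fit, "TEST")
        assert bl and bh
        assert lo <= 0.0 <= hi
        assert hi - lo < 0.01

    def test_point_estimate_inside_its_own_ci(self):
        c1, c2 = make_pair_curves(0.5, noise=5.0, n_reps=3, seed=3)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        lo, hi, _ = profile_ci(fit, "TEST")
        assert lo <= fit.ligands["TEST"].ddlogbf <= hi

    def test_noiseless_null_data_give_null_lrt(self):
        c1, c2 = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        stat, p = lrt_bias(fit, "TEST")
        assert stat == pytest.approx(0.0, abs=1e-4)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_lrt_statistic_never_negative(self):
        for i in range(3):
            c1, c2 = make_pair_curves(0.3, noise=5.0, n_reps=3, seed=50 + i)
            fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=6, seed=i))
            stat, p = lrt_bias(fit, "TEST")
            assert stat >= 0.0 and 0.0 <= p <= 1.0

    def test_strong_bias_is_detected(self):
        c1, c2 = make_pair_curves(1.5, noise=5.0, n_reps=6, seed=4)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        stat, p = lrt_bias(fit, "TEST")
        assert p < 1e-4


class TestIdentifiability:
    def test_zero_signal_curve_classified_flat(self):
        from biasquant.types import DoseResponseCurve

        c = DoseResponseCurve("WT", "L", "R", 30.0, np.linspace(-10, -5, 6),
                              np.zeros((6, 3)), "REF")
        assert classify_curve(c, resid_sd=2.0) == "flat_response"

    def test_high_snr_curve_classified_identifiable(self):
        c1, _ = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        assert classify_curve(c1["TEST"], resid_sd=5.0) == "identifiable"

    def test_wide_log_r_profile_triggers_flat(self):
        c1, _ = make_pair_curves(0.0, noise=0.0, n_reps=1, seed=0)
        assert classify_curve(c1["TEST"], resid_sd=5.0, log_r_ci_span=6.0) == "flat_response"

    def test_flat_ligand_never_reported_significant(self, flat_dataset):
        sc, ds = flat_dataset
        table = all_pairs_bias(ds, sc.readouts, "WT",
                               config=FitConfig(n_starts=8, seed=0))
        row = table[table.ligand == "FLAT"].iloc[0]
        assert row["identifiability1"] == "flat_response"
        assert row["display"] in ("observed", "nd")
        for est in bias_estimates(table):
            if est.ligand == "FLAT":
                assert est.display != "significant"

    def test_doubly_flat_ligand_has_unbounded_ci_and_nd_display(self):
        # ligand with tau ~ 0 on both responses: the bias parameter is free
        c1, c2 = make_pair_curves(0.0, noise=2.0, n_reps=3, seed=9)
        rng = np.random.default_rng(1)
        for cs in (c1, c2):
            t = cs["TEST"]
            t.responses = rng.normal(0.0, 2.0, size=t.responses.shape)
        fit = global_fit_pair(c1, c2, "REF", FitConfig(n_starts=8, seed=0))
        lo, hi, (bl, bh) = profile_ci(fit, "TEST")
        assert (not bl) or (not bh)  # at least one bound clipped at the box
        assert (not bl and lo == -5.0) or (not bh and hi == 5.0)


class TestAllPairs:
    def test_pair_count_for_five_readouts(self):
        import dataclasses

        sc = make_scenario("minimal", {"seed": 6, "n_replicates": 2,
                                       "time_grid": np.arange(0.0, 20.01, 2.0)})
        readouts = ["A", "B", "C", "D", "E"]
        ligs = []
        for lig in sc.ligands:
            op = lig.operational["R1"]
            kin = lig.kinetic["R1"]
            ligs.append(dataclasses.replace(
                lig, operational={r: op for r in readouts},
                kinetic={r: kin for r in readouts}))
        sc = sc.with_overrides(readouts=readouts, ligands=ligs,
                               noise_sd={r: 0.05 for r in readouts})
        ds = simulate_study(sc)
        table = all_pairs_bias(ds, readouts, "WT",
                               config=FitConfig(n_starts=4, seed=0,
                                                compute_ci=False, compute_lrt=False))
        assert len(table) == math.comb(5, 2)  # one test ligand per pair

    def test_sign_convention_follows_pair_orientation(self, minimal_dataset):
        cfg = FitConfig(n_starts=6, seed=0, compute_ci=False, compute_lrt=False)
        fwd = all_pairs_bias(minimal_dataset, ["R1", "R2"], "WT", config=cfg)
        rev = all_pairs_bias(minimal_dataset, ["R2", "R1"], "WT", config=cfg)
        v_fwd = float(fwd.ddlogbf.iloc[0])
        v_rev = float(rev.ddlogbf.iloc[0])
        assert v_fwd > 0  # injected bias points toward R2 (= response 2)
        assert v_rev == pytest.approx(-v_fwd, abs=0.02)

    def test_too_few_readouts_rejected(self, minimal_dataset):
        with pytest.raises(ValueError, match="at least 2"):
            all_pairs_bias(minimal_dataset, ["R1"], "WT")
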