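"""Normalization, 4PL fitting, EC fractions, endpoint profiles, Welch test."""

import dataclasses
import math

import numpy as np
import pytest

from biasquant import (
    DoseResponseCurve,
    OperationalParams,
    ec_fraction,
    endpoint_profiles,
    fit_hill,
    hill_response,
    make_scenario,
    normalize_to_reference,
    simulate_study,
    welch_compare,
)
from biasquant.synthetic import StudyDataset


def _curve(doses, responses):
    return DoseResponseCurve("WT", "L", "R", 30.0, np.asarray(doses, float),
                             np.asarray(responses, float), "REF")


class TestNormalization:
    def test_reference_top_dose_maps_to_mean_100(self, minimal_dataset):
        curves = normalize_to_reference(minimal_dataset)
        ref = curves[("WT", "REF", "R1")]
        assert float(np.mean(ref.responses[-1])) == pytest.approx(100.0, abs=1e-9)

    def test_zero_signal_ligand_maps_to_zero(self):
        sc = make_scenario("flat_ligand", {"seed": 2, "noise_sd": 0.0})
        curves = normalize_to_reference(simulate_study(sc))
        flat = curves[("WT", "FLAT", "R1")]
        # tau ~ 1e-7 leaves a vanishing fractional response; zero at the
        # resolution of a percent-scale readout
        np.testing.assert_allclose(flat.responses, 0.0, atol=1e-4)

    def test_scale_invariance(self, minimal_dataset):
        scaled_df = minimal_dataset.df.copy()
        scaled_df["signal"] *= 3.7
        scaled = StudyDataset(scaled_df, provenance=minimal_dataset.provenance)
        a = normalize_to_reference(minimal_dataset)
        b = normalize_to_reference(scaled)
        for key in a:
            np.testing.assert_allclose(a[key].responses, b[key].responses, rtol=1e-12)

    def test_missing_reference_rejected(self, minimal_dataset):
        df = minimal_dataset.df[minimal_dataset.df.ligand != "REF"]
        with pytest.raises(ValueError, match="reference ligand"):
            normalize_to_reference(StudyDataset(df), reference="REF")

    def test_double_plateau_ligand_reaches_emax_200(self):
        # test ligand whose noiseless plateau is twice the reference plateau
        sc = make_scenario("minimal", {"seed": 0, "noise_sd": 0.0})
        ligs = []
        for lig in sc.ligands:
            ops = dict(lig.operational)
            if lig.role == "reference":
                # tau = 1: reference plateaus at half the system maximum
                ops = {r: dataclasses.replace(op, log_r=-op.log_ka) for r, op in ops.items()}
            else:
                ops = {r: dataclasses.replace(op, log_r=4.0 - op.log_ka) for r, op in ops.items()}
            ligs.append(dataclasses.replace(lig, operational=ops))
        ds = simulate_study(sc.with_overrides(ligands=ligs))
        curves = normalize_to_reference(ds)
        fit = fit_hill(curves[("WT", "TEST", "R1")])
        assert fit.emax == pytest.approx(200.0, rel=0.01)

    def test_timepoint_convention_also_normalizes_to_100(self, minimal_dataset):
        curves = normalize_to_reference(minimal_dataset, convention="timepoint", norm_time=20.0)
        ref = curves[("WT", "REF", "R1")]
        assert float(np.mean(ref.responses[-1])) == pytest.approx(100.0, abs=1e-9)


class TestHillFit:
    def test_exact_recovery_of_4pl_truth(self):
        doses = np.linspace(-11, -5, 8)
        y = hill_response(doses, 0.0, 100.0, -8.0, 1.0)
        fit = fit_hill(_curve(doses, y[:, None]))
        assert fit.basal == pytest.approx(0.0, abs=1e-8)
        assert fit.emax == pytest.approx(100.0, abs=1e-8)
        assert fit.log_ec50 == pytest.approx(-8.0, abs=1e-8)
        assert fit.hill_n == pytest.approx(1.0, abs=1e-8)

    def test_fixed_slope_is_respected(self):
        doses = np.linspace(-11, -5, 8)
        y = hill_response(doses, 0.0, 100.0, -8.0, 1.0)
        fit = fit_hill(_curve(doses, y[:, None]), fix_n=2.0)
        assert fit.hill_n == 2.0

    def test_flat_curve_flagged_degenerate(self):
        fit = fit_hill(_curve(np.linspace(-10, -5, 6), np.full((6, 2), 42.0)))
        assert fit.degenerate and math.isnan(fit.emax)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="4 distinct doses"):
            fit_hill(_curve([-9, -8, -7], [[0.0], [50.0], [100.0]]))

    def test_dose_shift_equivariance(self):
        doses = np.linspace(-11, -5, 8)
        y = hill_response(doses, 5.0, 120.0, -8.2, 1.3)[:, None]
        a = fit_hill(_curve(doses, y))
        b = fit_hill(_curve(doses + 1.0, y))
        assert b.log_ec50 == pytest.approx(a.log_ec50 + 1.0, abs=1e-6)
        assert b.emax == pytest.approx(a.emax, abs=1e-6)
        assert b.hill_n == pytest.approx(a.hill_n, abs=1e-6)

    def test_descending_curve_flagged(self):
        doses = np.linspace(-10, -5, 7)
        y = hill_response(doses, 100.0, 20.0, -7.5, 1.0)[:, None]
        fit = fit_hill(_curve(doses, y))
        assert fit.descending

    def test_monte_carlo_ec50_recovery(self, rng):
        # noisy recovery study: sd 5 at 8 doses x 6 replicates
        doses = np.linspace(-11, -5, 8)
        clean = hill_response(doses, 0.0, 100.0, -8.0, 1.0)
        hits = 0
        n_sims = 200
        for _ in range(n_sims):
            y = clean[:, None] + rng.normal(0, 5.0, size=(8, 6))
            fit = fit_hill(_curve(doses, y))
            hits += abs(fit.log_ec50 - (-8.0)) < 0.2
        assert hits / n_sims >= 0.95


class TestEcFraction:
    def test_median_is_ec50(self):
        fit = fit_hill(_curve(np.linspace(-11, -5, 8),
                              hill_response(np.linspace(-11, -5, 8), 0, 100, -8, 1)[:, None]))
        assert ec_fraction(fit, 0.5) == pytest.approx(fit.log_ec50)

    @pytest.mark.parametrize("n,offset", [(1.0, math.log10(4.0)), (2.0, math.log10(4.0) / 2)])
    def test_ec80_offset_identity(self, n, offset):
        doses = np.linspace(-11, -5, 8)
        fit = fit_hill(_curve(doses, hill_response(doses, 0, 100, -8, n)[:, None]))
        assert ec_fraction(fit, 0.8) == pytest.approx(-8.0 + offset, abs=1e-6)

    def test_strictly_increasing_in_fraction(self):
        doses = np.linspace(-11, -5, 8)
        fit = fit_hill(_curve(doses, hill_response(doses, 0, 100, -8, 1.2)[:, None]))
        fs = [0.2, 0.5, 0.8, 0.95]
        vals = [ec_fraction(fit, f) for f in fs]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_invalid_fraction_rejected(self):
        doses = np.linspace(-11, -5, 8)
        fit = fit_hill(_curve(doses, hill_response(doses, 0, 100, -8, 1)[:, None]))
        for f in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                ec_fraction(fit, f)

    def test_degenerate_fit_rejected(self):
        fit = fit_hill(_curve(np.linspace(-10, -5, 6), np.full((6, 1), 10.0)))
        with pytest.raises(ValueError, match="degenerate"):
            ec_fraction(fit, 0.8)


class TestEndpointProfiles:
    def test_row_count(self, noiseless_minimal_dataset):
        prof = endpoint_profiles(noiseless_minimal_dataset, [2.0, 7.0, 20.0])
        # 2 ligands x 2 readouts x 3 endpoints
        assert len(prof) == 12
        assert set(prof["endpoint_min"]) == {2.0, 7.0, 20.0}

    def test_kinetics_matched_ligand_is_endpoint_invariant(self):
        sc = make_scenario("minimal", {"seed": 0, "noise_sd": 0.0})
        ligs = []
        ref_kin = sc.reference.kinetic
        for lig in sc.ligands:
            ligs.append(lig if lig.role == "reference"
                        else dataclasses.replace(lig, kinetic=dict(ref_kin)))
        prof = endpoint_profiles(simulate_study(sc.with_overrides(ligands=ligs)), [2.0, 20.0])
        sub = prof[(prof.ligand == "TEST") & (prof.readout == "R1")]
        emax = sub.set_index("endpoint_min")["emax"]
        assert emax[2.0] == pytest.approx(emax[20.0], rel=1e-6)

    def test_slow_ligand_gains_relative_emax_with_endpoint(self):
        from biasquant.validation import endpoint_sensitivity

        res = endpoint_sensitivity(seed=3)
        assert res["strictly_increasing"] == 1.0

    def test_endpoint_outside_window_rejected(self, noiseless_minimal_dataset):
        with pytest.raises(ValueError, match="outside recorded window"):
            endpoint_profiles(noiseless_minimal_dataset, [2.0, 99.0])


class TestWelch:
    def test_identical_samples_give_unit_p(self):
        t, df, p = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_oracle(self):
        # means 2 vs 5, each var 1, n=3: t = -3/sqrt(2/3), Satterthwaite df = 4
        t, df, p = welch_compare([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == pytest.approx(4.0, abs=1e-9)
        assert p == pytest.approx(0.0213, abs=1e-3)

    def test_antisymmetry(self):
        t1, _, p1 = welch_compare([1, 2, 3], [4, 5, 7])
        t2, _, p2 = welch_compare([4, 5, 7], [1, 2, 3])
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_zero_variance_equal_means_convention(self):
        t, _, p = welch_compare([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            welch_compare([1.0], [1.0, 2.0])
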