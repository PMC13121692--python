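"""Loading arithmetic, peak ratios, IC50 and Tm fits, interaction, SEC."""

import itertools

import numpy as np
import pytest

from acudyn import assays, synthio
from acudyn.assays import (
    AbsorbanceRecord,
    chromatogram_peak_ratio,
    fit_dose_response,
    fit_sec_calibration,
    melting_temperature,
    nonadditivity_interaction,
    normalize_fluorescence,
    nucleotide_loading,
    sec_mw_and_stoichiometry,
)


class TestNucleotideLoading:
    def test_hand_arithmetic_protein_concentration(self):
        rec = AbsorbanceRecord(0.873, 0.0, 0.4466, eps_protein=8730.0)
        res = nucleotide_loading(rec)
        assert res.protein_conc_M == pytest.approx(1.0e-4, rel=1e-12)

    def test_twenty_nine_percent_loading(self):
        # c(nuc) = 2.9e-5 M over c(prot) = 1.0e-4 M is 29% by definition
        rec = AbsorbanceRecord(
            0.873, 0.0, 2.9e-5 * 15400.0, eps_protein=8730.0, eps_nucleotide=15400.0
        )
        res = nucleotide_loading(rec)
        assert res.nucleotide_conc_M == pytest.approx(2.9e-5, rel=1e-12)
        assert res.loading_percent == pytest.approx(29.0, rel=1e-9)

    def test_zero_protein_concentration_errors(self):
        rec = AbsorbanceRecord(0.5, 0.5, 0.1, eps_protein=8730.0)
        with pytest.raises(ZeroDivisionError, match="undefined"):
            nucleotide_loading(rec)

    def test_negative_difference_clipped_then_errors(self, caplog):
        rec = AbsorbanceRecord(0.4, 0.5, 0.1, eps_protein=8730.0)
        with pytest.raises(ZeroDivisionError):
            nucleotide_loading(rec)

    def test_invalid_extinction_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            AbsorbanceRecord(1.0, 0.0, 0.1, eps_protein=-5.0)


class TestPeakRatio:
    def test_identical_triangular_peaks_split_evenly(self):
        v = np.linspace(0, 10, 2001)
        a = np.interp(v, [2, 3, 4], [0, 1, 0]) + np.interp(v, [6, 7, 8], [0, 1, 0])
        table = chromatogram_peak_ratio(v, a, {"p1": (1.5, 4.5), "p2": (5.5, 8.5)})
        pct = table.set_index("species")["area_percent"]
        assert pct["p1"] == pytest.approx(50.0, abs=0.5)
        assert pct["p2"] == pytest.approx(50.0, abs=0.5)

    def test_single_peak_takes_everything(self):
        v = np.linspace(0, 10, 2001)
        a = np.interp(v, [2, 3, 4], [0, 1, 0])
        table = chromatogram_peak_ratio(v, a, {"amp": (1.5, 4.5), "adp": (5.5, 8.5)})
        pct = table.set_index("species")["area_percent"]
        assert pct["amp"] == pytest.approx(100.0, abs=0.1)
        assert pct["adp"] == pytest.approx(0.0, abs=0.1)

    def test_generator_planted_99_to_1_ratio(self):
        df, truth = synthio.gen_assay_data(
            "chromatogram", {"areas": {"AMP": 99.0, "ADP": 1.0}}, seed=8
        )
        table = chromatogram_peak_ratio(
            df["volume_mL"].to_numpy(),
            df["a260"].to_numpy(),
            {"AMP": (2.0, 4.0), "ADP": (4.8, 6.8)},
        )
        pct = table.set_index("species")["area_percent"]
        assert pct["AMP"] == pytest.approx(99.0, abs=0.5)
        assert pct["ADP"] == pytest.approx(1.0, abs=0.5)

    def test_overlapping_windows_rejected(self):
        v = np.linspace(0, 10, 101)
        with pytest.raises(ValueError, match="overlap"):
            chromatogram_peak_ratio(v, v * 0, {"a": (1, 5), "b": (4, 8)})

    def test_empty_window_rejected(self):
        v = np.linspace(0, 10, 101)
        with pytest.raises(ValueError, match="<2"):
            chromatogram_peak_ratio(v, v * 0, {"a": (20.0, 21.0)})


class TestDoseResponse:
    def test_noiseless_curve_recovers_ic50(self):
        df, truth = synthio.gen_assay_data("dose_response", {"ic50": 3.8e-8}, seed=1)
        fit = fit_dose_response(df["conc_M"].to_numpy(), df["fluorescence"].to_numpy())
        assert fit.fit_ok
        assert fit.ic50_M == pytest.approx(3.8e-8, rel=0.01)

    def test_noisy_recovery_median_within_ten_percent(self):
        errs = []
        for seed in range(100):
            df, _ = synthio.gen_assay_data(
                "dose_response", {"ic50": 3.8e-8, "noise": 0.05}, seed=seed
            )
            fit = fit_dose_response(df["conc_M"].to_numpy(), df["fluorescence"].to_numpy())
            if fit.fit_ok:
                errs.append(abs(fit.ic50_M - 3.8e-8) / 3.8e-8)
            else:
                errs.append(np.inf)
        assert np.median(errs) <= 0.10

    def test_flat_response_falls_back_to_linear(self, rng):
        conc = np.logspace(-9, -5, 8)
        flat = 500.0 + rng.normal(scale=1.0, size=8)
        fit = fit_dose_response(conc, flat)
        assert not fit.fit_ok
        assert fit.ic50_M is None
        # slope of normalised pure noise against 4 decades stays small
        assert abs(fit.fallback_slope) < 0.2

    def test_normalization_modes_algebra(self):
        f = np.array([2.0, 6.0, 10.0])
        plain = normalize_fluorescence(f, "minmax")
        literal = normalize_fluorescence(f, "literal")
        np.testing.assert_allclose(plain, [0.0, 0.5, 1.0])
        # literal form keeps the additive minimum outside the ratio
        np.testing.assert_allclose(literal, [2.0, 2.5, 3.0])
        assert literal[-1] == pytest.approx(f.min() + 1.0)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError, match="4 distinct"):
            fit_dose_response(np.array([1e-8, 1e-7, 1e-6]), np.array([1.0, 0.5, 0.1]))


class TestMeltingTemperature:
    def test_logistic_inflection_recovered(self):
        df, _ = synthio.gen_assay_data("melt", {"tm": 68.0}, seed=2)
        res = melting_temperature(df["temperature_C"].to_numpy(), df["ratio"].to_numpy())
        assert res[0].tm_C == pytest.approx(68.0, abs=0.2)
        assert res[0].extremum == "max"

    def test_linear_baseline_has_no_transition(self):
        t = np.linspace(15, 95, 200)
        res = melting_temperature(t, 0.8 + 0.001 * t)
        assert res == []

    def test_double_transition_both_recovered(self):
        df, _ = synthio.gen_assay_data("melt", {"tm": 50.0, "tm2": 80.0}, seed=3)
        res = melting_temperature(df["temperature_C"].to_numpy(), df["ratio"].to_numpy())
        tms = sorted(r.tm_C for r in res[:2])
        assert tms[0] == pytest.approx(50.0, abs=0.3)
        assert tms[1] == pytest.approx(80.0, abs=0.3)

    @pytest.mark.parametrize("slope", [0.2, 0.5, 1.0, 2.0])
    def test_bias_small_across_transition_slopes(self, slope):
        df, _ = synthio.gen_assay_data("melt", {"tm": 60.0, "width": 1.0 / slope}, seed=4)
        res = melting_temperature(df["temperature_C"].to_numpy(), df["ratio"].to_numpy())
        assert res[0].tm_C == pytest.approx(60.0, abs=0.1)

    def test_non_monotone_temperature_rejected(self):
        t = np.linspace(15, 95, 100)
        t[50] = t[49]
        with pytest.raises(ValueError, match="increasing"):
            melting_temperature(t, np.ones(100))


class TestNonAdditivity:
    def test_exact_linear_combination_has_zero_residual(self):
        df, _ = synthio.gen_assay_data("mixture", {"a": 0.4, "b": 0.6}, seed=5)
        res = nonadditivity_interaction(
            df["temperature_C"], df["mix"], df["component_a"], df["component_b"]
        )
        assert res.a == pytest.approx(0.4, abs=1e-9)
        assert res.b == pytest.approx(0.6, abs=1e-9)
        assert res.residual_rms <= 1e-10
        assert not res.interaction

    @pytest.mark.parametrize("a,b", [(1.0, 0.0), (0.25, 1.75), (-0.3, 0.9)])
    def test_any_exact_combination_is_additive(self, a, b):
        dfa, _ = synthio.gen_assay_data("melt", {"tm": 55.0}, seed=6)
        dfb, _ = synthio.gen_assay_data("melt", {"tm": 75.0}, seed=6)
        mix = a * dfa["ratio"].to_numpy() + b * dfb["ratio"].to_numpy()
        res = nonadditivity_interaction(
            dfa["temperature_C"], mix, dfa["ratio"], dfb["ratio"]
        )
        assert res.residual_rms <= 1e-10
        assert res.a == pytest.approx(a, abs=1e-6)
        assert res.b == pytest.approx(b, abs=1e-6)

    def test_shifted_tm_complex_flags_interaction(self):
        df, _ = synthio.gen_assay_data(
            "mixture", {"interacting": True, "tm_complex": 85.0, "noise": 1e-4}, seed=7
        )
        res = nonadditivity_interaction(
            df["temperature_C"], df["mix"], df["component_a"], df["component_b"]
        )
        assert res.interaction
        assert res.residual_rms > res.threshold

    def test_collinear_components_flagged_non_identifiable(self):
        dfa, _ = synthio.gen_assay_data("melt", {"tm": 60.0}, seed=8)
        t = dfa["temperature_C"]
        r = dfa["ratio"]
        res = nonadditivity_interaction(t, r, r, r)
        assert not res.identifiable
        assert res.a + res.b == pytest.approx(1.0, abs=1e-6)
        assert res.residual_rms <= 1e-10


class TestSEC:
    def _calibration(self, jitter=0.0, seed=9):
        df, truth = synthio.gen_assay_data("sec", {"jitter": jitter}, seed=seed)
        return df, truth

    def test_void_volume_gives_zero_kav(self):
        df, truth = self._calibration()
        cal = fit_sec_calibration(df["mw_Da"], df["ve_mL"], truth.params["v0"],
                                  truth.params["vc"])
        assert cal.kav(truth.params["v0"]) == 0.0

    def test_held_out_standard_recovered(self):
        df, truth = self._calibration()
        train = df.iloc[1:]
        cal = fit_sec_calibration(train["mw_Da"], train["ve_mL"],
                                  truth.params["v0"], truth.params["vc"])
        held = df.iloc[0]
        assert cal.molecular_weight(held["ve_mL"]) == pytest.approx(
            held["mw_Da"], rel=0.01
        )
        assert cal.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_heterotetramer_composition_from_monomer_masses(self):
        df, truth = self._calibration()
        cal = fit_sec_calibration(df["mw_Da"], df["ve_mL"], truth.params["v0"],
                                  truth.params["vc"])
        # elution volume whose apparent MW equals the 2:2 complex mass
        target = 2 * 25405.0 + 2 * 44272.0
        kav = (np.log10(target) - cal.intercept) / cal.slope
        ve = cal.v0_mL + kav * (cal.vc_mL - cal.v0_mL)
        mw, combo = sec_mw_and_stoichiometry(
            cal, ve, {"BsAcuB": 25405.0, "BsAcuC": 44272.0}
        )
        assert combo == {"BsAcuB": 2, "BsAcuC": 2}
        assert mw == pytest.approx(target, rel=1e-6)

    def test_composition_search_matches_exhaustive_oracle(self):
        df, truth = self._calibration()
        cal = fit_sec_calibration(df["mw_Da"], df["ve_mL"], truth.params["v0"],
                                  truth.params["vc"])
        masses = {"X": 20000.0, "Y": 31000.0}
        for ve in (11.0, 13.0, 15.0, 17.0):
            mw, combo = sec_mw_and_stoichiometry(cal, ve, masses)
            best = min(
                (
                    (abs(nx * 20000.0 + ny * 31000.0 - mw), nx + ny, (nx, ny))
                    for nx, ny in itertools.product(range(5), range(5))
                    if nx + ny > 0
                ),
            )
            assert (combo["X"], combo["Y"]) == best[2]

    def test_elution_outside_column_rejected(self):
        df, truth = self._calibration()
        cal = fit_sec_calibration(df["mw_Da"], df["ve_mL"], truth.params["v0"],
                                  truth.params["vc"])
        with pytest.raises(ValueError, match="outside"):
            sec_mw_and_stoichiometry(cal, truth.params["vc"] + 5.0, {"X": 2e4})

    def test_too_few_standards_rejected(self):
        with pytest.raises(ValueError, match="3 standards"):
            fit_sec_calibration(np.array([1e4, 1e5]), np.array([18.0, 12.0]), 8.0, 24.0)
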