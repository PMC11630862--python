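"""Synthetic split-cell generator: kinetics, sign conventions, ground truth."""

import json

import numpy as np
import pytest

from sczra.faradaic import SECONDS_PER_HOUR, FaradayParams, faraday_mass, integrate_charge
from sczra.pipeline import analyze_treatment
from sczra.simulator import (FermentationParams, GalvanicModelParams,
                             MediumComposition, default_treatments,
                             generate_fixture_suite, simulate_fermentation,
                             simulate_sczra)


class TestFermentation:
    def test_no_inoculum_means_constant_series(self):
        fs = simulate_fermentation(FermentationParams(initial_a600=0.0),
                                   MediumComposition(), duration=240.0)
        assert np.ptp(fs.glucose) == 0 and np.ptp(fs.acetate) == 0
        assert np.all(fs.a600 == 0)

    def test_acetate_stoichiometry_is_exact(self):
        p = FermentationParams(acetate_yield=1.5)
        fs = simulate_fermentation(p, MediumComposition(), duration=400.0)
        consumed = fs.glucose[0] - fs.glucose
        assert np.allclose(fs.acetate, p.acetate_yield * consumed, rtol=1e-12)

    def test_series_monotonicity(self):
        fs = simulate_fermentation(FermentationParams(), MediumComposition(),
                                   duration=400.0)
        assert np.all(np.diff(fs.glucose) <= 1e-9)
        assert np.all(np.diff(fs.acetate) >= -1e-9)
        assert np.all(np.diff(fs.a600) >= -1e-9)
        assert np.all(fs.glucose >= 0)

    def test_small_ks_limit_matches_exponential_closed_form(self):
        # with Ks -> 0 growth is exponential and glucose hits zero at
        # t = lag + ln(1 + Y_X S0 / X0) / mu
        p = FermentationParams(mu_max=0.05, ks=1e-9, biomass_yield=0.05,
                               acetate_yield=1.0, lag=12.0, initial_a600=1.0)
        med = MediumComposition()
        t_star = p.lag + np.log(1 + p.biomass_yield * med.glucose / p.initial_a600) / p.mu_max
        fs = simulate_fermentation(p, med, duration=120.0, dt=0.05)
        t_dep = fs.time[np.argmax(fs.glucose <= 1e-3 * med.glucose)]
        assert t_dep == pytest.approx(t_star, rel=0.01)

    def test_yield_ceiling_enforced(self):
        with pytest.raises(ValueError, match="ceiling"):
            FermentationParams(acetate_yield=3.5)


def _noise_free(label):
    cfg = next(c for c in default_treatments() if c.label == label)
    return simulate_sczra(cfg, galv=GalvanicModelParams(noise_sd=0.0))


class TestSimulatedTreatments:
    def test_uninoculated_is_symmetric(self, uninoculated_noisefree):
        sim = uninoculated_noisefree
        assert np.all(sim.trace.current == 0)
        w = sim.ground_truth["mass_loss_g"]
        assert w["WE1"] == pytest.approx(w["WE2"], rel=1e-12)
        assert sim.ground_truth["crr"] == pytest.approx(1.0)

    def test_unbuffered_inoculated_acidifies_we1_only(self, unbuffered_inoculated_noisefree):
        sim = unbuffered_inoculated_noisefree
        ph1 = sim.chemistry["WE1"].pH
        ph2 = sim.chemistry["WE2"].pH
        assert np.all(np.diff(ph1) <= 1e-9)          # monotone decline
        assert ph1[-1] < ph1[0] - 1.5                # large drop, to ~4.5
        assert ph1[-1] == pytest.approx(4.5, abs=0.15)
        assert np.ptp(ph2) < 1e-6                    # WE2 chamber untouched
        assert integrate_charge(sim.trace).total < 0  # electrons WE2 -> WE1

    def test_unbuffered_inoculated_converts_glucose_to_acetate(
            self, unbuffered_inoculated_noisefree):
        chem = unbuffered_inoculated_noisefree.chemistry["WE1"]
        assert chem.glucose[-1] < 0.05 * chem.glucose[0]
        assert chem.acetate[-1] > 15.0               # ~20 mM at yield 1.0

    def test_buffered_inoculated_is_quenched(self, buffered_inoculated_noisefree,
                                             unbuffered_inoculated_noisefree):
        buf = buffered_inoculated_noisefree
        unbuf = unbuffered_inoculated_noisefree
        assert np.ptp(buf.chemistry["WE1"].pH) < 0.5
        q_buf = abs(integrate_charge(buf.trace).total)
        q_unbuf = abs(integrate_charge(unbuf.trace).total)
        assert q_buf < 0.10 * q_unbuf

    def test_charge_conservation_against_ground_truth(
            self, unbuffered_inoculated_noisefree):
        """Noise-free trace integrates to the Faraday equivalent of the
        imposed differential mass loss."""
        sim = unbuffered_inoculated_noisefree
        q = integrate_charge(sim.trace).total
        assert q == pytest.approx(sim.ground_truth["q_true_C"], rel=1e-9)
        dm = faraday_mass(q, FaradayParams())
        assert dm == pytest.approx(sim.ground_truth["biotic_mass_loss_g"], rel=1e-9)
        w = sim.ground_truth["mass_loss_g"]
        assert abs(w["WE2"] - w["WE1"]) == pytest.approx(dm, rel=1e-9)

    def test_noise_free_pipeline_recovery_within_1pct(
            self, unbuffered_inoculated_noisefree):
        sim = unbuffered_inoculated_noisefree
        res = analyze_treatment(sim.coupons["WE1"], sim.coupons["WE2"],
                                trace=sim.trace)
        imposed = sim.ground_truth["biotic_rate_predicted_mpy"]
        assert res.biotic_rate_predicted.mpy == pytest.approx(imposed, rel=0.01)
        assert res.biotic_rate_actual.mpy == pytest.approx(
            sim.ground_truth["biotic_rate_actual_mpy"], rel=0.01)
        assert res.net_anode_predicted == sim.ground_truth["net_anode"] == "WE2"

    def test_noisy_recovery_median_within_5pct(self):
        cfg = next(c for c in default_treatments()
                   if c.label == "without_bicarbonate__WE1_inoculated")
        errs, anode_ok = [], []
        for seed in range(20):
            sim = simulate_sczra(cfg, galv=GalvanicModelParams(noise_sd=0.05,
                                                               seed=seed))
            res = analyze_treatment(sim.coupons["WE1"], sim.coupons["WE2"],
                                    trace=sim.trace)
            imposed = sim.ground_truth["biotic_rate_predicted_mpy"]
            errs.append(abs(res.biotic_rate_predicted.mpy - imposed) / imposed)
            anode_ok.append(res.net_anode_predicted == sim.ground_truth["net_anode"])
        assert float(np.median(errs)) < 0.05
        assert all(anode_ok)

    def test_abiotic_baseline_matches_reported_scale(self, uninoculated_noisefree):
        # uninoculated coupons corrode at ~4 mpy, the scale of sterile controls
        rate = uninoculated_noisefree.ground_truth["rate_mpy"]["WE1"]
        assert 3.0 < rate < 5.5


class TestFixtureSuite:
    def test_manifest_deterministic_for_fixed_seed(self, tmp_path):
        m1 = generate_fixture_suite(11, tmp_path / "a")
        m2 = generate_fixture_suite(11, tmp_path / "b")
        assert json.dumps(m1, sort_keys=True) == json.dumps(m2, sort_keys=True)
        assert (tmp_path / "a" / "manifest.json").read_bytes() == \
               (tmp_path / "b" / "manifest.json").read_bytes()

    def test_suite_contents_and_uninoculated_crr(self, tmp_path):
        manifest = generate_fixture_suite(3, tmp_path / "fx")
        assert len(manifest["treatments"]) == 4
        for label, gt in manifest["treatments"].items():
            if "uninoculated" in label:
                assert gt["crr"] == pytest.approx(1.0, abs=1e-6)
        assert (tmp_path / "fx" / "without_bicarbonate__WE1_inoculated_trace.csv").exists()

    def test_pipeline_on_unbuffered_fixture_calls_we2_anode(self, tmp_path):
        from sczra.io import read_coupon_table, read_trace
        generate_fixture_suite(5, tmp_path / "fx")
        label = "without_bicarbonate__WE1_inoculated"
        trace = read_trace(tmp_path / "fx" / f"{label}_trace.csv")
        coupons = {c.coupon_id: c
                   for c in read_coupon_table(tmp_path / "fx" / f"{label}_coupons.csv")}
        res = analyze_treatment(coupons[f"{label}_WE1"], coupons[f"{label}_WE2"],
                                trace=trace)
        assert res.net_anode_predicted == "WE2"
        assert res.net_anode_actual == "WE2"
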