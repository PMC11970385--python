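"""Poisson loading, occupancy conversion, concentration, calibration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dropev import (OccupancySpec, beads_to_ev_percent, ev_concentration,
                    fit_calibration, poisson_loading, single_ev_statistics)


class TestPoissonLoading:
    def test_zero_concentration(self):
        m = poisson_loading(0.0, 27.9)
        assert m.lambda_bead == 0.0
        assert m.p_empty == 1.0

    def test_working_concentration_lambda_and_empty_fraction(self):
        # 1.4e7 beads/mL in 27.9 um droplets: lambda ~ 0.159, P(0) ~ 0.853
        m = poisson_loading(1.4e7, 27.9)
        assert m.droplet_volume_pl == pytest.approx(
            math.pi / 6 * 27.9 ** 3 / 1e3, rel=1e-6)
        assert m.lambda_bead == pytest.approx(0.159, abs=0.001)
        assert m.p_empty == pytest.approx(0.853, abs=0.001)

    def test_observed_empty_fraction_implies_singles_near_ten_percent(self):
        # lambda = -ln(0.901): P(1) ~ 9.4%, the observed loading regime
        lam = -math.log(0.901)
        m = poisson_loading(lam * 1e12 / (math.pi / 6 * 27.9 ** 3), 27.9)
        assert m.lambda_bead == pytest.approx(lam, rel=1e-6)
        assert m.p_single == pytest.approx(0.0939, abs=0.0005)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            poisson_loading(-1.0, 27.9)
        with pytest.raises(ValueError):
            poisson_loading(1e7, 0.0)

    def test_pmf_sums_to_one(self):
        m = poisson_loading(1.4e7, 27.9)
        assert m.pmf(np.arange(0, 50)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_pmf_matches_monte_carlo_encapsulation(self):
        # 10^6 simulated droplets vs the closed form, k <= 4
        m = poisson_loading(1.4e7, 27.9)
        rng = np.random.default_rng(123)
        sim = rng.poisson(m.lambda_bead, size=1_000_000)
        for k in range(5):
            p = float(m.pmf(k))
            phat = np.mean(sim == k)
            se = math.sqrt(max(p * (1 - p), 1e-12) / len(sim))
            assert abs(phat - p) < 3 * se + 1e-9


class TestOccupancy:
    def test_ratio_model_f_occ(self):
        spec = OccupancySpec(0.1, "ratio")
        assert spec.f_occ == pytest.approx(1 / 11)

    def test_poisson_single_ev_purity(self):
        rep = single_ev_statistics(OccupancySpec(0.1, "poisson"))
        assert rep["p_single_given_occupied"] == pytest.approx(0.951, abs=0.001)

    def test_zero_rate_limit_is_pure_single(self):
        rep = single_ev_statistics(OccupancySpec(0.0, "poisson"))
        assert rep["p_single_given_occupied"] == 1.0

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            OccupancySpec(0.1, "binomial")


class TestBeadsToEvPercent:
    @pytest.mark.parametrize("f_pos, expected", [
        (5.3, 58.3),   # CD11b on CD9-captured serum EVs
        (1.2, 13.2),   # NCAM
        (4.3, 47.3),   # membrane alpha-synuclein on L1CAM-captured EVs
    ])
    def test_printed_conversions_reproduced_exactly(self, f_pos, expected):
        spec = OccupancySpec(0.1, "ratio")
        assert beads_to_ev_percent(f_pos, spec) == pytest.approx(expected,
                                                                 abs=1e-9)

    def test_zero_maps_to_zero(self):
        assert beads_to_ev_percent(0.0, OccupancySpec(0.1, "ratio")) == 0.0

    def test_saturation_warns(self):
        with pytest.warns(UserWarning, match="exceeds"):
            beads_to_ev_percent(50.0, OccupancySpec(0.1, "ratio"))

    @given(st.floats(0.0, 9.0), st.floats(0.01, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_and_monotone(self, f_pos, scale):
        spec = OccupancySpec(0.1, "ratio")
        a = beads_to_ev_percent(f_pos, spec)
        b = beads_to_ev_percent(f_pos * 0.5, spec)
        assert a == pytest.approx(2 * b, rel=1e-9)
        assert a >= b

    def test_full_occupancy_maps_to_hundred(self):
        spec = OccupancySpec(0.1, "ratio")
        assert beads_to_ev_percent(100 * spec.f_occ, spec) == pytest.approx(100.0)


class TestEvConcentration:
    def test_basic_arithmetic(self):
        assert ev_concentration(100, sample_volume_ul=10.0) == pytest.approx(10.0)

    def test_dilution_linearity(self):
        a = ev_concentration(50, 10.0, dilution_factor=1.0)
        b = ev_concentration(50, 10.0, dilution_factor=2.0)
        assert b == pytest.approx(2 * a)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            ev_concentration(10, 0.0)

    def test_spiked_concentration_recovered_from_simulated_capture(self):
        # 500 EVs spiked into 10 uL, captured by 5,000 beads (10:1
        # excess): positive beads = occupied beads; the concentration
        # estimate must recover the spike within 3 SE of the occupancy
        # shortfall (two EVs on one bead merge into one positive)
        rng = np.random.default_rng(11)
        n_ev, n_beads, vol = 500, 5000, 10.0
        ests = []
        for _ in range(20):
            per_bead = rng.multinomial(n_ev, np.full(n_beads, 1 / n_beads))
            n_pos = int((per_bead >= 1).sum())
            ests.append(ev_concentration(n_pos, vol))
        # expected positives: n_beads * (1 - (1 - 1/n_beads)^n_ev)
        p_occ = 1 - (1 - 1 / n_beads) ** n_ev
        expected = n_beads * p_occ / vol
        se = np.sqrt(n_beads * p_occ * (1 - p_occ)) / vol / np.sqrt(20)
        assert np.mean(ests) == pytest.approx(expected, abs=3 * se)
        # and the merge shortfall is small at 10:1 excess
        assert expected == pytest.approx(n_ev / vol, rel=0.06)


class TestCalibration:
    def test_worked_lod_loq(self):
        # slope 0.001 %/(EV/uL), intercept 0.1%, background 0.1 +- 0.05:
        # LOD threshold 0.25% -> 150 EVs/uL; LOQ threshold 0.6% -> 500
        conc = np.array([0.0, 200.0, 400.0, 600.0])
        resp = 0.1 + 0.001 * conc
        bg = [0.05, 0.1, 0.15]  # mean 0.1, sd 0.05
        curve = fit_calibration(conc, resp, bg)
        assert curve.background_sd == pytest.approx(0.05)
        assert curve.lod == pytest.approx(150.0, rel=1e-6)
        assert curve.loq == pytest.approx(500.0, rel=1e-6)
        assert curve.dynamic_range[0] == pytest.approx(curve.lod)
        assert curve.r_squared == pytest.approx(1.0)

    def test_zero_background_sd_degenerates_with_warning(self):
        conc = [0.0, 100.0, 200.0]
        resp = [0.1, 1.1, 2.1]
        with pytest.warns(UserWarning, match="background SD"):
            curve = fit_calibration(conc, resp, [0.1, 0.1])
        assert curve.lod == pytest.approx(curve.loq)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_calibration([0, 1, 2], [3.0, 2.0, 1.0], [0.1, 0.2])

    def test_lod_below_loq_whenever_noise_positive(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            slope = rng.uniform(1e-4, 1e-1)
            intercept = rng.uniform(0, 1)
            conc = np.sort(rng.uniform(0, 1000, size=5))
            resp = intercept + slope * conc + rng.normal(0, 1e-4, 5)
            bg = intercept + rng.normal(0, rng.uniform(0.01, 0.2), size=4)
            curve = fit_calibration(conc, resp, bg)
            if curve.background_sd > 0:
                assert curve.lod < curve.loq

    def test_slope_recovery_within_ci(self):
        # synthetic series with known slope: fitted slope CI covers the
        # truth in >= 95% of replicates (two-sided 95% CI)
        from scipy import stats as sps

        rng = np.random.default_rng(42)
        slope_true, inter_true, noise = 0.002, 0.1, 0.05
        conc = np.array([0, 250, 500, 1000, 2000, 4000], dtype=float)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            resp = inter_true + slope_true * conc + rng.normal(0, noise, len(conc))
            curve = fit_calibration(conc, resp, [0.08, 0.1, 0.12])
            stderr = sps.linregress(conc, resp).stderr  # independent CI width
            half = sps.t.ppf(0.975, len(conc) - 2) * stderr
            hits += abs(curve.slope - slope_true) <= half
        assert hits >= 90  # binomial(100, 0.95) lower tail

    def test_log_log_fit_inverse_consistency(self):
        conc = np.array([10.0, 100.0, 1000.0])
        resp = 0.01 * conc ** 0.9
        curve = fit_calibration(conc, resp, [0.02, 0.03, 0.04], log_log=True)
        for c in conc:
            assert curve.inverse(float(curve.predict(c))) == pytest.approx(c, rel=1e-9)
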