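import numpy as np
import pandas as pd
import pytest

from ramanfd.dispersion import (
    HueRecord,
    amm_product,
    fit_dispersion,
    hue_trend,
    ratio_squared,
    tracks_from_table,
)
from ramanfd.errors import (
    DegenerateInputError,
    InsufficientDataError,
    ValidationError,
)
from ramanfd.peakfit import BandTrack
from ramanfd.units import CM_PER_EV, eV_to_invcm, invcm_to_eV, nm_to_invcm
from ramanfd import synthetic


def make_track(band, nm, centers, window=(1000.0, 2000.0)):
    nm = np.asarray(nm, dtype=float)
    centers = np.asarray(centers, dtype=float)
    order = np.argsort(-nm)
    nm, centers = nm[order], centers[order]
    e = nm_to_invcm(nm)
    return BandTrack(band=band, excitation_nm=nm, energy_invcm=e,
                     energy_eV=invcm_to_eV(e), centers=centers,
                     ref_center=float(centers[0]), ref_excitation_nm=float(nm[0]),
                     window=window)


class TestUnits:
    def test_nm_to_invcm_closed_form(self):
        assert nm_to_invcm(500.0) == 20000.0
        assert nm_to_invcm(1000.0) == 10000.0
        assert abs(nm_to_invcm(648.0) - 15432.1) < 0.1

    def test_ev_factor_definition(self):
        assert invcm_to_eV(8065.544) == 1.0
        assert invcm_to_eV(0.0) == 0.0

    def test_round_trip_identity(self):
        x = np.array([1.0, 1234.5, 25000.0])
        np.testing.assert_allclose(eV_to_invcm(invcm_to_eV(x)), x, rtol=1e-12)

    def test_non_positive_wavelength_refused(self):
        with pytest.raises(ValueError):
            nm_to_invcm(-5.0)


class TestRatioSquared:
    def test_constant_track_all_ones(self):
        t = make_track("cc2", [648, 568, 515, 458], [1528.0] * 4)
        np.testing.assert_array_equal(ratio_squared(t), 1.0)

    def test_single_ratio_arithmetic(self):
        t = make_track("cc2", [648, 500], [1525.0, 1542.0], window=(1490, 1590))
        vals = ratio_squared(t)
        assert vals[0] == 1.0
        assert abs(vals[1] - (1542.0 / 1525.0) ** 2) < 1e-12

    def test_linear_track_matches_closed_form(self):
        s, nu0 = 1e-3, 1528.0
        nm = np.array([648.0, 568.0, 515.0, 458.0, 407.0])
        e = nm_to_invcm(nm)
        centers = nu0 + s * (e - e.min())
        t = make_track("cc2", nm, centers)
        expected = (1.0 + s * (np.sort(e) - e.min()) / nu0) ** 2
        np.testing.assert_allclose(ratio_squared(t), expected, rtol=1e-12)


class TestAmmProduct:
    def test_constant_tracks_product_one(self):
        a = make_track("cc", [648, 568, 515], [1135.0] * 3)
        b = make_track("cc2", [648, 568, 515], [1528.0] * 3)
        np.testing.assert_array_equal(amm_product([a, b]), 1.0)

    def test_single_track_degenerates_to_ratio(self):
        t = make_track("cc2", [648, 568, 515], [1528.0, 1530.0, 1533.0],
                       window=(1490, 1590))
        np.testing.assert_array_equal(amm_product([t]), ratio_squared(t))

    def test_two_ratio_arithmetic(self):
        # ratio^2 of 1.010 and 1.020 at one excitation -> product 1.0302
        a = make_track("cc", [648, 500], [1135.0, 1135.0 * np.sqrt(1.010)])
        b = make_track("cc2", [648, 500], [1528.0, 1528.0 * np.sqrt(1.020)])
        prod = amm_product([a, b])
        assert abs(prod[1] - 1.0302) < 1e-12

    def test_track_order_invariant(self):
        rng = np.random.default_rng(0)
        nm = [648, 568, 515, 458]
        a = make_track("cc", nm, 1135 + rng.normal(0, 2, 4))
        b = make_track("cc2", nm, 1528 + rng.normal(0, 2, 4))
        np.testing.assert_array_equal(amm_product([a, b]), amm_product([b, a]))

    def test_matches_brute_force_oracle(self):
        # oracle: explicit loop over bands and excitations
        rng = np.random.default_rng(42)
        nm = [785, 648, 594, 532, 458, 407]
        tracks = [make_track(f"b{k}", nm, 1200 + 100 * k + rng.normal(0, 3, 6))
                  for k in range(4)]
        prod = amm_product(tracks)
        for i in range(len(nm)):
            brute = 1.0
            for t in tracks:
                brute *= (t.centers[i] / t.centers[0]) ** 2
            assert abs(prod[i] - brute) <= 1e-12 * brute

    def test_mismatched_excitations_refused(self):
        a = make_track("cc", [648, 568, 515], [1135.0] * 3)
        b = make_track("cc2", [648, 568, 491], [1528.0] * 3)
        with pytest.raises(ValidationError, match="excitation"):
            amm_product([a, b])


class TestFitDispersion:
    def test_constant_tracks_give_zero_rate(self):
        a = make_track("cc", [648, 568, 515, 458], [1135.0] * 4)
        b = make_track("cc2", [648, 568, 515, 458], [1528.0] * 4)
        fit = fit_dispersion([a, b])
        assert abs(fit.D_cm) < 1e-15
        assert fit.fit_error_pct is None
        assert not fit.significant

    def test_exact_linear_products_recovered_to_machine_precision(self):
        # choose centers so the *product* is exactly linear in E
        nm = np.array([648.0, 568.0, 515.0, 458.0, 407.0])
        e = np.sort(nm_to_invcm(nm))
        a_rate = 2.5e-6
        centers = 1528.0 * np.sqrt(1.0 + a_rate * (e - e[0]))
        t = make_track("cc2", 1e7 / e, centers)
        fit = fit_dispersion([t])
        assert abs(fit.D_cm - a_rate) < 1e-12 * a_rate
        assert abs(fit.product_fit.r_squared - 1.0) < 1e-12

    def test_small_shift_closed_form(self):
        """For small linear shifts D ~ 2 * sum_b s_b / nu0_b within 1%."""
        excs = (407.0, 458.0, 515.0, 568.0, 648.0)
        slopes = {"cc": 3e-4, "cc2": 4e-4}
        cfg = synthetic.red_like_config(
            dispersion_model="linear", ensemble=[], linear_slopes=slopes,
            reference_energy_invcm=nm_to_invcm(648.0), noise_sd=0.0)
        series, truth = synthetic.simulate_series(cfg, excitations=excs,
                                                  n_replicates=1, seed=0)
        from ramanfd.peakfit import track_band
        tracks = [track_band(series, band=b, method="lorentzian_ls")
                  for b in ("cc", "cc2")]
        fit = fit_dispersion(tracks)
        closed_form = 2.0 * (slopes["cc"] / 1135.0 + slopes["cc2"] / 1528.0)
        assert abs(fit.D_cm / closed_form - 1.0) < 0.01

    def test_unit_duality(self):
        rng = np.random.default_rng(9)
        nm = [648, 594, 532, 491, 458, 413]
        a = make_track("cc", nm, 1135 + rng.normal(0, 2, 6))
        b = make_track("cc2", nm, 1528 + rng.normal(0, 2, 6))
        f_cm = fit_dispersion([a, b], energy_axis="invcm")
        f_ev = fit_dispersion([a, b], energy_axis="eV")
        assert abs(f_cm.product_fit.r_squared - f_ev.product_fit.r_squared) < 1e-12
        assert abs(f_cm.product_fit.p_value - f_ev.product_fit.p_value) < 1e-12
        assert abs(f_ev.product_fit.slope - f_cm.product_fit.slope * CM_PER_EV) \
            <= 1e-9 * abs(f_ev.product_fit.slope)
        assert abs(f_cm.D_eV - f_cm.D_cm * CM_PER_EV) <= 1e-9 * abs(f_cm.D_eV)

    def test_rate_monotone_in_generator_slope(self):
        rates = []
        for s in (0.0, 2.5e-4, 5e-4, 1e-3, 2e-3):
            t = make_track("cc2", [648.0, 568.0, 515.0, 458.0, 407.0],
                           1528.0 + s * (nm_to_invcm(np.array(
                               [648.0, 568.0, 515.0, 458.0, 407.0]))
                               - nm_to_invcm(648.0)))
            rates.append(abs(fit_dispersion([t]).D_cm))
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_zero_energy_variance_refused(self):
        t = make_track("cc2", [648.0], [1528.0])
        with pytest.raises((DegenerateInputError, InsufficientDataError)):
            fit_dispersion([t, t])


class TestTracksFromTable:
    def _table(self):
        rows = []
        for band, nu0, s in (("cc", 1135.0, 8e-4), ("cc2", 1528.0, 1e-3)):
            for nm in synthetic.PAPER_EXCITATIONS_NM:
                e = nm_to_invcm(nm)
                rows.append({"band": band, "excitation_nm": nm,
                             "center": nu0 + s * (e - nm_to_invcm(648.0))})
        return pd.DataFrame(rows)

    def test_exclusions_and_reference(self):
        tracks = tracks_from_table(self._table(),
                                   exclusions=synthetic.DEFAULT_EXCLUSIONS)
        assert all(len(t) == 10 for t in tracks)
        assert all(t.ref_excitation_nm == 648.0 for t in tracks)
        assert {nm for nm, _ in tracks[0].excluded} == {351.0, 448.0, 785.0}

    def test_fit_from_table_matches_slopes(self):
        tracks = tracks_from_table(self._table(),
                                   exclusions=synthetic.DEFAULT_EXCLUSIONS)
        fit = fit_dispersion(tracks)
        closed_form = 2.0 * (8e-4 / 1135.0 + 1e-3 / 1528.0)
        assert abs(fit.D_cm / closed_form - 1.0) < 0.02
        assert fit.product_fit.r_squared > 0.999

    def test_missing_band_refused(self):
        with pytest.raises(ValidationError, match="no rows"):
            tracks_from_table(self._table(), bands=("cc", "nope"))


class TestHueTrend:
    def test_perfect_ranking_gives_rho_one(self):
        records = [HueRecord(f"s{i}", hue, 1120.0 + 5 * i, 1510.0 + 5 * i)
                   for i, hue in enumerate(("magenta", "red", "orange", "yellow"))]
        out = hue_trend(records)
        assert out["nu_cc"]["spearman_rho"] == pytest.approx(1.0)
        assert out["nu_cc2"]["spearman_rho"] == pytest.approx(1.0)

    def test_constant_positions_give_rho_zero(self):
        records = [HueRecord(f"s{i}", hue, 1135.0, 1528.0)
                   for i, hue in enumerate(("magenta", "red", "orange", "yellow"))]
        out = hue_trend(records)
        assert out["nu_cc"]["spearman_rho"] == 0.0

    def test_single_category_refused(self):
        records = [HueRecord("a", "red", 1135.0, 1528.0),
                   HueRecord("b", "red", 1136.0, 1529.0)]
        with pytest.raises(DegenerateInputError):
            hue_trend(records)

    def test_positive_trend_detected_across_seeds(self):
        """26-record panels with trend 3 cm^-1/step and noise 2 cm^-1 give
        rho > 0 in >= 95/100 seeds."""
        counts = {"magenta": 5, "red": 7, "orange": 7, "yellow": 7}
        wins = 0
        for seed in range(100):
            records = synthetic.simulate_hue_panel(
                trend=3.0, noise_sd=2.0, seed=seed, counts=counts)
            assert len(records) == 26
            out = hue_trend(records)
            if out["nu_cc"]["spearman_rho"] > 0 and out["nu_cc2"]["spearman_rho"] > 0:
                wins += 1
        assert wins >= 95
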