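import numpy as np
import pytest

from chromdoe import chromsim
from chromdoe.chromsim import (
    Chromatogram,
    DEFAULT_TEMPLATES,
    HI443_TEMPLATE,
    STP_TEMPLATE,
    emg_profile,
    lod_from_calibration,
    peak_area,
    peak_windows,
    recovery,
    resolution,
    rsd,
    simulate_chromatogram,
    sn_ratio,
    theoretical_plates,
    usp_tailing,
)
from chromdoe.errors import ChromDoeError, DataError, DomainError


def _gaussian_trace(amplitude=1.0, retention=3.2, sigma=0.02, dt=0.002, t_max=8.0):
    t = np.arange(0.0, t_max + dt / 2, dt)
    return Chromatogram(t, amplitude * np.exp(-0.5 * ((t - retention) / sigma) ** 2))


def _emg_trace(area=0.3, retention=3.2, sigma=0.05, tau=0.05, dt=0.002):
    t = np.arange(0.0, 8.0 + dt / 2, dt)
    return Chromatogram(t, area * emg_profile(t, retention, sigma, tau))


OPTIMIZED = {"flow": 0.6, "volume": 18.0, "organic_init": 82.0,
             "wavelength": 270.0, "organic_late": 95.0}


class TestGenerator:
    def test_same_seed_bit_identical(self):
        a = simulate_chromatogram(OPTIMIZED, seed=5)
        b = simulate_chromatogram(OPTIMIZED, seed=5)
        assert np.array_equal(a.signal, b.signal)
        c = simulate_chromatogram(OPTIMIZED, seed=6)
        assert not np.array_equal(a.signal, c.signal)

    def test_doubling_flow_halves_area(self):
        lo = {**OPTIMIZED, "flow": 0.5}
        hi = {**OPTIMIZED, "flow": 1.0}
        a_lo = peak_area(simulate_chromatogram(lo, noise_sd=0, injection_cv=0),
                         peak_windows(lo)[0])
        a_hi = peak_area(simulate_chromatogram(hi, noise_sd=0, injection_cv=0),
                         peak_windows(hi)[0])
        assert a_lo / a_hi == pytest.approx(2.0, rel=0.01)

    def test_area_flow_mass_law_is_constant_across_grid(self):
        # area * flow / mass invariant within 1% over the factor grid
        ratios = []
        for flow in (0.6, 0.8, 1.0):
            for vol in (10.0, 15.0, 20.0):
                cond = {"flow": flow, "volume": vol}
                chrom = simulate_chromatogram(cond, noise_sd=0, injection_cv=0)
                w = peak_windows(cond)[0]
                mass = STP_TEMPLATE.concentration * vol * 1e-3
                ratios.append(peak_area(chrom, w) * flow / mass)
        ratios = np.array(ratios)
        assert ratios.std() / ratios.mean() < 0.01

    def test_symmetric_peak_has_unit_tailing(self):
        sym = chromsim.DrugTemplate(
            name="sym", concentration=10.0, base_retention=3.2, sigma0=0.05,
            response_factor0=1.0, tau0=0.0, tail_volume=0.0, tail_organic=0.0,
            tail_flow=0.0,
        )
        chrom = simulate_chromatogram(
            {"flow": 0.8}, templates=(sym,), noise_sd=0, injection_cv=0
        )
        T = usp_tailing(chrom, (3.2 - 0.4, 3.2 + 0.4))
        assert T == pytest.approx(1.0, abs=0.01)

    def test_tailing_nondecreasing_in_volume_and_organic(self):
        for key, levels in (("volume", [10, 15, 20]), ("organic_init", [60, 70, 80])):
            tails = []
            for level in levels:
                cond = {key: float(level)}
                chrom = simulate_chromatogram(cond, noise_sd=0, injection_cv=0)
                w_stp, w_hi = peak_windows(cond)
                tails.append((usp_tailing(chrom, w_stp), usp_tailing(chrom, w_hi)))
            tails = np.array(tails)
            assert np.all(np.diff(tails[:, 0]) >= -1e-6)
            assert np.all(np.diff(tails[:, 1]) >= -1e-6)

    def test_lipophilic_drug_more_sensitive_to_organic(self):
        assert HI443_TEMPLATE.tail_organic >= STP_TEMPLATE.tail_organic

    def test_retention_order_and_resolution_at_optimized_conditions(self):
        chrom = simulate_chromatogram(OPTIMIZED, noise_sd=0, injection_cv=0)
        w1, w2 = peak_windows(OPTIMIZED)
        assert w1[1] <= w2[0] + 1e-9
        assert resolution(chrom, w1, w2) > 2.0

    def test_invalid_conditions_rejected(self):
        with pytest.raises(DomainError):
            simulate_chromatogram({"flow": 0.0})
        with pytest.raises(DomainError):
            simulate_chromatogram({"volume": -1.0})

    def test_batch_responses_shape(self):
        design = np.array([[0.6, 10.0], [1.0, 20.0]])
        resp = chromsim.simulate_responses(design, ["flow", "volume"], seed=0)
        assert list(resp.columns) == ["Y1", "Y2", "Y3", "Y4"]
        assert len(resp) == 2
        # more mass at less flow -> larger areas in the second ordering
        assert resp.loc[0, "Y1"] != resp.loc[1, "Y1"]


class TestPeakArea:
    def test_gaussian_closed_form(self):
        A, sigma = 2.0, 0.02
        chrom = _gaussian_trace(amplitude=A, sigma=sigma)
        area = peak_area(chrom, (3.0, 3.4))
        assert area == pytest.approx(A * sigma * np.sqrt(2 * np.pi), rel=1e-3)

    def test_zero_signal(self):
        t = np.arange(0, 8, 0.002)
        chrom = Chromatogram(t, np.zeros_like(t))
        assert peak_area(chrom, (2.0, 3.0)) == 0.0

    def test_additive_over_disjoint_windows(self):
        chrom = _gaussian_trace()
        total = peak_area(chrom, (2.8, 3.6))
        left = peak_area(chrom, (2.8, 3.2))
        right = peak_area(chrom, (3.2, 3.6))
        assert left + right == pytest.approx(total, rel=1e-6)

    def test_constant_baseline_invariance(self):
        chrom = _gaussian_trace()
        shifted = Chromatogram(chrom.time, chrom.signal + 0.35)
        assert peak_area(shifted, (2.8, 3.6)) == pytest.approx(
            peak_area(chrom, (2.8, 3.6)), abs=1e-6
        )

    def test_empty_window_rejected(self):
        chrom = _gaussian_trace()
        with pytest.raises(DomainError):
            peak_area(chrom, (3.4, 3.0))


class TestUspTailing:
    def test_symmetric_gaussian(self):
        chrom = _gaussian_trace(sigma=0.05)
        assert usp_tailing(chrom, (2.8, 3.6)) == pytest.approx(1.0, abs=0.01)

    def test_emg_matches_dense_grid_oracle(self):
        coarse = _emg_trace(sigma=0.05, tau=0.05, dt=0.002)
        dense = _emg_trace(sigma=0.05, tau=0.05, dt=0.0002)
        t_coarse = usp_tailing(coarse, (2.9, 4.0))
        t_dense = usp_tailing(dense, (2.9, 4.0))
        assert t_coarse > 1.0
        assert t_coarse == pytest.approx(t_dense, abs=1e-2)

    def test_fronting_peak_below_one(self):
        tailed = _emg_trace(sigma=0.05, tau=0.05)
        fronting = Chromatogram(tailed.time, tailed.signal[::-1].copy())
        apex = tailed.time[np.argmax(fronting.signal)]
        assert usp_tailing(fronting, (apex - 0.55, apex + 0.35)) < 1.0

    def test_truncated_peak_flagged(self):
        chrom = _gaussian_trace(sigma=0.05)
        with pytest.raises(ChromDoeError):
            usp_tailing(chrom, (3.15, 3.25))

    def test_time_translation_invariance(self):
        chrom = _emg_trace(retention=3.2)
        moved = _emg_trace(retention=4.2)
        a = usp_tailing(chrom, (2.9, 4.0))
        b = usp_tailing(moved, (3.9, 5.0))
        assert a == pytest.approx(b, abs=1e-3)


class TestTheoreticalPlates:
    def test_gaussian_closed_form(self):
        t_r, sigma = 3.2, 0.02
        chrom = _gaussian_trace(retention=t_r, sigma=sigma)
        expected = 5.54 * (t_r / (2.3548 * sigma)) ** 2
        assert theoretical_plates(chrom, (3.0, 3.4)) == pytest.approx(expected, rel=0.01)

    def test_scale_invariance(self):
        a = _gaussian_trace(retention=2.0, sigma=0.02, t_max=10.0)
        b = _gaussian_trace(retention=4.0, sigma=0.04, t_max=10.0)
        na = theoretical_plates(a, (1.8, 2.2))
        nb = theoretical_plates(b, (3.6, 4.4))
        assert na == pytest.approx(nb, rel=1e-3)

    def test_wider_peak_fewer_plates(self):
        narrow = _gaussian_trace(sigma=0.02)
        wide = _gaussian_trace(sigma=0.05)
        assert theoretical_plates(wide, (2.8, 3.6)) < theoretical_plates(
            narrow, (2.8, 3.6)
        )


class TestResolution:
    def test_coeluting_peaks_zero(self):
        chrom = _gaussian_trace(sigma=0.05)
        assert resolution(chrom, (2.8, 3.6), (2.8, 3.6)) == pytest.approx(0.0, abs=1e-9)

    def test_four_sigma_separation_is_unit_resolution(self):
        sigma = 0.05
        t = np.arange(0, 8, 0.002)
        sig = np.exp(-0.5 * ((t - 3.0) / sigma) ** 2) + np.exp(
            -0.5 * ((t - 3.0 - 4 * sigma) / sigma) ** 2
        )
        chrom = Chromatogram(t, sig)
        rs = resolution(chrom, (2.8, 3.1), (3.1, 3.45))
        assert rs == pytest.approx(1.0, rel=0.05)

    def test_reversed_windows_rejected(self):
        sigma = 0.05
        t = np.arange(0, 8, 0.002)
        sig = np.exp(-0.5 * ((t - 3.0) / sigma) ** 2) + np.exp(
            -0.5 * ((t - 4.0) / sigma) ** 2
        )
        chrom = Chromatogram(t, sig)
        with pytest.raises(DomainError):
            resolution(chrom, (3.8, 4.2), (2.8, 3.2))


class TestSignalToNoise:
    def test_convention_arithmetic(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 8, 0.002)
        noise_sd = 5.0
        sig = 30.0 * np.exp(-0.5 * ((t - 3.2) / 0.05) ** 2)
        sig[t < 2.0] += rng.normal(0, noise_sd, (t < 2.0).sum())
        chrom = Chromatogram(t, sig)
        sn = sn_ratio(chrom, (2.9, 3.5), (0.5, 1.9))
        assert sn == pytest.approx(30.0 / (2 * noise_sd), rel=0.1)

    def test_noiseless_trace_degenerate(self):
        chrom = _gaussian_trace()
        with pytest.raises(DomainError):
            sn_ratio(chrom, (2.9, 3.5), (0.5, 1.9))

    def test_halving_height_halves_sn(self):
        rng = np.random.default_rng(1)
        t = np.arange(0, 8, 0.002)
        noise = rng.normal(0, 0.01, t.size) * (t < 2.0)
        peak = np.exp(-0.5 * ((t - 3.2) / 0.05) ** 2)
        a = sn_ratio(Chromatogram(t, peak + noise), (2.9, 3.5), (0.5, 1.9))
        b = sn_ratio(Chromatogram(t, 0.5 * peak + noise), (2.9, 3.5), (0.5, 1.9))
        assert a / b == pytest.approx(2.0, rel=0.02)

    def test_lod_from_calibration(self):
        # S/N = h/(2 sd); h = slope*c  =>  c_lod = 3*2*sd/slope
        assert lod_from_calibration(slope=1.5, noise_sd=0.002) == pytest.approx(
            3 * 2 * 0.002 / 1.5
        )
        with pytest.raises(DomainError):
            lod_from_calibration(slope=0.0, noise_sd=0.002)


class TestValidationStatistics:
    def test_rsd_of_identical_values_is_zero(self):
        assert rsd([10.0, 10.0, 10.0]) == 0.0

    def test_recovery_of_nominal_is_hundred(self):
        assert recovery(5.0, 5.0) == 100.0
        with pytest.raises(DomainError):
            recovery(5.0, 0.0)

    def test_replicate_area_rsd_tracks_injection_cv(self):
        areas = []
        for seed in range(30):
            chrom = simulate_chromatogram(OPTIMIZED, injection_cv=0.01, seed=seed)
            areas.append(peak_area(chrom, peak_windows(OPTIMIZED)[0]))
        observed = rsd(areas)
        assert 0.5 < observed < 1.6  # ~1% with Monte Carlo slack

    def test_rsd_needs_two_values(self):
        with pytest.raises(DataError):
            rsd([1.0])


def test_chromatogram_csv_round_trip(tmp_path):
    chrom = simulate_chromatogram(OPTIMIZED, seed=2)
    path = tmp_path / "trace.csv"
    chrom.to_csv(path)
    back = Chromatogram.from_csv(path)
    assert np.allclose(back.time, chrom.time)
    assert np.allclose(back.signal, chrom.signal)


def test_non_uniform_grid_rejected():
    t = np.array([0.0, 0.1, 0.3, 0.35])
    with pytest.raises(DataError):
        Chromatogram(t, np.zeros_like(t))
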