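"""FTIR preprocessing and 2D correlation spectroscopy with Noda sequencing."""

import numpy as np
import pytest

from leafspec.ftir import (
    FTIRSeries,
    asynchronous_map,
    baseline_correct,
    compute_2dcos,
    dynamic_spectra,
    find_auto_peaks,
    hilbert_noda_matrix,
    noda_ordering,
    split_regions,
    synchronous_map,
    transmission_to_absorbance,
)
from leafspec.synth import simulate_ftir_series


def series_from(spectra, wn=None, mode="absorbance"):
    spectra = np.atleast_2d(np.asarray(spectra, dtype=float))
    if wn is None:
        wn = np.arange(4000.0, 799.0, -4.0)[: spectra.shape[1]]
    return FTIRSeries(wavenumbers=wn, spectra=spectra, mode=mode)


class TestAbsorbanceConversion:
    def test_closed_form_decades(self):
        s = series_from([[1.0, 0.1, 0.01, 0.001]], mode="transmission")
        a = transmission_to_absorbance(s)
        assert np.allclose(a.spectra, [[0.0, 1.0, 2.0, 3.0]], atol=1e-12)

    def test_round_trip_restores_transmittance(self):
        rng = np.random.default_rng(0)
        T = rng.uniform(0.05, 1.0, (3, 50))
        a = transmission_to_absorbance(series_from(T, mode="transmission"))
        assert np.max(np.abs(np.power(10.0, -a.spectra) - T)) < 1e-12

    def test_non_positive_transmittance_rejected_with_location(self):
        s = series_from([[0.5, 0.0, 0.5, 0.5]], mode="transmission")
        with pytest.raises(ValueError, match="level 0"):
            transmission_to_absorbance(s)

    def test_values_above_one_clipped_and_counted(self):
        s = series_from([[0.5, 1.2, 1.1, 0.9]], mode="transmission")
        a = transmission_to_absorbance(s)
        assert a.notes["n_clipped"] == 2
        assert a.spectra[0, 1] == 0.0


class TestBaseline:
    def test_constant_spectrum_corrects_to_zero(self):
        s = series_from([np.full(50, 0.7)])
        for method in ("rubberband", "als"):
            out = baseline_correct(s, method=method)
            assert np.max(np.abs(out.spectra)) < 1e-6

    def test_rubberband_recovers_gaussian_on_linear_ramp(self):
        wn = np.linspace(4000.0, 800.0, 400)
        ramp = 0.2 + 0.0001 * (4000.0 - wn)
        peak = 0.8 * np.exp(-0.5 * ((wn - 2400.0) / 40.0) ** 2)
        s = series_from([ramp + peak], wn=wn)
        out = baseline_correct(s, method="rubberband")
        assert np.max(np.abs(out.spectra[0] - peak)) < 1e-6
        assert out.spectra.min() >= -1e-9

    def test_rubberband_idempotent(self):
        rng = np.random.default_rng(1)
        wn = np.linspace(4000.0, 800.0, 200)
        y = 0.3 + 0.5 * np.exp(-0.5 * ((wn - 1600) / 60.0) ** 2) + 0.02 * rng.random(200)
        s = series_from([y], wn=wn)
        once = baseline_correct(s, method="rubberband")
        twice = baseline_correct(once, method="rubberband")
        assert np.max(np.abs(once.spectra - twice.spectra)) < 1e-8

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown baseline"):
            baseline_correct(series_from([np.ones(20)]), method="magic")

    def test_too_few_points_rejected(self):
        s = FTIRSeries(wavenumbers=np.arange(5.0), spectra=np.ones((1, 5)))
        with pytest.raises(ValueError, match="8 points"):
            baseline_correct(s)


class TestSplitRegions:
    def test_default_two_disjoint_regions(self):
        wn = np.arange(4000.0, 799.0, -4.0)
        s = series_from(np.ones((2, wn.size)), wn=wn)
        regions = split_regions(s)
        fg, fp = regions["functional_group"], regions["fingerprint"]
        assert fg.wavenumbers.min() >= 2800.0 and fg.wavenumbers.max() <= 4000.0
        assert fp.wavenumbers.min() >= 800.0 and fp.wavenumbers.max() <= 1800.0
        assert not set(fg.wavenumbers) & set(fp.wavenumbers)

    def test_boundary_point_2800_included_closed_interval(self):
        wn = np.arange(4000.0, 799.0, -4.0)
        s = series_from(np.ones((1, wn.size)), wn=wn)
        assert 2800.0 in split_regions(s)["functional_group"].wavenumbers

    def test_functional_group_region_has_301_points_on_4cm_grid(self):
        wn = np.arange(4000.0, 799.0, -4.0)
        s = series_from(np.ones((1, wn.size)), wn=wn)
        # arithmetic grid: points of [2800, 4000] at step 4 -> 1200/4 + 1
        assert split_regions(s)["functional_group"].wavenumbers.size == 301

    def test_empty_window_rejected(self):
        s = series_from(np.ones((1, 10)), wn=np.linspace(2000, 1900, 10))
        with pytest.raises(ValueError, match="functional_group"):
            split_regions(s)


class TestDynamicSpectra:
    def test_identical_levels_give_zero(self):
        s = series_from(np.tile(np.linspace(0, 1, 30), (4, 1)))
        assert np.array_equal(dynamic_spectra(s), np.zeros((4, 30)))

    def test_two_levels_with_mean_reference_are_plus_minus_half_difference(self):
        a, b = np.full(20, 0.2), np.full(20, 0.6)
        s = series_from(np.stack([a, b]))
        dyn = dynamic_spectra(s)
        assert np.allclose(dyn[0], -(b - a) / 2, atol=1e-15)
        assert np.allclose(dyn[1], +(b - a) / 2, atol=1e-15)

    def test_column_sums_vanish_with_mean_reference(self):
        rng = np.random.default_rng(2)
        s = series_from(rng.random((6, 40)))
        assert np.max(np.abs(dynamic_spectra(s).sum(axis=0))) < 1e-12

    def test_wrong_length_custom_reference_rejected(self):
        s = series_from(np.random.rand(3, 20))
        with pytest.raises(ValueError, match="length"):
            dynamic_spectra(s, reference=np.zeros(19))


class TestCorrelationMaps:
    def test_zero_dynamic_spectra_give_zero_maps(self):
        dyn = np.zeros((5, 12))
        assert np.array_equal(synchronous_map(dyn), np.zeros((12, 12)))
        assert np.array_equal(asynchronous_map(dyn), np.zeros((12, 12)))

    def test_hilbert_noda_matrix_definition(self):
        N = hilbert_noda_matrix(4)
        for j in range(4):
            for k in range(4):
                expected = 0.0 if j == k else 1.0 / (np.pi * (k - j))
                assert N[j, k] == pytest.approx(expected, abs=1e-15)

    def test_identically_varying_bands_have_pure_synchronous_cross_peak(self):
        t = np.linspace(0, 1, 16)
        resp = np.sin(np.pi * t)
        dyn = np.stack([resp, resp], axis=1)
        dyn -= dyn.mean(axis=0)
        phi = synchronous_map(dyn)
        psi = asynchronous_map(dyn)
        assert phi[0, 1] == pytest.approx(phi[0, 0], abs=1e-12)
        assert phi[0, 1] > 0
        assert abs(psi[0, 1]) < 1e-12

    def test_quarter_period_lead_gives_positive_asynchronous_peak(self):
        # band A leads band B by 90 degrees over 32 levels
        series, _ = simulate_ftir_series(
            [(3000.0, 30.0, 0), (1500.0, 30.0, 1)], n_levels=32,
            response="sin", phase_step_deg=90.0, mode="absorbance",
        )
        dyn = dynamic_spectra(series)
        phi = synchronous_map(dyn)
        psi = asynchronous_map(dyn)
        ia = int(np.argmin(np.abs(series.wavenumbers - 3000.0)))
        ib = int(np.argmin(np.abs(series.wavenumbers - 1500.0)))
        assert psi[ia, ib] > 0
        assert phi[ia, ib] >= 0

    def test_symmetry_psd_and_antisymmetry_properties(self):
        rng = np.random.default_rng(3)
        dyn = rng.random((8, 25)) - 0.5
        phi = synchronous_map(dyn)
        psi = asynchronous_map(dyn)
        assert np.max(np.abs(phi - phi.T)) < 1e-10
        assert np.min(np.linalg.eigvalsh(phi)) > -1e-10
        assert np.max(np.abs(psi + psi.T)) < 1e-12
        assert np.max(np.abs(np.diag(psi))) < 1e-12

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            synchronous_map(np.ones((1, 5)))


class TestAutoPeaks:
    def test_flat_diagonal_has_no_peaks(self):
        phi = np.eye(10) * 0.5
        phi[0, 0] = 0.5
        peaks = find_auto_peaks(np.full((10, 10), 0.1), np.arange(10.0))
        assert len(peaks) == 0

    def test_single_planted_variance_maximum(self):
        series, _ = simulate_ftir_series([(2000.0, 40.0, 0)], n_levels=12, mode="absorbance")
        res = compute_2dcos(series)
        assert len(res.auto_peaks) == 1
        assert res.auto_peaks.iloc[0]["wavenumber_cm-1"] == pytest.approx(2000.0, abs=4.0)

    def test_two_bands_ordered_by_variance(self):
        series, _ = simulate_ftir_series(
            [(3000.0, 30.0, 0), (1500.0, 30.0, 0)], n_levels=12,
            amplitude=0.8, mode="absorbance",
        )
        series.spectra[:, :] *= 1.0
        # shrink the 1500 band by blending toward its mean
        ib = np.abs(series.wavenumbers - 1500.0) < 100
        mean = series.spectra[:, ib].mean(axis=0)
        series.spectra[:, ib] = mean + 0.5 * (series.spectra[:, ib] - mean)
        res = compute_2dcos(series)
        assert len(res.auto_peaks) == 2
        assert res.auto_peaks.iloc[0]["wavenumber_cm-1"] == pytest.approx(3000.0, abs=4.0)


class TestNodaOrdering:
    def test_proportional_bands_are_simultaneous(self):
        t = np.linspace(0, 1, 16)
        resp = np.sin(np.pi * t)
        wn = np.array([3000.0, 1500.0])
        spectra = np.stack([resp, 2 * resp], axis=1) + 0.1
        s = FTIRSeries(wavenumbers=wn, spectra=spectra, mode="absorbance")
        res = compute_2dcos(s)
        order = noda_ordering(res.sync, res.async_, wn, [3000.0, 1500.0])
        assert order.groups == [(1500.0, 3000.0)]
        assert order.consistent

    def test_planted_three_band_sequence_recovered(self):
        bands = [(3356.0, 40.0, 0), (2910.0, 30.0, 1), (1730.0, 25.0, 2)]
        series, truth = simulate_ftir_series(bands, n_levels=16, mode="absorbance")
        res = compute_2dcos(series)
        order = noda_ordering(res.sync, res.async_, series.wavenumbers,
                              [3356.0, 2910.0, 1730.0])
        assert order.consistent
        assert order.groups == [(3356.0,), (2910.0,), (1730.0,)]
        assert [list(g) for g in order.groups] == [list(g) for g in truth]

    def test_arrow_notation_format(self):
        bands = [(3356.0, 40.0, 0), (2910.0, 30.0, 1)]
        series, _ = simulate_ftir_series(bands, n_levels=16, mode="absorbance")
        res = compute_2dcos(series)
        order = noda_ordering(res.sync, res.async_, series.wavenumbers, [3356.0, 2910.0])
        assert order.arrow_notation() == "3356 → 2910"

    def test_cyclic_conclusions_reported_inconsistent(self):
        wn = np.array([3.0, 2.0, 1.0])
        phi = np.ones((3, 3))
        psi = np.array([[0.0, 1.0, -1.0], [-1.0, 0.0, 1.0], [1.0, -1.0, 0.0]])
        order = noda_ordering(phi, psi, wn, [1.0, 2.0, 3.0])
        assert not order.consistent
        assert order.arrow_notation() == "inconsistent"

    @pytest.mark.parametrize("lead_deg", [15, 45, 90, 120, 165])
    @pytest.mark.parametrize("seed", range(10))
    def test_pairwise_direction_across_phase_leads_and_seeds(self, lead_deg, seed):
        series, _ = simulate_ftir_series(
            [(3000.0, 30.0, 0), (1500.0, 30.0, 1)], n_levels=16, seed=seed,
            response="sin", phase_step_deg=float(lead_deg), mode="absorbance",
            noise_sd=0.001,
        )
        res = compute_2dcos(series)
        order = noda_ordering(res.sync, res.async_, series.wavenumbers,
                              [3000.0, 1500.0])
        assert order.consistent
        assert order.groups == [(3000.0,), (1500.0,)]

    def test_band_off_grid_rejected(self):
        wn = np.arange(4000.0, 3899.0, -4.0)
        phi = np.eye(wn.size)
        psi = np.zeros((wn.size, wn.size))
        with pytest.raises(ValueError, match="not on the wavenumber grid"):
            noda_ordering(phi, psi, wn, [3950.0, 1000.0])

    def test_low_level_count_flagged_in_notes(self):
        series, _ = simulate_ftir_series(
            [(3000.0, 30.0, 0)], n_levels=3, mode="absorbance"
        )
        res = compute_2dcos(series)
        assert "low-rank" in res.notes["async_rank"]
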