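"""Baseline correction, normalization, second derivative and band picking."""

import numpy as np
import pytest

from amylir.spectra import (
    Spectrum,
    baseline_correct,
    normalize_amide_one,
    pick_bands,
    read_spectrum,
    second_derivative,
    write_spectrum,
    average_spectra,
)
from amylir.synthetic import SpectrumParams, default_grid, simulate_spectrum


def gaussian_spectrum(bands, baseline=(0.0,), noise_sd=0.0, seed=0):
    p = SpectrumParams("fibril", tuple(bands), tuple(baseline), noise_sd=noise_sd, seed=seed)
    return simulate_spectrum(p)


class TestBaseline:
    def test_constant_offset_removed_by_rubberband(self):
        spec = gaussian_spectrum([(1630, 5, 1.0)])
        shifted = spec.replace_absorbance(spec.absorbance + 3.0)
        corrected = baseline_correct(shifted, "rubberband")
        np.testing.assert_allclose(
            corrected.absorbance, baseline_correct(spec).absorbance, atol=1e-9
        )

    def test_idempotent_on_hull_touching_trace(self):
        spec = baseline_correct(gaussian_spectrum([(1630, 5, 1.0)]))
        again = baseline_correct(spec)
        np.testing.assert_allclose(again.absorbance, spec.absorbance, atol=1e-9)

    def test_planted_linear_baseline_recovered_within_2_percent(self):
        """Oracle: the noise-free forward model without its baseline term."""
        bands = [(1630.0, 5.0, 1.0), (1690.0, 4.0, 0.2)]
        clean = gaussian_spectrum(bands)
        drifted = gaussian_spectrum(bands, baseline=(0.05, 4e-4))
        corrected = baseline_correct(drifted, "rubberband")
        for center, _, amp in bands:
            i = np.argmin(np.abs(corrected.wavenumbers - center))
            assert corrected.absorbance[i] == pytest.approx(clean.absorbance[i], rel=0.02)

    def test_linear_method_subtracts_chord(self):
        w = default_grid()
        trace = 0.2 + 1e-3 * (w - w[0])
        corrected = baseline_correct(Spectrum(w, trace), "linear")
        np.testing.assert_allclose(corrected.absorbance, 0.0, atol=1e-12)


class TestNormalize:
    def test_amide_maximum_becomes_one(self):
        spec = gaussian_spectrum([(1655, 8, 0.37)])
        out = normalize_amide_one(spec)
        mask = (out.wavenumbers >= 1600) & (out.wavenumbers <= 1700)
        assert out.absorbance[mask].max() == pytest.approx(1.0)

    def test_idempotent(self):
        out = normalize_amide_one(gaussian_spectrum([(1655, 8, 0.37)]))
        np.testing.assert_allclose(
            normalize_amide_one(out).absorbance, out.absorbance
        )

    def test_all_zero_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize_amide_one(Spectrum(default_grid(), np.zeros(141)))


class TestSecondDerivative:
    def test_quadratic_gives_constant_second_derivative(self):
        w = default_grid()
        a = 3e-4 * (w - 1650.0) ** 2
        dii = second_derivative(Spectrum(w, a))
        interior = dii.dii[20:-20]
        np.testing.assert_allclose(interior, 6e-4, rtol=1e-8)

    def test_gaussian_band_minimum_at_center(self):
        dii = second_derivative(gaussian_spectrum([(1630, 5, 1.0)]))
        assert dii.wavenumbers[np.argmin(dii.dii)] == 1630.0

    def test_noisy_minima_within_2_wavenumbers_of_planted_centers(self):
        """Oracle: noise-free analytic DII of well-separated bands."""
        hits = 0
        for seed in range(20):
            spec = gaussian_spectrum(
                [(1630.0, 5.0, 1.0), (1689.0, 4.0, 0.25)], noise_sd=0.01, seed=seed
            )
            dii = second_derivative(normalize_amide_one(baseline_correct(spec)))
            bands = pick_bands(dii)
            found = sorted(b.position for b in bands)
            if any(abs(p - 1630) <= 2 for p in found) and any(
                abs(p - 1689) <= 2 for p in found
            ):
                hits += 1
        assert hits >= 19

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(gaussian_spectrum([(1630, 5, 1.0)]), window_pts=30)

    def test_window_longer_than_trace_rejected(self):
        with pytest.raises(ValueError):
            second_derivative(gaussian_spectrum([(1630, 5, 1.0)]), window_pts=201)

    def test_two_step_mode_agrees_on_band_position(self):
        spec = gaussian_spectrum([(1630, 5, 1.0)])
        one = second_derivative(spec, method="single_pass")
        two = second_derivative(spec, method="two_step")
        assert abs(
            one.wavenumbers[np.argmin(one.dii)] - two.wavenumbers[np.argmin(two.dii)]
        ) <= 1


class TestPickBands:
    def test_fibril_pattern_dominant_and_minor(self):
        spec = gaussian_spectrum([(1628.0, 5.0, 1.0), (1689.0, 4.0, 0.25)])
        dii = second_derivative(normalize_amide_one(baseline_correct(spec)))
        bands = pick_bands(dii)
        dominant = next(b for b in bands if b.is_dominant)
        assert abs(dominant.position - 1628) <= 2
        assert any(abs(b.position - 1689) <= 2 for b in bands if not b.is_dominant)

    def test_aromatic_exclusion_depends_on_sequence(self):
        spec = gaussian_spectrum([(1655.0, 6.0, 1.0), (1616.0, 3.0, 0.15)])
        dii = second_derivative(normalize_amide_one(baseline_correct(spec)))
        with_y = pick_bands(dii, sequence="YYTEFT")
        without_y = pick_bands(dii, sequence="STVVIE")
        assert not any(abs(b.position - 1616) <= 3 for b in with_y)
        assert any(abs(b.position - 1616) <= 3 for b in without_y)

    def test_flat_spectrum_rejected(self):
        w = default_grid()
        dii = second_derivative(Spectrum(w, np.full(w.size, 0.5)))
        with pytest.raises(ValueError):
            pick_bands(dii)

    def test_band_positions_invariant_to_positive_scaling(self):
        spec = gaussian_spectrum([(1633.0, 5.0, 1.0), (1685.0, 4.0, 0.2)])
        def positions(s):
            dii = second_derivative(normalize_amide_one(baseline_correct(s)))
            return [(b.position, b.is_dominant) for b in pick_bands(dii)]
        scaled = spec.replace_absorbance(spec.absorbance * 37.5)
        assert positions(spec) == positions(scaled)


class TestIO:
    def test_two_column_round_trip_and_descending_flip(self, tmp_path):
        spec = gaussian_spectrum([(1630, 5, 1.0)])
        path = tmp_path / "spec.txt"
        write_spectrum(spec, path)
        back = read_spectrum(path)
        np.testing.assert_allclose(back.wavenumbers, spec.wavenumbers)
        np.testing.assert_allclose(back.absorbance, spec.absorbance, rtol=1e-5)
        # descending instrument order is flipped to ascending
        desc = tmp_path / "desc.csv"
        desc.write_text(
            "\n".join(f"{w},{a}" for w, a in zip(spec.wavenumbers[::-1], spec.absorbance[::-1]))
        )
        np.testing.assert_allclose(read_spectrum(desc).wavenumbers, spec.wavenumbers)

    def test_average_spectra_is_pointwise_mean(self):
        a = gaussian_spectrum([(1630, 5, 1.0)])
        b = gaussian_spectrum([(1660, 5, 1.0)])
        avg = average_spectra([a, b])
        np.testing.assert_allclose(avg.absorbance, (a.absorbance + b.absorbance) / 2)

    def test_strictly_ascending_grid_enforced(self):
        with pytest.raises(ValueError):
            Spectrum(np.array([1580.0, 1580.0, 1581.0]), np.zeros(3))
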