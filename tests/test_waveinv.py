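"""Inversion chain: harmonic extraction, filtering, wavenumbers, compounding."""

import numpy as np
import pytest

from hepamre.synthcohort import gen_wavefield, liver_mask, phase_encode
from hepamre.waveinv import (
    FilterSettings,
    ParameterMap,
    PhaseOffsetSeries,
    bandpass_field,
    compound_pr,
    compound_sws,
    directional_filter,
    extract_harmonic,
    invert_wavefield,
    roi_stats,
    unwrap_gradient,
    wavenumber_maps,
    wrap_phase,
)

SP = (0.002, 0.002)  # 2 mm in-plane spacing, in meters


def _plane_wave(k_cycles_m, shape=(32, 32), angle=0.0, spacing=SP):
    yy, xx = np.meshgrid(
        np.arange(shape[0]) * spacing[0], np.arange(shape[1]) * spacing[1], indexing="ij"
    )
    s = xx * np.cos(angle) + yy * np.sin(angle)
    return np.exp(2j * np.pi * k_cycles_m * s)


class TestExtractHarmonic:
    def test_pure_cosine_yields_unit_amplitude_zero_phase(self):
        t = np.arange(8)
        imgs = np.cos(2 * np.pi * t / 8)[:, None, None, None] * np.ones((8, 1, 4, 4))
        series = PhaseOffsetSeries(imgs, 60.0, "HF", (5.0, 2.0, 2.0))
        u = extract_harmonic(series)
        assert np.allclose(np.abs(u), 1.0)
        assert np.allclose(np.angle(u), 0.0, atol=1e-12)

    def test_dc_offset_is_rejected(self):
        imgs = np.full((8, 1, 4, 4), 0.7)
        u = extract_harmonic(PhaseOffsetSeries(imgs, 60.0, "HF", (5.0, 2.0, 2.0)))
        assert np.allclose(u, 0.0, atol=1e-14)

    def test_cosine_with_dc_and_noise_recovers_amplitude(self, rng):
        t = np.arange(8)
        a_true = 0.8
        base = a_true * np.cos(2 * np.pi * t / 8 + 0.3)
        imgs = base[:, None, None, None] + 0.5 + 0.008 * rng.standard_normal((8, 1, 8, 8))
        u = extract_harmonic(PhaseOffsetSeries(imgs, 60.0, "HF", (5.0, 2.0, 2.0)))
        assert np.abs(u).mean() == pytest.approx(a_true, rel=0.02)

    def test_wrong_offset_count_rejected(self):
        with pytest.raises(ValueError, match="8 phase offsets"):
            PhaseOffsetSeries(np.zeros((6, 1, 4, 4)), 60.0, "HF", (5.0, 2.0, 2.0))

    def test_round_trip_with_phase_encode(self):
        wfs, _ = gen_wavefield(shape=(1, 24, 24), frequencies_hz=[60.0], snr=None)
        series = phase_encode(wfs, amplitude_rad=0.4)[0]
        u = extract_harmonic(series)
        assert np.allclose(u, 0.4 * wfs.fields[0, 0], rtol=1e-10, atol=1e-12)

    def test_wrapped_encoding_stays_in_range(self):
        wfs, _ = gen_wavefield(shape=(1, 16, 16), frequencies_hz=[60.0], snr=None)
        series = phase_encode(wfs, amplitude_rad=9.0)[0]
        assert series.images.max() <= np.pi
        assert series.images.min() > -np.pi


class TestUnwrapGradient:
    def test_wrapped_linear_ramp_gives_constant_slope(self):
        slope = 0.3  # rad/voxel
        phase = wrap_phase(np.arange(64)[None, :] * slope * np.ones((64, 1)))
        settings = FilterSettings(lowpass_threshold=None)
        gy, gx, aliased = unwrap_gradient(phase, settings, SP)
        interior = gx[4:-4, 4:-4] * SP[1]
        assert np.allclose(interior, slope, atol=1e-9)
        assert np.allclose(gy[4:-4, 4:-4], 0.0, atol=1e-9)
        assert not aliased

    def test_zero_field_zero_gradient(self):
        gy, gx, aliased = unwrap_gradient(np.zeros((16, 16)), FilterSettings(), SP)
        assert np.allclose(gy, 0) and np.allclose(gx, 0) and not aliased

    def test_wrapped_quadratic_matches_sequential_unwrap(self):
        x = np.arange(96)
        true_phase = 0.001 * x**2  # gradient stays below pi/voxel
        wrapped = wrap_phase(np.tile(true_phase, (4, 1)))
        settings = FilterSettings(lowpass_threshold=None)
        _, gx, _ = unwrap_gradient(wrapped, settings, SP)
        unwrapped = np.unwrap(wrapped, axis=-1)  # 1-D sequential oracle
        gx_oracle = np.gradient(unwrapped, SP[1], axis=-1)
        assert np.allclose(gx[:, 2:-2], gx_oracle[:, 2:-2], rtol=1e-6, atol=1e-6)

    def test_aliasing_flag_raised_beyond_pi_per_voxel(self):
        phase = wrap_phase(np.arange(32)[None, :] * 3.2 * np.ones((32, 1)))
        _, _, aliased = unwrap_gradient(phase, FilterSettings(lowpass_threshold=None), SP)
        assert aliased


class TestDirectionalFilter:
    def test_partition_of_unity(self):
        rng = np.random.default_rng(7)
        u = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        settings = FilterSettings()
        comps = directional_filter(u, settings, SP)
        recon = comps.sum(axis=0)
        ref = bandpass_field(u, settings, SP)
        assert np.max(np.abs(recon - ref)) < 1e-10

    def test_plane_wave_energy_concentrates_in_matching_wedge(self):
        u = _plane_wave(40.0, angle=0.0)  # +x propagation
        comps = directional_filter(u, FilterSettings(), SP)
        energies = [float(np.sum(np.abs(c) ** 2)) for c in comps]
        assert energies[0] / sum(energies) > 0.95

    def test_two_orthogonal_waves_match_isolated_references(self):
        ux = _plane_wave(40.0, angle=0.0)
        uy = _plane_wave(40.0, angle=np.pi / 2)
        settings = FilterSettings()
        both = directional_filter(ux + uy, settings, SP)
        alone_x = directional_filter(ux, settings, SP)[0]
        alone_y = directional_filter(uy, settings, SP)[2]
        for mixed, alone in ((both[0], alone_x), (both[2], alone_y)):
            denom = np.linalg.norm(alone)
            assert np.linalg.norm(mixed - alone) / denom < 0.02

    @pytest.mark.parametrize("scale", [0.25, 3.0])
    def test_filtering_is_linear(self, scale):
        rng = np.random.default_rng(3)
        u = rng.standard_normal((24, 24)) + 1j * rng.standard_normal((24, 24))
        settings = FilterSettings()
        a = directional_filter(scale * u, settings, SP)
        b = scale * directional_filter(u, settings, SP)
        assert np.max(np.abs(a - b)) < 1e-12 * max(1.0, scale)


class TestWavenumberMaps:
    def test_plane_wave_wavenumber_is_f_over_c(self):
        u = _plane_wave(60.0 / 1.6, shape=(48, 48))  # 37.5 cycles/m
        k, _, w = wavenumber_maps(u, 60.0, SP)
        assert np.allclose(k[4:-4, 4:-4], 37.5, rtol=1e-6)
        assert np.all(w >= 0)

    def test_doubling_frequency_doubles_wavenumber(self):
        k1, _, _ = wavenumber_maps(_plane_wave(25.0), 40.0, SP)
        k2, _, _ = wavenumber_maps(_plane_wave(50.0), 80.0, SP)
        assert np.median(k2[4:-4, 4:-4]) == pytest.approx(
            2 * np.median(k1[4:-4, 4:-4]), rel=1e-6
        )

    def test_all_zero_component_yields_zero_weight(self):
        k, att, w = wavenumber_maps(np.zeros((16, 16), complex), 60.0, SP)
        assert np.all(w == 0)

    def test_noisy_plane_wave_weighted_median_within_5pct(self, rng):
        u = _plane_wave(37.5, shape=(64, 64))
        noise = (rng.standard_normal(u.shape) + 1j * rng.standard_normal(u.shape))
        u = u + noise * np.sqrt(1.0 / 10.0 / 2.0)  # SNR 10
        from hepamre.waveinv import _lowpass_complex

        u = _lowpass_complex(u, FilterSettings(), SP)
        k, _, w = wavenumber_maps(u, 60.0, SP)
        sel = w > 0.5 * w.max()
        assert np.median(k[sel]) == pytest.approx(37.5, rel=0.05)


class TestCompounding:
    def test_single_entry_reduces_to_f_over_k(self):
        k = np.full((8, 8), 40.0)
        w = np.ones_like(k)
        pmap = compound_sws([k], [w], [60.0])
        assert np.allclose(pmap.values, 1.5)

    def test_zero_weight_corner_is_nan(self):
        k = np.full((8, 8), 40.0)
        w = np.ones_like(k)
        w[:4, :4] = 0.0
        pmap = compound_sws([k], [w], [60.0])
        assert np.all(np.isnan(pmap.values[:4, :4]))
        assert np.all(np.isfinite(pmap.values[4:, 4:]))

    def test_zero_attenuation_is_masked_not_infinite(self):
        att = np.zeros((8, 8))
        w = np.ones_like(att)
        pmap = compound_pr([att], [w], [60.0])
        assert not np.any(np.isinf(pmap.values))
        assert np.all(np.isnan(pmap.values))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compound_sws([], [], [])


class TestRoiStats:
    def test_constant_map(self):
        vals = np.full((4, 4), 1.59)
        pmap = ParameterMap(vals, "SWS", np.ones((4, 4), bool))
        s = roi_stats(pmap, np.ones((4, 4), bool))
        assert s["mean"] == pytest.approx(1.59) and s["sd"] == 0.0

    def test_two_level_map(self):
        vals = np.concatenate([np.ones((2, 4)), 2 * np.ones((2, 4))])
        pmap = ParameterMap(vals, "SWS", np.ones((4, 4), bool))
        assert roi_stats(pmap, np.ones((4, 4), bool))["mean"] == pytest.approx(1.5)

    def test_empty_intersection_rejected(self):
        pmap = ParameterMap(np.ones((4, 4)), "SWS", np.zeros((4, 4), bool))
        with pytest.raises(ValueError):
            roi_stats(pmap, np.ones((4, 4), bool))


class TestEndToEndRecovery:
    def test_noiseless_recovery(self):
        wfs, _ = gen_wavefield(snr=None, seed=0)
        sws_map, pr_map = invert_wavefield(wfs)
        roi = liver_mask(wfs.fields.shape[2:], margin=6)
        sws = roi_stats(sws_map, roi)["mean"]
        pr = roi_stats(pr_map, roi)["mean"]
        assert sws == pytest.approx(1.6, rel=0.02)
        assert pr == pytest.approx(1.0, rel=0.05)

    def test_halving_pr_doubles_recovered_attenuation(self):
        roi = liver_mask((2, 48, 48), margin=6)
        prs = []
        for pr_true in (1.0, 0.5):
            wfs, _ = gen_wavefield(pr_true=pr_true, snr=None, seed=0)
            _, pr_map = invert_wavefield(wfs)
            prs.append(roi_stats(pr_map, roi)["mean"])
        assert prs[0] / prs[1] == pytest.approx(2.0, rel=0.05)

    def test_resolution_invariance(self):
        wfs, _ = gen_wavefield(shape=(1, 48, 48), spacing_mm=(5, 2, 2), snr=None, seed=0)
        coarse = roi_stats(invert_wavefield(wfs)[0], liver_mask((1, 48, 48), 6))["mean"]
        wfs, _ = gen_wavefield(shape=(1, 96, 96), spacing_mm=(5, 1, 1), snr=None, seed=0)
        fine = roi_stats(invert_wavefield(wfs)[0], liver_mask((1, 96, 96), 12))["mean"]
        assert abs(fine - coarse) / coarse < 0.01
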