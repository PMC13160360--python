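import numpy as np
import pytest

import frontscan as fs
from frontscan.echogram import (PipelineOrderError, _db, _lin,
                                absorption_coefficient, apply_sv_threshold,
                                compute_mvbs, detect_and_exclude_bottom,
                                exclude_surface, near_field_depth,
                                recorrect_sv, remove_background_noise,
                                remove_impulse_noise, resample_to_reference,
                                smooth, wavelength)
from conftest import flat_grid


# ---------------------------------------------------------------------------
# physics


class TestAbsorption:
    def test_monotone_in_frequency(self):
        a = [absorption_coefficient(f, 4.0, 35.0, 100.0) for f in (18, 38, 120)]
        assert a[0] < a[1] < a[2]

    def test_independent_oracle(self):
        """Hand-coded evaluation of the published three-term formulation."""
        T, S, D, ph, f = 4.0, 35.0, 100.0, 8.0, 38.0
        c = 1412 + 3.21 * T + 1.19 * S + 0.0167 * D
        th = T + 273.0
        f1 = 2.8 * (S / 35) ** 0.5 * 10 ** (4 - 1245 / th)
        term1 = (8.86 / c) * 10 ** (0.78 * ph - 5) * f1 * f**2 / (f1**2 + f**2)
        f2 = (8.17 * 10 ** (8 - 1990 / th)) / (1 + 0.0018 * (S - 35))
        p2 = 1 - 1.37e-4 * D + 6.2e-9 * D**2
        term2 = 21.44 * (S / c) * (1 + 0.025 * T) * p2 * f2 * f**2 / (f2**2 + f**2)
        a3 = 4.937e-4 - 2.59e-5 * T + 9.11e-7 * T**2 - 1.50e-8 * T**3
        p3 = 1 - 3.83e-5 * D + 4.9e-10 * D**2
        expected = (term1 + term2 + a3 * p3 * f**2) / 1000.0
        got = absorption_coefficient(f, T, S, D, ph)
        assert got == pytest.approx(expected, rel=1e-4)

    def test_freshwater_limit_pure_water_only(self):
        T, D, f = 10.0, 50.0, 38.0
        a3 = 4.937e-4 - 2.59e-5 * T + 9.11e-7 * T**2 - 1.50e-8 * T**3
        p3 = 1 - 3.83e-5 * D + 4.9e-10 * D**2
        assert absorption_coefficient(f, T, 0.0, D) == pytest.approx(
            a3 * p3 * f**2 / 1000.0, rel=1e-12)

    def test_out_of_band_frequency_rejected(self):
        with pytest.raises(ValueError):
            absorption_coefficient(5.0, 4.0, 35.0, 100.0)


class TestNearField:
    def test_closed_form(self):
        # lambda = 1480/38000 = 0.03895 m; pi*0.04/lambda ~ 3.23 m; +2 m buffer
        assert wavelength(1480.0, 38.0) == pytest.approx(0.03895, abs=1e-5)
        assert near_field_depth(0.2, 38.0, 1480.0) == pytest.approx(5.23,
                                                                    abs=0.01)

    def test_zero_radius_limit(self):
        assert near_field_depth(0.0, 38.0, 1480.0, buffer_m=0.0) == 0.0

    def test_demo_defaults_mask_top_twelve_metres(self):
        """38 kHz survey defaults exclude roughly the top 12 m."""
        cfg = fs.PipelineConfig()
        d = near_field_depth(cfg.transducer_radius_m[38.0], 38.0, 1480.0)
        assert 10.0 <= d <= 13.0


# ---------------------------------------------------------------------------
# sv re-correction


class TestRecorrect:
    def test_identity(self):
        g = flat_grid()
        out = recorrect_sv(g, 1480.0, 1480.0, 0.01, 0.01)
        np.testing.assert_allclose(out.sv, g.sv)
        np.testing.assert_allclose(out.depth_edges, g.depth_edges)

    def test_sound_speed_doubling(self):
        g = flat_grid(n_bins=150)
        out = recorrect_sv(g, 740.0, 1480.0, 0.0, 0.0)
        i = np.argmin(np.abs(g.depth_centers - 100.0))
        assert (out.sv - g.sv)[0, i] == pytest.approx(20 * np.log10(2),
                                                      abs=1e-9)
        np.testing.assert_allclose(out.depth_edges, 2 * g.depth_edges)

    def test_absorption_delta(self):
        g = flat_grid(n_bins=150, bin_m=1.0)
        g.depth_edges = np.arange(151, dtype=float) - 0.5  # center bin at 100
        out = recorrect_sv(g, 1480.0, 1480.0, 0.0, 0.001)
        i = np.argmin(np.abs(g.depth_centers - 100.0))
        assert (out.sv - g.sv)[0, i] == pytest.approx(0.2, abs=1e-9)


# ---------------------------------------------------------------------------
# exclusions


class TestSurfaceExclusion:
    def test_masks_above_line(self):
        g = flat_grid()
        out = exclude_surface(g, 0.2, c=1480.0)  # line at 5.23 m
        assert out.masks["surface"][:, :5].all()
        assert not out.masks["surface"][:, 6:].any()

    def test_manual_override_deepens(self):
        g = flat_grid()
        out = exclude_surface(g, 0.2, c=1480.0,
                              manual_depth=np.full(g.n_pings, 10.0))
        assert out.masks["surface"][:, :10].all()


class TestBottomExclusion:
    def test_planted_seabed(self):
        g = flat_grid(sv_db=-70.0, n_bins=210)
        g.sv[:, 200:] = -20.0  # echo from 200 m down
        out, bottom = detect_and_exclude_bottom(g, threshold_db=-35.0)
        np.testing.assert_allclose(bottom, 200.0)
        # dead zone: every bin containing depths >= 198.5 m is masked
        assert out.masks["bottom"][:, 198:].all()  # bin [198,199) holds 198.5
        assert not out.masks["bottom"][:, :198].any()

    def test_no_bottom_no_masking(self):
        g = flat_grid(sv_db=-70.0)
        out, bottom = detect_and_exclude_bottom(g)
        assert np.isnan(bottom).all()
        assert not out.masks["bottom"].any()

    def test_manual_override(self):
        g = flat_grid(sv_db=-70.0, n_bins=210)
        manual = np.full(g.n_pings, np.nan)
        manual[0] = 100.0
        out, bottom = detect_and_exclude_bottom(g, manual_bottom=manual)
        assert bottom[0] == 100.0
        assert out.masks["bottom"][0, 99:].all()


# ---------------------------------------------------------------------------
# noise removal


class TestBackgroundNoise:
    def grid_with_noise(self, n0=-125.0, signal=None):
        g = flat_grid(n_pings=60, n_bins=100, alpha=0.01)
        r = g.depth_centers
        sv_noise = n0 + 20 * np.log10(r) + 2 * g.alpha_db_per_m * r
        lin = _lin(np.tile(sv_noise, (g.n_pings, 1)))
        if signal is not None:
            lin = lin + _lin(np.full_like(lin, signal))
        g.sv = _db(lin)
        return g

    def test_pure_noise_estimate_and_masking(self):
        g = self.grid_with_noise(n0=-125.0)
        out, est = remove_background_noise(g, block_pings=20)
        assert np.nanmax(np.abs(est.noise_db - (-125.0))) < 1.0
        assert out.masks["noise"].mean() >= 0.99

    def test_signal_recovered_exactly_under_additive_model(self):
        g = self.grid_with_noise(n0=-125.0, signal=-60.0)
        out, _ = remove_background_noise(g, block_pings=20)
        keep = ~out.mask
        assert keep.any()
        # noise is 30+ dB down at depth; subtraction restores the signal
        deep = g.depth_centers > 3.0
        assert np.nanmax(np.abs(out.sv[:, deep] - (-60.0))) < 0.01

    def test_cell_larger_than_grid_rejected(self):
        g = flat_grid()
        with pytest.raises(ValueError):
            remove_background_noise(g, block_pings=1000)


class TestImpulseNoise:
    def test_single_elevated_ping_restored(self):
        g = flat_grid(sv_db=-70.0)
        g.sv[10] += 20.0
        out = remove_impulse_noise(g, context_pings=1, threshold_db=10.0)
        np.testing.assert_allclose(out.sv[10], -70.0, atol=0.1)

    def test_flat_field_untouched(self):
        g = flat_grid(sv_db=-70.0)
        out = remove_impulse_noise(g)
        np.testing.assert_allclose(out.sv, g.sv)

    def test_adjacent_pair_survives_context_one(self):
        """Both-sides rule: adjacent contaminated pings defeat context 1."""
        g = flat_grid(sv_db=-70.0)
        g.sv[10] += 20.0
        g.sv[11] += 20.0
        out = remove_impulse_noise(g, context_pings=1)

        # brute-force oracle over the flag rule on the smoothed field
        sm = _db(np.apply_along_axis(
            lambda row: np.convolve(np.pad(_lin(row), 2, mode="edge"),
                                    np.ones(5) / 5, mode="valid"),
            1, g.sv))
        flags = np.zeros(g.sv.shape, dtype=bool)
        for p in range(1, g.n_pings - 1):
            flags[p] = ((sm[p] - sm[p - 1] > 10.0)
                        & (sm[p] - sm[p + 1] > 10.0))
        assert not flags[10].any() and not flags[11].any()
        np.testing.assert_allclose(out.sv[10], g.sv[10])
        np.testing.assert_allclose(out.sv[11], g.sv[11])

    def test_context_exceeding_pings_rejected(self):
        g = flat_grid(n_pings=5)
        with pytest.raises(ValueError):
            remove_impulse_noise(g, context_pings=5)


# ---------------------------------------------------------------------------
# resampling, smoothing, threshold


class TestResample:
    def make_pair(self, offset=0.0, freq=120.0):
        ref = flat_grid(sv_db=-70.0, freq=38.0)
        other = flat_grid(sv_db=-65.0, freq=freq)
        other.time_s = other.time_s + offset
        return ref, other

    def test_identical_clocks_identity(self):
        ref, other = self.make_pair(0.0)
        out = resample_to_reference([ref, other], 38.0)
        o = next(g for g in out if g.freq_khz == 120.0)
        inner = slice(1, -1)  # edge bins lack bracketing centers
        np.testing.assert_allclose(o.sv[:, inner], -65.0, atol=1e-9)
        assert not o.mask[:, inner].any()

    def test_small_offset_matches_all_pings(self):
        ref, other = self.make_pair(0.4)
        out = resample_to_reference([ref, other], 38.0, tolerance_s=2.0)
        o = next(g for g in out if g.freq_khz == 120.0)
        assert not o.mask[:, 1:-1].any()

    def test_gap_masks_columns(self):
        ref, other = self.make_pair(0.0)
        keep = np.abs(other.time_s - 15.0) > 5.0  # 10 s hole
        other.time_s = other.time_s[keep]
        other.sv = other.sv[keep]
        other.lat, other.lon = other.lat[keep], other.lon[keep]
        other.distance_nmi = other.distance_nmi[keep]
        out = resample_to_reference([ref, other], 38.0, tolerance_s=2.0)
        o = next(g for g in out if g.freq_khz == 120.0)
        gap = np.abs(ref.time_s - 15.0) < 3.0
        assert o.mask[gap].all()

    def test_no_overlap_rejected(self):
        ref, other = self.make_pair(0.0)
        other.time_s = other.time_s + 1e6
        with pytest.raises(ValueError):
            resample_to_reference([ref, other], 38.0)


class TestSmooth:
    def test_constant_unchanged(self):
        g = flat_grid(sv_db=-70.0)
        out = smooth(g, 5, 5)
        np.testing.assert_allclose(out.sv, -70.0, atol=1e-9)

    def test_single_sample_closed_form(self):
        g = flat_grid(sv_db=-300.0)  # effectively empty water
        g.sv[15, 20] = -60.0
        out = smooth(g, 5, 5)
        assert out.sv[15, 20] == pytest.approx(10 * np.log10(1e-6 / 25),
                                               abs=0.01)

    def test_masked_neighbors_excluded_from_denominator(self):
        g = flat_grid(sv_db=-70.0)
        g.masks["x"] = np.zeros(g.sv.shape, dtype=bool)
        g.masks["x"][14:17, 19:22] = True
        g.sv[14:17, 19:22] = 0.0  # junk under the mask must not leak
        out = smooth(g, 5, 5)
        assert out.sv[12, 20] == pytest.approx(-70.0, abs=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            smooth(flat_grid(), 4, 5)

    def test_db_domain_averaging_would_differ(self):
        """Linear-domain averaging is required; dB-domain gives another answer."""
        g = flat_grid(sv_db=-80.0)
        g.sv[15, 20] = -60.0
        out = smooth(g, 5, 5)
        db_mean = (24 * -80.0 + -60.0) / 25  # the (wrong) dB-domain mean
        assert abs(out.sv[15, 20] - db_mean) > 1.0


class TestThresholdAndOrder:
    def test_boundary_retained(self):
        g = flat_grid(sv_db=-80.0)
        out = apply_sv_threshold(g, -80.0)
        assert not out.masks["below-threshold"].any()

    def test_all_below_masked(self):
        g = flat_grid(sv_db=-90.0)
        out = apply_sv_threshold(g, -80.0)
        assert out.masks["below-threshold"].all()

    def test_surviving_count_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        g = flat_grid()
        g.sv = rng.uniform(-100.0, -60.0, g.sv.shape)
        out = apply_sv_threshold(g, -80.0)
        assert (~out.masks["below-threshold"]).sum() == (g.sv >= -80.0).sum()

    def test_reordering_raises(self):
        g = flat_grid(n_pings=40, n_bins=40)
        g2 = smooth(g, 5, 5)
        with pytest.raises(PipelineOrderError):
            remove_background_noise(g2, block_pings=10)

    def test_masks_are_monotone_through_pipeline(self, default_scene):
        """No cleaning stage ever unmasks a sample."""
        cfg, grids, _, _ = default_scene
        pc = fs.PipelineConfig(seed=7)
        aligned = resample_to_reference(list(grids.values()), 38.0)
        g = aligned[1]
        masked = g.mask.copy()
        g = exclude_surface(g, 0.35)
        assert (g.mask & masked).sum() == masked.sum(); masked = g.mask.copy()
        g, _ = detect_and_exclude_bottom(g)
        assert (g.mask & masked).sum() == masked.sum(); masked = g.mask.copy()
        g, _ = remove_background_noise(g)
        assert (g.mask & masked).sum() == masked.sum(); masked = g.mask.copy()
        g = remove_impulse_noise(g)
        g = smooth(g)
        g = apply_sv_threshold(g)
        assert (g.mask & masked).sum() == masked.sum()


# ---------------------------------------------------------------------------
# MVBS


class TestMvbs:
    def test_uniform_field(self):
        g = flat_grid(sv_db=-70.0)
        m = compute_mvbs(g, 5.0, 0.05)
        assert np.nanmax(np.abs(m.mvbs - (-70.0))) < 1e-9

    def test_mixed_cell_closed_form(self):
        g = flat_grid(sv_db=-70.0, n_pings=10, n_bins=10)
        g.sv[:, :5] = -60.0
        m = compute_mvbs(g, 10.0, 1.0)  # one cell
        expected = 10 * np.log10((1e-6 + 1e-7) / 2)
        assert m.mvbs[0, 0] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-62.60, abs=0.01)

    def test_fully_masked_cell_undefined(self):
        g = flat_grid(sv_db=-70.0, n_pings=10, n_bins=10)
        g.masks["x"] = np.ones(g.sv.shape, dtype=bool)
        m = compute_mvbs(g, 10.0, 1.0)
        assert np.isnan(m.mvbs).all()
        assert (m.valid_frac == 0).all()

    def test_trailing_partial_cell_flagged(self):
        g = flat_grid(n_pings=25)  # 0.24 nmi at 0.01 spacing
        m = compute_mvbs(g, 40.0, 0.1)
        assert m.partial[-1]

    def test_bad_cell_dims_rejected(self):
        with pytest.raises(ValueError):
            compute_mvbs(flat_grid(), -1.0, 0.1)
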