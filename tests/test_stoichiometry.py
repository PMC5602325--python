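"""Calibration, photobleach correction, periodicity, pool deconvolution."""

import numpy as np
import pytest

from slimcluster.segmentation import segment_compartment, smooth_boundary
from slimcluster.stoichiometry import (
    Calibration,
    ExcludedTrackError,
    autofluorescence_correct,
    copro_pool_counts,
    estimate_single_brightness,
    fit_bleach_constant,
    kde,
    periodicity,
    PoolBoundInputs,
    pool_stoichiometry_bound,
    track_stoichiometry,
)
from slimcluster.synthdata import (
    SimParams,
    generate_bleach_traces,
    generate_cell_stack,
    generate_stoichiometries,
)


class TestSingleBrightness:
    def test_recovers_unit_brightness_from_mixed_traces(self):
        pooled = np.concatenate([
            generate_bleach_traces(60, S, I_GFP=5000, t_b_ms=40,
                                   noise_cv=0.08, seed=S)[0].ravel()
            for S in (1, 2, 3, 4)])
        est = estimate_single_brightness(pooled)
        assert est == pytest.approx(5000, rel=0.10)

    def test_noiseless_single_step_trace(self):
        traces, _ = generate_bleach_traces(60, 1, I_GFP=5000, seed=0)
        est = estimate_single_brightness(traces.ravel())
        assert est == pytest.approx(5000, rel=0.02)

    def test_in_vivo_like_noise_across_seeds(self):
        errs = []
        for seed in range(25):
            pooled = np.concatenate([
                generate_bleach_traces(30, S, I_GFP=5000, t_b_ms=40,
                                       noise_cv=0.12, seed=1000 * seed + S)[0]
                .ravel() for S in (1, 2, 3)])
            errs.append(abs(estimate_single_brightness(pooled) - 5000) / 5000)
        assert np.median(errs) <= 0.15

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            estimate_single_brightness(np.full(10, 5000.0))


class TestBleachConstant:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.arange(0, 200, 5.0)
        assert fit_bleach_constant(3e4 * np.exp(-t / 40.0), t) == \
            pytest.approx(40.0, rel=1e-6)

    def test_recovery_from_stochastic_traces(self):
        traces, times = generate_bleach_traces(300, 3, t_b_ms=40,
                                               noise_cv=0.05, seed=3)
        assert fit_bleach_constant(traces, times) == pytest.approx(40.0,
                                                                   rel=0.10)

    def test_constant_trace_rejected(self):
        t = np.arange(0, 100, 5.0)
        with pytest.raises(ValueError):
            fit_bleach_constant(np.full_like(t, 1000.0), t)


class TestTrackStoichiometry:
    def test_constant_unbleached_track(self):
        calib = Calibration(I_GFP=5000, t_b_ms=40)
        t = np.zeros(5)
        s = track_stoichiometry((t, np.full(5, 7 * 5000.0)), calib)
        assert s == pytest.approx(7.0)

    def test_bleach_correction_is_exact_inverse(self):
        calib = Calibration(I_GFP=5000, t_b_ms=40)
        t = np.arange(0, 50, 5.0)
        trace = 7 * 5000 * np.exp(-t / 40.0)
        corrected = trace * np.exp(t / 40.0)
        assert np.allclose(corrected, 7 * 5000)
        assert track_stoichiometry((t, trace), calib) == pytest.approx(7.0)

    def test_recovery_from_stepwise_traces(self):
        calib = Calibration(I_GFP=5000, t_b_ms=40)
        est = []
        for seed in range(50):
            traces, times = generate_bleach_traces(
                1, 7, I_GFP=5000, t_b_ms=40, noise_cv=0.05,
                n_frames=10, seed=seed)
            est.append(track_stoichiometry((times, traces[0]), calib))
        assert np.mean(est) == pytest.approx(7.0, abs=1.0)

    def test_late_track_excluded_with_reason(self):
        calib = Calibration()
        t = 100 * 5.0 + np.arange(5) * 5.0  # starts at frame 100
        with pytest.raises(ExcludedTrackError, match="frame 100"):
            track_stoichiometry((t, np.full(5, 5000.0)), calib)


class TestPeriodicity:
    @pytest.mark.parametrize("unit", [3, 5, 7, 9])
    def test_unit_recovered_with_noise(self, unit):
        values = generate_stoichiometries(400, float(unit), (1, 4),
                                          noise_sd=unit / 7.0, seed=unit)
        res = periodicity(values)
        assert res.period == pytest.approx(unit, abs=0.5)

    def test_exact_multiples_of_three(self):
        values = generate_stoichiometries(200, 3.0, (1, 5), noise_sd=0.0,
                                          seed=1)
        res = periodicity(values)
        assert res.period == pytest.approx(3.0, abs=0.3)

    def test_uniform_values_have_no_periodicity(self):
        hits = 0
        for seed in range(10):
            values = np.random.default_rng(seed).uniform(2, 30, 400)
            if periodicity(values).period is not None:
                hits += 1
        assert hits <= 1

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            periodicity(np.arange(10.0))


class TestAutofluorescence:
    def test_proportional_red_cancels(self):
        rng = np.random.default_rng(0)
        green = rng.uniform(100, 1000, (32, 32))
        red = green / 0.9
        assert np.allclose(autofluorescence_correct(green, red, 0.9), 0.0,
                           atol=1e-9)

    def test_zero_factor_is_identity(self):
        green = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(autofluorescence_correct(green, green, 0.0),
                              green)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            autofluorescence_correct(np.zeros((4, 4)), np.zeros((5, 4)))


@pytest.fixture(scope="module")
def segmented_cell():
    """Segmented boundaries from one simulated two-channel cell."""
    params = SimParams(seed=42)
    green, _ = generate_cell_stack(params, {"cytoplasm": 500}, [],
                                   n_frames=1, seed=42)
    red, _ = generate_cell_stack(params, {"nucleus": 400}, [],
                                 n_frames=1, seed=43)
    cell = smooth_boundary(segment_compartment(green.frames[0], 0.3).points)
    nuc = smooth_boundary(
        segment_compartment(red.frames[0], 0.3, "nucleus").points,
        compartment="nucleus")
    return params, cell, nuc


class TestCoPro:
    def test_pool_recovery_within_ten_percent(self, circle_boundary):
        params = SimParams(seed=7)
        stack, _ = generate_cell_stack(params,
                                       {"cytoplasm": 500, "nucleus": 100},
                                       [], n_frames=1, seed=7)
        center = tuple((np.array(stack.shape)[::-1] - 1) / 2)
        cell = circle_boundary(params.cell_radius_px, center, "cell")
        nuc = circle_boundary(params.nucleus_radius_px, center, "nucleus")
        n_nuc, n_cyt = copro_pool_counts(stack.frames[0], cell, nuc,
                                         Calibration(), params.psf_sigma_px)
        assert n_nuc == pytest.approx(100, rel=0.10)
        assert n_cyt == pytest.approx(500, rel=0.10)

    def test_zero_image_gives_zero_pools(self, segmented_cell):
        params, cell, nuc = segmented_cell
        zero = np.zeros((int(2 * cell.radius(0.0)) + 40,) * 2)
        n_nuc, n_cyt = copro_pool_counts(zero, cell, nuc, Calibration(),
                                         params.psf_sigma_px)
        assert n_nuc == pytest.approx(0.0, abs=1e-6)
        assert n_cyt == pytest.approx(0.0, abs=1e-6)

    def test_nuclear_only_pool(self, segmented_cell):
        params, cell, nuc = segmented_cell
        stack, _ = generate_cell_stack(params, {"nucleus": 200}, [],
                                       n_frames=1, seed=8)
        n_nuc, n_cyt = copro_pool_counts(stack.frames[0], cell, nuc,
                                         Calibration(), params.psf_sigma_px)
        assert n_nuc == pytest.approx(200, rel=0.12)
        assert n_cyt <= 20

    def test_linearity_noise_free(self, segmented_cell):
        from slimcluster.synthdata import NoiseParams

        params, cell, nuc = segmented_cell
        quiet = params.replace(noise=NoiseParams.off())
        a, _ = generate_cell_stack(quiet, {"cytoplasm": 100, "nucleus": 50},
                                   [], n_frames=1, seed=1)
        b, _ = generate_cell_stack(quiet, {"cytoplasm": 200, "nucleus": 100},
                                   [], n_frames=1, seed=1)
        ra = copro_pool_counts(a.frames[0], cell, nuc, Calibration(),
                               params.psf_sigma_px)
        rb = copro_pool_counts(b.frames[0], cell, nuc, Calibration(),
                               params.psf_sigma_px)
        assert rb[0] == pytest.approx(2 * ra[0], rel=0.02)
        assert rb[1] == pytest.approx(2 * ra[1], rel=0.02)


class TestPoolBound:
    def test_blur_length_at_fast_pool_diffusion(self):
        inputs = PoolBoundInputs(n_pool=949, D=6.0, dt_ms=5.0)
        assert inputs.b == pytest.approx(346.4, abs=0.5)

    def test_printed_configuration(self):
        # n_pool=949, b=340 nm, w=230 nm, d=5 um
        inputs = PoolBoundInputs(n_pool=949, b_nm=340.0, w_nm=230.0,
                                 cell_diameter_um=5.0)
        assert pool_stoichiometry_bound(inputs) == pytest.approx(1.41,
                                                                 abs=0.01)

    def test_empty_pool_gives_zero(self):
        assert pool_stoichiometry_bound(PoolBoundInputs(n_pool=0)) == 0.0


class TestKDE:
    def test_density_integrates_to_one(self):
        d = kde(np.random.default_rng(0).normal(7, 2, 300))
        integral = np.trapezoid(d.density, d.grid)
        assert integral == pytest.approx(1.0, abs=0.02)

    def test_unimodal_peak_at_value(self):
        d = kde(5.0 + 0.01 * np.random.default_rng(1).normal(size=100))
        assert d.mode == pytest.approx(5.0, abs=0.05)

    def test_bimodal_sample_recovers_two_peaks(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(3, 0.4, 300),
                               rng.normal(10, 0.4, 300)])
        d = kde(vals)
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(d.density,
                              height=0.2 * d.density.max())
        locs = np.sort(d.grid[peaks])
        assert len(locs) == 2
        assert locs[0] == pytest.approx(3.0, abs=0.5)
        assert locs[1] == pytest.approx(10.0, abs=0.5)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            kde([])
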