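"""Generators: photon accounting, distributional correctness, determinism."""

import numpy as np
import pytest
from scipy import stats

from slimcluster.synthdata import (
    FocusSpec,
    NoiseParams,
    SimParams,
    generate_bleach_traces,
    generate_cell_stack,
    generate_displacements,
    generate_frap_curve,
    generate_stoichiometries,
    generate_toy_genome,
)


class TestCellStack:
    def test_single_fluorophore_integrates_to_single_brightness(self, quiet_params):
        stack, _ = generate_cell_stack(
            quiet_params, None, [FocusSpec(1, 0.0, "nucleus")], n_frames=1)
        total = stack.frames[0].sum()
        assert total == pytest.approx(quiet_params.single_brightness, rel=1e-3)

    def test_spot_brightness_linear_in_stoichiometry(self, quiet_params):
        stack, _ = generate_cell_stack(
            quiet_params, None, [FocusSpec(7, 0.0, "nucleus")], n_frames=1)
        assert stack.frames[0].sum() == pytest.approx(
            7 * quiet_params.single_brightness, rel=1e-3)

    def test_empty_cell_contains_only_background(self, default_params):
        stack, truth = generate_cell_stack(default_params, None, [], n_frames=3)
        assert truth.positions_px.size == 0
        # mean stays at the camera offset, fluctuations at the noise scale
        assert abs(stack.frames.mean() - default_params.noise.offset) < 3.0

    def test_photon_conservation_noise_free(self, quiet_params):
        pool = {"cytoplasm": 50, "nucleus": 20}
        stack, truth = generate_cell_stack(
            quiet_params, pool, [FocusSpec(5, 0.5, "nucleus")],
            n_frames=6, seed=4)
        for k in range(stack.n_frames):
            expected = truth.total_fluorophores(k) * quiet_params.single_brightness
            assert stack.frames[k].sum() == pytest.approx(expected, rel=0.02)

    def test_positions_stay_in_declared_compartment(self, quiet_params):
        stack, truth = generate_cell_stack(
            quiet_params, None,
            [FocusSpec(3, 2.0, "nucleus"), FocusSpec(3, 2.0, "cytoplasm")],
            n_frames=25, seed=9)
        center = (np.array(stack.shape)[::-1] - 1) / 2
        r_nuc = quiet_params.nucleus_radius_px
        r_cell = quiet_params.cell_radius_px
        r = np.hypot(*(truth.positions_px[0] - center).T)
        assert np.all(r <= r_nuc + 1e-6)  # nuclear focus stays nuclear
        r = np.hypot(*(truth.positions_px[1] - center).T)
        assert np.all(r <= r_cell + 1e-6)

    def test_invalid_compartment_rejected(self):
        with pytest.raises(ValueError, match="compartment"):
            FocusSpec(1, 0.1, "vacuole")

    def test_fixed_seed_is_bit_identical(self, default_params):
        a, _ = generate_cell_stack(default_params, {"cytoplasm": 100},
                                   [FocusSpec(2, 1.0, "cytoplasm")],
                                   n_frames=3, seed=7)
        b, _ = generate_cell_stack(default_params, {"cytoplasm": 100},
                                   [FocusSpec(2, 1.0, "cytoplasm")],
                                   n_frames=3, seed=7)
        assert np.array_equal(a.frames, b.frames)


class TestDisplacements:
    def test_single_component_mean_matches_brownian_moment(self):
        r2 = generate_displacements(20_000, [(1.0, 1.0)], dt_ms=5.0,
                                    sigma_nm=0.0, seed=0)
        assert r2.mean() == pytest.approx(4 * 1.0 * 0.005, rel=0.03)

    def test_immobile_noiseless_gives_zero(self):
        r2 = generate_displacements(100, [(1.0, 0.0)], sigma_nm=0.0, seed=0)
        assert np.all(r2 == 0)

    def test_localization_jitter_adds_four_sigma_squared(self):
        r2 = generate_displacements(40_000, [(1.0, 0.0)], dt_ms=5.0,
                                    sigma_nm=40.0, seed=1)
        assert r2.mean() == pytest.approx(4 * 0.04**2, rel=0.03)

    def test_mixture_matches_analytic_cdf(self):
        mixture = [(0.2, 0.15), (0.8, 1.5)]
        dt_s = 0.005
        r2 = generate_displacements(30_000, mixture, dt_ms=5.0, sigma_nm=0.0,
                                    seed=2)

        def cdf(x):
            return sum(a * (1 - np.exp(-x / (4 * d * dt_s)))
                       for a, d in mixture)

        ks = stats.kstest(r2, cdf).statistic
        assert ks < 0.01

    def test_negative_d_rejected(self):
        with pytest.raises(ValueError):
            generate_displacements(10, [(1.0, -0.5)])

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_displacements(10, [(0.5, 1.0), (0.4, 0.1)])


class TestBleachTraces:
    def test_single_fluorophore_is_one_step(self):
        traces, _ = generate_bleach_traces(20, 1, I_GFP=5000, seed=0)
        for tr in traces:
            levels = np.unique(tr)
            assert set(levels) <= {0.0, 5000.0}
            # once bleached it stays dark
            dark = np.nonzero(tr == 0)[0]
            if dark.size:
                assert np.all(tr[dark[0]:] == 0)

    def test_ensemble_mean_decays_exponentially(self):
        traces, times = generate_bleach_traces(3000, 4, I_GFP=5000,
                                               t_b_ms=40, seed=1)
        expected = 4 * 5000 * np.exp(-times / 40)
        sel = times <= 120
        assert np.allclose(traces.mean(axis=0)[sel], expected[sel], rtol=0.06)

    def test_pairwise_differences_cluster_at_brightness_multiples(self):
        traces, _ = generate_bleach_traces(30, 3, I_GFP=5000, seed=2)
        vals = traces[traces > 0]
        diffs = np.abs(vals[:, None] - vals[None, :]).ravel()
        assert np.all(np.isclose(diffs % 5000, 0) | np.isclose(diffs % 5000, 5000))

    def test_negative_noise_cv_rejected(self):
        with pytest.raises(ValueError):
            generate_bleach_traces(5, 2, noise_cv=-0.1)


class TestFrapCurve:
    @pytest.mark.parametrize("t, expected", [
        (1e6, 10.0),                      # saturation
        (0.0, 0.0),                       # bleach instant
        (133.0, 10.0 * (1 - np.exp(-1))),  # one time constant
    ])
    def test_noise_free_closed_form(self, t, expected):
        c = generate_frap_curve(10.0, 133.0, [t], noise_sd=0.0)
        assert c[0] == pytest.approx(expected, abs=1e-9)

    def test_empty_timepoints_rejected(self):
        with pytest.raises(ValueError):
            generate_frap_curve(10.0, 133.0, [])


class TestStoichiometrySample:
    def test_noise_free_values_are_exact_multiples(self):
        v = generate_stoichiometries(200, 7.0, (1, 2), noise_sd=0.0, seed=0)
        assert set(np.unique(v)) <= {7.0, 14.0}

    def test_pairwise_differences_are_unit_multiples(self):
        v = generate_stoichiometries(50, 5.0, (1, 4), noise_sd=0.0, seed=1)
        diffs = np.abs(v[:, None] - v[None, :])
        assert np.allclose(diffs % 5.0, 0.0)

    def test_empty_request(self):
        assert generate_stoichiometries(0, 7.0).size == 0


class TestToyGenome:
    def test_planted_sites_are_recovered_and_confined(self, toy_genome_mapped):
        genome, sites = toy_genome_mapped
        planted = set(zip(genome.sites.chrom, genome.sites.start,
                          genome.sites.strand))
        found = {(s.chrom, s.start, s.strand) for s in sites}
        assert planted <= found
        radii = np.linalg.norm([s.position_nm for s in sites], axis=1)
        assert np.all(radii <= 1000.0 + 1e-6)  # nuclear radius, nm

    def test_promoter_flags_match_plant(self, toy_genome_mapped):
        genome, sites = toy_genome_mapped
        planted_prom = {(r.chrom, r.start) for r in genome.sites.itertuples()
                        if r.in_promoter}
        found_prom = {(s.chrom, s.start) for s in sites if s.in_promoter}
        assert planted_prom <= found_prom

    def test_zero_sites_scan_clean_pattern(self):
        from slimcluster.genomemodel import scan_sites

        genome = generate_toy_genome(n_chrom=1, lengths=(4000,), n_sites=0,
                                     planted_pattern="ACGTACGTACGTACGTA",
                                     seed=5)
        assert len(genome.sites) == 0
        found = scan_sites(genome.sequences, genome.pattern)
        # a 17-mer essentially never occurs by chance in 4 kb
        assert len(found) == 0

    def test_invalid_iupac_pattern_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            generate_toy_genome(planted_pattern="ACGTX")

    def test_overfull_genome_rejected(self):
        with pytest.raises(ValueError, match="capacity"):
            generate_toy_genome(n_chrom=1, lengths=(2000,), n_sites=500,
                                seed=0)

    def test_determinism(self):
        a = generate_toy_genome(n_chrom=1, lengths=(5000,), n_sites=4, seed=3)
        b = generate_toy_genome(n_chrom=1, lengths=(5000,), n_sites=4, seed=3)
        assert a.sequences == b.sequences
        assert a.coords.equals(b.coords)


def test_noise_model_adds_offset_and_shot_noise():
    rng = np.random.default_rng(0)
    noise = NoiseParams(read_sd=0.0, shot=True, offset=100.0)
    out = noise.apply(np.full(20_000, 400.0), rng)
    assert out.mean() == pytest.approx(500.0, abs=1.0)
    assert out.std() == pytest.approx(20.0, rel=0.05)  # sqrt(400)
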