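"""Site scanning, binding models, rendering and model comparison."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slimcluster.core import IUPAC_CODES
from slimcluster.genomemodel import (
    BindingModelSpec,
    charge_profile,
    assign_binding,
    combine_configurations,
    compare_model,
    map_sites_to_3d,
    scan_sites,
    simulate_nuclear_image,
    site_nn_distances,
    BindingSite,
)
from slimcluster.synthdata import NoiseParams, SimParams


def brute_force_scan(seq: str, pattern: str):
    """Position-by-position IUPAC matcher (oracle)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    inv = {"".join(sorted(v)): k for k, v in IUPAC_CODES.items()}
    hits = set()
    plen = len(pattern)
    for strand in "+-":
        if strand == "+":
            pat = pattern
        else:  # complement each symbol's base set, then reverse
            pat = "".join(inv["".join(sorted(comp[b] for b in IUPAC_CODES[c]))]
                          for c in reversed(pattern))
        for i in range(len(seq) - plen + 1):
            if all(seq[i + j] in IUPAC_CODES[pat[j]] for j in range(plen)):
                hits.add((i + 1, strand))
    return hits


class TestScanSites:
    @settings(max_examples=40, deadline=None)
    @given(seq=st.text(alphabet="ACGT", min_size=30, max_size=300),
           pattern=st.text(alphabet="ACGTRYSWKMN", min_size=3, max_size=8))
    def test_matches_brute_force_oracle(self, seq, pattern):
        found = {(s.start, s.strand)
                 for s in scan_sites({"c": seq}, pattern)}
        assert found == brute_force_scan(seq, pattern)

    def test_planted_sites_all_found(self, toy_genome_mapped):
        genome, sites = toy_genome_mapped
        planted = set(zip(genome.sites.chrom, genome.sites.start,
                          genome.sites.strand))
        found = {(s.chrom, s.start, s.strand) for s in sites}
        assert planted <= found

    def test_absent_pattern_gives_empty_list(self):
        assert scan_sites({"c": "ACGT" * 50}, "TTTTTTTTTT") == []

    def test_palindrome_reported_once_per_strand_position(self):
        # GAATTC is its own reverse complement
        seq = "TTTTGAATTCTTTT"
        sites = scan_sites({"c": seq}, "GAATTC")
        assert {(s.start, s.strand) for s in sites} == {(5, "+"), (5, "-")}

    def test_invalid_symbol_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_sites({"c": "ACGT"}, "ACXG")

    def test_promoter_flag_respects_strand(self):
        ann = pd.DataFrame([
            {"chrom": "c", "start": 600, "end": 900, "strand": "+",
             "gene_id": "g1"},
        ])
        seq = ["A"] * 1000
        seq[299:302] = list("GGG")   # at 300, inside [100, 599] upstream
        seq[949:952] = list("GGG")   # inside the gene, not promoter
        sites = scan_sites({"c": "".join(seq)}, "GGG", ann)
        flags = {s.start: s.in_promoter for s in sites if s.strand == "+"}
        assert flags[300] is True
        assert flags[950] is False


class TestAssignBinding:
    def test_cluster_placement_counts(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        cfg = assign_binding(sites, BindingModelSpec(
            model="dna_cluster", total_molecules=190, cluster_unit=7), seed=0)
        assert len(cfg.molecules) == 27           # floor(190 / 7)
        assert np.all(cfg.molecules == 7)
        assert cfg.total_molecules == 189         # remainder dropped

    def test_ne_cluster_placement_counts(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        cfg = assign_binding(sites, BindingModelSpec(
            model="ne_cluster", ne_molecules=130, cluster_unit=7), seed=0)
        assert len(cfg.molecules) == 18           # floor(130 / 7)
        radii = np.linalg.norm(cfg.positions_nm, axis=1)
        assert np.allclose(radii, 1000.0)         # on the envelope sphere

    def test_unit_one_cluster_equals_monomer_counts(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        n_prom = sum(s.in_promoter for s in sites)
        total = min(40, n_prom)
        cl = assign_binding(sites, BindingModelSpec(
            model="dna_cluster", total_molecules=total, cluster_unit=1),
            seed=1)
        assert len(cl.molecules) == total
        assert np.all(cl.molecules == 1)

    def test_molecule_conservation_monomer(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        cfg = assign_binding(sites, BindingModelSpec(
            model="monomer", total_molecules=80), seed=2)
        assert cfg.total_molecules == 80

    def test_insufficient_molecules_rejected(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        with pytest.raises(ValueError):
            assign_binding(sites, BindingModelSpec(
                model="dna_cluster", total_molecules=3, cluster_unit=7))

    def test_mixture_draws_both_models(self, toy_genome_mapped):
        _, sites = toy_genome_mapped
        spec = BindingModelSpec(model="mixture", total_molecules=70,
                                ne_molecules=70)
        models = {assign_binding(sites, spec, seed=s).model
                  for s in range(30)}
        assert models == {"ne_cluster", "dna_cluster"}


class TestRendering:
    def test_single_cluster_integrates_to_unit_times_brightness(self):
        from slimcluster.genomemodel import BindingConfiguration

        params = SimParams(noise=NoiseParams.off())
        cfg = BindingConfiguration(np.array([[0.0, 0.0, 0.0]]),
                                   np.array([7]), "dna_cluster")
        frame = simulate_nuclear_image(cfg, params, rotation="identity")
        assert frame.sum() == pytest.approx(7 * params.single_brightness,
                                            rel=1e-3)

    def test_empty_configuration_is_background_only(self):
        from slimcluster.genomemodel import BindingConfiguration

        params = SimParams(noise=NoiseParams.off(offset=50.0))
        cfg = BindingConfiguration(np.empty((0, 3)), np.empty(0, dtype=int),
                                   "monomer")
        frame = simulate_nuclear_image(cfg, params)
        assert np.all(frame == 50.0)

    def test_two_near_placements_detected_as_one_focus(self):
        from slimcluster.genomemodel import BindingConfiguration
        from slimcluster.tracking import DetectionParams, detect_foci

        params = SimParams(seed=0)
        cfg = BindingConfiguration(
            np.array([[0.0, 0.0, 0.0], [100.0, 0.0, 0.0]]),
            np.array([7, 7]), "dna_cluster")
        frame = simulate_nuclear_image(cfg, params, rotation="identity",
                                       seed=1)
        foci = detect_foci(frame, DetectionParams())
        assert len(foci) == 1
        assert foci[0].intensity / params.single_brightness == \
            pytest.approx(14, rel=0.15)


class TestCompareModel:
    def test_sample_against_itself_scores_one(self):
        rng = np.random.default_rng(0)
        sample = rng.normal(7, 2, 200)
        assert compare_model(sample, sample).r_squared == pytest.approx(1.0)

    def test_disjoint_distributions_score_negative(self):
        rng = np.random.default_rng(1)
        a = rng.normal(5, 0.5, 100)
        b = rng.normal(50, 0.5, 100)
        assert compare_model(a, b).r_squared < 0

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_model(np.random.default_rng(0).normal(size=50),
                          np.full(50, 7.0))


class TestChargeProfile:
    def test_poly_lysine_is_plus_one(self):
        assert np.allclose(charge_profile("K" * 100, window=75), 1.0)

    def test_poly_aspartate_is_minus_one(self):
        assert np.allclose(charge_profile("D" * 100, window=75), -1.0)

    def test_dkh_window_three(self):
        prof = charge_profile("DKH" * 10, window=3)
        assert np.allclose(prof, 0.5 / 3)

    def test_non_residue_rejected(self):
        with pytest.raises(ValueError):
            charge_profile("ACDB" * 30, window=10)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            charge_profile("ACDE", window=75)


class TestNNDistances:
    def test_two_sites_mutual_nearest(self):
        sites = [
            BindingSite("c1", 1, "+", True, np.array([0.0, 0.0, 0.0])),
            BindingSite("c1", 50, "+", True, np.array([10.0, 0.0, 0.0])),
        ]
        df = site_nn_distances(sites)
        assert np.allclose(df["nn_nm"], 10.0)

    def test_grid_distances_match_construction(self):
        sites = []
        for i in range(4):
            for j in range(4):
                sites.append(BindingSite("c1", 10 * (4 * i + j + 1), "+",
                                         True,
                                         np.array([30.0 * i, 30.0 * j, 0.0])))
        df = site_nn_distances(sites, threshold_nm=50.0)
        assert np.allclose(df["nn_nm"], 30.0)
        assert df.attrs["fraction_below"] == 1.0

    def test_single_chromosome_has_no_different_chromosome_set(self):
        sites = [
            BindingSite("c1", 1, "+", True, np.array([0.0, 0.0, 0.0])),
            BindingSite("c1", 30, "+", True, np.array([40.0, 0.0, 0.0])),
        ]
        df = site_nn_distances(sites)
        assert df["nn_diff_chrom_nm"].isna().all()
        assert np.allclose(df["nn_same_chrom_nm"], 40.0)


def test_combined_configuration_conserves_molecules(toy_genome_mapped):
    _, sites = toy_genome_mapped
    dna = assign_binding(sites, BindingModelSpec(
        model="dna_cluster", total_molecules=21, cluster_unit=7), seed=0)
    ne = assign_binding(sites, BindingModelSpec(
        model="ne_cluster", ne_molecules=14, cluster_unit=7), seed=0)
    both = combine_configurations(dna, ne)
    assert both.total_molecules == 21 + 14
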