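"""Shared fixtures: small simulated inputs generated at test time."""

import numpy as np
import pytest

from slimcluster.segmentation import smooth_boundary
from slimcluster.synthdata import NoiseParams, SimParams


@pytest.fixture()
def quiet_params():
    """Noise-free imaging parameters (no offset) for exact checks."""
    return SimParams(noise=NoiseParams.off(), seed=0)


@pytest.fixture()
def default_params():
    """Default imaging parameters with realistic camera noise."""
    return SimParams(seed=0)


def circle_points(radius_px, center=(0.0, 0.0), n=200, noise_sd=0.0, seed=0):
    rng = np.random.default_rng(seed)
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius_px + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
    return np.stack([center[0] + r * np.cos(th),
                     center[1] + r * np.sin(th)], axis=1)


@pytest.fixture()
def circle_boundary():
    """Factory for an exact circular boundary spline."""
    def make(radius_px, center=(0.0, 0.0), compartment="nucleus"):
        return smooth_boundary(circle_points(radius_px, center), p=1.0,
                               compartment=compartment)
    return make


@pytest.fixture(scope="session")
def toy_genome_mapped():
    """A toy genome with scanned, 3D-mapped sites (session-scoped; the
    polymer build is the slow part)."""
    from slimcluster.genomemodel import map_sites_to_3d, scan_sites
    from slimcluster.synthdata import generate_toy_genome

    genome = generate_toy_genome(
        n_chrom=3, lengths=(40_000, 40_000, 40_000), n_sites=120,
        promoter_fraction=0.5, genes_per_kb=0.4, seed=1)
    sites = scan_sites(genome.sequences, genome.pattern, genome.annotation)
    map_sites_to_3d(sites, genome.coords)
    return genome, sites
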