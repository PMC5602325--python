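"""Binding-site scanning and monomer-versus-cluster binding models.

A genome is scanned on both strands for an IUPAC target pattern; matches
falling within 500 bp upstream of an annotated gene start are flagged as
promoter sites.  Sites are mapped onto 3D coordinates from a chromosome
model, molecules are placed under monomer / DNA-cluster / nuclear-envelope
model variants (or per-cell mixtures), nuclear images are rendered from
random projections with realistic signal and noise, and simulated versus
reference stoichiometry distributions are compared by R-squared between
their KDEs.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slimcluster.core import IUPAC_CODES, iupac_regex, rng_from_seed

logger = logging.getLogger(__name__)

NM_PER_UM = 1000.0
PROMOTER_BP = 500

BINDING_MODELS = ("monomer", "dna_cluster", "ne_monomer", "ne_cluster",
                  "mixture")


@dataclass
class BindingSite:
    """One pattern match: chromosome, 1-based inclusive start, strand,
    promoter flag, and (when mapped) 3D position in nm."""

    chrom: str
    start: int
    strand: str
    in_promoter: bool = False
    position_nm: np.ndarray | None = None


@dataclass
class BindingModelSpec:
    """Specification of a nuclear binding model.

    model : one of monomer, dna_cluster, ne_monomer, ne_cluster, mixture.
    cluster_unit : molecules per cluster (7 by default).
    total_molecules : molecules associated with nuclear foci (190).
    ne_molecules : molecules in envelope transit (130).
    mixture_weights : (ne_cluster, dna_cluster) per-cell weights for the
        mixture model (0.75 / 0.25).
    """

    model: str = "dna_cluster"
    cluster_unit: int = 7
    total_molecules: int = 190
    ne_molecules: int = 130
    mixture_weights: tuple[float, float] = (0.75, 0.25)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.model not in BINDING_MODELS:
            raise ValueError(f"model must be one of {BINDING_MODELS}")
        if self.cluster_unit < 1:
            raise ValueError("cluster unit must be >= 1")
        if not np.isclose(sum(self.mixture_weights), 1.0):
            raise ValueError("mixture weights must sum to 1")


@dataclass
class BindingConfiguration:
    """Molecule placements under a binding model: an (N, 3) array of
    positions (nm, nucleus-centered) and molecules per placement."""

    positions_nm: np.ndarray
    molecules: np.ndarray
    model: str

    @property
    def total_molecules(self) -> int:
        return int(self.molecules.sum())


@dataclass
class ModelComparison:
    """R-squared agreement between simulated and reference stoichiometry
    KDEs on a shared grid (1 is perfect; can be negative)."""

    r_squared: float
    grid: np.ndarray = field(repr=False, default=None)
    simulated_density: np.ndarray = field(repr=False, default=None)
    reference_density: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def scan_sites(sequences, pattern: str, annotation: pd.DataFrame | None = None,
               ) -> list[BindingSite]:
    """Find all IUPAC pattern matches on both strands of a genome.

    ``sequences`` maps chromosome name to sequence (or is a FASTA path).
    Matches are reported 1-based by the start of the match on the forward
    strand, deduplicated by (chrom, start, strand); overlapping matches are
    allowed.  With an annotation (chrom, start, end, strand, gene_id;
    1-based inclusive), sites within 500 bp upstream of a gene start on the
    matching strand are flagged as promoter sites.
    """
    from Bio.Seq import Seq

    if isinstance(sequences, (str, bytes)) or hasattr(sequences, "read"):
        from Bio import SeqIO

        sequences = {rec.id: str(rec.seq)
                     for rec in SeqIO.parse(sequences, "fasta")}

    fwd = re.compile(f"(?=({iupac_regex(pattern)}))")
    plen = len(pattern)
    seen = set()
    sites: list[BindingSite] = []
    for chrom, seq in sequences.items():
        seq = str(seq).upper()
        for m in fwd.finditer(seq):
            key = (chrom, m.start() + 1, "+")
            if key not in seen:
                seen.add(key)
                sites.append(BindingSite(chrom, m.start() + 1, "+"))
        rc = str(Seq(seq).reverse_complement())
        L = len(seq)
        for m in fwd.finditer(rc):
            start = L - (m.start() + plen) + 1  # forward-strand coordinate
            key = (chrom, start, "-")
            if key not in seen:
                seen.add(key)
                sites.append(BindingSite(chrom, start, "-"))

    if annotation is not None and len(annotation):
        windows = []
        for _, g in annotation.iterrows():
            if g.strand == "+":
                windows.append((g.chrom, g.start - PROMOTER_BP, g.start - 1,
                                "+"))
            else:
                windows.append((g.chrom, g.end + 1, g.end + PROMOTER_BP, "-"))
        for s in sites:
            end = s.start + plen - 1
            s.in_promoter = any(
                c == s.chrom and st == s.strand and s.start <= hi and end >= lo
                for c, lo, hi, st in windows)
    sites.sort(key=lambda s: (s.chrom, s.start, s.strand))
    return sites


def sites_to_frame(sites: list[BindingSite], bed: bool = False) -> pd.DataFrame:
    """Sites as a table; ``bed=True`` gives 0-based half-open coordinates."""
    rows = []
    for s in sites:
        if bed:
            rows.append({"chrom": s.chrom, "start": s.start - 1,
                         "end": s.start - 1 + 1, "strand": s.strand,
                         "in_promoter": s.in_promoter})
        else:
            rows.append({"chrom": s.chrom, "start": s.start,
                         "strand": s.strand, "in_promoter": s.in_promoter})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 3D mapping and binding-configuration assignment
# ---------------------------------------------------------------------------

def map_sites_to_3d(sites: list[BindingSite], coords: pd.DataFrame) -> None:
    """Attach 3D positions (nm) to sites by linear interpolation between the
    two nearest modeled loci on the same chromosome (in place)."""
    for s in sites:
        sub = coords[coords["chrom"] == s.chrom]
        if not len(sub):
            raise ValueError(f"no 3D model for chromosome {s.chrom}")
        bp = sub["bp"].to_numpy(float)
        xyz = sub[["x_nm", "y_nm", "z_nm"]].to_numpy(float)
        order = np.argsort(bp)
        bp, xyz = bp[order], xyz[order]
        s.position_nm = np.array([
            np.interp(s.start, bp, xyz[:, k]) for k in range(3)])


def _sphere_surface_points(n, radius_nm, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * radius_nm


def assign_binding(sites: list[BindingSite], spec: BindingModelSpec,
                   nucleus_diameter_um: float = 2.0,
                   seed=None) -> BindingConfiguration:
    """Place molecules on the genome model under a binding model.

    monomer : one molecule on every promoter site, remaining molecules on
        randomly chosen non-promoter sites.
    dna_cluster : floor(total / u) clusters of u molecules on randomly
        chosen promoter sites (remainder molecules dropped, logged).
    ne_monomer / ne_cluster : the envelope complement, placed uniformly on
        the nuclear-envelope sphere using ``ne_molecules``.
    mixture : one of (ne_cluster, dna_cluster) drawn per cell by
        ``mixture_weights``.
    """
    rng = rng_from_seed(spec.seed if seed is None else seed)
    model = spec.model
    if model == "mixture":
        model = "ne_cluster" if rng.random() < spec.mixture_weights[0] \
            else "dna_cluster"

    r_ne = nucleus_diameter_um * NM_PER_UM / 2
    if model in ("ne_monomer", "ne_cluster"):
        if model == "ne_cluster":
            if spec.ne_molecules < spec.cluster_unit:
                raise ValueError("fewer molecules than one cluster unit")
            n_cl = spec.ne_molecules // spec.cluster_unit
            dropped = spec.ne_molecules - n_cl * spec.cluster_unit
            if dropped:
                logger.info("NE cluster model drops %d remainder molecules",
                            dropped)
            pos = _sphere_surface_points(n_cl, r_ne, rng)
            mol = np.full(n_cl, spec.cluster_unit)
        else:
            pos = _sphere_surface_points(spec.ne_molecules, r_ne, rng)
            mol = np.ones(spec.ne_molecules, dtype=int)
        return BindingConfiguration(pos, mol, model)

    promoter = [s for s in sites if s.in_promoter]
    others = [s for s in sites if not s.in_promoter]
    if any(s.position_nm is None for s in sites):
        raise ValueError("sites must carry 3D positions (map_sites_to_3d)")

    if model == "monomer":
        if spec.total_molecules < len(promoter):
            chosen = list(rng.choice(len(promoter), spec.total_molecules,
                                     replace=False))
            pos = np.array([promoter[i].position_nm for i in chosen])
        else:
            n_rest = spec.total_molecules - len(promoter)
            if n_rest > len(others):
                raise ValueError("not enough non-promoter sites for the "
                                 "monomer model")
            rest_idx = rng.choice(len(others), n_rest, replace=False)
            pos = np.array([s.position_nm for s in promoter]
                           + [others[i].position_nm for i in rest_idx])
        mol = np.ones(len(pos), dtype=int)
        return BindingConfiguration(pos, mol, model)

    # dna_cluster
    if spec.total_molecules < spec.cluster_unit:
        raise ValueError("fewer molecules than one cluster unit")
    n_cl = spec.total_molecules // spec.cluster_unit
    dropped = spec.total_molecules - n_cl * spec.cluster_unit
    if dropped:
        logger.info("cluster model drops %d remainder molecules", dropped)
    if not promoter:
        raise ValueError("cluster model needs promoter sites")
    replace = n_cl > len(promoter)
    idx = rng.choice(len(promoter), n_cl, replace=replace)
    pos = np.array([promoter[i].position_nm for i in idx])
    mol = np.full(n_cl, spec.cluster_unit)
    return BindingConfiguration(pos, mol, model)


def combine_configurations(*configs: BindingConfiguration) -> BindingConfiguration:
    """Concatenate binding configurations (e.g. genome-bound plus
    nuclear-envelope components of one simulated cell)."""
    if not configs:
        raise ValueError("need at least one configuration")
    pos = np.vstack([c.positions_nm for c in configs if len(c.molecules)])
    mol = np.concatenate([c.molecules for c in configs if len(c.molecules)])
    model = "+".join(c.model for c in configs)
    return BindingConfiguration(pos, mol, model)


# ---------------------------------------------------------------------------
# rendering and comparison
# ---------------------------------------------------------------------------

def simulate_nuclear_image(configuration: BindingConfiguration, params=None,
                           rotation: np.ndarray | str = "random",
                           shape: tuple[int, int] | None = None,
                           seed=None) -> np.ndarray:
    """Render one nuclear frame from a binding configuration.

    The configuration is rotated (uniform random rotation by default, or a
    given 3x3 matrix, or ``"identity"``), projected onto the image plane,
    convolved with the Gaussian PSF and overlaid with the camera noise model.
    """
    from scipy.stats import special_ortho_group

    from slimcluster.synthdata import SimParams, _add_gaussian_spot

    if params is None:
        params = SimParams()
    rng = rng_from_seed(seed)
    if isinstance(rotation, str):
        if rotation == "identity":
            R = np.eye(3)
        elif rotation == "random":
            R = special_ortho_group.rvs(3, random_state=rng)
        else:
            raise ValueError(f"unknown rotation {rotation!r}")
    else:
        R = np.asarray(rotation, dtype=float)

    r_nuc_px = params.nucleus_radius_px
    if shape is None:
        side = int(np.ceil(2 * r_nuc_px + 8 * params.psf_sigma_px + 8))
        shape = (side, side)
    center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    frame = np.zeros(shape)
    if configuration.positions_nm.size:
        rot = configuration.positions_nm @ R.T
        for (x_nm, y_nm, _z), n in zip(rot, configuration.molecules):
            _add_gaussian_spot(frame,
                               center[0] + x_nm / params.pixel_size_nm,
                               center[1] + y_nm / params.pixel_size_nm,
                               params.psf_sigma_px,
                               n * params.single_brightness)
    return params.noise.apply(frame, rng)


def measure_model_stoichiometries(configuration_factory, n_cells: int,
                                  params=None, detection=None,
                                  calibration=None, seed=0) -> np.ndarray:
    """End-to-end stoichiometry sample from a binding model.

    For each simulated cell a fresh configuration is drawn
    (``configuration_factory(rng)``), rendered from a random projection, run
    through the same focus detector as experimental data, and the detected
    focus intensities converted to stoichiometries with the calibration.
    """
    from slimcluster.stoichiometry import Calibration
    from slimcluster.synthdata import SimParams
    from slimcluster.tracking import DetectionParams, detect_foci

    if params is None:
        params = SimParams()
    if detection is None:
        detection = DetectionParams(pixel_size_nm=params.pixel_size_nm,
                                    psf_width_nm=params.psf_sigma_nm)
    if calibration is None:
        calibration = Calibration(I_GFP=params.single_brightness,
                                  t_b_ms=params.bleach_constant_ms)
    rng = rng_from_seed(seed)
    out = []
    for _ in range(n_cells):
        config = configuration_factory(rng)
        frame = simulate_nuclear_image(config, params, rotation="random",
                                       seed=rng)
        for f in detect_foci(frame, detection):
            out.append(f.intensity / calibration.I_GFP)
    return np.asarray(out)


def compare_model(simulated, reference, grid_points: int = 256) -> ModelComparison:
    """R-squared between the KDEs of two stoichiometry samples.

    Both KDEs are evaluated on a shared grid spanning the reference sample;
    R^2 = 1 - SS_res / SS_tot about the reference KDE.
    """
    from slimcluster.stoichiometry import kde

    simulated = np.asarray(simulated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if simulated.size < 30 or reference.size < 30:
        raise ValueError("need at least 30 values in each sample")
    if reference.std() == 0:
        raise ValueError("degenerate reference sample (zero variance)")
    ref_kde = kde(reference)
    lo = min(ref_kde.grid.min(), simulated.min())
    hi = max(ref_kde.grid.max(), simulated.max())
    grid = np.linspace(lo, hi, grid_points)
    from scipy.stats import gaussian_kde

    ref_d = gaussian_kde(reference, bw_method="silverman")(grid)
    sim_d = gaussian_kde(simulated, bw_method="silverman")(grid) \
        if simulated.std() > 0 else np.zeros_like(grid)
    ss_res = np.sum((sim_d - ref_d) ** 2)
    ss_tot = np.sum((ref_d - ref_d.mean()) ** 2)
    r2 = 1 - ss_res / ss_tot
    return ModelComparison(float(r2), grid, sim_d, ref_d)


# ---------------------------------------------------------------------------
# sequence-derived descriptors
# ---------------------------------------------------------------------------

#: Residue charges for the rolling-charge profile: D/E -1, K/R +1, H +0.5.
RESIDUE_CHARGE = {"D": -1.0, "E": -1.0, "K": 1.0, "R": 1.0, "H": 0.5}

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def charge_profile(sequence: str, window: int = 75) -> np.ndarray:
    """Rolling mean electrostatic charge per residue window.

    Returns one value per full window (length ``len(sequence) - window + 1``).
    """
    seq = sequence.upper()
    bad = set(seq) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)}")
    if len(seq) < window:
        raise ValueError("sequence shorter than the window")
    charges = np.array([RESIDUE_CHARGE.get(c, 0.0) for c in seq])
    kernel = np.ones(window) / window
    return np.convolve(charges, kernel, mode="valid")


def site_nn_distances(sites: list[BindingSite],
                      threshold_nm: float = 50.0) -> pd.DataFrame:
    """Per-site 3D nearest-neighbor distances, split by chromosome.

    Returns a table with, per site, the nearest-neighbor distance overall
    and restricted to same-/different-chromosome partners; the fraction of
    sites with an NN distance below ``threshold_nm`` is stored in
    ``df.attrs["fraction_below"]``.
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    pos = np.array([s.position_nm for s in sites])
    if any(p is None for p in pos):
        raise ValueError("sites must carry 3D positions")
    chroms = np.array([s.chrom for s in sites])
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    rows = []
    for i in range(len(sites)):
        same = chroms == chroms[i]
        same[i] = False
        diff = chroms != chroms[i]
        rows.append({
            "chrom": chroms[i],
            "start": sites[i].start,
            "nn_nm": float(d[i].min()),
            "nn_same_chrom_nm": float(d[i][same].min()) if same.any() else np.nan,
            "nn_diff_chrom_nm": float(d[i][diff].min()) if diff.any() else np.nan,
        })
    df = pd.DataFrame(rows)
    df.attrs["fraction_below"] = float((df["nn_nm"] < threshold_nm).mean())
    return df
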