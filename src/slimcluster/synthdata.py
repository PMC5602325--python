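"""Synthetic Slimfield data with ground truth.

Every generator in this module produces one of the inputs the analysis
pipeline consumes -- fluorescence image stacks of yeast-like cells, first-step
displacement samples, stepwise photobleach intensity traces, FRAP recovery
curves, periodic stoichiometry samples, and toy genomes with planted binding
sites plus polymer 3D coordinates -- together with the ground truth needed to
score parameter recovery downstream.

Conventions: lengths in nm (pixel size nm/px), times in ms, diffusion
coefficients in um^2/s, intensities in camera counts.  All randomness flows
through a single :class:`numpy.random.Generator`; a fixed seed reproduces
every output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from slimcluster.core import (
    COMPARTMENTS,
    ImageStack,
    check_positive,
    iupac_regex,
    IUPAC_CODES,
    rng_from_seed,
)

MS_PER_S = 1000.0
NM_PER_UM = 1000.0


@dataclass
class NoiseParams:
    """EMCCD-like camera noise: Poisson shot noise on expected counts plus
    Gaussian read noise, with an additive baseline offset.  ``gain`` rescales
    the Poisson variate (electron-multiplying register not modeled)."""

    read_sd: float = 10.0
    shot: bool = True
    gain: float = 1.0
    offset: float = 100.0
    enabled: bool = True

    @classmethod
    def off(cls, offset: float = 0.0) -> "NoiseParams":
        return cls(read_sd=0.0, shot=False, offset=offset, enabled=False)

    def apply(self, expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if not self.enabled:
            return expected + self.offset
        out = np.asarray(expected, dtype=float)
        if self.shot:
            out = self.gain * rng.poisson(np.clip(out / self.gain, 0, None))
        if self.read_sd > 0:
            out = out + rng.normal(0.0, self.read_sd, size=out.shape)
        return out + self.offset


@dataclass
class SimParams:
    """Acquisition and sample parameters for the Slimfield simulator.

    Defaults follow the imaging conditions the pipeline is designed for:
    80 nm/pixel EMCCD sampling, 5 ms exposures, a ~230 nm Gaussian PSF sigma,
    ~5 um spherical cells with ~2 um nuclei, a 40 ms photobleach time constant
    and ~5000 counts per GFP molecule.
    """

    pixel_size_nm: float = 80.0
    frame_interval_ms: float = 5.0
    psf_sigma_nm: float = 230.0
    cell_diameter_um: float = 5.0
    nucleus_diameter_um: float = 2.0
    bleach_constant_ms: float = 40.0
    single_brightness: float = 5000.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int | None = 0

    def __post_init__(self) -> None:
        check_positive(
            pixel_size_nm=self.pixel_size_nm,
            frame_interval_ms=self.frame_interval_ms,
            psf_sigma_nm=self.psf_sigma_nm,
            cell_diameter_um=self.cell_diameter_um,
            nucleus_diameter_um=self.nucleus_diameter_um,
            bleach_constant_ms=self.bleach_constant_ms,
            single_brightness=self.single_brightness,
        )
        if self.nucleus_diameter_um >= self.cell_diameter_um:
            raise ValueError("nucleus must be smaller than the cell")

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma_nm / self.pixel_size_nm

    @property
    def cell_radius_px(self) -> float:
        return self.cell_diameter_um * NM_PER_UM / 2 / self.pixel_size_nm

    @property
    def nucleus_radius_px(self) -> float:
        return self.nucleus_diameter_um * NM_PER_UM / 2 / self.pixel_size_nm

    def replace(self, **changes) -> "SimParams":
        return dataclasses.replace(self, **changes)


@dataclass
class FocusSpec:
    """A simulated multi-fluorophore focus: stoichiometry S, diffusion
    coefficient D (um^2/s), compartment label."""

    S: int
    D: float
    compartment: str = "cytoplasm"

    def __post_init__(self) -> None:
        if self.S < 1:
            raise ValueError("stoichiometry must be >= 1")
        if self.D < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"compartment must be one of {COMPARTMENTS}, got {self.compartment!r}")


@dataclass
class GroundTruth:
    """True per-focus trajectories and states behind a simulated stack.

    positions_px has shape (n_foci, n_frames, 2) in (x, y) image pixel
    coordinates (sub-pixel); alive counts the unbleached fluorophores per
    focus per frame.
    """

    positions_px: np.ndarray
    stoichiometries: np.ndarray
    diffusion: np.ndarray
    compartments: list[str]
    alive: np.ndarray
    pool_counts: dict[str, int]
    params: SimParams

    def total_fluorophores(self, frame: int) -> float:
        """Pool (expected unbleached) plus focus (actual unbleached) content."""
        t = frame * self.params.frame_interval_ms
        pool = sum(self.pool_counts.values()) * np.exp(-t / self.params.bleach_constant_ms)
        foci = self.alive[:, frame].sum() if self.alive.size else 0
        return pool + foci

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(len(self.stoichiometries)):
            for k in range(self.positions_px.shape[1]):
                rows.append({
                    "focus": i, "frame": k,
                    "x_px": self.positions_px[i, k, 0],
                    "y_px": self.positions_px[i, k, 1],
                    "S": int(self.stoichiometries[i]),
                    "alive": int(self.alive[i, k]),
                    "D": float(self.diffusion[i]),
                    "compartment": self.compartments[i],
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# image-stack generation
# ---------------------------------------------------------------------------

def _sphere_projection(shape, center, radius_px) -> np.ndarray:
    """Projected (chord-length) intensity image of a uniform sphere,
    normalized to unit sum."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    rho2 = (xx - center[0]) ** 2 + (yy - center[1]) ** 2
    chord = np.sqrt(np.clip(radius_px**2 - rho2, 0, None))
    total = chord.sum()
    return chord / total if total > 0 else chord


def _add_gaussian_spot(frame, x, y, sigma, amplitude) -> None:
    """Add an integrated-intensity ``amplitude`` Gaussian spot in place."""
    if amplitude <= 0:
        return
    half = int(np.ceil(5 * sigma))
    x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
    y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
    x0c, x1c = max(x0, 0), min(x1, frame.shape[1])
    y0c, y1c = max(y0, 0), min(y1, frame.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c)
    ys = np.arange(y0c, y1c)
    gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
    frame[y0c:y1c, x0c:x1c] += amplitude / (2 * np.pi * sigma**2) * np.outer(gy, gx)


def _sample_in_shell(rng, r_inner, r_outer) -> np.ndarray:
    """Uniform 3D point with r_inner <= |p| <= r_outer (rejection)."""
    while True:
        p = rng.uniform(-r_outer, r_outer, size=3)
        r = np.linalg.norm(p)
        if r_inner <= r <= r_outer:
            return p


def _reflect_radius(p: np.ndarray, r_inner: float, r_outer: float) -> np.ndarray:
    """Reflect a 3D point back into the spherical shell [r_inner, r_outer]."""
    r = np.linalg.norm(p)
    if r == 0:
        return p
    for _ in range(8):
        if r > r_outer:
            p = p * (2 * r_outer - r) / r
        elif r < r_inner:
            p = p * (2 * r_inner - r) / r
        else:
            break
        r = abs(np.linalg.norm(p))
    return p


def _simulate_trajectory(spec: FocusSpec, params: SimParams, n_frames: int,
                         rng: np.random.Generator,
                         pause_ms: float = 10.0) -> np.ndarray:
    """3D trajectory (nm, relative to cell center) for one focus."""
    r_cell = params.cell_diameter_um * NM_PER_UM / 2
    r_nuc = params.nucleus_diameter_um * NM_PER_UM / 2
    dt_s = params.frame_interval_ms / MS_PER_S
    step_sd = np.sqrt(2 * spec.D * dt_s) * NM_PER_UM

    if spec.compartment == "trans-nuclear":
        # straight crossing path through the envelope along a random radial
        # direction in the focal plane (a crossing is only observable when it
        # happens in-plane), with an exponential-mean pause at the envelope
        phi = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(phi), np.sin(phi), 0.0])
        speed = step_sd / (params.frame_interval_ms or 1.0)  # nm/ms
        if speed <= 0:
            speed = 40.0
        pause = rng.exponential(pause_ms) if pause_ms > 0 else 0.0
        entering = rng.random() < 0.5
        total_t = n_frames * params.frame_interval_ms
        # cross near mid-track with a random sub-frame phase so dwell
        # sampling is not locked to the frame grid
        t_cross = total_t / 2 + rng.uniform(-0.5, 0.5) * params.frame_interval_ms
        out = np.empty((n_frames, 3))
        for k in range(n_frames):
            t = k * params.frame_interval_ms
            if t < t_cross - pause / 2:
                s = (t - (t_cross - pause / 2)) * speed
            elif t <= t_cross + pause / 2:
                s = 0.0
            else:
                s = (t - (t_cross + pause / 2)) * speed
            radial = r_nuc - s if entering else r_nuc + s
            radial = float(np.clip(radial, 0.0, r_cell * 0.98))
            out[k] = direction * radial
        return out

    if spec.compartment == "nucleus":
        lo, hi = 0.0, r_nuc
    else:  # cytoplasm
        lo, hi = r_nuc, r_cell
    p = _sample_in_shell(rng, lo, hi)
    out = np.empty((n_frames, 3))
    out[0] = p
    for k in range(1, n_frames):
        p = _reflect_radius(p + rng.normal(0, step_sd, size=3), lo, hi)
        out[k] = p
    return out


def generate_cell_stack(
    params: SimParams,
    pool_counts: dict[str, int] | int | None = None,
    foci_spec: list[FocusSpec] | None = None,
    n_frames: int = 30,
    shape: tuple[int, int] | None = None,
    pause_ms: float = 10.0,
    seed=None,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a Slimfield stack of one yeast-like cell.

    The diffuse fluorophore pool is rendered as a compartment-uniform density
    (the chord-length projection of a uniform sphere) convolved with the PSF;
    foci are diffusing Gaussian spots whose fluorophores photobleach in
    discrete steps with exponential lifetimes of mean ``bleach_constant_ms``.
    The pool bleaches with the same constant in expectation.

    Parameters
    ----------
    pool_counts : dict or int
        Copy numbers per compartment, e.g. ``{"cytoplasm": 500, "nucleus":
        100}``.  A bare int is taken as cytoplasmic.
    foci_spec : list of FocusSpec
        Stoichiometry, D and compartment for each simulated focus.

    Returns
    -------
    (ImageStack, GroundTruth)
    """
    from scipy.ndimage import gaussian_filter

    rng = rng_from_seed(params.seed if seed is None else seed)
    if pool_counts is None:
        pool_counts = {}
    if isinstance(pool_counts, (int, np.integer)):
        pool_counts = {"cytoplasm": int(pool_counts)}
    for comp, n in pool_counts.items():
        if comp not in ("cytoplasm", "nucleus"):
            raise ValueError(f"pool compartment must be cytoplasm or nucleus, got {comp!r}")
        if n < 0:
            raise ValueError("pool counts must be non-negative")
    foci_spec = list(foci_spec or [])

    r_cell_px = params.cell_radius_px
    r_nuc_px = params.nucleus_radius_px
    if shape is None:
        side = int(np.ceil(2 * r_cell_px + 8 * params.psf_sigma_px + 8))
        shape = (side, side)
    center = ((shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0)
    if r_cell_px > min(center[0], center[1]) + 0.5:
        raise ValueError("image too small to contain the cell")

    # pool basis images (unit sum before PSF; PSF preserves the sum)
    cell_proj = _sphere_projection(shape, center, r_cell_px)
    nuc_proj = _sphere_projection(shape, center, r_nuc_px)
    cyto_proj = cell_proj - nuc_proj * (
        (r_nuc_px / r_cell_px) ** 3)  # subtract nuclear volume share
    cyto_proj = np.clip(cyto_proj, 0, None)
    s = cyto_proj.sum()
    if s > 0:
        cyto_proj = cyto_proj / s
    cyto_proj = gaussian_filter(cyto_proj, params.psf_sigma_px, mode="constant")
    nuc_proj = gaussian_filter(nuc_proj, params.psf_sigma_px, mode="constant")

    # trajectories (3D, nm) and bleach schedules
    trajs = [
        _simulate_trajectory(spec, params, n_frames, rng, pause_ms)
        for spec in foci_spec
    ]
    bleach_times = [
        rng.exponential(params.bleach_constant_ms, size=spec.S)
        for spec in foci_spec
    ]

    times = np.arange(n_frames) * params.frame_interval_ms
    alive = np.zeros((len(foci_spec), n_frames), dtype=int)
    positions_px = np.zeros((len(foci_spec), n_frames, 2))
    frames = np.zeros((n_frames,) + tuple(shape))
    I1 = params.single_brightness

    for k, t in enumerate(times):
        decay = np.exp(-t / params.bleach_constant_ms)
        frame = (
            pool_counts.get("cytoplasm", 0) * I1 * decay * cyto_proj
            + pool_counts.get("nucleus", 0) * I1 * decay * nuc_proj
        )
        for i, spec in enumerate(foci_spec):
            n_alive = int(np.sum(bleach_times[i] > t))
            alive[i, k] = n_alive
            x = center[0] + trajs[i][k, 0] / params.pixel_size_nm
            y = center[1] + trajs[i][k, 1] / params.pixel_size_nm
            positions_px[i, k] = (x, y)
            _add_gaussian_spot(frame, x, y, params.psf_sigma_px, n_alive * I1)
        frames[k] = params.noise.apply(frame, rng)

    stack = ImageStack(frames, params.pixel_size_nm, params.frame_interval_ms)
    truth = GroundTruth(
        positions_px=positions_px,
        stoichiometries=np.array([s.S for s in foci_spec], dtype=int),
        diffusion=np.array([s.D for s in foci_spec], dtype=float),
        compartments=[s.compartment for s in foci_spec],
        alive=alive,
        pool_counts=dict(pool_counts),
        params=params,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# derived-observable generators
# ---------------------------------------------------------------------------

def generate_displacements(
    n_tracks: int,
    mixture: list[tuple[float, float]],
    dt_ms: float = 5.0,
    sigma_nm: float = 40.0,
    seed=None,
) -> np.ndarray:
    """Squared first-step displacements (um^2) from a Brownian mixture.

    ``mixture`` is a list of (fraction, D um^2/s) components; fractions must
    sum to one.  Each endpoint of a step carries independent Gaussian
    localization error of sd ``sigma_nm`` per axis, so E[r^2] = 4 D dt +
    4 sigma^2 for each component.
    """
    rng = rng_from_seed(seed)
    fractions = np.array([a for a, _ in mixture], dtype=float)
    ds = np.array([d for _, d in mixture], dtype=float)
    if np.any(ds < 0):
        raise ValueError("diffusion coefficients must be non-negative")
    if not np.isclose(fractions.sum(), 1.0, atol=1e-6):
        raise ValueError("mixture fractions must sum to 1")
    check_positive(dt_ms=dt_ms)
    if sigma_nm < 0:
        raise ValueError("localization precision must be non-negative")

    comp = rng.choice(len(ds), size=n_tracks, p=fractions / fractions.sum())
    dt_s = dt_ms / MS_PER_S
    sigma_um = sigma_nm / NM_PER_UM
    var = 2 * ds[comp] * dt_s + 2 * sigma_um**2  # per-axis displacement variance
    dx = rng.normal(0, 1, size=n_tracks) * np.sqrt(var)
    dy = rng.normal(0, 1, size=n_tracks) * np.sqrt(var)
    return dx**2 + dy**2


def generate_bleach_traces(
    n: int,
    S: int,
    I_GFP: float = 5000.0,
    t_b_ms: float = 40.0,
    noise_cv: float = 0.0,
    dt_ms: float = 5.0,
    n_frames: int | None = None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Stepwise-photobleaching intensity traces.

    Each of ``n`` traces starts with ``S`` fluorophores of brightness
    ``I_GFP``; fluorophores bleach independently with exponential lifetimes of
    mean ``t_b_ms``, so traces fall in integer steps of ``I_GFP`` and the
    ensemble mean decays as ``S * I_GFP * exp(-t / t_b)``.  ``noise_cv`` adds
    multiplicative Gaussian noise to nonzero levels.

    Returns (traces, times_ms) with traces of shape (n, n_frames).
    """
    if S < 1:
        raise ValueError("stoichiometry must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    check_positive(I_GFP=I_GFP, t_b_ms=t_b_ms, dt_ms=dt_ms)
    rng = rng_from_seed(seed)
    if n_frames is None:
        n_frames = int(np.ceil(6 * t_b_ms / dt_ms))
    times = np.arange(n_frames) * dt_ms
    lifetimes = rng.exponential(t_b_ms, size=(n, S))
    alive = (lifetimes[:, :, None] > times[None, None, :]).sum(axis=1)
    traces = alive * I_GFP
    if noise_cv > 0:
        traces = traces * (1 + noise_cv * rng.normal(size=traces.shape))
    return traces.astype(float), times


def generate_frap_curve(
    C0: float,
    t_R_s: float,
    timepoints_s,
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Samples of the FRAP recovery C(t) = C0 (1 - exp(-t / t_R)) with
    additive Gaussian noise of sd ``noise_sd`` (molecule units)."""
    check_positive(t_R_s=t_R_s)
    timepoints_s = np.asarray(timepoints_s, dtype=float)
    if timepoints_s.size == 0:
        raise ValueError("timepoints must be non-empty")
    rng = rng_from_seed(seed)
    curve = C0 * (1 - np.exp(-timepoints_s / t_R_s))
    if noise_sd > 0:
        curve = curve + rng.normal(0, noise_sd, size=curve.shape)
    return curve


def generate_stoichiometries(
    n: int,
    unit: float,
    k_range: tuple[int, int] = (1, 4),
    noise_sd: float = 0.0,
    seed=None,
) -> np.ndarray:
    """Stoichiometry sample at integer multiples of a periodic unit:
    values k * unit + Gaussian noise with k uniform over ``k_range``
    (inclusive)."""
    check_positive(unit=unit)
    rng = rng_from_seed(seed)
    if n == 0:
        return np.empty(0)
    k = rng.integers(k_range[0], k_range[1] + 1, size=n)
    values = k * float(unit)
    if noise_sd > 0:
        values = values + rng.normal(0, noise_sd, size=n)
    return values


# ---------------------------------------------------------------------------
# toy genome with planted sites and polymer 3D coordinates
# ---------------------------------------------------------------------------

@dataclass
class ToyGenome:
    """A small random genome with planted IUPAC sites, gene annotation and
    confined random-walk polymer 3D coordinates standing in for a consensus
    3D chromosome model."""

    sequences: dict[str, str]
    annotation: pd.DataFrame      # chrom, start, end, strand, gene_id (1-based incl.)
    coords: pd.DataFrame          # chrom, bp, x_nm, y_nm, z_nm
    sites: pd.DataFrame           # chrom, start, strand, in_promoter (1-based)
    pattern: str

    def write(self, outdir) -> None:
        from pathlib import Path
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio import SeqIO

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = [SeqRecord(Seq(s), id=name, description="")
                   for name, s in self.sequences.items()]
        SeqIO.write(records, outdir / "genome.fasta", "fasta")
        self.annotation.to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        self.coords.to_csv(outdir / "coords.csv", index=False)
        self.sites.to_csv(outdir / "planted_sites.csv", index=False)


def _confined_walk(n_points: int, radius_nm: float, segment_nm: float,
                   rng: np.random.Generator, min_sep_nm: float) -> np.ndarray:
    """Self-avoiding random walk confined to a sphere of given radius."""
    pts = np.empty((n_points, 3))
    pts[0] = _sample_in_shell(rng, 0.0, radius_nm * 0.9)
    for i in range(1, n_points):
        placed = False
        for _ in range(200):
            step = rng.normal(size=3)
            step *= segment_nm / np.linalg.norm(step)
            cand = pts[i - 1] + step
            if np.linalg.norm(cand) > radius_nm:
                continue
            if i > 1 and np.min(
                    np.linalg.norm(pts[: i - 1] - cand, axis=1)) < min_sep_nm:
                continue
            pts[i] = cand
            placed = True
            break
        if not placed:  # fall back to confinement only
            step = rng.normal(size=3)
            step *= segment_nm / np.linalg.norm(step)
            cand = pts[i - 1] + step
            r = np.linalg.norm(cand)
            if r > radius_nm:
                cand *= (2 * radius_nm - r) / r if r < 2 * radius_nm else radius_nm / r
            pts[i] = cand
    return pts


def generate_toy_genome(
    n_chrom: int = 2,
    lengths=(10_000, 8_000),
    planted_pattern: str = "AATTTATCCGGGGTA",
    n_sites: int = 10,
    promoter_fraction: float = 0.5,
    nucleus_diameter_um: float = 2.0,
    coarse_bp: int = 500,
    segment_nm: float = 100.0,
    genes_per_kb: float = 0.25,
    seed=None,
) -> ToyGenome:
    """Generate a toy genome with planted binding sites and 3D coordinates.

    Random A/C/G/T sequences carry ``n_sites`` concrete instances of the
    IUPAC ``planted_pattern`` at non-overlapping positions; a fraction
    ``promoter_fraction`` of them is placed within 500 bp upstream of an
    annotated gene start on the matching strand.  3D coordinates come from a
    self-avoiding random walk (one locus per ``coarse_bp`` bp, step
    ``segment_nm``) confined to a sphere of the nuclear diameter.
    """
    rng = rng_from_seed(seed)
    pattern = planted_pattern.upper()
    if any(c not in IUPAC_CODES for c in pattern):
        raise ValueError(f"invalid IUPAC pattern {planted_pattern!r}")
    lengths = list(lengths)[:n_chrom]
    if len(lengths) < n_chrom:
        lengths = lengths + [lengths[-1]] * (n_chrom - len(lengths))
    plen = len(pattern)

    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    seqs = {
        name: rng.choice(list("ACGT"), size=L)
        for name, L in zip(chrom_names, lengths)
    }

    # genes: non-overlapping 1 kb ORFs with 600 bp clearance upstream
    ann_rows = []
    gene_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}
    gid = 0
    for name, L in zip(chrom_names, lengths):
        n_genes = max(1, int(round(genes_per_kb * L / 1000)))
        for _ in range(n_genes):
            for _ in range(100):
                strand = "+" if rng.random() < 0.5 else "-"
                start = int(rng.integers(700, max(701, L - 1700)))
                end = start + 999
                window = (start - 650, end + 650)
                if all(window[1] < w0 or window[0] > w1
                       for w0, w1 in gene_windows[name]):
                    gene_windows[name].append(window)
                    gid += 1
                    ann_rows.append({"chrom": name, "start": start, "end": end,
                                     "strand": strand, "gene_id": f"G{gid:04d}"})
                    break
    annotation = pd.DataFrame(ann_rows)

    # plant sites
    n_promoter = int(round(n_sites * promoter_fraction))
    site_rows = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    def free(chrom, start):
        span = (start, start + plen - 1)
        return all(span[1] < a or span[0] > b for a, b in occupied[chrom])

    def concrete(rng):
        return "".join(rng.choice(list(IUPAC_CODES[c])) for c in pattern)

    promoter_slots = []
    for _, g in annotation.iterrows():
        if g.strand == "+":
            lo, hi = max(1, g.start - 500), g.start - plen
        else:
            lo, hi = g.end + 1, g.end + 500 - plen + 1
        if hi > lo:
            promoter_slots.append((g.chrom, lo, hi, g.strand))
    if n_promoter > 0 and not promoter_slots:
        raise ValueError("no promoter capacity for requested promoter sites")

    attempts = 0
    placed_prom = 0
    while placed_prom < n_promoter:
        attempts += 1
        if attempts > 200 * max(1, n_promoter):
            raise ValueError("site count exceeds promoter capacity")
        chrom, lo, hi, strand = promoter_slots[int(rng.integers(len(promoter_slots)))]
        start = int(rng.integers(lo, hi + 1))
        if not free(chrom, start):
            continue
        inst = concrete(rng)
        if strand == "-":
            from Bio.Seq import Seq
            inst_seq = str(Seq(inst).reverse_complement())
        else:
            inst_seq = inst
        seqs[chrom][start - 1: start - 1 + plen] = list(inst_seq)
        occupied[chrom].append((start, start + plen - 1))
        site_rows.append({"chrom": chrom, "start": start, "strand": strand,
                          "in_promoter": True})
        placed_prom += 1

    attempts = 0
    while len(site_rows) < n_sites:
        attempts += 1
        if attempts > 200 * max(1, n_sites):
            raise ValueError("site count exceeds sequence capacity")
        chrom = chrom_names[int(rng.integers(n_chrom))]
        L = len(seqs[chrom])
        start = int(rng.integers(1, L - plen + 1))
        if not free(chrom, start):
            continue
        # keep non-promoter plants out of promoter windows
        in_any_prom = any(
            chrom == c and lo - plen < start <= hi + plen
            for c, lo, hi, _ in promoter_slots)
        if in_any_prom:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        inst = concrete(rng)
        if strand == "-":
            from Bio.Seq import Seq
            inst = str(Seq(inst).reverse_complement())
        seqs[chrom][start - 1: start - 1 + plen] = list(inst)
        occupied[chrom].append((start, start + plen - 1))
        site_rows.append({"chrom": chrom, "start": start, "strand": strand,
                          "in_promoter": False})

    sites = pd.DataFrame(site_rows,
                         columns=["chrom", "start", "strand", "in_promoter"])

    # polymer coordinates
    radius_nm = nucleus_diameter_um * NM_PER_UM / 2
    coord_rows = []
    for name, L in zip(chrom_names, lengths):
        bps = np.arange(0, L + 1, coarse_bp)
        pts = _confined_walk(len(bps), radius_nm, segment_nm, rng,
                             min_sep_nm=segment_nm / 3)
        for bp, (x, y, z) in zip(bps, pts):
            coord_rows.append({"chrom": name, "bp": int(bp),
                               "x_nm": x, "y_nm": y, "z_nm": z})
    coords = pd.DataFrame(coord_rows)

    sequences = {name: "".join(arr) for name, arr in seqs.items()}
    return ToyGenome(sequences, annotation, coords, sites, pattern)
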