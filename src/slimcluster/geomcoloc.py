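"""Cluster geometry, colocalization and rendering.

Cluster diameters are estimated from fitted focus widths corrected for the
single-fluorophore reference width and for motion blur over the camera
exposure; their scaling with stoichiometry is summarized by a power-law
exponent (1/3 for ideal spherical packing, 1 for a rotating rod, 0 for an
anchor of fixed size).  Colocalization between two detected foci uses the
closed-form overlap integral of their fitted 2D Gaussians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from slimcluster.core import check_positive

MS_PER_S = 1000.0
NM_PER_UM = 1000.0


@dataclass
class ClusterGeometry:
    """Effective cluster diameter from a measured focus width.

    p_foci and the reference p_GFP are full widths = 2x the fitted Gaussian
    sigma.  ``diameter_nm`` is None when the correction leaves nothing
    resolvable."""

    p_foci_nm: float
    p_GFP_nm: float
    D: float
    dt_ms: float
    diameter_nm: float | None

    @property
    def resolvable(self) -> bool:
        return self.diameter_nm is not None


def diffusion_blur_nm(D: float, dt_ms: float) -> float:
    """Mean 2D diffusion distance sqrt(4 D dt) in nm."""
    return float(np.sqrt(4 * D * dt_ms / MS_PER_S) * NM_PER_UM)


def cluster_diameter(p_foci_nm: float, p_GFP_nm: float = 460.0,
                     D: float = 0.0, dt_ms: float = 5.0,
                     blur: str = "length") -> ClusterGeometry:
    """Effective cluster diameter d = p_foci - p_GFP - sqrt(4 D dt).

    The motion-blur correction subtracts the diffusion length sqrt(4 D dt)
    travelled during one exposure (``blur="length"``); ``blur="area"``
    subtracts the raw area term 4 D dt expressed in nm^2 / nm, kept only for
    comparison as it is dimensionally inconsistent.  A non-positive result
    is reported as unresolvable rather than raised.
    """
    if p_foci_nm < 0 or p_GFP_nm < 0 or D < 0 or dt_ms < 0:
        raise ValueError("inputs must be non-negative")
    if blur == "length":
        blur_nm = diffusion_blur_nm(D, dt_ms)
    elif blur == "area":
        blur_nm = 4 * D * dt_ms / MS_PER_S * NM_PER_UM**2 / NM_PER_UM
    else:
        raise ValueError("blur must be 'length' or 'area'")
    d = p_foci_nm - p_GFP_nm - blur_nm
    return ClusterGeometry(p_foci_nm, p_GFP_nm, D, dt_ms,
                           float(d) if d > 0 else None)


@dataclass
class PackingFit:
    """Power-law fit d ~ S^a of cluster diameter versus stoichiometry."""

    exponent: float
    exponent_se: float
    prefactor: float

    def summary(self) -> str:
        return (f"packing law d ~ S^a: a = {self.exponent:.3f} "
                f"+/- {self.exponent_se:.3f} (SEM), "
                f"d1 = {self.prefactor:.3g} nm")


def packing_exponent(stoichiometries, diameters_nm) -> PackingFit:
    """Least-squares fit of log d versus log S."""
    from scipy.stats import linregress

    S = np.asarray(stoichiometries, dtype=float)
    d = np.asarray(diameters_nm, dtype=float)
    if S.size < 5:
        raise ValueError("need at least 5 (S, d) pairs")
    if np.any(S <= 0) or np.any(d <= 0):
        raise ValueError("stoichiometries and diameters must be positive")
    res = linregress(np.log(S), np.log(d))
    return PackingFit(exponent=float(res.slope),
                      exponent_se=float(res.stderr),
                      prefactor=float(np.exp(res.intercept)))


@dataclass
class OverlapResult:
    """Gaussian overlap integral between two foci and the colocalization
    call at the configured threshold."""

    delta_r2: float
    nu: float
    colocalized: bool
    threshold: float = 0.75


def overlap_integral(focus1, focus2, threshold: float = 0.75,
                     max_pair_px: float = 5.0,
                     pixel_units: bool = True) -> OverlapResult | None:
    """Closed-form overlap nu = exp(-dr^2 / (2 (s1^2 + s2^2))).

    ``focus1``/``focus2`` are (x, y, sigma) triples or detected Focus
    objects (pixel units).  Pairs whose centroids are farther apart than
    ``max_pair_px`` are never formed (returns None).  nu is 1 exactly for
    identical centers and decreases monotonically with separation.
    """
    x1, y1, s1 = _focus_triple(focus1)
    x2, y2, s2 = _focus_triple(focus2)
    check_positive(sigma1=s1, sigma2=s2)
    dr2 = (x1 - x2) ** 2 + (y1 - y2) ** 2
    if max_pair_px is not None and np.sqrt(dr2) > max_pair_px:
        return None
    nu = float(np.exp(-dr2 / (2 * (s1**2 + s2**2))))
    return OverlapResult(delta_r2=float(dr2), nu=nu,
                         colocalized=nu > threshold, threshold=threshold)


def _focus_triple(f):
    if hasattr(f, "x_px"):
        return f.x_px, f.y_px, f.sigma_px
    x, y, s = f
    return float(x), float(y), float(s)


def genome_mesh_size(genome_bp: float = 12.1e6, rise_per_bp_nm: float = 0.34,
                     nucleus_diameter_um: float = 2.0) -> tuple[float, float]:
    """(tube length mm, tube diameter nm) of the genome as a space-filling
    tube in the nucleus.

    The genome is modeled as a tube of length L = genome_bp * rise whose
    circular cross-section fills the nuclear sphere: pi r^2 L = (4/3) pi R^3.
    The tube diameter approximates the DNA mesh size (mean strand spacing).
    """
    check_positive(genome_bp=genome_bp, rise_per_bp_nm=rise_per_bp_nm,
                   nucleus_diameter_um=nucleus_diameter_um)
    L_nm = genome_bp * rise_per_bp_nm
    R_nm = nucleus_diameter_um * NM_PER_UM / 2
    r_nm = np.sqrt(4 * R_nm**3 / (3 * L_nm))
    return float(L_nm / 1e6), float(2 * r_nm)


def subunit_diameter(cluster_d_nm: float, S: float) -> float:
    """Monomer diameter implied by spherical packing: d / S^(1/3)."""
    check_positive(cluster_d_nm=cluster_d_nm, S=S)
    if S < 1:
        raise ValueError("stoichiometry must be >= 1")
    return float(cluster_d_nm / S ** (1.0 / 3.0))


def render_heatmap(points, weights=None, mode: str = "foci",
                   grid: int | None = None, sigma_px: float | None = None,
                   pixel_size_nm: float | None = None,
                   extent=None) -> np.ndarray:
    """Sum-of-Gaussians heat map of point localizations.

    mode="foci" uses a 1000-pixel square grid over the data extent with
    15-pixel-sigma Gaussians; mode="storm" renders a super-resolved map at
    20 nm/pixel with sigma 40 nm (points then in nm).  The map integral
    equals the sum of the weights (in pixel units).
    """
    from scipy.ndimage import gaussian_filter

    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("no points to render")
    points = np.atleast_2d(points)
    n = len(points)
    weights = np.ones(n) if weights is None else np.asarray(weights, float)

    if mode == "foci":
        grid = 1000 if grid is None else grid
        sigma_px = 15.0 if sigma_px is None else sigma_px
        if extent is None:
            lo = points.min(axis=0) - 3 * sigma_px
            hi = points.max(axis=0) + 3 * sigma_px
        else:
            (lo, hi) = np.asarray(extent[0], float), np.asarray(extent[1], float)
        scale = (grid - 1) / np.maximum(hi - lo, 1e-9)
        px = (points - lo) * scale
        shape = (grid, grid)
    elif mode == "storm":
        pixel_size_nm = 20.0 if pixel_size_nm is None else pixel_size_nm
        if sigma_px is None:
            sigma_px = 40.0 / pixel_size_nm  # 40 nm localization precision
        pad = 4 * sigma_px * pixel_size_nm
        lo = points.min(axis=0) - pad
        px = (points - lo) / pixel_size_nm
        shape = tuple(int(np.ceil(v)) + 1 for v in
                      (px[:, 1].max() + 4 * sigma_px,
                       px[:, 0].max() + 4 * sigma_px))
    else:
        raise ValueError("mode must be 'foci' or 'storm'")

    img = np.zeros(shape)
    # bilinear splat conserves total weight exactly; Gaussian blur preserves it
    for (x, y), w in zip(px, weights):
        x0, y0 = int(np.floor(x)), int(np.floor(y))
        fx, fy = x - x0, y - y0
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                yy, xx = y0 + dy, x0 + dx
                if 0 <= yy < shape[0] and 0 <= xx < shape[1]:
                    img[yy, xx] += w * wy * wx
    return gaussian_filter(img, sigma_px, mode="constant")
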