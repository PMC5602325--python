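"""Single-fluorophore calibration, stoichiometry and pool quantification.

Stoichiometries are obtained by correcting tracked focus intensities for
photobleaching with exp(+t/t_b), estimating the unbleached initial intensity
I0, and dividing by the characteristic single-fluorophore brightness I_GFP
(the modal value of all focus intensities, cross-checked against the
fundamental of the pairwise-difference power spectrum).  Pool copy numbers
come from a linear decomposition of the image into PSF-integrated uniform
nuclear and cytoplasmic sphere models (CoPro).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from slimcluster.core import check_positive

logger = logging.getLogger(__name__)

MS_PER_S = 1000.0
NM_PER_UM = 1000.0


class ExcludedTrackError(ValueError):
    """Track excluded from stoichiometry analysis, with a reason code."""

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


@dataclass
class Calibration:
    """Imaging calibration: single-fluorophore brightness (counts), the
    photobleach time constant (ms), and the green/red autofluorescence
    scaling factor."""

    I_GFP: float = 5000.0
    t_b_ms: float = 40.0
    autofluorescence_factor: float = 0.9

    def __post_init__(self) -> None:
        check_positive(I_GFP=self.I_GFP, t_b_ms=self.t_b_ms)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class StoichiometryDistribution:
    """A stoichiometry sample with its Gaussian KDE and periodicity."""

    values: np.ndarray
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    periodicity: float | None = None
    periodicity_power: float | None = None

    @property
    def mode(self) -> float:
        return float(self.grid[np.argmax(self.density)])


@dataclass
class PeriodicityResult:
    """Dominant non-DC period of the pairwise-difference power spectrum."""

    period: float | None
    power: float
    significant: bool
    periods: np.ndarray = field(repr=False, default=None)
    spectrum: np.ndarray = field(repr=False, default=None)


def kde(values, bandwidth: str | float = "silverman",
        grid_points: int = 512) -> StoichiometryDistribution:
    """Gaussian kernel density estimate (Silverman bandwidth by default)."""
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a KDE")
    spread = values.std()
    if spread == 0:  # degenerate sample: KDE needs nonzero variance
        values = values + 1e-9 * np.arange(values.size)
        spread = values.std()
    k = gaussian_kde(values, bw_method=bandwidth)
    bw = float(k.factor * spread)
    lo, hi = values.min() - 3 * bw, values.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    return StoichiometryDistribution(values=values, grid=grid,
                                     density=k(grid), bandwidth=bw)


def _pairwise_spectrum(values, bin_width, min_period, max_period=None,
                       detrend_periods=3.0, pad_factor=8):
    """Power spectrum of the histogram of all pairwise absolute differences.

    The slowly varying envelope of the difference distribution is removed by
    subtracting a Gaussian-smoothed trend (sigma ``detrend_periods`` in the
    difference units) before the FFT, so the spectrum isolates genuinely
    periodic structure.  Returns (periods, power) for min_period <= period
    <= max_period.
    """
    from scipy.ndimage import gaussian_filter1d

    values = np.asarray(values, dtype=float)
    diffs = np.abs(values[:, None] - values[None, :])[
        np.triu_indices(values.size, k=1)]
    span = diffs.max()
    if span <= bin_width * 4:
        return np.empty(0), np.empty(0)
    edges = np.arange(0, span + bin_width, bin_width)
    density, _ = np.histogram(diffs, bins=edges, density=True)
    trend = gaussian_filter1d(density, sigma=detrend_periods / bin_width,
                              mode="nearest")
    resid = density - trend
    n = len(resid)
    nfft = int(2 ** np.ceil(np.log2(n * pad_factor)))
    power = np.abs(np.fft.rfft(resid, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=bin_width)
    if max_period is None:
        max_period = span / 2
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    sel = (periods >= min_period) & (periods <= max_period)
    return periods[sel], power[sel]


def periodicity(values, bin_width: float = 0.2, min_period: float = 2.0,
                max_period: float | None = 12.0,
                n_surrogates: int = 40, seed: int = 0) -> PeriodicityResult:
    """Fundamental interval (molecules) of a stoichiometry sample.

    The histogram of all pairwise stoichiometry differences is detrended
    and Fourier transformed; the dominant peak at periods >= ``min_period``
    (DC and sub-``min_period`` harmonics excluded; the band is capped at
    ``max_period``, where detrending leakage from the envelope of the
    difference distribution would otherwise dominate) is the candidate
    periodicity.  Significance is calibrated by Monte Carlo: ``n_surrogates``
    samples of the same size are drawn from a deliberately over-smoothed
    (doubled-bandwidth) KDE of the values -- which preserves the overall
    stoichiometry distribution but washes out any comb structure -- and the
    observed peak power must exceed every surrogate maximum.  Otherwise a
    "no periodicity" result (period None) is returned.
    """
    from scipy.stats import gaussian_kde

    values = np.asarray(values, dtype=float)
    if values.size < 30:
        raise ValueError("need at least 30 stoichiometry values")
    periods, power = _pairwise_spectrum(values, bin_width, min_period,
                                        max_period)
    if periods.size == 0 or power.max() <= 0:
        return PeriodicityResult(None, 0.0, False, periods, power)
    i = int(np.argmax(power))

    rng = np.random.default_rng(seed)
    if values.std() > 0:
        lo, hi = values.min(), values.max()
        mu, var = values.mean(), values.var()
        bw = 2 * gaussian_kde(values, bw_method="silverman").factor * values.std()
        shrink = np.sqrt(max(1 - bw**2 / var, 0.0))
        surrogate_max = []
        for _ in range(n_surrogates):
            # variance-corrected smoothed bootstrap with boundary
            # reflection: preserves the overall distribution (variance and
            # sharp edges, whose spectral ringing mimics periodicity) while
            # the kernel noise washes out comb structure
            surr = rng.choice(values, size=values.size, replace=True)
            surr = mu + (surr - mu) * shrink + rng.normal(0.0, bw,
                                                          size=values.size)
            for _ in range(4):
                surr = np.where(surr < lo, 2 * lo - surr, surr)
                surr = np.where(surr > hi, 2 * hi - surr, surr)
            _, p_s = _pairwise_spectrum(surr, bin_width, min_period,
                                        max_period)
            surrogate_max.append(p_s.max() if p_s.size else 0.0)
        # genuine combs exceed the surrogate ceiling by 1-2 orders of
        # magnitude; require a twofold margin over the worst surrogate
        significant = power[i] > 2 * max(surrogate_max)
    else:
        significant = False
    return PeriodicityResult(float(periods[i]) if significant else None,
                             float(power[i]), bool(significant),
                             periods, power)


def estimate_single_brightness(intensities, min_obs: int = 50,
                               spectral_check: bool = True) -> float:
    """Characteristic single-fluorophore brightness I_GFP.

    I_GFP is the modal value (Silverman-KDE peak) of all pooled focus
    intensities over time; non-positive values (fully bleached samples) are
    discarded.  The estimate is cross-checked against the fundamental of the
    pairwise-distance power spectrum of the same intensities; a disagreement
    beyond 30% logs a warning.
    """
    if isinstance(intensities, (list, tuple)):
        intensities = np.concatenate(
            [np.ravel(np.asarray(i, dtype=float)) for i in intensities])
    else:
        intensities = np.ravel(np.asarray(intensities, dtype=float))
    intensities = intensities[np.isfinite(intensities) & (intensities > 0)]
    if intensities.size < min_obs:
        raise ValueError(f"need at least {min_obs} positive intensity values")
    if np.ptp(intensities) == 0:
        return float(intensities[0])
    dist = kde(intensities)
    mode = dist.mode

    if spectral_check and intensities.size >= 30:
        scaled = intensities / mode
        res = periodicity(scaled, bin_width=0.05, min_period=0.5,
                          max_period=2.0)
        if res.period is not None and abs(res.period - 1.0) > 0.3:
            warnings.warn(
                "modal brightness and pairwise-spectrum fundamental disagree "
                f"by more than 30% (ratio {res.period:.2f})", stacklevel=2)
    return float(mode)


def fit_bleach_constant(traces, times_ms) -> float:
    """Photobleach time constant t_b (ms) from exponential decay fits.

    ``traces`` may be a single intensity trace or a (n, T) stack; stacks are
    ensemble-averaged before a least-squares fit of A exp(-t / t_b).
    Raises on non-decaying input.
    """
    from scipy.optimize import curve_fit

    traces = np.asarray(traces, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    mean_trace = traces.mean(axis=0) if traces.ndim == 2 else traces
    if mean_trace.size < 10:
        raise ValueError("need at least 10 time points")
    half = mean_trace.size // 2
    if mean_trace[:half].mean() <= mean_trace[half:].mean():
        raise ValueError("input does not decay; cannot fit a bleach constant")

    def model(t, a, tb):
        return a * np.exp(-t / tb)

    span = times[-1] - times[0] if times[-1] > times[0] else 1.0
    popt, _ = curve_fit(model, times, mean_trace,
                        p0=[mean_trace[0], span / 3],
                        bounds=([0, 1e-6], [np.inf, np.inf]), maxfev=5000)
    return float(popt[1])


def track_stoichiometry(track, calibration: Calibration,
                        frame_interval_ms: float = 5.0,
                        start_frame_limit: int = 70,
                        estimator: str = "mean") -> float:
    """Stoichiometry S of one track: bleach-corrected I0 over I_GFP.

    Measured intensities I(t) are weighted by exp(+t/t_b) to undo the
    exponential photobleach decay; the initial intensity I0 is then the mean
    of the corrected values (``estimator="mean"``), the first corrected
    point (``"first"``) or the intercept of an exponential fit to the raw
    trace (``"fit"``).  Tracks starting after ``start_frame_limit`` frames
    of illumination are excluded (:class:`ExcludedTrackError`).
    """
    times_ms, intensities = _track_arrays(track, frame_interval_ms)
    start_frame = times_ms[0] / frame_interval_ms
    if start_frame > start_frame_limit:
        raise ExcludedTrackError(
            f"track starts at frame {start_frame:.0f} > {start_frame_limit}")
    corrected = intensities * np.exp(times_ms / calibration.t_b_ms)
    if estimator == "mean":
        i0 = corrected.mean()
    elif estimator == "first":
        i0 = corrected[0]
    elif estimator == "fit":
        from scipy.optimize import curve_fit

        popt, _ = curve_fit(
            lambda t, a: a * np.exp(-t / calibration.t_b_ms),
            times_ms, intensities, p0=[max(corrected.mean(), 1.0)],
            maxfev=2000)
        i0 = popt[0]
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return float(i0 / calibration.I_GFP)


def _track_arrays(track, frame_interval_ms):
    if hasattr(track, "intensities"):
        return track.times_ms(frame_interval_ms), track.intensities
    times_ms, intensities = track
    return np.asarray(times_ms, float), np.asarray(intensities, float)


def autofluorescence_correct(green: np.ndarray, red: np.ndarray,
                             factor: float = 0.9) -> np.ndarray:
    """Pixelwise green - factor * red, clipped at zero."""
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red images must be co-registered")
    return np.clip(green - factor * red, 0, None)


def _in_focus_fraction(radius_um: float, depth_um: float | None) -> float:
    """Fraction of a sphere's volume within |z| <= depth/2 of the focal plane."""
    if depth_um is None:
        return 1.0
    h = min(depth_um / 2, radius_um)
    return (3 * radius_um**2 * h - h**3) / (2 * radius_um**3)


def copro_pool_counts(
    image: np.ndarray,
    cell_boundary,
    nucleus_boundary,
    calibration: Calibration,
    psf_sigma_px: float,
    pixel_size_nm: float = 80.0,
    depth_of_field_um: float | None = None,
) -> tuple[float, float]:
    """Pool copy numbers (nuclear, cytoplasmic) by linear deconvolution.

    Nuclear and cytoplasmic pools are modeled as uniform fluorescence over
    the segmented spheres; a Gaussian model PSF is integrated over the two
    volumes to give basis images whose amplitudes, plus a constant camera
    background, are obtained by non-negative least squares over the cell
    region.  Amplitudes divided by I_GFP give copy numbers, optionally
    corrected for the fraction of each compartment within the depth of field.
    """
    from scipy.ndimage import gaussian_filter
    from scipy.optimize import nnls

    from slimcluster.synthdata import _sphere_projection

    image = np.asarray(image, dtype=float)
    cc = getattr(cell_boundary, "center", None)
    cell_center = cc if cc is not None else cell_boundary.centroid
    nc = getattr(nucleus_boundary, "center", None)
    nuc_center = nc if nc is not None else nucleus_boundary.centroid
    r_cell = _mean_radius(cell_boundary)
    r_nuc = _mean_radius(nucleus_boundary)
    if r_nuc <= psf_sigma_px / 2:
        raise ValueError("nucleus not distinguishable: radius below PSF scale")

    cell_proj = _sphere_projection(image.shape, cell_center, r_cell)
    nuc_proj = _sphere_projection(image.shape, nuc_center, r_nuc)
    cyto_proj = np.clip(cell_proj - nuc_proj * (r_nuc / r_cell) ** 3, 0, None)
    s = cyto_proj.sum()
    if s <= 0:
        raise ValueError("degenerate geometry: cytoplasm model is empty")
    cyto_proj /= s
    nuc_b = gaussian_filter(nuc_proj, psf_sigma_px, mode="constant")
    cyto_b = gaussian_filter(cyto_proj, psf_sigma_px, mode="constant")

    yy, xx = np.mgrid[: image.shape[0], : image.shape[1]]
    sel = ((xx - cell_center[0]) ** 2 + (yy - cell_center[1]) ** 2
           <= (r_cell + 3 * psf_sigma_px) ** 2)
    A = np.stack([nuc_b[sel], cyto_b[sel], np.ones(sel.sum())], axis=1)
    corr = np.corrcoef(A[:, 0], A[:, 1])[0, 1]
    if not np.isfinite(corr) or corr > 0.999:
        raise ValueError("singular design: nucleus not distinguishable "
                         "from cytoplasm")
    amp, _ = nnls(A, image[sel])
    r_cell_um = r_cell * pixel_size_nm / NM_PER_UM
    r_nuc_um = r_nuc * pixel_size_nm / NM_PER_UM
    n_nuc = amp[0] / calibration.I_GFP / _in_focus_fraction(
        r_nuc_um, depth_of_field_um)
    n_cyto = amp[1] / calibration.I_GFP / _in_focus_fraction(
        r_cell_um, depth_of_field_um)
    return float(n_nuc), float(n_cyto)


def _mean_radius(boundary) -> float:
    if hasattr(boundary, "radius"):  # BoundarySpline
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        return float(np.mean(boundary.radius(th)))
    return float(np.mean(boundary.radii()))


@dataclass
class PoolBoundInputs:
    """Inputs for the diffraction-limited upper bound on the mean
    oligomeric state of the diffuse pool.

    n_pool : pool copy number (molecules); D : pool diffusion coefficient
    (um^2/s); dt_ms : camera sampling time; w_nm : optical resolution limit;
    cell_diameter_um : mean cell diameter.  ``b_nm`` (mean 2D diffusion
    distance per frame) defaults to sqrt(4 D dt).
    """

    n_pool: float
    D: float = 6.0
    dt_ms: float = 5.0
    w_nm: float = 230.0
    cell_diameter_um: float = 5.0
    b_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_pool < 0:
            raise ValueError("n_pool must be non-negative")
        check_positive(D=self.D, dt_ms=self.dt_ms, w_nm=self.w_nm,
                       cell_diameter_um=self.cell_diameter_um)

    @property
    def b(self) -> float:
        """Diffusion blur length per frame (nm)."""
        if self.b_nm is not None:
            return self.b_nm
        return np.sqrt(4 * self.D * self.dt_ms / MS_PER_S) * NM_PER_UM


def pool_stoichiometry_bound(inputs: PoolBoundInputs) -> float:
    """Upper bound S_max on the mean pool-focus stoichiometry.

    A pool of n_pool molecules in a cell of diameter d appears diffuse when
    neighboring foci are closer than the resolution limit w, after allowing
    for the per-frame diffusion distance b = sqrt(4 D dt):
    S < n_pool ((b + w) / d)^3.
    """
    d_nm = inputs.cell_diameter_um * NM_PER_UM
    return float(inputs.n_pool * ((inputs.b + inputs.w_nm) / d_nm) ** 3)
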