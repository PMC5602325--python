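"""Translocation geometry and turnover kinetics.

Trans-nuclear tracks are re-expressed in an envelope-relative frame: the
nuclear-boundary crossing point is found by linear interpolation between the
first pair of points straddling the boundary, and coordinates are translated
to that point and rotated so x' runs parallel and y' perpendicular to the
envelope (nucleus interior at y' < 0), with times normalized to the crossing.
Dwell times are contiguous periods spent within a band around the envelope,
fitted with a single exponential.  Molecular turnover is quantified by
fitting FRAP recoveries with C(t) = C(0) (1 - exp(-t / t_R)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from slimcluster.core import check_positive

logger = logging.getLogger(__name__)

MS_PER_S = 1000.0


@dataclass
class TransNuclearTrack:
    """A trans-nuclear track in envelope-relative coordinates.

    x_par_nm runs parallel and y_perp_nm perpendicular to the envelope at
    the crossing point (interior negative); t_rel_ms is time relative to the
    crossing.  direction is "entering" or "leaving".
    """

    t_rel_ms: np.ndarray
    x_par_nm: np.ndarray
    y_perp_nm: np.ndarray
    crossing_point_px: np.ndarray
    crossing_time_ms: float
    direction: str
    multiple_crossings: bool = False


def transform_transnuclear(track, nucleus_boundary,
                           frame_interval_ms: float = 5.0,
                           pixel_size_nm: float = 80.0) -> TransNuclearTrack:
    """Rotate a trans-nuclear track into the envelope tangent/normal frame.

    The crossing is located by linear interpolation of the signed radial
    distance to the nuclear boundary between the first pair of straddling
    points.  If the track crosses more than once, the first crossing is used
    and the result flagged.
    """
    pts = track.positions_px if hasattr(track, "positions_px") else \
        np.asarray(track, dtype=float)
    times = (track.times_ms(frame_interval_ms)
             if hasattr(track, "times_ms")
             else np.arange(len(pts)) * frame_interval_ms)
    sd = nucleus_boundary.signed_distance(pts)
    signs = np.sign(sd)
    crossings = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
    if crossings.size == 0:
        raise ValueError("track does not cross the nuclear boundary")
    multiple = crossings.size > 1
    if multiple:
        logger.warning("track crosses the envelope %d times; using the first",
                       crossings.size)
    i = int(crossings[0])
    # linear interpolation on the signed distance
    f = sd[i] / (sd[i] - sd[i + 1])
    crossing_pt = pts[i] + f * (pts[i + 1] - pts[i])
    crossing_t = times[i] + f * (times[i + 1] - times[i])

    theta = nucleus_boundary.angle_of(crossing_pt)
    tangent = nucleus_boundary.tangent(theta)
    normal = np.array([-tangent[1], tangent[0]])
    # orient the normal outward (positive signed distance side)
    probe = crossing_pt + 0.5 * normal
    if nucleus_boundary.signed_distance(probe) < 0:
        normal = -normal
        tangent = -tangent

    rel = (pts - crossing_pt) * pixel_size_nm
    x_par = rel @ tangent
    y_perp = rel @ normal
    direction = "entering" if sd[i] > 0 else "leaving"
    return TransNuclearTrack(
        t_rel_ms=times - crossing_t,
        x_par_nm=x_par,
        y_perp_nm=y_perp,
        crossing_point_px=crossing_pt,
        crossing_time_ms=float(crossing_t),
        direction=direction,
        multiple_crossings=multiple,
    )


@dataclass
class DwellResult:
    """Envelope dwell durations and their exponential time constant."""

    durations_ms: np.ndarray
    tau_ms: float | None
    n_crossings: int

    @property
    def has_dwells(self) -> bool:
        return self.durations_ms.size > 0


def dwell_times(transformed_tracks, envelope_band_nm: float = 40.0,
                frame_interval_ms: float = 5.0,
                min_crossings: int = 20,
                discrete_correction: bool = True) -> DwellResult:
    """Dwell durations at the nuclear envelope and their exponential fit.

    A dwell is the contiguous time a track spends with |y'| <= band/2
    around its crossing.  The time constant is the maximum-likelihood
    exponential mean; with ``discrete_correction`` the geometric-sampling
    MLE tau = dt / ln(nbar / (nbar - 1)) is used to undo the frame-interval
    discretization of the observed durations.
    """
    check_positive(envelope_band_nm=envelope_band_nm)
    half = envelope_band_nm / 2
    durations = []
    for tr in transformed_tracks:
        inside = np.abs(tr.y_perp_nm) <= half
        if not inside.any():
            continue
        # contiguous run containing the crossing (t_rel = 0)
        i0 = int(np.argmin(np.abs(tr.t_rel_ms)))
        if not inside[i0]:
            j = np.nonzero(inside)[0]
            i0 = int(j[np.argmin(np.abs(tr.t_rel_ms[j]))])
        a = b = i0
        while a > 0 and inside[a - 1]:
            a -= 1
        while b < len(inside) - 1 and inside[b + 1]:
            b += 1
        durations.append((b - a + 1) * frame_interval_ms)
    durations = np.asarray(durations, dtype=float)
    n = len(durations)
    if n == 0:
        return DwellResult(durations, None, 0)
    if n < min_crossings:
        logger.warning("only %d crossings (< %d); dwell fit may be unstable",
                       n, min_crossings)
    nbar = durations.mean() / frame_interval_ms
    if discrete_correction and nbar > 1:
        tau = frame_interval_ms / np.log(nbar / (nbar - 1))
    else:
        tau = durations.mean()
    return DwellResult(durations, float(tau), n)


@dataclass
class FRAPFit:
    """Single-exponential FRAP recovery fit C(t) = C(0)(1 - exp(-t/t_R))."""

    C0: float
    t_R_s: float
    residual_sd: float
    C0_se: float = np.nan
    t_R_se: float = np.nan

    def summary(self) -> str:
        return (f"FRAP fit: C(0) = {self.C0:.3g} +/- {self.C0_se:.2g} "
                f"molecules, t_R = {self.t_R_s:.4g} +/- {self.t_R_se:.2g} s "
                f"(residual sd {self.residual_sd:.3g})")


def fit_frap(timepoints_s, recovery, p0: tuple[float, float] | None = None,
             t_b_ms: float | None = None) -> FRAPFit:
    """Fit a post-bleach recovery with C(t) = C(0)(1 - exp(-t / t_R)).

    If ``t_b_ms`` is given, intensities are first corrected for imaging
    photobleach with the exp(+t/t_b) weighting used for stoichiometry
    (stroboscopic timestamps are taken as given).  Raises on monotonically
    decreasing input (no recovery to fit).
    """
    from scipy.optimize import curve_fit

    t = np.asarray(timepoints_s, dtype=float)
    c = np.asarray(recovery, dtype=float)
    if t_b_ms is not None:
        c = c * np.exp(t * MS_PER_S / t_b_ms)
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach time points")
    order = np.argsort(t)
    t, c = t[order], c[order]
    half = c.size // 2
    if c[half:].mean() < c[:half].mean():
        raise ValueError("recovery decreases with time; not a FRAP recovery")

    def model(t, c0, tr):
        return c0 * (1 - np.exp(-t / tr))

    if p0 is None:
        c0_guess = max(float(c[-max(1, c.size // 5):].mean()), 1e-9)
        # time at half recovery as a scale guess
        above = np.nonzero(c >= 0.5 * c0_guess)[0]
        tr_guess = float(t[above[0]] / np.log(2)) if above.size else t[-1] / 2
        p0 = (c0_guess, max(tr_guess, t[t > 0].min() / 10 if (t > 0).any() else 1e-3))
    popt, pcov = curve_fit(model, t, c, p0=p0,
                           bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10000)
    resid = c - model(t, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return FRAPFit(C0=float(popt[0]), t_R_s=float(popt[1]),
                   residual_sd=float(resid.std(ddof=1)),
                   C0_se=float(se[0]), t_R_se=float(se[1]))
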