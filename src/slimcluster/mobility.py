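"""Track mobility analysis: MSD, CDF mixtures, Gamma fits, anomalous fits.

The microscopic diffusion coefficient of a track is the slope/4 of a line
fitted to the first four points of its time-averaged mean square
displacement, MSD(n dt) = 4 D n dt + 4 sigma^2, with sigma the lateral
localization precision.  Population structure is resolved by fitting the
empirical cumulative distribution of first-step squared displacements to
Brownian mixtures p_c(r^2) = sum_i A_i (1 - exp(-r^2 / 4 D_i dt)), by Gamma
mixtures over per-track D estimates, and by an anomalous-diffusion model
MSD = 4 sigma^2 + 4 K tau^alpha on ensemble-mean MSD curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from slimcluster.core import check_positive

MS_PER_S = 1000.0
NM_PER_UM = 1000.0


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track (or ensemble mean)."""

    tau_ms: np.ndarray
    msd_um2: np.ndarray
    sem_um2: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        self.tau_ms = np.asarray(self.tau_ms, float)
        self.msd_um2 = np.asarray(self.msd_um2, float)
        self.sem_um2 = np.asarray(self.sem_um2, float)
        if np.any(np.diff(self.tau_ms) <= 0):
            raise ValueError("tau must be strictly increasing")


def msd(track, frame_interval_ms: float = 5.0, pixel_size_nm: float = 80.0,
        max_lag: int | None = None) -> MSDCurve:
    """Time-averaged mean square displacement of a track.

    For each lag n the squared displacements over all available start points
    are averaged.  Accepts a :class:`~slimcluster.tracking.Track` or an
    (N, 2) position array in pixels.
    """
    pos = track.positions_px if hasattr(track, "positions_px") else \
        np.asarray(track, dtype=float)
    n = len(pos)
    if n < 5:
        raise ValueError("track too short for MSD (need >= 5 points)")
    pos_um = pos * pixel_size_nm / NM_PER_UM
    if max_lag is None:
        max_lag = n - 1
    max_lag = min(max_lag, n - 1)
    taus, vals, sems = [], [], []
    for lag in range(1, max_lag + 1):
        d = pos_um[lag:] - pos_um[:-lag]
        sq = (d**2).sum(axis=1)
        taus.append(lag * frame_interval_ms)
        vals.append(sq.mean())
        sems.append(sq.std(ddof=1) / np.sqrt(len(sq)) if len(sq) > 1 else 0.0)
    return MSDCurve(np.array(taus), np.array(vals), np.array(sems), n)


def ensemble_msd(tracks, frame_interval_ms: float = 5.0,
                 pixel_size_nm: float = 80.0,
                 max_lag: int | None = None) -> MSDCurve:
    """Mean MSD across tracks, per lag, with SEM across tracks."""
    curves = [msd(t, frame_interval_ms, pixel_size_nm, max_lag)
              for t in tracks]
    n_lags = max(len(c.tau_ms) for c in curves)
    taus = np.arange(1, n_lags + 1) * frame_interval_ms
    vals, sems = [], []
    for i in range(n_lags):
        pts = np.array([c.msd_um2[i] for c in curves if len(c.tau_ms) > i])
        vals.append(pts.mean())
        sems.append(pts.std(ddof=1) / np.sqrt(len(pts)) if len(pts) > 1 else 0.0)
    return MSDCurve(taus, np.array(vals), np.array(sems),
                    sum(len(c.tau_ms) + 1 for c in curves))


def fit_D(msd_curve: MSDCurve, sigma_nm: float = 40.0,
          n_points: int = 4, fix_intercept: bool = False) -> float:
    """Microscopic D (um^2/s) from the first ``n_points`` MSD points.

    D = slope / 4 of a straight-line fit; by default the intercept is free,
    optionally it is pinned to the localization-precision offset 4 sigma^2.
    """
    if len(msd_curve.tau_ms) < n_points:
        raise ValueError(f"need at least {n_points} MSD points")
    t = msd_curve.tau_ms[:n_points] / MS_PER_S  # s
    y = msd_curve.msd_um2[:n_points]
    if fix_intercept:
        offset = 4 * (sigma_nm / NM_PER_UM) ** 2
        slope = np.sum(t * (y - offset)) / np.sum(t * t)
    else:
        slope = np.polyfit(t, y, 1)[0]
    return float(slope / 4)


# ---------------------------------------------------------------------------
# CDF mixture fitting with model selection
# ---------------------------------------------------------------------------

@dataclass
class CDFMixtureFit:
    """A fitted Brownian CDF mixture: weights and diffusion coefficients
    sorted by ascending D, with reduced chi-squared and the selection path."""

    fractions: np.ndarray
    D: np.ndarray
    chi2_reduced: float
    n_components: int
    dt_ms: float
    chi2_path: list[float] = field(default_factory=list)
    converged: bool = True

    def cdf(self, r2_um2) -> np.ndarray:
        r2 = np.asarray(r2_um2, float)
        dt_s = self.dt_ms / MS_PER_S
        out = np.zeros_like(r2, dtype=float)
        for a, d in zip(self.fractions, self.D):
            out += a * (1 - np.exp(-r2 / (4 * d * dt_s)))
        return out

    def summary(self) -> str:
        lines = [f"CDF mixture fit ({self.n_components} component(s)), "
                 f"reduced chi2 = {self.chi2_reduced:.3g}"]
        for i, (a, d) in enumerate(zip(self.fractions, self.D), 1):
            lines.append(f"  component {i}: fraction {a:.3f}, "
                         f"D = {d:.4g} um^2/s")
        return "\n".join(lines)


def _fit_cdf_k(r2_sorted, ecdf, dt_s, k, rng):
    """Least-squares fit of a k-component Brownian CDF mixture.

    Parameters are fitted with uniform weights over all observed r^2; the
    reported chi-squared scales residuals by the binomial sd of the
    empirical CDF, sqrt(F(1-F)/n), so it is ~1 for an adequate model and
    the >10% improvement rule for adding components is meaningful."""
    from scipy.optimize import least_squares

    n_obs = len(r2_sorted)
    f = np.clip(ecdf, 0.5 / n_obs, 1 - 0.5 / n_obs)
    sd = np.sqrt(f * (1 - f) / n_obs)

    # init D from quantile-implied scales
    qs = np.linspace(0.25, 0.9, k)
    r2q = np.quantile(r2_sorted, qs)
    d0 = np.clip(r2q / (4 * dt_s), 1e-6, None)
    w0 = np.zeros(k - 1)

    def unpack(theta):
        logd = theta[:k]
        wfree = theta[k:]
        z = np.concatenate([wfree, [0.0]])
        z = z - z.max()
        w = np.exp(z)
        return w / w.sum(), np.exp(logd)

    def model_cdf(theta):
        w, d = unpack(theta)
        model = np.zeros_like(r2_sorted)
        for a, dd in zip(w, d):
            model += a * (1 - np.exp(-r2_sorted / (4 * dd * dt_s)))
        return model

    def resid(theta):
        return model_cdf(theta) - ecdf

    theta0 = np.concatenate([np.log(d0), w0])
    best, best_cost = None, np.inf
    for attempt in range(3):
        t0 = theta0 if attempt == 0 else theta0 + rng.normal(
            0, 0.5, size=theta0.shape)
        try:
            sol = least_squares(resid, t0, max_nfev=4000)
        except Exception:
            continue
        if sol.cost < best_cost:
            best, best_cost = sol, sol.cost
    if best is None:
        return None
    w, d = unpack(best.x)
    order = np.argsort(d)
    wss = float(np.sum(((model_cdf(best.x) - ecdf) / sd) ** 2))
    n_params = 2 * k - 1
    dof = max(len(r2_sorted) - n_params, 1)
    return w[order], d[order], wss / dof


def fit_cdf_mixture(r2_um2, dt_ms: float = 5.0, max_components: int = 3,
                    improvement: float = 0.10, seed: int = 0,
                    min_component_fraction: float = 0.08,
                    min_d_ratio: float = 2.5) -> CDFMixtureFit:
    """Fit the empirical CDF of first-step r^2 with a Brownian mixture.

    Components are added one at a time (1, 2, then 3); an extra component is
    kept only while it lowers the reduced chi-squared by more than
    ``improvement`` (10% by default) *and* remains identifiable: every
    component must carry at least ``min_component_fraction`` of the weight
    and successive D values must differ by at least ``min_d_ratio`` (mixture
    components closer than that are not resolvable at these sample sizes and
    only absorb ECDF sampling noise).  Requires >= 100 displacements.
    """
    r2 = np.sort(np.asarray(r2_um2, dtype=float))
    if r2.size < 100:
        raise ValueError("need at least 100 first-step displacements")
    if np.ptp(r2) == 0:
        raise ValueError("degenerate displacements: all r^2 identical")
    check_positive(dt_ms=dt_ms)
    ecdf = (np.arange(1, r2.size + 1) - 0.5) / r2.size
    dt_s = dt_ms / MS_PER_S
    rng = np.random.default_rng(seed)

    chosen = None
    chi2_path = []
    converged = True
    for k in range(1, max_components + 1):
        fit = _fit_cdf_k(r2, ecdf, dt_s, k, rng)
        if fit is None:
            converged = False
            break
        w, d, chi2 = fit
        chi2_path.append(chi2)
        if chosen is not None and chi2 > chosen[2] * (1 - improvement):
            break  # improvement below threshold: keep the simpler model
        if k > 1 and (w.min() < min_component_fraction
                      or np.any(d[1:] / d[:-1] < min_d_ratio)):
            break  # extra component not identifiable: keep the simpler model
        chosen = (w, d, chi2, k)
    w, d, chi2, k = chosen
    return CDFMixtureFit(fractions=w, D=d, chi2_reduced=chi2, n_components=k,
                         dt_ms=dt_ms, chi2_path=chi2_path, converged=converged)


# ---------------------------------------------------------------------------
# Gamma mixture over per-track D
# ---------------------------------------------------------------------------

@dataclass
class GammaFit:
    """Two-component Gamma mixture over microscopic D estimates.

    Each component has density (m/D_i)^m x^(m-1) exp(-m x / D_i) / (m-1)!,
    the sampling distribution of a D estimate averaged over m MSD steps.
    """

    fractions: np.ndarray
    D: np.ndarray
    m: int
    chi2_reduced: float
    converged: bool = True

    def pdf(self, x) -> np.ndarray:
        from scipy.special import factorial

        x = np.asarray(x, float)
        out = np.zeros_like(x)
        for a, d in zip(self.fractions, self.D):
            out += a * (self.m / d) ** self.m * x ** (self.m - 1) * \
                np.exp(-self.m * x / d) / factorial(self.m - 1)
        return out

    def summary(self) -> str:
        comps = ", ".join(f"(A={a:.3f}, D={d:.3g})"
                          for a, d in zip(self.fractions, self.D))
        return (f"Gamma mixture (m={self.m}): {comps}; "
                f"reduced chi2 = {self.chi2_reduced:.3g}")


def fit_gamma_mixture(d_values, m: int = 4, n_components: int = 2,
                      n_bins: int = 40, seed: int = 0) -> GammaFit:
    """Least-squares Gamma-mixture fit to the distribution of D estimates.

    ``m`` is the number of MSD steps used per D estimate (4 by default),
    fixing the Gamma shape.  Falls back to a single component when the
    mixture fit does not converge.
    """
    from scipy.optimize import least_squares

    d = np.asarray(d_values, dtype=float)
    d = d[np.isfinite(d) & (d > 0)]
    if d.size < 100:
        raise ValueError("need at least 100 D estimates")
    if m < 2 and n_components > 1:
        pass  # m=1 exponential mixture is allowed
    hist, edges = np.histogram(d, bins=n_bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def mix_pdf(theta, k):
        logd = theta[:k]
        wfree = theta[k:]
        z = np.concatenate([wfree, [0.0]])
        z = z - z.max()
        w = np.exp(z)
        w = w / w.sum()
        return w, np.exp(logd)

    def resid(theta, k):
        w, dd = mix_pdf(theta, k)
        fit = GammaFit(w, dd, m, 0.0)
        return fit.pdf(centers) - hist

    rng = np.random.default_rng(seed)
    result = None
    for k in (n_components, 1):
        qs = np.linspace(0.3, 0.8, k)
        theta0 = np.concatenate([np.log(np.quantile(d, qs)), np.zeros(k - 1)])
        best, best_cost = None, np.inf
        for attempt in range(3):
            t0 = theta0 if attempt == 0 else theta0 + rng.normal(
                0, 0.4, size=theta0.shape)
            try:
                sol = least_squares(resid, t0, args=(k,), max_nfev=4000)
            except Exception:
                continue
            if sol.success and sol.cost < best_cost:
                best, best_cost = sol, sol.cost
        if best is not None:
            w, dd = mix_pdf(best.x, k)
            order = np.argsort(dd)
            dof = max(len(centers) - (2 * k - 1), 1)
            chi2 = float(2 * best.cost / dof)
            result = GammaFit(w[order], dd[order], m, chi2,
                              converged=(k == n_components))
            break
    if result is None:
        raise RuntimeError("Gamma mixture fit failed to converge")
    return result


# ---------------------------------------------------------------------------
# anomalous diffusion
# ---------------------------------------------------------------------------

@dataclass
class AnomalousFit:
    """Precision-corrected anomalous-diffusion fit MSD = 4 sigma^2 +
    4 K tau^alpha, with the Brownian special case (alpha = 1) for
    comparison."""

    K: float
    alpha: float
    sigma_nm: float
    chi2: float
    K_brownian: float
    chi2_brownian: float

    def summary(self) -> str:
        return (f"anomalous fit: K = {self.K:.4g} um^2/s^alpha, "
                f"alpha = {self.alpha:.3f}, chi2 = {self.chi2:.3g} "
                f"(Brownian chi2 = {self.chi2_brownian:.3g})")


def fit_anomalous(msd_curve: MSDCurve, sigma_nm: float = 40.0,
                  max_tau_ms: float = 30.0) -> AnomalousFit:
    """Fit MSD(tau) = 4 sigma^2 + 4 K tau^alpha over tau <= ``max_tau_ms``.

    K is in um^2/s^alpha with tau in seconds.  The Brownian restriction
    alpha = 1 is also fitted and its chi-squared reported.
    """
    from scipy.optimize import curve_fit

    sel = msd_curve.tau_ms <= max_tau_ms
    t = msd_curve.tau_ms[sel] / MS_PER_S
    y = msd_curve.msd_um2[sel]
    if t.size < 4:
        raise ValueError("need at least 4 MSD points within the time window")
    offset = 4 * (sigma_nm / NM_PER_UM) ** 2
    y_corr = y - offset
    if np.any(y_corr <= 0):
        raise ValueError("MSD below the localization-precision floor after "
                         "correction")

    # log-log linear init
    slope, logk = np.polyfit(np.log(t), np.log(y_corr / 4), 1)
    alpha0 = float(np.clip(slope, 0.05, 1.0))
    k0 = float(np.exp(logk))

    def model(t, k, a):
        return offset + 4 * k * t**a

    popt, _ = curve_fit(model, t, y, p0=[k0, alpha0],
                        bounds=([1e-9, 1e-3], [np.inf, 1.0]), maxfev=5000)
    chi2 = float(np.sum((model(t, *popt) - y) ** 2))

    kb = float(np.sum(t * y_corr) / np.sum(t * t) / 4)
    chi2_b = float(np.sum((offset + 4 * kb * t - y) ** 2))
    return AnomalousFit(K=float(popt[0]), alpha=float(popt[1]),
                        sigma_nm=sigma_nm, chi2=chi2,
                        K_brownian=kb, chi2_brownian=chi2_b)
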