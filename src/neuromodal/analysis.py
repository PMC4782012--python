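"""Post-processing of simulation recordings.

Weighted linear fits of converged weight ratios against programmed
amplitude ratios, exponential convergence time constants, peak-sampled
deflection ratios, principal-component extraction of joint trajectories,
jump-apex statistics of the hopping leg, the energy inserted per actuation
cycle, and the one-sided F-test (with its assumption checks) used to
compare apex-height fluctuation between network sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "FitResult",
    "JumpSeries",
    "weighted_linear_fit",
    "exp_time_constant",
    "peak_deflection_ratio",
    "dominant_principal_component",
    "jump_metrics",
    "plateau_ratios",
    "inserted_energy",
    "variance_comparison",
]


@dataclass
class FitResult:
    """Slope/intercept of a (weighted) linear fit with adjusted R^2."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r2_adj: float
    residuals: np.ndarray


def weighted_linear_fit(x, y, sigma_y=None) -> FitResult:
    """Weighted least-squares line fit minimizing ``sum(((y-mx-b)/sigma)^2)``.

    ``sigma_y`` are per-point standard deviations (equal weights if
    omitted); with equal weights the result reduces exactly to ordinary
    least squares.  Requires at least three points and non-degenerate x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    if sigma_y is None:
        sigma_y = np.ones_like(y)
    sigma_y = np.asarray(sigma_y, dtype=float)
    if np.any(sigma_y <= 0):
        raise ValueError("sigma_y must be positive")
    wt = 1.0 / sigma_y**2
    # closed-form weighted normal equations
    S = wt.sum()
    Sx = (wt * x).sum()
    Sy = (wt * y).sum()
    Sxx = (wt * x * x).sum()
    Sxy = (wt * x * y).sum()
    delta = S * Sxx - Sx * Sx
    slope = (S * Sxy - Sx * Sy) / delta
    intercept = (Sxx * Sy - Sx * Sxy) / delta
    slope_se = np.sqrt(S / delta)
    intercept_se = np.sqrt(Sxx / delta)
    resid = y - slope * x - intercept
    # adjusted R^2 on the weighted residuals
    ybar = Sy / S
    ss_res = (wt * resid**2).sum()
    ss_tot = (wt * (y - ybar) ** 2).sum()
    n, k = x.size, 1
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)
    return FitResult(float(slope), float(intercept), float(slope_se),
                     float(intercept_se), float(r2_adj), resid)


def exp_time_constant(t, y, return_full: bool = False):
    """Fit ``y(t) = y_inf + (y_0 - y_inf) exp(-t/tau)`` and return tau (s).

    Raises ``ValueError`` for degenerate (constant) signals and
    ``RuntimeError`` if the fit does not converge.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(y) < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("constant signal: time constant unidentifiable")

    def model(tt, y_inf, y0, tau):
        return y_inf + (y0 - y_inf) * np.exp(-tt / tau)

    tail = np.mean(y[-max(len(y) // 10, 1):])
    p0 = (tail, y[0], (t[-1] - t[0]) / 3.0)
    try:
        popt, _ = optimize.curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"exponential fit failed to converge: {err}") from err
    if popt[2] <= 0:
        raise RuntimeError("exponential fit returned non-positive tau")
    if return_full:
        return float(popt[2]), {"y_inf": float(popt[0]), "y0": float(popt[1])}
    return float(popt[2])


def _dominant_period(x, dt):
    """Period of the strongest Fourier component (ignoring the mean)."""
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), dt)
    idx = np.argmax(spec[1:]) + 1
    return 1.0 / freqs[idx]


def peak_deflection_ratio(t, phi1, phi2, min_separation: float | None = None):
    """Sample ``phi2/phi1`` at the local maxima of ``phi1``.

    Peaks are strict local maxima separated by at least half the dominant
    period of ``phi1`` (robust against spiking jitter).  Returns
    ``(peak_times, ratios)``; raises ``ValueError`` if no peaks are found.
    """
    t = np.asarray(t, dtype=float)
    phi1 = np.asarray(phi1, dtype=float)
    phi2 = np.asarray(phi2, dtype=float)
    dt = t[1] - t[0]
    if min_separation is None:
        min_separation = 0.5 * _dominant_period(phi1, dt)
    peaks, _ = signal.find_peaks(phi1, distance=max(int(min_separation / dt), 1))
    peaks = peaks[np.abs(phi1[peaks]) > 0]
    if peaks.size == 0:
        raise ValueError("no peaks found in phi1")
    return t[peaks], phi2[peaks] / phi1[peaks]


def dominant_principal_component(traj) -> np.ndarray:
    """First principal component (unit vector) of a multivariate series.

    Mean-centers the samples, computes the sample covariance and returns
    the top eigenvector, oriented into the non-negative orthant when
    possible (weights are non-negative in this controller).
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[0] < 2 or traj.shape[1] < 2:
        raise ValueError("need >= 2 samples of >= 2 dimensions")
    centered = traj - traj.mean(axis=0)
    cov = centered.T @ centered / (traj.shape[0] - 1)
    if np.allclose(cov, 0):
        raise ValueError("zero-variance data")
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    if np.all(v <= 0):
        v = -v
    elif not np.all(v >= 0) and abs(v.min()) > abs(v.max()):
        v = -v
    return v


@dataclass
class JumpSeries:
    """Apex times/heights of the flight phases inside a window."""

    apex_times: np.ndarray
    apex_heights: np.ndarray
    window: tuple[float, float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.apex_heights))

    @property
    def std(self) -> float:
        return float(np.std(self.apex_heights, ddof=1))


def jump_metrics(t, h, contact, window=None, min_flight: float = 0.05) -> JumpSeries:
    """Extract per-flight apex heights of the trunk.

    A jump apex is the maximum of ``h`` within each contiguous airborne
    phase (``contact == False``).  Flight phases shorter than
    ``min_flight`` seconds are stutter rebounds within a landing, not
    jumps, and are discarded (set ``min_flight=0`` to keep everything).
    Raises ``ValueError`` if the window holds no flight phase.
    """
    t = np.asarray(t, dtype=float)
    h = np.asarray(h, dtype=float)
    contact = np.asarray(contact, dtype=bool)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        t, h, contact = t[sel], h[sel], contact[sel]
    else:
        window = (float(t[0]), float(t[-1]))
    airborne = ~contact
    # contiguous airborne runs
    padded = np.concatenate(([False], airborne, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    apex_t, apex_h = [], []
    for a, b in zip(starts, ends):
        if t[b - 1] - t[a] < min_flight:
            continue
        j = a + int(np.argmax(h[a:b]))
        apex_t.append(t[j])
        apex_h.append(h[j])
    if not apex_h:
        raise ValueError("no flight phase in window")
    return JumpSeries(np.array(apex_t), np.array(apex_h), tuple(window))


def plateau_ratios(ratios, mean_heights, tolerance: float = 0.05):
    """Contiguous ratio range whose mean apex height is near the maximum.

    The plateau is the contiguous set of ratios (containing the argmax)
    whose mean jump height is within ``tolerance`` (relative) of the sweep
    maximum.  Returns ``(low_edge, high_edge)``.
    """
    ratios = np.asarray(ratios, dtype=float)
    mean_heights = np.asarray(mean_heights, dtype=float)
    order = np.argsort(ratios)
    ratios, mean_heights = ratios[order], mean_heights[order]
    hmax = mean_heights.max()
    good = mean_heights >= (1.0 - tolerance) * hmax
    i = int(np.argmax(mean_heights))
    lo = i
    while lo > 0 and good[lo - 1]:
        lo -= 1
    hi = i
    while hi < len(ratios) - 1 and good[hi + 1]:
        hi += 1
    return float(ratios[lo]), float(ratios[hi])


def inserted_energy(w, c_f_hat: float, k0: float, k1: float) -> float:
    """Energy inserted per actuation cycle, ``E = c_f^2 (w1^2 k0 + w2^2 k1)/2``.

    With equal joint stiffnesses the inserted energy depends only on
    ``||w||``, so sweeping the weight ratio at fixed norm compares
    movements at constant energy input.
    """
    if k0 <= 0 or k1 <= 0:
        raise ValueError("stiffnesses must be positive")
    w = np.asarray(w, dtype=float)
    return float(0.5 * c_f_hat**2 * (w[0] ** 2 * k0 + w[1] ** 2 * k1))


def variance_comparison(sample_a, sample_b, times_a=None, times_b=None) -> dict:
    """One-sided F-test that ``var(sample_a) > var(sample_b)``.

    Returns the F statistic (ratio of unbiased sample variances), the
    one-sided p-value, and the assumption checks run before the test:
    a Lilliefors normality test and a value-vs-time trend correlation for
    each sample (time indices are used when explicit times are absent).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per sample")
    var_b = np.var(b, ddof=1)
    if var_b == 0:
        raise ValueError("zero variance in denominator sample")
    F = np.var(a, ddof=1) / var_b
    p = stats.f.sf(F, a.size - 1, b.size - 1)
    checks = {}
    for name, sample, tt in (("a", a, times_a), ("b", b, times_b)):
        tt = np.arange(sample.size) if tt is None else np.asarray(tt, dtype=float)
        rho, p_trend = stats.pearsonr(tt, sample)
        _, p_norm = lilliefors(sample, dist="norm")
        checks[name] = {
            "trend_r": float(rho),
            "trend_p": float(p_trend),
            "lilliefors_p": float(p_norm),
        }
    return {"F": float(F), "p": float(p), "checks": checks}
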