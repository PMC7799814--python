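"""Monte-Carlo logistic null-model test for an observed SPD.

The null hypothesis is that long-term population follows logistic growth:
the SPD is fitted with f(τ) = K / (1 + exp(−r·(τ − τ_mid))), τ counted in
years elapsed since the older edge of the analysis window (so r > 0 means
growth toward the present).  ``nsim`` synthetic SPDs are generated under the
fitted curve — calendar years drawn ∝ f, back-sampled through the
calibration curve with lab errors resampled from the observed pool,
recalibrated and summed — and a pointwise 95% envelope is taken.  Calendar
years where the observed SPD escapes the envelope mark growth (above) or
decline (below) beyond logistic expectation; a global p-value compares the
observed total out-of-envelope deviation with the simulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .calibration import CalibrationCurve, density_matrix
from .config import AnalysisConfig
from .errors import FitError, ValidationError
from .spd import SPD


@dataclass
class LogisticFit:
    """Least-squares logistic fit to an SPD."""

    K: float
    r: float
    t_mid: float  # inflection point, cal BP
    rss: float
    boundary: bool = False  # r pinned at a bound (e.g. constant input)
    window: tuple[float, float] | None = None

    def curve(self, grid: np.ndarray) -> np.ndarray:
        """Fitted f evaluated on a cal BP grid."""
        older = self.window[0] if self.window else float(np.max(grid))
        tau = older - np.asarray(grid, dtype=float)
        tau_mid = older - self.t_mid
        return _logistic(tau, self.K, self.r, tau_mid)


@dataclass
class EnvelopeTestResult:
    """Observed SPD against the simulated 95% envelope."""

    grid: np.ndarray
    observed: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    positive_regions: list[tuple[float, float]]
    negative_regions: list[tuple[float, float]]
    global_p: float
    nsim: int
    fit: LogisticFit
    meta: dict = field(default_factory=dict)


def _logistic(tau, K, r, tau_mid):
    return K / (1.0 + np.exp(-r * (tau - tau_mid)))


def fit_logistic(spd: SPD) -> LogisticFit:
    """Fit the logistic null to an observed SPD by least squares.

    Deterministic: initialized at K = max(SPD), r = 0.004 /yr and τ_mid at
    the window midpoint, with r constrained to [0, 1].  When the SPD
    retains padded tails (``ext_grid``), the fit uses them so the model is
    constrained wherever simulated dates will be drawn.
    """
    if spd.ext_grid is not None:
        grid = np.asarray(spd.ext_grid, dtype=float)
        y = np.asarray(spd.ext_value, dtype=float)
    else:
        grid = np.asarray(spd.grid, dtype=float)
        y = np.asarray(spd.value, dtype=float)
    if not np.any(y > 0):
        raise ValidationError("SPD must be positive somewhere")
    older = float(grid[0])
    tau = older - grid
    span = float(tau[-1])
    p0 = (float(y.max()), 0.004, span / 2.0)
    bounds = ([1e-12, 0.0, -span], [np.inf, 1.0, 2.0 * span])
    try:
        popt, _ = curve_fit(_logistic, tau, y, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - scipy convergence failure
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    K, r, tau_mid = (float(v) for v in popt)
    resid = y - _logistic(tau, K, r, tau_mid)
    boundary = r <= 1e-6 or r >= 1.0 - 1e-9
    return LogisticFit(
        K=K,
        r=r,
        t_mid=older - tau_mid,
        rss=float(resid @ resid),
        boundary=boundary,
        window=(older, float(grid[-1])),
    )


def simulate_spd_under_model(
    fit: LogisticFit,
    n_bins: int,
    errors_pool,
    curve: CalibrationCurve,
    config: AnalysisConfig,
    rng: np.random.Generator,
    normalize: bool = False,
) -> SPD:
    """One synthetic SPD of ``n_bins`` dates drawn under the fitted logistic."""
    ext, ext_vals = _simulate_values(fit, n_bins, errors_pool, curve, config, rng, normalize)
    grid = config.grid
    i0 = int(ext[0] - grid[0])
    return SPD(
        grid=grid,
        value=ext_vals[i0 : i0 + grid.size],
        meta={"n_bins": n_bins, "simulated": True, "normalized": normalize},
        ext_grid=ext,
        ext_value=ext_vals,
    )


def _ext_grid(config, curve) -> np.ndarray:
    """Window grid padded by the collection margin, clipped to curve span."""
    grid = config.grid
    cal, _, _ = curve.fine_grid()
    older = min(float(grid[0]) + config.simulation_pad, float(cal[-1]))
    younger = max(float(grid[-1]) - config.simulation_pad, float(cal[0]))
    return np.arange(older, younger - 1, -1)


def _simulate_values(fit, n_bins, errors_pool, curve, config, rng, normalize):
    """Simulated SPD values on the padded grid (grid, values).

    Calendar years are drawn over the padded grid so the simulated SPD has
    the same edge mass as an observed SPD built from a broader collection
    window.
    """
    errors_pool = np.asarray(errors_pool, dtype=float)
    if errors_pool.size == 0 or np.any(errors_pool <= 0):
        raise ValidationError("errors_pool must be non-empty and positive")
    ext = _ext_grid(config, curve)
    f = fit.curve(ext)
    p = f / f.sum()
    thetas = rng.choice(ext, size=n_bins, p=p)
    m = curve.c14_at(thetas)
    s = curve.sigma_at(thetas)
    cras = m + rng.normal(0.0, 1.0, size=n_bins) * s
    errs = rng.choice(errors_pool, size=n_bins, replace=True)
    vals = density_matrix(cras, errs, curve, ext, normalize=normalize).sum(axis=0)
    return ext, vals


def deviation_statistic(observed, lo, hi) -> float:
    """Total out-of-envelope mass: Σ max(0, obs−hi) + max(0, lo−obs)."""
    observed = np.asarray(observed, dtype=float)
    return float(np.clip(observed - hi, 0, None).sum() + np.clip(lo - observed, 0, None).sum())


def exceedance_regions(grid, observed, lo, hi) -> tuple[list, list]:
    """Maximal year intervals where the observed SPD escapes the envelope.

    Returned as (older, younger) cal BP pairs, positive (above hi) and
    negative (below lo) separately.
    """
    return (
        _runs(grid, np.asarray(observed) > np.asarray(hi)),
        _runs(grid, np.asarray(observed) < np.asarray(lo)),
    )


def _runs(grid, mask) -> list[tuple[float, float]]:
    grid = np.asarray(grid, dtype=float)
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    for a, b in zip(starts, ends):
        out.append((float(grid[a]), float(grid[b])))
    return out


def model_test(
    spd: SPD,
    curve: CalibrationCurve,
    errors_pool,
    config: AnalysisConfig | None = None,
    rng: np.random.Generator | None = None,
    nsim: int | None = None,
    fit: LogisticFit | None = None,
) -> EnvelopeTestResult:
    """Logistic null-model envelope test of an observed SPD.

    The envelope is the pointwise (100−level)/2 and 100−(100−level)/2
    percentiles of ``nsim`` simulations; the global p-value is
    (1 + #{S_sim ≥ S_obs}) / (nsim + 1) with every simulated statistic
    measured against the pooled envelope.
    """
    config = config or AnalysisConfig()
    rng = rng if rng is not None else np.random.default_rng()
    nsim = int(nsim if nsim is not None else config.nsim)
    if nsim < 20:
        raise ValidationError("nsim < 20 cannot support a 95% envelope")
    if fit is None:
        fit = fit_logistic(spd)
    n_bins = int(spd.meta.get("n_bins", 0)) or 1
    normalize = bool(spd.meta.get("normalized", False))
    sims = np.empty((nsim, spd.grid.size))
    for i in range(nsim):
        ext, ext_vals = _simulate_values(fit, n_bins, errors_pool, curve, config, rng, normalize)
        i0 = int(ext[0] - spd.grid[0])
        sims[i] = ext_vals[i0 : i0 + spd.grid.size]
    alpha = (100.0 - config.envelope_level) / 2.0
    lo = np.percentile(sims, alpha, axis=0)
    hi = np.percentile(sims, 100.0 - alpha, axis=0)
    s_obs = deviation_statistic(spd.value, lo, hi)
    s_sim = np.clip(sims - hi, 0, None).sum(axis=1) + np.clip(lo - sims, 0, None).sum(axis=1)
    global_p = (1.0 + int(np.sum(s_sim >= s_obs))) / (nsim + 1.0)
    pos, neg = exceedance_regions(spd.grid, spd.value, lo, hi)
    return EnvelopeTestResult(
        grid=spd.grid,
        observed=np.asarray(spd.value, dtype=float),
        lo=lo,
        hi=hi,
        positive_regions=pos,
        negative_regions=neg,
        global_p=global_p,
        nsim=nsim,
        fit=fit,
        meta={"s_obs": s_obs, "n_bins": n_bins},
    )
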