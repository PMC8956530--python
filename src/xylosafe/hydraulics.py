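"""Xylem vulnerability curves from flow-centrifuge conductivity series.

The curve model is a logistic ("sigmoidal") loss of specific conductivity
with xylem pressure, fitted directly on the conductivity scale rather
than on percent loss of conductivity (PLC).  For branch *j* measured at
rotor pressures :math:`\\Psi_i` (MPa, negative):

.. math::

    K_{ij} = K_{\\max,j}\\left(1 - \\frac{1}
             {1 + \\exp\\!\\big(s_j(\\Psi_i - P_{50,j})\\big)}\\right)

where :math:`K_{\\max}` is the conductivity of the fully functional
segment, :math:`P_{50}` the pressure at 50 % loss and *s* the slope of
the loss curve on the logit scale (MPa⁻¹).  Pressures at other loss
quantiles follow in closed form:
:math:`\\Psi_q = P_{50} + \\ln((1-q)/q)/s`, giving P12 and P88.

Fitting is ordinary nonlinear least squares (trust-region reflective
with analytic Jacobian); uncertainty comes from the asymptotic
covariance and, where requested, from a case-resampling bootstrap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit

from xylosafe.errors import ConfigurationError, DomainError, FitError, InputError

__all__ = [
    "CavitronSeries",
    "VCFit",
    "BootstrapBands",
    "loss_fraction",
    "conductivity",
    "pressure_at_loss",
    "fit_vulnerability_curve",
    "bootstrap_vc",
    "compare_groups_kruskal",
]

MIN_POINTS = 5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CavitronSeries:
    """One branch segment's (pressure, conductivity) series.

    Pressures are xylem water potentials in MPa (strictly negative,
    ordered from least to most negative, i.e. non-increasing);
    conductivities are non-negative, in kg m⁻¹ MPa⁻¹ s⁻¹ when the series
    is expressed as specific conductivity.
    """

    branch_id: str
    pressure: np.ndarray
    conductivity: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pressure, dtype=float)
        k = np.asarray(self.conductivity, dtype=float)
        object.__setattr__(self, "pressure", p)
        object.__setattr__(self, "conductivity", k)
        if p.ndim != 1 or k.ndim != 1 or p.size != k.size:
            raise InputError("pressure and conductivity must be equal-length 1-d arrays")
        if p.size < MIN_POINTS:
            raise InputError(
                f"series {self.branch_id!r} has {p.size} points; at least {MIN_POINTS} required"
            )
        if not np.all(np.isfinite(p)) or not np.all(np.isfinite(k)):
            raise InputError(f"series {self.branch_id!r} contains non-finite values")
        if np.any(p >= 0):
            raise InputError(f"series {self.branch_id!r}: pressures must be strictly negative")
        if np.any(np.diff(p) > 0):
            raise InputError(
                f"series {self.branch_id!r}: pressures must be ordered least to most negative"
            )
        if np.any(k < 0):
            raise InputError(f"series {self.branch_id!r}: conductivities must be non-negative")

    def __len__(self) -> int:
        return int(self.pressure.size)


@dataclass
class VCFit:
    """Fitted vulnerability-curve parameters for one branch."""

    branch_id: str
    kmax: float
    p50: float
    slope: float
    p12: float
    p88: float
    se_kmax: float
    se_p50: float
    se_slope: float
    converged: bool
    rss: float
    n: int
    identifiable: bool = True

    def predict(self, pressure) -> np.ndarray:
        """Expected conductivity at the given pressures (MPa)."""
        return conductivity(pressure, self.kmax, self.p50, self.slope)


@dataclass
class BootstrapBands:
    """Percentile bootstrap uncertainty for a vulnerability curve."""

    branch_id: str
    n_replicates: int
    n_failed: int
    ci_kmax: tuple[float, float]
    ci_p50: tuple[float, float]
    ci_slope: tuple[float, float]
    ci_p12: tuple[float, float]
    ci_p88: tuple[float, float]
    band_pressure: np.ndarray = field(repr=False)
    band_loss_lower: np.ndarray = field(repr=False)
    band_loss_upper: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def loss_fraction(pressure, p50, slope):
    """Fractional loss of conductivity L(Ψ) = 1 / (1 + exp(s (Ψ − P50))).

    Vectorized over ``pressure``.  ``slope`` must be positive; loss runs
    from 0 at lax (near-zero) pressures to 1 at very negative pressures.
    """
    pressure = np.asarray(pressure, dtype=float)
    if not np.all(np.isfinite(pressure)):
        raise DomainError("pressure must be finite")
    if not (np.isfinite(p50) and np.isfinite(slope)):
        raise DomainError("p50 and slope must be finite")
    if slope <= 0:
        raise DomainError(f"slope must be positive, got {slope}")
    # expit(-x) = 1/(1+e^x), numerically stable at both tails
    out = expit(-slope * (pressure - p50))
    return out if out.ndim else float(out)


def conductivity(pressure, kmax, p50, slope):
    """Expected conductivity K(Ψ) = Kmax · (1 − L(Ψ))."""
    return kmax * (1.0 - loss_fraction(pressure, p50, slope))


def pressure_at_loss(p50: float, slope: float, q: float) -> float:
    """Pressure at which the modelled loss equals ``q``.

    Closed form of inverting the logistic:
    Ψ_q = P50 + ln((1 − q)/q) / s.  q = 0.12 gives P12, q = 0.88 gives
    P88 and q = 0.5 returns P50 itself.
    """
    if not (0.0 < q < 1.0):
        raise DomainError(f"loss quantile must be in (0, 1), got {q}")
    if slope <= 0:
        raise DomainError(f"slope must be positive, got {slope}")
    return p50 + math.log((1.0 - q) / q) / slope


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _initial_guess(psi: np.ndarray, k: np.ndarray) -> tuple[float, float, float]:
    """Deterministic starting values.

    Kmax₀ is the maximum observed conductivity; P50₀ the pressure where
    the observations first cross Kmax₀/2 (linear interpolation); s₀ the
    slope of a logit-linear regression through the interior points.
    """
    kmax0 = float(np.max(k))
    half = kmax0 / 2.0
    p50_0 = float(psi[-1])
    below = np.nonzero(k < half)[0]
    if below.size:
        i = int(below[0])
        if i == 0:
            p50_0 = float(psi[0])
        else:
            k_hi, k_lo = k[i - 1], k[i]
            t = (k_hi - half) / (k_hi - k_lo) if k_hi != k_lo else 0.5
            p50_0 = float(psi[i - 1] + t * (psi[i] - psi[i - 1]))
    # logit-linearized slope from interior losses
    loss = 1.0 - np.clip(k / kmax0, 1e-9, 1.0 - 1e-9)
    interior = (loss > 0.01) & (loss < 0.99)
    s0 = 2.0
    if interior.sum() >= 2:
        x = psi[interior]
        y = np.log(loss[interior] / (1.0 - loss[interior]))
        denom = np.sum((x - x.mean()) ** 2)
        if denom > 0:
            s0 = float(-np.sum((x - x.mean()) * (y - y.mean())) / denom)
    s0 = float(np.clip(s0, 0.2, 20.0))
    return kmax0, p50_0, s0


def _residuals_and_jac(psi: np.ndarray, k: np.ndarray):
    def resid(theta):
        kmax, p50, s = theta
        L = expit(-s * (psi - p50))
        return kmax * (1.0 - L) - k

    def jac(theta):
        kmax, p50, s = theta
        L = expit(-s * (psi - p50))
        w = L * (1.0 - L)
        J = np.empty((psi.size, 3))
        J[:, 0] = 1.0 - L
        J[:, 1] = -kmax * s * w
        J[:, 2] = kmax * w * (psi - p50)
        return J

    return resid, jac


def fit_vulnerability_curve(
    series: CavitronSeries,
    *,
    xtol: float = 1e-12,
    ftol: float = 1e-12,
    max_restarts: int = 5,
    restart_seed: int = 0,
) -> VCFit:
    """Least-squares fit of (Kmax, P50, s) to one cavitron series.

    Minimizes Σ(K_obs − K_model)² with a trust-region-reflective solver,
    analytic Jacobian and the deterministic starts of
    :func:`_initial_guess`.  On failure the start is jittered up to
    ``max_restarts`` times (seeded) before a :class:`FitError` is raised.

    A series with no observation below half the maximum observed
    conductivity cannot pin down P50; the fit proceeds but the result is
    flagged ``identifiable=False``.
    """
    psi = series.pressure
    k = series.conductivity
    identifiable = bool(np.any(k < 0.5 * np.max(k)))

    resid, jac = _residuals_and_jac(psi, k)
    theta0 = np.array(_initial_guess(psi, k))
    lower = np.array([1e-12, psi.min() * 10.0, 1e-6])
    upper = np.array([np.inf, -1e-9, 1e3])
    theta0 = np.clip(theta0, lower * 1.0000001 + 1e-15, upper - 1e-12)

    rng = np.random.default_rng(restart_seed)
    attempts = []
    sol = None
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else np.clip(
            theta0 * rng.uniform(0.7, 1.3, size=3), lower + 1e-12, upper - 1e-9
        )
        res = optimize.least_squares(
            resid, start, jac=jac, bounds=(lower, upper), xtol=xtol, ftol=ftol, gtol=1e-12
        )
        attempts.append({"start": start.tolist(), "status": res.status, "cost": float(res.cost)})
        if res.success:
            sol = res
            break
    if sol is None:
        raise FitError(
            f"vulnerability-curve fit failed for {series.branch_id!r} "
            f"after {max_restarts} restarts",
            diagnostics={"attempts": attempts},
        )

    kmax, p50, s = (float(v) for v in sol.x)
    rss = float(2.0 * sol.cost)
    n = psi.size
    dof = max(n - 3, 1)
    # asymptotic covariance from the Jacobian at the optimum
    J = jac(sol.x)
    try:
        cov = np.linalg.inv(J.T @ J) * (rss / dof)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)

    return VCFit(
        branch_id=series.branch_id,
        kmax=kmax,
        p50=p50,
        slope=s,
        p12=pressure_at_loss(p50, s, 0.12),
        p88=pressure_at_loss(p50, s, 0.88),
        se_kmax=float(se[0]),
        se_p50=float(se[1]),
        se_slope=float(se[2]),
        converged=True,
        rss=rss,
        n=int(n),
        identifiable=identifiable,
    )


def _refit_resampled(series: CavitronSeries, fit: VCFit, idx: np.ndarray):
    """Single bootstrap replicate fit, warm-started at the point estimate."""
    psi = series.pressure[idx]
    k = series.conductivity[idx]
    resid, jac = _residuals_and_jac(psi, k)
    lower = np.array([1e-12, series.pressure.min() * 10.0, 1e-6])
    upper = np.array([np.inf, -1e-9, 1e3])
    start = np.clip(np.array([fit.kmax, fit.p50, fit.slope]), lower + 1e-12, upper - 1e-9)
    # warm start + modest tolerances: percentile endpoints are insensitive
    # far below the Monte-Carlo resolution of the replicate ensemble
    res = optimize.least_squares(
        resid, start, jac=jac, bounds=(lower, upper), xtol=1e-8, ftol=1e-8, max_nfev=60
    )
    return res.x if res.success else None


def bootstrap_vc(
    series: CavitronSeries,
    fit: VCFit,
    B: int = 1000,
    seed: int | None = None,
    n_grid: int = 50,
) -> BootstrapBands:
    """Case-resampling (pairs) bootstrap of a fitted vulnerability curve.

    Resamples (Ψ, K) pairs with replacement, refits each replicate from
    the original point estimate, and returns percentile 95 % intervals
    for the parameters plus a pointwise 95 % band of predicted loss over
    the observed pressure range.  Replicates that fail to converge are
    dropped and counted.
    """
    if not fit.converged:
        raise FitError("bootstrap requires a converged vulnerability-curve fit")
    if B < 100:
        warnings.warn(
            f"bootstrap with B={B} replicates gives unstable percentile intervals",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = len(series)
    grid = np.linspace(series.pressure[0], series.pressure[-1], n_grid)

    params = np.empty((B, 3))
    n_failed = 0
    kept = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        theta = _refit_resampled(series, fit, idx)
        if theta is None:
            n_failed += 1
            continue
        params[kept] = theta
        kept += 1
    if kept == 0:
        raise FitError("every bootstrap replicate failed to converge")
    params = params[:kept]

    def ci(values):
        lo, hi = np.percentile(values, [2.5, 97.5])
        return float(lo), float(hi)

    p12s = params[:, 1] + math.log(0.88 / 0.12) / params[:, 2]
    p88s = params[:, 1] + math.log(0.12 / 0.88) / params[:, 2]
    losses = np.array([loss_fraction(grid, p50, s) for _, p50, s in params])
    lo_band, hi_band = np.percentile(losses, [2.5, 97.5], axis=0)

    return BootstrapBands(
        branch_id=series.branch_id,
        n_replicates=kept,
        n_failed=n_failed,
        ci_kmax=ci(params[:, 0]),
        ci_p50=ci(params[:, 1]),
        ci_slope=ci(params[:, 2]),
        ci_p12=ci(p12s),
        ci_p88=ci(p88s),
        band_pressure=grid,
        band_loss_lower=lo_band,
        band_loss_upper=hi_band,
    )


# ---------------------------------------------------------------------------
# treatment comparison
# ---------------------------------------------------------------------------

def compare_groups_kruskal(values_a, values_b) -> tuple[float, float]:
    """Kruskal–Wallis H test between two trait groups.

    Used to compare curve parameters (slope, P50) of flushed versus
    non-flushed branch samples.  Returns (H, p); H is tie-corrected and
    p comes from the χ² distribution with 1 degree of freedom.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        raise DomainError("all values identical across both groups; H is undefined")
    h, p = stats.kruskal(a, b)
    return float(h), float(p)
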