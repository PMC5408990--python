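"""The multiplicative polygenic model for carrier risk stratification.

Disease hazard is modelled as ``lambda(t | z) = lambda_0(t) * exp(beta(t) z)``
with ``z`` the standardized PRS, normally distributed across carriers, so
the relative risk is lognormal.  Two directions are implemented:

* forward — given a baseline hazard and per-SD effect, the *marginal*
  hazard among surviving carriers (:func:`marginal_hazard`);
* inverse — given the known average carrier incidence ``lambda_bar(t)``,
  the baseline ``lambda_0(t)`` consistent with it
  (:func:`constrained_baseline`), which pins down absolute cumulative
  risk (penetrance) curves at any PRS percentile.

Also provides the theoretical percentile-category hazard ratios of the
model (truncated-lognormal expectations) and threshold arithmetic: the age
at which a percentile's cumulative risk crosses a threshold, and the
fraction of carriers below a risk threshold at a given age.

The per-SD log hazard ratio ``beta`` may be constant, piecewise by age
band (``{(lo, hi): value}``), or any callable of age, supporting
age-decaying PRS effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import optimize, stats

from .incidence import IncidenceCurve

_GH_NODES = 64

BetaLike = Union[float, dict, "callable"]


def _beta_on_grid(beta: BetaLike, midpoints: np.ndarray) -> np.ndarray:
    """Per-SD log HR evaluated on interval midpoints of the age grid."""
    if callable(beta):
        return np.array([float(beta(t)) for t in midpoints])
    if isinstance(beta, dict):
        out = np.full(midpoints.shape, np.nan)
        for (lo, hi), value in beta.items():
            out[(midpoints >= lo) & (midpoints < hi)] = float(value)
        if np.isnan(out).any():
            t = midpoints[np.isnan(out)][0]
            raise ValueError(f"age {t:g} not covered by any beta band")
        return out
    return np.full(midpoints.shape, float(beta))


def _gauss_hermite_standard_normal(n: int = _GH_NODES):
    """Nodes/weights for E[f(Z)] with Z ~ N(0, 1)."""
    x, w = np.polynomial.hermite.hermgauss(n)
    return x * np.sqrt(2.0), w / np.sqrt(np.pi)


@dataclass(frozen=True)
class PolygenicModelSpec:
    """Per-SD effect + PRS moments + average carrier incidence."""

    beta: BetaLike
    incidence: IncidenceCurve
    prs_mean: float = 0.0
    prs_sd: float = 1.0
    age_start: float = 18.0
    age_stop: float = 80.0
    age_step: float = 1.0

    def __post_init__(self):
        if self.prs_sd <= 0:
            raise ValueError("prs_sd must be positive")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(
            self.age_start, self.age_stop + 0.5 * self.age_step, self.age_step
        )


@dataclass(frozen=True)
class RiskProjection:
    """Cumulative risk by age for one PRS percentile."""

    percentile: float
    age_grid: np.ndarray
    cumulative_risk: np.ndarray


def truncated_exp_moment(beta: float, a: float, b: float) -> float:
    """E[e^{beta Z}; a < Z < b] for standard normal Z (closed form)."""
    return float(
        np.exp(0.5 * beta**2) * (stats.norm.cdf(b - beta) - stats.norm.cdf(a - beta))
    )


def theoretical_category_hr(beta: float, category, reference=(40.0, 60.0)) -> float:
    """Hazard ratio of a PRS percentile category relative to a reference band.

    Baseline (no-depletion) approximation: with Z ~ N(0,1),
    ``E[e^{beta Z} | Z in category] / E[e^{beta Z} | Z in reference]`` where
    the categories are percent intervals mapped through the normal quantile
    function.
    """

    def conditional(interval):
        lo, hi = (np.clip(x / 100.0, 0.0, 1.0) for x in interval)
        if not lo < hi:
            raise ValueError(f"empty percentile interval {interval}")
        a, b = stats.norm.ppf(lo), stats.norm.ppf(hi)
        mass = hi - lo
        return truncated_exp_moment(beta, a, b) / mass

    return conditional(category) / conditional(reference)


def _survival_given_z(lambda0: np.ndarray, beta_grid: np.ndarray, widths, z):
    """S(t_j | z_m) at every grid point (rows) for every node z (cols)."""
    cumhaz = np.concatenate(
        [
            np.zeros((1, z.size)),
            np.cumsum(
                (lambda0 * widths)[:, None] * np.exp(np.outer(beta_grid, z)), axis=0
            ),
        ]
    )
    return np.exp(-cumhaz)


def marginal_hazard(
    lambda0: IncidenceCurve, beta: BetaLike
) -> IncidenceCurve:
    """Average-carrier incidence implied by a baseline hazard and PRS effect.

    The marginal survival is ``S_bar(t) = E_z[S(t | z)]``; the returned
    curve is its hazard, piecewise constant on the baseline's grid:
    ``lambda_bar_j = -log(S_bar(t_{j+1}) / S_bar(t_j)) / dt_j``.
    """
    grid = lambda0.age
    widths = np.diff(grid)
    if widths.size == 0:
        raise ValueError("baseline grid needs at least two points")
    mids = grid[:-1] + widths / 2
    beta_grid = _beta_on_grid(beta, mids)
    z, w = _gauss_hermite_standard_normal()
    S = _survival_given_z(lambda0.hazard[:-1], beta_grid, widths, z)
    Sbar = S @ w
    haz = -np.diff(np.log(Sbar)) / widths
    return IncidenceCurve(grid, np.append(haz, haz[-1]))


def constrained_baseline(spec: PolygenicModelSpec) -> IncidenceCurve:
    """Baseline hazard consistent with the average carrier incidence.

    Solves, interval by interval, for the piecewise-constant
    ``lambda_0`` whose PRS-marginalized survival matches the marginal
    survival of the input incidence at every grid age:

        E_z[ S(t_j | z) ] = exp(-int_18^{t_j} lambda_bar du)   for all j,

    with ``S(t | z) = exp(-int lambda_0 e^{beta z} du)`` and the
    expectation over z ~ N(0,1) taken by 64-node Gauss-Hermite quadrature.
    Each interval is a monotone one-dimensional root solved by Newton steps
    (bisection fallback) to a relative tolerance of 1e-12, which enforces
    the marginal-incidence constraint — and hence conservation of the
    marginalized risk curve — to numerical precision.
    """
    grid = spec.grid
    widths = np.diff(grid)
    mids = grid[:-1] + widths / 2
    beta_grid = _beta_on_grid(spec.beta, mids)
    target_cumhaz = spec.incidence.cumulative_hazard(grid) - spec.incidence.cumulative_hazard(
        grid[0]
    )
    Sbar_target = np.exp(-target_cumhaz)

    z, w = _gauss_hermite_standard_normal()
    lam0 = np.empty(widths.size)
    S = np.ones(z.size)  # S(t_j | z_m) running product
    for j in range(widths.size):
        ez = np.exp(beta_grid[j] * z)
        target = Sbar_target[j + 1]
        num = S @ w
        if target >= num - 1e-15:
            lam0[j] = 0.0
            continue

        def sbar_next(lam):
            return (S * np.exp(-lam * ez * widths[j])) @ w

        # Newton on log-scale residual, bracketed by bisection
        lam = spec.incidence.hazard_at(mids[j]) * np.exp(-0.5 * beta_grid[j] ** 2)
        lam = max(float(lam), 1e-12)
        lo, hi = 0.0, lam
        while sbar_next(hi) > target:
            hi *= 2.0
            if hi > 1e6:
                raise RuntimeError(
                    f"constrained baseline failed to bracket at age {grid[j]:g}"
                )
        lam = min(max(lam, lo), hi)
        for _ in range(100):
            Snew = S * np.exp(-lam * ez * widths[j])
            f = Snew @ w - target
            if f > 0:
                lo = lam
            else:
                hi = lam
            fprime = -((Snew * ez * widths[j]) @ w)
            step = f / fprime
            lam_new = lam - step
            if not lo < lam_new < hi:
                lam_new = 0.5 * (lo + hi)
            if abs(lam_new - lam) <= 1e-12 * max(lam, 1e-12):
                lam = lam_new
                break
            lam = lam_new
        else:
            raise RuntimeError(
                f"constrained baseline did not converge at age {grid[j]:g}"
            )
        lam0[j] = lam
        S = S * np.exp(-lam * ez * widths[j])
    return IncidenceCurve(grid, np.append(lam0, lam0[-1]))


def risk_at_percentile(
    spec: PolygenicModelSpec, percentile: float, baseline: IncidenceCurve = None
) -> RiskProjection:
    """Absolute cumulative risk curve at the PRS percentile's point quantile.

    ``F(t | z_p) = 1 - exp(-int lambda_0(u) e^{beta(u) z_p} du)`` with
    ``z_p`` the standard-normal quantile of the percentile.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if baseline is None:
        baseline = constrained_baseline(spec)
    grid = spec.grid
    widths = np.diff(grid)
    mids = grid[:-1] + widths / 2
    beta_grid = _beta_on_grid(spec.beta, mids)
    z_p = stats.norm.ppf(percentile / 100.0)
    cumhaz = np.concatenate(
        [[0.0], np.cumsum(baseline.hazard[:-1] * widths * np.exp(beta_grid * z_p))]
    )
    return RiskProjection(percentile, grid, 1.0 - np.exp(-cumhaz))


def age_reaching_risk(
    spec: PolygenicModelSpec,
    percentile: float,
    risk_threshold: float,
    baseline: IncidenceCurve = None,
) -> float:
    """Age at which the percentile's cumulative risk crosses the threshold.

    Linear interpolation on the grid; returns ``inf`` (with a warning) if
    the threshold is never attained.
    """
    proj = risk_at_percentile(spec, percentile, baseline=baseline)
    F = proj.cumulative_risk
    if risk_threshold > F[-1]:
        import warnings

        warnings.warn(
            f"risk threshold {risk_threshold:g} never attained by age "
            f"{proj.age_grid[-1]:g} at percentile {percentile:g}",
            stacklevel=2,
        )
        return float("inf")
    j = int(np.searchsorted(F, risk_threshold, side="left"))
    if j == 0:
        return float(proj.age_grid[0])
    t0, t1 = proj.age_grid[j - 1], proj.age_grid[j]
    f0, f1 = F[j - 1], F[j]
    if f1 == f0:
        return float(t1)
    return float(t0 + (risk_threshold - f0) / (f1 - f0) * (t1 - t0))


def risk_quantile_share(
    spec: PolygenicModelSpec,
    age: float,
    risk_threshold: float,
    baseline: IncidenceCurve = None,
) -> float:
    """Fraction of carriers whose cumulative risk at ``age`` is below threshold.

    ``F(age | z)`` is monotone in z, so the share is ``Phi(z*)`` (or its
    complement for a protective effect) with ``F(age | z*) = r`` found by
    bisection; 0 or 1 when the threshold is outside the attainable range.
    """
    if baseline is None:
        baseline = constrained_baseline(spec)
    grid = spec.grid
    widths = np.diff(grid)
    mids = grid[:-1] + widths / 2
    beta_grid = _beta_on_grid(spec.beta, mids)
    keep = grid[1:] <= age + 1e-9
    eff = baseline.hazard[:-1][keep] * widths[keep]
    partial = 0.0
    j = int(keep.sum())
    if j < widths.size and grid[j] < age:
        partial = baseline.hazard[j] * (age - grid[j])

    def risk_given_z(z):
        cum = float(np.sum(eff * np.exp(beta_grid[keep] * z)))
        if partial:
            cum += partial * np.exp(beta_grid[j] * z)
        return 1.0 - np.exp(-cum)

    increasing = risk_given_z(8.0) >= risk_given_z(-8.0)
    lo_risk = risk_given_z(-8.0 if increasing else 8.0)
    hi_risk = risk_given_z(8.0 if increasing else -8.0)
    if risk_threshold <= lo_risk:
        return 0.0
    if risk_threshold >= hi_risk:
        return 1.0
    zstar = optimize.brentq(
        lambda z: risk_given_z(z) - risk_threshold, -8.0, 8.0, xtol=1e-10
    )
    share = stats.norm.cdf(zstar)
    return float(share if increasing else 1.0 - share)


def project_percentiles(
    spec: PolygenicModelSpec, percentiles
) -> "list[RiskProjection]":
    """Risk curves for several percentiles sharing one baseline solve."""
    baseline = constrained_baseline(spec)
    return [risk_at_percentile(spec, p, baseline=baseline) for p in percentiles]
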