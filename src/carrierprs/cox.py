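"""Weighted Cox partial-likelihood engine and the carrier model battery.

Implements Cox proportional-hazards regression on the age time scale with
delayed entry, sampling weights (the weighted-cohort ascertainment
correction), baseline-hazard strata, Breslow tie handling (Efron behind a
flag), and a cluster sandwich ("robust") covariance aggregated over
families.  Covariates may interact with attained age through
:class:`AgeTerm` columns evaluated at each event age, which is how the
PRS-by-age interaction and the age-group-specific PRS effects are fitted.

The estimator maximizes

    l(b) = sum_events w_i eta_i(t_i) - sum_k d_k log sum_{j in R(t_k)} w_j e^{eta_j(t_k)}

by Newton-Raphson, where ``R(t)`` is the at-risk set ``entry < t <= exit``
and ``d_k`` the weighted event count at ``t_k``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_SEPARATION_BOUND = 40.0


class ConvergenceError(RuntimeError):
    """Newton-Raphson failed; carries the iteration trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


@dataclass(frozen=True)
class AgeTerm:
    """A covariate of the form ``values_i * transform(t)`` at event age t."""

    name: str
    values: np.ndarray
    transform: Callable[[float], float]


@dataclass
class CoxFit:
    """A fitted weighted Cox model (coefficients on the log-HR scale)."""

    terms: list
    params: np.ndarray
    cov: np.ndarray
    robust_cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    gradient_norm: float = float("nan")
    trace: list = field(default_factory=list, repr=False)
    band_contrasts: Optional[pd.DataFrame] = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def summary(self) -> pd.DataFrame:
        """Tidy one-row-per-term table (CIs from the robust SE)."""
        coef = self.params
        rse = self.robust_se
        z = coef / rse
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": coef,
                "se": self.se,
                "robust_se": rse,
                "hr": np.exp(coef),
                "ci_low": np.exp(coef - 1.96 * rse),
                "ci_high": np.exp(coef + 1.96 * rse),
                "p_one_sided": stats.norm.sf(z),
                "p_two_sided": 2 * stats.norm.sf(np.abs(z)),
            }
        )

    def __getitem__(self, term: str) -> float:
        return float(self.params[self.terms.index(term)])


# ----------------------------------------------------------------------
# partial likelihood internals


class _StratumData:
    def __init__(self, t, d, entry, w, X, age_terms):
        self.t, self.d, self.entry, self.w, self.X = t, d, entry, w, X
        self.age_terms = age_terms
        self.n, self.p_fixed = X.shape
        self.p = self.p_fixed + len(age_terms)
        self.te, inv = np.unique(t[d], return_inverse=True)
        self.event_rows = [np.flatnonzero(d)[inv == k] for k in range(self.te.size)]
        self.dk = np.array([w[rows].sum() for rows in self.event_rows])
        if not age_terms:
            self.order_exit = np.argsort(t, kind="stable")
            self.order_entry = np.argsort(entry, kind="stable")
            self.idx_exit = np.searchsorted(t[self.order_exit], self.te, side="left")
            self.idx_entry = np.searchsorted(
                entry[self.order_entry], self.te, side="left"
            )

    def design_at(self, t_k, rows):
        """Covariate matrix for ``rows`` with age terms evaluated at t_k."""
        Z = np.empty((rows.size, self.p))
        Z[:, : self.p_fixed] = self.X[rows]
        for j, term in enumerate(self.age_terms):
            Z[:, self.p_fixed + j] = term.values[rows] * term.transform(t_k)
        return Z


def _suffix(values, order):
    """suffix[i] = sum over sorted positions >= i; len = n + 1."""
    v = values[order]
    out = np.zeros((v.shape[0] + 1,) + v.shape[1:])
    out[:-1] = np.cumsum(v[::-1], axis=0)[::-1]
    return out


def _fast_quantities(s: _StratumData, beta, ties, compute_resid):
    t, d, entry, w, X = s.t, s.d, s.entry, s.w, s.X
    eta = X @ beta if s.p else np.zeros(s.n)
    r = w * np.exp(eta)
    rX = r[:, None] * X
    rXX = X[:, :, None] * rX[:, None, :]

    S0 = _suffix(r, s.order_exit)[s.idx_exit] - _suffix(r, s.order_entry)[s.idx_entry]
    S1 = _suffix(rX, s.order_exit)[s.idx_exit] - _suffix(rX, s.order_entry)[s.idx_entry]
    S2 = (
        _suffix(rXX, s.order_exit)[s.idx_exit]
        - _suffix(rXX, s.order_entry)[s.idx_entry]
    )

    sum_w_eta_events = sum((w[rows] * eta[rows]).sum() for rows in s.event_rows)
    sum_wZ_events = sum((w[rows, None] * X[rows]).sum(axis=0) for rows in s.event_rows)

    Zbar = S1 / S0[:, None]
    ll = -np.sum(s.dk * np.log(S0))
    grad = -(s.dk[:, None] * Zbar).sum(axis=0)
    hess = -np.einsum(
        "k,kab->ab", s.dk, S2 / S0[:, None, None]
    ) + np.einsum("k,ka,kb->ab", s.dk, Zbar, Zbar)
    ll += sum_w_eta_events
    grad = grad + sum_wZ_events

    resid = None
    if compute_resid:
        Zbar = S1 / S0[:, None]
        a = s.dk / S0
        cumA = np.concatenate([[0.0], np.cumsum(a)])
        cumB = np.concatenate(
            [np.zeros((1, s.p)), np.cumsum(a[:, None] * Zbar, axis=0)]
        )
        hi = np.searchsorted(s.te, t, side="right")
        lo = np.searchsorted(s.te, entry, side="right")
        G1 = cumA[hi] - cumA[lo]
        G2 = cumB[hi] - cumB[lo]
        resid = -np.exp(eta)[:, None] * (X * G1[:, None] - G2)
        for k, rows in enumerate(s.event_rows):
            resid[rows] += X[rows] - Zbar[k]
    return ll, grad, hess, resid


def _slow_quantities(s: _StratumData, beta, ties, compute_resid):
    """Per-event-time loop; required when covariates depend on attained age."""
    ll, grad = 0.0, np.zeros(s.p)
    hess = np.zeros((s.p, s.p))
    resid = np.zeros((s.n, s.p)) if compute_resid else None
    for k, t_k in enumerate(s.te):
        at_risk = np.flatnonzero((s.entry < t_k) & (s.t >= t_k))
        Z = s.design_at(t_k, at_risk)
        eta = Z @ beta
        r = s.w[at_risk] * np.exp(eta)
        rows = s.event_rows[k]
        Ze = s.design_at(t_k, rows)
        we = s.w[rows]
        dk = s.dk[k]
        if ties == "efron":
            in_risk = np.searchsorted(at_risk, rows)
            S0D = r[in_risk].sum()
            S1D = (r[in_risk, None] * Z[in_risk]).sum(axis=0)
            S2D = np.einsum("i,ia,ib->ab", r[in_risk], Z[in_risk], Z[in_risk])
            S0 = r.sum()
            S1 = r @ Z
            S2 = np.einsum("i,ia,ib->ab", r, Z, Z)
            m = rows.size
            for l in range(m):
                f = l / m
                s0, s1, s2 = S0 - f * S0D, S1 - f * S1D, S2 - f * S2D
                zbar = s1 / s0
                ll -= (dk / m) * np.log(s0)
                grad -= (dk / m) * zbar
                hess -= (dk / m) * (s2 / s0 - np.outer(zbar, zbar))
            S0_breslow, Zbar = S0, S1 / S0
        else:
            S0_breslow = r.sum()
            S1 = r @ Z
            Zbar = S1 / S0_breslow
            S2 = np.einsum("i,ia,ib->ab", r, Z, Z)
            ll -= dk * np.log(S0_breslow)
            grad -= dk * Zbar
            hess -= dk * (S2 / S0_breslow - np.outer(Zbar, Zbar))
        ll += (we * eta[np.searchsorted(at_risk, rows)]).sum()
        grad += (we[:, None] * Ze).sum(axis=0)
        if compute_resid:
            resid[at_risk] -= (
                np.exp(eta)[:, None] * (dk / S0_breslow) * (Z - Zbar)
            )
            resid[rows] += Ze - Zbar
    return ll, grad, hess, resid


def fit_weighted_cox(
    cohort: pd.DataFrame,
    covariates: Optional[pd.DataFrame] = None,
    weights=None,
    strata=None,
    cluster="family_id",
    age_terms: Optional[Sequence[AgeTerm]] = None,
    ties: str = "breslow",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxFit:
    """Fit a weighted Cox model on the age time scale with delayed entry.

    Parameters
    ----------
    cohort : frame with ``age_end``, ``affected`` and optional ``age_entry``.
    covariates : fixed (time-constant) design columns, aligned by position.
    weights : per-record sampling weights (array, Series, or the frame
        produced by :func:`carrierprs.weighting.build_weights`, joined on
        ``individual_id``); default all 1.
    strata : column name in ``cohort`` (e.g. ``"study"``) or an array of
        labels defining separate baseline hazards; None = one stratum.
    cluster : column name or array of labels for the sandwich covariance
        (default family); None = one cluster per record.
    age_terms : attained-age-interacting covariates evaluated at each
        event age.
    ties : ``"breslow"`` (default) or ``"efron"``.
    """
    n = len(cohort)
    t = cohort["age_end"].to_numpy(float)
    d = cohort["affected"].to_numpy(bool)
    entry = (
        cohort["age_entry"].to_numpy(float)
        if "age_entry" in cohort.columns
        else np.full(n, 18.0)
    )
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")

    X = (
        covariates.to_numpy(float)
        if covariates is not None and covariates.shape[1] > 0
        else np.empty((n, 0))
    )
    names = list(covariates.columns) if covariates is not None else []
    age_terms = list(age_terms or [])
    names += [term.name for term in age_terms]
    p = X.shape[1] + len(age_terms)
    if p == 0:
        raise ValueError("model has no covariates")

    w = _resolve_weights(cohort, weights, n)
    strata_labels = _resolve_labels(cohort, strata, n, default=None)
    cluster_labels = _resolve_labels(cohort, cluster, n, default="__row__")

    # Internal per-column scaling keeps the Newton system well conditioned
    # (an age-interaction column lives on a ~50x larger scale than the PRS);
    # coefficients and covariances are mapped back exactly afterwards.
    t_events_mean = float(t[d].mean())
    scales = np.ones(p)
    for j in range(X.shape[1]):
        s = float(np.std(X[:, j]))
        scales[j] = s if s > 0 else 1.0
    for j, term in enumerate(age_terms):
        s = float(np.std(np.asarray(term.values, float))) * max(
            1.0, abs(float(term.transform(t_events_mean)))
        )
        scales[X.shape[1] + j] = s if s > 0 else 1.0
    X = X / scales[: X.shape[1]]
    age_terms = [
        AgeTerm(
            term.name,
            np.asarray(term.values, float) / scales[X.shape[1] + j],
            term.transform,
        )
        for j, term in enumerate(age_terms)
    ]

    strata_data = []
    for label in (
        [None] if strata_labels is None else np.unique(strata_labels)
    ):
        rows = (
            np.arange(n)
            if strata_labels is None
            else np.flatnonzero(strata_labels == label)
        )
        if not d[rows].any():
            continue  # stratum contributes no events
        sd = _StratumData(
            t[rows],
            d[rows],
            entry[rows],
            w[rows],
            X[rows],
            [
                AgeTerm(term.name, np.asarray(term.values, float)[rows], term.transform)
                for term in age_terms
            ],
        )
        strata_data.append((rows, sd))
    if not strata_data:
        raise ValueError("no events in any stratum")
    for _, sd in strata_data:
        const = np.ptp(sd.X, axis=0) == 0 if sd.p_fixed else np.array([])
        if len(strata_data) == 1 and const.any():
            j = int(np.flatnonzero(const)[0])
            raise ValueError(f"covariate {names[j]!r} is constant within the stratum")

    quantities = _slow_quantities if age_terms or ties == "efron" else _fast_quantities

    def objective(beta, compute_resid=False):
        ll, grad = 0.0, np.zeros(p)
        hess = np.zeros((p, p))
        resid = np.zeros((n, p)) if compute_resid else None
        for rows, sd in strata_data:
            l_s, g_s, h_s, r_s = quantities(sd, beta, ties, compute_resid)
            ll += l_s
            grad += g_s
            hess += h_s
            if compute_resid:
                resid[rows] = r_s
        return ll, grad, hess, resid

    beta = np.zeros(p)
    ll, grad, hess, _ = objective(beta)
    trace = [(0, ll, float(np.abs(grad).max()))]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(grad).max() < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix at iteration {it} "
                "(constant covariate within all risk sets?)",
                trace,
            ) from exc
        new_beta = beta + step
        new_ll, new_grad, new_hess, _ = objective(new_beta)
        halvings = 0
        # tolerate float noise in the loglik comparison (|ll| can be ~1e4)
        while (
            not np.isfinite(new_ll) or new_ll < ll - 1e-10 * max(1.0, abs(ll))
        ) and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess, _ = objective(new_beta)
            halvings += 1
        if np.abs(new_beta).max() > _SEPARATION_BOUND:
            raise ConvergenceError(
                "monotone partial likelihood detected (separation): "
                f"|coefficient| exceeded {_SEPARATION_BOUND}",
                trace,
            )
        stalled = np.abs(step).max() < 1e-14
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        trace.append((it, ll, float(np.abs(grad).max())))
        if stalled:
            converged = np.abs(grad).max() < 1e-4
            break
    else:
        raise ConvergenceError(
            f"Newton-Raphson did not converge in {max_iter} iterations "
            f"(last gradient norm {np.abs(grad).max():.3g})",
            trace,
        )
    if not converged and np.abs(grad).max() >= tol:
        raise ConvergenceError(
            f"Newton-Raphson stalled with gradient norm {np.abs(grad).max():.3g}",
            trace,
        )
    # monotone likelihood: the gradient also vanishes as a separating
    # coefficient drifts to infinity, so flag absurd standardized effects
    if np.abs(beta).max() > 10.0:
        j = int(np.abs(beta).argmax())
        raise ConvergenceError(
            f"monotone partial likelihood (separation) suspected: standardized "
            f"coefficient for {names[j]!r} is {beta[j]:.2f}",
            trace,
        )

    ll, grad, hess, resid = objective(beta, compute_resid=True)
    info = -hess
    cov = np.linalg.inv(info)
    wu = w[:, None] * resid
    groups = pd.Series(range(n)).groupby(cluster_labels, sort=False).indices
    meat = np.zeros((p, p))
    for rows in groups.values():
        g = wu[list(rows)].sum(axis=0)
        meat += np.outer(g, g)
    robust_cov = cov @ meat @ cov

    # undo the internal column scaling
    beta = beta / scales
    cov = cov / np.outer(scales, scales)
    robust_cov = robust_cov / np.outer(scales, scales)

    return CoxFit(
        terms=names,
        params=beta,
        cov=cov,
        robust_cov=robust_cov,
        loglik=float(ll),
        n=n,
        n_events=int(d.sum()),
        converged=converged,
        n_iter=it,
        gradient_norm=float(np.abs(grad).max()),
        trace=trace,
    )


def _resolve_weights(cohort, weights, n):
    if weights is None:
        return np.ones(n)
    if isinstance(weights, pd.DataFrame):
        if "individual_id" in weights.columns and "individual_id" in cohort.columns:
            mapped = cohort["individual_id"].map(
                weights.set_index("individual_id")["weight"]
            )
            if mapped.isna().any():
                missing = cohort["individual_id"][mapped.isna()].iloc[0]
                raise ValueError(f"no weight for individual {missing!r}")
            w = mapped.to_numpy(float)
        else:
            w = weights["weight"].to_numpy(float)
    else:
        w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights have shape {w.shape}, expected ({n},)")
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    return w


def _resolve_labels(cohort, spec, n, default=None):
    if spec is None:
        if default == "__row__":
            return np.arange(n)
        return None
    if isinstance(spec, str):
        if spec not in cohort.columns:
            if default == "__row__":
                return np.arange(n)
            return None
        return cohort[spec].to_numpy()
    arr = np.asarray(spec)
    if arr.shape != (n,):
        raise ValueError(f"labels have shape {arr.shape}, expected ({n},)")
    return arr


# ----------------------------------------------------------------------
# the model battery


def fit_continuous_prs(
    cohort: pd.DataFrame, prs_std, weights=None, strata="study", cluster="family_id", **kw
) -> CoxFit:
    """Per-SD hazard ratio: single standardized-PRS column."""
    X = pd.DataFrame({"prs_per_sd": np.asarray(prs_std, dtype=float)})
    return fit_weighted_cox(cohort, X, weights=weights, strata=strata, cluster=cluster, **kw)


def fit_percentile_model(
    cohort: pd.DataFrame,
    categories,
    weights=None,
    reference: str = "40-60",
    strata="study",
    cluster="family_id",
    **kw,
) -> CoxFit:
    """One indicator per PRS percentile category, reference = middle band."""
    cats = pd.Categorical(categories)
    levels = [c for c in cats.categories if c != reference]
    if reference not in cats.categories:
        raise ValueError(f"reference category {reference!r} not present")
    counts = pd.Series(cats).value_counts()
    empty = [c for c in cats.categories if counts.get(c, 0) == 0]
    if empty:
        raise ValueError(
            f"empty PRS categories {empty}; use a coarser percentile scheme"
        )
    X = pd.DataFrame(
        {f"prs_{c}": (np.asarray(cats) == c).astype(float) for c in levels}
    )
    return fit_weighted_cox(cohort, X, weights=weights, strata=strata, cluster=cluster, **kw)


def fit_age_interaction(
    cohort: pd.DataFrame,
    prs_std,
    weights=None,
    strata="study",
    cluster="family_id",
    time_varying: bool = True,
    **kw,
) -> CoxFit:
    """Main PRS effect plus a PRS-by-age interaction.

    The interaction covariate is ``prs_std * t`` with t the attained age in
    raw years (anchor 0), evaluated at each event age, so ``exp(b2)`` is
    the per-year multiplicative change in the PRS hazard ratio and
    ``exp(b1)`` the extrapolated HR at age 0.  ``time_varying=False`` uses
    the fixed covariate ``prs_std * age_end`` instead.
    """
    z = np.asarray(prs_std, dtype=float)
    X = pd.DataFrame({"prs_per_sd": z})
    if time_varying:
        terms = [AgeTerm("prs_x_age", z, lambda t: t)]
        return fit_weighted_cox(
            cohort, X, weights=weights, strata=strata, cluster=cluster,
            age_terms=terms, **kw,
        )
    X["prs_x_age"] = z * cohort["age_end"].to_numpy(float)
    return fit_weighted_cox(cohort, X, weights=weights, strata=strata, cluster=cluster, **kw)


DEFAULT_BC_AGE_BANDS = ((18.0, 40.0), (40.0, 50.0), (50.0, 60.0), (60.0, np.inf))
DEFAULT_OC_AGE_BANDS = ((18.0, 50.0), (50.0, 60.0), (60.0, np.inf))


def fit_agegroup_model(
    cohort: pd.DataFrame,
    prs_std,
    weights=None,
    age_bands=DEFAULT_BC_AGE_BANDS,
    strata="study",
    cluster="family_id",
    **kw,
) -> CoxFit:
    """Separate per-SD PRS effect within each attained-age band.

    Fitted with time-varying indicator interactions, so an individual's PRS
    effect switches band as they age through it.  The returned fit carries
    ``band_contrasts``: a Wald test of each adjacent-band difference using
    the robust covariance.
    """
    z = np.asarray(prs_std, dtype=float)
    t = cohort["age_end"].to_numpy(float)
    d = cohort["affected"].to_numpy(bool)

    def band_indicator(lo, hi):
        return lambda age, lo=lo, hi=hi: float(lo <= age < hi)

    names = []
    terms = []
    for lo, hi in age_bands:
        if not ((t >= lo) & (t < hi) & d).any():
            raise ValueError(f"age band {lo:g}-{hi:g} contains no events")
        label = f"prs_age_{lo:g}_{hi:g}" if np.isfinite(hi) else f"prs_age_{lo:g}plus"
        names.append(label)
        terms.append(AgeTerm(label, z, band_indicator(lo, hi)))
    fit = fit_weighted_cox(
        cohort, None, weights=weights, strata=strata, cluster=cluster,
        age_terms=terms, **kw,
    )

    contrasts = []
    for j in range(len(names) - 1):
        delta = fit.params[j + 1] - fit.params[j]
        var = (
            fit.robust_cov[j, j]
            + fit.robust_cov[j + 1, j + 1]
            - 2 * fit.robust_cov[j, j + 1]
        )
        zstat = delta / np.sqrt(var)
        contrasts.append(
            {
                "contrast": f"{names[j + 1]} - {names[j]}",
                "estimate": delta,
                "se": np.sqrt(var),
                "p_two_sided": 2 * stats.norm.sf(abs(zstat)),
            }
        )
    fit.band_contrasts = pd.DataFrame(contrasts)
    return fit


def pairwise_interaction_scan(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    weights=None,
    alpha: float = 0.05,
    strata="study",
    cluster="family_id",
) -> pd.DataFrame:
    """Wald tests for all pairwise SNP-by-SNP product terms.

    For each pair (j, k) fits a weighted Cox model with ``g_j``, ``g_k``
    and ``g_j * g_k`` and reports the two-sided Wald p for the product
    term, Bonferroni-adjusted across the scanned pairs (family-wise level
    ``alpha``).  Monomorphic SNPs are skipped with a warning.
    """
    cols = []
    for c in dosages.columns:
        vals = dosages[c].to_numpy(float)
        if np.nanstd(vals) == 0:
            warnings.warn(f"skipping monomorphic SNP {c!r}", stacklevel=2)
            continue
        cols.append(c)
    records = []
    pairs = list(itertools.combinations(cols, 2))
    for a, b in pairs:
        ga = np.nan_to_num(dosages[a].to_numpy(float), nan=0.0)
        gb = np.nan_to_num(dosages[b].to_numpy(float), nan=0.0)
        X = pd.DataFrame({a: ga, b: gb, f"{a}*{b}": ga * gb})
        try:
            fit = fit_weighted_cox(
                cohort, X, weights=weights, strata=strata, cluster=cluster
            )
        except (ConvergenceError, ValueError) as exc:
            warnings.warn(f"pair ({a}, {b}) skipped: {exc}", stacklevel=2)
            continue
        zstat = fit.params[2] / fit.robust_se[2]
        p = 2 * stats.norm.sf(abs(zstat))
        records.append(
            {"snp_a": a, "snp_b": b, "coef": fit.params[2], "p_two_sided": p}
        )
    out = pd.DataFrame(
        records, columns=["snp_a", "snp_b", "coef", "p_two_sided"]
    )
    if len(out):
        n_tests = len(out)
        out["p_bonferroni"] = np.minimum(1.0, out["p_two_sided"] * n_tests)
        out["significant"] = out["p_bonferroni"] < alpha
    else:
        out["p_bonferroni"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
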