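"""Synthetic clinic-ascertained retrospective carrier cohorts.

Generates cohorts with the statistical structure the weighted-cohort
analysis assumes: Hardy-Weinberg genotypes at unlinked SNPs, a
proportional-hazards disease model in which the standardized polygenic
score ``z`` scales a piecewise-constant baseline hazard as
``lambda_0(t) * exp(beta(t) z)`` (optionally age-decaying,
``beta(t) = beta_0 + t log(decay)``, and optionally multiplied by a shared
family frailty), uniform right censoring, and Bernoulli oversampling of
affected individuals as happens when carriers are recruited through cancer
genetics clinics.

The latent score is standardized by its Hardy-Weinberg population moments
(mean ``sum 2 f beta``, variance ``sum 2 f (1-f) beta^2``) so the
generating per-SD effect is defined against the population SD.  Event ages
are drawn by exact inverse-CDF sampling on the piecewise-constant hazard
(no numerical root finding), which keeps the generator amenable to
closed-form oracle checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .incidence import IncidenceCurve
from . import polygenic

_MAX_BATCHES = 50
_HORIZON = 120.0  # hazard extended to this age; later "events" are never seen

PROFILES = {
    # synthetic average-carrier incidence calibrations (per-year hazards);
    # the BRCA1 ovarian curve is pinned to a 2.8% cumulative risk by age 40
    "brca1_bc": ("BRCA1", [(30, 0.004), (40, 0.018), (50, 0.030), (81, 0.022)], 1.27),
    "brca2_bc": ("BRCA2", [(30, 0.002), (40, 0.012), (50, 0.025), (81, 0.024)], 1.22),
    "brca1_oc": ("BRCA1", [(40, 0.0013), (50, 0.009), (81, 0.016)], 1.28),
    "brca2_oc": ("BRCA2", [(40, 0.0002), (50, 0.0025), (60, 0.005), (81, 0.0055)], 1.49),
}


def profile_incidence(profile: str) -> IncidenceCurve:
    """Synthetic average carrier incidence for a gene/cancer profile."""
    _, pieces, _ = PROFILES[profile]
    grid = np.arange(18.0, 81.0)
    rate = np.empty_like(grid)
    lo = 18.0
    for hi, value in pieces:
        rate[(grid >= lo) & (grid < hi)] = value
        lo = hi
    rate[-1] = pieces[-1][1]
    return IncidenceCurve(grid, rate)


@dataclass
class SimulationSpec:
    """Generating parameters for one synthetic carrier cohort."""

    n_target: int
    snp_freqs: np.ndarray
    snp_weights: np.ndarray
    baseline_hazard: IncidenceCurve
    beta_sd: float = 0.0
    beta_age: Optional[Tuple[float, float]] = None  # (log HR at age 0, per-year decay)
    ascertain_prob_affected: float = 1.0
    ascertain_prob_unaffected: float = 1.0
    censor_age_range: Tuple[float, float] = (25.0, 80.0)
    family_frailty_sd: float = 0.0
    family_size: int = 1
    gene: str = "BRCA1"
    study: str = "S1"
    seed: int = 0

    def __post_init__(self):
        self.snp_freqs = np.asarray(self.snp_freqs, dtype=float)
        self.snp_weights = np.asarray(self.snp_weights, dtype=float)
        if self.snp_freqs.shape != self.snp_weights.shape:
            raise ValueError("snp_freqs and snp_weights must have equal length")
        if np.any((self.snp_freqs <= 0) | (self.snp_freqs >= 1)):
            raise ValueError("snp_freqs must lie strictly inside (0, 1)")
        if self.ascertain_prob_affected < self.ascertain_prob_unaffected:
            raise ValueError(
                "clinic series oversample the affected: "
                "ascertain_prob_affected must be >= ascertain_prob_unaffected"
            )
        for p in (self.ascertain_prob_affected, self.ascertain_prob_unaffected):
            if not 0 < p <= 1:
                raise ValueError("ascertainment probabilities must be in (0, 1]")
        lo, hi = self.censor_age_range
        if not (18.0 < lo < hi <= 100.0):
            raise ValueError("censor_age_range must satisfy 18 < low < high <= 100")
        if self.family_frailty_sd < 0:
            raise ValueError("family_frailty_sd must be nonnegative")
        if self.family_size < 1:
            raise ValueError("family_size must be >= 1")

    def beta_at(self, t):
        """Per-SD log hazard ratio at age(s) t."""
        t = np.asarray(t, dtype=float)
        if self.beta_age is not None:
            b0, decay = self.beta_age
            return b0 + t * math.log(decay)
        return np.full_like(t, self.beta_sd)

    @property
    def prs_population_mean(self) -> float:
        return float(np.sum(2.0 * self.snp_freqs * self.snp_weights))

    @property
    def prs_population_sd(self) -> float:
        var = np.sum(
            2.0 * self.snp_freqs * (1.0 - self.snp_freqs) * self.snp_weights**2
        )
        return float(np.sqrt(var))


def make_study_spec(
    profile: str,
    n_target: int,
    seed: int,
    hr_per_sd: Optional[float] = None,
    beta_age: Optional[Tuple[float, float]] = None,
    n_snps: int = 50,
    hazard_scale: float = 1.0,
    **overrides,
) -> SimulationSpec:
    """Study conditions for a gene/cancer profile.

    SNP frequencies are drawn Uniform(0.1, 0.9) and per-allele log risk
    ratios Normal(0, 0.08^2) from the seed; the per-SD effect defaults to
    the profile's published-scale hazard ratio.  Clinic oversampling keeps
    every affected carrier and 40% of unaffected ones; censoring ages are
    Uniform(25, 80).
    """
    gene, _, default_hr = PROFILES[profile]
    rng = np.random.default_rng([seed, 0xC0F])
    freqs = rng.uniform(0.1, 0.9, size=n_snps)
    weights = rng.normal(0.0, 0.08, size=n_snps)
    hr = default_hr if hr_per_sd is None else hr_per_sd
    return SimulationSpec(
        n_target=n_target,
        snp_freqs=freqs,
        snp_weights=weights,
        baseline_hazard=profile_incidence(profile).rescaled(hazard_scale),
        beta_sd=math.log(hr),
        beta_age=beta_age,
        ascertain_prob_affected=overrides.pop("ascertain_prob_affected", 1.0),
        ascertain_prob_unaffected=overrides.pop("ascertain_prob_unaffected", 0.4),
        gene=gene,
        seed=seed,
        **overrides,
    )


def gen_genotypes(n: int, freqs, seed) -> np.ndarray:
    """HWE dosages: Binomial(2, f) independently per SNP."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("freqs must lie strictly inside (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.binomial(2, freqs, size=(n, freqs.size)).astype(np.int8)


def _interval_rates(spec: SimulationSpec):
    """Piecewise intervals (edges, baseline rate, per-SD beta at midpoints)."""
    curve = spec.baseline_hazard
    edges = np.append(curve.age, _HORIZON)
    rates = curve.hazard.copy()
    mids = edges[:-1] + np.diff(edges) / 2.0
    betas = np.asarray(spec.beta_at(mids), dtype=float)
    return edges, rates, betas


def _draw_event_ages(spec, z, log_frailty, rng):
    """Exact inverse-CDF sampling on the piecewise-constant hazard."""
    edges, rates, betas = _interval_rates(spec)
    widths = np.diff(edges)
    # per-individual per-interval rate: lambda_j * exp(beta_j z_i + frailty)
    log_rel = np.outer(z, betas) + log_frailty[:, None]
    rate = rates[None, :] * np.exp(log_rel)
    cum = np.concatenate(
        [np.zeros((z.size, 1)), np.cumsum(rate * widths[None, :], axis=1)], axis=1
    )
    target = -np.log(rng.uniform(size=z.size))
    k = (cum[:, 1:] < target[:, None]).sum(axis=1)
    ages = np.full(z.size, np.inf)
    seen = k < widths.size
    ks = k[seen]
    ages[seen] = edges[ks] + (target[seen] - cum[seen, ks]) / rate[seen, ks]
    return ages


def gen_cohort(spec: SimulationSpec):
    """Generate one ascertained cohort.

    Returns ``(cohort, genotypes, truth)``: a validated carrier phenotype
    table, the genotype dosages of the retained individuals (variants
    ``snp1..snpK``), and a truth record with every generating parameter.
    Raises if the target size cannot be reached after a retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sd = spec.prs_population_mean, spec.prs_population_sd
    if sd == 0 and np.any(spec.snp_weights != 0):
        raise ValueError("degenerate PRS variance")

    kept_parts = []
    n_kept = 0
    n_generated = 0
    fam_offset = 0
    for _ in range(_MAX_BATCHES):
        if n_kept >= spec.n_target:
            break
        if n_generated == 0:
            batch = max(spec.n_target, 100)
        else:
            retention = max(n_kept / n_generated, 0.05)
            batch = int((spec.n_target - n_kept) / retention * 1.2) + 100
        batch = min(batch, 4 * spec.n_target + 1000)

        g = gen_genotypes(batch, spec.snp_freqs, rng)
        raw = g @ spec.snp_weights
        z = (raw - mu) / sd if sd > 0 else np.zeros(batch)

        n_fam = -(-batch // spec.family_size)
        fam_ids = np.repeat(np.arange(n_fam), spec.family_size)[:batch] + fam_offset
        fam_offset += n_fam
        if spec.family_frailty_sd > 0:
            log_frailty = rng.normal(0.0, spec.family_frailty_sd, size=n_fam)[
                fam_ids - (fam_offset - n_fam)
            ]
        else:
            log_frailty = np.zeros(batch)

        event_age = _draw_event_ages(spec, z, log_frailty, rng)
        censor_age = rng.uniform(*spec.censor_age_range, size=batch)
        affected = event_age <= censor_age
        age_end = np.where(affected, event_age, censor_age)

        keep_prob = np.where(
            affected, spec.ascertain_prob_affected, spec.ascertain_prob_unaffected
        )
        keep = rng.uniform(size=batch) < keep_prob
        kept_parts.append(
            {
                "genotypes": g[keep],
                "affected": affected[keep],
                "age_end": age_end[keep],
                "family": fam_ids[keep],
            }
        )
        n_kept += int(keep.sum())
        n_generated += batch
    if n_kept < spec.n_target:
        raise RuntimeError(
            f"could not reach n_target={spec.n_target} after {_MAX_BATCHES} "
            f"batches ({n_kept} retained of {n_generated} generated)"
        )

    genotypes = np.concatenate([p["genotypes"] for p in kept_parts])[: spec.n_target]
    affected = np.concatenate([p["affected"] for p in kept_parts])[: spec.n_target]
    age_end = np.concatenate([p["age_end"] for p in kept_parts])[: spec.n_target]
    family = np.concatenate([p["family"] for p in kept_parts])[: spec.n_target]

    n = spec.n_target
    ids = [f"ind{i + 1:06d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "individual_id": ids,
            "family_id": [f"fam{f + 1:06d}" for f in family],
            "study": spec.study,
            "gene": spec.gene,
            "affected": affected,
            "age_end": age_end,
            "age_entry": 18.0,
        }
    )
    from .io import GenotypeMatrix

    snp_ids = [f"snp{j + 1}" for j in range(spec.snp_freqs.size)]
    gmat = GenotypeMatrix(
        pd.DataFrame(genotypes.astype(float), index=pd.Index(ids, name="individual_id"), columns=snp_ids)
    )
    truth = {
        "seed": int(spec.seed),
        "n_target": int(spec.n_target),
        "n_generated": int(n_generated),
        "beta_sd": float(spec.beta_sd),
        "beta_age": list(spec.beta_age) if spec.beta_age is not None else None,
        "ascertain_prob_affected": float(spec.ascertain_prob_affected),
        "ascertain_prob_unaffected": float(spec.ascertain_prob_unaffected),
        "censor_age_range": list(spec.censor_age_range),
        "family_frailty_sd": float(spec.family_frailty_sd),
        "family_size": int(spec.family_size),
        "gene": spec.gene,
        "prs_population_mean": spec.prs_population_mean,
        "prs_population_sd": spec.prs_population_sd,
        "snp_freqs": spec.snp_freqs.tolist(),
        "snp_weights": spec.snp_weights.tolist(),
        "baseline_hazard": {
            "age": spec.baseline_hazard.age.tolist(),
            "rate": spec.baseline_hazard.hazard.tolist(),
        },
    }
    return cohort, gmat, truth


def marginal_incidence(spec: SimulationSpec) -> IncidenceCurve:
    """Average carrier incidence implied by the generating model.

    Marginalizes the generating hazard over the standard-normal PRS (the
    forward direction of the multiplicative polygenic model); this is the
    curve the ascertainment weights should be built from.  Frailty is not
    marginalized (it defaults to zero and exists to test cluster variance).
    """
    if spec.beta_age is not None:
        b0, decay = spec.beta_age
        beta = lambda t: b0 + t * math.log(decay)  # noqa: E731
    else:
        beta = spec.beta_sd
    return polygenic.marginal_hazard(spec.baseline_hazard, beta)


def weight_table_for_spec(spec: SimulationSpec, phenotype_tag: str = "custom") -> pd.DataFrame:
    """The simulated SNPs as a weight table consumable by the PRS module."""
    k = spec.snp_freqs.size
    return pd.DataFrame(
        {
            "variant_id": [f"snp{j + 1}" for j in range(k)],
            "chrom": ["1"] * k,
            "pos": np.arange(1, k + 1) * 1000,
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "effect_allele_freq": spec.snp_freqs,
            "weight": spec.snp_weights,
            "phenotype_tag": phenotype_tag,
        }
    )
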