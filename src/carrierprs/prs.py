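"""Polygenic risk score construction.

The score for individual *i* is the weighted allele-dosage sum
``PRS_i = sum_l beta_l * g_li`` over the variants of a weight table, where
``beta_l`` is the per-allele log risk ratio of the effect allele and
``g_li`` the effect-allele dosage.  Scores are standardized to mean 0 /
SD 1 over the analysis cohort, and percentile categories are assigned from
the quantiles of a normal distribution fitted to the cohort (the category
boundaries of the published percentile analyses assume a normally
distributed PRS, rather than using empirical quantiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix

AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PercentileScheme:
    """Ordered percent cut-points defining half-open PRS categories.

    Default boundaries give the nine categories 0-5, 5-10, 10-20, 20-40,
    40-60 (reference), 60-80, 80-90, 90-95, 95-100.
    """

    boundaries: Sequence[float] = (5, 10, 20, 40, 60, 80, 90, 95)
    reference: str = "40-60"

    def __post_init__(self):
        b = tuple(float(x) for x in self.boundaries)
        if any(not 0 < x < 100 for x in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("boundaries must be strictly increasing within (0, 100)")
        object.__setattr__(self, "boundaries", b)
        if self.reference not in self.labels:
            raise ValueError(f"reference {self.reference!r} is not a category label")

    @property
    def labels(self) -> list:
        edges = (0.0,) + self.boundaries + (100.0,)
        return [f"{lo:g}-{hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]


@dataclass
class HarmonizationReport:
    n_weight_variants: int
    n_matched: int
    flipped: list = field(default_factory=list)
    ambiguous: list = field(default_factory=list)
    dropped: list = field(default_factory=list)


@dataclass
class PrsResult:
    """Raw and standardized scores with the cohort moments used to scale them."""

    table: pd.DataFrame  # individual_id, prs_raw, prs_std, n_missing_imputed
    sample_mean: float
    sample_sd: float
    scheme: Optional[PercentileScheme] = None


def harmonize(weights: pd.DataFrame, genotypes):
    """Align a weight table with a genotype matrix on variant id and allele.

    Where the genotype file's counted allele is the weight table's
    *other* allele the dosage is flipped to ``2 - g``.  Strand-ambiguous
    variants (A/T, C/G) are matched by id only and flagged.  Weight-table
    variants absent from the genotypes are dropped with a warning; losing
    more than half the table is treated as a wrong-file error.
    """
    if isinstance(genotypes, pd.DataFrame):
        genotypes = GenotypeMatrix(genotypes)
    dos = genotypes.dosages
    matched = weights[weights["variant_id"].isin(dos.columns)].reset_index(drop=True)
    dropped = [v for v in weights["variant_id"] if v not in set(dos.columns)]
    if len(weights) > 0 and len(dropped) > len(weights) / 2:
        raise ValueError(
            f"{len(dropped)}/{len(weights)} weight-table variants are absent from "
            "the genotype file; the files are probably mismatched"
        )
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} weight-table variant(s) absent from genotypes",
            stacklevel=2,
        )
    report = HarmonizationReport(
        n_weight_variants=len(weights), n_matched=len(matched), dropped=dropped
    )
    aligned = dos[list(matched["variant_id"])].copy()
    counted = genotypes.counted_allele or {}
    for _, row in matched.iterrows():
        vid = row["variant_id"]
        if frozenset({row["effect_allele"], row["other_allele"]}) in AMBIGUOUS_PAIRS:
            report.ambiguous.append(vid)
            continue  # use dosage as-is; alleles are strand-uninformative
        allele = counted.get(vid)
        if allele is None:
            continue  # no allele labels: assume effect allele is counted
        if allele == row["other_allele"] or allele == _COMPLEMENT.get(
            row["other_allele"]
        ):
            aligned[vid] = 2.0 - aligned[vid]
            report.flipped.append(vid)
    return matched, aligned, report


def compute_prs(
    weights: pd.DataFrame,
    dosages: pd.DataFrame,
    max_missing_fraction: float = 0.10,
) -> pd.DataFrame:
    """Weighted allele-dosage sum per individual.

    Missing dosages are imputed at their expectation ``2 * effect_allele_freq``
    (standard scoring practice); individuals with more than
    ``max_missing_fraction`` of variants missing are flagged, not excluded.
    """
    dosages = dosages[list(weights["variant_id"])]
    g = dosages.to_numpy(dtype=float)
    beta = weights["weight"].to_numpy()
    expected = 2.0 * weights["effect_allele_freq"].to_numpy()
    missing = np.isnan(g)
    g_filled = np.where(missing, expected[None, :], g)
    raw = g_filled @ beta
    n_missing = missing.sum(axis=1)
    out = pd.DataFrame(
        {
            "individual_id": dosages.index,
            "prs_raw": raw,
            "n_missing_imputed": n_missing.astype(int),
        }
    )
    if len(weights):
        out["flag_high_missing"] = n_missing > max_missing_fraction * len(weights)
    else:
        out["flag_high_missing"] = False
    return out


def standardize(prs_raw: np.ndarray):
    """Z-score against the analysis cohort's sample mean and SD (ddof=1)."""
    x = np.asarray(prs_raw, dtype=float)
    if x.size < 2:
        raise ValueError("standardization needs a cohort of at least 2")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("PRS has zero variance; cannot standardize")
    return (x - mean) / sd, mean, sd


def assign_categories(
    prs_raw: np.ndarray,
    scheme: PercentileScheme,
    sample_mean: float,
    sample_sd: float,
    empirical: bool = False,
) -> pd.Categorical:
    """Percentile category per individual.

    Cut-points are quantiles of Normal(sample_mean, sample_sd^2) at the
    scheme's percents (not empirical quantiles); ``empirical=True`` switches
    to empirical quantiles of the raw score.  Categories are half-open
    ``[low%, high%)`` intervals.
    """
    x = np.asarray(prs_raw, dtype=float)
    percents = np.asarray(scheme.boundaries) / 100.0
    if empirical:
        cuts = np.quantile(x, percents)
    else:
        cuts = sample_mean + sample_sd * stats.norm.ppf(percents)
    idx = np.searchsorted(cuts, x, side="right")
    labels = scheme.labels
    return pd.Categorical.from_codes(idx, categories=labels, ordered=True)


def score_cohort(
    weights: pd.DataFrame,
    genotypes,
    scheme: Optional[PercentileScheme] = None,
    empirical_categories: bool = False,
) -> PrsResult:
    """Full scoring pipeline: harmonize, score, standardize, categorize."""
    matched, aligned, _ = harmonize(weights, genotypes)
    table = compute_prs(matched, aligned)
    prs_std, mean, sd = standardize(table["prs_raw"].to_numpy())
    table = table.copy()
    table["prs_std"] = prs_std
    if scheme is not None:
        table["category"] = assign_categories(
            table["prs_raw"].to_numpy(), scheme, mean, sd, empirical=empirical_categories
        )
    cols = ["individual_id", "prs_raw", "prs_std"] + (
        ["category"] if scheme is not None else []
    ) + ["n_missing_imputed", "flag_high_missing"]
    return PrsResult(table[cols], sample_mean=mean, sample_sd=sd, scheme=scheme)
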