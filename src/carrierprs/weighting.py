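"""Sampling weights for the weighted-cohort analysis of carrier series.

Carriers recruited through genetics clinics are sampled nonrandomly with
respect to disease status: affected carriers are over-represented.  A naive
retrospective Cox fit on such a series is biased.  The weighted-cohort
correction assigns each record a weight so that, within strata of attained
age (and gene), the weighted affected/unaffected mix equals the mix
expected from the average carrier incidence: with expected affected
proportion ``p`` (the cumulative risk at the stratum midpoint) and observed
proportion ``q``, affected records get ``p/q`` and unaffected records
``(1-p)/(1-q)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .incidence import IncidenceCurve

logger = logging.getLogger(__name__)

WEIGHT_CAP = 50.0


def default_age_bands(start: float = 18.0, stop: float = 80.0, width: float = 5.0):
    """5-year bands from 18 to 80 with an open-ended top band."""
    edges = list(np.arange(start, stop, width)) + [stop]
    bands = [(float(lo), float(hi)) for lo, hi in zip(edges[:-1], edges[1:])]
    bands.append((float(stop), np.inf))
    return bands


def expected_affected_proportion(incidence: IncidenceCurve, band) -> float:
    """Probability of being affected by the band midpoint under the curve.

    ``F(a) = 1 - exp(-int_18^a lambda_bar du)`` evaluated at the midpoint of
    the age band; for the open top band the midpoint is taken half a typical
    band-width above its lower edge.
    """
    lo, hi = band
    if lo < incidence.age[0] - 1e-9:
        raise ValueError(
            f"band {band} starts before the incidence support (age {incidence.age[0]:g})"
        )
    mid = lo + 2.5 if np.isinf(hi) else 0.5 * (lo + hi)
    return float(incidence.cumulative_risk(mid))


def expected_cohort_affected_fraction(
    cohort: pd.DataFrame, incidence: IncidenceCurve
) -> float:
    """Affected fraction expected in the series absent status oversampling.

    Status-based thinning leaves the observation-age distribution of each
    status group intact and only distorts the affected/unaffected balance.
    The unaffected records' censoring ages therefore identify the
    censoring-age distribution up to the survival tilt ``S_bar(c)``, and the
    pre-ascertainment affected fraction ``P(T <= C)`` is recovered as

        pi = sum_j odds(c_j) / sum_j (1 + odds(c_j)),
        odds(a) = F_bar(a) / (1 - F_bar(a)),

    summed over unaffected records with censoring age ``c_j``, with
    ``F_bar`` the cumulative risk of the average-carrier incidence.
    """
    unaffected = ~cohort["affected"].to_numpy(bool)
    if not unaffected.any():
        raise ValueError("no unaffected records; cannot calibrate")
    ages = cohort["age_end"].to_numpy(float)[unaffected]
    F = incidence.cumulative_risk(ages)
    if np.any(F >= 1.0):
        raise ValueError("incidence implies certain disease at an observed age")
    odds = F / (1.0 - F)
    return float(odds.sum() / (1.0 + odds).sum())


def build_weights(
    cohort: pd.DataFrame,
    incidence: IncidenceCurve,
    bands=None,
    by_gene: bool = True,
    method: str = "calibrated",
) -> pd.DataFrame:
    """Per-record weighted-cohort sampling weights.

    Strata are age bands (by ``age_end``) crossed with gene.  The expected
    affected proportion ``p`` per stratum comes from the average carrier
    incidence in one of two ways:

    * ``method="calibrated"`` (default): status-based oversampling
      rescales the affected/unaffected balance by a common factor in every
      age band, so the expected per-band proportions are the observed
      counts rescaled by one factor ``rho`` chosen to make the overall
      weighted affected fraction equal the incidence-implied fraction
      (:func:`expected_cohort_affected_fraction`).  This is the
      design-consistent correction for series oversampled purely on
      disease status.
    * ``method="cumulative-risk"``: the classic construction, ``p`` =
      cumulative risk at the band midpoint
      (:func:`expected_affected_proportion`).  Appropriate when the
      observation design makes "affected by one's observed age" the right
      expectation within a band (e.g. cross-sectional current-age
      sampling).

    In both cases affected records in a stratum receive ``p/q`` and
    unaffected ``(1-p)/(1-q)`` with ``q`` the observed proportion, so the
    weighted mix matches ``p`` exactly.  Strata whose observed affected
    proportion is 0 or 1 are pooled with the nearest band (within gene)
    until mixed.  Weights are renormalized to sum to the cohort size and
    capped at ``WEIGHT_CAP`` to stop single records from dominating small
    cohorts.

    Returns a frame with columns individual_id, stratum, weight.
    """
    if method not in ("calibrated", "cumulative-risk"):
        raise ValueError(f"unknown weighting method {method!r}")
    if bands is None:
        bands = default_age_bands()
    bands = sorted(bands)
    edges = [b[0] for b in bands] + [bands[-1][1]]
    age = cohort["age_end"].to_numpy(float)
    if age.min() < edges[0]:
        raise ValueError(
            f"record with age_end {age.min():g} falls before the first band {bands[0]}"
        )
    band_idx = np.clip(np.searchsorted(edges, age, side="right") - 1, 0, len(bands) - 1)
    affected = cohort["affected"].to_numpy(bool)
    genes = cohort["gene"].to_numpy() if by_gene else np.repeat("all", len(cohort))

    if method == "calibrated":
        pi = expected_cohort_affected_fraction(cohort, incidence)
        n_aff = affected.sum()
        n_unaff = len(cohort) - n_aff
        if n_aff == 0 or n_unaff == 0:
            raise ValueError("cohort needs both affected and unaffected records")
        rho = pi / (1.0 - pi) * n_unaff / n_aff

    weight = np.full(len(cohort), np.nan)
    stratum = np.empty(len(cohort), dtype=object)
    for gene in np.unique(genes):
        in_gene = genes == gene
        groups = _merge_degenerate(band_idx[in_gene], affected[in_gene], len(bands))
        for members in groups:
            sel = np.flatnonzero(in_gene)[members]
            lo = bands[int(band_idx[sel].min())][0]
            hi = bands[int(band_idx[sel].max())][1]
            if method == "calibrated":
                a_s = affected[sel].sum()
                u_s = sel.size - a_s
                p = rho * a_s / (rho * a_s + u_s)
            else:
                p = expected_affected_proportion(incidence, (lo, hi))
            if not 0.0 < p < 1.0:
                raise ValueError(
                    f"incidence implies affected proportion {p:g} outside (0, 1) "
                    f"for occupied stratum {gene} {lo:g}-{hi:g}"
                )
            q = affected[sel].mean()
            label = f"{gene}:{lo:g}-{hi:g}"
            stratum[sel] = label
            weight[sel] = np.where(affected[sel], p / q, (1 - p) / (1 - q))

    weight *= len(cohort) / weight.sum()
    if (weight > WEIGHT_CAP).any():
        n_capped = int((weight > WEIGHT_CAP).sum())
        logger.warning("capping %d weight(s) at %g", n_capped, WEIGHT_CAP)
        warnings.warn(f"capping {n_capped} weight(s) at {WEIGHT_CAP:g}", stacklevel=2)
        weight = np.minimum(weight, WEIGHT_CAP)
    return pd.DataFrame(
        {
            "individual_id": cohort["individual_id"].to_numpy(),
            "stratum": stratum,
            "weight": weight,
        }
    )


def _merge_degenerate(band_idx: np.ndarray, affected: np.ndarray, n_bands: int):
    """Group occupied bands, pooling all-affected/all-unaffected ones.

    Nearest-neighbour pooling: a degenerate band is merged with the closest
    occupied band (preferring the younger side on ties) until every group
    contains both affected and unaffected records.
    """
    occupied = sorted(set(int(b) for b in band_idx))
    groups = [[b] for b in occupied]

    def is_mixed(group):
        members = np.isin(band_idx, group)
        return 0 < affected[members].sum() < members.sum()

    changed = True
    while changed and len(groups) > 1:
        changed = False
        for i, g in enumerate(groups):
            if not is_mixed(g):
                if i == 0:
                    j = 1
                elif i == len(groups) - 1:
                    j = i - 1
                else:
                    gap_lo = g[0] - groups[i - 1][-1]
                    gap_hi = groups[i + 1][0] - g[-1]
                    j = i - 1 if gap_lo <= gap_hi else i + 1
                keep, drop = (i, j) if i < j else (j, i)
                groups[keep] = sorted(groups[keep] + groups[drop])
                del groups[drop]
                changed = True
                break
    if len(groups) == 1 and not is_mixed(groups[0]):
        raise ValueError(
            "cohort is entirely affected or entirely unaffected; "
            "weighted-cohort weights are undefined"
        )
    return [np.flatnonzero(np.isin(band_idx, g)) for g in groups]
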