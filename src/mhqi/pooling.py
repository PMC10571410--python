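"""Pooling regional estimates: homogeneity, I², SMR and standardized rates.

Regional indicator estimates are combined by aggregate (fixed-effect)
pooling: proportions are summed numerator over summed denominator, so the
whole-sample value is the denominator-weighted mean of the regional values.
Between-region homogeneity is tested with the Pearson chi-square statistic
of the regions x {event, non-event} table for proportions, and with a
one-way ANOVA across regions of the per-patient rates for intensity
medians.  Heterogeneity is expressed as

    I^2 = max(0, (Q - df) / Q) x 100

the percentage of between-region variability attributable to heterogeneity
rather than chance, banded Negligible (0-25], Moderate (25-50],
Substantive (50-75], Considerable (75-100] with boundary values falling in
the lower band.

Standardized mortality ratios use exact Poisson 95% limits in the
chi-square-quantile form, and treated-prevalence rates are directly
standardized to a reference population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

I2_BANDS = ((25.0, "Negligible"), (50.0, "Moderate"), (75.0, "Substantive"), (100.0, "Considerable"))


def i2_from_q(q: float, df: int) -> float:
    """I² (percent) from a homogeneity statistic and its degrees of freedom."""
    if q <= 0 or df <= 0:
        return 0.0
    return float(np.clip((q - df) / q * 100.0, 0.0, 100.0))


def i2_band(i2: float) -> str:
    """Heterogeneity band; boundary values go to the lower band."""
    for upper, name in I2_BANDS:
        if i2 <= upper:
            return name
    return I2_BANDS[-1][1]


@dataclass(frozen=True)
class PooledEstimate:
    indicator_id: str
    cohort: str
    pooled_value: float
    regions_included: tuple[str, ...]
    numerator: float
    denominator: float
    q: float
    df: int
    p_hom: float
    i2: float
    band: str


class PoolingError(ValueError):
    pass


def pool_proportions(
    regional: pd.DataFrame, indicator_id: str = "", cohort: str = ""
) -> PooledEstimate:
    """Pool regional proportion counts into a whole-sample estimate.

    ``regional`` needs columns ``region``, ``numerator``, ``denominator``
    (and optionally ``n_available``, which filters contributing regions).
    The pooled value is 100 x sum(numerators) / sum(denominators); Q is the
    Pearson chi-square of the regions x {event, non-event} table with
    df = regions - 1.
    """
    df_in = regional
    if "n_available" in df_in.columns:
        df_in = df_in[df_in["n_available"].astype(bool)]
    df_in = df_in.dropna(subset=["numerator", "denominator"])
    df_in = df_in[df_in["denominator"] > 0]
    if df_in.empty or df_in["denominator"].sum() <= 0:
        raise PoolingError(f"indicator {indicator_id}: no region with a usable denominator")
    num = df_in["numerator"].to_numpy(dtype=float)
    den = df_in["denominator"].to_numpy(dtype=float)
    pooled = 100.0 * num.sum() / den.sum()

    k = len(df_in)
    dof = k - 1
    # Pearson chi-square on the k x 2 contingency table of events/non-events
    table = np.column_stack([num, den - num])
    if k >= 2 and table.sum(axis=0).min() > 0:
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        q = float(((table - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(q, dof))
    else:
        q, p = 0.0, 1.0
    i2 = i2_from_q(q, dof)
    return PooledEstimate(
        indicator_id=indicator_id,
        cohort=cohort,
        pooled_value=pooled,
        regions_included=tuple(df_in["region"]),
        numerator=float(num.sum()),
        denominator=float(den.sum()),
        q=q,
        df=dof,
        p_hom=p,
        i2=i2,
        band=i2_band(i2),
    )


def pool_medians(
    regional: pd.DataFrame,
    samples: Optional[dict] = None,
    indicator_id: str = "",
    cohort: str = "",
) -> PooledEstimate:
    """Pool regional intensity medians.

    The whole-sample value is the denominator-weighted mean of the regional
    medians — a documented surrogate for a patient-level pooled median,
    which aggregate regional data cannot reproduce exactly.  When
    ``samples`` maps region -> per-patient rate arrays, homogeneity is
    assessed by one-way ANOVA across regions and converted to an I²-style
    percentage via Q = F x df_between.
    """
    df_in = regional
    if "n_available" in df_in.columns:
        df_in = df_in[df_in["n_available"].astype(bool)]
    df_in = df_in.dropna(subset=["value"])
    df_in = df_in[df_in["denominator"] > 0]
    if df_in.empty:
        raise PoolingError(f"indicator {indicator_id}: no regional medians to pool")
    w = df_in["denominator"].to_numpy(dtype=float)
    med = df_in["value"].to_numpy(dtype=float)
    pooled = float((w * med).sum() / w.sum())

    k = len(df_in)
    dof = k - 1
    q, p = 0.0, 1.0
    if samples and k >= 2:
        groups = [
            np.asarray(samples[r])
            for r in df_in["region"]
            if r in samples and len(np.asarray(samples[r])) >= 2
        ]
        if len(groups) >= 2:
            f_stat, p = stats.f_oneway(*groups)
            if math.isfinite(f_stat):
                dof = len(groups) - 1
                q = float(f_stat * dof)
                p = float(p)
            else:
                q, p = 0.0, 1.0
    i2 = i2_from_q(q, dof)
    return PooledEstimate(
        indicator_id=indicator_id,
        cohort=cohort,
        pooled_value=pooled,
        regions_included=tuple(df_in["region"]),
        numerator=float("nan"),
        denominator=float(w.sum()),
        q=q,
        df=dof,
        p_hom=p,
        i2=i2,
        band=i2_band(i2),
    )


@dataclass(frozen=True)
class SMRResult:
    observed: int
    expected: float
    smr: float
    ci95: tuple[float, float]


def compute_smr(observed: int, expected: float) -> SMRResult:
    """Standardized mortality ratio with exact Poisson 95% limits.

    The limits invert the Poisson tails via chi-square quantiles:
    lower = qchisq(0.025, 2O) / 2 / E (0 when O = 0),
    upper = qchisq(0.975, 2(O + 1)) / 2 / E.
    """
    if expected <= 0:
        raise ValueError("expected deaths must be positive")
    if observed < 0 or observed != int(observed):
        raise ValueError("observed deaths must be a non-negative integer")
    o = int(observed)
    lower = 0.0 if o == 0 else float(stats.chi2.ppf(0.025, 2 * o) / 2.0 / expected)
    upper = float(stats.chi2.ppf(0.975, 2 * (o + 1)) / 2.0 / expected)
    return SMRResult(observed=o, expected=expected, smr=o / expected, ci95=(lower, upper))


def pool_smr(regional: pd.DataFrame) -> SMRResult:
    """Whole-sample SMR: summed observed over summed expected deaths."""
    obs = int(regional["numerator"].sum())
    exp = float(regional["denominator"].sum())
    return compute_smr(obs, exp)


@dataclass(frozen=True)
class StandardizedRate:
    rate_per_10k: float
    crude_per_10k: float
    strata_used: int


def standardized_rate(
    counts: Sequence[float],
    population: Sequence[float],
    reference_weights: Sequence[float],
) -> StandardizedRate:
    """Directly standardized rate per 10,000.

    ``counts`` and ``population`` align stratum-wise with the reference
    weights (which are renormalized over usable strata); strata with empty
    population are skipped.
    """
    counts = np.asarray(counts, dtype=float)
    pop = np.asarray(population, dtype=float)
    wref = np.asarray(reference_weights, dtype=float)
    if not (len(counts) == len(pop) == len(wref)):
        raise ValueError("strata of counts, population and weights must align")
    usable = pop > 0
    if not usable.any():
        raise ValueError("no stratum with population")
    w = wref[usable] / wref[usable].sum()
    rate = float((w * counts[usable] / pop[usable]).sum() * 1e4)
    crude = float(counts[usable].sum() / pop[usable].sum() * 1e4)
    return StandardizedRate(rate_per_10k=rate, crude_per_10k=crude, strata_used=int(usable.sum()))
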