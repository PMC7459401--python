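"""Desiccation-survival statistics: recovery rates, t-test, Tukey-Kramer.

Recovery rate = fraction of desiccated animals showing spontaneous
movement or touch response after rehydration, per replicate dish
(typically ~15 animals, 3 replicates per condition).  Rates are analyzed
untransformed, as they are reported; an arcsine-square-root transform is
available as a flag for variance stabilization near 0/1.

Two conditions are compared by Student's t-test on the replicate rates;
three or more by the Tukey-Kramer all-pairs procedure, which controls
the family-wise error rate through the studentized-range distribution
(with the Kramer harmonic adjustment for unequal group sizes).  The
studentized-range tail probability is computed here by direct numerical
integration, since this test is itself part of the reproduced analysis:

    P(Q <= q) = \\int_0^inf g_nu(u) * F_range(q u; k) du

where ``F_range(w; k) = k \\int phi(z) [Phi(z) - Phi(z - w)]^{k-1} dz`` is
the CDF of the range of k iid standard normals and ``g_nu`` is the
density of ``sqrt(chi^2_nu / nu)``.  The inner integral is evaluated by
high-order Gauss-Legendre quadrature on [-8, 8] (the normal density is
negligible outside), the outer by adaptive quadrature; absolute accuracy
is well below 1e-4 across the ranges used.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import lgamma

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from tardilfq.evidence_io import ValidationError
from tardilfq.select import student_t_test

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(240)
_Z_LO, _Z_HI = -8.0, 8.0
_Z = 0.5 * (_Z_HI - _Z_LO) * _GL_NODES + 0.5 * (_Z_HI + _Z_LO)
_W = 0.5 * (_Z_HI - _Z_LO) * _GL_WEIGHTS
_PHI_Z = stats.norm.pdf(_Z)
_CDF_Z = stats.norm.cdf(_Z)


def _range_cdf(w: float, k: int) -> float:
    """CDF of the range of k iid standard normals at w >= 0."""
    if w <= 0:
        return 0.0
    inner = (_CDF_Z - stats.norm.cdf(_Z - w)) ** (k - 1)
    return float(k * np.sum(_W * _PHI_Z * inner))


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """Upper-tail probability P(Q >= q) of the studentized range.

    Parameters
    ----------
    q:
        Observed studentized-range statistic (>= 0 gives tail 1 at 0).
    k:
        Number of groups (>= 2).
    df:
        Error degrees of freedom (>= 1).
    """
    if k < 2 or int(k) != k:
        raise ValueError("k must be an integer >= 2")
    if df < 1 or int(df) != df:
        raise ValueError("df must be an integer >= 1")
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 0:
        return 1.0

    nu = float(df)
    # log normalization of the density of u = sqrt(chi2_nu / nu)
    log_c = (nu / 2) * np.log(nu) - lgamma(nu / 2) - (nu / 2 - 1) * np.log(2)

    def integrand(u: float) -> float:
        if u <= 0:
            return 0.0
        log_g = log_c + (nu - 1) * np.log(u) - nu * u * u / 2
        return np.exp(log_g) * _range_cdf(q * u, int(k))

    cdf, _ = integrate.quad(integrand, 0, np.inf, epsabs=1e-10, epsrel=1e-8, limit=200)
    return float(min(1.0, max(0.0, 1.0 - cdf)))


def studentized_range_crit(alpha: float, k: int, df: int) -> float:
    """Critical value q* with P(Q >= q*) = alpha (bisection on the tail)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(
        optimize.brentq(
            lambda q: studentized_range_sf(q, k, df) - alpha, 1e-6, 100.0, xtol=1e-8
        )
    )


@dataclass
class RecoverySummary:
    """Per-replicate recovery rates plus per-condition mean and SD."""

    rates: pd.DataFrame  # condition, replicate, rate
    summary: pd.DataFrame  # condition, n, mean_rate, sd_rate


def recovery_summary(assays: pd.DataFrame) -> RecoverySummary:
    """Recovery rates and per-condition mean / sample SD (ddof=1).

    ``assays`` is the survival count table (condition / replicate /
    recovered / total).
    """
    if assays.empty:
        raise ValidationError("survival table is empty")
    if (assays["total"] <= 0).any():
        raise ValidationError("total animal count must be positive")
    rates = assays.copy()
    rates["rate"] = rates["recovered"] / rates["total"]
    summary = (
        rates.groupby("condition", sort=False)["rate"]
        .agg(n="size", mean_rate="mean", sd_rate=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return RecoverySummary(
        rates=rates[["condition", "replicate", "rate"]], summary=summary
    )


def tukey_kramer(groups, labels=None) -> pd.DataFrame:
    """All-pairs Tukey-Kramer comparison.

    Parameters
    ----------
    groups:
        Sequence of 1-D samples (k >= 2, each with n >= 2 observations).
    labels:
        Optional group names (defaults to g1..gk).

    Returns
    -------
    DataFrame with one row per unordered pair: mean difference,
    studentized statistic ``q = |mean_i - mean_j| /
    sqrt((MSE/2)(1/n_i + 1/n_j))`` with MSE the pooled within-group
    variance from one-way ANOVA on df = N - k, and the family-wise
    adjusted p from the studentized-range distribution.
    """
    samples = [np.asarray(g, dtype=float) for g in groups]
    k = len(samples)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least 2 observations")
    if labels is None:
        labels = [f"g{i + 1}" for i in range(k)]

    ns = np.array([len(s) for s in samples])
    means = np.array([s.mean() for s in samples])
    sse = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df = int(ns.sum() - k)
    mse = sse / df

    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        se = np.sqrt((mse / 2) * (1 / ns[i] + 1 / ns[j]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = studentized_range_sf(q, k, df)
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "mean_diff": diff,
                "q": q,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def survival_test(
    assays: pd.DataFrame, test: str = "auto", arcsine: bool = False
) -> pd.DataFrame:
    """Compare recovery rates between conditions.

    ``test="auto"`` picks Student's t-test for two conditions and
    Tukey-Kramer for three or more, following the reporting convention
    of the assay design.  ``arcsine=True`` applies the
    arcsine-square-root variance-stabilizing transform to the rates
    before testing.
    """
    rs = recovery_summary(assays)
    rates = rs.rates.copy()
    if arcsine:
        rates["rate"] = np.arcsin(np.sqrt(rates["rate"]))
    conditions = list(dict.fromkeys(rates["condition"]))
    samples = [
        rates.loc[rates["condition"] == c, "rate"].to_numpy() for c in conditions
    ]

    if test == "auto":
        test = "t" if len(conditions) == 2 else "tukey"
    if test == "t":
        if len(conditions) != 2:
            raise ValueError("t-test requires exactly 2 conditions")
        r = student_t_test(samples[0], samples[1])
        return pd.DataFrame(
            [
                {
                    "group1": conditions[0],
                    "group2": conditions[1],
                    "mean_diff": samples[0].mean() - samples[1].mean(),
                    "statistic": r.statistic,
                    "p": r.pvalue,
                }
            ]
        )
    if test == "tukey":
        return tukey_kramer(samples, labels=conditions)
    raise ValueError(f"unknown test {test!r}")
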