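"""Parametric fitting, lack-of-fit screening and comparison of durations.

Block-performance times have historically been modeled with the normal,
two-parameter lognormal, gamma, and Weibull families.  :func:`fit_family`
fits any of these by maximum likelihood and screens the fit with a
Kolmogorov-Smirnov test against the fitted distribution.  The KS test is run
as if the parameters were known; with estimated parameters this
overestimates p-values (anti-conservative screening), so a family rejected
here would be rejected even more strongly by a corrected test.  No
Lilliefors-type bootstrap correction is applied.

:func:`rank_sum_test` compares two independent duration samples with the
Mann-Whitney U (Wilcoxon rank-sum) test: mid-ranks and a tie-corrected
normal approximation for large samples, exact permutation enumeration for
tiny ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .records import DurationSample

__all__ = [
    "FAMILIES",
    "FitResult",
    "RankSumResult",
    "fit_family",
    "fit_all_families",
    "rank_sum_test",
    "summarize",
]

log = logging.getLogger(__name__)

FAMILIES = ("normal", "lognormal", "gamma", "weibull")

#: Total size below which the rank-sum test enumerates all permutations.
_EXACT_LIMIT = 12


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family plus its KS screen."""

    family: str
    params: dict[str, float]
    ks_D: float
    ks_p: float
    n: int
    n_dropped_zeros: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ks_D <= 1 or not 0 <= self.ks_p <= 1:
            raise ValueError("KS statistic and p-value must lie in [0, 1]")


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    method: str

    def __post_init__(self) -> None:
        if not 0 <= self.p_two_sided <= 1:
            raise ValueError("p-value must lie in [0, 1]")


def _frozen_dist(family: str, x: np.ndarray):
    if family == "normal":
        loc, scale = stats.norm.fit(x)
        return stats.norm(loc, scale), {"mean": loc, "sd": scale}
    if family == "lognormal":
        s, _, scale = stats.lognorm.fit(x, floc=0)
        return stats.lognorm(s, 0, scale), {"mu": math.log(scale), "sigma": s}
    if family == "gamma":
        a, _, scale = stats.gamma.fit(x, floc=0)
        return stats.gamma(a, 0, scale), {"shape": a, "scale": scale}
    if family == "weibull":
        c, _, scale = stats.weibull_min.fit(x, floc=0)
        return stats.weibull_min(c, 0, scale), {"shape": c, "scale": scale}
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def fit_family(sample: DurationSample, family: str) -> FitResult:
    """Fit one family by ML and KS-screen the fit.

    Zero durations are dropped (with a logged warning) for the three
    positive-support families, for which they have zero likelihood.
    """
    x = np.asarray(sample.durations, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 observations to fit")
    dropped = 0
    if family != "normal":
        nz = x > 0
        dropped = int(x.size - nz.sum())
        if dropped:
            log.warning(
                "dropping %d zero duration(s) for %s fit", dropped, family
            )
        x = x[nz]
        if x.size < 10:
            raise ValueError(
                f"family {family!r} undefined: too few positive durations"
            )
    dist, params = _frozen_dist(family, x)
    ks = stats.kstest(x, dist.cdf)
    return FitResult(
        family=family,
        params=params,
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        n=int(x.size),
        n_dropped_zeros=dropped,
    )


def fit_all_families(sample: DurationSample) -> dict[str, FitResult]:
    return {fam: fit_family(sample, fam) for fam in FAMILIES}


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided permutation p-value by full enumeration of group labels.

    p = P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|) over all C(n, n_a)
    relabelings; exact in the presence of ties.
    """
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    center = a.size * b.size / 2.0
    dev = abs(u_obs - center)
    hits = 0
    total = 0
    for idx in combinations(range(n), n_a):
        r = ranks[list(idx)].sum()
        u = r - n_a * (n_a + 1) / 2.0
        if abs(u - center) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total


def rank_sum_test(a: DurationSample, b: DurationSample) -> RankSumResult:
    """Mann-Whitney U test of two independent duration samples.

    Reports U for ``a`` versus ``b`` (number of (a, b) pairs with a < b,
    counting ties as 1/2).  Small samples (n_a + n_b <= 12) use exact
    enumeration of all relabelings; larger ones use the tie-corrected normal
    approximation with continuity correction.
    """
    xa = np.asarray(a.durations, dtype=float)
    xb = np.asarray(b.durations, dtype=float)
    pooled = np.concatenate([xa, xb])
    ranks = stats.rankdata(pooled)
    u_a = ranks[: xa.size].sum() - xa.size * (xa.size + 1) / 2.0
    if xa.size + xb.size <= _EXACT_LIMIT:
        p = _exact_rank_sum_p(xa, xb, u_a)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(xa, xb, alternative="two-sided",
                               method="asymptotic").pvalue
        )
        method = "asymptotic"
    return RankSumResult(
        statistic=float(u_a),
        p_two_sided=float(p),
        n_a=int(xa.size),
        n_b=int(xb.size),
        method=method,
    )


def summarize(sample: DurationSample) -> dict[str, float]:
    """Descriptive summary: mean, sd, se, median, q80, q90 (minutes).

    Quantiles use linear interpolation (summaries describe the sample, not
    a simulated planning limit).
    """
    x = np.asarray(sample.durations, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations (sd undefined)")
    sd = float(x.std(ddof=1))
    q50, q80, q90 = (float(v) for v in np.quantile(x, [0.5, 0.8, 0.9]))
    return {
        "n": int(x.size),
        "mean": float(x.mean()),
        "sd": sd,
        "se": sd / math.sqrt(x.size),
        "median": q50,
        "q80": q80,
        "q90": q90,
    }
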