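"""Monte-Carlo engine for upper prediction limits of block-series times.

The planning question: an anesthesiologist must perform ``k`` nerve blocks
back-to-back before the first cases of the day — how much time should be set
aside so the whole series finishes on schedule with high probability?  Block
times do not follow any of the classic duration families, so the total is
simulated by resampling: each simulated series is the sum of ``k`` draws with
replacement from the observed (empirical) duration sample, and the p-th
percentile of the 100,000 simulated totals is the 100p% upper prediction
limit (UPL).

For ``m`` anesthesiologists working in parallel the per-person coverage is
raised to ``1 - (1 - P)/m`` (Bonferroni), so the joint chance that everyone
finishes within the planned time stays at least ``P``; with two staff and a
90% goal this is the 95% UPL of one person's series.

Uniform variates come from the Mersenne Twister generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .records import DurationSample

__all__ = [
    "SimulationConfig",
    "UPLTable",
    "ConvergenceReport",
    "PlanRequest",
    "simulate_totals",
    "percentile",
    "build_upl_table",
    "plan_series_time",
    "incremental_upl",
    "convergence_check",
    "exact_totals_quantile",
]

_DEF_PERCENTILES = (0.5, 0.8, 0.9, 0.95)


@dataclass(frozen=True)
class SimulationConfig:
    """Resampling settings.

    ``quantile_rule`` is ``"nearest_rank"`` (the ceil(p*n)-th order
    statistic; conservative, and the natural reading of a percentile of a
    large simulated sample) or ``"linear"`` (interpolated, as in
    ``numpy.quantile``).  At ``n_sims = 100_000`` the two differ negligibly.
    """

    n_sims: int = 100_000
    seed: int = 0
    quantile_rule: str = "nearest_rank"
    percentiles: tuple[float, ...] = _DEF_PERCENTILES

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.quantile_rule not in ("nearest_rank", "linear"):
            raise ValueError(f"unknown quantile_rule {self.quantile_rule!r}")
        if any(not 0 < p < 1 for p in self.percentiles):
            raise ValueError("percentiles must lie in (0, 1)")

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Mersenne Twister generator for an independent substream."""
        seq = np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        return np.random.Generator(np.random.MT19937(seq))


@dataclass(frozen=True)
class UPLTable:
    """Rows k = 1..k_max of series-time summaries, in (unrounded) minutes.

    ``upl95`` doubles as the planned time for two anesthesiologists each
    performing k blocks in parallel at overall 90% coverage.
    """

    block_type: str
    k: tuple[int, ...]
    median: tuple[float, ...]
    mean: tuple[float, ...]
    upl80: tuple[float, ...]
    upl90: tuple[float, ...]
    upl95: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.k)
        for name in ("median", "mean", "upl80", "upl90", "upl95"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} length mismatch")
        for med, u80, u90, u95 in zip(
            self.median, self.upl80, self.upl90, self.upl95
        ):
            if not med <= u80 <= u90 <= u95:
                raise ValueError("row percentiles must be non-decreasing")

    def row(self, k: int) -> dict[str, float]:
        i = self.k.index(k)
        return {
            "k": k,
            "median": self.median[i],
            "mean": self.mean[i],
            "upl80": self.upl80[i],
            "upl90": self.upl90[i],
            "upl95": self.upl95[i],
        }


@dataclass(frozen=True)
class ConvergenceReport:
    """Stability of a UPL against truncating the simulation stream."""

    p: float
    n_sims: int
    m_subset: int
    k: tuple[int, ...]
    diff_seconds: tuple[float, ...]

    @property
    def max_diff_seconds(self) -> float:
        return max(self.diff_seconds)


@dataclass(frozen=True)
class PlanRequest:
    """A planning query: n_blocks split among n_anesthesiologists."""

    n_blocks: int
    n_anesthesiologists: int = 1
    coverage: float = 0.90

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.n_anesthesiologists < 1:
            raise ValueError("n_anesthesiologists must be >= 1")
        if not 0 < self.coverage < 1:
            raise ValueError("coverage must lie in (0, 1)")

    @property
    def blocks_per_person(self) -> int:
        """Largest per-person load under an even split."""
        return -(-self.n_blocks // self.n_anesthesiologists)

    @property
    def per_person_coverage(self) -> float:
        """Bonferroni-adjusted coverage so the joint coverage is kept."""
        return 1.0 - (1.0 - self.coverage) / self.n_anesthesiologists


def simulate_totals(
    sample: DurationSample, k: int, config: SimulationConfig, stream: int = 0
) -> np.ndarray:
    """Simulate ``config.n_sims`` totals of k draws with replacement.

    ``stream`` selects an independent substream of the seeded generator so
    that different table rows use independent resamples.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = config.rng(stream)
    idx = rng.integers(0, sample.n, size=(config.n_sims, k))
    return sample.durations[idx].sum(axis=1)


def percentile(
    values: np.ndarray, p: float, rule: str = "nearest_rank"
) -> float:
    """Order-statistic quantile of a simulated vector.

    Nearest-rank returns the ceil(p*n)-th smallest value; ``linear``
    interpolates as ``numpy.quantile`` does.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if rule == "nearest_rank":
        rank = math.ceil(p * values.size)  # 1-based
        return float(np.partition(values, rank - 1)[rank - 1])
    if rule == "linear":
        return float(np.quantile(values, p))
    raise ValueError(f"unknown quantile rule {rule!r}")


def build_upl_table(
    sample: DurationSample, k_max: int, config: SimulationConfig
) -> UPLTable:
    """Simulate rows k = 1..k_max with independent resampling per row."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    med, mean, u80, u90, u95 = [], [], [], [], []
    for k in range(1, k_max + 1):
        totals = simulate_totals(sample, k, config, stream=k)
        med.append(percentile(totals, 0.5, config.quantile_rule))
        mean.append(float(totals.mean()))
        u80.append(percentile(totals, 0.8, config.quantile_rule))
        u90.append(percentile(totals, 0.9, config.quantile_rule))
        u95.append(percentile(totals, 0.95, config.quantile_rule))
    return UPLTable(
        block_type=sample.block_type,
        k=tuple(range(1, k_max + 1)),
        median=tuple(med),
        mean=tuple(mean),
        upl80=tuple(u80),
        upl90=tuple(u90),
        upl95=tuple(u95),
    )


def plan_series_time(
    sample: DurationSample, req: PlanRequest, config: SimulationConfig
) -> float:
    """Planned minutes for the whole team to finish with ``req.coverage``.

    Blocks are split as evenly as possible; the planned time is the
    Bonferroni-adjusted UPL of the largest per-person series.
    """
    k = req.blocks_per_person
    totals = simulate_totals(sample, k, config, stream=k)
    return percentile(totals, req.per_person_coverage, config.quantile_rule)


def incremental_upl(table: UPLTable, p: float) -> np.ndarray:
    """Per-block increments of the UPL column: UPL(k) - UPL(k-1).

    The first increment is the k = 1 UPL itself, so the increments telescope
    back to the cumulative limits.
    """
    if len(table.k) < 2:
        raise ValueError("table must have at least 2 rows")
    col = {0.8: table.upl80, 0.9: table.upl90, 0.95: table.upl95, 0.5: table.median}
    if p not in col:
        raise ValueError(f"no UPL column at p = {p}")
    vals = np.asarray(col[p], dtype=float)
    return np.diff(vals, prepend=0.0)


def convergence_check(
    sample: DurationSample,
    k_max: int,
    config: SimulationConfig,
    m_subset: int = 90_000,
    p: float = 0.95,
) -> ConvergenceReport:
    """Compare UPLs from the full stream against its first ``m_subset`` totals.

    The subset is a prefix of the same stream, so the two estimates are
    positively correlated and the difference isolates the effect of the
    extra simulations.  Differences are reported in seconds.
    """
    if m_subset >= config.n_sims:
        raise ValueError("m_subset must be smaller than n_sims")
    ks, diffs = [], []
    for k in range(1, k_max + 1):
        totals = simulate_totals(sample, k, config, stream=k)
        full = percentile(totals, p, config.quantile_rule)
        part = percentile(totals[:m_subset], p, config.quantile_rule)
        ks.append(k)
        diffs.append(abs(full - part) * 60.0)
    return ConvergenceReport(
        p=p,
        n_sims=config.n_sims,
        m_subset=m_subset,
        k=tuple(ks),
        diff_seconds=tuple(diffs),
    )


def exact_totals_quantile(
    dist: dict[float, float],
    k: int,
    p: float,
    guard: int = 10**6,
) -> float:
    """Exact quantile of the k-fold sum of a finite discrete distribution.

    Brute-force oracle: convolves the value -> probability map k times and
    takes the nearest-rank quantile on the exact CDF (smallest support point
    with CDF >= p).  Refuses supports whose k-fold enumeration would exceed
    ``guard`` outcomes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {total}, not 1")
    if len(dist) ** k > guard:
        raise ValueError("enumeration guard exceeded")
    acc: dict[float, float] = {0.0: 1.0}
    for _ in range(k):
        nxt: dict[float, float] = {}
        for v1, p1 in acc.items():
            for v2, p2 in dist.items():
                key = round(v1 + v2, 9)
                nxt[key] = nxt.get(key, 0.0) + p1 * p2
        acc = nxt
    cdf = 0.0
    for v in sorted(acc):
        cdf += acc[v]
        if cdf >= p - 1e-12:
            return float(v)
    return float(max(acc))  # numerical safety


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
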