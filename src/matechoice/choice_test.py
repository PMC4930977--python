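"""Distance-weighted bootstrap test of random mate choice.

For every reproductive event the eligible candidate males (present that
year, above a minimum age) form a pool, weighted by a dispersal-distance
kernel evaluated at the territory distance to the focal female.  The test
statistic is the mean, over events, of the difference between the observed
social male's (or social pair's) genetic score and the kernel-weighted mean
score of the other candidates.  The null distribution is generated by
re-allocating a pseudo-social male per event from the weighted pool, and the
exact two-tailed P is the proportion of null statistics farther from the
null mean than the observed statistic, by reflection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .genotype_io import PopulationRegistry, ReproductiveEvent

log = logging.getLogger(__name__)

__all__ = [
    "uniform_kernel",
    "exponential_kernel",
    "table_kernel",
    "CandidatePool",
    "build_pool",
    "observed_difference",
    "BootstrapResult",
    "bootstrap_null",
    "exact_two_tailed_p",
    "SpearmanResult",
    "spearman_correlation",
]


# -- dispersal kernels ---------------------------------------------------------


def uniform_kernel(distance: float) -> float:
    """Degenerate kernel: every candidate equally likely regardless of distance."""
    return 1.0


def exponential_kernel(rate: float) -> Callable[[float], float]:
    """Exponential-decay kernel ``exp(-rate * d)`` (rate per distance unit)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")

    def kernel(distance: float) -> float:
        return math.exp(-rate * distance)

    return kernel


def table_kernel(breaks: Sequence[float], probs: Sequence[float]) -> Callable[[float], float]:
    """Step kernel from a distance-bin probability table.

    ``breaks`` are the right edges of the bins (increasing); a distance
    beyond the last edge takes the last bin's probability.
    """
    breaks = list(breaks)
    probs = list(probs)
    if len(breaks) != len(probs):
        raise ValueError("breaks and probs must have equal length")
    if any(p <= 0 for p in probs):
        raise ValueError("bin probabilities must be positive")

    def kernel(distance: float) -> float:
        for edge, p in zip(breaks, probs):
            if distance <= edge:
                return p
        return probs[-1]

    return kernel


# -- candidate pools -----------------------------------------------------------


@dataclass
class CandidatePool:
    """Eligible candidate males for one reproductive event, with weights.

    The observed social male is always a member (the null allocation must be
    able to re-draw him); weights are kernel values normalised to sum 1.
    """

    event: ReproductiveEvent
    males: tuple[str, ...]
    distances: tuple[float, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("pool weights must sum to 1")
        if (self.weights <= 0).any():
            raise ValueError("pool weights must be positive")
        if self.event.social_male not in self.males:
            raise ValueError("social male must be in the pool")

    @property
    def size(self) -> int:
        return len(self.males)

    def index_of_social(self) -> int:
        return self.males.index(self.event.social_male)


def build_pool(
    event: ReproductiveEvent,
    registry: PopulationRegistry,
    min_age: int = 3,
    kernel: Callable[[float], float] = uniform_kernel,
) -> CandidatePool:
    """Build the kernel-weighted candidate pool for one event.

    Eligibility: male, present in the population in the event's year, and at
    least *min_age* years old.  The observed social male is included even if
    he fails the age filter (he demonstrably was available).
    """
    year = event.year
    female_terr = event.territory or registry.territory(event.female, year)
    if female_terr is None:
        raise ValueError(f"no territory for female {event.female!r} in {year}")
    males = registry.males_present(year, min_age=min_age)
    if event.social_male not in males:
        males = males + [event.social_male]
    males = sorted(males)
    distances = []
    weights = []
    for m in males:
        terr = registry.territory(m, year)
        d = registry.distance(female_terr, terr) if terr is not None else 0.0
        k = kernel(d)
        if not (k > 0 and math.isfinite(k)):
            raise ValueError(f"kernel returned non-positive value for distance {d}")
        distances.append(d)
        weights.append(k)
    if not males:
        raise ValueError(f"empty candidate pool for {event.litter_id}")
    w = np.array(weights, dtype=float)
    return CandidatePool(event, tuple(males), tuple(distances), w / w.sum())


# -- the statistic -------------------------------------------------------------


def _event_contributions(
    pool: CandidatePool,
    value: Callable[[ReproductiveEvent, str], float | None],
) -> np.ndarray | None:
    """Per-candidate difference d_i = v_i - weighted mean of the others.

    Returns None when a value is undefined for any pool member (the event is
    dropped) or when the pool is a singleton (contribution pinned at 0).
    """
    vals = []
    for m in pool.males:
        v = value(pool.event, m)
        if v is None or not math.isfinite(v):
            return None
        vals.append(float(v))
    v = np.array(vals)
    w = pool.weights
    if pool.size == 1:
        return np.zeros(1)
    s = float(w @ v)
    return v - (s - w * v) / (1.0 - w)


def observed_difference(
    events: Sequence[ReproductiveEvent],
    pools: Sequence[CandidatePool],
    value: Callable[[ReproductiveEvent, str], float | None],
) -> float:
    """Mean over events of (observed male's score - weighted candidate mean).

    Candidates exclude the observed social male, with weights renormalised.
    Events with any undefined score are dropped with a warning.
    """
    diffs = []
    for pool in pools:
        d = _event_contributions(pool, value)
        if d is None:
            log.warning("dropping %s: undefined statistic", pool.event.litter_id)
            continue
        diffs.append(d[pool.index_of_social()])
    if not diffs:
        raise ValueError("all events dropped: statistic undefined everywhere")
    return float(np.mean(diffs))


@dataclass
class BootstrapResult:
    statistic_name: str
    observed_mean: float
    observed_diff: float
    sim_diffs: np.ndarray
    sim_mean: float
    ci95: tuple[float, float]
    p_two_tailed: float
    B: int
    seed: int | None
    n_events: int
    n_dropped: int = 0
    n_singleton: int = 0
    mode: str = "pool_mean"


def exact_two_tailed_p(observed_diff: float, sim_diffs: Sequence[float]) -> float:
    """Exact two-tailed bootstrap P by reflection around the simulated mean.

    With ``mu = mean(sims)`` and ``d = |observed - mu|``::

        p = (#{s > mu + d} + #{s < mu - d}) / B

    using strict inequalities; the resolution is 1/B.
    """
    sims = np.asarray(sim_diffs, dtype=float)
    if sims.size == 0:
        raise ValueError("sim_diffs must be non-empty")
    mu = sims.mean()
    d = abs(observed_diff - mu)
    return float(((sims > mu + d).sum() + (sims < mu - d).sum()) / sims.size)


def bootstrap_null(
    events: Sequence[ReproductiveEvent],
    pools: Sequence[CandidatePool],
    value: Callable[[ReproductiveEvent, str], float | None],
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    mode: str = "pool_mean",
    statistic_name: str = "statistic",
) -> BootstrapResult:
    """Bootstrap test of random mate choice.

    Each of the *B* replicates re-allocates, per event, a pseudo-social male
    drawn from the kernel-weighted pool, then evaluates the same difference
    statistic against the remaining candidates (weights renormalised).

    ``mode='pool_mean'`` (default) compares each (pseudo-)social male with
    the weighted mean of all other pool members; ``mode='single_candidate'``
    draws one weighted candidate instead, matching a sampled-pair procedure
    (the pool mean is that procedure's expectation).

    Singleton pools contribute 0 and are flagged; events with an undefined
    score are dropped with a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    obs_terms: list[float] = []
    obs_means: list[float] = []
    sim_terms: list[np.ndarray] = []
    n_dropped = n_singleton = 0
    for pool in pools:
        d = _event_contributions(pool, value)
        if d is None:
            log.warning("dropping %s: undefined statistic", pool.event.litter_id)
            n_dropped += 1
            continue
        i_obs = pool.index_of_social()
        obs_means.append(float(value(pool.event, pool.event.social_male)))
        if pool.size == 1:
            n_singleton += 1
            obs_terms.append(0.0)
            sim_terms.append(np.zeros(B))
            continue
        obs_terms.append(float(d[i_obs]))
        # inverse-CDF draws of the pseudo-social male, one per replicate
        cdf = np.cumsum(pool.weights)
        cdf[-1] = 1.0
        draws = np.searchsorted(cdf, rng.random(B), side="right")
        if mode == "pool_mean":
            sim_terms.append(d[draws])
        elif mode == "single_candidate":
            vals = np.array([float(value(pool.event, m)) for m in pool.males])
            others = np.empty(B)
            for b in range(B):
                j = draws[b]
                w = pool.weights.copy()
                w[j] = 0.0
                w /= w.sum()
                k = np.searchsorted(np.cumsum(w), rng.random(), side="right")
                others[b] = vals[min(k, pool.size - 1)]
            sim_terms.append(vals[draws] - others)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    if not obs_terms:
        raise ValueError("all events dropped: statistic undefined everywhere")
    observed_diff = float(np.mean(obs_terms))
    sims = np.vstack(sim_terms).mean(axis=0)
    ci = (float(np.percentile(sims, 2.5)), float(np.percentile(sims, 97.5)))
    return BootstrapResult(
        statistic_name=statistic_name,
        observed_mean=float(np.mean(obs_means)),
        observed_diff=observed_diff,
        sim_diffs=sims,
        sim_mean=float(sims.mean()),
        ci95=ci,
        p_two_tailed=exact_two_tailed_p(observed_diff, sims),
        B=B,
        seed=seed,
        n_events=len(obs_terms),
        n_dropped=n_dropped,
        n_singleton=n_singleton,
        mode=mode,
    )


# -- rank correlations ---------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci95: tuple[float, float]
    p: float
    n: int


def spearman_correlation(a: Sequence[float], b: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average-rank ties.

    The 95% CI uses the Fisher z-transform with standard error
    ``1/sqrt(n - 3)``; the P value is the two-sided test of rho = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(a, b)
    n = a.size
    if n > 3 and abs(rho) < 1:
        z = np.arctanh(rho)
        se = 1.0 / math.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959963984540054 * se)),
              float(np.tanh(z + 1.959963984540054 * se)))
    else:
        ci = (float(rho), float(rho))
    return SpearmanResult(float(rho), ci, float(p), int(n))
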