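"""Shared stratified-permutation machinery.

Every permutation test in the package (timeline enrichment, phenotype age,
gene-set age, regional expression) reduces to the same scheme: draw
``n_perm`` random sets from one or more candidate pools, matching the
observed set's per-stratum counts, compute a statistic per draw, and
summarise the null by its mean and standard deviation.  Centralising the
draw loop guarantees that tests which are formally special cases of one
another (a gene-set age test is a phenotype age test with a single stratum)
consume the random stream identically and return identical numbers at a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import ContractError, ParameterError

__all__ = [
    "DrawLog",
    "NullSummary",
    "stratified_index_draws",
    "stratified_null",
    "z_and_p",
    "empirical_p",
]


@dataclass
class DrawLog:
    """Record of every permutation draw, for brute-force re-computation.

    ``draws[i][s]`` holds the pool indices (positions into ``pools[s]``)
    sampled in permutation ``i`` from stratum ``s``.
    """

    pools: list[np.ndarray]
    counts: list[int]
    draws: list[list[np.ndarray]] = field(default_factory=list)


@dataclass
class NullSummary:
    """Per-statistic null moments over permutations."""

    mean: np.ndarray
    sd: np.ndarray
    stats: np.ndarray  # (n_perm, ...) raw null statistics


def null_moments(null_stats: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample sd over permutations (axis 0).

    A statistic that is *exactly* constant across permutations (e.g. the
    target exhausts its pool) gets mean = that constant and sd = 0 exactly,
    guarding against float summation noise that would otherwise make the
    degenerate case look merely near-degenerate.
    """
    mean = null_stats.mean(axis=0)
    n = null_stats.shape[0]
    sd = null_stats.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    constant = (null_stats == null_stats[0]).all(axis=0)
    mean = np.where(constant, null_stats[0], mean)
    sd = np.where(constant, 0.0, sd)
    return mean, sd


def stratified_index_draws(
    rng: np.random.Generator, pool_sizes: Sequence[int], counts: Sequence[int]
) -> list[np.ndarray]:
    """One permutation: per-stratum index samples without replacement."""
    out = []
    for size, k in zip(pool_sizes, counts):
        if k > size:
            raise ContractError(f"cannot draw {k} from a stratum of size {size}")
        out.append(rng.choice(size, size=k, replace=False, shuffle=False))
    return out


def stratified_null(
    pools: Sequence[np.ndarray],
    counts: Sequence[int],
    n_perm: int,
    statistic: Callable[[np.ndarray], np.ndarray | float],
    seed: int | np.random.Generator | None,
    return_draws: bool = False,
) -> tuple[NullSummary, DrawLog | None]:
    """Null distribution of ``statistic`` over stratified random sets.

    Parameters
    ----------
    pools
        Per-stratum payload arrays (ages, bin indices, ...); a draw
        concatenates per-stratum samples in stratum order.
    counts
        Per-stratum sample sizes, matched for every permutation.
    statistic
        Maps a concatenated payload sample to a scalar or vector.
    seed
        Integer seed or an existing Generator (consumed in place).
    """
    if n_perm < 1:
        raise ContractError("n_perm must be >= 1")
    pools = [np.asarray(p) for p in pools]
    counts = [int(c) for c in counts]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sizes = [p.shape[0] for p in pools]
    log = DrawLog(pools=list(pools), counts=counts) if return_draws else None
    null_stats = None
    for i in range(n_perm):
        idx = stratified_index_draws(rng, sizes, counts)
        sample = np.concatenate([p[j] for p, j in zip(pools, idx)]) if pools else np.array([])
        val = np.asarray(statistic(sample), dtype=float)
        if null_stats is None:
            null_stats = np.empty((n_perm,) + val.shape, dtype=float)
        null_stats[i] = val
        if log is not None:
            log.draws.append(idx)
    mean, sd = null_moments(null_stats)
    return NullSummary(mean=mean, sd=sd, stats=null_stats), log


def z_and_p(observed, null_mean, null_sd):
    """z-score and two-sided normal-tail p against a permutation null.

    Degenerate strata (``null_sd == 0``) follow the convention: z = 0 and
    p = 1 when the observation equals the null mean, otherwise z = +/-inf
    and p = nan (callers fall back on the empirical p there).
    """
    observed = np.asarray(observed, dtype=float)
    null_mean = np.asarray(null_mean, dtype=float)
    null_sd = np.asarray(null_sd, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (observed - null_mean) / null_sd
    degenerate = null_sd == 0
    equal = degenerate & (observed == null_mean)
    z = np.where(equal, 0.0, z)
    with np.errstate(invalid="ignore"):
        z = np.where(degenerate & ~equal, np.sign(observed - null_mean) * np.inf, z)
    p = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(np.where(np.isfinite(z), z, 0.0))), np.nan)
    p = np.where(equal, 1.0, p)
    if np.ndim(z) == 0:
        return float(z), float(p)
    return z, p


def empirical_p(observed, null_stats, null_mean=None):
    """One-tailed empirical p with the +1 correction.

    The tail is chosen by the side of the observation relative to the null
    mean: p = (1 + #{null >= obs}) / (n_perm + 1) for observations at or
    above the mean, the mirror count below.  Bounded below by
    1 / (n_perm + 1).
    """
    null_stats = np.asarray(null_stats, dtype=float)
    n_perm = null_stats.shape[0]
    if null_mean is None:
        null_mean = null_stats.mean(axis=0)
    observed = np.asarray(observed, dtype=float)
    upper = observed >= null_mean
    ge = (null_stats >= observed).sum(axis=0)
    le = (null_stats <= observed).sum(axis=0)
    count = np.where(upper, ge, le)
    p = (1.0 + count) / (n_perm + 1.0)
    if np.ndim(p) == 0:
        return float(p)
    return p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0 < alpha < 1):
        raise ParameterError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ParameterError(f"m must be >= 1, got {m}")
    return alpha / m


def display_threshold(value: float, sig: int = 2) -> float:
    """Round a threshold to ``sig`` significant figures, presentation only."""
    if value == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    factor = 10 ** (exponent - sig + 1)
    return round(value / factor) * factor
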