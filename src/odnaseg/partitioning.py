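"""Sampling distributions for organelle DNA partitioning and amplification.

Division and subsampling are without-replacement (hypergeometric) processes:
each molecule has exactly one fate.  A binomial (with-replacement) variant is
provided for comparison; it allows the same molecule to be inherited twice
and inflates the division variance from n_c/n to 2/n.  Reamplification is a
Polya urn — each new molecule copies a template chosen proportionally to
current counts — whose final composition is beta-binomial.

A minimal physical simulation (`spatial_partition_experiment`) demonstrates
that ordered spatial partitioning (organelle repulsion before cytokinesis)
narrows daughter copy-number variance but leaves heteroplasmy variance
untouched: position ordering carries no information about genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "Pool",
    "partition_binomial",
    "partition_hypergeometric",
    "partition_perfect",
    "polya_amplify",
    "spatial_partition_experiment",
    "subsample",
]


@dataclass
class Pool:
    """A well-mixed pool of wild-type and mutant organelle DNA molecules."""

    n_wild: int
    n_mut: int

    def __post_init__(self) -> None:
        if self.n_wild < 0 or self.n_mut < 0:
            raise ValueError(f"negative counts: ({self.n_wild}, {self.n_mut})")

    @property
    def total(self) -> int:
        return self.n_wild + self.n_mut

    @property
    def h(self) -> float:
        if self.total == 0:
            raise ValueError("heteroplasmy undefined for an empty pool")
        return self.n_mut / self.total


def _check_conserved(parent: Pool, d1: Pool, d2: Pool) -> None:
    assert d1.n_wild + d2.n_wild == parent.n_wild
    assert d1.n_mut + d2.n_mut == parent.n_mut


def _cluster_units(count: int, n_c: int) -> np.ndarray:
    """Sizes of the sampling units for one type: full homoplasmic clusters of
    size n_c plus leftover singletons."""
    full, rem = divmod(count, n_c)
    return np.concatenate([np.full(full, n_c, dtype=np.int64), np.ones(rem, dtype=np.int64)])


def partition_hypergeometric(
    pool: Pool, n_out: int, n_c: int = 1, rng: np.random.Generator | None = None
) -> tuple[Pool, Pool]:
    """Partition ``n_out`` molecules to daughter 1 without replacement.

    For ``n_c > 1`` molecules co-segregate in homoplasmic clusters of size
    n_c (leftovers as singletons); a cluster straddling the n_out boundary is
    split so molecule counts are conserved exactly.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 <= n_out <= pool.total:
        raise ValueError(f"n_out={n_out} outside [0, {pool.total}]")
    if n_c == 1:
        w1 = int(rng.hypergeometric(pool.n_wild, pool.n_mut, n_out)) if n_out else 0
        m1 = n_out - w1
    else:
        sizes = np.concatenate(
            [_cluster_units(pool.n_wild, n_c), _cluster_units(pool.n_mut, n_c)]
        )
        is_mut = np.concatenate(
            [
                np.zeros(len(_cluster_units(pool.n_wild, n_c)), dtype=bool),
                np.ones(len(_cluster_units(pool.n_mut, n_c)), dtype=bool),
            ]
        )
        order = rng.permutation(len(sizes))
        sizes, is_mut = sizes[order], is_mut[order]
        cum = np.cumsum(sizes)
        k = int(np.searchsorted(cum, n_out))
        taken = np.zeros(len(sizes), dtype=np.int64)
        taken[:k] = sizes[:k]
        if k < len(sizes):
            prev = cum[k - 1] if k > 0 else 0
            taken[k] = n_out - prev  # split the straddling unit
        m1 = int(taken[is_mut].sum())
        w1 = n_out - m1
    d1 = Pool(w1, m1)
    d2 = Pool(pool.n_wild - w1, pool.n_mut - m1)
    _check_conserved(pool, d1, d2)
    return d1, d2


def partition_binomial(
    pool: Pool, p: float = 0.5, rng: np.random.Generator | None = None
) -> tuple[Pool, Pool]:
    """With-replacement (binomial) division, provided for comparison.

    Daughter sizes are binomial in the parent total; each daughter then
    draws its molecules with replacement from the parent composition, so the
    same molecule can be inherited several times or by both daughters (the
    deliberately unphysical feature of this model).  Daughter totals sum to
    the parent total, but molecular identity is not conserved, and a halving
    division adds 2/n to the variance instead of the hypergeometric n_c/n.
    """
    rng = np.random.default_rng() if rng is None else rng
    if not 0 < p < 1:
        raise ValueError(f"p must be in (0,1); got {p}")
    if pool.total == 0:
        return Pool(0, 0), Pool(0, 0)
    h = pool.n_mut / pool.total
    n1 = int(rng.binomial(pool.total, p))
    n2 = pool.total - n1
    m1 = int(rng.binomial(n1, h)) if n1 else 0
    m2 = int(rng.binomial(n2, h)) if n2 else 0
    return Pool(n1 - m1, m1), Pool(n2 - m2, m2)


def partition_perfect(
    pool: Pool, rng: np.random.Generator | None = None
) -> tuple[Pool, Pool]:
    """Split each type exactly in half; odd remainders go to a fair coin."""
    rng = np.random.default_rng() if rng is None else rng
    halves = []
    for count in (pool.n_wild, pool.n_mut):
        q, r = divmod(count, 2)
        halves.append(q + (int(rng.integers(2)) if r else 0))
    d1 = Pool(halves[0], halves[1])
    d2 = Pool(pool.n_wild - halves[0], pool.n_mut - halves[1])
    _check_conserved(pool, d1, d2)
    return d1, d2


def polya_amplify(
    pool: Pool, n_target: int, rng: np.random.Generator | None = None
) -> Pool:
    """Amplify a pool to ``n_target`` molecules by a Polya urn.

    Each added molecule copies a template drawn proportionally to current
    counts.  The number of wild-type molecules among the additions is exactly
    beta-binomial(n_add; n_wild, n_mut), which is how it is sampled here
    (Beta mixture of a binomial); tests verify exact agreement with full
    urn-history enumeration.
    """
    rng = np.random.default_rng() if rng is None else rng
    if pool.total == 0:
        raise ValueError("cannot amplify an empty pool")
    if n_target < pool.total:
        raise ValueError(f"n_target={n_target} below current total {pool.total}")
    n_add = n_target - pool.total
    # homoplasmic pools stay homoplasmic; nothing random happens
    if pool.n_mut == 0:
        return Pool(n_target, 0)
    if pool.n_wild == 0:
        return Pool(0, n_target)
    if n_add == 0:
        return Pool(pool.n_wild, pool.n_mut)
    p = rng.beta(pool.n_wild, pool.n_mut)
    w_add = int(rng.binomial(n_add, p))
    return Pool(pool.n_wild + w_add, pool.n_mut + n_add - w_add)


def subsample(
    pool: Pool,
    n_out: int,
    with_replacement: bool = False,
    n_c: int = 1,
    rng: np.random.Generator | None = None,
) -> Pool:
    """Sample ``n_out`` molecules from the pool (hypergeometric by default,
    binomial if ``with_replacement``)."""
    rng = np.random.default_rng() if rng is None else rng
    if with_replacement:
        if pool.total == 0:
            raise ValueError("cannot subsample an empty pool")
        m = int(rng.binomial(n_out, pool.n_mut / pool.total))
        return Pool(n_out - m, m)
    d1, _ = partition_hypergeometric(pool, n_out, n_c=n_c, rng=rng)
    return d1


# ---------------------------------------------------------------------------
# spatial partitioning toy


@njit(cache=True)
def _relax_repulsive(pos: np.ndarray, step: float, tol: float, max_iter: int) -> None:
    """Spread points in the unit square by inverse-distance pair repulsion
    with reflecting boundaries, iterating until max displacement < tol."""
    n = pos.shape[0]
    for _ in range(max_iter):
        fx = np.zeros(n)
        fy = np.zeros(n)
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                r2 = dx * dx + dy * dy + 1e-12
                f = 1.0 / r2
                r = np.sqrt(r2)
                fx[i] += f * dx / r
                fy[i] += f * dy / r
                fx[j] -= f * dx / r
                fy[j] -= f * dy / r
        maxdisp = 0.0
        for i in range(n):
            ddx = step * fx[i]
            ddy = step * fy[i]
            d = np.sqrt(ddx * ddx + ddy * ddy)
            if d > 0.05:  # cap per-iteration motion for stability
                ddx *= 0.05 / d
                ddy *= 0.05 / d
                d = 0.05
            if d > maxdisp:
                maxdisp = d
            x = pos[i, 0] + ddx
            y = pos[i, 1] + ddy
            # reflecting boundaries
            if x < 0.0:
                x = -x
            if x > 1.0:
                x = 2.0 - x
            if y < 0.0:
                y = -y
            if y > 1.0:
                y = 2.0 - y
            pos[i, 0] = x
            pos[i, 1] = y
        if maxdisp < tol:
            break


def spatial_partition_experiment(
    n_organelles: int = 30,
    h0: float = 0.5,
    interaction: str = "none",
    n_reps: int = 10_000,
    seed: int | None = None,
    repulsion_step: float = 2e-4,
    tol: float = 1e-4,
    max_iter: int = 400,
) -> tuple[float, float]:
    """Place organelles in the unit square, optionally relax by short-range
    repulsion, bisect at x = 1/2, and return (var of daughter copy number,
    normalised heteroplasmy variance) across replicates.

    Genotypes are assigned independently of position, so repulsion narrows
    copy-number variance without touching heteroplasmy variance.
    """
    if n_organelles < 2:
        raise ValueError("need at least 2 organelles")
    if interaction not in ("none", "repulsive"):
        raise ValueError(f"unknown interaction {interaction!r}")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_reps, dtype=np.int64)
    hs = np.empty(n_reps)
    valid = np.ones(n_reps, dtype=bool)
    for r in range(n_reps):
        pos = rng.random((n_organelles, 2))
        if interaction == "repulsive":
            _relax_repulsive(pos, repulsion_step, tol, max_iter)
        types = rng.random(n_organelles) < h0  # True = mutant
        left = pos[:, 0] < 0.5
        n_left = int(left.sum())
        counts[r] = n_left
        if n_left == 0:
            valid[r] = False
        else:
            hs[r] = types[left].mean()
    var_n = float(np.var(counts, ddof=1))
    h_ok = hs[valid]
    mh = float(h_ok.mean())
    if not 0 < mh < 1:
        norm_var_h = float("nan")
    else:
        norm_var_h = float(np.var(h_ok, ddof=1) / (mh * (1 - mh)))
    return var_n, norm_var_h
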