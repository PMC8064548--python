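"""Exact stochastic simulation of a single cell's organelle DNA population.

State is the four copy numbers (W_f, W_s, M_f, M_s): wild-type/mutant
molecules in fused versus singleton (fragmented) organelles.  Poisson
processes drive:

* replication with copy-number feedback — per-molecule rate
  r(N) = max(0, nu + (lam - nu)(1 - alpha N)), which equals lam at N = 0 and
  exactly nu at the set point N = 1/alpha, so birth balances death there;
  mutant molecules replicate at r(N)(1 + delta);
* autophagic degradation of singleton molecules only — events at rate
  nu * pool / n_d, each destroying min(n_d, pool) same-type molecules (a
  homoplasmic cluster), preserving the per-molecule rate nu;
* gene conversion restricted to the fused pool — mass action in discordant
  pairs, toward mutant at rate kappa (1 + eps) W_f M_f and toward wild type
  at kappa (1 - eps) W_f M_f, the unique scaling for which dV'/dt =
  2 kappa (1-f)^2 independent of copy number;
* per-molecule fission (alpha_s, fused -> singleton) and fusion (alpha_f,
  singleton -> fused), with equilibrium fragmented fraction
  f = alpha_s / (alpha_s + alpha_f).

The simulator is Gillespie's exact algorithm, compiled with numba; a fixed
seed gives a bitwise-reproducible trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from . import partitioning as pt
from .variance import transform_heteroplasmy

__all__ = [
    "CellState",
    "EnsembleResult",
    "SimParams",
    "apply_division",
    "effective_rho",
    "propensities",
    "run_ensemble",
    "run_trajectory",
]


@dataclass
class CellState:
    """Copy numbers of wild-type/mutant molecules in fused/singleton pools."""

    w_fused: int
    w_single: int
    m_fused: int
    m_single: int
    time_days: float = 0.0

    def __post_init__(self) -> None:
        if min(self.w_fused, self.w_single, self.m_fused, self.m_single) < 0:
            raise ValueError("copy numbers must be nonnegative")

    @property
    def n(self) -> int:
        return self.w_fused + self.w_single + self.m_fused + self.m_single

    @property
    def h(self) -> float:
        if self.n == 0:
            raise ValueError("heteroplasmy undefined at N = 0 (extinct cell)")
        return (self.m_fused + self.m_single) / self.n

    @property
    def f(self) -> float:
        if self.n == 0:
            raise ValueError("fragmentation fraction undefined at N = 0")
        return (self.w_single + self.m_single) / self.n

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.w_fused, self.w_single, self.m_fused, self.m_single],
            dtype=np.int64,
        )


@dataclass
class SimParams:
    """Rates of the stochastic cell model (all per day).

    Defaults: lam = 2, nu = 1, alpha_ctrl = 1/1000 (set point 1000
    molecules), kappa = 0.002, n_d = 1.  ``eps_bias`` > 0 biases gene
    conversion toward the mutant type (aA -> AA favoured).
    """

    lam: float = 2.0
    nu: float = 1.0
    alpha_ctrl: float = 1e-3
    kappa: float = 0.002
    delta_sel: float = 0.0
    eps_bias: float = 0.0
    n_d: int = 1
    rate_fission: float = 0.0
    rate_fusion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lam", "nu", "alpha_ctrl", "kappa", "rate_fission", "rate_fusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not -1.0 <= self.eps_bias <= 1.0:
            raise ValueError("eps_bias must lie in [-1, 1]")
        if self.n_d < 1:
            raise ValueError("n_d must be a positive integer")
        if self.lam < self.nu and self.alpha_ctrl > 0:
            warnings.warn(
                "lam < nu makes the replication feedback destabilising above "
                "the set point (rate grows with N); copy number will not be "
                "controlled",
                stacklevel=2,
            )

    def as_tuple(self) -> tuple:
        return (
            self.lam,
            self.nu,
            self.alpha_ctrl,
            self.kappa,
            self.delta_sel,
            self.eps_bias,
            int(self.n_d),
            self.rate_fission,
            self.rate_fusion,
        )


PROPENSITY_LABELS = (
    "replicate_w_fused",
    "replicate_w_single",
    "replicate_m_fused",
    "replicate_m_single",
    "autophagy_w_single",
    "autophagy_m_single",
    "convert_to_mutant",
    "convert_to_wild",
    "fission_w",
    "fission_m",
    "fusion_w",
    "fusion_m",
)


def propensities(state: CellState, params: SimParams) -> dict[str, float]:
    """Labelled event rates for the current state (empty if extinct)."""
    if state.n == 0:
        return {}
    r = max(0.0, params.nu + (params.lam - params.nu) * (1.0 - params.alpha_ctrl * state.n))
    rm = r * (1.0 + params.delta_sel)
    wf, ws, mf, ms = state.w_fused, state.w_single, state.m_fused, state.m_single
    rates = (
        r * wf,
        r * ws,
        rm * mf,
        rm * ms,
        params.nu * ws / params.n_d,
        params.nu * ms / params.n_d,
        params.kappa * (1.0 + params.eps_bias) * wf * mf,
        params.kappa * (1.0 - params.eps_bias) * wf * mf,
        params.rate_fission * wf,
        params.rate_fission * mf,
        params.rate_fusion * ws,
        params.rate_fusion * ms,
    )
    return dict(zip(PROPENSITY_LABELS, rates))


@njit(cache=True)
def _ssa_core(
    wf: int,
    ws: int,
    mf: int,
    ms: int,
    lam: float,
    nu: float,
    alpha: float,
    kappa: float,
    delta: float,
    eps: float,
    n_d: int,
    a_s: float,
    a_f: float,
    t0: float,
    record_times: np.ndarray,
    seed: int,
) -> np.ndarray:
    np.random.seed(seed)
    n_rec = record_times.shape[0]
    out = np.zeros((n_rec, 4), dtype=np.int64)
    t = t0
    idx = 0
    while idx < n_rec:
        N = wf + ws + mf + ms
        r = nu + (lam - nu) * (1.0 - alpha * N)
        if r < 0.0:
            r = 0.0
        rm = r * (1.0 + delta)
        a0 = r * wf
        a1 = r * ws
        a2 = rm * mf
        a3 = rm * ms
        a4 = nu * ws / n_d
        a5 = nu * ms / n_d
        a6 = kappa * (1.0 + eps) * wf * mf
        a7 = kappa * (1.0 - eps) * wf * mf
        a8 = a_s * wf
        a9 = a_s * mf
        a10 = a_f * ws
        a11 = a_f * ms
        tot = a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9 + a10 + a11
        if tot <= 0.0:
            break  # absorbed (extinct or frozen): state no longer changes
        dt = np.random.exponential(1.0 / tot)
        while idx < n_rec and t + dt > record_times[idx]:
            out[idx, 0] = wf
            out[idx, 1] = ws
            out[idx, 2] = mf
            out[idx, 3] = ms
            idx += 1
        t += dt
        u = np.random.random() * tot
        if u < a0:
            wf += 1
        elif u < a0 + a1:
            ws += 1
        elif u < a0 + a1 + a2:
            mf += 1
        elif u < a0 + a1 + a2 + a3:
            ms += 1
        elif u < a0 + a1 + a2 + a3 + a4:
            k = n_d if ws >= n_d else ws
            ws -= k
        elif u < a0 + a1 + a2 + a3 + a4 + a5:
            k = n_d if ms >= n_d else ms
            ms -= k
        elif u < a0 + a1 + a2 + a3 + a4 + a5 + a6:
            wf -= 1
            mf += 1
        elif u < a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7:
            mf -= 1
            wf += 1
        elif u < a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8:
            wf -= 1
            ws += 1
        elif u < a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9:
            mf -= 1
            ms += 1
        elif u < a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7 + a8 + a9 + a10:
            ws -= 1
            wf += 1
        else:
            ms -= 1
            mf += 1
    # absorbed or past t_max: remaining record points see the frozen state
    while idx < n_rec:
        out[idx, 0] = wf
        out[idx, 1] = ws
        out[idx, 2] = mf
        out[idx, 3] = ms
        idx += 1
    return out


@njit(cache=True)
def _ssa_ensemble(
    init: np.ndarray,
    lam: float,
    nu: float,
    alpha: float,
    kappa: float,
    delta: float,
    eps: float,
    n_d: int,
    a_s: float,
    a_f: float,
    record_times: np.ndarray,
    seeds: np.ndarray,
) -> np.ndarray:
    n_reps = seeds.shape[0]
    out = np.zeros((n_reps, record_times.shape[0], 4), dtype=np.int64)
    for rep in range(n_reps):
        out[rep] = _ssa_core(
            init[0], init[1], init[2], init[3],
            lam, nu, alpha, kappa, delta, eps, n_d, a_s, a_f,
            0.0, record_times, seeds[rep],
        )
    return out


def _seeds(seed: int | None, n: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n, dtype=np.uint32).astype(np.int64)


def run_trajectory(
    initial: CellState,
    params: SimParams,
    t_max: float,
    record_times: np.ndarray | list | None = None,
    seed: int | None = None,
) -> list[CellState]:
    """One exact SSA trajectory, recorded at ``record_times`` (default: 51
    evenly spaced points on [0, t_max])."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if record_times is None:
        record_times = np.linspace(0.0, t_max, 51)
    rt = np.asarray(record_times, dtype=np.float64)
    seed_val = int(_seeds(seed, 1)[0])
    raw = _ssa_core(
        initial.w_fused, initial.w_single, initial.m_fused, initial.m_single,
        *params.as_tuple(), initial.time_days, rt, seed_val,
    )
    return [
        CellState(*map(int, raw[i]), time_days=float(rt[i])) for i in range(len(rt))
    ]


@dataclass
class EnsembleResult:
    """Per-time heteroplasmy statistics across SSA replicates.

    Extinct cells (N = 0) carry no heteroplasmy and are excluded from the
    statistics; their count is tracked in ``extinct_frac``.
    """

    times: np.ndarray
    mean_h: np.ndarray
    var_h: np.ndarray
    norm_var: np.ndarray
    norm_var_se: np.ndarray
    mean_n: np.ndarray
    extinct_frac: np.ndarray
    n_reps: int
    seed: int | None
    states: np.ndarray | None = field(default=None, repr=False)


def run_ensemble(
    initial: CellState,
    params: SimParams,
    t_max: float,
    record_times: np.ndarray | list | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
    keep_states: bool = False,
) -> EnsembleResult:
    """Ensemble heteroplasmy statistics: E(h), V(h), V'(h) per record time,
    with SE(V') = V' sqrt(2/(m-1)) for m surviving replicates."""
    if n_reps < 2:
        raise ValueError("need at least 2 replicates")
    if record_times is None:
        record_times = np.linspace(0.0, t_max, 11)
    rt = np.asarray(record_times, dtype=np.float64)
    seeds = _seeds(seed, n_reps)
    raw = _ssa_ensemble(
        initial.as_array(), *params.as_tuple(), rt, seeds
    )  # (reps, times, 4)
    n_tot = raw.sum(axis=2).astype(float)  # (reps, times)
    m_tot = raw[:, :, 2] + raw[:, :, 3]
    alive = n_tot > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        h = np.where(alive, m_tot / np.where(alive, n_tot, 1.0), np.nan)
    n_alive = alive.sum(axis=0)
    mean_h = np.full(len(rt), np.nan)
    var_h = np.full(len(rt), np.nan)
    norm_var = np.full(len(rt), np.nan)
    se = np.full(len(rt), np.nan)
    for j in range(len(rt)):
        hj = h[alive[:, j], j]
        if len(hj) < 2:
            continue
        mean_h[j] = hj.mean()
        var_h[j] = hj.var(ddof=1)
        if 0.0 < mean_h[j] < 1.0:
            norm_var[j] = var_h[j] / (mean_h[j] * (1.0 - mean_h[j]))
            se[j] = norm_var[j] * np.sqrt(2.0 / (len(hj) - 1))
    return EnsembleResult(
        times=rt,
        mean_h=mean_h,
        var_h=var_h,
        norm_var=norm_var,
        norm_var_se=se,
        mean_n=n_tot.mean(axis=0),
        extinct_frac=1.0 - n_alive / n_reps,
        n_reps=n_reps,
        seed=seed,
        states=raw if keep_states else None,
    )


def apply_division(
    state: CellState,
    mode: str = "hypergeometric",
    n_c: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[CellState, CellState]:
    """Partition a cell's four pools into two daughters (molecules conserved).

    Modes: 'hypergeometric' (each daughter gets exactly N/2 molecules sampled
    without replacement, cluster-wise for n_c > 1), 'binomial' (independent
    fair coin per molecule), 'perfect' (each pool halved exactly, odd
    remainders by coin).
    """
    rng = np.random.default_rng() if rng is None else rng
    if state.n < 2:
        raise ValueError("cannot divide a cell with fewer than 2 molecules")
    pools = state.as_array()
    if mode == "perfect":
        d1 = np.array([p // 2 + (int(rng.integers(2)) if p % 2 else 0) for p in pools])
    elif mode == "binomial":
        d1 = np.array([int(rng.binomial(p, 0.5)) for p in pools])
    elif mode == "hypergeometric":
        n_half = state.n // 2
        if n_c == 1:
            d1 = rng.multivariate_hypergeometric(pools, n_half)
        else:
            w_tot = int(pools[0] + pools[1])
            m_tot = int(pools[2] + pools[3])
            p1, _ = pt.partition_hypergeometric(
                pt.Pool(w_tot, m_tot), n_half, n_c=n_c, rng=rng
            )
            # distribute each type's share over fused/singleton pools
            wf1 = int(rng.hypergeometric(pools[0], pools[1], p1.n_wild)) if p1.n_wild else 0
            mf1 = int(rng.hypergeometric(pools[2], pools[3], p1.n_mut)) if p1.n_mut else 0
            d1 = np.array([wf1, p1.n_wild - wf1, mf1, p1.n_mut - mf1])
    else:
        raise ValueError(f"unknown division mode {mode!r}")
    d2 = pools - d1
    t = state.time_days
    return (
        CellState(*map(int, d1), time_days=t),
        CellState(*map(int, d2), time_days=t),
    )


def effective_rho(
    params: SimParams,
    h0: float = 0.5,
    t_grid: np.ndarray | list | None = None,
    n_reps: int = 2000,
    n_init: int = 1000,
    seed: int | None = None,
) -> float:
    """Calibrate the effective selection strength rho empirically.

    Runs an ensemble, transforms the mean heteroplasmy trajectory to
    z(t) = logit(E(h)) - logit(h0), and fits the through-origin slope, which
    under logistic dynamics is exactly rho.  Warns if the trajectory is not
    logistic (through-origin R^2 < 0.99).
    """
    if t_grid is None:
        t_grid = np.linspace(0.0, 10.0, 11)
    t_grid = np.asarray(t_grid, dtype=float)
    m0 = int(round(n_init * h0))
    init = CellState(0, n_init - m0, 0, m0)
    res = run_ensemble(
        init, params, t_max=float(t_grid[-1]), record_times=t_grid,
        n_reps=n_reps, seed=seed,
    )
    ok = np.isfinite(res.mean_h) & (res.mean_h > 0) & (res.mean_h < 1)
    t = t_grid[ok]
    z = np.array([transform_heteroplasmy(m, h0) for m in res.mean_h[ok]])
    denom = float(np.sum(t * t))
    if denom == 0:
        raise ValueError("t_grid must contain nonzero times")
    slope = float(np.sum(t * z) / denom)
    resid = z - slope * t
    ss_tot = float(np.sum(z**2))
    if ss_tot > 1e-4:  # a near-zero trajectory carries no shape information
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
        if r2 < 0.99:
            warnings.warn(
                f"transformed mean trajectory is not well described by a "
                f"linear (logistic) law: through-origin R^2 = {r2:.3f}",
                stacklevel=2,
            )
    return slope
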