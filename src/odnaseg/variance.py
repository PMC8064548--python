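"""Closed-form contributions of cellular mechanisms to heteroplasmy variance.

The central quantity is the normalised cell-to-cell heteroplasmy variance

    V'(h) = V(h) / (E(h) (1 - E(h))),

a drift-scale measure of how far a population of cells has segregated towards
homoplasmy.  Its reciprocal N_b = 1/V'(h) is the effective bottleneck size:
the number of independently segregating units that would produce the same
variance under a single binomial sampling step.

Five cellular mechanisms add to V'(h), and to first order their contributions
sum:

    (i)   partitioning at cell division        n_c / n
    (ii)  turnover (autophagy + replication)   (1 + n_d) f nu t / n
    (iii) gene conversion (recombination)      2 kappa (1 - f)^2 t
    (iv)  cellular subsampling                 n_c (1/n2 - 1/n1)
    (v)   reamplification (Polya urn growth)   1/n1 - 1/n2

where n is copy number, n_c the homoplasmic cluster size of co-segregating
molecules, n_d the number of molecules destroyed per autophagy event, f the
fraction of molecules in fragmented (singleton) organelles, nu the
per-molecule degradation rate and kappa the gene-conversion rate.  Note that
(iii) is independent of copy number: gene conversion can segregate organelle
DNA without any physical bottleneck.

Under selection with scaled replicative difference rho, the mean follows a
logistic trajectory and the variance a closed form implemented in
:func:`selection_variance`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
import numpy as np

__all__ = [
    "EventKind",
    "MechanismEvent",
    "Schedule",
    "SelectionParams",
    "VarianceSummary",
    "amplification_contribution",
    "bottleneck_param",
    "bottleneck_size",
    "cascade_variance",
    "conversion_contribution",
    "division_contribution",
    "inverse_transform",
    "normalise_variance",
    "selection_mean",
    "selection_norm_var",
    "selection_variance",
    "subsample_contribution",
    "total_normalised_variance",
    "transform_heteroplasmy",
    "turnover_contribution",
]


class SegregationWarning(UserWarning):
    """Total variance is approaching the first-order theory's validity limit."""


# ---------------------------------------------------------------------------
# basic statistics


def normalise_variance(var_h: float, mean_h: float) -> float:
    """Normalised heteroplasmy variance V'(h) = V(h) / (E(h)(1-E(h))).

    Parameters
    ----------
    var_h : nonnegative heteroplasmy variance V(h).
    mean_h : mean heteroplasmy E(h), strictly inside (0, 1).
    """
    if not 0.0 < mean_h < 1.0:
        raise ValueError(
            f"mean heteroplasmy must lie strictly in (0,1); got {mean_h} "
            "(variance is undefined at fixation)"
        )
    if var_h < 0:
        raise ValueError(f"variance must be nonnegative; got {var_h}")
    return var_h / (mean_h * (1.0 - mean_h))


def bottleneck_size(norm_var: float) -> float:
    """Effective bottleneck size N_b = 1/V'(h)."""
    if norm_var <= 0:
        raise ValueError(f"normalised variance must be positive; got {norm_var}")
    return 1.0 / norm_var


def bottleneck_param(norm_var: float) -> float:
    """Bottleneck parameter b = 1 - V'(h) (1 at no segregation, 0 at fixation)."""
    if norm_var <= 0:
        raise ValueError(f"normalised variance must be positive; got {norm_var}")
    return 1.0 - norm_var


# ---------------------------------------------------------------------------
# per-mechanism contributions


def division_contribution(n: float, n_c: float = 1) -> float:
    """Variance added by one cell division: n_c / n.

    ``n`` is the copy number immediately before division; ``n_c`` the size of
    homoplasmic clusters partitioned as single units (n_c = 1 for individual
    molecules or heteroplasmic clusters).  Copy numbers may be non-integral
    when they represent points on an average (e.g. geometric) profile.
    """
    if n < 2:
        raise ValueError(f"need at least 2 molecules to divide; got n={n}")
    if n_c < 1 or n_c > n:
        raise ValueError(f"cluster size n_c={n_c} outside [1, n={n}]")
    return n_c / n


def turnover_contribution(
    nu: float, f: float, t: float, n: float, n_d: int = 1
) -> float:
    """Variance added by turnover over a cell cycle: (1 + n_d) nu f t / n.

    Only molecules in fragmented organelles (fraction ``f``) are exposed to
    autophagy, which removes ``n_d`` same-type molecules per event; the
    compensating replication contributes the extra ``1`` in ``(1 + n_d)``.
    With n_d = 1 and f = 1 this is the classical 2 nu t / n.
    """
    if nu < 0 or t < 0 or not 0 <= f <= 1 or n < 1 or n_d < 1:
        raise ValueError("turnover parameters out of domain")
    return (1 + n_d) * nu * f * t / n


def conversion_contribution(
    kappa: float, f: float, t: float, n_compartments: int = 1
) -> float:
    """Variance added by gene conversion over a cell cycle: 2 kappa (1-f)^2 t.

    Independent of copy number.  Only the fused fraction ``(1-f)`` of
    molecules can recombine.  For plastid-like cells where organelles never
    fuse, the conversion rate is divided by ``n_compartments``, the number of
    separate organelle gene pools.
    """
    if kappa < 0 or t < 0 or not 0 <= f <= 1 or n_compartments < 1:
        raise ValueError("conversion parameters out of domain")
    return 2.0 * (kappa / n_compartments) * (1.0 - f) ** 2 * t


def subsample_contribution(
    n1: float, n2: float, n_c: float = 1, exact: bool = False
) -> float:
    """Variance added by subsampling n1 -> n2 molecules without replacement.

    Default is the first-order form n_c (1/n2 - 1/n1); ``exact=True`` gives
    the exact hypergeometric normalised variance n_c (n1-n2) / (n2 (n1-1)),
    which matters only at very small copy numbers.
    """
    if not 1 <= n2 <= n1:
        raise ValueError(f"need 1 <= n2 <= n1; got n1={n1}, n2={n2}")
    if n_c < 1:
        raise ValueError(f"cluster size must be >= 1; got {n_c}")
    if exact:
        if n1 == 1:
            return 0.0
        return n_c * (n1 - n2) / (n2 * (n1 - 1))
    return n_c * (1.0 / n2 - 1.0 / n1)


def amplification_contribution(n1: float, n2: float) -> float:
    """Variance added by Polya-urn reamplification n1 -> n2: 1/n1 - 1/n2."""
    if not 1 <= n1 <= n2:
        raise ValueError(f"need 1 <= n1 <= n2; got n1={n1}, n2={n2}")
    return 1.0 / n1 - 1.0 / n2


# ---------------------------------------------------------------------------
# event / schedule containers


class EventKind(str, Enum):
    DIVISION = "division"
    TURNOVER_EPOCH = "turnover_epoch"
    CONVERSION_EPOCH = "conversion_epoch"
    SUBSAMPLE = "subsample"
    AMPLIFY = "amplify"


_EPOCH_KINDS = {EventKind.TURNOVER_EPOCH, EventKind.CONVERSION_EPOCH}


@dataclass
class MechanismEvent:
    """One variance-generating event in a cell lineage.

    ``n1``/``n2`` are copy numbers before/after the event; epochs carry a
    duration and rates, instantaneous events (division, subsample, amplify)
    have zero duration.
    """

    kind: EventKind
    n1: float
    n2: float | None = None
    duration_days: float = 0.0
    turnover_rate: float = 0.0
    conversion_rate: float = 0.0
    frag_fraction: float = 1.0
    cluster_size: int = 1
    autophagy_size: int = 1
    n_compartments: int = 1

    def __post_init__(self) -> None:
        self.kind = EventKind(self.kind)
        if self.n1 < 1:
            raise ValueError(f"{self.kind.value}: n1 must be >= 1, got {self.n1}")
        if self.n2 is None:
            self.n2 = self.n1 // 2 if self.kind is EventKind.DIVISION else self.n1
        if self.kind in _EPOCH_KINDS:
            if self.duration_days <= 0:
                raise ValueError(
                    f"{self.kind.value}: epochs need duration_days > 0"
                )
        elif self.duration_days != 0:
            raise ValueError(
                f"{self.kind.value}: instantaneous events have duration_days = 0"
            )
        if self.kind is EventKind.SUBSAMPLE and self.n2 > self.n1:
            raise ValueError(f"subsample requires n2 <= n1 ({self.n2} > {self.n1})")
        if self.kind is EventKind.AMPLIFY and self.n2 < self.n1:
            raise ValueError(f"amplify requires n2 >= n1 ({self.n2} < {self.n1})")
        if not 0 <= self.frag_fraction <= 1:
            raise ValueError(f"frag_fraction must be in [0,1]; got {self.frag_fraction}")

    def contribution(self, exact_sampling: bool = False) -> float:
        """This event's additive contribution to V'(h)."""
        if self.kind is EventKind.DIVISION:
            return division_contribution(self.n1, self.cluster_size)
        if self.kind is EventKind.TURNOVER_EPOCH:
            return turnover_contribution(
                self.turnover_rate,
                self.frag_fraction,
                self.duration_days,
                self.n1,
                self.autophagy_size,
            )
        if self.kind is EventKind.CONVERSION_EPOCH:
            return conversion_contribution(
                self.conversion_rate,
                self.frag_fraction,
                self.duration_days,
                self.n_compartments,
            )
        if self.kind is EventKind.SUBSAMPLE:
            return subsample_contribution(
                self.n1, self.n2, self.cluster_size, exact=exact_sampling
            )
        return amplification_contribution(self.n1, self.n2)


@dataclass
class Schedule:
    """An ordered chain of mechanism events with consistent copy numbers."""

    events: list[MechanismEvent] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for i, (a, b) in enumerate(zip(self.events, self.events[1:])):
            if not math.isclose(a.n2, b.n1, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"schedule {self.label!r}: copy numbers do not chain at "
                    f"event {i}->{i+1}: n2={a.n2} but next n1={b.n1}"
                )

    @property
    def total_duration_days(self) -> float:
        return sum(e.duration_days for e in self.events)

    def __add__(self, other: "Schedule") -> "Schedule":
        return Schedule(self.events + other.events, label=f"{self.label}+{other.label}")


@dataclass
class VarianceSummary:
    """Mean/variance of heteroplasmy with the derived bottleneck statistics."""

    mean_h: float
    var_h: float
    norm_var: float
    bottleneck_size: float
    bottleneck_param: float

    @classmethod
    def from_moments(cls, mean_h: float, var_h: float) -> "VarianceSummary":
        nv = normalise_variance(var_h, mean_h)
        return cls.from_norm_var(nv, mean_h)

    @classmethod
    def from_norm_var(cls, norm_var: float, mean_h: float = 0.5) -> "VarianceSummary":
        if norm_var > 1.0:
            raise ValueError(
                f"normalised variance {norm_var} > 1 exceeds the fixation bound"
            )
        if norm_var < 0:
            raise ValueError(f"normalised variance must be >= 0; got {norm_var}")
        nb = math.inf if norm_var == 0 else 1.0 / norm_var
        return cls(
            mean_h=mean_h,
            var_h=norm_var * mean_h * (1 - mean_h),
            norm_var=norm_var,
            bottleneck_size=nb,
            bottleneck_param=1.0 - norm_var,
        )


def total_normalised_variance(
    schedule: Schedule,
    h0: float = 0.5,
    exact_sampling: bool = False,
) -> VarianceSummary:
    """Sum the per-event contributions of a schedule into a VarianceSummary.

    The first-order theory is additive; sums above 0.5 are flagged and sums
    above 1.0 (beyond the fixation bound, where the linear theory has broken
    down) are capped at 1.0 with a hard warning.
    """
    total = sum(e.contribution(exact_sampling=exact_sampling) for e in schedule.events)
    if total > 1.0:
        warnings.warn(
            f"summed V'(h) = {total:.4g} exceeds the fixation bound 1; the "
            "first-order theory has saturated (reporting capped at 1)",
            SegregationWarning,
            stacklevel=2,
        )
        total = 1.0
    elif total > 0.5:
        warnings.warn(
            f"summed V'(h) = {total:.4g} > 0.5: first-order additivity is "
            "approaching the fixation bound and will overestimate variance",
            SegregationWarning,
            stacklevel=2,
        )
    return VarianceSummary.from_norm_var(total, mean_h=h0)


# ---------------------------------------------------------------------------
# division/reamplification cascades


def cascade_variance(N0: float, Nk: float, k: int, n_c: float = 1) -> float:
    """V'(h) accrued when copy number moves from N0 to Nk over k cell cycles.

    Each cycle amplifies the population by a constant factor a = 2(Nk/N0)^(1/k)
    (replication during the cycle) and then halves it at division, so the
    post-division copy number follows the geometric profile N0 (a/2)^i.
    Closed form:

        V' = (a + n_c - 1) / (a N0) * ((2/a)^k - 1) / ((2/a) - 1)

    with the a -> 2 (constant copy number) limit k (a + n_c - 1) / (a N0).
    Requires a >= 1, i.e. depletion no faster than halving each cycle.
    """
    if k < 1:
        raise ValueError(f"need at least one cell cycle; got k={k}")
    if N0 < 2 or Nk < 1:
        raise ValueError(f"copy numbers out of domain: N0={N0}, Nk={Nk}")
    if n_c < 1:
        raise ValueError(f"cluster size must be >= 1; got {n_c}")
    a = 2.0 * (Nk / N0) ** (1.0 / k)
    if a < 1.0:
        raise ValueError(
            f"depletion faster than halving per division (a={a:.4g} < 1); "
            "the amplify-then-divide cascade does not apply"
        )
    r = 2.0 / a
    if abs(r - 1.0) < 1e-12:
        geo = float(k)
    else:
        geo = (r**k - 1.0) / (r - 1.0)
    return (a + n_c - 1.0) / (a * N0) * geo


def cascade_schedule(N0: float, Nk: float, k: int, n_c: float = 1, label: str = "") -> Schedule:
    """The explicit event chain whose summed contributions equal
    :func:`cascade_variance`: per cycle, amplify n -> a*n then divide."""
    a = 2.0 * (Nk / N0) ** (1.0 / k)
    events: list[MechanismEvent] = []
    n = float(N0)
    for i in range(k):
        n_hi = n * a
        events.append(MechanismEvent(EventKind.AMPLIFY, n1=n, n2=n_hi))
        events.append(
            MechanismEvent(
                EventKind.DIVISION, n1=n_hi, n2=n_hi / 2, cluster_size=n_c
            )
        )
        n = n_hi / 2.0
    return Schedule(events, label=label or f"cascade-{N0}-{Nk}-{k}")


# ---------------------------------------------------------------------------
# selection theory


@dataclass
class SelectionParams:
    """Parameters of the selection theory.

    ``rho`` is the scaled replicative difference between the two organelle
    DNA types (per day); ``turnover_nu`` and ``frag_fraction`` enter only
    through the product nu*f; ``copy_number`` is the (equilibrated) cellular
    copy number N; ``h0`` the founder heteroplasmy.
    """

    rho: float
    turnover_nu: float = 0.0
    frag_fraction: float = 1.0
    copy_number: int = 1000
    h0: float = 0.5

    def __post_init__(self) -> None:
        if self.copy_number < 1:
            raise ValueError(f"copy_number must be >= 1; got {self.copy_number}")
        if not 0 < self.h0 < 1:
            raise ValueError(f"h0 must be in (0,1); got {self.h0}")


def selection_mean(rho: float, t: float, h0: float = 0.5):
    """Mean heteroplasmy under selection: the logistic trajectory.

    E(h)(t) = h0 e^{rho t} / (1 + h0 (e^{rho t} - 1)), i.e. the curve whose
    logit is logit(h0) + rho t.  At h0 = 1/2 this is 1/(1 + e^{-rho t}).
    """
    h0 = np.asarray(h0, dtype=float)
    if np.any(h0 <= 0) or np.any(h0 >= 1):
        raise ValueError("h0 must be in (0,1)")
    e = np.exp(np.asarray(rho, dtype=float) * np.asarray(t, dtype=float))
    out = h0 * e / (1.0 + h0 * (e - 1.0))
    return out if out.ndim else float(out)

# |rho t| below this uses the neutral-limit variance (the closed form is 0/0
# at rho = 0; cancellation is still benign at 1e-8 but pointless).
_RHO_T_TINY = 1e-9


def selection_norm_var(rho: float, nu_f: float, N: int, t: float):
    """Normalised heteroplasmy variance V'(h)(t) under selection.

    Closed-form solution of the linear-noise moment equations at reference
    h0 = 1/2 — dE/dt = rho E(1-E), dV/dt = 2 rho (1-2E) V + 2 nu_f E(1-E)/N
    — ignoring recombination and assuming large, equilibrated copy number N:

        V'(t) = (2 nu_f / N) [2t + 2 sinh(rho t)/rho] x/(1+x)^2,  x = e^{rho t}

    (equivalently Var(z)(t) = (2 nu_f/N)[2t + 2 sinh(rho t)/rho] on the
    transformed scale, rescaled by E(1-E)).  The rho -> 0 limit is the
    neutral 2 nu_f t / N, to which this dispatches for tiny |rho t|.
    """
    if N < 1:
        raise ValueError(f"copy number must be >= 1; got {N}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    if abs(rho) * float(np.max(t, initial=0.0)) < _RHO_T_TINY:
        out = 2.0 * nu_f * t / N
        return out if out.ndim else float(out)
    x = np.exp(rho * t)
    var_z = (2.0 * nu_f / N) * (2.0 * t + 2.0 * np.sinh(rho * t) / rho)
    out = var_z * x / (1.0 + x) ** 2
    return out if out.ndim else float(out)


def selection_variance(params: SelectionParams, t: float):
    """Raw heteroplasmy variance V(h)(t) under selection for founder h0.

    The normalised variance from the closed form (derived at h0 = 1/2) is
    rescaled by E(1-E) at the founder's own logistic mean trajectory; at
    h0 = 1/2 this is exactly the closed form.
    """
    nu_f = params.turnover_nu * params.frag_fraction
    nv = selection_norm_var(params.rho, nu_f, params.copy_number, t)
    mean = selection_mean(params.rho, t, params.h0)
    out = np.asarray(nv) * np.asarray(mean) * (1.0 - np.asarray(mean))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# the heteroplasmy transform


def transform_heteroplasmy(h, h0: float = 0.5):
    """z = logit(h) - logit(h0): heteroplasmy on the founder-referenced
    transformed scale, on which the selection mean is exactly rho*t.

    Raises for fixated values h in {0, 1} (report those as censored).
    """
    h = np.asarray(h, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if np.any(h <= 0) or np.any(h >= 1):
        raise ValueError("h must be strictly in (0,1); fixated cells are censored")
    if np.any(h0 <= 0) or np.any(h0 >= 1):
        raise ValueError("h0 must be strictly in (0,1)")
    out = np.log(h / (1.0 - h)) - np.log(h0 / (1.0 - h0))
    return out if out.ndim else float(out)


def inverse_transform(z, h0: float = 0.5):
    """Invert :func:`transform_heteroplasmy`: maps any real z into (0,1)."""
    z = np.asarray(z, dtype=float)
    h0 = np.asarray(h0, dtype=float)
    if np.any(h0 <= 0) or np.any(h0 >= 1):
        raise ValueError("h0 must be strictly in (0,1)")
    logit = z + np.log(h0 / (1.0 - h0))
    out = 1.0 / (1.0 + np.exp(-logit))
    return out if out.ndim else float(out)
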