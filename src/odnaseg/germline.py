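"""Developmental schedules for the mouse female germline bottleneck.

Germline development is represented as phases of paired replication/division
cycles: 29 divisions of period 7 h during which mtDNA copy number falls
geometrically from ~1e5 to a minimum b (the physical bottleneck, a fitted
quantity), then 7 divisions of period 16 h during which it regrows to ~5,000,
followed by reamplification to 1e5 in the maturing oocyte — 36 divisions in
all.  After development, ongoing mtDNA turnover in the ageing oocyte adds
variance linearly with age at rate (1 + n_d) * (nu f / n) per day; only the
compound nu f / n is identifiable from oocyte data.

Competing bottleneck mechanisms are expressed as schedule variants:

* ``div_turnover_amp`` — divisions + turnover + reamplification (i+ii+v);
* ``subsample_amp``    — a single discrete subsampling event during oogenesis
                         followed by reamplification (iv+v), no ageing term;
* ``clustered``        — divisions of homoplasmic mtDNA clusters, n_c > 1 (i+v);
* ``with_selection``   — div_turnover_amp plus a replicative difference rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variance import (
    EventKind,
    MechanismEvent,
    Schedule,
    amplification_contribution,
    cascade_schedule,
    cascade_variance,
    inverse_transform,
    selection_norm_var,
    subsample_contribution,
)

__all__ = [
    "GermlineSchedule",
    "Prediction",
    "MODEL_TAGS",
    "developmental_norm_var",
    "model_variants",
    "mouse_schedule",
    "predict_norm_var",
    "predict_with_selection",
    "prediction_interval",
]

MOUSE_N_START = 100_000
MOUSE_DEPLETE_DIVISIONS = 29
MOUSE_DEPLETE_PERIOD_DAYS = 7.0 / 24.0
MOUSE_REGROW_TO = 5_000
MOUSE_REGROW_DIVISIONS = 7
MOUSE_REGROW_PERIOD_DAYS = 16.0 / 24.0

MODEL_TAGS = ("div_turnover_amp", "subsample_amp", "clustered", "with_selection")


@dataclass
class GermlineSchedule:
    """A phased developmental copy-number profile plus ageing turnover.

    ``phases`` is a list of (n_divisions, period_days, copy_start, copy_end);
    within each phase, copy number follows the amplify-then-halve geometric
    cascade.  ``subsample_to`` (used by the subsample_amp variant) inserts a
    single discrete subsampling event after the phases.  ``final_amplify_to``
    is the mature-oocyte copy number.  ``ageing_turnover`` is the compound
    statistic nu f / n (per day).
    """

    phases: list[tuple[int, float, float, float]] = field(default_factory=list)
    ageing_turnover: float = 0.0
    bottleneck_min: float = 0.0
    n_c: float = 1
    n_d: int = 1
    subsample_to: float | None = None
    final_amplify_to: float | None = None
    model_tag: str = "div_turnover_amp"

    def __post_init__(self) -> None:
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {self.model_tag!r}")
        if self.ageing_turnover < 0:
            raise ValueError("ageing_turnover must be nonnegative")
        for i, (a, b) in enumerate(zip(self.phases, self.phases[1:])):
            if not np.isclose(a[3], b[2]):
                raise ValueError(
                    f"phase copy numbers do not chain at {i}->{i+1}: "
                    f"{a[3]} vs {b[2]}"
                )
        mins = [min(p[2], p[3]) for p in self.phases]
        if self.subsample_to is not None:
            mins.append(self.subsample_to)
        if mins and self.bottleneck_min == 0.0:
            self.bottleneck_min = min(mins)

    @property
    def n_divisions(self) -> int:
        return sum(p[0] for p in self.phases)

    @property
    def total_duration_days(self) -> float:
        return sum(p[0] * p[1] for p in self.phases)

    @property
    def oocyte_copy_number(self) -> float:
        if self.final_amplify_to is not None:
            return self.final_amplify_to
        if self.phases:
            return self.phases[-1][3]
        return MOUSE_N_START

    def to_event_schedule(self) -> Schedule:
        """The explicit mechanism-event chain of the developmental part
        (divisions/amplifications/subsampling; ageing epochs are appended by
        the prediction functions, which know the age)."""
        events: list[MechanismEvent] = []
        for (k, _period, n0, nk) in self.phases:
            events.extend(cascade_schedule(n0, nk, k, n_c=self.n_c).events)
        n_cur = self.phases[-1][3] if self.phases else float(MOUSE_N_START)
        if self.subsample_to is not None:
            events.append(
                MechanismEvent(
                    EventKind.SUBSAMPLE,
                    n1=n_cur,
                    n2=self.subsample_to,
                    cluster_size=int(self.n_c) if self.n_c == int(self.n_c) else 1,
                )
            )
            n_cur = self.subsample_to
        if self.final_amplify_to is not None and self.final_amplify_to > n_cur:
            events.append(
                MechanismEvent(EventKind.AMPLIFY, n1=n_cur, n2=self.final_amplify_to)
            )
        return Schedule(events, label=self.model_tag)


def mouse_schedule(
    b: float, nu_f_over_n: float = 0.0, n_c: float = 1, n_d: int = 1
) -> GermlineSchedule:
    """The canonical mouse female germline schedule with bottleneck depth b.

    Copy number falls 1e5 -> b over 29 divisions (7 h period), regrows
    b -> 5,000 over 7 divisions (16 h period), then reamplifies to 1e5.
    """
    if not 1 < b < MOUSE_N_START:
        raise ValueError(f"bottleneck copy number must be in (1, 1e5); got {b}")
    return GermlineSchedule(
        phases=[
            (MOUSE_DEPLETE_DIVISIONS, MOUSE_DEPLETE_PERIOD_DAYS, float(MOUSE_N_START), float(b)),
            (MOUSE_REGROW_DIVISIONS, MOUSE_REGROW_PERIOD_DAYS, float(b), float(MOUSE_REGROW_TO)),
        ],
        ageing_turnover=nu_f_over_n,
        n_c=n_c,
        n_d=n_d,
        final_amplify_to=float(MOUSE_N_START),
        model_tag="div_turnover_amp",
    )


def developmental_norm_var(schedule: GermlineSchedule) -> float:
    """V'(h) accrued during development (age-0 value), via the closed-form
    cascades; equals the summed event-schedule contributions exactly."""
    total = 0.0
    for (k, _period, n0, nk) in schedule.phases:
        total += cascade_variance(n0, nk, k, n_c=schedule.n_c)
    n_cur = schedule.phases[-1][3] if schedule.phases else float(MOUSE_N_START)
    if schedule.subsample_to is not None:
        total += subsample_contribution(n_cur, schedule.subsample_to, n_c=schedule.n_c)
        n_cur = schedule.subsample_to
    if schedule.final_amplify_to is not None and schedule.final_amplify_to > n_cur:
        total += amplification_contribution(n_cur, schedule.final_amplify_to)
    return total


@dataclass
class Prediction:
    """Predicted trajectories of V'(h), transformed mean and N_b versus age."""

    ages_days: np.ndarray
    norm_var: np.ndarray
    transformed_mean: np.ndarray
    bottleneck_size: np.ndarray


def predict_norm_var(schedule: GermlineSchedule, ages_days) -> Prediction:
    """Neutral prediction: V'(age) = V'_dev + (1 + n_d)(nu f / n) * age."""
    ages = np.asarray(ages_days, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    v0 = developmental_norm_var(schedule)
    nv = v0 + (1 + schedule.n_d) * schedule.ageing_turnover * ages
    with np.errstate(divide="ignore"):
        nb = np.where(nv > 0, 1.0 / np.where(nv > 0, nv, 1.0), np.inf)
    return Prediction(
        ages_days=ages,
        norm_var=nv,
        transformed_mean=np.zeros_like(ages),
        bottleneck_size=nb,
    )


def predict_with_selection(
    schedule: GermlineSchedule, rho: float, ages_days, h0: float = 0.5
) -> Prediction:
    """Non-neutral prediction: transformed mean rho*age, ageing variance from
    the selection closed form at the oocyte copy number, plus developmental
    V'.  Reduces exactly to :func:`predict_norm_var` at rho = 0, n_d = 1."""
    ages = np.asarray(ages_days, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    if rho == 0.0 and schedule.n_d == 1:
        pred = predict_norm_var(schedule, ages)
        return pred
    n_oo = schedule.oocyte_copy_number
    nu_f = schedule.ageing_turnover * n_oo
    v0 = developmental_norm_var(schedule)
    nv = v0 + np.asarray(selection_norm_var(rho, nu_f, int(round(n_oo)), ages))
    with np.errstate(divide="ignore"):
        nb = np.where(nv > 0, 1.0 / np.where(nv > 0, nv, 1.0), np.inf)
    return Prediction(
        ages_days=ages,
        norm_var=nv,
        transformed_mean=rho * ages,
        bottleneck_size=nb,
    )


def prediction_interval(
    pred: Prediction, h0: float = 0.5, level: float = 0.95
) -> tuple[np.ndarray, np.ndarray]:
    """Back-transformed (lo, hi) heteroplasmy band for a founder at h0.

    On the transformed scale z is Gaussian with mean rho*age and variance
    V'(age)/(E(1-E)) (delta method); the band is mean +/- q*sd mapped back
    through the inverse transform.
    """
    from scipy.stats import norm as _norm

    q = _norm.ppf(0.5 + level / 2.0)
    mean_h = np.array([inverse_transform(m, h0) for m in pred.transformed_mean])
    var_z = pred.norm_var / (mean_h * (1.0 - mean_h))
    sd = np.sqrt(np.maximum(var_z, 0.0))
    lo = np.array(
        [inverse_transform(m - q * s, h0) for m, s in zip(pred.transformed_mean, sd)]
    )
    hi = np.array(
        [inverse_transform(m + q * s, h0) for m, s in zip(pred.transformed_mean, sd)]
    )
    return lo, hi


def model_variants(
    b: float = 670.0,
    nu_f_over_n: float = 1.4e-4,
    subsample_to: float = 1000.0,
    n_c: float = 10.0,
    n_d: int = 1,
) -> dict[str, GermlineSchedule]:
    """The comparison set of candidate bottleneck mechanisms."""
    base = mouse_schedule(b, nu_f_over_n, n_c=1, n_d=n_d)
    sub = GermlineSchedule(
        phases=[],
        ageing_turnover=0.0,
        subsample_to=float(subsample_to),
        final_amplify_to=float(MOUSE_N_START),
        model_tag="subsample_amp",
    )
    clus = mouse_schedule(b, 0.0, n_c=n_c, n_d=n_d)
    clus.model_tag = "clustered"
    sel = mouse_schedule(b, nu_f_over_n, n_c=1, n_d=n_d)
    sel.model_tag = "with_selection"
    return {
        "div_turnover_amp": base,
        "subsample_amp": sub,
        "clustered": clus,
        "with_selection": sel,
    }
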