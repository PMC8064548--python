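"""Synthetic single-cell heteroplasmy datasets with known ground truth.

Emulates the oocyte study design the inference module expects: mothers of
several ages, each with her own founder heteroplasmy h0, contributing a
clutch of single-oocyte heteroplasmy measurements whose founder-referenced
transformed values are Gaussian with age-dependent mean (rho * age) and
variance (V'(age) / (E (1 - E))).

Two backends:

* ``gaussian_transformed`` (default) — draw z directly from the model the
  likelihood assumes and map back through the inverse transform; exact
  inverse of the inference construction, any parameter scale.
* ``full_ssa`` — push each oocyte's molecule population through the actual
  stochastic machinery: Polya-urn amplification and hypergeometric
  partitioning along the developmental schedule, then an exact-SSA turnover
  epoch for the ageing oocyte.  Neutral only, and intended for desk-scale
  schedules (copy numbers of order 10^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import germline as gl
from . import partitioning as pt
from . import ssa
from .inference import GermlineModel, HeteroplasmyDataset, compare_models
from .variance import inverse_transform

__all__ = ["GeneratorConfig", "generate", "recovery_experiment"]


@dataclass
class GeneratorConfig:
    """Study design and ground truth for a synthetic oocyte dataset.

    Defaults mimic the scale of published mouse germline studies: four age
    groups from young to aged animals, tens of mothers, tens of oocytes per
    mother, founder heteroplasmy uniform in (0.2, 0.8), neutral truth at the
    canonical bottleneck b = 670 and turnover nu f / n = 1.4e-4 per day.
    """

    n_individuals: int = 40
    oocytes_per_individual: int = 30
    ages_days: tuple = (25.0, 120.0, 250.0, 400.0)
    h0_range: tuple = (0.2, 0.8)
    truth: dict = field(
        default_factory=lambda: {"b": 670.0, "nu_f_over_n": 1.4e-4, "rho": 0.0, "n_d": 1}
    )
    backend: str = "gaussian_transformed"
    schedule: gl.GermlineSchedule | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.ages_days:
            raise ValueError("ages_days must be nonempty")
        lo, hi = self.h0_range
        if not (0 < lo < hi < 1):
            raise ValueError("h0_range bounds must satisfy 0 < low < high < 1")
        if self.backend not in ("gaussian_transformed", "full_ssa"):
            raise ValueError(f"unknown backend {self.backend!r}")

    def resolve_schedule(self) -> gl.GermlineSchedule:
        if self.schedule is not None:
            return self.schedule
        return gl.mouse_schedule(
            self.truth["b"],
            self.truth.get("nu_f_over_n", 0.0),
            n_d=self.truth.get("n_d", 1),
        )


def _truth_meta(config: GeneratorConfig) -> dict:
    return {**config.truth, "backend": config.backend, "seed": config.seed}


def generate(config: GeneratorConfig) -> HeteroplasmyDataset:
    """Generate one dataset; deterministic for a fixed config seed."""
    rng = np.random.default_rng(config.seed)
    sched = config.resolve_schedule()
    rho = config.truth.get("rho", 0.0)
    ages = np.asarray(config.ages_days, dtype=float)
    if config.backend == "full_ssa" and rho != 0.0:
        raise NotImplementedError(
            "full_ssa backend generates neutral data only; use the "
            "gaussian_transformed backend for selection"
        )
    if rho == 0.0:
        nv_by_age = gl.predict_norm_var(sched, ages).norm_var
    else:
        nv_by_age = gl.predict_with_selection(sched, rho, ages).norm_var

    rows = []
    for i in range(config.n_individuals):
        age = float(ages[i % len(ages)])
        nv = float(nv_by_age[i % len(ages)])
        h0 = float(rng.uniform(*config.h0_range))
        mid = f"M{i:03d}"
        if config.backend == "gaussian_transformed":
            mu = rho * age
            mean = inverse_transform(mu, h0) if rho else h0
            var_z = nv / (mean * (1.0 - mean))
            z = rng.normal(mu, np.sqrt(var_z), size=config.oocytes_per_individual)
            hs = inverse_transform(z, h0)
        else:
            hs = [
                _simulate_oocyte(sched, h0, age, rng)
                for _ in range(config.oocytes_per_individual)
            ]
        for h in np.atleast_1d(hs):
            rows.append((mid, age, h0, float(h)))
    df = pd.DataFrame(rows, columns=["individual_id", "age_days", "h0", "h"])
    df = df[np.isfinite(df["h"])].reset_index(drop=True)  # extinct oocytes: no h
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")  # fixated-cell exclusions are expected here
        return HeteroplasmyDataset.from_dataframe(
            df, label=f"synthetic-{config.backend}", truth=_truth_meta(config)
        )


def _simulate_oocyte(
    sched: gl.GermlineSchedule, h0: float, age_days: float, rng: np.random.Generator
) -> float:
    """One oocyte through the schedule by explicit stochastic sampling."""
    n0 = sched.phases[0][2] if sched.phases else gl.MOUSE_N_START
    m = int(round(n0 * h0))
    pool = pt.Pool(int(round(n0)) - m, m)
    for (k, _period, n_start, n_end) in sched.phases:
        a = 2.0 * (n_end / n_start) ** (1.0 / k)
        n = float(n_start)
        for _ in range(k):
            n_hi = n * a
            pool = pt.polya_amplify(pool, int(round(n_hi)), rng=rng)
            pool, _d2 = pt.partition_hypergeometric(
                pool, pool.total // 2, n_c=max(int(sched.n_c), 1), rng=rng
            )
            n = n_hi / 2.0
    if sched.subsample_to is not None:
        pool = pt.subsample(pool, int(round(sched.subsample_to)), rng=rng)
    if sched.final_amplify_to is not None and sched.final_amplify_to > pool.total:
        pool = pt.polya_amplify(pool, int(round(sched.final_amplify_to)), rng=rng)
    if sched.ageing_turnover > 0 and age_days > 0:
        n_oo = pool.total
        nu = sched.ageing_turnover * n_oo  # f = 1: all molecules fragmented
        params = ssa.SimParams(
            lam=nu + 1.0,
            nu=nu,
            alpha_ctrl=1.0 / n_oo,
            kappa=0.0,
            n_d=sched.n_d,
        )
        init = ssa.CellState(0, pool.n_wild, 0, pool.n_mut)
        traj = ssa.run_trajectory(
            init,
            params,
            t_max=age_days,
            record_times=[age_days],
            seed=int(rng.integers(2**31 - 1)),
        )
        final = traj[-1]
        if final.n == 0:
            return float("nan")  # extinct oocyte: no measurement
        return final.h
    return pool.h if pool.total else float("nan")


def recovery_experiment(
    config: GeneratorConfig,
    model_tags=("div_turnover_amp",),
    n_datasets: int = 20,
    n_boot: int = 0,
    compare: bool = False,
    seed: int | None = None,
) -> dict:
    """Generate-fit-tabulate harness: bias, RMSE and CI coverage per
    parameter, plus (optionally) AIC model-selection outcomes.

    Returns a dict with a per-dataset DataFrame (``fits``) and per-parameter
    summary (``summary``).
    """
    if n_datasets < 2:
        raise ValueError("need at least 2 datasets")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(n_datasets, dtype=np.uint32)
    truth = config.truth
    rows = []
    selection_wins = 0
    for d in range(n_datasets):
        cfg = GeneratorConfig(
            **{
                **asdict_config(config),
                "seed": int(child_seeds[d]),
            }
        )
        data = generate(cfg)
        for tag in model_tags:
            est = GermlineModel(
                model=tag, n_boot=n_boot, seed=int(child_seeds[d])
            ).fit(data)
            row = {"dataset": d, "model": tag, "aic": est.aic_, "loglik": est.loglik_}
            for p, v in est.params_.items():
                row[f"est_{p}"] = v
                if est.bootstrap_intervals_ and p in est.bootstrap_intervals_:
                    lo, hi = est.bootstrap_intervals_[p]
                    row[f"lo_{p}"], row[f"hi_{p}"] = lo, hi
                    t = _truth_value(truth, p)
                    if t is not None:
                        row[f"cover_{p}"] = lo <= t <= hi
            rows.append(row)
        if compare:
            table = compare_models(
                data, model_tags=("div_turnover_amp", "with_selection")
            )
            if table.iloc[0]["model"] == "with_selection" and (
                table.set_index("model").loc["div_turnover_amp", "delta_aic"] > 2.0
            ):
                selection_wins += 1
    fits = pd.DataFrame(rows)
    summary = {}
    for tag in model_tags:
        sub = fits[fits["model"] == tag]
        for p in _estimated_params(sub):
            t = _truth_value(truth, p)
            est = sub[f"est_{p}"].to_numpy()
            entry = {
                "median": float(np.median(est)),
                "mean": float(np.mean(est)),
            }
            if t is not None and t != 0:
                entry["median_rel_bias"] = float(np.median(est) / t - 1.0)
                entry["rmse"] = float(np.sqrt(np.mean((est - t) ** 2)))
            if f"cover_{p}" in sub.columns:
                entry["coverage"] = float(sub[f"cover_{p}"].mean())
            summary[f"{tag}.{p}"] = entry
    out = {"fits": fits, "summary": summary}
    if compare:
        out["selection_win_frac"] = selection_wins / n_datasets
    return out


def _estimated_params(df: pd.DataFrame) -> list[str]:
    return [c[4:] for c in df.columns if c.startswith("est_") and df[c].notna().any()]


def _truth_value(truth: dict, param: str) -> float | None:
    return truth.get(param)


def asdict_config(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["schedule"] = config.schedule  # keep the object, not a dict
    return d


def write_dataset(
    data: HeteroplasmyDataset, path: str | Path, truth_sidecar: bool = True
) -> None:
    """Write the standard CSV plus a ground-truth JSON sidecar."""
    path = Path(path)
    data.to_csv(path)
    if truth_sidecar and data.truth is not None:
        side = path.with_suffix(".truth.json")
        side.write_text(json.dumps(data.truth, indent=2))
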