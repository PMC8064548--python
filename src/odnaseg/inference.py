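"""Maximum-likelihood fitting of germline bottleneck models to single-cell
heteroplasmy measurements.

Each record is one oocyte: (individual_id, age_days, founder h0, measured h).
Measurements are transformed to z = logit(h) - logit(h0), on which scale the
selection mean is exactly rho * age and, by the delta method
(g'(h) = 1/(h(1-h))), the variance is V'(age) / (E(h)(1 - E(h))).  The
likelihood is Gaussian in z; records at h in {0, 1} (fixated) cannot be
transformed and are excluded with a count.

Point estimates come from Nelder-Mead simplex maximisation with positive
parameters (b, nu f/n, ...) optimised on log scale; uncertainty from
nonparametric bootstrap (resampling oocytes with replacement within each
mother, preserving the per-mother founder structure); model comparison by
AIC and by R^2 between per-age-group empirical V'(h) and the model curve.

The front door is the sklearn-style estimator :class:`GermlineModel`;
:func:`fit_ml`, :func:`bootstrap` and :func:`compare_models` are thin
functional wrappers over it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from . import germline as gl
from .variance import inverse_transform, transform_heteroplasmy

__all__ = [
    "FitResult",
    "GermlineModel",
    "HeteroplasmyDataset",
    "bootstrap",
    "compare_models",
    "empirical_norm_var",
    "fit_ml",
    "log_likelihood",
]

REQUIRED_COLUMNS = ("individual_id", "age_days", "h0", "h")


@dataclass
class HeteroplasmyDataset:
    """Clustered single-cell heteroplasmy measurements.

    ``records`` has columns individual_id, age_days, h0, h with all fittable
    rows strictly inside (0, 1); fixated rows are removed at construction and
    counted in ``n_excluded``.
    """

    records: pd.DataFrame
    label: str = ""
    n_excluded: int = 0
    truth: dict | None = None

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label: str = "", truth: dict | None = None
    ) -> "HeteroplasmyDataset":
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        for col in ("age_days", "h0", "h"):
            bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
            if len(bad):
                raise ValueError(
                    f"column {col!r}: non-numeric values at rows {list(bad[:5])}"
                )
            df[col] = df[col].astype(float)
        if (df["age_days"] < 0).any():
            rows = df.index[df["age_days"] < 0]
            raise ValueError(f"negative ages at rows {list(rows[:5])}")
        out_of_range = (df["h"] < 0) | (df["h"] > 1) | (df["h0"] <= 0) | (df["h0"] >= 1)
        if out_of_range.any():
            rows = df.index[out_of_range]
            raise ValueError(
                f"h outside [0,1] or h0 outside (0,1) at rows {list(rows[:5])}"
            )
        fixated = (df["h"] <= 0) | (df["h"] >= 1)
        n_excluded = int(fixated.sum())
        if n_excluded:
            warnings.warn(
                f"excluding {n_excluded} fixated record(s) with h in {{0,1}} "
                "(transform undefined)",
                stacklevel=2,
            )
        return cls(
            records=df.loc[~fixated].reset_index(drop=True),
            label=label,
            n_excluded=n_excluded,
            truth=truth,
        )

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "HeteroplasmyDataset":
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        df = pd.read_csv(path, sep=sep)
        return cls.from_dataframe(df, label=str(path), **kwargs)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ages(self) -> np.ndarray:
        return np.sort(self.records["age_days"].unique())


# ---------------------------------------------------------------------------
# model parameterisations

# natural-scale parameter names per model tag; all but rho are positive and
# optimised as logs
_MODEL_PARAMS: dict[str, tuple[str, ...]] = {
    "div_turnover_amp": ("b", "nu_f_over_n"),
    "subsample_amp": ("subsample_to",),
    "clustered": ("b", "n_c"),
    "with_selection": ("b", "nu_f_over_n", "rho"),
}

_DEFAULT_INIT: dict[str, dict[str, float]] = {
    "div_turnover_amp": {"b": 1000.0, "nu_f_over_n": 1e-4},
    "subsample_amp": {"subsample_to": 1000.0},
    "clustered": {"b": 1000.0, "n_c": 5.0},
    "with_selection": {"b": 1000.0, "nu_f_over_n": 1e-4, "rho": 0.0},
}


def _params_to_theta(tag: str, params: dict[str, float]) -> np.ndarray:
    return np.array(
        [params[p] if p == "rho" else math.log(params[p]) for p in _MODEL_PARAMS[tag]]
    )


def _theta_to_params(tag: str, theta: np.ndarray) -> dict[str, float]:
    return {
        p: (theta[i] if p == "rho" else math.exp(theta[i]))
        for i, p in enumerate(_MODEL_PARAMS[tag])
    }


def _build_schedule(tag: str, params: dict[str, float]) -> tuple[gl.GermlineSchedule, float]:
    """Schedule plus selection strength for a parameter vector (raises
    ValueError for out-of-domain parameters; callers penalise)."""
    if tag == "div_turnover_amp":
        return gl.mouse_schedule(params["b"], params["nu_f_over_n"]), 0.0
    if tag == "with_selection":
        return gl.mouse_schedule(params["b"], params["nu_f_over_n"]), params["rho"]
    if tag == "clustered":
        sched = gl.mouse_schedule(params["b"], 0.0, n_c=params["n_c"])
        sched.model_tag = "clustered"
        return sched, 0.0
    if tag == "subsample_amp":
        s = params["subsample_to"]
        if not 1 < s < gl.MOUSE_N_START:
            raise ValueError(f"subsample size out of (1, 1e5): {s}")
        sched = gl.GermlineSchedule(
            phases=[],
            subsample_to=float(s),
            final_amplify_to=float(gl.MOUSE_N_START),
            model_tag="subsample_amp",
        )
        return sched, 0.0
    raise ValueError(f"unknown model tag {tag!r}")


def model_norm_var(tag: str, params: dict[str, float], ages) -> np.ndarray:
    """Model V'(h) at the given ages."""
    sched, rho = _build_schedule(tag, params)
    if rho == 0.0:
        return np.asarray(gl.predict_norm_var(sched, ages).norm_var)
    return np.asarray(gl.predict_with_selection(sched, rho, ages).norm_var)


def log_likelihood(
    data: HeteroplasmyDataset, model_tag: str, params: dict[str, float]
) -> float:
    """Gaussian log-likelihood of the transformed measurements.

    z_i ~ Normal(rho * age_i, V'(age_i) / (E_i (1 - E_i))) with
    E_i the logistic mean from the record's own founder h0_i (equal to h0_i
    when neutral).  Returns -inf if the model variance is nonpositive
    anywhere.
    """
    df = data.records
    if not len(df):
        raise ValueError("empty dataset")
    age = df["age_days"].to_numpy()
    h0 = df["h0"].to_numpy()
    z = transform_heteroplasmy(df["h"].to_numpy(), h0)
    rho = params.get("rho", 0.0)
    try:
        nv = model_norm_var(model_tag, params, age)
    except ValueError:
        return -math.inf
    mu = rho * age
    mean = inverse_transform(mu, h0) if rho != 0.0 else h0
    var_z = nv / (mean * (1.0 - mean))
    if np.any(~np.isfinite(var_z)) or np.any(var_z <= 0):
        return -math.inf
    resid = z - mu
    return float(-0.5 * np.sum(np.log(2.0 * math.pi * var_z) + resid**2 / var_z))


@dataclass
class FitResult:
    """ML point estimates with optional bootstrap intervals and fit metrics."""

    model_tag: str
    point_estimates: dict[str, float]
    loglik: float
    aic: float
    r_squared: float
    converged: bool
    bootstrap_intervals: dict[str, tuple[float, float]] | None = None
    n_boot: int = 0
    boot_failures: int = 0
    seed: int | None = None
    n_records: int = 0
    n_excluded: int = 0

    @property
    def k(self) -> int:
        return len(self.point_estimates)


# ---------------------------------------------------------------------------
# estimator


class GermlineModel(BaseEstimator):
    """Sklearn-style estimator for germline bottleneck mechanism models.

    Parameters
    ----------
    model : one of 'div_turnover_amp', 'subsample_amp', 'clustered',
        'with_selection'.
    n_boot : bootstrap resamples for 95% percentile intervals (0 disables).
    bootstrap_unit : 'record' (resample oocytes within each mother, the
        default) or 'individual' (resample mothers).
    n_starts : extra jittered Nelder-Mead restarts beyond the default init.
    seed : controls bootstrap resampling and restart jitter.

    Fitted attributes: ``params_`` (natural-scale estimates), ``loglik_``,
    ``aic_``, ``r_squared_``, ``bootstrap_intervals_``, ``result_``.
    """

    def __init__(
        self,
        model: str = "div_turnover_amp",
        n_boot: int = 0,
        bootstrap_unit: str = "record",
        n_starts: int = 1,
        seed: int | None = None,
        init: dict | None = None,
        optimizer_options: dict | None = None,
    ):
        self.model = model
        self.n_boot = n_boot
        self.bootstrap_unit = bootstrap_unit
        self.n_starts = n_starts
        self.seed = seed
        self.init = init
        self.optimizer_options = optimizer_options

    # -- internals ---------------------------------------------------------

    def _coerce(self, data) -> HeteroplasmyDataset:
        if isinstance(data, HeteroplasmyDataset):
            return data
        if isinstance(data, pd.DataFrame):
            return HeteroplasmyDataset.from_dataframe(data)
        return HeteroplasmyDataset.from_csv(data)

    def _optimise(
        self, data: HeteroplasmyDataset, init: dict[str, float], rng=None
    ) -> tuple[dict[str, float], float, bool]:
        tag = self.model
        if tag not in _MODEL_PARAMS:
            raise ValueError(f"unknown model tag {tag!r}")
        theta0 = _params_to_theta(tag, init)

        def neg(theta: np.ndarray) -> float:
            ll = log_likelihood(data, tag, _theta_to_params(tag, theta))
            return -ll if math.isfinite(ll) else 1e12

        opts = {"xatol": 1e-6, "fatol": 1e-9, "maxiter": 4000, "maxfev": 4000}
        if self.optimizer_options:
            opts.update(self.optimizer_options)
        starts = [theta0]
        if self.n_starts > 1:
            if rng is None:
                rng = np.random.default_rng(self.seed)
            for _ in range(self.n_starts - 1):
                starts.append(theta0 + rng.normal(0.0, 0.3, size=theta0.shape))
        best = None
        for th0 in starts:
            res = minimize(neg, th0, method="Nelder-Mead", options=opts)
            if best is None or res.fun < best.fun:
                best = res
        params = _theta_to_params(tag, best.x)
        if not best.success:
            warnings.warn(
                f"Nelder-Mead did not converge for {tag}: {best.message}",
                stacklevel=2,
            )
        return params, -float(best.fun), bool(best.success)

    def _resample(self, df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
        if self.bootstrap_unit == "record":
            parts = []
            for _, grp in df.groupby("individual_id", sort=False):
                idx = rng.integers(0, len(grp), size=len(grp))
                parts.append(grp.iloc[idx])
            return pd.concat(parts, ignore_index=True)
        if self.bootstrap_unit == "individual":
            ids = df["individual_id"].unique()
            pick = rng.integers(0, len(ids), size=len(ids))
            parts = [df[df["individual_id"] == ids[i]] for i in pick]
            return pd.concat(parts, ignore_index=True)
        raise ValueError(f"unknown bootstrap unit {self.bootstrap_unit!r}")

    # -- API ---------------------------------------------------------------

    def fit(self, data, y=None) -> "GermlineModel":
        ds = self._coerce(data)
        if ds.records["age_days"].nunique() < 2 and self.model in (
            "div_turnover_amp",
            "with_selection",
        ):
            warnings.warn(
                "all records share one age: the ageing turnover rate is not "
                "identifiable from this design",
                stacklevel=2,
            )
        init = dict(_DEFAULT_INIT[self.model])
        if self.init:
            init.update(self.init)
        rng = np.random.default_rng(self.seed)
        params, loglik, converged = self._optimise(ds, init, rng=rng)
        k = len(params)
        aic = 2.0 * k - 2.0 * loglik
        r2 = self._r_squared(ds, params)

        intervals = None
        failures = 0
        if self.n_boot:
            if self.n_boot < 100:
                raise ValueError("need at least 100 bootstrap resamples")
            draws = {p: [] for p in params}
            for _ in range(self.n_boot):
                bs = HeteroplasmyDataset(self._resample(ds.records, rng))
                try:
                    p_b, _, ok = self._optimise(bs, params)
                    if not ok:
                        failures += 1
                        continue
                    for name, val in p_b.items():
                        draws[name].append(val)
                except Exception:
                    failures += 1
            if failures > 0.1 * self.n_boot:
                warnings.warn(
                    f"{failures}/{self.n_boot} bootstrap refits failed",
                    stacklevel=2,
                )
            intervals = {
                p: (
                    float(np.percentile(v, 2.5)),
                    float(np.percentile(v, 97.5)),
                )
                for p, v in draws.items()
                if len(v)
            }

        self.params_ = params
        self.loglik_ = loglik
        self.aic_ = aic
        self.r_squared_ = r2
        self.bootstrap_intervals_ = intervals
        self.converged_ = converged
        self.result_ = FitResult(
            model_tag=self.model,
            point_estimates=params,
            loglik=loglik,
            aic=aic,
            r_squared=r2,
            converged=converged,
            bootstrap_intervals=intervals,
            n_boot=self.n_boot,
            boot_failures=failures,
            seed=self.seed,
            n_records=len(ds),
            n_excluded=ds.n_excluded,
        )
        self._train_data_ = ds
        return self

    def predict(self, ages) -> np.ndarray:
        """Model V'(h) at the given ages (days)."""
        if not hasattr(self, "params_"):
            raise AttributeError("call fit() first")
        return model_norm_var(self.model, self.params_, np.asarray(ages, dtype=float))

    def score(self, data=None, y=None) -> float:
        """R^2 between per-age empirical V'(h) and the model curve."""
        if data is None:
            return self.r_squared_
        return self._r_squared(self._coerce(data), self.params_)

    def _r_squared(self, ds: HeteroplasmyDataset, params: dict[str, float]) -> float:
        emp = empirical_norm_var(ds, scale="transformed")
        if len(emp) < 2:
            return float("nan")
        obs = emp["norm_var"].to_numpy()
        pred = model_norm_var(self.model, params, emp["age_days"].to_numpy())
        ss_res = float(np.sum((obs - pred) ** 2))
        ss_tot = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


# ---------------------------------------------------------------------------
# functional wrappers


def fit_ml(
    data,
    model_tag: str = "div_turnover_amp",
    init: dict | None = None,
    n_starts: int = 1,
    seed: int | None = None,
    optimizer_options: dict | None = None,
) -> FitResult:
    """ML point estimate for one mechanism model (no bootstrap)."""
    est = GermlineModel(
        model=model_tag,
        init=init,
        n_starts=n_starts,
        seed=seed,
        optimizer_options=optimizer_options,
    ).fit(data)
    return est.result_


def bootstrap(
    data,
    model_tag: str = "div_turnover_amp",
    n_boot: int = 1000,
    seed: int | None = None,
    unit: str = "record",
    init: dict | None = None,
) -> FitResult:
    """Fit plus nonparametric bootstrap 95% percentile intervals."""
    est = GermlineModel(
        model=model_tag, n_boot=n_boot, bootstrap_unit=unit, seed=seed, init=init
    ).fit(data)
    return est.result_


def compare_models(
    data,
    model_tags=("div_turnover_amp", "subsample_amp", "clustered"),
    seed: int | None = None,
) -> pd.DataFrame:
    """AIC comparison table (sorted; delta_aic relative to the best model)."""
    if len(model_tags) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for tag in model_tags:
        res = fit_ml(data, tag, seed=seed)
        rows.append(
            {
                "model": tag,
                "k": res.k,
                "loglik": res.loglik,
                "aic": res.aic,
                "r_squared": res.r_squared,
                **{f"est_{p}": v for p, v in res.point_estimates.items()},
            }
        )
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table


def empirical_norm_var(
    data, bins=None, scale: str = "h", min_group: int = 2
) -> pd.DataFrame:
    """Per-age-group empirical heteroplasmy summary.

    scale='h' computes moments of raw h (comparable across cells sharing a
    founder); scale='transformed' estimates V'(h) from founder-referenced
    z values, weighting each squared deviation by h0(1-h0) — the right
    estimator when founder levels differ between mothers.  SE of V' is
    V' sqrt(2/(m-1)).  Groups smaller than ``min_group`` are dropped with a
    warning.
    """
    ds = data if isinstance(data, HeteroplasmyDataset) else HeteroplasmyDataset.from_dataframe(data)
    df = ds.records.copy()
    if bins is not None:
        df["__group"] = pd.cut(df["age_days"], bins=bins)
    else:
        df["__group"] = df["age_days"]
    rows = []
    for key, grp in df.groupby("__group", sort=True, observed=True):
        m = len(grp)
        if m < min_group:
            warnings.warn(
                f"dropping age group {key}: only {m} record(s)", stacklevel=2
            )
            continue
        h = grp["h"].to_numpy()
        mean_h = float(h.mean())
        if scale == "h":
            var_h = float(h.var(ddof=1))
            nv = (
                var_h / (mean_h * (1 - mean_h))
                if 0 < mean_h < 1
                else float("nan")
            )
        elif scale == "transformed":
            h0 = grp["h0"].to_numpy()
            z = transform_heteroplasmy(h, h0)
            w = h0 * (1 - h0)
            nv = float(np.sum((z - z.mean()) ** 2 * w) / (m - 1))
            var_h = nv * mean_h * (1 - mean_h)
        else:
            raise ValueError(f"unknown scale {scale!r}")
        age = float(grp["age_days"].mean())
        if nv < 1e-15:  # numerically zero spread: bottleneck undefined
            nv = 0.0
        nb = 1.0 / nv if nv > 0 else float("inf")
        rows.append(
            {
                "age_days": age,
                "m": m,
                "mean_h": mean_h,
                "var_h": var_h,
                "norm_var": nv,
                "bottleneck_size": nb if math.isfinite(nb) else float("nan"),
                "norm_var_se": nv * math.sqrt(2.0 / (m - 1)) if nv >= 0 else float("nan"),
            }
        )
    return pd.DataFrame(rows)
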