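"""Rate-constant estimation from conversion/yield tables and Arrhenius fitting.

The estimation mirrors how the model was parameterised from micro-flow
data: per-temperature nonlinear least squares of the four rate constants
against observed (X_EDA, Y_EC, Y_DIM) time courses, followed by ordinary
least squares of ln k on 1/T to extract activation energies and
pre-exponential factors.  K, the catalyst–DMH coordination constant, is held
fixed by default: in the saturation regime (K * C_DMH >> 1) the loss surface
is flat in K, so it is not identifiable from yield data alone.

Rate constants are optimised in log10 space, which enforces positivity and
puts the four constants (spanning decades) on comparable footing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetic_core import (
    GAS_CONSTANT,
    ArrheniusLaw,
    ModelParams,
    RateSet,
    SpeciesState,
    celsius_to_kelvin,
    rate_constants_at,
)
from .reactor import IntegrationError, simulate_batch, to_observables

__all__ = [
    "ExperimentTable",
    "FitOptions",
    "FitResult",
    "ArrheniusFit",
    "JointFitResult",
    "tables_to_csv",
    "tables_from_csv",
    "predict_observables",
    "sum_of_squares",
    "fit_rate_constants",
    "fit_arrhenius",
    "joint_fit",
    "bootstrap_ci",
]

OBS_COLUMNS = ("X_EDA", "Y_EC", "Y_DIM")
TABLE_COLUMNS = ("t_s", "X_EDA", "Y_EC", "Y_DIM", "replicate")
CSV_COLUMNS = ("condition_id", "T_C", "C_EDA0", "C_DMH0", "C_cat0") + TABLE_COLUMNS


@dataclass
class ExperimentTable:
    """Observed conversion/yield rows for one experimental condition.

    ``data`` holds one row per (residence time, replicate) with columns
    t_s, X_EDA, Y_EC, Y_DIM, replicate.  Y_DIM follows the package's
    initial-EDA basis convention.
    """

    condition_id: str
    T: float  # K
    C_EDA0: float
    C_DMH0: float
    C_cat0: float
    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TABLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"experiment table missing columns {sorted(missing)}")
        if (self.data["t_s"] <= 0).any():
            raise ValueError("residence times must be positive")
        obs = self.data[list(OBS_COLUMNS)].to_numpy(float)
        if ((obs < -1e-9) | (obs > 1 + 1e-9)).any():
            raise ValueError("observables must lie in [0, 1]")
        if self.data["t_s"].nunique() < 2:
            raise ValueError("need at least 2 distinct residence times per condition")

    @property
    def times(self) -> np.ndarray:
        return np.sort(self.data["t_s"].unique())


def tables_to_csv(tables: list[ExperimentTable], path: str | Path) -> None:
    frames = []
    for tab in tables:
        df = tab.data.copy()
        df.insert(0, "condition_id", tab.condition_id)
        df.insert(1, "T_C", tab.T - 273.15)
        df.insert(2, "C_EDA0", tab.C_EDA0)
        df.insert(3, "C_DMH0", tab.C_DMH0)
        df.insert(4, "C_cat0", tab.C_cat0)
        frames.append(df[list(CSV_COLUMNS)])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def tables_from_csv(path: str | Path) -> list[ExperimentTable]:
    df = pd.read_csv(path)
    tables = []
    for cid, grp in df.groupby("condition_id", sort=False):
        tables.append(ExperimentTable(
            condition_id=str(cid),
            T=celsius_to_kelvin(float(grp["T_C"].iloc[0])),
            C_EDA0=float(grp["C_EDA0"].iloc[0]),
            C_DMH0=float(grp["C_DMH0"].iloc[0]),
            C_cat0=float(grp["C_cat0"].iloc[0]),
            data=grp[list(TABLE_COLUMNS)].reset_index(drop=True),
        ))
    return tables


@dataclass(frozen=True)
class FitOptions:
    """Tuning knobs of the nonlinear fits.

    Multi-start guards against local minima: ``n_starts - 1`` extra starting
    points are drawn log-uniformly within ``start_spread_decades`` decades of
    the initial guess (seeded, reproducible).  ``average_replicates``
    switches the loss from individual-replicate residuals to per-time means.
    """

    n_starts: int = 5
    start_spread_decades: float = 2.0
    seed: int = 0
    fit_K: bool = False
    K_max: float = 1.0e6
    average_replicates: bool = False
    gtol: float = 1e-10
    xtol: float = 1e-12
    ftol: float = 1e-12
    #: relative finite-difference step of the numerical Jacobian, in log10
    #: parameter space.  Must stay well above the ODE solver's rtol or the
    #: Jacobian drowns in integration noise and the fit stalls in the
    #: quasi-steady-state valley (the loss is nearly flat along a common
    #: rescaling of k1..k3).
    diff_step: float = 1e-6
    solver_opts: dict | None = None


@dataclass
class FitResult:
    """Best-fit rate constants at one temperature with diagnostics."""

    rates: RateSet
    residuals: np.ndarray
    loss: float
    converged: bool
    message: str = ""
    n_obs: int = 0
    ci: dict | None = None


@dataclass
class ArrheniusFit:
    """OLS of ln k on 1/T: law plus straight-line diagnostics."""

    law: ArrheniusLaw
    r_squared: float
    slope: float
    intercept: float


@dataclass
class JointFitResult:
    """Two-stage (or global) fit across temperatures."""

    params: ModelParams
    per_temperature: dict
    arrhenius: dict
    mode: str = "two-stage"


def _table_observations(table: ExperimentTable,
                        average_replicates: bool) -> pd.DataFrame:
    if average_replicates:
        return (table.data.groupby("t_s", as_index=False)[list(OBS_COLUMNS)]
                .mean())
    return table.data


def predict_observables(table: ExperimentTable, rates: RateSet,
                        params_template: ModelParams,
                        solver_opts: dict | None = None) -> pd.DataFrame:
    """Model-predicted (X_EDA, Y_EC, Y_DIM) at the table's residence times."""
    params = params_template.with_catalyst(C_cat0=table.C_cat0)
    # evaluate the trajectory with the trial constants (not Arrhenius laws):
    # reuse the batch integrator by injecting constant laws that reproduce
    # the trial k's at the table temperature.
    laws = {name: ArrheniusLaw(A=getattr(rates, name), Ea=0.0)
            for name in ("k0", "k1", "k2", "k3")}
    params = replace(params, arrhenius_laws=laws, K=rates.K)
    initial = SpeciesState(C_EDA=table.C_EDA0, C_DMH=table.C_DMH0)
    times = table.times
    traj = simulate_batch(initial, params, table.T, float(times[-1]),
                          solver_opts=solver_opts, t_eval=times)
    rows = []
    for t in times:
        obs = to_observables(traj, table.C_EDA0, float(t))
        rows.append((t, obs.X_EDA, obs.Y_EC, obs.Y_DIM))
    return pd.DataFrame(rows, columns=["t_s", *OBS_COLUMNS])


def _residuals_for_rates(tables: list[ExperimentTable], rates: RateSet,
                         params_template: ModelParams,
                         average_replicates: bool,
                         solver_opts: dict | None) -> np.ndarray:
    res = []
    for table in tables:
        pred = predict_observables(table, rates, params_template, solver_opts)
        pred = pred.set_index("t_s")
        obs = _table_observations(table, average_replicates)
        for col in OBS_COLUMNS:
            res.append(obs[col].to_numpy(float)
                       - pred.loc[obs["t_s"], col].to_numpy(float))
    return np.concatenate(res)


def sum_of_squares(tables: list[ExperimentTable], rates: RateSet,
                   params_template: ModelParams | None = None,
                   average_replicates: bool = False) -> float:
    """Unweighted least-squares loss of a candidate rate set on the tables."""
    params_template = params_template or ModelParams.default()
    r = _residuals_for_rates(tables, rates, params_template,
                             average_replicates, None)
    return float(np.sum(r**2))


def _n_residuals(tables, average_replicates):
    return sum(len(_table_observations(t, average_replicates)) * len(OBS_COLUMNS)
               for t in tables)


def fit_rate_constants(tables: list[ExperimentTable], params_init: RateSet,
                       options: FitOptions | None = None,
                       params_template: ModelParams | None = None) -> FitResult:
    """Estimate k0..k3 (optionally K) at one temperature by least squares.

    All tables must share one temperature.  The loss is the unweighted sum
    of squared residuals over the three observables; replicates contribute
    individual residuals unless ``options.average_replicates``.
    """
    options = options or FitOptions()
    params_template = params_template or ModelParams.default()
    if not tables:
        raise ValueError("no experiment tables supplied")
    T = tables[0].T
    if any(abs(t.T - T) > 1e-9 for t in tables):
        raise ValueError("fit_rate_constants requires tables at one temperature")
    n_res = _n_residuals(tables, options.average_replicates)
    n_par = 5 if options.fit_K else 4
    if n_res < n_par:
        raise ValueError(
            f"{n_res} observations cannot determine {n_par} parameters"
        )

    x0 = np.log10(params_init.as_array())
    if options.fit_K:
        x0 = np.append(x0, np.log10(params_init.K))
    # box the search 2 decades beyond the start spread; trial points outside
    # it (or non-finite) are rejected with a flat penalty before any ODE work
    lo = x0 - options.start_spread_decades - 2.0
    hi = x0 + options.start_spread_decades + 2.0
    if options.fit_K:
        hi[-1] = min(hi[-1], math.log10(options.K_max))

    def unpack(x) -> RateSet:
        ks = 10.0 ** x[:4]
        K = 10.0 ** x[4] if options.fit_K else params_init.K
        return RateSet(k0=ks[0], k1=ks[1], k2=ks[2], k3=ks[3], K=K, T=T)

    def fun(x):
        if not np.all(np.isfinite(x)) or np.any(x < lo - 1) or np.any(x > hi + 1):
            return np.full(n_res, 1e3)
        try:
            return _residuals_for_rates(
                tables, unpack(x), params_template,
                options.average_replicates, options.solver_opts)
        except (IntegrationError, ValueError):
            return np.full(n_res, 1e3)

    rng = np.random.default_rng(options.seed)
    starts = [x0]
    for _ in range(options.n_starts - 1):
        starts.append(x0 + rng.uniform(-options.start_spread_decades,
                                       options.start_spread_decades,
                                       size=x0.size))
    # stage 1: bounded trust-region runs locate the basin (exploratory
    # restarts get a capped iteration budget)
    best = None
    for i, start in enumerate(starts):
        sol = least_squares(fun, np.clip(start, lo, hi), method="trf",
                            bounds=(lo, hi), x_scale="jac",
                            diff_step=options.diff_step,
                            ftol=1e-10, xtol=1e-10, gtol=1e-10,
                            max_nfev=None if i == 0 else 100)
        if best is None or sol.cost < best.cost:
            best = sol
    # stage 2: tight polish from the best basin; LM handles the nearly flat
    # quasi-steady-state valley much better than bounded trust region
    tol_kw = dict(gtol=max(options.gtol, 1e-15), xtol=max(options.xtol, 1e-15),
                  ftol=max(options.ftol, 1e-15), diff_step=options.diff_step)
    if options.fit_K:
        sol = least_squares(fun, best.x, method="trf", bounds=(lo, hi),
                            x_scale="jac", **tol_kw)
    else:
        sol = least_squares(fun, best.x, method="lm", **tol_kw)
    if sol.cost <= best.cost:
        best = sol
    loss = float(np.sum(best.fun**2))
    return FitResult(
        rates=unpack(best.x),
        residuals=best.fun,
        loss=loss,
        converged=bool(best.status > 0),
        message=best.message,
        n_obs=n_res,
    )


def fit_arrhenius(points: list[tuple[float, float]]) -> ArrheniusFit:
    """Fit k = A exp(-Ea/RT) by OLS of ln k against 1/T.

    ``points`` are (T in K, k) pairs; Ea is returned in kJ/mol.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    T = np.array([p[0] for p in points], float)
    k = np.array([p[1] for p in points], float)
    if (k <= 0).any():
        raise ValueError("all rate constants must be positive")
    if (T <= 0).any():
        raise ValueError("all temperatures must be positive")
    if np.unique(T).size < 2:
        raise ValueError("need at least 2 distinct temperatures")
    x = 1.0 / T
    y = np.log(k)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    law = ArrheniusLaw(A=float(np.exp(intercept)),
                       Ea=float(-slope * GAS_CONSTANT / 1e3))
    return ArrheniusFit(law=law, r_squared=r2, slope=float(slope),
                        intercept=float(intercept))


def _group_by_temperature(tables: list[ExperimentTable]) -> dict:
    groups: dict[float, list[ExperimentTable]] = {}
    for t in tables:
        key = round(t.T, 6)
        groups.setdefault(key, []).append(t)
    return dict(sorted(groups.items()))


def joint_fit(tables: list[ExperimentTable], init: ModelParams,
              options: FitOptions | None = None,
              mode: str = "two-stage") -> JointFitResult:
    """Fit the full temperature-dependent model across experiment tables.

    Default two-stage procedure: per-temperature :func:`fit_rate_constants`
    with a globally shared (fixed) K, then :func:`fit_arrhenius` per step.
    ``mode="global"`` instead fits all {A_i, Ea_i} (and optionally K) in one
    nonlinear least-squares problem over every table.
    """
    options = options or FitOptions()
    groups = _group_by_temperature(tables)
    if len(groups) < 2:
        raise ValueError("joint_fit requires tables at >= 2 temperatures")
    if mode == "two-stage":
        per_T = {}
        for T, group in groups.items():
            init_rates = rate_constants_at(T, init)
            per_T[T] = fit_rate_constants(group, init_rates, options,
                                          params_template=init)
        arr = {}
        for name in ("k0", "k1", "k2", "k3"):
            pts = [(T, getattr(res.rates, name)) for T, res in per_T.items()]
            arr[name] = fit_arrhenius(pts)
        params = replace(init,
                         arrhenius_laws={n: f.law for n, f in arr.items()},
                         K=init.K)
        return JointFitResult(params=params, per_temperature=per_T,
                              arrhenius=arr, mode=mode)
    if mode == "global":
        return _global_fit(tables, init, options)
    raise ValueError(f"unknown joint_fit mode {mode!r}")


def _global_fit(tables: list[ExperimentTable], init: ModelParams,
                options: FitOptions) -> JointFitResult:
    """One-shot fit of {A_i, Ea_i} (+K when freed) over all tables."""
    names = ("k0", "k1", "k2", "k3")
    x0 = []
    for n in names:
        law = init.arrhenius_laws[n]
        x0 += [math.log10(law.A), law.Ea]
    if options.fit_K:
        x0.append(math.log10(init.K))
    x0 = np.array(x0)

    def unpack(x) -> ModelParams:
        laws = {n: ArrheniusLaw(A=10.0 ** x[2 * i], Ea=max(x[2 * i + 1], 0.0))
                for i, n in enumerate(names)}
        K = 10.0 ** x[8] if options.fit_K else init.K
        return replace(init, arrhenius_laws=laws, K=K)

    n_res = _n_residuals(tables, options.average_replicates)
    lo = x0 - 6.0
    hi = x0 + 6.0
    lo[1::2] = 0.0       # activation energies stay non-negative
    hi[1::2] = 300.0     # ... and physically plausible (kJ/mol)

    def fun(x):
        if not np.all(np.isfinite(x)) or np.any(x < lo) or np.any(x > hi):
            return np.full(n_res, 1e3)
        try:
            p = unpack(x)
            res = []
            for table in tables:
                rates = rate_constants_at(table.T, p)
                res.append(_residuals_for_rates(
                    [table], rates, p, options.average_replicates,
                    options.solver_opts))
            return np.concatenate(res)
        except (IntegrationError, ValueError, OverflowError):
            return np.full(n_res, 1e3)

    sol = least_squares(fun, x0, method="trf", x_scale="jac",
                        gtol=max(options.gtol, 1e-15),
                        xtol=max(options.xtol, 1e-15),
                        ftol=max(options.ftol, 1e-15),
                        diff_step=options.diff_step)
    params = unpack(sol.x)
    per_T = {}
    for T, group in _group_by_temperature(tables).items():
        rates = rate_constants_at(T, params)
        r = _residuals_for_rates(group, rates, params,
                                 options.average_replicates, None)
        per_T[T] = FitResult(rates=rates, residuals=r,
                             loss=float(np.sum(r**2)),
                             converged=bool(sol.status > 0),
                             message=sol.message, n_obs=r.size)
    arr = {n: ArrheniusFit(law=params.arrhenius_laws[n], r_squared=1.0,
                           slope=-params.arrhenius_laws[n].Ea * 1e3 / GAS_CONSTANT,
                           intercept=math.log(params.arrhenius_laws[n].A))
           for n in names}
    return JointFitResult(params=params, per_temperature=per_T,
                          arrhenius=arr, mode="global")


def bootstrap_ci(tables: list[ExperimentTable], fitted: ModelParams,
                 n_boot: int, seed: int,
                 options: FitOptions | None = None) -> dict:
    """Residual-resampling bootstrap intervals for the fitted parameters.

    Residuals of the fitted model are pooled per observable, resampled with
    replacement onto the fitted predictions, and the whole two-stage fit is
    repeated; intervals are the 2.5/97.5 percentiles.  Returns a dict with
    per-temperature rate-constant intervals (``"k1@403.15K"``) and per-step
    activation-energy intervals (``"Ea_k1"``).
    """
    if n_boot < 10:
        raise ValueError("n_boot must be at least 10")
    options = options or FitOptions()
    # refits start at the fitted optimum; multi-start is unnecessary there
    refit_options = replace(options, n_starts=1)

    preds = []
    resids = {c: [] for c in OBS_COLUMNS}
    for table in tables:
        rates = rate_constants_at(table.T, fitted)
        pred = predict_observables(table, rates, fitted).set_index("t_s")
        preds.append(pred)
        for c in OBS_COLUMNS:
            resids[c].append(table.data[c].to_numpy(float)
                             - pred.loc[table.data["t_s"], c].to_numpy(float))
    pool = {c: np.concatenate(v) for c, v in resids.items()}

    rng = np.random.default_rng(seed)
    samples: dict[str, list[float]] = {}
    for _ in range(n_boot):
        boot_tables = []
        for table, pred in zip(tables, preds):
            df = table.data.copy()
            for c in OBS_COLUMNS:
                noise = rng.choice(pool[c], size=len(df), replace=True)
                df[c] = np.clip(
                    pred.loc[df["t_s"], c].to_numpy(float) + noise, 0.0, 1.0)
            boot_tables.append(replace(table, data=df))
        fit = joint_fit(boot_tables, fitted, refit_options)
        for T, res in fit.per_temperature.items():
            for name in ("k0", "k1", "k2", "k3"):
                samples.setdefault(f"{name}@{T}K", []).append(
                    getattr(res.rates, name))
        for name, arr in fit.arrhenius.items():
            samples.setdefault(f"Ea_{name}", []).append(arr.law.Ea)
            samples.setdefault(f"A_{name}", []).append(arr.law.A)
    return {key: (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))
            for key, v in samples.items()}
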