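"""Condition screening: EC-yield maps over (temperature, time) and the
low-temperature validation predictions.

The selectivity-temperature tradeoff is the practical point of the model:
the cyclopropanation step has the lowest activation energy of the network,
so cooler, longer operation buys EC yield at the cost of reaction time.  The
yield map quantifies that tradeoff; the validation report compares the
model's extrapolated 60/70 degC, 3 h predictions with the yields measured in
semi-batch stirred-tank runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinetic_core import ModelParams, SpeciesState, celsius_to_kelvin
from .reactor import simulate_batch, to_observables

__all__ = [
    "YieldMap",
    "STANDARD_INITIAL",
    "VALIDATION_EXPERIMENTS",
    "default_temperature_grid",
    "default_time_grid",
    "yield_map",
    "validation_report",
]

#: Standard initial state of the kinetic campaign (mol/L).
STANDARD_INITIAL = SpeciesState(C_EDA=0.02, C_DMH=0.022)

#: Measured EC yields of the semi-batch stirred validation runs:
#: (temperature degC, reaction time s) -> yield.
VALIDATION_EXPERIMENTS = {
    (60.0, 10800.0): 0.516,
    (70.0, 10800.0): 0.494,
}


def default_temperature_grid() -> np.ndarray:
    """60-140 degC in 10 K steps, returned in kelvin."""
    return celsius_to_kelvin(np.arange(60.0, 141.0, 10.0))


def default_time_grid(n: int = 40) -> np.ndarray:
    """Logarithmic 1 s - 5 h grid covering both the micro-flow window and
    the slow low-temperature region."""
    return np.logspace(0.0, np.log10(5 * 3600.0), n)


@dataclass
class YieldMap:
    """Observables on a (temperature, time) grid for one initial state."""

    T_grid: np.ndarray   # K, ascending
    t_grid: np.ndarray   # s, ascending
    X_EDA: np.ndarray    # (nT, nt)
    Y_EC: np.ndarray
    Y_DIM: np.ndarray
    initial_state: SpeciesState = STANDARD_INITIAL
    C_cat0: float = 2.0e-5

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, T in enumerate(self.T_grid):
            for j, t in enumerate(self.t_grid):
                rows.append((T - 273.15, t, self.X_EDA[i, j],
                             self.Y_EC[i, j], self.Y_DIM[i, j]))
        return pd.DataFrame(rows, columns=["T_C", "t_s", "X_EDA", "Y_EC",
                                           "Y_DIM"])


def yield_map(T_grid, t_grid, initial: SpeciesState,
              params: ModelParams) -> YieldMap:
    """One batch integration per temperature, observables sampled on ``t_grid``."""
    T_grid = np.asarray(T_grid, float)
    t_grid = np.asarray(t_grid, float)
    if T_grid.size == 0 or t_grid.size == 0:
        raise ValueError("grids must be non-empty")
    if np.any(np.diff(T_grid) <= 0) or np.any(np.diff(t_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    shape = (T_grid.size, t_grid.size)
    X = np.empty(shape)
    Yec = np.empty(shape)
    Ydim = np.empty(shape)
    for i, T in enumerate(T_grid):
        traj = simulate_batch(initial, params, float(T), float(t_grid[-1]),
                              t_eval=t_grid)
        for j, t in enumerate(t_grid):
            obs = to_observables(traj, initial.C_EDA, float(t))
            X[i, j] = obs.X_EDA
            Yec[i, j] = obs.Y_EC
            Ydim[i, j] = obs.Y_DIM
    return YieldMap(T_grid=T_grid, t_grid=t_grid, X_EDA=X, Y_EC=Yec,
                    Y_DIM=Ydim, initial_state=initial,
                    C_cat0=params.catalyst.C_cat0)


def validation_report(params: ModelParams) -> pd.DataFrame:
    """Predicted vs measured EC yield at the extrapolation check points.

    Predictions are batch integrations from the standard initial state
    (EDA 0.02, DMH 0.022, catalyst 2e-5 mol/L) at 60 and 70 degC for 3 h.
    """
    rows = []
    for (T_C, t_s), y_exp in sorted(VALIDATION_EXPERIMENTS.items()):
        traj = simulate_batch(STANDARD_INITIAL, params,
                              celsius_to_kelvin(T_C), t_s)
        obs = to_observables(traj, STANDARD_INITIAL.C_EDA, t_s)
        rows.append((T_C, t_s, obs.Y_EC, y_exp, abs(obs.Y_EC - y_exp)))
    return pd.DataFrame(rows, columns=["T_C", "t_s", "Y_EC_pred", "Y_EC_exp",
                                       "abs_gap"])
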