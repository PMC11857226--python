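"""Synthetic micro-flow experiment generator.

Emulates the three experimental series the kinetic model was regressed
from — olefin-excess, reactant-concentration and temperature series — by
simulating the plug-flow observables at a grid of residence times and adding
independent Gaussian measurement noise per replicate.  The residence-time
grid follows the real pipeline: tube-section combinations spanning reactor
volumes of about 1.7 to 19 mL at a fixed total flow rate, i.e. residence
times of roughly 5 to 56 s.

The generator reproduces the *statistical* structure of the measurements
(triplicates, additive yield noise of GC-internal-standard magnitude,
truncation to [0, 1]); it does not emulate GC analytics, feed impurity or
flow non-idealities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetic_core import ModelParams, SpeciesState, celsius_to_kelvin
from .reactor import (
    FlowConfig,
    TubeSection,
    residence_time,
    simulate_batch,
    to_observables,
)
from .regression import OBS_COLUMNS, ExperimentTable

__all__ = [
    "DesignSpec",
    "paper_residence_grid",
    "paper_design",
    "design_conditions",
    "generate_dataset",
]

SERIES_TYPES = ("olefin-excess", "concentration", "temperature")

#: Standard loadings of the micro-flow campaign.
BASE_C_EDA0 = 0.02      # mol/L
BASE_RATIO = 1.1        # DMH:EDA
BASE_C_CAT0 = 2.0e-5    # mol/L
BASE_T_C = 130.0        # degC
DEFAULT_NOISE_SD = 0.01  # absolute, on each observable
DEFAULT_REPLICATES = 3


@dataclass(frozen=True)
class DesignSpec:
    """One experimental series: which factor is varied and how it is sampled.

    ``levels`` are DMH:EDA excess ratios (olefin-excess series),
    concentration multipliers on the standard 0.02/0.022 mol/L loadings
    (concentration series), or temperatures in degC (temperature series).
    """

    series: str
    levels: tuple
    times: tuple  # residence times, s
    replicates: int = DEFAULT_REPLICATES
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.series not in SERIES_TYPES:
            raise ValueError(f"unknown series type {self.series!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.levels or not self.times:
            raise ValueError("levels and times must be non-empty")
        if any(t <= 0 or t > 120 for t in self.times):
            raise ValueError("flow residence times must lie in (0, 120] s")


def paper_residence_grid(flow_rate_mL_min: float = 20.4,
                         accessory_volume_mL: float = 0.13) -> tuple:
    """Residence times of the six tube-section configurations at fixed flow.

    The pipeline offers four 1 mm i.d. sections (S1) and two 2 mm i.d.
    sections (S2), 2 m each, connected cumulatively: 1-4 x S1, then adding
    the S2 sections.
    """
    configs = [(1, 0), (2, 0), (3, 0), (4, 0), (4, 1), (4, 2)]
    times = []
    for n1, n2 in configs:
        sections = []
        if n1:
            sections.append(TubeSection(inner_diameter_mm=1.0, length_m=2.0,
                                        count=n1))
        if n2:
            sections.append(TubeSection(inner_diameter_mm=2.0, length_m=2.0,
                                        count=n2))
        flow = FlowConfig(sections=tuple(sections),
                          total_flow_rate_mL_min=flow_rate_mL_min,
                          accessory_volume_mL=accessory_volume_mL)
        times.append(round(residence_time(flow), 2))
    return tuple(times)


def paper_design(noise_sd: float = DEFAULT_NOISE_SD,
                 seed: int = 0) -> list[DesignSpec]:
    """The three series of the kinetic campaign.

    (a) olefin-excess at 130 degC, DMH:EDA in {1.1, 2, 5} (levels above 1.1
    are this package's choices; only the 1:1.1 baseline is pinned down);
    (b) concentration series at 130 degC, 1:1.1 ratio, multipliers
    {0.5, 1, 2}; (c) temperature series at {110, 120, 130, 140} degC with
    the standard loadings.  Triplicates throughout.
    """
    grid = paper_residence_grid()
    return [
        DesignSpec(series="olefin-excess", levels=(1.1, 2.0, 5.0),
                   times=grid, noise_sd=noise_sd, seed=seed),
        DesignSpec(series="concentration", levels=(0.5, 1.0, 2.0),
                   times=grid, noise_sd=noise_sd, seed=seed + 1),
        DesignSpec(series="temperature", levels=(110.0, 120.0, 130.0, 140.0),
                   times=grid, noise_sd=noise_sd, seed=seed + 2),
    ]


def design_conditions(design: DesignSpec) -> list[dict]:
    """Expand a design into per-condition records (id, T, loadings)."""
    conds = []
    for level in design.levels:
        if design.series == "olefin-excess":
            cond = dict(T_C=BASE_T_C, C_EDA0=BASE_C_EDA0,
                        C_DMH0=BASE_C_EDA0 * level, C_cat0=BASE_C_CAT0,
                        condition_id=f"excess_{level:g}")
        elif design.series == "concentration":
            cond = dict(T_C=BASE_T_C, C_EDA0=BASE_C_EDA0 * level,
                        C_DMH0=BASE_C_EDA0 * BASE_RATIO * level,
                        C_cat0=BASE_C_CAT0,
                        condition_id=f"conc_{level:g}x")
        else:  # temperature
            cond = dict(T_C=level, C_EDA0=BASE_C_EDA0,
                        C_DMH0=BASE_C_EDA0 * BASE_RATIO, C_cat0=BASE_C_CAT0,
                        condition_id=f"temp_{level:g}C")
        conds.append(cond)
    return conds


def generate_dataset(design: DesignSpec, truth: ModelParams,
                     seed: int | None = None) -> list[ExperimentTable]:
    """Simulate one series and add replicate measurement noise.

    Each condition is integrated once; observables at the residence-time
    grid get independent N(0, noise_sd) noise per replicate and observable,
    truncated to [0, 1].  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    tables = []
    times = np.sort(np.asarray(design.times, float))
    for cond in design_conditions(design):
        T = celsius_to_kelvin(cond["T_C"])
        params = truth.with_catalyst(C_cat0=cond["C_cat0"])
        initial = SpeciesState(C_EDA=cond["C_EDA0"], C_DMH=cond["C_DMH0"])
        traj = simulate_batch(initial, params, T, float(times[-1]),
                              t_eval=times)
        clean = np.array([
            [to_observables(traj, cond["C_EDA0"], float(t)).__getattribute__(a)
             for a in ("X_EDA", "Y_EC", "Y_DIM")]
            for t in times
        ])
        rows = []
        for rep in range(1, design.replicates + 1):
            noisy = clean + rng.normal(0.0, design.noise_sd, size=clean.shape) \
                if design.noise_sd > 0 else clean.copy()
            noisy = np.clip(noisy, 0.0, 1.0)
            for t, (x, yec, ydim) in zip(times, noisy):
                rows.append((t, x, yec, ydim, rep))
        tables.append(ExperimentTable(
            condition_id=cond["condition_id"],
            T=T,
            C_EDA0=cond["C_EDA0"],
            C_DMH0=cond["C_DMH0"],
            C_cat0=cond["C_cat0"],
            data=pd.DataFrame(rows, columns=["t_s", *OBS_COLUMNS, "replicate"]),
        ))
    return tables
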