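"""Rate laws and ODE right-hand side for the simplified cyclopropanation network.

The network condenses the Cu(stearate)/phenylhydrazine-catalysed reaction of
ethyl diazoacetate (EDA) with 2,5-dimethyl-2,4-hexadiene (DMH) to four
irreversible second-order steps plus one fast coordination equilibrium:

    step 0:  EDA + Cat        -> N2 + MC          (rate constant k0)
    step 1:  MC  + DMH        -> Cat + EC         (k1, main cyclopropanation)
    step 2:  MC  + EDA        -> Cat + DIM        (k2, carbene dimerisation)
    step 3:  MC  + DIM        -> Cat + trimer     (k3, dimer consumption)
    equil:   Cat + DMH       <-> Cat-complex      (equilibrium constant K)

MC is the copper carbene, EC the cyclopropanated product (ethyl
chrysanthemate) and DIM the pooled EDA dimers (diethyl fumarate + maleate).
The free-carbene pathway, higher oligomers and cis/trans isomerism are
deliberately outside this model.

The carbene-forming step is driven by the DMH-bound catalyst complex by
default (``complex-active``); selecting ``free-active`` instead drives it by
the uncomplexed catalyst, which resolves the same network under the
alternative reading of step 0.

Units throughout: concentrations mol/L, time s, temperature K, rate
constants L mol^-1 s^-1, K in L/mol, activation energies kJ/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GAS_CONSTANT",
    "SPECIES",
    "ArrheniusLaw",
    "RateSet",
    "SpeciesState",
    "CatalystSpec",
    "ModelParams",
    "celsius_to_kelvin",
    "rate_constants_at",
    "free_catalyst",
    "active_complex",
    "rhs",
    "eda_unit_balance",
]

#: Gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.314

#: Canonical species ordering used by every state vector in the package.
SPECIES = ("EDA", "DMH", "MC", "EC", "DIM", "TRI")


def celsius_to_kelvin(T_C: float) -> float:
    return T_C + 273.15


@dataclass(frozen=True)
class ArrheniusLaw:
    """Temperature dependence k(T) = A * exp(-Ea / (R T)) of one rate constant.

    Parameters
    ----------
    A : pre-exponential factor, L mol^-1 s^-1.
    Ea : activation energy, kJ/mol.
    """

    A: float
    Ea: float

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"pre-exponential factor must be positive, got {self.A}")
        if self.Ea < 0:
            raise ValueError(f"activation energy must be non-negative, got {self.Ea}")

    def k_at(self, T: float) -> float:
        """Evaluate the rate constant at temperature ``T`` (K)."""
        if T <= 0:
            raise ValueError(f"temperature must be positive, got {T} K")
        return self.A * math.exp(-self.Ea * 1e3 / (GAS_CONSTANT * T))


@dataclass(frozen=True)
class RateSet:
    """The four second-order rate constants at one temperature plus K.

    k0 forms the metal carbene, k1 is cyclopropanation, k2 dimerisation,
    k3 trimerisation; K is the catalyst–DMH coordination constant (L/mol).
    """

    k0: float
    k1: float
    k2: float
    k3: float
    K: float
    T: float

    def __post_init__(self) -> None:
        for name in ("k0", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.K < 0:
            raise ValueError("K must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2, self.k3])


@dataclass(frozen=True)
class SpeciesState:
    """Concentrations (mol/L) of the six tracked species at one time point.

    The trimer is carried only to close the diazo-unit balance; it takes no
    part in any rate law beyond being the k3 product.
    """

    C_EDA: float = 0.0
    C_DMH: float = 0.0
    C_MC: float = 0.0
    C_EC: float = 0.0
    C_DIM: float = 0.0
    C_TRI: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.C_EDA, self.C_DMH, self.C_MC, self.C_EC, self.C_DIM, self.C_TRI]
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SpeciesState":
        return cls(*(float(v) for v in y))


@dataclass(frozen=True)
class CatalystSpec:
    """Total catalyst loading and the choice of carbene-forming partner.

    ``active_species_mode`` is ``"complex-active"`` (the DMH-bound complex
    reacts with EDA, as the model equations are written) or ``"free-active"``
    (the uncomplexed catalyst reacts).
    """

    C_cat0: float
    active_species_mode: str = "complex-active"

    def __post_init__(self) -> None:
        if self.C_cat0 <= 0:
            raise ValueError("total catalyst concentration must be positive")
        if self.active_species_mode not in ("complex-active", "free-active"):
            raise ValueError(
                f"unknown active_species_mode {self.active_species_mode!r}"
            )


# Published Arrhenius parameters of the four steps (A in L mol^-1 s^-1,
# Ea in kJ/mol), regressed from micro-flow data at 110-140 degC.
DEFAULT_ARRHENIUS = {
    "k0": ArrheniusLaw(A=1.9555e15, Ea=89.60),
    "k1": ArrheniusLaw(A=1.4989e13, Ea=71.77),
    "k2": ArrheniusLaw(A=8.0898e17, Ea=104.07),
    "k3": ArrheniusLaw(A=5.3287e14, Ea=78.49),
}

#: Default coordination constant, L/mol.  Chosen deep in the saturation
#: regime (K * C_DMH ~ 200 at the standard DMH loading) where predictions
#: are insensitive to its exact value; it was never measured independently.
DEFAULT_K = 1.0e4

#: Standard catalyst loading of the micro-flow experiments, mol/L.
DEFAULT_C_CAT0 = 2.0e-5


@dataclass(frozen=True)
class ModelParams:
    """Full parameterisation: one Arrhenius law per step, K, catalyst spec.

    K is treated as temperature-insensitive.
    """

    arrhenius_laws: dict = field(
        default_factory=lambda: dict(DEFAULT_ARRHENIUS)
    )
    K: float = DEFAULT_K
    catalyst: CatalystSpec = field(
        default_factory=lambda: CatalystSpec(C_cat0=DEFAULT_C_CAT0)
    )

    def __post_init__(self) -> None:
        if set(self.arrhenius_laws) != {"k0", "k1", "k2", "k3"}:
            raise ValueError(
                "arrhenius_laws must hold exactly the keys k0, k1, k2, k3"
            )
        if self.K < 0:
            raise ValueError("K must be non-negative")

    @classmethod
    def default(cls) -> "ModelParams":
        return cls()

    def with_catalyst(self, C_cat0: float | None = None,
                      active_species_mode: str | None = None) -> "ModelParams":
        cat = CatalystSpec(
            C_cat0=self.catalyst.C_cat0 if C_cat0 is None else C_cat0,
            active_species_mode=(
                self.catalyst.active_species_mode
                if active_species_mode is None
                else active_species_mode
            ),
        )
        return replace(self, catalyst=cat)


def rate_constants_at(T: float, params: ModelParams) -> RateSet:
    """Evaluate all four Arrhenius laws at ``T`` (K); K passes through unchanged."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    laws = params.arrhenius_laws
    return RateSet(
        k0=laws["k0"].k_at(T),
        k1=laws["k1"].k_at(T),
        k2=laws["k2"].k_at(T),
        k3=laws["k3"].k_at(T),
        K=params.K,
        T=T,
    )


def free_catalyst(state: SpeciesState, params: ModelParams) -> float:
    """Uncomplexed catalyst concentration from the coordination balance.

    C_cat = (C_cat0 - C_MC) / (1 + K * C_DMH): whatever catalyst is not tied
    up as carbene partitions between free form and the DMH adduct.
    """
    C_cat0 = params.catalyst.C_cat0
    if state.C_MC > C_cat0 * (1 + 1e-12):
        raise ValueError(
            f"carbene concentration {state.C_MC} exceeds total catalyst {C_cat0}"
        )
    return max(C_cat0 - state.C_MC, 0.0) / (1.0 + params.K * state.C_DMH)


def active_complex(state: SpeciesState, params: ModelParams) -> float:
    """Concentration of the catalytic species that reacts with EDA in step 0.

    Complex-active mode returns the DMH-bound adduct K*C_DMH*C_cat (the
    species the model equations multiply k0 by); free-active mode returns
    the uncomplexed catalyst.  In complex-active mode the catalyst balance
    C_cat + C_cat-complex + C_MC = C_cat0 closes exactly.
    """
    free = free_catalyst(state, params)
    if params.catalyst.active_species_mode == "complex-active":
        return params.K * state.C_DMH * free
    return free


def _rhs_array(y: np.ndarray, k: np.ndarray, K: float, C_cat0: float,
               complex_active: bool) -> np.ndarray:
    """Raw derivative on a plain state vector; hot path for the integrators."""
    C_EDA, C_DMH, C_MC, C_EC, C_DIM, _ = y
    free = (C_cat0 - C_MC) / (1.0 + K * C_DMH)
    active = K * C_DMH * free if complex_active else free
    r0 = k[0] * C_EDA * active
    r1 = k[1] * C_MC * C_DMH
    r2 = k[2] * C_MC * C_EDA
    r3 = k[3] * C_MC * C_DIM
    return np.array([
        -r0 - r2,            # EDA
        -r1,                 # DMH
        r0 - r1 - r2 - r3,   # MC
        r1,                  # EC
        r2 - r3,             # DIM
        r3,                  # trimer
    ])


def rhs(state: SpeciesState, rates: RateSet, params: ModelParams) -> SpeciesState:
    """Time derivative of the species state, mol L^-1 s^-1.

    d[EDA]/dt = -k0 [EDA][active] - k2 [MC][EDA]
    d[MC]/dt  =  k0 [EDA][active] - k1 [MC][DMH] - k2 [MC][EDA] - k3 [MC][DIM]
    d[EC]/dt  = -d[DMH]/dt = k1 [MC][DMH]
    d[DIM]/dt =  k2 [MC][EDA] - k3 [MC][DIM]
    d[TRI]/dt =  k3 [MC][DIM]
    """
    # validate via free_catalyst (raises on MC > C_cat0)
    free_catalyst(state, params)
    dy = _rhs_array(
        state.as_array(),
        rates.as_array(),
        rates.K,
        params.catalyst.C_cat0,
        params.catalyst.active_species_mode == "complex-active",
    )
    return SpeciesState.from_array(dy)


def eda_unit_balance(state: SpeciesState, C_EDA0: float) -> float:
    """Residual of the diazo-unit balance, mol/L.

    Every EDA molecule ends up as unreacted EDA, carbene, one EC, half a
    dimer or a third of a trimer, so
    C_EDA + C_MC + C_EC + 2 C_DIM + 3 C_TRI - C_EDA0 vanishes along any
    closed-system trajectory.
    """
    return (
        state.C_EDA + state.C_MC + state.C_EC
        + 2.0 * state.C_DIM + 3.0 * state.C_TRI - C_EDA0
    )
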