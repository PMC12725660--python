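"""Kinetic model of blood glucose regulation with a transient glucose store.

The model tracks four quantities: blood glucose ``G`` (mg/dL), blood insulin
``I`` (ng/mL), a transient, insulin-independently filled glucose store ``stG``
(mg/dL-equivalent, capacity ``k7``), and the cumulative glucose uptake ``AG``
(mg/dL-equivalent; multiply by circulating blood volume in dL to get mg).

Six mass-transfer fluxes connect them:

====== ===================================== ==========================
flux   meaning                               form
====== ===================================== ==========================
flux1  endogenous glucose production (EGP),  ``k1 / (1 + I + k8*G)``
       suppressed by insulin and glucose
flux2  insulin-dependent glucose uptake      ``k2 * G * I``
flux3  glucose-stimulated insulin secretion  ``k3 * G``
flux4  insulin clearance                     ``k4 * I``
flux5  insulin-independent uptake into the   ``k5 * G * (k7 - stG)``
       store ("glucose effectiveness")
flux6  insulin-dependent consumption of the  ``k6 * stG * I``
       store
====== ===================================== ==========================

with exogenous infusion ``f(t)`` (mg/dL/min) entering the glucose pool:

.. math::

    dG/dt   &= flux_1 - flux_2 - flux_5 + f(t) \\
    dI/dt   &= flux_3 - flux_4 \\
    dstG/dt &= flux_5 - flux_6 \\
    dAG/dt  &= flux_2 - flux_1 + flux_5

Uptake is counted when glucose leaves the blood (flux2 and flux5, net of
EGP), not when the store is later consumed, so flux6 does not enter dAG/dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParameters",
    "ModelState",
    "FluxVector",
    "PARAM_NAMES",
    "eval_fluxes",
    "eval_rhs",
    "basal_steady_state",
    "conditional_store_equilibrium",
    "DomainError",
    "SteadyStateError",
]

PARAM_NAMES = ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "G0", "I0")

#: default physiological plausibility bounds for the estimated initial levels
G0_BOUNDS = (40.0, 300.0)
I0_BOUNDS = (0.05, 20.0)


class DomainError(ValueError):
    """A state or parameter violates a model bound."""


class SteadyStateError(RuntimeError):
    """No basal steady state in the positive orthant."""


@dataclass(frozen=True)
class ModelParameters:
    """The eight rate constants plus the estimated initial levels.

    ``k8`` may be zero (pure insulin suppression of EGP, useful for ablation
    experiments); all other entries must be strictly positive. ``G0`` and
    ``I0`` must lie in the configured physiological bounds.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    G0: float
    I0: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not np.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v}")
            if name == "k8":
                if v < 0:
                    raise DomainError(f"k8 must be >= 0, got {v}")
            elif v <= 0:
                raise DomainError(f"{name} must be > 0, got {v}")
        if not (G0_BOUNDS[0] <= self.G0 <= G0_BOUNDS[1]):
            raise DomainError(
                f"G0={self.G0} outside physiological bounds {G0_BOUNDS}"
            )
        if not (I0_BOUNDS[0] <= self.I0 <= I0_BOUNDS[1]):
            raise DomainError(
                f"I0={self.I0} outside physiological bounds {I0_BOUNDS}"
            )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "ModelParameters":
        """Build from a flat mapping with exactly the keys k1..k8, G0, I0."""
        unknown = set(mapping) - set(PARAM_NAMES)
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(mapping)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(mapping[k]) for k in PARAM_NAMES})

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr) -> "ModelParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} values, got {arr.shape}")
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def replace(self, **kwargs) -> "ModelParameters":
        d = self.to_dict()
        d.update(kwargs)
        return ModelParameters.from_dict(d)


@dataclass(frozen=True)
class ModelState:
    G: float
    I: float
    stG: float
    AG: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.G, self.I, self.stG, self.AG])

    @classmethod
    def from_array(cls, arr) -> "ModelState":
        G, I, stG, AG = (float(x) for x in arr)
        return cls(G=G, I=I, stG=stG, AG=AG)


@dataclass(frozen=True)
class FluxVector:
    flux1: float
    flux2: float
    flux3: float
    flux4: float
    flux5: float
    flux6: float
    influxG: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.flux1, self.flux2, self.flux3, self.flux4,
             self.flux5, self.flux6, self.influxG]
        )


def _check_state(state: ModelState, params: ModelParameters) -> None:
    if state.G < 0:
        raise DomainError(f"G must be >= 0, got {state.G}")
    if state.I < 0:
        raise DomainError(f"I must be >= 0, got {state.I}")
    if state.stG < 0:
        raise DomainError(f"stG must be >= 0, got {state.stG}")
    if state.stG > params.k7:
        raise DomainError(
            f"stG={state.stG} exceeds the store capacity k7={params.k7}"
        )


def eval_fluxes(
    state: ModelState, params: ModelParameters, infusion_rate: float = 0.0
) -> FluxVector:
    """Evaluate all six model fluxes plus the exogenous infusion.

    ``infusion_rate`` is in mg/dL/min (glucose mass flux already divided by
    the circulating blood volume).
    """
    _check_state(state, params)
    if infusion_rate < 0:
        raise DomainError(f"infusion_rate must be >= 0, got {infusion_rate}")
    G, I, stG = state.G, state.I, state.stG
    p = params
    return FluxVector(
        flux1=p.k1 / (1.0 + I + p.k8 * G),
        flux2=p.k2 * G * I,
        flux3=p.k3 * G,
        flux4=p.k4 * I,
        flux5=p.k5 * G * (p.k7 - stG),
        flux6=p.k6 * stG * I,
        influxG=float(infusion_rate),
    )


def eval_rhs(
    state: ModelState, params: ModelParameters, infusion_rate: float = 0.0
) -> np.ndarray:
    """Time derivatives (dG/dt, dI/dt, dstG/dt, dAG/dt) from the fluxes."""
    fl = eval_fluxes(state, params, infusion_rate)
    return np.array(
        [
            fl.flux1 - fl.flux2 - fl.flux5 + fl.influxG,
            fl.flux3 - fl.flux4,
            fl.flux5 - fl.flux6,
            fl.flux2 - fl.flux1 + fl.flux5,
        ]
    )


def conditional_store_equilibrium(params: ModelParameters, G: float, I: float) -> float:
    """Store level at which filling balances consumption for fixed G, I."""
    fill = params.k5 * G
    drain = params.k6 * I
    if fill + drain <= 0:
        return 0.0
    return params.k7 * fill / (fill + drain)


def basal_steady_state(params: ModelParameters, tol: float = 1e-12) -> ModelState:
    """Fasting fixed point of the model with no infusion.

    Solves the three algebraic balances flux1=flux2+flux5, flux3=flux4,
    flux5=flux6 for (G, I, stG). The insulin balance gives I = k3*G/k4 in
    closed form; the store balance gives stG as a function of (G, I); the
    glucose balance is then a scalar root problem in G, solved by bracketing.
    """
    p = params

    def imbalance(G: float) -> float:
        I = p.k3 * G / p.k4
        stG = conditional_store_equilibrium(p, G, I)
        flux1 = p.k1 / (1.0 + I + p.k8 * G)
        return flux1 - p.k2 * G * I - p.k5 * G * (p.k7 - stG)

    lo = 1e-9
    if imbalance(lo) <= 0:  # EGP positive at G->0, so this should not happen
        raise SteadyStateError(
            "no basal steady state in the positive orthant; widen parameter bounds"
        )
    hi = 1.0
    while imbalance(hi) > 0:
        hi *= 10.0
        if hi > 1e9:
            raise SteadyStateError(
                "no basal steady state below G=1e9; check parameter bounds"
            )
    G = brentq(imbalance, lo, hi, xtol=tol, rtol=8.9e-16)
    I = p.k3 * G / p.k4
    stG = conditional_store_equilibrium(p, G, I)
    state = ModelState(G=G, I=I, stG=stG, AG=0.0)
    resid = eval_rhs(state, p, 0.0)[:3]
    if np.max(np.abs(resid)) >= 1e-9:
        raise SteadyStateError(
            f"steady-state residual {np.max(np.abs(resid)):.3e} exceeds 1e-9"
        )
    return state
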