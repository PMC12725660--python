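"""Data-side quantities: blood volume, cumulative uptake, tracer conversion, AUC.

These are the formulas applied to measured (or simulated) clamp records rather
than to model trajectories: the circulating-blood-volume constant, the
discrete cumulative glucose uptake AG(ti) reconstructed from infusion doses
and glucose differences, the 2-deoxyglucose organ-uptake conversion, and
trapezoidal AUC windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClampRecord",
    "blood_volume",
    "cumulative_uptake",
    "organ_uptake",
    "auc",
    "BLOOD_VOLUME_ML_PER_KG",
    "GLUCOSE_GRID",
    "INSULIN_GRID",
]

#: circulating blood volume per unit body weight
BLOOD_VOLUME_ML_PER_KG = 72.0

#: clamp glucose measurement times (min): 0,1,2,3,5, every 5 to 70, every 10 to 180
GLUCOSE_GRID = np.array(
    [0, 1, 2, 3, 5]
    + list(range(10, 75, 5))
    + list(range(80, 190, 10)),
    dtype=float,
)

#: clamp insulin sampling times tj (min)
INSULIN_GRID = np.array(
    [0, 1, 2, 3, 5, 10, 20, 30, 45, 60, 90, 120, 150, 180], dtype=float
)


def blood_volume(body_weight_g: float) -> float:
    """Circulating blood volume in dL for a mouse of ``body_weight_g`` grams.

    Uses 72 mL blood per kg body weight; e.g. a 25 g mouse carries
    1.8 mL = 0.018 dL.
    """
    if body_weight_g <= 0:
        raise ValueError(f"body weight must be > 0 g, got {body_weight_g}")
    return body_weight_g / 1000.0 * BLOOD_VOLUME_ML_PER_KG / 100.0


@dataclass
class ClampRecord:
    """One mouse's hyperglycemic-clamp measurements.

    ``doses`` holds the glucose mass (mg) administered in the interval
    ``(dose_times[i-1], dose_times[i]]``; ``dose_times`` must start after 0
    or align with the glucose grid tail (the first glucose time is 0 and has
    no preceding interval).
    """

    mouse_id: str
    group: str
    body_weight: float  # g
    glucose_times: np.ndarray  # min
    glucose_values: np.ndarray  # mg/dL
    insulin_times: np.ndarray  # min
    insulin_values: np.ndarray  # ng/mL
    dose_times: np.ndarray  # min, interval right edges
    doses: np.ndarray  # mg per interval
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("glucose_times", "glucose_values", "insulin_times",
                     "insulin_values", "dose_times", "doses"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.body_weight <= 0:
            raise ValueError(f"{self.mouse_id}: body weight must be positive")
        for tname, vname in (("glucose_times", "glucose_values"),
                             ("insulin_times", "insulin_values"),
                             ("dose_times", "doses")):
            t, v = getattr(self, tname), getattr(self, vname)
            if t.shape != v.shape:
                raise ValueError(f"{self.mouse_id}: {tname} and {vname} differ in length")
            if t.size and (np.any(np.diff(t) <= 0)):
                raise ValueError(f"{self.mouse_id}: {tname} must be strictly increasing")
            if t.size and (t[0] < 0 or t[-1] > 180):
                raise ValueError(f"{self.mouse_id}: {tname} outside [0, 180] min")
        if np.any(self.glucose_values <= 0) or np.any(self.insulin_values <= 0):
            raise ValueError(f"{self.mouse_id}: glucose and insulin values must be > 0")
        if np.any(self.doses < 0):
            raise ValueError(f"{self.mouse_id}: doses must be >= 0")

    @property
    def blood_volume_dl(self) -> float:
        return blood_volume(self.body_weight)


def cumulative_uptake(record: ClampRecord, missing_dose: str = "error") -> np.ndarray:
    """Cumulative glucose uptake AG(ti) in mg at the record's glucose times.

    AG(t0)=0 and, per measurement interval,

        AG(ti) = AG(ti-1) + dose_i - (G(ti) - G(ti-1)) * V_blood(dL)

    i.e. every mg infused that did not raise the circulating glucose mass has
    been taken up. Doses must align with the glucose-grid intervals;
    ``missing_dose`` selects the policy for intervals without a recorded dose
    ("error" or "zero", the latter warns once).
    """
    if missing_dose not in ("error", "zero"):
        raise ValueError("missing_dose must be 'error' or 'zero'")
    t = record.glucose_times
    g = record.glucose_values
    v = record.blood_volume_dl

    dose_map = dict(zip(record.dose_times.tolist(), record.doses.tolist()))
    extra = set(record.dose_times.tolist()) - set(t[1:].tolist())
    if extra:
        raise ValueError(
            f"{record.mouse_id}: dose times {sorted(extra)} do not align with "
            "the glucose measurement grid"
        )
    doses = np.empty(t.size - 1)
    missing = []
    for i, ti in enumerate(t[1:]):
        if ti in dose_map:
            doses[i] = dose_map[ti]
        else:
            missing.append(ti)
            doses[i] = 0.0
    if missing:
        if missing_dose == "error":
            raise ValueError(
                f"{record.mouse_id}: no dose recorded for intervals ending at "
                f"{missing}; pass missing_dose='zero' to treat them as 0"
            )
        warnings.warn(
            f"{record.mouse_id}: treating missing doses at {missing} as 0 mg",
            stacklevel=2,
        )
    ag = np.concatenate([[0.0], np.cumsum(doses - np.diff(g) * v)])
    return ag


def organ_uptake(
    glucose_administered_10min_mg: float,
    dg_uptake_nmol: float,
    dg_administered_nmol: float = 5000.0,
) -> float:
    """Glucose mass (mg) taken up by an organ, from its 2-DG tracer uptake.

    The tracer is co-infused over the 10 min before sampling (5 µmol = 5000
    nmol by default); the organ's share of the tracer is assumed to equal its
    share of the glucose administered over the same window.
    """
    if glucose_administered_10min_mg < 0 or dg_uptake_nmol < 0:
        raise ValueError("inputs must be non-negative")
    if dg_administered_nmol <= 0:
        raise ValueError("administered 2-DG must be positive")
    if dg_uptake_nmol > dg_administered_nmol:
        warnings.warn(
            "organ 2-DG uptake exceeds the administered dose; value returned "
            "but physically suspect",
            stacklevel=2,
        )
    return glucose_administered_10min_mg * dg_uptake_nmol / dg_administered_nmol


def auc(times, values, window: tuple[float, float]) -> float:
    """Trapezoidal area under (times, values) over ``window`` = [a, b].

    Endpoints not on the sampling grid are linearly interpolated.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    a, b = window
    if a >= b:
        raise ValueError(f"window must satisfy a < b, got {window}")
    if a < t[0] or b > t[-1]:
        raise ValueError(f"window {window} outside data span [{t[0]}, {t[-1]}]")
    inside = (t > a) & (t < b)
    tt = np.concatenate([[a], t[inside], [b]])
    vv = np.concatenate([[np.interp(a, t, v)], v[inside], [np.interp(b, t, v)]])
    return float(np.trapezoid(vv, tt))
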