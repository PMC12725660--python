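"""Experiment protocols on top of the kinetic model.

Integrates the model ODEs under three infusion regimes — a closed-loop
hyperglycemic clamp (glucose titrated at the measurement times to hold
G at fasting + 200 mg/dL), fixed piecewise-constant infusion schedules
(used when replaying recorded doses during fitting), and an IVGTT bolus —
and computes windowed flux decompositions separating insulin-independent
(flux5) from insulin-dependent (flux2) glucose uptake.

Infusion bookkeeping: pump rates are in µL/g/min of a glucose solution of
``glucose_solution_concentration`` mg/µL; multiplied by body weight (g) they
give mg/min, and divided by the circulating blood volume (dL) they give the
model's f(t) in mg/dL/min. The infused volume is assumed not to change the
blood volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

from .model import (
    ModelParameters,
    ModelState,
    conditional_store_equilibrium,
)
from .observables import GLUCOSE_GRID, blood_volume

__all__ = [
    "InfusionProtocol",
    "ClampControllerConfig",
    "Trajectory",
    "FluxDecomposition",
    "SimulationError",
    "simulate_infusion",
    "simulate_fixed",
    "run_clamp",
    "simulate_ivgtt",
    "decompose_fluxes",
    "initial_state",
    "IVGTT_GRID",
]

IVGTT_GRID = np.array([0, 1, 2, 3, 5, 10, 20, 30, 60, 90], dtype=float)

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    """ODE integration failed; carries the failing time and state."""

    def __init__(self, message: str, t: float | None = None, y=None):
        super().__init__(message)
        self.t = t
        self.y = y


@dataclass(frozen=True)
class ClampControllerConfig:
    """Discrete-time clamp controller, updated only at the adjustment times.

    The commanded rate is a model-based feedforward (the instantaneous net
    disposal flux, which would hold G exactly constant) plus a proportional-
    integral correction on the tracking error, clamped at zero. The
    proportional term is normalized by the length of the upcoming interval
    (deadbeat-style): rate += kp * error / dt_next, so a 5-min and a 10-min
    titration interval receive comparable corrective mass. ``ki`` is a
    conventional integral gain in (mg/dL/min) per (mg/dL * min).
    """

    kp: float = 0.6
    ki: float = 0.005
    use_feedforward: bool = True


@dataclass(frozen=True)
class InfusionProtocol:
    """Infusion schedule or clamp-controller configuration for one run."""

    mode: str  # "clamp" | "fixed_schedule" | "ivgtt_bolus"
    body_weight: float  # g
    glucose_solution_concentration: float = 0.25  # mg/µL ("25% solution")
    initial_rate: float = 0.15  # µL/g/min, clamp priming rate
    target_offset: float = 200.0  # mg/dL above fasting
    adjustment_times: np.ndarray | None = None  # min; default = glucose grid
    schedule_times: np.ndarray | None = None  # fixed_schedule: segment left edges
    schedule_rates: np.ndarray | None = None  # µL/g/min per segment
    bolus_dose: float = 0.75  # g/kg (IVGTT)
    bolus_duration: float = 3.0  # min (IVGTT)
    total_duration: float = 180.0  # min
    controller: ClampControllerConfig = field(default_factory=ClampControllerConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("clamp", "fixed_schedule", "ivgtt_bolus"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be positive")
        if self.initial_rate < 0 or self.bolus_dose < 0:
            raise ValueError("rates and doses must be non-negative")
        at = self.adjustment_times
        if at is None and self.mode == "clamp":
            at = GLUCOSE_GRID
        if at is not None:
            at = np.asarray(at, dtype=float)
            if np.any(np.diff(at) <= 0):
                raise ValueError("adjustment_times must be strictly increasing")
            if at[0] < 0 or at[-1] > self.total_duration:
                raise ValueError("adjustment_times outside [0, total_duration]")
            object.__setattr__(self, "adjustment_times", at)
        if self.schedule_rates is not None:
            r = np.asarray(self.schedule_rates, dtype=float)
            if np.any(r < 0):
                raise ValueError("schedule rates must be non-negative")
            object.__setattr__(self, "schedule_rates", r)
        if self.schedule_times is not None:
            object.__setattr__(
                self, "schedule_times", np.asarray(self.schedule_times, dtype=float)
            )

    @property
    def blood_volume_dl(self) -> float:
        return blood_volume(self.body_weight)

    def pump_to_f(self, rate_ul_per_g_min: float | np.ndarray):
        """µL/g/min pump rate -> model infusion f in mg/dL/min."""
        return (
            np.asarray(rate_ul_per_g_min)
            * self.body_weight
            * self.glucose_solution_concentration
            / self.blood_volume_dl
        )


@dataclass
class Trajectory:
    """Dense simulated solution with per-flux time courses.

    ``fluxes`` has one row per output time, columns flux1..flux6, influxG.
    ``infusion_breaks``/``infusion_rates`` describe the piecewise-constant
    f(t) (mg/dL/min on ``[breaks[i], breaks[i+1])``); ``dose_times``/
    ``doses_mg`` give the mass administered per inter-measurement interval.
    """

    times: np.ndarray
    G: np.ndarray
    I: np.ndarray
    stG: np.ndarray
    AG: np.ndarray
    fluxes: np.ndarray
    infusion_breaks: np.ndarray
    infusion_rates: np.ndarray
    body_weight: float
    params: ModelParameters
    dose_times: np.ndarray | None = None
    doses_mg: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def blood_volume_dl(self) -> float:
        return blood_volume(self.body_weight)

    def infusion_at(self, t) -> np.ndarray:
        """f(t) in mg/dL/min (piecewise-constant, right-open segments)."""
        t = np.asarray(t, dtype=float)
        idx = np.clip(
            np.searchsorted(self.infusion_breaks, t, side="right") - 1,
            0,
            len(self.infusion_rates) - 1,
        )
        return self.infusion_rates[idx]

    def cumulative_infused_mg(self, t) -> np.ndarray:
        """Exact cumulative infused glucose mass (mg) up to each time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        edges = np.append(self.infusion_breaks, self.times[-1])
        out = np.empty_like(t)
        cum = np.concatenate(
            [[0.0], np.cumsum(self.infusion_rates * np.diff(edges))]
        )
        idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0,
                      len(self.infusion_rates) - 1)
        out = cum[idx] + self.infusion_rates[idx] * (t - edges[idx])
        return out * self.blood_volume_dl

    def sample(self, t, what: str) -> np.ndarray:
        arr = getattr(self, what)
        return np.interp(np.asarray(t, dtype=float), self.times, arr)

    def mass_balance_residual(self) -> float:
        """Max relative gap of infused = ΔG·V + AG·V over the output grid."""
        v = self.blood_volume_dl
        infused = self.cumulative_infused_mg(self.times)
        accounted = (self.G - self.G[0]) * v + self.AG * v
        scale = max(1.0, float(np.max(np.abs(infused))))
        return float(np.max(np.abs(infused - accounted)) / scale)

    def to_frame(self):
        import pandas as pd

        cols = {
            "time_min": self.times,
            "G_mgdl": self.G,
            "I_ngml": self.I,
            "stG": self.stG,
            "AG": self.AG,
        }
        for j in range(6):
            cols[f"flux{j + 1}"] = self.fluxes[:, j]
        cols["infusion_mg_per_min"] = (
            self.fluxes[:, 6] * self.blood_volume_dl
        )
        return pd.DataFrame(cols)


@dataclass
class FluxDecomposition:
    """10-min windowed integrals of flux5 and flux2 plus the store course."""

    window_ends: np.ndarray
    flux5_integrals: np.ndarray
    flux2_integrals: np.ndarray
    stG_times: np.ndarray
    stG_series: np.ndarray
    window_width: float = 10.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "window_end_min": self.window_ends,
                "flux5_integral": self.flux5_integrals,
                "flux2_integral": self.flux2_integrals,
            }
        )


def initial_state(params: ModelParameters, stg0_mode: str = "fasted") -> ModelState:
    """Protocol starting state: (G0, I0) from the parameters, AG = 0.

    ``stg0_mode``: "fasted" starts with an empty store (overnight fast);
    "conditional_ss" starts it at its filling/consumption equilibrium for
    the fasting (G0, I0).
    """
    if stg0_mode == "fasted":
        stg = 0.0
    elif stg0_mode == "conditional_ss":
        stg = conditional_store_equilibrium(params, params.G0, params.I0)
    else:
        raise ValueError("stg0_mode must be 'fasted' or 'conditional_ss'")
    return ModelState(G=params.G0, I=params.I0, stG=stg, AG=0.0)


def _fluxes_on_grid(params: ModelParameters, y: np.ndarray, f: np.ndarray) -> np.ndarray:
    G, I, stG = y[:, 0], y[:, 1], y[:, 2]
    p = params
    out = np.empty((y.shape[0], 7))
    out[:, 0] = p.k1 / (1.0 + I + p.k8 * G)
    out[:, 1] = p.k2 * G * I
    out[:, 2] = p.k3 * G
    out[:, 3] = p.k4 * I
    out[:, 4] = p.k5 * G * (p.k7 - stG)
    out[:, 5] = p.k6 * stG * I
    out[:, 6] = f
    return out


def simulate_infusion(
    params: ModelParameters,
    breaks: np.ndarray,
    rates_f: np.ndarray,
    t_eval: np.ndarray,
    init: ModelState,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model under piecewise-constant infusion f(t) (mg/dL/min).

    ``rates_f[i]`` applies on ``[breaks[i], breaks[i+1])`` (last segment open
    to the end of ``t_eval``). Uses LSODA with the segment edges passed as
    critical points so the integrator restarts cleanly at each rate change.
    The reported ``body_weight`` of the returned trajectory is nominal (f is
    already volume-normalized); use the wrappers for pump-rate protocols.
    """
    breaks = np.asarray(breaks, dtype=float)
    rates_f = np.asarray(rates_f, dtype=float)
    if breaks.size != rates_f.size:
        raise ValueError("breaks and rates must have equal length")
    if np.any(rates_f < 0):
        raise ValueError("infusion rates must be non-negative")
    t_eval = np.asarray(t_eval, dtype=float)

    k = params.to_array()[:8]
    nseg = len(rates_f)

    def rhs(y, t):
        i = np.searchsorted(breaks, t, side="right") - 1
        f = rates_f[i] if 0 <= i < nseg else 0.0
        G, I, stG = y[0], y[1], y[2]
        flux1 = k[0] / (1.0 + I + k[7] * G)
        flux2 = k[1] * G * I
        flux5 = k[4] * G * (k[6] - stG)
        return (
            flux1 - flux2 - flux5 + f,
            k[2] * G - k[3] * I,
            flux5 - k[5] * stG * I,
            flux2 - flux1 + flux5,
        )

    t_full = np.unique(np.concatenate([t_eval, breaks[breaks <= t_eval[-1]]]))
    if t_full[0] != t_eval[0]:
        t_full = t_full[t_full >= t_eval[0]]
    y0 = init.to_array()
    tcrit = breaks[(breaks > t_full[0]) & (breaks < t_full[-1])]
    y, info = odeint(
        rhs, y0, t_full, rtol=rtol, atol=atol, tcrit=tcrit,
        full_output=True, mxstep=100000,
    )
    if info["message"] != "Integration successful.":
        bad = int(info.get("nst", [0])[-1]) if "nst" in info else -1
        raise SimulationError(
            f"ODE integration failed: {info['message']} (last step index {bad})",
            t=float(info.get("tcur", [np.nan])[-1]),
            y=y[-1],
        )
    keep = np.isin(t_full, t_eval)
    t_out, y_out = t_full[keep], y[keep]
    idx = np.clip(np.searchsorted(breaks, t_out, side="right") - 1, 0, nseg - 1)
    f_out = rates_f[idx]
    return Trajectory(
        times=t_out,
        G=y_out[:, 0],
        I=y_out[:, 1],
        stG=y_out[:, 2],
        AG=y_out[:, 3],
        fluxes=_fluxes_on_grid(params, y_out, f_out),
        infusion_breaks=breaks,
        infusion_rates=rates_f,
        body_weight=25.0,
        params=params,
    )


def _dense_grid(t_end: float, extra: np.ndarray | None = None, step: float = 0.25):
    g = np.arange(0.0, t_end + step / 2, step)
    if extra is not None:
        g = np.unique(np.concatenate([g, np.asarray(extra, dtype=float)]))
    return g[(g >= 0) & (g <= t_end)]


def simulate_fixed(
    params: ModelParameters,
    protocol: InfusionProtocol,
    init: ModelState | None = None,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    stg0_mode: str = "fasted",
) -> Trajectory:
    """Simulate a fixed (open-loop) pump schedule."""
    if protocol.mode != "fixed_schedule":
        raise ValueError("protocol.mode must be 'fixed_schedule'")
    if protocol.schedule_times is None or protocol.schedule_rates is None:
        raise ValueError("fixed_schedule protocol needs schedule_times/rates")
    if init is None:
        init = initial_state(params, stg0_mode)
    breaks = protocol.schedule_times
    rates_f = np.asarray(protocol.pump_to_f(protocol.schedule_rates), dtype=float)
    t_eval = _dense_grid(protocol.total_duration, extra=breaks)
    traj = simulate_infusion(params, breaks, rates_f, t_eval, init, rtol, atol)
    traj.body_weight = protocol.body_weight
    return traj


def run_clamp(
    params: ModelParameters,
    protocol: InfusionProtocol,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    stg0_mode: str = "fasted",
    dense_step: float = 0.25,
) -> Trajectory:
    """Closed-loop hyperglycemic clamp at target = G0 + target_offset.

    The pump runs at ``initial_rate`` until blood glucose first reaches the
    target at an adjustment time; thereafter the rate is recomputed at each
    adjustment time by the controller (feedforward + PI, clamped at >= 0) and
    held constant in between, mimicking titration at the measurement times.
    """
    if protocol.mode != "clamp":
        raise ValueError("protocol.mode must be 'clamp'")
    ctrl = protocol.controller
    target = params.G0 + protocol.target_offset
    adj = protocol.adjustment_times
    if adj is None:
        adj = GLUCOSE_GRID
    edges = np.unique(np.concatenate([adj, [0.0, protocol.total_duration]]))

    state = initial_state(params, stg0_mode)
    rate_f = float(protocol.pump_to_f(protocol.initial_rate))
    attained = False
    attained_time = None
    integ = 0.0
    prev_t = edges[0]

    seg_rates, seg_breaks = [], []
    ts, ys = [], []
    y = state.to_array()
    p = params

    def disposal(yv, t0, t1):
        """Mean net disposal over [t0, t1] with G pinned at the target.

        Integrates the insulin and store sub-dynamics forward (RK4, fixed
        steps) and averages flux2 + flux5 - flux1: the infusion that would
        hold G at the target for the whole interval, not just instantaneously
        (the store can fill substantially within one titration interval).
        """
        G = target
        I, stG = yv[1], yv[2]
        nstep = 8
        h = (t1 - t0) / nstep
        acc = 0.0

        def sub_rhs(Iv, sv):
            return (p.k3 * G - p.k4 * Iv,
                    p.k5 * G * (p.k7 - sv) - p.k6 * sv * Iv)

        def disp(Iv, sv):
            return (p.k2 * G * Iv + p.k5 * G * (p.k7 - sv)
                    - p.k1 / (1.0 + Iv + p.k8 * G))

        for _ in range(nstep):
            acc += disp(I, stG)
            d1 = sub_rhs(I, stG)
            d2 = sub_rhs(I + 0.5 * h * d1[0], stG + 0.5 * h * d1[1])
            d3 = sub_rhs(I + 0.5 * h * d2[0], stG + 0.5 * h * d2[1])
            d4 = sub_rhs(I + h * d3[0], stG + h * d3[1])
            I += h / 6.0 * (d1[0] + 2 * d2[0] + 2 * d3[0] + d4[0])
            stG += h / 6.0 * (d1[1] + 2 * d2[1] + 2 * d3[1] + d4[1])
            stG = min(max(stG, 0.0), p.k7)
        acc += disp(I, stG)
        return acc / (nstep + 1)

    for i in range(len(edges) - 1):
        t0, t1 = edges[i], edges[i + 1]
        if i > 0:
            # controller acts at segment left edge t0
            e = target - y[0]
            if not attained and y[0] >= target:
                attained = True
                attained_time = t0
                integ = 0.0
            if attained:
                dt = t0 - prev_t
                integ += ctrl.ki * dt * e
                ff = disposal(y, t0, t1) if ctrl.use_feedforward else 0.0
                rate_f = ff + ctrl.kp * e / (t1 - t0) + integ
                if rate_f < 0:
                    integ -= ctrl.ki * dt * e  # anti-windup
                    rate_f = 0.0
            prev_t = t0
        seg_breaks.append(t0)
        seg_rates.append(rate_f)
        sub = _dense_grid(t1, step=dense_step)
        sub = sub[(sub >= t0) & (sub <= t1)]
        sub = np.unique(np.concatenate([[t0], sub, [t1]]))
        traj_seg = _integrate_segment(p, y, sub, rate_f, rtol, atol)
        if i > 0:
            ts.append(sub[1:])
            ys.append(traj_seg[1:])
        else:
            ts.append(sub)
            ys.append(traj_seg)
        y = traj_seg[-1]

    times = np.concatenate(ts)
    yy = np.vstack(ys)
    breaks = np.array(seg_breaks)
    rates = np.array(seg_rates)
    idx = np.clip(np.searchsorted(breaks, times, side="right") - 1, 0, len(rates) - 1)
    f_out = rates[idx]

    meas_edges = adj[adj > 0]
    dose_edges = np.concatenate([[0.0], meas_edges])
    traj = Trajectory(
        times=times,
        G=yy[:, 0],
        I=yy[:, 1],
        stG=yy[:, 2],
        AG=yy[:, 3],
        fluxes=_fluxes_on_grid(p, yy, f_out),
        infusion_breaks=breaks,
        infusion_rates=rates,
        body_weight=protocol.body_weight,
        params=p,
        metadata={"target": target, "attained_time": attained_time},
    )
    cum = traj.cumulative_infused_mg(dose_edges)
    doses = np.diff(cum)
    traj.dose_times = meas_edges
    traj.doses_mg = doses
    if attained_time is None:
        msg = (
            f"clamp target {target:.1f} mg/dL never attained within "
            f"{protocol.total_duration:.0f} min"
        )
        traj.metadata["warning"] = msg
        warnings.warn(msg, stacklevel=2)
    return traj


def _integrate_segment(params, y0, t, rate_f, rtol, atol):
    k = params.to_array()[:8]

    def rhs(y, _t):
        G, I, stG = y[0], y[1], y[2]
        flux1 = k[0] / (1.0 + I + k[7] * G)
        flux2 = k[1] * G * I
        flux5 = k[4] * G * (k[6] - stG)
        return (
            flux1 - flux2 - flux5 + rate_f,
            k[2] * G - k[3] * I,
            flux5 - k[5] * stG * I,
            flux2 - flux1 + flux5,
        )

    y, info = odeint(rhs, y0, t, rtol=rtol, atol=atol, full_output=True,
                     mxstep=100000)
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"ODE integration failed in [{t[0]}, {t[-1]}] min: {info['message']}",
            t=t[0], y=y0,
        )
    return y


def simulate_ivgtt(
    params: ModelParameters,
    protocol: InfusionProtocol,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    stg0_mode: str = "fasted",
) -> Trajectory:
    """Glucose bolus (dose g/kg infused over bolus_duration min), then nothing.

    The dense trajectory spans [0, total_duration]; sample it at ``IVGTT_GRID``
    for the standard measurement times.
    """
    if protocol.mode != "ivgtt_bolus":
        raise ValueError("protocol.mode must be 'ivgtt_bolus'")
    mass_mg = protocol.bolus_dose * protocol.body_weight  # g/kg * g = mg
    rate_f = mass_mg / protocol.bolus_duration / protocol.blood_volume_dl
    breaks = np.array([0.0, protocol.bolus_duration])
    rates = np.array([rate_f, 0.0])
    init = initial_state(params, stg0_mode)
    t_eval = _dense_grid(protocol.total_duration, extra=np.append(IVGTT_GRID, breaks))
    t_eval = t_eval[t_eval <= protocol.total_duration]
    traj = simulate_infusion(params, breaks, rates, t_eval, init, rtol, atol)
    traj.body_weight = protocol.body_weight
    return traj


def decompose_fluxes(
    traj: Trajectory, window_ends=(10.0, 20.0, 60.0, 120.0, 180.0),
    window_width: float = 10.0,
) -> FluxDecomposition:
    """Windowed integrals of flux5 and flux2 over [end - width, end].

    Integrals are trapezoidal on the trajectory's output grid with linearly
    interpolated window endpoints; units are mg/dL (flux in mg/dL/min times
    minutes).
    """
    from .observables import auc

    ends = np.asarray(window_ends, dtype=float)
    if np.any(ends - window_width < traj.times[0] - 1e-12) or np.any(
        ends > traj.times[-1] + 1e-12
    ):
        raise ValueError(
            f"windows {window_ends} (width {window_width}) outside the "
            f"trajectory span [{traj.times[0]}, {traj.times[-1]}]"
        )
    f5 = np.array(
        [auc(traj.times, traj.fluxes[:, 4], (e - window_width, e)) for e in ends]
    )
    f2 = np.array(
        [auc(traj.times, traj.fluxes[:, 1], (e - window_width, e)) for e in ends]
    )
    return FluxDecomposition(
        window_ends=ends,
        flux5_integrals=f5,
        flux2_integrals=f2,
        stG_times=traj.times,
        stG_series=traj.stG,
        window_width=window_width,
    )
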