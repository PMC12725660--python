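"""Synthetic mouse cohorts for the hyperglycemic-clamp analysis pipeline.

Generates complete per-mouse datasets (clamp glucose/insulin time courses,
per-interval glucose doses, body weights, group labels) with the statistical
structure the analysis assumes: chow-fed controls and high-fat-diet groups of
increasing age with elevated fasting glucose/insulin, rising body weight, and
monotone parameter trends — insulin-dependent uptake (k2) and glucose
effectiveness (k5) declining, insulin secretion (k3) and store capacity (k7)
rising with obesity. Measurement noise is multiplicative Gaussian per sample
(glucometer ~5% CV, insulin ELISA ~10% CV, conventional instrument figures).

Each mouse's parameters are drawn log-normally around its group's medians;
the clamp is then simulated closed-loop with the group's priming rate and a
target of fasting + 200 mg/dL, sampled on the experimental grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelParameters, DomainError
from .observables import ClampRecord, GLUCOSE_GRID, INSULIN_GRID
from .protocols import InfusionProtocol, run_clamp

__all__ = [
    "GroupSpec",
    "CohortSpec",
    "CohortDataset",
    "REFERENCE_CD",
    "sample_mouse",
    "generate_cohort",
    "study_cohort_spec",
    "scaled_down_cohort_spec",
    "dose_shape_metrics",
]

#: reference chow-diet parameter set: fasting G 120 mg/dL, I 0.5 ng/mL,
#: insulin relaxation ~40 min, store fill ~10 min at the clamp target with
#: weak insulin-dependent consumption (the store saturates sharply near its
#: capacity k7, as expected if it reflects concentration-equilibrating
#: diffusion), basal store emptied by the overnight fast.
REFERENCE_CD = ModelParameters(
    k1=3.0, k2=1.0e-2, k3=2.08e-4, k4=2.5e-2, k5=3.0e-4, k6=1.0e-3,
    k7=600.0, k8=3.0e-3, G0=120.0, I0=0.5,
)


@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one mouse group."""

    label: str
    n: int
    body_weight_mean: float  # g
    body_weight_sd: float
    fasting_G_mean: float  # mg/dL
    fasting_G_sd: float
    fasting_I_mean: float  # ng/mL
    fasting_I_sd: float
    initial_rate: float  # µL/g/min clamp priming rate
    #: multiplicative shifts of the reference rate constants (k1..k8)
    k_multipliers: dict = field(default_factory=dict)
    #: lognormal sigma (of ln) for the rate constants
    k_sigma: float = 0.15
    target_offset: float = 200.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"{self.label}: need n >= 2 mice")
        if any(m <= 0 for m in self.k_multipliers.values()):
            raise ValueError(f"{self.label}: trend multipliers must be positive")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    glucose_cv: float = 0.05
    insulin_cv: float = 0.10
    seed: int = 0
    dose_round_mg: float = 0.1
    baseline: ModelParameters = REFERENCE_CD

    def __post_init__(self) -> None:
        for cv in (self.glucose_cv, self.insulin_cv):
            if not 0 <= cv <= 0.5:
                raise ValueError("measurement CVs must lie in [0, 0.5]")


@dataclass
class CohortDataset:
    records: list[ClampRecord]
    true_params: pd.DataFrame  # mouse_id, group, body_weight, k1..k8, G0, I0
    manifest: dict


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Draw with median ``mean`` and lognormal shape sigma (of ln)."""
    if sigma == 0:
        return mean
    return float(mean * np.exp(rng.normal(0.0, sigma)))


def sample_mouse(group: GroupSpec, rng: np.random.Generator,
                 baseline: ModelParameters = REFERENCE_CD,
                 max_rejections: int = 1000):
    """Draw one mouse's parameters and body weight from the group spec.

    Rate constants are lognormal around the group's shifted medians; fasting
    G0/I0 and body weight are truncated normal. Draws violating the model's
    physiological bounds are rejected and redrawn.
    """
    for _ in range(max_rejections):
        try:
            kw = {}
            for name in ("k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8"):
                center = getattr(baseline, name) * group.k_multipliers.get(name, 1.0)
                kw[name] = _lognormal(rng, center, group.k_sigma)
            kw["G0"] = rng.normal(group.fasting_G_mean, group.fasting_G_sd)
            kw["I0"] = rng.normal(group.fasting_I_mean, group.fasting_I_sd)
            params = ModelParameters(**kw)
            bw = rng.normal(group.body_weight_mean, group.body_weight_sd)
            if bw <= 5.0:
                continue
            return params, float(bw)
        except DomainError:
            continue
    raise ValueError(
        f"{group.label}: {max_rejections} consecutive draws violated the "
        "model bounds; check the group spec"
    )


def generate_cohort(spec: CohortSpec) -> CohortDataset:
    """Simulate every mouse's clamp and emit noisy records on the study grids.

    Mice whose clamp never attains the target are redrawn (at most 5 times,
    logged in the manifest).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ClampRecord] = []
    rows = []
    retries_log = []
    idx = 1
    for group in spec.groups:
        for _ in range(group.n):
            for attempt in range(6):
                params, bw = sample_mouse(group, rng, spec.baseline)
                protocol = InfusionProtocol(
                    mode="clamp",
                    body_weight=bw,
                    initial_rate=group.initial_rate,
                    target_offset=group.target_offset,
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    traj = run_clamp(params, protocol)
                if traj.metadata.get("attained_time") is not None:
                    break
                retries_log.append(
                    {"group": group.label, "attempt": attempt + 1}
                )
            mouse_id = f"m{idx:03d}"
            idx += 1
            g_true = traj.sample(GLUCOSE_GRID, "G")
            i_true = traj.sample(INSULIN_GRID, "I")
            g_obs = g_true * np.exp(
                rng.normal(0.0, spec.glucose_cv, size=g_true.size)
            ) if spec.glucose_cv else g_true.copy()
            i_obs = i_true * np.exp(
                rng.normal(0.0, spec.insulin_cv, size=i_true.size)
            ) if spec.insulin_cv else i_true.copy()
            doses = traj.doses_mg
            if spec.dose_round_mg:
                doses = np.round(doses / spec.dose_round_mg) * spec.dose_round_mg
            records.append(
                ClampRecord(
                    mouse_id=mouse_id,
                    group=group.label,
                    body_weight=bw,
                    glucose_times=GLUCOSE_GRID.copy(),
                    glucose_values=g_obs,
                    insulin_times=INSULIN_GRID.copy(),
                    insulin_values=i_obs,
                    dose_times=traj.dose_times.copy(),
                    doses=doses,
                    metadata={"target": traj.metadata["target"]},
                )
            )
            row = {"mouse_id": mouse_id, "group": group.label, "body_weight": bw}
            row.update(params.to_dict())
            rows.append(row)
    import hashlib
    import json

    from . import __version__

    spec_digest = hashlib.sha256(
        json.dumps(
            {"groups": [vars(g) for g in spec.groups],
             "glucose_cv": spec.glucose_cv, "insulin_cv": spec.insulin_cv,
             "dose_round_mg": spec.dose_round_mg,
             "baseline": spec.baseline.to_dict()},
            sort_keys=True, default=str,
        ).encode()
    ).hexdigest()[:16]
    manifest = {
        "seed": spec.seed,
        "spec_digest": spec_digest,
        "package_version": __version__,
        "glucose_cv": spec.glucose_cv,
        "insulin_cv": spec.insulin_cv,
        "groups": [{"label": g.label, "n": g.n} for g in spec.groups],
        "clamp_retries": retries_log,
    }
    return CohortDataset(records=records, true_params=pd.DataFrame(rows),
                         manifest=manifest)


# ---------------------------------------------------------------------------
# study-condition fixtures

def _group(label, n, bw, fg, fi, rate, k2m, k3m, k5m, k7m, **kw) -> GroupSpec:
    return GroupSpec(
        label=label, n=n,
        body_weight_mean=bw, body_weight_sd=0.06 * bw,
        fasting_G_mean=fg, fasting_G_sd=0.06 * fg,
        fasting_I_mean=fi, fasting_I_sd=0.12 * fi,
        initial_rate=rate,
        k_multipliers={"k2": k2m, "k3": k3m, "k5": k5m, "k7": k7m},
        **kw,
    )


def study_cohort_spec(seed: int = 0) -> CohortSpec:
    """Six groups emulating the study design: one chow-fed control cohort and
    five high-fat-diet cohorts of increasing age, with monotone trends in
    insulin-dependent uptake (down), insulin secretion (up), glucose
    effectiveness (down) and store capacity (up)."""
    groups = (
        _group("CD14wk", 13, 27.0, 120.0, 0.5, 0.15, 1.00, 1.0, 1.00, 1.00),
        _group("HFD10wk", 13, 35.0, 180.0, 1.2, 0.10, 0.95, 1.3, 0.95, 1.05),
        _group("HFD14wk", 16, 42.0, 220.0, 2.0, 0.10, 0.85, 1.6, 0.85, 1.15),
        _group("HFD18wk", 13, 48.0, 230.0, 2.8, 0.10, 0.70, 2.0, 0.70, 1.35),
        _group("HFD28wk", 10, 52.0, 200.0, 3.8, 0.13, 0.40, 2.6, 0.50, 1.70),
        _group("HFD36wk", 10, 55.0, 180.0, 4.5, 0.13, 0.25, 3.0, 0.40, 2.00),
    )
    return CohortSpec(groups=groups, seed=seed)


def scaled_down_cohort_spec(seed: int = 0, n_per_group: int = 8) -> CohortSpec:
    """Three-group reduction (control, mid, oldest) for fast end-to-end runs."""
    full = study_cohort_spec(seed)
    keep = {"CD14wk": 0, "HFD18wk": 3, "HFD36wk": 5}
    groups = tuple(
        replace(full.groups[i], n=n_per_group) for i in keep.values()
    )
    return CohortSpec(groups=groups, seed=seed)


def dose_shape_metrics(records: list[ClampRecord]) -> dict:
    """Shape summary of a group's mean dose-per-interval series.

    Returns the per-interval means (mg), the local dip inside (20, 70) min,
    the final-hour interval mean, and the late/plateau infusion-rate ratio
    (mg/min over [120, 180] divided by mg/min over (20, 70)) used to detect
    loss of the insulin-driven late rise.
    """
    t = records[0].dose_times
    mat = np.vstack([r.doses for r in records])
    mean_doses = mat.mean(axis=0)
    widths = np.diff(np.concatenate([[0.0], t]))
    rates = mean_doses / widths
    mid = (t > 20) & (t < 70)
    late = t > 120
    dip_idx = np.argmin(mean_doses[mid])
    return {
        "dose_times": t,
        "mean_doses": mean_doses,
        "dip_time": float(t[mid][dip_idx]),
        "dip_mg": float(mean_doses[mid][dip_idx]),
        "final_hour_min_mg": float(mean_doses[late].min()),
        "final_hour_mean_mg": float(mean_doses[late].mean()),
        "late_rate_ratio": float(rates[late].mean() / rates[mid].mean()),
    }
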