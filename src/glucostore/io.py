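"""Dataset readers/writers, configuration, and report export.

The on-disk dataset layout mirrors the supplementary-spreadsheet structure
of mouse clamp studies as four tidy CSV files keyed by ``mouse_id``:

* ``glucose.csv``     — mouse_id, time_min, glucose_mgdl
* ``insulin.csv``     — mouse_id, time_min, insulin_ngml
* ``doses.csv``       — mouse_id, time_min, dose_mg   (interval right edges)
* ``body_weight.csv`` — mouse_id, group, body_weight_g

plus an optional ``manifest.json`` carrying the generating seed and spec
hash. An importer for one-sheet-per-group XLSX workbooks (mice as rows,
time points as columns) is provided for spreadsheet-shaped data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observables import ClampRecord

__all__ = [
    "write_dataset",
    "read_dataset",
    "read_group_workbooks",
    "write_param_table",
    "read_param_table",
    "write_comparison_reports",
    "RunConfig",
    "load_run_config",
    "spawn_seeds",
]

_FILES = ("glucose.csv", "insulin.csv", "doses.csv", "body_weight.csv")


def write_dataset(records: list[ClampRecord], outdir, manifest: dict | None = None):
    """Write records to the 4-file CSV layout (UTF-8, '.' decimal, header)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g_rows, i_rows, d_rows, b_rows = [], [], [], []
    for r in records:
        for t, v in zip(r.glucose_times, r.glucose_values):
            g_rows.append({"mouse_id": r.mouse_id, "time_min": t, "glucose_mgdl": v})
        for t, v in zip(r.insulin_times, r.insulin_values):
            i_rows.append({"mouse_id": r.mouse_id, "time_min": t, "insulin_ngml": v})
        for t, v in zip(r.dose_times, r.doses):
            d_rows.append({"mouse_id": r.mouse_id, "time_min": t, "dose_mg": v})
        b_rows.append(
            {"mouse_id": r.mouse_id, "group": r.group, "body_weight_g": r.body_weight}
        )
    pd.DataFrame(g_rows).to_csv(outdir / "glucose.csv", index=False)
    pd.DataFrame(i_rows).to_csv(outdir / "insulin.csv", index=False)
    pd.DataFrame(d_rows).to_csv(outdir / "doses.csv", index=False)
    pd.DataFrame(b_rows).to_csv(outdir / "body_weight.csv", index=False)
    if manifest is not None:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_dataset(path) -> list[ClampRecord]:
    """Read the 4-file CSV layout back into validated records.

    Raises ``ValueError`` listing the offending mice/rows on mismatched ids
    or invalid values.
    """
    path = Path(path)
    missing = [f for f in _FILES if not (path / f).exists()]
    if missing:
        raise ValueError(f"dataset at {path} is missing {missing}")
    glu = pd.read_csv(path / "glucose.csv")
    ins = pd.read_csv(path / "insulin.csv")
    dos = pd.read_csv(path / "doses.csv")
    bw = pd.read_csv(path / "body_weight.csv")

    ids = set(bw["mouse_id"])
    problems = []
    for name, frame in (("glucose", glu), ("insulin", ins), ("doses", dos)):
        extra = set(frame["mouse_id"]) - ids
        if extra:
            problems.append(f"{name}.csv has unknown mouse ids {sorted(extra)}")
        lacking = ids - set(frame["mouse_id"])
        if lacking:
            problems.append(f"{name}.csv lacks mice {sorted(lacking)}")
    neg = dos[dos["dose_mg"] < 0]
    if len(neg):
        problems.append(
            "negative doses in doses.csv rows "
            f"{neg.index.tolist()} (mice {neg['mouse_id'].tolist()})"
        )
    if problems:
        raise ValueError("invalid dataset: " + "; ".join(problems))

    records = []
    for _, row in bw.sort_values("mouse_id").iterrows():
        mid = row["mouse_id"]
        g = glu[glu["mouse_id"] == mid].sort_values("time_min")
        i = ins[ins["mouse_id"] == mid].sort_values("time_min")
        d = dos[dos["mouse_id"] == mid].sort_values("time_min")
        try:
            records.append(
                ClampRecord(
                    mouse_id=str(mid),
                    group=str(row["group"]),
                    body_weight=float(row["body_weight_g"]),
                    glucose_times=g["time_min"].to_numpy(),
                    glucose_values=g["glucose_mgdl"].to_numpy(),
                    insulin_times=i["time_min"].to_numpy(),
                    insulin_values=i["insulin_ngml"].to_numpy(),
                    dose_times=d["time_min"].to_numpy(),
                    doses=d["dose_mg"].to_numpy(),
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid record for mouse {mid}: {exc}") from exc
    return records


def read_group_workbooks(
    glucose_xlsx, insulin_xlsx, doses_xlsx, body_weight_xlsx
) -> list[ClampRecord]:
    """Import one-sheet-per-group workbooks (supplementary-file shape).

    In the glucose/insulin/doses workbooks every sheet is one group; the
    first column is ``mouse_id`` and the remaining column headers are times
    in minutes. The body-weight workbook's sheets have columns ``mouse_id``
    and ``body_weight_g``.
    """
    def load(path):
        sheets = pd.read_excel(path, sheet_name=None)
        out = {}
        groups = {}
        for gname, df in sheets.items():
            df = df.set_index(df.columns[0])
            times = np.array([float(c) for c in df.columns])
            for mid, row in df.iterrows():
                out[str(mid)] = (times, row.to_numpy(dtype=float))
                groups[str(mid)] = gname
        return out, groups

    gmap, groups = load(glucose_xlsx)
    imap, _ = load(insulin_xlsx)
    dmap, _ = load(doses_xlsx)
    bw_sheets = pd.read_excel(body_weight_xlsx, sheet_name=None)
    bwmap = {}
    for _, df in bw_sheets.items():
        for _, row in df.iterrows():
            bwmap[str(row["mouse_id"])] = float(row["body_weight_g"])

    records = []
    for mid in sorted(gmap):
        gt, gv = gmap[mid]
        it, iv = imap[mid]
        dt, dv = dmap[mid]
        records.append(
            ClampRecord(
                mouse_id=mid,
                group=groups[mid],
                body_weight=bwmap[mid],
                glucose_times=gt, glucose_values=gv,
                insulin_times=it, insulin_values=iv,
                dose_times=dt, doses=dv,
            )
        )
    return records


# ---------------------------------------------------------------------------
# fitted-parameter tables and comparison reports

PARAM_TABLE_COLUMNS = [
    "mouse_id", "group", "body_weight",
    "k1", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "G0", "I0", "rss",
]


def write_param_table(frame: pd.DataFrame, path):
    cols = [c for c in PARAM_TABLE_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)


def read_param_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_comparison_reports(reports: dict, outdir) -> dict[str, Path]:
    """Export the comparison workflow as three tidy CSVs.

    ``summaries.csv`` (per-group box statistics), ``pairwise.csv``
    (Welch+BH) and ``trend.csv`` (Williams step-down decisions).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summaries, pairwise, trend = [], [], []
    for pname, rep in reports.items():
        s = rep.summaries.copy()
        s.insert(0, "parameter", pname)
        summaries.append(s)
        if rep.pairwise is not None:
            pairwise.append(rep.pairwise)
        if rep.trend is not None:
            trend.append(rep.trend)
    paths = {}
    paths["summaries"] = outdir / "summaries.csv"
    pd.concat(summaries, ignore_index=True).to_csv(paths["summaries"], index=False)
    if pairwise:
        paths["pairwise"] = outdir / "pairwise.csv"
        pd.concat(pairwise, ignore_index=True).to_csv(paths["pairwise"], index=False)
    if trend:
        paths["trend"] = outdir / "trend.csv"
        pd.concat(trend, ignore_index=True).to_csv(paths["trend"], index=False)
    meta = next(iter(reports.values())).meta if reports else {}
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2, default=str))
    paths["meta"] = outdir / "meta.json"
    return paths


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Master configuration for a pipeline run.

    Every stochastic stage receives its own child seed spawned from the
    master seed via numpy's SeedSequence (documented splitting: children are
    spawned in the fixed order cohort, fits, stats).
    """

    seed: int = 0
    output_dir: str = "out"
    cohort_spec: str = "full_study"  # | scaled_down
    n_per_group: int = 8
    population_size: int = 32
    generations: int = 30
    normalization: str = "per_stream_mean"
    group_order: list[str] = field(default_factory=list)
    n_mc: int = 100_000
    verbosity: int = 1

    def stage_seeds(self) -> dict[str, int]:
        ss = np.random.SeedSequence(self.seed)
        cohort, fits, stats = ss.spawn(3)
        return {
            "cohort": int(cohort.generate_state(1)[0] % (2**31)),
            "fits": int(fits.generate_state(1)[0] % (2**31)),
            "stats": int(stats.generate_state(1)[0] % (2**31)),
        }


def spawn_seeds(master: int, n: int) -> list[int]:
    """n reproducible child seeds (< 2^31) from one master seed."""
    return [int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(master).spawn(n)]


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)
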