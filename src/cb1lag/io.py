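"""File I/O: long-format trace CSVs, schedule JSON, lag tables.

The trace dialect is fixed: UTF-8 CSV with a header row, times in minutes
with a decimal point, one row per (condition, time) observation.  Columns:
``condition, segment, time_min, value, baseline, fsk_efficacy`` (the last
two are per-condition metadata, constant within a condition).  Write/read
round-trips are lossless.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import CampTrace, DoseEvent, DoseSchedule

__all__ = [
    "write_traces",
    "read_traces",
    "schedule_to_dict",
    "schedule_from_dict",
    "write_schedule",
    "read_schedule",
    "write_lag_table",
]

TRACE_COLUMNS = ("condition", "segment", "time_min", "value", "baseline", "fsk_efficacy")


def write_traces(traces: Sequence[CampTrace], path) -> None:
    """Write a set of traces as long-format CSV (deterministic ordering:
    conditions lexicographically, times ascending)."""
    frames = []
    for trace in sorted(traces, key=lambda tr: tr.condition):
        frames.append(
            pd.DataFrame(
                {
                    "condition": trace.condition,
                    "segment": np.where(trace.times < 0.0, "pre_read", "read"),
                    "time_min": trace.times,
                    "value": trace.values,
                    "baseline": trace.baseline,
                    "fsk_efficacy": trace.fsk_efficacy,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces(path) -> list[CampTrace]:
    """Read a long-format trace CSV back into CampTrace objects.

    Malformed rows and non-monotone times raise ``ValueError`` with the
    offending line numbers (1-based, counting the header as line 1).
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty trace file") from exc
    missing = [c for c in ("condition", "time_min", "value") if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    bad = frame.index[frame[["time_min", "value"]].isna().any(axis=1)]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(f"{path}: malformed rows at lines {lines}")
    traces = []
    for condition, grp in frame.groupby("condition", sort=True):
        t = grp["time_min"].to_numpy(float)
        nonmono = np.where(np.diff(t) <= 0.0)[0]
        if nonmono.size:
            line = grp.index[nonmono[0] + 1] + 2
            raise ValueError(
                f"{path}: non-monotone times within condition {condition!r} at line {line}"
            )
        traces.append(
            CampTrace(
                times=t,
                values=grp["value"].to_numpy(float),
                condition=str(condition),
                baseline=float(grp["baseline"].iloc[0]) if "baseline" in grp else 0.0,
                fsk_efficacy=float(grp["fsk_efficacy"].iloc[0]) if "fsk_efficacy" in grp else 1.0,
            )
        )
    return traces


def schedule_to_dict(schedule: DoseSchedule) -> dict:
    return {
        "events": [
            {"time": e.time, "ligand": e.ligand, "conc_uM": e.concentration}
            for e in schedule.events
        ],
        "horizon": schedule.horizon,
        "pre_read": schedule.pre_read,
    }


def schedule_from_dict(data: dict) -> DoseSchedule:
    events = tuple(
        DoseEvent(time=float(e["time"]), ligand=str(e["ligand"]), concentration=float(e["conc_uM"]))
        for e in data["events"]
    )
    return DoseSchedule(
        events=events,
        horizon=float(data.get("horizon", 20.0)),
        pre_read=float(data.get("pre_read", 5.0)),
    )


def write_schedule(schedule: DoseSchedule, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(schedule_to_dict(schedule), fh, indent=1)
        fh.write("\n")


def read_schedule(path) -> DoseSchedule:
    with open(path, encoding="utf-8") as fh:
        return schedule_from_dict(json.load(fh))


def write_lag_table(results: Sequence[dict], path) -> None:
    """Write lag results (one dict per condition x method) as CSV with the
    fixed column order condition, method, tolerance, T_S, T_d, separated."""
    frame = pd.DataFrame(list(results))
    cols = ["condition", "method", "tolerance", "T_S", "T_d", "separated"]
    frame = frame[[c for c in cols if c in frame.columns]]
    frame = frame.sort_values(["condition"] + (["method"] if "method" in frame else []))
    frame.to_csv(path, index=False)
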