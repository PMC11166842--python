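"""Probe dependence: agonist-specific parameter substitution and calibration
of the modulator-agonist interaction rate kon3.

Only three orthosteric-agonist-specific parameters distinguish agonists in
the model — pKd, k_int and log10_eps — so swapping them predicts how the
same modulator behaves with a different agonist.  Where that fails (as for
the partial agonist THC), the interaction parameter kon3 (modulator binding
to the agonist-occupied receptor) is calibrated against kinetic cAMP traces;
a ten-fold reduction of kon3 encodes the modulator's lower affinity for the
partial-agonist-bound receptor.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .lag import LagResult, model_lag
from .params import ParameterSet, reference_parameters
from .simulate import CampTrace, DoseSchedule, observe_trace, simulate_timecourse

__all__ = [
    "agonist_library",
    "agonist_overrides",
    "calibrate_kon3",
    "compare_profiles",
    "DEFAULT_KON3_GRID",
]

#: Default calibration grid: 21 log-spaced kon3 values in [0.005, 5] 1/(uM*min).
DEFAULT_KON3_GRID = np.geomspace(0.005, 5.0, 21)

_AGONIST_FIELDS = ("pKd", "k_int", "log10_eps")


def agonist_library() -> dict[str, dict]:
    """The shipped agonist library (CP55940, WIN55,212-2, THC and the
    calibrated THC variant) with citation tags per entry."""
    txt = resources.files("cb1lag").joinpath("params/agonists.json").read_text("utf-8")
    return json.loads(txt)


def agonist_overrides(name: str, base: ParameterSet | None = None) -> ParameterSet:
    """Reference set with the three agonist-specific parameters replaced.

    Only pKd, k_int and log10_eps change between agonists; every modulator
    and system parameter is retained.  kon3 is replaced only when the
    library entry carries an explicitly calibrated value (the THC_calibrated
    variant's ten-fold reduction to 0.05).
    """
    lib = agonist_library()
    if name not in lib:
        raise KeyError(
            f"unknown agonist {name!r}; known agonists: {', '.join(sorted(lib))}"
        )
    if base is None:
        base = reference_parameters()
    entry = lib[name]
    overrides = {f: float(entry[f]) for f in _AGONIST_FIELDS}
    if "kon3" in entry:
        overrides["kon3"] = float(entry["kon3"])
    return base.with_overrides(tag="user", **overrides)


def _aligned_sse(sim: np.ndarray, obs: np.ndarray) -> float:
    """Residual SS of obs against an affine (baseline + efficacy) alignment
    of the simulated curve."""
    X = np.column_stack([np.ones_like(sim), sim])
    coef, *_ = np.linalg.lstsq(X, obs, rcond=None)
    resid = obs - X @ coef
    return float(resid @ resid)


def calibrate_kon3(
    targets: Sequence[tuple[DoseSchedule, CampTrace]],
    candidate_grid: Sequence[float] = DEFAULT_KON3_GRID,
    p_base: ParameterSet | None = None,
    grid_step: float = 0.25,
    model: str = "reduced",
) -> tuple[float, pd.DataFrame]:
    """Grid-search kon3 against target kinetic traces.

    For each candidate, every target condition is simulated, sampled on the
    target's time grid, affinely aligned (per-trace baseline and forskolin
    efficacy) and scored by summed squared discrepancy.  Returns the
    minimising kon3 (ties go to the smaller value) and the full loss
    profile as a DataFrame with columns ``kon3`` and ``loss``.
    """
    grid = np.sort(np.asarray(list(candidate_grid), dtype=float))
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    if not targets:
        raise ValueError("no target traces supplied")
    if p_base is None:
        p_base = reference_parameters()
    losses = np.empty_like(grid)
    for j, kon3 in enumerate(grid):
        p = p_base.with_overrides(kon3=float(kon3))
        sse = 0.0
        for schedule, trace in targets:
            traj = simulate_timecourse(p, schedule, grid_step=grid_step, model=model)
            sim = np.interp(trace.times, traj.times, traj.C)
            sse += _aligned_sse(sim, trace.values)
        losses[j] = sse
    profile = pd.DataFrame({"kon3": grid, "loss": losses})
    best = float(grid[int(np.argmin(losses))])  # argmin -> first (smallest) on ties
    return best, profile


def compare_profiles(
    agonists: Sequence[str],
    schedule: DoseSchedule,
    p_base: ParameterSet | None = None,
    tolerance: float = 0.01,
    grid_step: float = 0.1,
    tail_fraction: float = 0.2,
    model: str = "reduced",
) -> pd.DataFrame:
    """Simulate each agonist under an identical modulator/forskolin schedule.

    Reports the model-method lag T_d (against the matching agonist-alone
    curve) and an inverse-agonism flag: whether the mean of the last
    ``tail_fraction`` of the modulator trace exceeds the forskolin-alone
    trace.  Per-agonist simulation errors are captured in the ``error``
    column without aborting the batch.
    """
    if p_base is None:
        p_base = reference_parameters()
    t_B = schedule.t_B
    rows = []
    for name in agonists:
        row: dict = {"agonist": name, "T_d": np.nan, "separated": False,
                     "inverse_agonism": False, "error": ""}
        try:
            p = agonist_overrides(name, base=p_base)
            with_B = observe_trace(simulate_timecourse(p, schedule, grid_step, model))
            without_B = observe_trace(
                simulate_timecourse(p, schedule.without(["B"]), grid_step, model)
            )
            fsk_only = observe_trace(
                simulate_timecourse(p, schedule.without(["A", "B"]), grid_step, model)
            )
            if t_B is None:
                res = LagResult(np.nan, np.nan, tolerance, "model", False)
            else:
                res = model_lag(with_B, without_B, tolerance=tolerance, t_B=t_B)
            row["T_d"] = res.T_d
            row["separated"] = res.separated
            n_tail = max(1, int(round(tail_fraction * with_B.times.size)))
            tail_diff = with_B.values[-n_tail:] - fsk_only.values[-n_tail:]
            row["inverse_agonism"] = bool(tail_diff.mean() > 0.0)
        except (KeyError, ValueError, RuntimeError, FloatingPointError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
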