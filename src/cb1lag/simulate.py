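"""Time-course integration with timed drug additions (dosing schedules).

A :class:`DoseSchedule` lists timed additions of agonist A, modulator B and
forskolin.  Time zero is the first post-baseline drug addition; the pre-read
baseline window occupies negative times (drug-free, dark incubation before
addition).  Between events the ambient ligand concentrations are constant
(free-ligand depletion is ignored: receptor amounts are far below ligand
amounts in the assay) and integration restarts at every event time, so dose
discontinuities are handled exactly.

The default integrator is stiff-capable (LSODA) with rtol 1e-8 / atol 1e-10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model as _m
from .params import ParameterSet

__all__ = [
    "DoseEvent",
    "DoseSchedule",
    "Trajectory",
    "CampTrace",
    "co_addition_schedule",
    "preincubation_schedule",
    "simulate_timecourse",
    "species_fractions",
    "observe_trace",
]

LIGANDS = ("A", "B", "forskolin")

#: Assay forskolin concentration (uM).  Forskolin acts as a binary drive at
#: this single level; no forskolin dose-response is modelled.
FORSKOLIN_UM = 5.0


@dataclass(frozen=True)
class DoseEvent:
    """A timed addition: ``ligand`` in {"A", "B", "forskolin"}, minutes, uM."""

    time: float
    ligand: str
    concentration: float

    def __post_init__(self) -> None:
        if self.ligand not in LIGANDS:
            raise ValueError(f"ligand must be one of {LIGANDS}, got {self.ligand!r}")
        if not (np.isfinite(self.time) and self.time >= 0.0):
            raise ValueError(f"event time must be >= 0 min, got {self.time}")
        if not (np.isfinite(self.concentration) and self.concentration >= 0.0):
            raise ValueError(f"concentration must be >= 0 uM, got {self.concentration}")


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered dose events plus the simulated horizon and pre-read window."""

    events: tuple[DoseEvent, ...]
    horizon: float = 20.0
    pre_read: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        times = [e.time for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be sorted by time")
        if self.events and self.horizon < times[-1]:
            raise ValueError("horizon must be >= the last event time")
        if self.pre_read < 0.0:
            raise ValueError("pre_read must be >= 0")

    @property
    def t_B(self) -> float | None:
        """Time of the first modulator (B) addition, or None."""
        for e in self.events:
            if e.ligand == "B" and e.concentration > 0.0:
                return e.time
        return None

    def without(self, ligands: Iterable[str]) -> "DoseSchedule":
        """Copy of the schedule with the given ligands' events removed."""
        drop = set(ligands)
        return replace(self, events=tuple(e for e in self.events if e.ligand not in drop))

    def label(self) -> str:
        parts = [f"{e.ligand}{e.concentration:g}@{e.time:g}" for e in self.events]
        return "+".join(parts) if parts else "vehicle"


def co_addition_schedule(
    A_uM: float,
    B_uM: float,
    forskolin: bool = True,
    horizon: float = 20.0,
    pre_read: float = 5.0,
) -> DoseSchedule:
    """All drugs (plus forskolin) added together at t = 0."""
    events = []
    if forskolin:
        events.append(DoseEvent(0.0, "forskolin", FORSKOLIN_UM))
    if A_uM > 0.0:
        events.append(DoseEvent(0.0, "A", A_uM))
    if B_uM > 0.0:
        events.append(DoseEvent(0.0, "B", B_uM))
    return DoseSchedule(tuple(events), horizon=horizon, pre_read=pre_read)


def preincubation_schedule(
    A_uM: float,
    B_uM: float,
    delay: float = 15.0,
    forskolin: bool = True,
    horizon: float = 35.0,
    pre_read: float = 5.0,
) -> DoseSchedule:
    """Agonist (+forskolin) at t = 0; modulator added ``delay`` minutes later.

    Mirrors the design in which the agonist is incubated first to drive
    receptor internalisation (lowering AR) before the modulator arrives.
    """
    events = []
    if forskolin:
        events.append(DoseEvent(0.0, "forskolin", FORSKOLIN_UM))
    if A_uM > 0.0:
        events.append(DoseEvent(0.0, "A", A_uM))
    if B_uM > 0.0:
        events.append(DoseEvent(delay, "B", B_uM))
    return DoseSchedule(tuple(events), horizon=horizon, pre_read=pre_read)


@dataclass(frozen=True)
class Trajectory:
    """Simulated receptor species (fractions of R0) and cAMP on a time grid."""

    times: np.ndarray
    species: dict[str, np.ndarray]
    schedule: DoseSchedule
    params: ParameterSet
    model: str = "reduced"

    @property
    def C(self) -> np.ndarray:
        return self.species["C"]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: segment, time_min, variable, value."""
        seg = np.where(self.times < 0.0, "pre_read", "read")
        rows = []
        for name in _m.FULL_SPECIES:
            rows.append(
                pd.DataFrame(
                    {
                        "segment": seg,
                        "time_min": self.times,
                        "variable": name,
                        "value": self.species[name],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class CampTrace:
    """Observed-scale kinetic response: values = baseline + fsk_efficacy * C."""

    times: np.ndarray
    values: np.ndarray
    condition: str = ""
    baseline: float = 0.0
    fsk_efficacy: float = 1.0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.shape != values.shape:
            raise ValueError("times and values must have the same length")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        if times.size and np.any(np.diff(times) <= 0.0):
            raise ValueError("trace times must be strictly increasing")


def _grid(schedule: DoseSchedule, grid_step: float) -> tuple[np.ndarray, np.ndarray]:
    t0 = -schedule.pre_read
    base = np.arange(t0, schedule.horizon + grid_step * 1e-9, grid_step)
    boundaries = np.unique(
        np.concatenate(
            [[t0], [e.time for e in schedule.events], [schedule.horizon]]
        )
    )
    boundaries = boundaries[(boundaries >= t0) & (boundaries <= schedule.horizon)]
    pts = np.union1d(base, boundaries)
    keep = np.concatenate([[True], np.diff(pts) > 1e-9])
    return pts[keep], boundaries


def simulate_timecourse(
    p: ParameterSet,
    schedule: DoseSchedule,
    grid_step: float = 0.1,
    model: Literal["reduced", "full"] = "reduced",
) -> Trajectory:
    """Integrate the model over a dosing schedule.

    The trajectory starts at ``-pre_read`` with all receptor free (R = R0)
    and cAMP at its drug-free steady state (0).  Event times are grid points
    and integration restarts there, so step additions are exact.

    Raises ``RuntimeError`` naming the failing segment if the integrator
    does not converge.
    """
    if grid_step <= 0.0:
        raise ValueError("grid_step must be > 0")
    rates = _m._Rates.from_params(p)
    pts, boundaries = _grid(schedule, grid_step)
    ambient = {"A": 0.0, "B": 0.0, "forskolin": 0.0}
    if model == "reduced":
        y = _m.reduced_initial_state(p)
        rhs = _m._reduced_rhs
    elif model == "full":
        y = _m.full_initial_state(p)
        rhs = _m._full_rhs
    else:
        raise ValueError(f"model must be 'reduced' or 'full', got {model!r}")

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    b_per_segment: list[float] = []
    for ta, tb in zip(boundaries[:-1], boundaries[1:]):
        for e in schedule.events:
            if abs(e.time - ta) <= 1e-9:
                ambient[e.ligand] += e.concentration
        A, B = ambient["A"], ambient["B"]
        fsk = ambient["forskolin"] > 0.0
        t_eval = np.clip(pts[(pts >= ta - 1e-12) & (pts <= tb + 1e-12)], ta, tb)
        sol = solve_ivp(
            rhs,
            (ta, tb),
            y,
            method="LSODA",
            rtol=1e-8,
            atol=1e-10,
            t_eval=t_eval,
            args=(rates, A, B, fsk),
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on segment [{ta:g}, {tb:g}] min: {sol.message}"
            )
        y = sol.y[:, -1]
        start = 1 if all_t else 0  # drop duplicated boundary point
        all_t.append(sol.t[start:])
        all_y.append(sol.y[:, start:])
        b_per_segment.append(B)

    times = np.concatenate(all_t)
    # Expand to the full species layout, honouring the per-segment ambient B
    # for the algebraic members of the reduced model.
    if model == "full":
        ymat = np.concatenate(all_y, axis=1)
        species = {name: ymat[i] for i, name in enumerate(_m.FULL_SPECIES)}
    else:
        blocks = []
        for yblock, B in zip(all_y, b_per_segment):
            blocks.append(_m.reduced_to_full(yblock, p, B))
        ymat = np.concatenate(blocks, axis=1)
        species = {name: ymat[i] for i, name in enumerate(_m.FULL_SPECIES)}
    return Trajectory(times=times, species=species, schedule=schedule, params=p, model=model)


def species_fractions(traj: Trajectory) -> pd.DataFrame:
    """Per-species fraction-of-R0 time series, plus total surface receptor."""
    R0 = traj.params.system.R0
    out = pd.DataFrame({"time_min": traj.times})
    surface = np.zeros_like(traj.times)
    for name in ("R", "AR", "ARB_T", "ARB", "RB", "R_lost"):
        out[name] = traj.species[name] / R0
        if name != "R_lost":
            surface = surface + traj.species[name] / R0
    out["surface_total"] = surface
    return out


def observe_trace(
    traj: Trajectory,
    baseline: float = 0.0,
    fsk_efficacy: float = 1.0,
    condition: str | None = None,
) -> CampTrace:
    """Map a trajectory to the observed (inverse-BRET-like) response scale.

    ``values = baseline + fsk_efficacy * C(t)``; the additive baseline and
    multiplicative forskolin efficacy absorb experiment-to-experiment
    differences in raw BRET magnitude.
    """
    if fsk_efficacy <= 0.0:
        raise ValueError("fsk_efficacy must be > 0")
    if condition is None:
        condition = traj.schedule.label()
    return CampTrace(
        times=traj.times.copy(),
        values=baseline + fsk_efficacy * traj.C,
        condition=condition,
        baseline=baseline,
        fsk_efficacy=fsk_efficacy,
    )
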