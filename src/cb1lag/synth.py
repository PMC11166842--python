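"""Synthetic CAMYEL-BRET plate data generator.

Emulates the statistical structure of kinetic cAMP plate assays: a 5 uM
forskolin drive, co-added or staggered drug additions, reads every ~30 s
over 20-35 min, n = 3 independent replicates with technical duplicates,
experiment-specific additive baseline and multiplicative forskolin efficacy,
and additive i.i.d. Gaussian residual noise.  Duplicates share their
replicate's baseline/efficacy draw but have independent residual noise.

Datasets are regenerable bit-exactly from (design, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet, reference_parameters
from .probe import agonist_overrides
from .simulate import (
    DoseSchedule,
    co_addition_schedule,
    preincubation_schedule,
    simulate_timecourse,
)

__all__ = ["Condition", "ExperimentDesign", "PlateDataset", "generate_dataset", "preset_design"]


@dataclass(frozen=True)
class Condition:
    """One assay condition: agonist/modulator concentrations and schedule."""

    label: str
    agonist: str
    agonist_conc: float
    org_conc: float
    forskolin: bool
    schedule: DoseSchedule


@dataclass(frozen=True)
class ExperimentDesign:
    """Plate design: conditions, replication structure and noise model.

    ``baseline_sd`` / ``fsk_efficacy_mean`` / ``fsk_efficacy_sd`` set the
    per-replicate draws baseline ~ N(0, baseline_sd) and efficacy ~
    N(mean, sd) truncated positive; ``residual_sigma`` is the per-point
    additive Gaussian noise on the normalised response scale.  The optional
    forskolin overshoot artifact (a decaying exponential seen in raw plate
    reads, mechanistically irrelevant) is off by default.
    """

    conditions: tuple[Condition, ...]
    n_replicates: int = 3
    n_duplicates: int = 2
    read_interval: float = 0.5
    baseline_sd: float = 0.02
    fsk_efficacy_mean: float = 1.0
    fsk_efficacy_sd: float = 0.05
    residual_sigma: float = 0.01
    overshoot_amp: float = 0.0
    overshoot_tau: float = 2.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conditions", tuple(self.conditions))
        if not self.conditions:
            raise ValueError("design needs at least one condition")
        if self.n_replicates < 1 or self.n_duplicates < 1:
            raise ValueError("replicate and duplicate counts must be >= 1")
        if self.read_interval <= 0.0:
            raise ValueError("read_interval must be > 0")
        if self.residual_sigma < 0.0 or self.baseline_sd < 0.0 or self.fsk_efficacy_sd < 0.0:
            raise ValueError("noise scales must be >= 0")


@dataclass(frozen=True)
class PlateDataset:
    """Long-format synthetic plate table plus everything needed to re-make it."""

    frame: pd.DataFrame
    design: ExperimentDesign
    params: ParameterSet
    seed: int

    COLUMNS = ("experiment_id", "condition", "replicate", "duplicate", "time_min", "value")


def _truncated_positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0.0:
            return float(x)
    raise RuntimeError("could not draw a positive forskolin efficacy")


def generate_dataset(
    design: ExperimentDesign,
    p: ParameterSet | None = None,
    seed: int = 0,
    model: str = "reduced",
) -> PlateDataset:
    """Simulate every condition and dress it with plate-level noise.

    Per replicate a baseline and forskolin efficacy are drawn once and
    shared by its technical duplicates; every observed point then receives
    independent Gaussian residual noise.  Simulation failure raises
    ``RuntimeError`` naming the condition.
    """
    if p is None:
        p = reference_parameters()
    rng = np.random.default_rng(seed)
    # Per-replicate plate factors, drawn once up front in a fixed order so
    # the dataset is bit-reproducible regardless of condition count.
    plate_factors = [
        (
            rng.normal(0.0, design.baseline_sd),
            _truncated_positive_normal(rng, design.fsk_efficacy_mean, design.fsk_efficacy_sd),
        )
        for _ in range(design.n_replicates)
    ]

    sims: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for cond in design.conditions:
        p_cond = agonist_overrides(cond.agonist, base=p) if cond.agonist != "CP" else p
        try:
            traj = simulate_timecourse(
                p_cond, cond.schedule, grid_step=design.read_interval, model=model
            )
        except (RuntimeError, FloatingPointError) as exc:
            raise RuntimeError(f"simulation failed for condition {cond.label!r}: {exc}") from exc
        values = traj.C.copy()
        if design.overshoot_amp > 0.0 and cond.forskolin:
            post = traj.times >= 0.0
            values[post] = values[post] + design.overshoot_amp * np.exp(
                -traj.times[post] / design.overshoot_tau
            )
        sims[cond.label] = (traj.times, values)

    records = []
    for cond in design.conditions:
        times, clean = sims[cond.label]
        for rep in range(1, design.n_replicates + 1):
            baseline, efficacy = plate_factors[rep - 1]
            for dup in range(1, design.n_duplicates + 1):
                noise = rng.normal(0.0, design.residual_sigma, size=clean.shape)
                values = baseline + efficacy * clean + noise
                records.append(
                    pd.DataFrame(
                        {
                            "experiment_id": f"rep{rep}",
                            "condition": cond.label,
                            "replicate": rep,
                            "duplicate": dup,
                            "time_min": times,
                            "value": values,
                        }
                    )
                )
    frame = pd.concat(records, ignore_index=True)
    return PlateDataset(frame=frame, design=design, params=p, seed=seed)


def _cond_label(agonist: str, a: float, b: float, schedule_id: str) -> str:
    return f"{agonist}{a:g}uM+ORG{b:g}uM+FSK|{schedule_id}"


def preset_design(name: str) -> ExperimentDesign:
    """Named plate designs mirroring the study's three experiment families.

    ``validation``
        CP55940 {0, 0.001, 0.01, 0.1, 1, 10} uM x ORG {0, 0.1, 1, 10} uM,
        co-added with forskolin (24 conditions, 20 min).
    ``preincubation``
        1 uM CP55940 with ORG {0.1, 0.316, 1} uM, co-addition versus
        agonist 15 min prior to modulator, plus modulator-free references.
    ``probe``
        {CP, WIN, THC} x ORG {0, 0.1, 1} uM co-added (30 min).
    """
    if name == "validation":
        cps = (0.0, 0.001, 0.01, 0.1, 1.0, 10.0)
        orgs = (0.0, 0.1, 1.0, 10.0)
        conditions = tuple(
            Condition(
                label=_cond_label("CP", a, b, "co"),
                agonist="CP",
                agonist_conc=a,
                org_conc=b,
                forskolin=True,
                schedule=co_addition_schedule(a, b, horizon=20.0),
            )
            for a in cps
            for b in orgs
        )
        return ExperimentDesign(conditions=conditions)
    if name == "preincubation":
        conditions = []
        for b in (0.0, 0.1, 0.316, 1.0):
            conditions.append(
                Condition(
                    label=_cond_label("CP", 1.0, b, "co"),
                    agonist="CP",
                    agonist_conc=1.0,
                    org_conc=b,
                    forskolin=True,
                    schedule=co_addition_schedule(1.0, b, horizon=35.0),
                )
            )
            conditions.append(
                Condition(
                    label=_cond_label("CP", 1.0, b, "pre15"),
                    agonist="CP",
                    agonist_conc=1.0,
                    org_conc=b,
                    forskolin=True,
                    schedule=preincubation_schedule(1.0, b, delay=15.0, horizon=35.0),
                )
            )
        return ExperimentDesign(conditions=tuple(conditions))
    if name == "probe":
        conditions = tuple(
            Condition(
                label=_cond_label(ag, 1.0, b, "co"),
                agonist=ag,
                agonist_conc=1.0,
                org_conc=b,
                forskolin=True,
                schedule=co_addition_schedule(1.0, b, horizon=30.0),
            )
            for ag in ("CP", "WIN", "THC")
            for b in (0.0, 0.1, 1.0)
        )
        return ExperimentDesign(conditions=conditions)
    raise ValueError(f"unknown preset {name!r}; choose validation, preincubation or probe")
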