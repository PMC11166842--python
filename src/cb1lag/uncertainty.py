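"""Parameter-uncertainty propagation: multivariate-normal sampling of the
variance-covariance matrix of parameter estimates, simulation-based
prediction bands, and observation-coverage reporting.

The original estimation covariance is consumed, not produced, here: a
CovarianceSpec can be loaded from a labelled CSV matrix plus a JSON sidecar
giving each parameter's estimation scale ("log" keeps rates positive and is
the default).  A small synthetic demonstration matrix ships with the package
(``params/synthetic_demo_cov.csv``) since no real covariance is published
with the model parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet
from .simulate import CampTrace, DoseSchedule, observe_trace, simulate_timecourse

__all__ = [
    "CovarianceSpec",
    "PredictionBand",
    "sample_parameters",
    "prediction_band",
    "coverage_report",
    "demo_covariance",
]


@dataclass(frozen=True)
class CovarianceSpec:
    """Mean vector and covariance of parameter estimates on estimation scale.

    ``scale_map[label]`` is "log" (natural-log estimation scale; draws are
    exponentiated back) or "linear".  Labels must resolve to ParameterSet
    fields (flat names such as ``k_int`` or dotted ``allosteric.kon3``).
    """

    labels: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    scale_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        if len(set(labels)) != len(labels):
            raise ValueError("parameter labels must be unique")
        k = len(labels)
        if mean.shape != (k,) or cov.shape != (k, k):
            raise ValueError("mean/cov dimensions must match the labels")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10 * max(eigvals.max(), 1.0):
            raise ValueError(
                f"covariance matrix is not positive semi-definite (min eigenvalue {eigvals.min():g})"
            )
        for label in labels:
            scale = self.scale_map.get(label, "log")
            if scale not in ("log", "linear"):
                raise ValueError(f"scale for {label!r} must be 'log' or 'linear'")

    def scale(self, label: str) -> str:
        return self.scale_map.get(label, "log")

    @classmethod
    def from_params(
        cls,
        p: ParameterSet,
        labels: Sequence[str],
        cov: np.ndarray,
        scale_map: dict[str, str] | None = None,
    ) -> "CovarianceSpec":
        """Build a spec whose mean is taken from an existing parameter set."""
        scale_map = dict(scale_map or {})
        mean = []
        for label in labels:
            value = p.get(label)
            if scale_map.get(label, "log") == "log":
                if value is None or value <= 0.0:
                    raise ValueError(f"cannot log-scale non-positive parameter {label!r}")
                mean.append(np.log(value))
            else:
                mean.append(float(value))
        return cls(labels=tuple(labels), mean=np.array(mean), cov=np.asarray(cov, float),
                   scale_map=scale_map)

    @classmethod
    def from_csv(cls, cov_path, scales_path, p: ParameterSet | None = None) -> "CovarianceSpec":
        """Load a labelled square covariance CSV plus its JSON sidecar.

        The sidecar holds ``{"scale_map": {label: "log"|"linear"},
        "mean": {label: value}}``; a missing mean block pulls the mean from
        ``p`` (transformed per scale).
        """
        mat = pd.read_csv(cov_path, index_col=0)
        if list(mat.index) != list(mat.columns):
            raise ValueError("covariance CSV must be square with matching row/column labels")
        with open(scales_path, encoding="utf-8") as fh:
            sidecar = json.load(fh)
        scale_map = dict(sidecar.get("scale_map", {}))
        labels = tuple(mat.columns)
        if "mean" in sidecar:
            mean = np.array([float(sidecar["mean"][label]) for label in labels])
            return cls(labels=labels, mean=mean, cov=mat.to_numpy(float), scale_map=scale_map)
        if p is None:
            raise ValueError("no mean in sidecar; supply a base ParameterSet")
        return cls.from_params(p, labels, mat.to_numpy(float), scale_map)


def demo_covariance(p: ParameterSet) -> CovarianceSpec:
    """The shipped synthetic demonstration covariance (diagonal, log-scale
    coefficients of variation of 10-30% on selected rates), centred on ``p``.

    This matrix is a stand-in for an estimation covariance that is not
    published; it demonstrates the propagation procedure, nothing more.
    """
    base = resources.files("cb1lag").joinpath("params")
    import io as _io

    cov_txt = base.joinpath("synthetic_demo_cov.csv").read_text(encoding="utf-8")
    mat = pd.read_csv(_io.StringIO(cov_txt), index_col=0)
    scales = json.loads(base.joinpath("synthetic_demo_cov_scales.json").read_text("utf-8"))
    return CovarianceSpec.from_params(
        p, tuple(mat.columns), mat.to_numpy(float), scales["scale_map"]
    )


@dataclass(frozen=True)
class PredictionBand:
    """Pointwise median and lower/upper quantile envelopes of simulations."""

    times: np.ndarray
    median: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_draws: int
    seed: int
    n_failed: int = 0
    flagged: bool = False

    def __post_init__(self) -> None:
        if np.any(self.lower > self.median + 1e-12) or np.any(self.median > self.upper + 1e-12):
            raise ValueError("band quantiles must be ordered lower <= median <= upper")


def sample_parameters(
    spec: CovarianceSpec,
    n: int,
    seed: int,
    base: ParameterSet,
    max_rejections: int = 10_000,
) -> tuple[list[ParameterSet], int]:
    """Draw ``n`` parameter sets from the multivariate normal of estimates.

    Draws are taken on the estimation scale and back-transformed per the
    scale map.  Draws that violate parameter-domain invariants (e.g. a
    negative rate on a linear scale) are rejected and redrawn; the second
    return value is the rejection count.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[ParameterSet] = []
    rejected = 0
    while len(out) < n:
        z = rng.multivariate_normal(spec.mean, spec.cov, method="svd")
        overrides = {}
        for label, value in zip(spec.labels, z):
            overrides[label] = float(np.exp(value)) if spec.scale(label) == "log" else float(value)
        try:
            out.append(base.with_overrides(**overrides))
        except (ValueError, KeyError):
            rejected += 1
            if rejected > max_rejections:
                raise RuntimeError(
                    f"rejected {rejected} invalid draws; check the covariance scale map"
                )
    return out, rejected


def prediction_band(
    p_draws: Sequence[ParameterSet],
    schedule: DoseSchedule,
    level: float = 0.95,
    residual_sigma: float = 0.0,
    seed: int = 0,
    grid_step: float = 0.25,
    baseline: float = 0.0,
    fsk_efficacy: float = 1.0,
    model: str = "reduced",
) -> PredictionBand:
    """Simulate every parameter draw and return pointwise quantile bands.

    Independent Gaussian residual error (sd ``residual_sigma``, observed
    scale) is added per draw and observation time before taking quantiles
    (2.5/50/97.5% at level 0.95).  Failed simulations are excluded and
    counted; the band is flagged when more than 5% fail.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if not p_draws:
        raise ValueError("need at least one parameter draw")
    rng = np.random.default_rng(seed)
    sims = []
    n_failed = 0
    times = None
    for p in p_draws:
        try:
            traj = simulate_timecourse(p, schedule, grid_step=grid_step, model=model)
        except (RuntimeError, FloatingPointError):
            n_failed += 1
            continue
        values = observe_trace(traj, baseline, fsk_efficacy).values
        if residual_sigma > 0.0:
            values = values + rng.normal(0.0, residual_sigma, size=values.shape)
        times = traj.times
        sims.append(values)
    if not sims:
        raise RuntimeError("all simulations failed; no band can be formed")
    mat = np.vstack(sims)
    alpha = (1.0 - level) / 2.0
    lower, median, upper = np.quantile(mat, [alpha, 0.5, 1.0 - alpha], axis=0)
    return PredictionBand(
        times=times,
        median=median,
        lower=lower,
        upper=upper,
        level=level,
        n_draws=len(sims),
        seed=seed,
        n_failed=n_failed,
        flagged=n_failed > 0.05 * len(p_draws),
    )


def coverage_report(
    observations: Sequence[CampTrace],
    band: PredictionBand,
    threshold: float = 0.90,
) -> pd.DataFrame:
    """Fraction of observed points falling inside the band, per condition.

    Band envelopes are interpolated linearly at the observation times, which
    must lie within the band support.  The returned frame has one row per
    condition plus an ``overall`` row carrying a pass flag against
    ``threshold`` (default 0.90 for a nominal 0.95 band).
    """
    if not observations:
        raise ValueError("no observations supplied")
    t0, t1 = band.times[0], band.times[-1]
    rows = []
    total_in = 0
    total_n = 0
    for trace in observations:
        t = trace.times
        if t.min() < t0 - 1e-9 or t.max() > t1 + 1e-9:
            raise ValueError(
                f"observation times for {trace.condition!r} fall outside the band support"
            )
        lo = np.interp(t, band.times, band.lower)
        hi = np.interp(t, band.times, band.upper)
        inside = (trace.values >= lo) & (trace.values <= hi)
        rows.append(
            {
                "condition": trace.condition,
                "n_points": int(t.size),
                "fraction_inside": float(inside.mean()),
            }
        )
        total_in += int(inside.sum())
        total_n += int(t.size)
    overall = total_in / total_n
    rows.append(
        {"condition": "overall", "n_points": total_n, "fraction_inside": overall}
    )
    out = pd.DataFrame(rows)
    out["passes"] = out["fraction_inside"] >= threshold
    return out
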