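"""Parameterisation of the CB1/ORG27569 allosteric kinetic model.

The model describes an orthosteric agonist A (CP55940 by default), an
allosteric modulator B (ORG27569) and the CB1 receptor R.  Receptor amounts
are expressed as fractions of the initial surface receptor R0 = 1, ligand
concentrations in micromolar, time in minutes, and the cAMP readout is
normalised so that the receptor-free forskolin steady state equals 1
(k_in = k_out).

Parameters carry provenance tags: "printed" values come straight from the
published parameter table for CP55940/ORG27569, "derived" values follow from
printed quantities by closed-form arithmetic or root-finding, and
"calibrated" values are fixed by the shipped calibration script against the
published lag-time and species-crossing anchors (see docs/methods.md).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping

__all__ = [
    "LigandParams",
    "AllostericParams",
    "SystemParams",
    "ParameterSet",
    "reference_parameters",
    "UNITS",
    "PROVENANCE_TAGS",
]

PROVENANCE_TAGS = ("printed", "derived", "calibrated", "user")

#: Unit string for every scalar model parameter.
UNITS: dict[str, str] = {
    "pKd": "-log10(M)",
    "k_int": "1/min",
    "log10_eps": "log10(dimensionless)",
    "kon_A": "1/(uM*min)",
    "kon3": "1/(uM*min)",
    "koff3": "1/min",
    "kon2": "1/(uM*min)",
    "Kd_B": "uM",
    "k_TI": "1/min",
    "K_TI_eq": "dimensionless",
    "k_int_T": "1/min",
    "R0": "fraction of R0",
    "k_syn_R": "R0/min",
    "eps_R": "dimensionless",
    "I50": "R0-equivalents",
    "Imax": "dimensionless",
    "k_in": "response/min",
    "k_out": "1/min",
}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _finite(name: str, value: float) -> None:
    _require(math.isfinite(value), f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class LigandParams:
    """Orthosteric-agonist-specific parameters.

    pKd
        -log10 of the equilibrium dissociation constant (molar).
    k_int
        Internalisation rate of agonist-bound receptor AR (1/min).
    log10_eps
        log10 of the intrinsic efficacy eps_c of AR in the inhibition signal
        I = eps_R*R + eps_c*AR.
    kon_A
        Association rate of agonist to free receptor (1/(uM*min)).  The
        dissociation rate follows as koff_A = kon_A * Kd_uM.
    """

    pKd: float
    k_int: float
    log10_eps: float
    kon_A: float

    def __post_init__(self) -> None:
        for name in ("pKd", "k_int", "log10_eps", "kon_A"):
            _finite(name, getattr(self, name))
        _require(4.0 < self.pKd < 12.0, f"pKd must lie in (4, 12), got {self.pKd}")
        _require(self.k_int >= 0.0, f"k_int must be >= 0, got {self.k_int}")
        _require(self.kon_A > 0.0, f"kon_A must be > 0, got {self.kon_A}")

    @property
    def Kd_uM(self) -> float:
        """Equilibrium dissociation constant in micromolar, 10**(6 - pKd)."""
        return 10.0 ** (6.0 - self.pKd)

    @property
    def eps(self) -> float:
        """Intrinsic efficacy eps_c = 10**log10_eps (dimensionless)."""
        return 10.0 ** self.log10_eps

    @property
    def koff_A(self) -> float:
        """Agonist dissociation rate (1/min), kon_A * Kd_uM."""
        return self.kon_A * self.Kd_uM


@dataclass(frozen=True)
class AllostericParams:
    """Modulator and agonist-modulator interaction parameters.

    kon3/koff3 govern B binding to the agonist-occupied receptor AR, forming
    the transitional ternary species ARB_T; k_TI and K_TI_eq govern the
    ARB_T <-> ARB transition (K_TI_eq is the equilibrium ratio ARB/ARB_T used
    by the reduced model); kon2/Kd_B govern B binding to free receptor R.
    k_int_T is the internalisation rate of ARB_T; None means "inherit the
    agonist k_int".
    """

    kon3: float = 0.528
    koff3: float = 0.0
    kon2: float = 1.0
    Kd_B: float = 1.0
    k_TI: float = 1.0
    K_TI_eq: float = 1.0
    k_int_T: float | None = None

    def __post_init__(self) -> None:
        for name in ("kon3", "koff3", "kon2", "Kd_B", "k_TI", "K_TI_eq"):
            value = getattr(self, name)
            _finite(name, value)
            _require(value >= 0.0, f"{name} must be >= 0, got {value}")
        _require(self.Kd_B > 0.0, f"Kd_B must be > 0, got {self.Kd_B}")
        if self.k_int_T is not None:
            _finite("k_int_T", self.k_int_T)
            _require(self.k_int_T >= 0.0, f"k_int_T must be >= 0, got {self.k_int_T}")
        if self.k_TI > 0.0:
            _require(
                self.K_TI_eq > 0.0,
                "K_TI_eq must be > 0 when k_TI > 0 (the backward rate is k_TI/K_TI_eq)",
            )

    @property
    def koff_B(self) -> float:
        """Dissociation rate of B from free receptor (1/min), kon2 * Kd_B."""
        return self.kon2 * self.Kd_B


@dataclass(frozen=True)
class SystemParams:
    """System (cell/assay) parameters shared by all ligand pairs."""

    R0: float = 1.0
    k_syn_R: float = 0.0
    eps_R: float = 1.0
    I50: float = 1.0
    Imax: float = 1.0
    k_in: float = 0.018
    k_out: float = 0.018

    def __post_init__(self) -> None:
        for name in ("R0", "k_syn_R", "eps_R", "I50", "Imax", "k_in", "k_out"):
            _finite(name, getattr(self, name))
        _require(self.R0 == 1.0, "R0 is the normalisation unit and must equal 1")
        _require(self.eps_R == 1.0, "eps_R is fixed to 1 in this model")
        _require(0.0 < self.Imax <= 1.0, f"Imax must lie in (0, 1], got {self.Imax}")
        _require(self.I50 > 0.0, f"I50 must be > 0, got {self.I50}")
        _require(self.k_out > 0.0, f"k_out must be > 0, got {self.k_out}")
        _require(self.k_in >= 0.0, f"k_in must be >= 0, got {self.k_in}")
        _require(self.k_syn_R >= 0.0, f"k_syn_R must be >= 0, got {self.k_syn_R}")


_SECTION_FIELDS: dict[str, tuple[str, ...]] = {
    "agonist": ("pKd", "k_int", "log10_eps", "kon_A"),
    "allosteric": ("kon3", "koff3", "kon2", "Kd_B", "k_TI", "K_TI_eq", "k_int_T"),
    "system": ("R0", "k_syn_R", "eps_R", "I50", "Imax", "k_in", "k_out"),
}

_FIELD_SECTION: dict[str, str] = {
    name: section for section, names in _SECTION_FIELDS.items() for name in names
}


@dataclass(frozen=True)
class ParameterSet:
    """Full parameterisation: agonist, allosteric/interaction and system blocks.

    ``provenance`` maps flat field names to one of
    ``{"printed", "derived", "calibrated", "user"}``; fields not listed are
    treated as "calibrated".  Serialisation through :meth:`to_dict` /
    :meth:`from_dict` is lossless (values, units and provenance round-trip).
    """

    agonist: LigandParams
    allosteric: AllostericParams
    system: SystemParams
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, tag in self.provenance.items():
            _require(name in _FIELD_SECTION, f"provenance names unknown field {name!r}")
            _require(tag in PROVENANCE_TAGS, f"unknown provenance tag {tag!r} for {name!r}")

    # -- field access ------------------------------------------------------

    def get(self, name: str) -> float | None:
        """Return a parameter by flat name (e.g. ``"k_int"``) or dotted name."""
        section, name = self._resolve(name)
        return getattr(getattr(self, section), name)

    @property
    def k_int_T(self) -> float:
        """Effective ARB_T internalisation rate (defaults to agonist k_int)."""
        if self.allosteric.k_int_T is not None:
            return self.allosteric.k_int_T
        return self.agonist.k_int

    @staticmethod
    def _resolve(name: str) -> tuple[str, str]:
        if "." in name:
            section, _, leaf = name.partition(".")
            if section not in _SECTION_FIELDS or leaf not in _SECTION_FIELDS[section]:
                raise KeyError(
                    f"unknown parameter {name!r}; known fields: "
                    + ", ".join(sorted(_FIELD_SECTION))
                )
            return section, leaf
        if name not in _FIELD_SECTION:
            raise KeyError(
                f"unknown parameter {name!r}; known fields: "
                + ", ".join(sorted(_FIELD_SECTION))
            )
        return _FIELD_SECTION[name], name

    def with_overrides(self, tag: str = "user", **overrides: float) -> "ParameterSet":
        """Return a copy with the named fields replaced (validation re-runs).

        Keys may be flat (``kon3``) or dotted (``allosteric.kon3``).  Unknown
        keys raise :class:`KeyError`; invalid values raise :class:`ValueError`.
        """
        updates: dict[str, dict[str, float]] = {"agonist": {}, "allosteric": {}, "system": {}}
        prov = dict(self.provenance)
        for key, value in overrides.items():
            section, leaf = self._resolve(key)
            if value is not None and not math.isfinite(value):
                raise ValueError(f"override {key}={value!r} is not finite")
            updates[section][leaf] = value
            prov[leaf] = tag
        agonist = replace(self.agonist, **updates["agonist"]) if updates["agonist"] else self.agonist
        allosteric = (
            replace(self.allosteric, **updates["allosteric"]) if updates["allosteric"] else self.allosteric
        )
        system = replace(self.system, **updates["system"]) if updates["system"] else self.system
        return ParameterSet(agonist=agonist, allosteric=allosteric, system=system, provenance=prov)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section, names in _SECTION_FIELDS.items():
            block = getattr(self, section)
            out[section] = {
                name: {
                    "value": getattr(block, name),
                    "unit": UNITS[name],
                    "provenance": self.provenance.get(name, "calibrated"),
                }
                for name in names
            }
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ParameterSet":
        kwargs: dict[str, dict[str, float]] = {}
        prov: dict[str, str] = {}
        for section, names in _SECTION_FIELDS.items():
            block = data[section]
            kwargs[section] = {}
            for name in names:
                entry = block[name]
                if isinstance(entry, Mapping):
                    kwargs[section][name] = entry["value"]
                    if "provenance" in entry:
                        prov[name] = entry["provenance"]
                else:
                    kwargs[section][name] = entry
        return cls(
            agonist=LigandParams(**kwargs["agonist"]),
            allosteric=AllostericParams(**kwargs["allosteric"]),
            system=SystemParams(**kwargs["system"]),
            provenance=prov,
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ParameterSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _load_reference() -> ParameterSet:
    ref = resources.files("cb1lag").joinpath("params/reference_cp_org.json")
    return ParameterSet.from_dict(json.loads(ref.read_text(encoding="utf-8")))


def reference_parameters(**overrides: float) -> ParameterSet:
    """Shipped CP55940/ORG27569 reference parameter set, optionally overridden.

    The printed agonist block is pKd = 8.6, k_int = 0.15 1/min,
    log10_eps = 1.66; the printed modulator association rate is
    kon3 = 0.528 1/(uM*min).  Unprinted fields carry calibrated defaults
    (tagged "calibrated") regenerable with ``scripts/calibrate_defaults.py``.

    >>> p = reference_parameters(kon3=0.05)   # ten-fold lower B-to-AR rate
    """
    base = _load_reference()
    if overrides:
        return base.with_overrides(**overrides)
    return base
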