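"""Right-hand sides and output functions of the allosteric kinetic model.

Receptor scheme (mass action, concentrations of A and B ambient in uM)::

    A + R    <->  AR        kon_A * A,  koff_A = kon_A * Kd
    B + R    <->  RB        kon2 * B,   koff2  = kon2 * Kd_B
    B + AR   <->  ARB_T     kon3 * B,   koff3
    ARB_T    <->  ARB       k_TI,       k_TI / K_TI_eq
    AR       -->  lost      k_int          (internalisation)
    ARB_T    -->  lost      k_int_T        (internalisation)
    (synthesis of R at k_syn_R, 0 by default on the assay horizon)

Only R and AR signal: the inhibition signal is I = eps_R*R + eps_c*AR and
suppresses cAMP production through an E_MAX model,
``fractional_inhibition = Imax * I / (I50 + I)``.  cAMP follows a turnover
equation ``dC/dt = k_in * (1 - fractional_inhibition) - k_out * C`` while
forskolin is present (``dC/dt = -k_out * C`` otherwise), normalised so the
receptor-free forskolin steady state is k_in/k_out = 1.

Two right-hand sides are provided: :func:`full_rhs` integrates all five
surface species, while :func:`reduced_rhs` assumes quasi-equilibrium for
ARB (ratio K_TI_eq with ARB_T) and RB (equilibrium with R via Kd_B) and
integrates the lumped pools, matching the full model in the
fast-equilibration limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "FULL_SPECIES",
    "REDUCED_SPECIES",
    "inhibition_signal",
    "fractional_inhibition",
    "derived_quantities",
    "full_rhs",
    "reduced_rhs",
    "full_initial_state",
    "reduced_initial_state",
    "reduced_to_full",
]

#: State ordering of the full model: five surface species, the cumulative
#: internalised pool, and the normalised cAMP response.
FULL_SPECIES = ("R", "AR", "ARB_T", "ARB", "RB", "R_lost", "C")

#: State ordering of the reduced model.  R_pool = R + RB and
#: T_pool = ARB_T + ARB are integrated; the members are algebraic.
REDUCED_SPECIES = ("R_pool", "AR", "T_pool", "R_lost", "C")


@dataclass(frozen=True)
class _Rates:
    """Scalar rate constants pre-extracted from a ParameterSet."""

    kon_A: float
    koff_A: float
    k_int: float
    eps: float
    kon3: float
    koff3: float
    kon2: float
    koff2: float
    Kd_B: float
    k_TI: float
    k_IT: float
    K_TI_eq: float
    k_int_T: float
    k_syn_R: float
    eps_R: float
    I50: float
    Imax: float
    k_in: float
    k_out: float

    @classmethod
    def from_params(cls, p: ParameterSet) -> "_Rates":
        a, b, s = p.agonist, p.allosteric, p.system
        k_IT = b.k_TI / b.K_TI_eq if b.k_TI > 0.0 else 0.0
        return cls(
            kon_A=a.kon_A,
            koff_A=a.koff_A,
            k_int=a.k_int,
            eps=a.eps,
            kon3=b.kon3,
            koff3=b.koff3,
            kon2=b.kon2,
            koff2=b.koff_B,
            Kd_B=b.Kd_B,
            k_TI=b.k_TI,
            k_IT=k_IT,
            K_TI_eq=b.K_TI_eq,
            k_int_T=p.k_int_T,
            k_syn_R=s.k_syn_R,
            eps_R=s.eps_R,
            I50=s.I50,
            Imax=s.Imax,
            k_in=s.k_in,
            k_out=s.k_out,
        )


def inhibition_signal(R, AR, p: ParameterSet):
    """Combined inhibition signal I = eps_R*R + eps_c*AR (R0-equivalents).

    Both the constitutively active free receptor R (efficacy eps_R = 1) and
    the agonist-bound receptor AR (efficacy eps_c, typically ~45.7 for
    CP55940) drive cAMP inhibition; the ternary species do not.
    """
    return p.system.eps_R * np.asarray(R) + p.agonist.eps * np.asarray(AR)


def fractional_inhibition(I, p: ParameterSet):
    """E_MAX fraction of cAMP production suppressed, Imax*I/(I50 + I).

    Strictly increasing in I and bounded by Imax.  Raises ``ValueError`` for
    negative inhibition signals.
    """
    I = np.asarray(I, dtype=float)
    if np.any(I < 0.0):
        raise ValueError("inhibition signal I must be >= 0")
    out = p.system.Imax * I / (p.system.I50 + I)
    return out if out.ndim else float(out)


def derived_quantities(p: ParameterSet) -> dict[str, float]:
    """Closed-form quantities implied by a parameter set.

    Returns Kd_uM = 10**(6 - pKd), eps = 10**log10_eps, the agonist and
    modulator dissociation rates, and the modulator free-receptor
    dissociation constant.
    """
    return {
        "Kd_uM": p.agonist.Kd_uM,
        "eps": p.agonist.eps,
        "koff_A": p.agonist.koff_A,
        "Kd_B_uM": p.allosteric.Kd_B,
        "koff_B": p.allosteric.koff_B,
        "k_int_T": p.k_int_T,
    }


def _camp_rate(C: float, frac: float, fsk: bool, r: _Rates) -> float:
    if fsk:
        return r.k_in * (1.0 - frac) - r.k_out * C
    return -r.k_out * C


def _check_state(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite state encountered: {y!r}")


def full_rhs(t, y, p, A: float, B: float, fsk: bool):
    """Mass-action derivatives of the full model.

    ``y`` is ordered as :data:`FULL_SPECIES`; ``A`` and ``B`` are the ambient
    agonist/modulator concentrations in uM (held constant between dose
    events; free-ligand depletion is ignored) and ``fsk`` flags the presence
    of the 5 uM forskolin drive.
    """
    return _full_rhs(t, y, _Rates.from_params(p), A, B, fsk)


def _full_rhs(t, y, r: _Rates, A: float, B: float, fsk: bool):
    _check_state(y)
    R, AR, ARB_T, ARB, RB, R_lost, C = y
    bindA = r.kon_A * A * R - r.koff_A * AR
    bindB_R = r.kon2 * B * R - r.koff2 * RB
    bindB_AR = r.kon3 * B * AR - r.koff3 * ARB_T
    trans = r.k_TI * ARB_T - r.k_IT * ARB
    dR = -bindA - bindB_R + r.k_syn_R
    dAR = bindA - bindB_AR - r.k_int * AR
    dARB_T = bindB_AR - trans - r.k_int_T * ARB_T
    dARB = trans
    dRB = bindB_R
    dR_lost = r.k_int * AR + r.k_int_T * ARB_T
    frac = r.Imax * max(r.eps_R * R + r.eps * AR, 0.0) / (
        r.I50 + max(r.eps_R * R + r.eps * AR, 0.0)
    )
    dC = _camp_rate(C, frac, fsk, r)
    return np.array([dR, dAR, dARB_T, dARB, dRB, dR_lost, dC])


def reduced_rhs(t, y, p, A: float, B: float, fsk: bool):
    """Quasi-equilibrium (reduced) model derivatives.

    ``y`` is ordered as :data:`REDUCED_SPECIES`.  Within the pools,
    R = R_pool / (1 + B/Kd_B) and ARB_T = T_pool / (1 + K_TI_eq); with B = 0
    the system collapses exactly to the two-species (R, AR) agonist-only
    model.
    """
    return _reduced_rhs(t, y, _Rates.from_params(p), A, B, fsk)


def _reduced_rhs(t, y, r: _Rates, A: float, B: float, fsk: bool):
    _check_state(y)
    R_pool, AR, T_pool, R_lost, C = y
    R = R_pool / (1.0 + B / r.Kd_B)
    ARB_T = T_pool / (1.0 + r.K_TI_eq)
    bindA = r.kon_A * A * R - r.koff_A * AR
    bindB_AR = r.kon3 * B * AR - r.koff3 * ARB_T
    dR_pool = -bindA + r.k_syn_R
    dAR = bindA - bindB_AR - r.k_int * AR
    dT_pool = bindB_AR - r.k_int_T * ARB_T
    dR_lost = r.k_int * AR + r.k_int_T * ARB_T
    frac = r.Imax * max(r.eps_R * R + r.eps * AR, 0.0) / (
        r.I50 + max(r.eps_R * R + r.eps * AR, 0.0)
    )
    dC = _camp_rate(C, frac, fsk, r)
    return np.array([dR_pool, dAR, dT_pool, dR_lost, dC])


def full_initial_state(p: ParameterSet, C0: float = 0.0) -> np.ndarray:
    """Initial condition: all receptor free at the surface, cAMP at the
    pre-drug steady state (0 in the absence of forskolin)."""
    y = np.zeros(len(FULL_SPECIES))
    y[0] = p.system.R0
    y[-1] = C0
    return y


def reduced_initial_state(p: ParameterSet, C0: float = 0.0) -> np.ndarray:
    y = np.zeros(len(REDUCED_SPECIES))
    y[0] = p.system.R0
    y[-1] = C0
    return y


def reduced_to_full(y: np.ndarray, p: ParameterSet, B: float) -> np.ndarray:
    """Expand reduced states (columns = time) to the full species layout.

    The quasi-equilibrium members are recovered algebraically:
    RB = R_pool * (B/Kd_B)/(1 + B/Kd_B) and ARB = T_pool * K_TI_eq/(1 + K_TI_eq).
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != len(REDUCED_SPECIES):
        y = y.T
    R_pool, AR, T_pool, R_lost, C = y
    b_frac = (B / p.allosteric.Kd_B) / (1.0 + B / p.allosteric.Kd_B)
    t_frac = p.allosteric.K_TI_eq / (1.0 + p.allosteric.K_TI_eq)
    R = R_pool * (1.0 - b_frac)
    RB = R_pool * b_frac
    ARB_T = T_pool * (1.0 - t_frac)
    ARB = T_pool * t_frac
    return np.vstack([R, AR, ARB_T, ARB, RB, R_lost, C])
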