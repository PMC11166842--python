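# cb1lag

Kinetic modelling of allosteric modulation at the cannabinoid CB₁ receptor:
why does the modulator ORG27569 take minutes to switch off agonist-driven
cAMP inhibition, and how does that lag depend on dose, timing and which
agonist is bound?

`cb1lag` is aimed at quantitative pharmacologists working with real-time
cAMP biosensor (CAMYEL/BRET) assays. It implements a unified
receptor/signalling model in which an orthosteric agonist A (CP55940 by
default), an allosteric modulator B (ORG27569) and the receptor R interact
by mass action:

```
A + R  ⇌ AR          (kon_A, koff_A = kon_A·Kd)
B + R  ⇌ RB          (kon2, Kd_B)
B + AR ⇌ ARB_T       (kon3, koff3)
ARB_T  ⇌ ARB         (k_TI, equilibrium ratio K_TI_eq)
AR     → internalised (k_int);   ARB_T → internalised (k_int_T)
```

Only the constitutively active free receptor R and the agonist-bound
receptor AR signal. Their combined inhibition signal **I = ε_R·R + ε_c·AR**
(ε_R = 1, ε_c = 10^1.66 ≈ 45.7 for CP55940) suppresses forskolin-driven
cAMP production through an E_MAX model,

```
dC/dt = k_in·(1 − I_max·I/(I50 + I)) − k_out·C,
```

normalised so the receptor-free forskolin steady state is 1. The ternary
species ARB_T (transitional: silent at G proteins but still internalising)
and ARB (inactive) are the heart of the mechanism: because signalling
saturates at low occupancy (AR = 0.1·R₀ already gives 82% inhibition),
modulator binding only becomes visible once internalisation and ternary
complex formation deplete AR below ~10% of R₀ — producing a kinetic lag
T_d between modulator addition and the divergence of the cAMP curves.

The package provides, as importable modules with a thin `cb1lag` CLI on
top:

- `params` / `model` — validated parameter sets with units and provenance
  tags, the full mass-action and reduced (quasi-equilibrium) ODE systems,
  and the E_MAX inhibition coupling;
- `simulate` — stiff-capable time-course integration over dosing schedules
  (co-addition, staggered addition, pre-read baseline), species fractions,
  and mapping to the observed inverse-BRET-like scale;
- `lag` — the kinetic lag T_d by both definitions: tolerance crossing of
  the curve difference (for simulations) and closed-form crossing of a
  fitted plateau-plus-one-phase-association curve (for noisy data);
- `uncertainty` — multivariate-normal sampling of a parameter covariance,
  simulation-based prediction bands, and observation-coverage reports;
- `probe` — agonist substitution (CP55940, WIN55,212-2, THC) and grid
  calibration of the interaction rate kon3 for probe-dependence analysis;
- `synth` — a synthetic CAMYEL plate-data generator (replicates, technical
  duplicates, per-experiment baseline/efficacy, residual noise) so the
  whole pipeline is testable without laboratory data.

## Worked example

```python
from cb1lag import (reference_parameters, co_addition_schedule,
                    simulate_timecourse, observe_trace, model_lag)

p = reference_parameters()          # shipped CP55940/ORG27569 set
print(f"agonist Kd = {p.agonist.Kd_uM:.5f} uM, eps_c = {p.agonist.eps:.1f}")

for org in (0.1, 0.316, 1.0, 10.0):
    sch = co_addition_schedule(1.0, org, horizon=30.0)   # 1 uM CP + ORG + FSK at t=0
    with_org = observe_trace(simulate_timecourse(p, sch))
    without  = observe_trace(simulate_timecourse(p, sch.without(["B"])))
    res = model_lag(with_org, without, tolerance=0.01)
    print(f"ORG {org:5.3f} uM: T_d = {res.T_d:5.2f} min")
```

prints

```
agonist Kd = 0.00251 uM, eps_c = 45.7
ORG 0.100 uM: T_d = 14.01 min
ORG 0.316 uM: T_d =  8.75 min
ORG 1.000 uM: T_d =  4.95 min
ORG 10.000 uM: T_d =  2.00 min
```

i.e. with 100 nM modulator the cAMP curves stay together for ~14–15 min
before diverging, the lag shrinks as the modulator concentration rises,
and at 10 µM it has essentially vanished. The same simulation shows AR
falling below 10% of R₀ at ~7.8 min when 300 nM ORG is co-added — the
receptor-reserve threshold at which cAMP becomes sensitive to the
modulator-bound species.

The same operations are exposed on the command line:

```bash
cb1lag simulate --design validation --out runs/validation
cb1lag lag --traces runs/validation/traces.csv \
           --reference-condition "CP1uM+ORG0uM+FSK|co" --out runs/lag
cb1lag synth --design preincubation --seed 1 --out runs/plate
cb1lag band --n-draws 200 --seed 1 --out runs/band
cb1lag probe --agonists CP,WIN,THC_calibrated --org-conc 1 --out runs/probe
```

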