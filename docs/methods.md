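# Methods

## Model

The model couples a ternary-complex receptor scheme to an indirect-response
cAMP equation. Species (all as fractions of the initial surface receptor
R₀ = 1): free receptor R, agonist-bound AR, transitional ternary ARB_T,
inactive ternary ARB, modulator-bound RB, and the cumulative internalised
pool R_lost. Ambient ligand concentrations A and B (µM) are held constant
between dose events; free-ligand depletion is ignored because receptor
amounts are far below ligand amounts in a plate assay.

Mass action (full model):

- A + R ⇌ AR with association `kon_A` and dissociation `kon_A·Kd`,
  Kd = 10^(6−pKd) µM;
- B + R ⇌ RB with `kon2` and `kon2·Kd_B`;
- B + AR ⇌ ARB_T with `kon3`, `koff3`;
- ARB_T ⇌ ARB with `k_TI` forward and `k_TI/K_TI_eq` backward, so the
  equilibrium ratio ARB/ARB_T is `K_TI_eq`;
- AR and ARB_T internalise at `k_int` and `k_int_T` (flux into R_lost);
  constitutive R and the inactive species do not internalise;
- optional zero-order receptor synthesis `k_syn_R` (0 by default on the
  ≤35-min assay horizon).

Signalling: only R (efficacy ε_R = 1) and AR (efficacy ε_c = 10^log10_eps)
contribute to the inhibition signal I = ε_R·R + ε_c·AR, which suppresses
cAMP production through an E_MAX term, I_max·I/(I50 + I). cAMP follows
`dC/dt = k_in·(1 − inhibition) − k_out·C` while forskolin is present and
`−k_out·C` otherwise. Units: time in minutes, concentrations in µM,
receptor amounts in fractions of R₀, and C normalised so the receptor-free
forskolin steady state k_in/k_out = 1. The 0.01 lag tolerance is applied
on this normalised scale and is exposed as a parameter throughout.

The transitional state is what produces the signature kinetics: ARB_T is
silent at G proteins but keeps internalising, so modulator binding both
removes signalling-competent AR and accelerates its loss from the surface,
yet nothing is visible in cAMP until AR falls below the receptor-reserve
threshold (~10% of R₀, where the E_MAX curve leaves saturation).

### Reduced model

The default integrated system assumes quasi-equilibrium for ARB (ratio
`K_TI_eq` with ARB_T) and for RB (equilibrium with R via `Kd_B`), and
integrates the lumped pools R+RB and ARB_T+ARB alongside AR, R_lost and C.
With B = 0 it collapses exactly to the two-species (R, AR) agonist-only
model. The full mass-action system is retained as an independent check:
with the lumped reactions made fast (k_TI and kon2 scaled ×1000) its
trajectories match the reduced model within 1% sup-norm (tested on random
parameter draws).

### Numerical choices

Integration uses LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10. Dose
events restart the integrator at the event time, so step changes in
ambient concentration are handled without discontinuity smoothing. The
default analysis grid is 0.1 min; exported synthetic plates use a 0.5-min
plate-reader-like cadence. Halving the grid step changes C(t) by far less
than 0.1% (tested). Receptor-mass conservation holds to <1e-6 along every
trajectory with synthesis off.

## Parameters: printed, derived, calibrated

Every field of the shipped reference set
(`src/cb1lag/params/reference_cp_org.json`) carries a provenance tag.

Printed (CP55940/ORG27569): pKd = 8.6, k_int = 0.15 min⁻¹,
log10(ε_c) = 1.66 (ε_c ≈ 45.7), kon3 = 0.528 µM⁻¹·min⁻¹, ε_R = 1.

Derived: I50 is obtained by root-finding from the printed operating point
of the inhibition curve — with ε_c = 45.7 and the R contribution ignored,
AR = 0.1·R₀ must produce 82% inhibition, giving I50 = 1.0032
R₀-equivalents (I_max = 1). `scripts/calibrate_defaults.py` re-derives it
with `scipy.optimize.brentq` rather than hard-coding.

Calibrated: the remaining rate constants are not published with the model
summary. Two of them shape the lag statistic directly and are fixed by a
deterministic grid search + golden-section refinement
(`scripts/calibrate_defaults.py`) against four published kinetic anchors
for 1 µM CP55940 co-added with ORG27569 — lag ≈ 15 min at 100 nM ORG,
lag ≈ 5 min at 1 µM ORG (insensitive to CP over 0.1–10 µM), AR crossing
below 0.1·R₀ at ≈ 7 min with 300 nM ORG, and an essentially immediate
response at 10 µM ORG. The result is k_out = k_in = 0.023 min⁻¹ and
koff3 = 0.01 min⁻¹. The remaining constants sit on timescales those
anchors do not constrain tightly and keep declared defaults:

| parameter | default | rationale |
| --- | --- | --- |
| kon_A | 10 µM⁻¹·min⁻¹ | binding equilibrates well inside 1 min at ≥10 nM agonist (the observed fast AR rise) |
| kon2 | 1 µM⁻¹·min⁻¹ | modulator binding to free receptor on the minutes scale |
| Kd_B | 1 µM | µM-range modulator affinity at free receptor; at 10 µM ORG most constitutive R is sequestered (inverse agonism), at 100 nM little is |
| k_TI | 1 min⁻¹ | transitional→inactive conversion fast relative to internalisation (full model only; the reduced model uses the ratio) |
| K_TI_eq | 1 | comparable transitional and inactive ternary pools |
| k_int_T | = k_int | the transitional state internalises; no separate rate is published |
| k_syn_R | 0 | negligible synthesis on a ≤35-min horizon; exposed as a knob |

Because the calibration targets are themselves the headline lag values,
the regression tests on those values are anchors of the shipped set, not
independent validations — the independent content is that one pair
(k_out, koff3) satisfies all four anchors simultaneously, plus the
structural properties (monotonicity, pre-incubation effect, probe
ordering) that were never targeted.

## Lag definitions

Model method: subtract the modulator-free curve pointwise; T_S is the
first time (linear interpolation between grid points) the signed
difference exceeds the tolerance (default 0.01); T_d = T_S − t_B where t_B
is the modulator addition time. The crossing is one-sided in the direction
of disinhibition — a modulator curve falling below the reference never
separates.

Experimental method (for noisy data): fit the difference curve with a
plateau followed by one-phase association, Y0 for t < X0 and
Y0 + (plateau−Y0)(1−e^(−K(t−X0))) beyond, by bounded least squares with an
analytic Jacobian and multi-start over an X0 grid (5th–95th percentile of
observation times; ties by lowest RSS then earliest X0). T_S then solves
the fitted curve in closed form, T_S = X0 + ln(span/(span−tol))/K with
span = plateau − Y0; span ≤ tol means no separation. The near-linear-rise
limit of this family is a ridge (plateau → ∞, K → 0 with the product
fixed); the fitter accepts a ridge solution as converged when a restart no
longer improves it, since the crossing time depends only on the identified
product. On noise-free data drawn from the association family itself the
fit recovers parameters to ~1e-6 relative and the two lag definitions
agree within a grid step.

The estimator-recovery study (noisy difference curves at the
mean-of-replicates noise level, 100 seeds) uses the staggered-addition
design — agonist 15 min before modulator — at a 0.25-min read grid: that
design gives the difference curve the plateau-then-rise shape the fit
family assumes, mirroring how the lag was measured experimentally. On
co-addition curves, whose early difference grows convexly from zero, the
association fit systematically places the crossing slightly late (~15–20%
at the shortest lags); this is an intrinsic disagreement between the two
published definitions on that curve shape, not a fitting failure.

## Uncertainty propagation

Parameter uncertainty enters as a multivariate normal on the estimation
scale (log for rates, keeping positivity; linear optional per label).
Draws violating domain invariants are rejected, redrawn and counted.
Prediction bands simulate every draw, add independent Gaussian residual
error (additive, observed scale) at each time, and report pointwise
2.5/50/97.5% quantiles; failed simulations are excluded and the band is
flagged if more than 5% fail. Coverage reports interpolate the band at the
observation times and compare the inside fraction to a configurable
threshold (default 0.90 for a nominal 0.95 band).

No estimation covariance is published for this model, so the shipped
matrix (`params/synthetic_demo_cov.csv`) is synthetic — diagonal,
log-scale CVs of 10–30% on k_int, kon3, koff3, k_out and kon_A — and
exists to demonstrate the procedure. Band and coverage results with it are
demonstrations, not reconstructions of the original analysis.

## Probe dependence

Agonists differ only in (pKd, k_int, log10_eps):
CP55940 (8.6, 0.15, 1.66), WIN55,212-2 (7.7, 0.28, 2.63), THC
(8.0, 0.029, 0.85); all modulator and system parameters are shared. The
efficacy ordering WIN > CP > THC drives the lag ordering — a high-efficacy
agonist needs deeper AR depletion before the modulator effect surfaces, so
its lag is longer and inverse agonism is weaker. The THC_calibrated
variant additionally lowers kon3 ten-fold to 0.05 µM⁻¹·min⁻¹, encoding a
lower modulator affinity for the partial-agonist-bound receptor; with it
the model shows the longer lag and absent inverse agonism seen with THC.
`calibrate_kon3` reproduces this kind of adjustment: grid search (default
21 log-spaced values in [0.005, 5]) over summed squared trace discrepancy
after per-trace affine (baseline/efficacy) alignment, ties to the smaller
value.

## Synthetic data generator

`synth.generate_dataset` emulates the assay's statistical structure:
5 µM forskolin drive, co-added or staggered additions after a 5-min
drug-free pre-read, reads every 0.5 min, n = 3 independent replicates with
2 technical duplicates, per-replicate additive baseline ~ N(0, 0.02) and
multiplicative forskolin efficacy ~ N(1, 0.05) truncated positive, and
i.i.d. Gaussian residual noise with σ = 0.01 on the normalised scale
(chosen so the 0.01 lag tolerance is meaningful yet recoverable; no
numeric σ is published). Duplicates share their replicate's plate factors
but have independent residuals. Datasets are bit-reproducible from
(design, parameters, seed). A decaying-exponential forskolin overshoot
artifact can be enabled but is off by default, as it is irrelevant to the
mechanism.

What the generator does **not** emulate: well-position and temperature
effects, luminescence photophysics (the two BRET channels are not
modelled separately), substrate depletion, and any non-Gaussian or
time-correlated error. Tests passing on synthetic plates therefore
demonstrate pipeline correctness and statistical behaviour under the
declared noise model, not robustness to every artifact of real plate
reads.

## Problem sizes

Default analysis runs integrate 5-state ODEs over 20–35 min at 0.1-min
grids; the recovery and coverage studies use 100 and 5 seeded replicates
respectively with 150–2000 parameter draws for bands. These sizes make the
full test suite and the reproduction script desk-scale while keeping
Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- G proteins, adenylate cyclase and β-arrestin are not explicit; R and AR
  inhibit cAMP directly, so the model cannot resolve mechanism below the
  receptor level.
- All unprinted rates are calibrated against cAMP kinetics only; binding
  and internalisation data would be needed to pin them individually.
- The reduced model's quasi-equilibrium is an approximation whose error
  grows if k_TI or modulator–free-receptor binding is made slow.
- The experimental lag definition inherits the bias described above on
  co-addition curve shapes.
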