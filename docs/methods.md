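# Methods

## The biological system

During Drosophila bristle (mechanoreceptor) development, one cell of each
proneural cluster — the sensory-organ parental cell (SOPC) — adopts the
neural fate. The committed cell is marked by an elevated level of the
proneural ASC proteins, products of the achaete–scute complex (AS-C).
AS-C activity is controlled by a seven-gene subcircuit, here called the
central regulatory circuit (CRC): AS-C itself, the repressors *hairy* and
*emc*, the ASC-driven targets *sens*, *scrt* and *chn*, and the
degradation adaptor *phyl*, together with the accessory proteins DA, GRO,
UB and SINA whose concentrations are treated as constant.

`crcsim` models the CRC of a single presumptive SOPC. Intercellular
(Notch-mediated) interactions between cluster cells are outside its scope.

## Model equations

State variables (arbitrary concentration units, AU): ASC `x`, Hairy `y`,
EMC `E`, SENS `z`, SCRT `u`, CHN `w`, PHYL `p`. Time is in hours, with
t = 0 the moment the proneural cluster is established and all cells still
have equal neural potency.

```
dx/dt = k_x [σ1(D·x) + σ4(z) + σ6(w)] / (1 + G·y + E·x) − m_x·x − q·S·U·p·x
dy/dt = k_y Cy / (1 + d2·u + d3·w) − m_y·y
dE/dt = k_e Ce / (1 + d1·w)        − m_e·E
dz/dt = k_z s4(D·x) − m_z·z
du/dt = k_u s5(D·x) − m_u·u
dw/dt = k_w s6(D·x) − m_w·w
dp/dt = k_p s7(D·x(t−τ)) − m_p·p ,  x(t−τ) ≡ 0 for t < τ
```

All σ/s functions are Hill activations `a vⁿ/(bⁿ + vⁿ)`. The ASC/DA
heterodimer is represented by the mass-action product `D·x`; the two
repressive heterodimers Hairy/GRO and ASC/EMC enter as the products `G·y`
and `E·x` inside the rational repression factor. PHYL, with UB and SINA,
routes ASC to degradation through the `q·S·U·p·x` term; its production
reads the ASC level a fixed delay τ in the past with zero pre-history,
representing the late onset of *phyl* expression. Per-gene mutation
coefficients `k ∈ [0, 1]` scale production terms (1 = wild type, 0 = null
allele).

Model structure worth noting:

* **x = 0 is locally stable.** With Hill exponents ≥ 2 the per-capita ASC
  production vanishes as x → 0, so the origin attracts once ASC has been
  driven low enough — determination is lost irreversibly, and the
  trajectory cannot "un-divide".
* **Bistability.** Between the off state and the high quasi-plateau
  (~2.95 AU, set by the balance of saturated activation against the
  ASC/EMC- and Hairy/GRO-weighted repression) lies a separatrix; the
  wild-type initial condition x₀ = 0.8 AU sits above it, a >40 % reduced
  one below.
* **The delay is the commitment timer.** Until t = τ no PHYL is made at
  all; afterwards PHYL tracks the delayed ASC level with relaxation time
  1/m_p. Large m_p makes PHYL a tight (but lagged) follower: in the
  wild type the delayed ASC signal is already high when PHYL switches on,
  giving a hard, sustained degradation pulse; at small τ the feedback
  loop closes on a still-low ASC history and self-limits.

## The reference parameterization

The kinetic constants of this circuit have never been measured
directly, so the package ships its own reference
set, `crcsim/data/reference_params.json`, produced by the `calibration`
workflow: a multi-start Nelder–Mead fit of nine free parameters (the
three activation amplitudes into AS-C, the constitutive Hairy/EMC scales
Cy and Ce, the turnover rates m_x and m_p, the degradation coupling q,
and the reference delay τ_ref) to five wild-type curve anchors:

| anchor | value |
|---|---|
| initial ASC level x₀ | 0.8 AU |
| peak ASC level | 2.95 AU (≈3.7-fold) |
| time of peak | ≈10 h |
| onset of sharp decline | ≈15 h |
| decline duration | ≈3 h (ASC ≈ 0 by ≈18 h) |

Fixed-by-convention choices: D = G = S = U = 1 AU; x₀ = 0.8, y₀ = E₀ =
0.5 AU (repressors present when the cluster forms), z₀ = u₀ = w₀ = p₀ = 0
(ASC targets and PHYL not yet expressed); Hill exponents n = 2 for all
activations except the PHYL input (n = 3, a threshold-like response to
the delayed ASC signal); horizon 28 h. The remaining shape parameters
(cascade amplitudes, half-saturations, repression weights d1–d3, slow
Hairy/EMC kinetics) were fixed during model development and are recorded
in the shipped JSON; all are overridable.

Two slow modes matter for the curve anatomy. Hairy relaxes on a
multi-day timescale (m_y ≈ 0.028/h), so its level creeps upward through
the whole run; this creep, together with the first trickle of
PHYL-mediated degradation, turns the top of the ASC curve into a genuine
(if shallow) maximum near 10 h rather than a saturating ramp. EMC
declines slowly under CHN repression, extending the rise phase. Neither
mode is free during calibration.

**Calibration/validation separation.** Only the five anchors above enter
the objective. Everything else the model is expected to reproduce — the
minimal viable delay τ* = 2.1 h with its ≈2.5-fold peak, the dosage
threshold k_x = 0.6, the bounded rise and low plateau of the τ = 0 run,
the knockout hierarchy — is computed by `validate_reference` on the
calibrated set, out of sample. The two target lists are disjoint by
construction; a validation failure is reported, not refitted away.

## Scenario conventions

* **Features.** "Division time" (T) is the first time after the ASC peak
  with x ≤ ε, ε = 0.01 AU (1.25 % of x₀) — an operational reading of
  "dropped to almost zero". Decline onset is the first post-peak time at
  which the smoothed slope (Savitzky–Golay, ≈0.5 h window) falls below
  −0.1 AU/h. A plateau requires, over the last 20 % of the horizon, a
  relative ASC range under 2 % at a level above ε. Determination
  requires a ≥2.5-fold peak over baseline *and* a recorded division
  time. All features are read off a uniform 0.01 h output grid so that
  they do not depend on adaptive step placement.
* **Minimal-delay search** scans τ = 0, 0.1, 0.2, … and returns the
  first grid point whose run both reaches zero and divides within 0.5 h
  of the 9 h experimental minimum.
* **Dosage sweep.** A reduced AS-C dose k_x scales both the production
  bracket and the initial content (x₀ᵢ = 0.8·k_x). The determination
  band is fixed at 2.5 × the *wild-type* baseline (2.0 AU), not rescaled
  per mutant.
* **Knockouts** zero a gene's coefficient *and* its product's initial
  concentration. Deviation from the wild type is the integral of
  |Δ ASC| over [0, T_wt], the circuit's operational lifetime (the SOPC
  divides at T_wt; comparing beyond that point would let the
  non-dividing *phyl*⁻ plateau dominate every ranking and carries no
  biological meaning). The maximal pointwise difference on the same
  window is reported alongside. Direction is "above"/"below" when ≥95 %
  of the deviation area lies on one side.
* **Delay sweep.** Division time is monotone in τ on the main branch,
  but in a narrow window just above the minimal viable delay it is not:
  near τ* the degradation pulse arrives while ASC is still climbing, and
  slightly longer delays produce *faster* collapses. The default sweep
  grid therefore spans the monotone branch mapping onto division times
  of 9–30 h (`admissible_tau_range`), which is where shape stability is
  asserted.

## Numerics

Integration is by the method of steps: the delay interval [kτ, (k+1)τ]
is integrated with adaptive RK45 (`scipy.integrate.solve_ivp`, rtol 1e-7,
atol 1e-9, max step 0.25 h), with the delayed ASC value cubic-spline
interpolated from the stored solution; for t < τ the delayed term is
identically zero, so PHYL stays exactly at its zero initial value. A
τ = 0 run closes the loop instantaneously (p reads the current x).
Output is resampled to the uniform feature grid and clipped at zero
(negative excursions beyond 1e3·atol are an error). `verify_peak=True`
repeats the run at halved tolerances and rejects peak discrepancies
above 0.1 %; an independent fixed-step RK4 oracle at h = 0.001 h agrees
with the adaptive solution to well under 0.5 % in the tests.

Derivative-free optimization (Nelder–Mead within bounds) is used for
calibration because the feature map is piecewise-smooth at best: peak
times and threshold crossings move on a discrete output grid. The
multi-start draw is seeded; identical seeds give identical results.

## What the synthetic data are and are not

The package needs no external data. Test fixtures are either (a)
trajectories regenerated from the shipped reference set — regression
anchors, not ground truth — or (b) synthetic piecewise curves
(`synthetic_feature_curves`) whose features are known by construction
and which exercise the feature extractor independently of the solver.
Passing tests demonstrate internal consistency of the reconstruction and
reproduction of the reference summary numbers; they cannot validate the
circuit against measured expression kinetics, which were only ever
described qualitatively.

## Known limitations

* The reference parameter set is one member of a family consistent with
  the reference curve features; individual rate constants should not be
  interpreted quantitatively. Feature-level identifiability is what the
  recovery tests assert.
* Single-cell model: no lateral inhibition, no bristle-pattern
  prediction.
* The wild-type ASC maximum is shallow (the curve is within ~2 % of its
  peak from ≈5 h onward), so the reported peak *time* is sensitive to
  the slow-mode parameterization in a way the peak *height* is not.
* Division-time non-monotonicity near τ* (see above) is a genuine
  property of the delayed-feedback reconstruction; the qualitative rule "the later PHYL appears, the later the cell divides" holds on the monotone branch.
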