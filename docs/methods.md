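# Methods

## The model

`qqcr` simulates *metaphysiological* consumer–resource dynamics in which each
population carries two states: an abundance (biomass density) and an average
quality index calibrated to [0, 1].  Biomass is gained by extracting and
converting resources and lost to metabolism, to quality-dependent senescence,
and (optionally) to extrinsic removal.  An allocation proportion
u ∈ [0, 1] splits converted intake between increasing abundance (u) and
raising average quality (1 − u).

Working in the log variables x = ln X and q = ln Q_X ≤ 0, the consumer core
is

    dx/dt = u·I − µ + α·q − ε
    dq/dt = a·(−q)·(1 − u)·I − c·µ − b·α·q

with converted intake

    I = κ(Q_R) · sech(w·(u − v)) · δ·F(R, X),
    F(R, X) = ρ / (1 + ρ + (X/K)^γ),       ρ = R/β.

Interpretation of the pieces:

* **Extraction** is a Beddington–DeAngelis functional response.  δ is the
  ceiling intake rate; β the resource level giving half the ceiling for a
  lone consumer; intraspecific interference sets in around abundance K with
  abruptness γ ≥ 1 (γ → large makes density dependence switch-like).
* **Conversion** κ(Q_R) = λ·Q_R^(1/(1+c)) rises from 0 (worthless resource)
  to λ (perfect resource).  The exponent keeps κ above the linear ramp for
  c > 0: consumers preferentially extract higher-than-average-quality
  material.
* **Efficiency cost** sech(w·(u − v)) penalises allocations away from the
  physiological set point v; w = 0 disables the cost.
* **Quality dynamics.**  Intake invested in quality pushes q up at rate
  a·(−q)·(1−u)·I — the (−q) factor makes Q approach 1 only asymptotically.
  Metabolism burns the best tissue first, dragging quality down at rate c·µ;
  senescence (θ = −α·q, faster for poor-quality populations) removes the
  worst individuals first, *raising* average quality at rate −b·α·q.
  Because dq/dt = −c·µ < 0 at q = 0, the bound Q ≤ 1 is invariant.

Three variants share this core:

* **`fixed`** — the consumer alone on a constant background ρ = R/β
  (default ρ = 2·10⁵/β), with a constant conversion coefficient
  κ = κ(0.5).
* **`cr3`** — the resource grows logistically toward a seasonally forced
  carrying capacity and is harvested by the consumer,

      dR/dt = r·R·(1 − R/S(t)) − δ·F(R, X)·X,
      S(t)  = S0·(1 + 2·d_s·sin(2πt/12)),
      Q_R(t) = 0.5 + d_r·sin(2πt/12),

  with annual period (12 months) and amplitudes bounded so S ≥ 0 and
  Q_R ∈ (0, 1).
* **`cr4`** — the resource is itself a quantity–quality population: the
  same two-equation core applied to (R, Q_R), feeding on a substrate held at
  the seasonal carrying-capacity level, with self-limitation scale
  `K_r_dd` (default S0/6, placing the unharvested resource equilibrium near
  S0).  Setting the resource growth to the logistic form and freezing Q_R to
  the seasonal driver reduces `cr4` to `cr3` exactly; the test-suite asserts
  this identity to 1e-12.

## Optimal constant allocation

Under constant conditions, maximising J = ∫ ln X dt drives the system to a
singular-arc equilibrium u = v*.  Solving the singular conditions gives

    q̂  = sqrt(c·µ / (a·α)),
    v*± = (a·µ ± E) / (a·µ ± 2E − α·b),      E = sqrt(a·α·c·µ),

independent of every extraction parameter (δ, β, γ, K, w).  Both roots are
always reported: the optimality conditions are necessary only, so the
numerical u-sweep of long-run equilibrium abundance adjudicates which root
maximises abundance.  At the baseline parameters the sweep's argmax and v*⁺
agree to three decimals — a mutual cross-check of the closed form and the
integrator that the acceptance suite reruns.

## Baseline parameters

Rates are per month; biomass units are arbitrary but shared.

| symbol | field | default | meaning |
|---|---|---|---|
| r | `r` | 0.5 | resource max per-capita growth |
| a | `a` | 0.1 | quality response rate |
| d_s, d_r | `d_s`, `d_r` | 0 | seasonal amplitudes (≤ 0.5, < 0.5) |
| δ | `delta` | 5 | max extraction rate |
| λ | `lam` | 0.2 | max conversion |
| α | `alpha` | 0.1 | senescence scale |
| µ | `mu` | 0.05 | metabolic maintenance |
| β | `beta` | 30 000 | half-saturation resource level |
| γ | `gamma` | 2 | interference abruptness |
| K | `K_dd` | 10 000 | interference scale |
| S0 | `S0` | 10⁶ | mean carrying capacity |
| c | `c_bias` | 0.3 | metabolism quality bias |
| b | `b_bias` | 0.05 | senescence quality bias |
| v | `v_set` | 0.5 | allocation set point |
| w | `w_cost` | 0 | efficiency-cost scale |
| ε | `eps_removal` | 0 | extrinsic removal |

Standard initial conditions: R(0) = 2·10⁵, X(0) = 10⁴, Q_X(0) = 0.45
(Q_R(0) = 0.5 in `cr4`).

## Allocation switching and sliding modes

The threshold policy applies one bound of [u_min, u_max] when X ≤ X_switch
and the other above it; the boundary belongs to the "below" branch.  Two
directions exist because both appear in practice:

* `grow_below` (u_max below the threshold) clips abundance peaks and can
  *regulate* X at X_switch: when the below-field pushes X up and the
  above-field pushes it down, infinitely fast switching pins the state to
  the surface.
* `quality_below` (u_min below) makes small populations invest in quality
  first — the mechanism behind the lag phase of culture growth curves.

On an attractive switching surface the engine integrates the Filippov
(equivalent-control) dynamics: the convex combination of the two branch
vector fields whose X-component vanishes, with event functions detecting
entry, exit (either branch field changing sign) and extinction.  This is
the exact limit of fast chattering and avoids resolving each switching
event; a literal chattering integrator (fixed RK4 step, default cap
0.01 month) is available via `SolverSettings(sliding="chatter")` and agrees
with the Filippov path to ~2% on regulation runs.  The recorded `u` along a
sliding segment is the effective duty-cycle value s·u_below + (1−s)·u_above.
An optional hysteresis band converts sliding into finite-rate relay
switching for experimentation.

## Numerics

* **Coordinates.**  All integration uses (ln R, ln X, ln Q): positivity and
  Q ≤ 1 hold structurally, with no clamping.  Consistency between log and
  natural coordinates is tested to 1e-6.
* **Solver.**  `scipy.integrate.solve_ivp` with LSODA (automatic stiffness
  handling) at rtol 1e-8 / atol 1e-10 by default; any solve_ivp method can
  be selected.  Halving tolerances moves final abundances by far less than
  0.1% on the preset scenarios (tested).
* **Extinction** is an event at X < 1 (configurable); abundance is reported
  as 0 from the event time on, and `extinct_at` is recorded.
* **Equilibria** are located by a hybrid root search in log coordinates
  seeded from a simulation endpoint and accepted only below a residual norm
  of 1e-10.  Local stability uses a central-difference Jacobian (step
  insensitivity tested) and eigenvalue classification.
* **Equilibrium sweeps** integrate 600 months per grid point with a
  relative-convergence check over the final 60 months; values under the
  extinction cutoff report 0.
* **Period estimation** takes the mean inter-peak interval of consumer
  maxima, prominence-filtered at 5% of the windowed range, requiring at
  least three peaks, with a periodogram cross-check; estimates are quoted
  to 0.1 year.  For seasonally forced runs the dominant multi-year period
  is computed after averaging X over 12-month blocks, which removes the
  annual imprint exactly; a multi-year cycle is reported only when the
  annual-averaged series retains relative range above 1e-3.
* **Transient discard** defaults to the first 80 years for forced scenarios
  and the first half of the horizon otherwise.

## Growth-phase classification

Phases of a growth trajectory are segmented on the smoothed per-capita rate
g = d ln X/dt: *lag* (g below 25% of its later maximum), *LogEx* (g rising
to its maximum — stronger-than-exponential growth), *RegEx* (g
approximately constant: |dg/dt| under 5% of its maximum), *inhibition*
(g decreasing but positive), *stationary* (|g| within 2% of the maximum
rate of zero) and *decline* (g < 0).  The thresholds are heuristics for
qualitatively defined phases; segments shorter than three samples are
merged, and windows too short to classify return an explicit
"unclassified" segment.

## Reconstruction provenance and known limitations

The algebraic forms above were fixed by cross-checking closed-form and
simulated quantities against the published numerical anchors:

* the closed-form roots v*⁺ = 0.704124 / v*⁻ = 0.295876 reproduce to six
  decimals, which pins the two-state equations (including where u and the
  bias terms sit);
* the fixed-background u-sweep reproduces the published maximum equilibrium
  abundance to 0.6% at the same argmax, pinning the extraction law and the
  conversion exponent.

Two caveats follow from the same cross-checks.  First, the published
abundance sweep is attributed to the coupled model but is only reproduced
by the fixed-background variant; the library exposes both, and the
acceptance script uses the variant that matches.  Second, with these forms
the coupled model's oscillation onset sits at distinctly slower resource
growth (Hopf near r ≈ 0.31 at baseline) than the published period tables
indicate (onset near r ≈ 0.48), and no variant examined reconciles the two
sets of printed values simultaneously.  The acceptance suite therefore
reports the computed periods as they are; the oscillation phenomenology
(equilibrium at fast resource growth, multi-year cycles at slower growth,
extinction below it, forced multi-year cycles emerging as the quality
response strengthens, sliding-mode stabilisation, cost-threshold collapse)
is reproduced qualitatively throughout.

Scan problem sizes: switching-cost scans integrate 200 simulated years per
grid point with statistics over the final 100 years (the original figures
average over 1000 years); period estimates use 300-year runs discarding the
first half.  These sizes keep full reruns to minutes without materially
changing any reported quantity.

Not modelled: age/size/stage structure, allometric scaling, stochastic
perturbation, demographic noise, multispecies food webs, and formal
bifurcation continuation (all sweeps are brute-force numerical).
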