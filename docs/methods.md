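# Methods

## Model

The model is a mean-field description of an excitatory neural network.
Network activity `a ∈ (0,1)` is the population- and time-averaged firing
rate; `s ∈ [0,1]` is the fraction of undepressed synapses; `θ ∈ [0,1]`
the level of a cellular adaptation process that raises the firing
threshold. With time in units of the activity time constant (τ_a = 1):

    da/dt = a_∞(w·s·a − g·θ) − a
    ds/dt = (s_∞(a) − s)/τ_s
    dθ/dt = (θ_∞(a) − θ)/τ_θ

All three steady-state functions are logistic sigmoids
`σ(x) = 1/(1 + exp(−(x − center)/spread))`: `a_∞` increasing in its input
with half-activation θ₀ and spread k_a; `s_∞` decreasing in `a` (center
θ_s, spread k_s); `θ_∞` increasing in `a` (center θ_θ, spread k_θ).
Depression is *divisive* (it multiplies the recurrent input `w·s·a`),
adaptation is *subtractive* (`−g·θ` shifts the input). Because every
sigmoid maps into (0,1), the unit cube is forward invariant.

Assumptions: s and θ are slow relative to a (τ_s, τ_θ ≫ τ_a), the system
is deterministic, and the rhythm is a relaxation oscillation with clearly
separated active (a > 0.35) and silent phases. The sensitivity measure
additionally requires that both slow variables vary monotonically within
each phase; a warning flag reports violations.

### Parameters (defaults, dimensionless; time in units of τ_a)

| name | meaning | default | documented sweep range |
|---|---|---|---|
| w | connectivity (synaptic strength) | 1 | 0.5–3.5 |
| θ₀ | input for half-maximal activation | 0 | −0.2–0.2 |
| k_a | spread of a_∞ | 0.05 | |
| θ_s, k_s | center/spread of s_∞ | 0.3, 0.05 | |
| τ_s | depression time constant | 250 | 25–2500 |
| θ_θ, k_θ | center/spread of θ_∞ | 0.3, 0.05 | |
| τ_θ | adaptation time constant | 250 | 25–2500 |
| g | adaptation strength | 1 | 0–1.5 |
| dt | integrator step | 0.05 | |

The sweep ranges are documentation, not hard limits; validation only
enforces positivity (and dt ≪ min(τ_s, τ_θ)).

## Numerics

**Integration.** Classical 4th-order Runge–Kutta at fixed step dt = 0.05
(numba-compiled kernel). No adaptive or implicit stepping, no event
location: determinism and exact reproducibility take precedence, and the
dynamics are well resolved at this step (the period converges at 4th
order, verified by Richardson comparison in the tests). Non-finite states
raise with a time stamp.

**Settling.** Integration proceeds in windows of `20·max(τ_s, τ_θ)` from
the default initial state (a, s, θ) = (0, 1, 0) — a silent, fully
recovered network, guaranteed to enter the silent-phase basin. After each
window the accumulated trajectory is segmented; convergence is declared
when three consecutive onset-to-onset periods agree to a relative
tolerance of 1e−4 (small against the 4% perturbations measured
downstream), and the returned trajectory spans exactly those three
cycles. Rhythm loss is declared when no complete episode occurs within
40,000 time units or the activity range over a whole window falls below
0.05; these two criteria are implementation choices for "rhythmicity was
abolished". Neither outcome within 400,000 time units raises an error.

**Segmentation.** Phase boundaries are linear interpolations of the
threshold crossings of `a` at 0.35. No hysteresis is applied: the
relaxation dynamics cross the threshold in a fast jump, so chatter cannot
occur at dt = 0.05. Metrics (AP, SP, period = AP + SP, duty = AP/period)
average over all complete converged cycles (≥ 2) to suppress residual
settling error.

**Knees.** Setting ds/da = 0 on the dynamic a-nullcline
`s(a; θ) = (g·θ + θ₀ + k_a·ln(a/(1−a)))/(w·a)` gives the knee condition
`1/(1−a_k) − ln(a_k/(1−a_k)) = (g·θ + θ₀)/k_a`, whose left side has
minimum 2 at a = 1/2. Two knees exist iff the right side exceeds 2; the
degenerate double root at exactly 2 is reported as non-existence (a
degenerate knee cannot support a jump). Roots are located by bisection on
(ε, 1/2) and (1/2, 1−ε), ε = 1e−9, to xtol 1e−12 — robustness over speed.

## The measures

**Correlative.** On the converged cycle, Δs and Δθ are max − min over an
integer number of cycles (both processes cover the same range in either
phase, so per-phase ranges are unnecessary). `R = w·Δs/(g·Δθ)`,
`C = (R−1)/(R+1)`; the analytic counterpart `c = (r−1)/(r+1)` with
`r = (w/g)(τ_θ/τ_s)` follows from exponential relaxation, whose range
over a phase is inversely proportional to its time constant. Undefined at
g = 0 (signalled).

**Blockade.** The control rhythm is settled, g is set to 0 at an episode
onset (so the acute AP is well defined; the protocol does not otherwise
fix the block phase), the first complete AP and SP after the block are
the acute response, and re-settling from the post-block state gives the
equilibrated response or rhythm loss. Percent changes follow
`100·(blocked − control)/control`.

**Time-constant sensitivity** (the central measure). The perturbed run
starts from the limit-cycle state at the phase's onset crossing
(linearly interpolated), with the selected τ multiplied by 1 + δ for the
whole run — the measured phase ends before the other phase begins, so
this simplification cannot affect the measured duration. The duration is
the time to the phase-terminating crossing. δ = 4%, one-sided forward
difference, acute (no re-equilibration): this matches the experimental
logic the measure is designed to mimic; a central-difference or smaller-δ
variant can be selected through `delta_frac` but is not the default.
Baseline durations come from the same converged cycle whose crossing
states seed the perturbed runs, so settling bias cancels; a δ = 0 run
reproduces the baseline to ~1e−5 relative. Monotonicity of s and θ within
each phase is pre-checked with a retracement criterion (largest move
against the net direction > 5% of the excursion), because the slow
variables turn around slightly *after* the threshold crossing — a strict
sample-wise check would always fail in the fast boundary layer.

**Combination.** `C_xP = (C^s_xP − C^θ_xP)/(C^s_xP + C^θ_xP)` per phase,
in [−1, 1]; undefined (signalled) when both coefficients vanish, e.g.
a hypothetical phase controlled by neither slow process.

**Geometric.** θ is read at the interpolated onset and termination
crossings of the converged cycle (equivalent to deriving the transition
values from the simulated phase durations, and simpler); the low knee is
evaluated at the onset θ, the high knee at the termination θ, and
`ds/ds_k = (τ_θ/τ_s)(w/g)·a_k` per phase with
`C_geo = (ds/ds_k − 1)/(ds/ds_k + 1)`. Knee evaluation is pointwise at
the transition θ values (no averaging over the phase, no continuation in
θ). The derivation assumes near-uniform slow-variable speeds; the package
reports, and never corrects, the regime where that fails (see
limitations). Inapplicable (signalled) at g = 0 or when a knee is missing
at a transition θ.

**Sweeps.** One-parameter sweeps over τ_θ/τ_s, w, θ₀ or g compute every
measure per point independently and retain non-rhythmic points as flagged
rows. The ratio axis varies τ_s with τ_θ held at its base value, so the
slower process never drops below the base time constant and every sweep
point remains a relaxation oscillation; varying τ_θ downward instead can
collapse the rhythm into a fast quasi-harmonic (a, θ) oscillation with
`s` frozen, where the measure's applicability conditions fail.

## Design choices in open territory

- The preset tables (`fig1c` … `fig8b`, the blockade grid) use parameter
  grids inside the documented sweep ranges; where a published layout is
  known only graphically, the grids are representative, labelled
  non-canonical in their docstrings.
- The blockade grid exposes θ₀ ∈ {0.06, 0.12, 0.18} × τ_θ/τ_s ∈
  {0.5, 1, 2} as a configurable default.
- Coefficients are measured on a single acute cycle, not averaged over
  several perturbed cycles — the measure is defined by its immediate
  response.

## Known limitations

- **The summation relation is approximate at finite τ_a.** Phase
  durations are the sum of a slow-drift part, proportional to the slow
  time constants, and jump plus knee-passage parts set by the fast
  dynamics (the passage time scales like τ^(1/3)). Scaling both slow time
  constants by k therefore multiplies AP and SP by slightly less than k
  (measured AP(2τ)/AP(τ) = 1.937 at defaults, confirmed against an
  independent adaptive-step, event-located integrator), and the
  coefficient sums land at ≈ 0.88–0.97 rather than exactly 1 — lowest
  where a phase is short (small τ_s or small w). The deficit is a
  property of the model and protocol, not of the integrator; the exact
  relation holds only in the singular relaxation limit τ_a/τ → 0.
- **The geometric and sensitivity measures genuinely diverge** when θ
  saturates near its asymptote during the silent phase (large θ₀ with
  τ_θ ≪ τ_s): θ then "waits" for the slow crawl of s to the low knee, the
  uniform-speed assumption fails, and close to the rhythm-loss boundary
  the sensitivity C_SP even turns positive while the geometric estimate
  stays near −1 (e.g. θ₀ = 0.1855, τ_s = 2500, τ_θ = 250). The package
  flags gaps above 0.15 and leaves both values side by side.
- The simulator generates exactly the study conditions — a deterministic
  relaxation oscillator with two slow processes. It does not emulate
  noise (noise-driven transitions invalidate the measure), spiking or
  bursting sub-structure, more than two slow feedback processes, or
  partial blockade dose–response. Passing tests therefore demonstrate
  the internal consistency of the measures on this model class, not
  their robustness on noisy experimental recordings.
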