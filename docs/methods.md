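# Methods

## Model

`myoswarm` simulates an unloaded in vitro motility assay: a rigid actin
filament gliding at constant velocity v over a bed of N independent myosin
agents, with binding sites every x_d = 36 nm. Each agent follows a
three-state mechanochemical cycle:

1. **Detached.** The head waits at its capture position, δ₊ ahead of zero
   strain. While a binding site is inside the binding zone (width x_z) it
   may attach; attachment is a Poisson process with rate k_on while a site
   is in reach.
2. **Power-stroke.** On binding, head displacement is initialised to exactly
   δ₊ and decreases with the filament, exerting positive force κ·d
   (κ = e_ATP/δ₊², one ATP of elastic energy at full displacement).
3. **Drag-stroke.** Past zero displacement the head resists motion and
   detaches as a Poisson process with rate k_off.

Assumptions inherited from the modelled assay: velocity and force are
constant regardless of how many myosins are attached (valid for unloaded or
lightly loaded systems; with few attached motors a real filament's
instantaneous velocity would fluctuate); agents are mutually independent (no
steric exclusion — at ~200–400 nm of filament travel per myosin cycle,
same-site collisions are negligible); the filament is rigid and
one-dimensional; the cycle has exactly three states (no load- or
strain-dependent kinetics, no explicit ATPase chemistry).

A processive event starts with all agents detached. The lifetime clock
starts at the first binding; a dissociation timer accumulates over
contiguous zero-attachment steps and fires at the dissociation window
(1 ms). The recorded lifetime runs from first contact to the last
detachment, *excluding* the terminal window — the inclusive convention is
one `dissociation_window` away and can be recovered by addition; excluding
it avoids a constant additive offset in the master-curve intercept.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| k_on | attachment rate in reach | isoform | s⁻¹ |
| k_off | drag-stroke detachment rate | isoform | s⁻¹ |
| δ₊ | power-stroke length (= l·sin θ) | isoform | nm |
| x_d | binding-site spacing | 36 | nm |
| x_z | binding-zone width | 1.15 | nm |
| e_ATP | energy per ATP | 62.5 | zJ (= pN·nm) |
| θ | lever step angle | 30 | degrees |
| dX | engine spatial step | 1 | nm |
| dissociation_window | zero-attachment gap ending a run | 1 | ms |
| s_e threshold | SE target on per-myosin mean force | 0.005 | pN |
| v increment | unloaded-velocity search grid | 100 | nm/s |

Named isoforms (chicken skeletal 900/1600/5; median 2000/2500/10; baseline
1250/1500/7.5; low 1000/1500/5; high 3000/3500/15 in k_on/k_off/δ₊ units
s⁻¹/s⁻¹/nm) ship in `myoswarm/data/isoforms.json`.

**x_z calibration.** The binding-zone width is the one model constant with
no direct measurement. The default 1.15 nm is anchored to the operating
point with an empirical handle: motility velocity saturates at about N = 60
chicken-skeletal myosins per filament, where the contact probability is
~91%. `calibrate_binding_zone` inverts P_C = 1−(1−r)^N for r and then
Eqs P_on/Δ/r for x_z; at exactly (0.91, N=60) it returns 1.140 nm, and the
retained default 1.15 nm corresponds to P_C = 0.9117. Every lifetime result
downstream is conditional on this anchor, because x_z controls the
rebinding rate during zero-attachment gaps.

**Energy bookkeeping.** Energies are ATP turnovers per second: per-myosin
rate e = v/Δ, system rate E_sys = e·N, adjusted system energy
E\* = E_sys·N_att with N_att = N·r. The required energy to keep N_att
motors attached, E_req = N_att·v/(δ₊ + v/k_off), equals e·N_att/r
identically and N_att·k_off·(√2−1) at the unloaded velocity. Master-curve
units follow: A in ms, B in s.

## Discretisation conventions

The engine advances in dX = 1 nm steps, dT = dX/v. Choices that matter:

- **Transition probabilities.** Binding uses the exact within-step survival
  p_on = 1 − exp(−k_on·dT): per site passage this reproduces the analytic
  P_on = 1 − exp(−k_on·x_z/v) up to a small quantisation remainder. (The
  first-order form k_on·dT would inflate per-passage binding by ~7% at the
  named isoforms' unloaded velocities, where k_on·dT ≈ 0.05–0.3.)
  Detachment uses the linear p_off = k_off·dT, which makes the mean drag
  dwell exactly 1/k_off. A `DiscretizationWarning` flags k·dT > 0.1, where
  dwell-time *distributions* (not means) are coarse.
- **Drag ordering and force quadrature.** A drag-stroking agent moves first
  and faces the detachment check at the end of the step, so every drag
  phase includes at least one negative sweep. Force samples use trapezoid
  quadrature for power-stroke sweeps and the right endpoint for drag
  sweeps. Jointly these make the stationary estimator of the mean attached
  displacement *exactly* unbiased for the continuum
  ⟨d⟩ = (δ₊²/2 − δ₋²)/δ_on at every velocity when δ₊/dX is an integer —
  so the simulated unloaded-velocity search converges on the analytic
  (√2/2)·δ₊·k_off within its 100 nm/s grid, which plainer conventions
  (check-then-move, uniform endpoint sampling) miss by 5–25%. Non-integer
  δ₊/dX (the baseline isoform's 7.5 nm) leaves an O(dX/δ₋) remainder,
  handled by pro-rating the first drag hazard over the partial crossing
  step.
- **Window quantisation.** With dX = 1 nm and x_z = 1.15 nm, an agent's
  anchor phase (i.i.d. uniform per run, as independent anchoring of motors
  on the surface implies) fixes whether a passing site offers one or two
  binding checks: 15% of agents are "two-check" agents with ~1.9× the duty
  ratio of the rest. Population means are preserved (Jensen gap of order
  (k_on·dT)², −0.4% to −1.9% on duty over tested isoforms;
  `discrete_duty_ratio` gives the exact stationary expectation of the
  discretised engine), but small-ensemble averages carry this quenched
  disorder. Consequently `duty_ratio_replicates` stratifies phase
  fractional parts (unbiased variance reduction), and contact-probability
  estimates pool over fresh-phase replicate ensembles.
- **Dissociation timer.** The window is enforced as
  ceil(window/dT) consecutive zero-attachment steps, i.e. the first
  discrete count not shorter than 1 ms.
- **RNG.** One root seed; per-run/per-block substreams derived through
  `numpy.random.SeedSequence`, so batches are reproducible and independent
  of execution order. All seeds stay below 2³¹.
- **Convergence.** Steady-state runs discard a burn-in of five analytic
  cycles, then stop when the naive standard error of the per-step
  per-myosin force stream reaches 0.005 pN (after ≥1000 samples) or at
  `max_steps`, flagged non-converged. The per-step stream is autocorrelated
  over ~Δ/dX steps, so this SE understates the true sampling error — it is
  a stopping heuristic, not an error bar; attachment statistics are
  recorded at a stride of one analytic cycle to decorrelate them.

## What the simulations establish (and what they do not)

The generator *is* the model under study — there is no external data path.
Green tests establish that the stochastic engine realises the stated
three-state model (state-machine legality, exact dwell means, duty ratio
equal to its closed-form expectation, Eq-1 contact probabilities, unloaded
velocities at the analytic balance point) and that the emergent claims hold
inside that model: exponential lifetime distributions, lifetimes monotone
in N, required energy flat under k_on and δ₊ perturbations but growing
with k_off, and a cross-isoform collapse of lifetimes in E\*
(r² ≈ 0.95 over seven isoform families). They do not establish anything
about real filaments beyond the model's assumptions: constant velocity,
independent motors, rigid one-dimensional geometry, a fixed 1 ms window.

Two published quantitative anchors are *not* reproduced, and the
discrepancies are structural rather than statistical:

- **Attached-count law.** Counts of attached myosins are exactly
  Poisson-binomial (a sum of N independent Bernoullis with duty ~r), i.e.
  under-dispersed relative to Poisson by a variance factor ≈ (1−r). At the
  historically used 1000-sample resolution a χ² test cannot tell the
  difference (p = 0.24–0.74 at N = 100); at 10⁴ samples it can
  (p down to 10⁻³). The Poisson description is the sparse limit, not the
  model's exact law, and the corresponding acceptance test at 10⁴ samples
  is left failing by design.
- **Master-curve coefficients.** Within this engine, per-isoform
  ln-lifetime grows linearly in N — both the zero-attachment probability
  (1−r)^N and the probability that a gap survives the 1 ms window
  contribute ≈N to the exponent — so in E\* ∝ N² coordinates the curves
  are √E\*-like (local slopes fall from 6.5×10⁻⁴ at E\* ≈ 1.5×10³ to
  2.9×10⁻⁴ at 1.3×10⁴, tracking 1/√E\*). A single exponential fitted over
  lifetimes of 20–500 ms yields A ≈ 9–11 ms and B ≈ 3.0–3.2×10⁻⁴ s
  (r² ≈ 0.95), against published values A ≈ 14.5, B ≈ 4.5×10⁻⁴. The
  lifetime scale cannot be raised honestly: gap-survival is controlled by
  the per-passage binding probability, which the x_z anchor pins. The
  collapse itself — the scientific claim that equal E\* implies equal
  lifetime across isoforms, including k_off variants that diverge badly in
  P_C coordinates — reproduces well; the fitted constants differ.

## Protocol scales

Desk-scale defaults: 200 runs per lifetime point, three ensemble sizes per
isoform spanning mean lifetimes ~20–500 ms (chosen by pilot batches of ~40
runs, interpolating ln P against N²), required-energy searches at 200 runs
with a geometric bracket before the unit scan. Publication-scale protocols
(1000 runs, lifetimes to 1 s and beyond, unit-increment searches from
N = 2 via `coarse=False`) are plain parameter choices on the same
functions; nothing is gated. With the numba kernels the full desk-scale
acceptance surface runs in minutes on one CPU.

## Known limitations

- No load on the filament, hence no force–velocity inversion for loaded
  systems; velocity is an input everywhere.
- No filament compliance, diffusion, or 3-D geometry; the dissociation
  window is a fixed constant rather than a viscosity model.
- dX = 1 nm quantises the binding window (see above); results at
  k·dT ≳ 0.3 should be treated as coarse.
- Agents never interact; crowding effects at high surface densities are
  out of scope.
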