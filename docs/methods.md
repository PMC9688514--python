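# Methods

## Model

The package integrates a five-compartment ODE system coupling four CAR-T
phenotypes to a logistic tumor (equations in the README). The biological
picture: an infused bolus `CD` mostly dies (rate `β`) and engrafts only at a
small rate `η ≪ β`; engrafted effectors `CT` proliferate on antigen contact
at the time-dependent rate `κ(t)·F(T)`, convert to long-lived memory `CM`
(rate `ε`), re-convert on antigen encounter (`θ·T·CM`), and lose function to
the exhausted pool `CE` (rate `λ`), which is cytotoxically inert and dies at
`δ`. Both distributed and effector cells kill tumor cells through the
saturating cytotoxicity `γ·f(CF,T)`.

The cytotoxicity function is `f(CF,T) = CF/(ϑT + a + CF)`. This is the
unique reading of the saturation consistent with both asymptotic regimes —
killing limited by the number of killers (`γ·f·T → γ·CF/ϑ` when `T ≫ CF`)
and by the available targets (`→ γ·T` when `T ≪ CF`) — and with a
dimensionless `ϑ`.

Initial conditions: the infused dose enters `CD` impulsively at its
scheduled day (so `CD(0)` equals a day-0 dose), all other CAR-T phenotypes
start at zero, and the tumor starts at `T(0) = 1e7` cells by default.
Split dosing follows the clinical 3-day 10%/30%/60% regimen; fractions that
do not sum to one are used verbatim with a warning, never renormalised.

## Numerics

The system is integrated with the classical fixed-step RK4 scheme,
JIT-compiled inner loop, internal step `dt = 1e-3` day for oracle-grade
runs and `1e-2` day inside fitting loops (the step-halving test shows
relative changes below 1e-6 at `1e-3`, and agreement with a tight-tolerance
adaptive reference integrator to better than 1e-5 wherever populations
exceed one cell). States are recorded on a sparse output grid (default
0.1 day) and small negative excursions are clipped to zero at output
samples, with the worst pre-clip excursion reported as a diagnostic.

Populations are continuous cell numbers; nothing enforces extinction at
sub-cell densities. Two consequences are handled explicitly:

* **Atto-cell artifacts.** A crushed tumor can reach absurdly small
  continuum values and later "regrow" from them. This is a known property
  of such models and is left intact — it underlies the theoretical-relapse
  clock — but comparisons against reference integrators are made only above
  one cell.
* **Post-escape stiffness.** If the tumor escapes toward its carrying
  capacity (`1/b = 1e12` cells), the bilinear memory-reconversion term
  `θ·T·CM` can reach thousands per day and the dynamics become stiff and
  clinically meaningless. Simulations whose purpose is relapse detection or
  outcome classification therefore stop once `T` exceeds twice its initial
  burden: any detection-threshold up-crossing has already happened by then,
  and a patient in that state is progressive disease.

## Phase analysis

Segmentation is automated and deterministic: the expansion/contraction
boundary is the global maximum of the log counts (earliest on ties), the
distribution/expansion boundary the pre-peak minimum, and the
contraction/persistence boundary the split minimising the two-segment
log-linear SSE over the post-peak points, accepted only when BIC favours
two segments over one (so a single post-peak line yields contraction only).
Manual breakpoints can be supplied through `peak_hint` and by constructing
`PhaseSegmentation` directly.

Slopes are OLS of ln(count) against time within each phase. Two refinements
matter in practice, because the true dynamics are only asymptotically
log-linear inside each phase: the shared extremum samples (nadir, peak) are
excluded whenever two other points remain, and densely sampled phases are
fitted on their most log-linear contiguous sub-window (at least 60% of the
points, best SSE per degree of freedom). Exact piecewise-linear data are
unaffected by either rule. On the timescale-separated reference parameter
set, the full segment→slope→estimate chain recovers `β` to ~3%, `δ` to
~11%, `μ` to better than 1%, and the compound `p1 + r_min` to ~26% — the
expansion identification `m_e ≈ r_min + p1 − ξ` systematically ignores the
conversion and exhaustion outflows `ε + λ` and therefore under-estimates by
that amount, which is why its tolerance is looser.

The effector death rate `ξ` is not identifiable from the expansion slope
alone and must be assumed (package default 0.3/day); it is fixed during
refinement.

## Calibration

The loss is the sum of squared log10 residuals of the total CAR-T
population at the detectable observations; censored points (at or below the
detection threshold) are excluded entirely. The procedure is the multi-step
strategy suggested by the phase analysis:

1. **β from the distribution phase, dose-anchored.** For a single day-0
   dose the initial condition `C(0) = dose` is known exactly, so
   `β̂ = Σ tᵢ·ln(dose/Cᵢ) / Σ tᵢ²` over the pre-nadir detectable points.
   This anchored estimator is substantially more precise than a free joint
   refit of `β` (which trades against the expansion parameters) and `β` is
   held fixed at it.
2. **Slope seeding.** The remaining slope identifications seed `δ`, `μ` and
   `p1` (given the assumed `ξ`).
3. **Bounded multi-start least squares** (trust-region reflective, log10
   parameter space, deterministic jittered starts) refines the free set.

The free set adapts to the data (`free="auto"`): parameters of phases the
record never samples stay at package defaults instead of drifting to a
bound, and the number of free parameters is capped at two fewer than the
number of detectable points. This matters because the observable — total
`C(t)` only — cannot distinguish which compartment carries the slow tail:
unconstrained refits slide along a `δ`/`μ` compensation ridge and reach
losses *below* that of the true parameters. Only the slope-identified
quantities (`β`, `δ`, `μ`, `p1 + r_min`) should be interpreted; `θ`, `α`,
`ε` and friends are reported as one member of a non-unique set.

Fixed-by-default constants are package-level assumptions, not fitted
values: tumor growth `r = 0.1`/day, carrying capacity `1/b = 1e12` cells,
kill rate `γ = 1`/day, `ϑ = 1`, half-saturations `A = 1e4` and `a = 1e5`
cells, `η = 1e-3`/day, `ξ = 0.3`/day, `ε = 0.02`/day. `A` is deliberately
small so that antigen-driven expansion continues while the tumor is driven
far below the detection threshold, which is what produces peaks one to two
weeks after infusion.

**Outcome-aware fitting.** When kinetic data cannot constrain the late
dynamics, an optional penalty (weight from the caller) pulls the simulated
tumor burden at follow-up into the recorded response class. A recorded
complete response additionally frees the basal rate `r_min` and seeds the
optimiser inside the durable-response region `r_min > ξ + ε + λ` — the only
regime of this model in which the tumor is held down indefinitely — because
relapse-type local optima cannot cross into it. Without the penalty,
model/outcome mismatches are printed in `summary()` and the pipeline table,
never hidden.

## Kinetic outcome metrics

Per-phenotype AUCs are trapezoidal integrals over 28/60/90-day horizons
(the 28-day horizon matches the usual response-assessment time); the
non-exhausted fraction is `(AUC_CD + AUC_CT + AUC_CM)/AUC_total`. The peak
summary reports the argmax of total `C` (earliest grid point on ties), its
phenotype composition and the expansion ratio `C(t_peak)/dose`. The
theoretical relapse time `t_TR` is the first up-crossing of the detection
threshold after the tumor first falls below it, linearly interpolated
between grid points, searched out to 20,000 days; sub-threshold
oscillations whose last three local maxima keep amplitude ratios within
[0.8, 1.25] are reported as a limit cycle (NA), monotone decay as no
recurrence (NA), and a tumor that never fell below threshold as no
remission (NA with a warning-grade reason — the bound is undefined there).
Response classes use the standard definitions with a documented half-open
convention at the boundaries: CR below the detection threshold, PR below
50% of the initial burden, SD within ±50% (boundaries inclusive), PD above.

## Synthetic cohorts

The generator emulates the structure of published CAR-T kinetics datasets:
sparse clinical sampling (days 1, 3, 7, 10, 14, 21, 28, 60, 90, 180, 365),
multiplicative lognormal measurement noise (default 0.2 dex, typical of
qPCR transgene quantification), left-censoring at a 2.5e6-cell detection
threshold (equivalently 25 transgene copies/µg DNA), single or 3-day
split dosing with a 1e8-cell default dose, and `T(0) = 1e7` cells.

Archetypes encode the response regimes:

* **CR** — low exhaustion and a basal expansion rate exceeding total
  effector losses (`r_min > ξ + ε + λ`). This gives a coexistence attractor
  deep below the detection threshold: the tumor is held, or cycles, at
  undetectable levels indefinitely, as observed in decade-long responders.
  Mechanisms that instead balance a *detectable* tumor (strong tumor
  inhibition `α`, or θ-mediated equilibria far above the antigen
  half-saturation) proved violently unstable — relaxation oscillations to
  carrying capacity — and were rejected during design.
* **PR** — strong initial response without the basal reserve: the tumor
  relapses across the detection threshold months after infusion.
* **SD** — substantial raw expansion (as reported clinically for
  stable-disease patients) but heavy exhaustion (`λ = 0.9`/day): the
  exposure is exhausted-dominated and the tumor returns to near its initial
  burden. This makes the 28-day non-exhausted fraction separate CR (~0.56)
  from SD (~0.45) in the direction observed clinically.

Because PR/SD dynamics progress, their follow-up day is set the way clinics
set it — at detection of progression (threshold re-crossing + 5 days for
PR-type, return to 90% of the initial burden for SD-type) — and kinetic
sampling stops at follow-up. Outcome labels are computed from the true
noise-free trajectory, and archetype fidelity is 100% in 25-draw Monte
Carlo per archetype.

Within an archetype, the identifiable rates (`β`, `p1`, `p2`, `δ`, `μ`)
vary log-uniformly between patients (roughly ±25%); the remaining constants
are shared population values equal to the package defaults — the same
convention as fixing literature values during calibration. The priors were
chosen once, during design, so that each kinetic phase is resolvable at the
clinical sampling cadence (distribution half-lives of 0.7–1.7 days against
samples at days 1 and 3; contraction windows of roughly two weeks;
persistence detectable for 100–300 days): parameter recovery is only a
meaningful claim when the phases are in principle observable. Under these
conditions a 20-patient cohort study at 0.2 dex noise recovers `β`, `δ`
and `μ` with median relative errors of roughly 10–25% (seed-dependent),
with `μ` the least precise — its persistence window spans only one to two
e-folds of decay.

What the generator does *not* emulate: assay changes between laboratories,
dose fractionation other than the standard split, inter-occasion
variability, antigen-negative escape (the model has a single
antigen-positive tumor compartment), and immune-competent host effects
(normal T cells, cytokines). Passing recovery tests on these cohorts
therefore demonstrates estimator correctness under the stated noise and
sampling model, not robustness to model misspecification in real data.

## Known limitations

* Only the total CAR-T count is observable; the phenotype decomposition is
  model-inferred and non-unique. Phenotype-resolved metrics (non-exhausted
  fraction, relapse composition) inherit that caveat.
* The continuum ODE cannot represent extinction; sub-cell populations and
  the relapse times derived from them are theoretical constructs.
* The stable-disease regime has no robust detectable-tumor equilibrium in
  this model; SD is a matter of follow-up timing relative to relapse.
* `ξ` is assumed, not estimated; mis-specifying it shifts the inferred
  `p1 + r_min` one-for-one.
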