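# Methods

`tbinflam` analyzes serial cerebrospinal-fluid (CSF) cytokine panels
from severe traumatic brain injury (TBI) patients, contrasting
survivors (12-month Glasgow Outcome Scale > 1) with non-survivors
(GOS = 1). It chains four stages — statistical screening, principal
component analysis, dynamic Bayesian network (DyBN) inference, and
ensemble calibration of a mechanistic ODE model — plus a synthetic
cohort generator that stands in for patient data, which are not
publicly deposited.

## The mechanistic model

Six states on a dimensionless 0–10 scale: damage/DAMPs `D`, activated
inflammatory cells (microglia) `M`, a lumped chemokine pool `C`, and
the cytokines `IL10`, `TNF`, `IL6`:

```
dD/dt    = d0·M − d1·D
dM/dt    = [ m0·D/(1+m1·D) + m2·C/(1+m3·C) + m4·TNF/(1+m5·TNF)
             + m6·IL6/(1+m7·IL6) ] / (1+m8·IL10) − m9·M
dC/dt    = c0·D/(1+c1·D) − c2·C
dIL10/dt = i0·M − i1·IL10
dTNF/dt  = t0·M/(1+t1·IL10) − t2·TNF
dIL6/dt  = b0·M⁶/(1+b1·IL10) − b2·IL6
```

All activation terms saturate; IL-10 suppresses activation globally and
TNF/IL-6 production individually. The sixth power of `M` in the IL-6
equation is a deliberately strong formalism for the self-amplifying
IL-6 feedback the network analyses point to; it is the model's one
aggressively non-linear term and the main source of stiffness. Every
production term carries a factor of `D`, `M` or `C`, so the origin is
an equilibrium and the non-negative orthant is forward-invariant.

There are 23 rate/saturation constants plus two estimated initial
conditions (`init_M`, `init_C`) — 25 free parameters. Admission GCS
maps linearly to initial damage (GCS 15 → 0, GCS 3 → 10; the linear
interpolation is the simplest map through the two stated anchors).
Cytokine initial values are taken from the group-mean data at t = 0
rather than estimated — only `M` and `C` lack a measured counterpart.

Integration uses LSODA (via `scipy.integrate.odeint`) at
rtol 1e-8 / atol 1e-10 by default (1e-6 / 1e-8 inside the fit loop,
where hundreds of solves per simplex run are needed). Negative
excursions within 1e4·atol are attributed to round-off and clipped;
anything larger raises a solver-failure error naming the parameter
set — large negative states indicate a genuinely failed integration,
not noise. The observation window is 0–120 h (the 5-day ICU sampling
period); the survival/death damage anchor (0 or 10) is applied at
t = 120 h, since the data specify no explicit time for "final" damage.

## Cohort handling

Clinical tables (`patient_id, age, sex, gcs, gos6, gos12`) and
long-format mediator tables (`patient_id, mediator, time_h,
conc_pg_ml`) are validated on read: mediator names are matched
case-insensitively against the 13-analyte panel (Greek letters spelled
out), malformed rows are reported and dropped, rows referencing unknown
patients are hard errors, and outcome groups are derived from GOS12
(any supplied label must agree).

Normalization is per-mediator min–max to [0, 10], computed over both
outcome groups jointly so the groups share one scale (and share the
damage variable's 0–10 range). The stored per-mediator min/max allow
exact de-normalization. Group mean curves at the six fit times (0, 17,
35, 60, 82, 104 h) assign each patient the nearest sample within
±12 h; unmatched cells are missing and excluded from the mean. The
±12 h window is half the median gap between fit times — wide enough
that the jittered sampling schedule almost always matches, narrow
enough that a sample cannot serve two neighboring fit times badly.

## Screening and PCA

Because sampling is irregular across patients, values are first
averaged into five 24-h bins (shared with the DyBN stage). Per
mediator the screen reports: a two-sided Welch t-test (unequal
variances — the groups are ~29 vs ~5), a two-way fixed-effects ANOVA
of group × time-bin with type-II sums of squares (robust to the
unbalanced design), and the AUC fold change (trapezoidal area under
the non-survivor group-mean curve over the survivor one, at the six
fit times). The significance flag is the interaction p-value at
α = 0.05, with no multiple-testing correction. Under a pure-noise null
the interaction flag rate calibrates to ≈5%; a non-survivor-specific
linear time trend of 3 within-cell standard deviations over the window
is detected with power > 0.9 at these group sizes.

PCA treats each complete patient×bin observation as a point in
13-dimensional mediator space (centered, full SVD). Mediators are
ranked by the maximum absolute loading over the first k components,
ties broken by panel order.

## DyBN inference

The discretized panel (per-mediator tertiles over all patients and
slices) is modeled as a stationary first-order discrete Markov chain
over the five 24-h slices: candidate parents of mediator X at slice
t+1 are the mediators at slice t, X itself included. The four slice
transitions are pooled; structure is learned per child by greedy
hill-climbing (single-parent additions/removals, at most 3 parents) on
the BDeu score with equivalent sample size 1. BDeu was chosen over BIC
after calibration on planted-structure fixtures: BIC's fixed penalty
either missed two-parent families or, when uniformly lightened,
admitted spurious edges on independence fixtures; BDeu at ess=1
recovers the planted IL-6/IL-8 switch motif in ≥90% of seeded runs
with no spurious edges on the null. CPDs are maximum-likelihood with
add-one smoothing. Transition records are complete-cases over the full
candidate panel so competing parent sets are scored on identical data.
All edges point forward in time by construction.

Central nodes follow the switch-motif rule: a mediator with a
self-edge that also exchanges at least one edge with another
self-edged mediator, ranked by total degree.

## Ensemble calibration and fold changes

Each group's fit target is: the group-mean TNF-α/IL-6/IL-10 curves at
the six fit times, initial damage from the rounded group-mean GCS, and
the terminal damage anchor. The objective is the plain Euclidean
distance between the concatenated simulated and target vectors (19
coordinates: 3 cytokines × 6 times + terminal damage).

Optimization is Nelder-Mead on log-parameters (positivity for free),
with an upper box bound of 10² on every parameter: without it the
simplex occasionally wanders to extreme, degenerately-compensating
values that then dominate ensemble means. Each of the n ensemble fits
draws a seeded pool of log-uniform candidates on [10⁻³, 10] and starts
from the pool's best — random initialization with screening, in the
spirit of "random or previously estimated" starting points. The
iteration budget is split over restarts (default 3) because a
25-dimensional simplex degenerates long before convergence; restarting
around the best point recovers progress. An optional multi-start stage
(`n_starts` > 1) runs a short exploratory simplex from the few best
pool candidates and spends the main budget on the winner; this is the
cheap reliable way past the model's worst local trap, the flat basin
in which sixth-power IL-6 production is numerically zero and the
simplex sees no gradient toward producing IL-6 at all (its objective
plateaus at exactly the norm of the IL-6 target). The direction-
recovery checks use `n_starts = 3`. A fit counts as converged
when it reaches a finite objective (solver failures are +inf); fit
*quality* is policed by the ensemble trim, not by the flag, because at
this dimensionality the tolerance-based termination criterion is never
met within any practical budget.

The trim removes the worst ceil(0.25·n) fits by objective
(non-converged fits count toward the quota first), reproducing the
100 → 75 ensemble arithmetic. Fold changes are per-parameter ratios of
accepted-fit arithmetic means, survivor over non-survivor, sorted
descending (a geometric-mean variant is available behind a flag). With
25 parameters constrained by three curves and two damage anchors the
fit is deeply under-determined; the supported claim is *direction
recovery* of the strongly shifted parameters (d1 and i0 above 1, d0
and init_M below 1 when the generator plants those shifts), not point
estimation. Point values of individual parameters should not be
interpreted.

## The synthetic cohort generator

Each virtual patient draws a GCS from {3..8} (mean ≈ 6, the severe-TBI
range), a patient-specific log-normal perturbation (σ = 0.2) of the
group parameter set, a simulated trajectory, and 8–15 samples at times
jittered (±4 h) around the six fit times plus uniform extras, with
multiplicative log-normal measurement noise (σ = 0.3, a typical
Luminex replicate CV). Default cohort sizes are 29 survivors and 5
non-survivors.

The survivor base parameter set was calibrated once so the simulated
course reproduces the qualitative timing reported for CSF mediators:
median TNF-α and IL-10 peaks before 20 h, median IL-6 peak near 30 h
(across noisy patients), and survivor damage decaying toward 0 by
120 h from a GCS-6 start. Non-survivors shift exactly four parameters,
by the reciprocals of the headline survivor:non-survivor fold changes
(d0 ×1/0.17567, init_M ×1/0.263824, d1 ×1/3.538564, i0 ×1/2.701914),
giving direction-recovery tests a known ground truth: more damage
production and more baseline microglia, slower damage clearance and a
weaker IL-10 response.

Model outputs feed the measured panel as TNF→TNF-α, IL6→IL-6,
IL10→IL-10 and C→{IL-8, MIP-1α, MIP-1β} (scaled copies); the seven
analytes the model does not describe (IL-1α/β, IL-2, IL-4, IL-5,
IL-13, VEGF) are damage-scaled baselines with noise. Per-mediator
pg/ml scales make IL-6 and IL-8 the high-abundance analytes
(>1000 pg/ml), as in real CSF panels. The generator does **not**
emulate: absolute pg/ml magnitudes of any specific dataset, missing
visits/dropout, assay floors and ceilings, treatment effects, or
inter-mediator correlations beyond what the six-state model induces.
Passing tests therefore demonstrate that the pipeline recovers
structure *of the kind the model can express*, not that it would
recover every structure present in real CSF data.

A separate fixture generator (`plant_dybn_cohort`) produces
slice-structured panels where planted children are noisy averages of
their parents (Gaussian, sd 0.75 on the 0–10 scale) and everything
else is independent — ground truth for DyBN recovery and
false-positive tests.

## Problem sizes and numerical choices

Test-suite and acceptance runs use reduced ensembles (n = 8 fits per
group, ~3000 simplex iterations over 5 restarts, noise-free cohorts)
— the package's own smoke configuration for the direction-recovery
property; larger ensembles sharpen the fold-change table but do not
change the recovered directions. DyBN recovery uses 20 seeded
30-patient fixtures; ANOVA calibration uses 400 null and 200 planted
replicates; PCA block recovery uses 40 replicates of 200 observations.
Ties in peak times resolve to the earliest sample; ties in mediator
rankings resolve to panel order; the trim quota rounds up.

## Known limitations

* The fold-change table inherits the under-determination of the fit;
  only signs/directions of the strongly shifted parameters are tested,
  and not all of them are recoverable. In particular `init_M` — the
  initial level of the unobserved cell population — is forgotten by
  the dynamics on the ~1/m9 ≈ 4 h timescale while the first
  post-baseline fit time is 17 h, so equally good fits scatter over
  roughly [0.03, 3] regardless of the generating value (0.1 vs 0.38).
  At desk-scale ensembles its fold-change direction is effectively a
  coin flip, and the dedicated direction-recovery test documents this
  by failing on that component; d1, i0 and d0 recover robustly.
* The DyBN learner assumes a stationary transition structure pooled
  across patients within a group; per-patient heterogeneity in network
  wiring is invisible to it.
* The ANOVA is a fixed-effects approximation that ignores
  within-patient correlation across bins; with ~5 non-survivors a
  mixed model would not be estimable anyway.
* GCS→damage and the terminal anchors compress outcome heterogeneity
  to the interval ends; GOS 2–5 survivors all anchor at damage 0.
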