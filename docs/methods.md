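# Methods

## Models

All concentration axes are molar; all fitted concentration parameters
(log K_D, log IC50, log EC50) are optimized on the log10 scale inside the
box [−13, −2], so their standard errors are Gaussian on the scale the
results are reported on. Every curve is unit-slope (Hill coefficient 1),
matching the equation forms the fits implement; steeper or shallower
empirical slopes are out of scope.

**Binding.** Specific binding is computed per plate as
(well − mean nonspecific), normalized to percent of
(mean total − mean nonspecific). Saturation data are fit as
`SB = Bmax·A/(A+K_D)` on the raw specific-binding scale with matched
per-concentration nonspecific wells; competition data as
`100 − 100·A/(A+IC50) + NS` on the percent scale, with `NS` bounded to
[0, 100]. If no concentration inhibits at least half the specific window
the result is censored (`log IC50 > log top concentration`), never
extrapolated. Cheng–Prusoff converts IC50 to K_D; censoring propagates
through the correction with its direction.

**Functional curves.** Reporter signal is normalized affinely to percent
of the 10 µM isoprenaline window,
`100·(well − mean basal)/(mean positive − mean basal)`. Replicate wells
are fit jointly (unweighted), preserving n for standard errors. The
two-site stimulatory fit is constrained to `log EC1_50 < log EC2_50` and
multistarted on a deterministic lattice of split points (the objective is
multimodal); the one-site solution is included as a degenerate start so
`RSS(two-site) ≤ RSS(one-site)` holds by construction. The dip fit holds
basal and the fixed-reference ("control") level at their measured plate
means and fits only `log IC50`, `log EC50` and `S_max`.

**Model selection** ("best described by"). Nested extra-sum-of-squares
F-tests at α = 0.05: flat ⊂ one-site ⊂ two-site, and, when a fixed
reference agonist is present, inhibition-only / stimulation-only ⊂ dip
(both components must be individually significant and the fitted curve
must actually dip, `log IC50 < log EC50`). Two refinements make the
one/two-site comparison statistically honest on plate data:

1. *Baseline nuisance.* Normalization subtracts a basal mean estimated
   from n_basal (default 6) wells, so the normalized curve's true baseline
   is uncertain by σ/√n_basal. Both competing models carry a baseline
   offset penalized by exactly that uncertainty (a Gaussian
   pseudo-observation). Without it, ordinary basal error masquerades as a
   small saturated "site" and inflates the two-site false-positive rate
   several-fold.
2. *Admissibility.* The decision fit is restricted to resolvable
   two-site shapes: components ≥ 1 log unit apart, each carrying ≥ 10% of
   the response, the first component's EC50 at least 1 log above the lowest
   tested concentration (a component whose rise is unobserved is
   indistinguishable from baseline), the second's no more than 0.5 log
   above the highest (otherwise it is a rising trend, not a quantifiable
   site), and the minor component's absolute amplitude at least
   2.5·σ̂/√n_replicates above zero (σ̂ from the within-concentration
   replicate scatter). When the F-test is significant but the shape
   inadmissible, the curve is reported one-site with the diagnostics
   attached — the conservative tie-break.

   `NormalizedCurve.n_basal` carries the number of wells behind the
   baseline estimate; curves constructed directly on the percent scale
   (simulation studies) can declare an exactly known baseline with a large
   `n_basal`, which pins the nuisance at zero.

Measured operating characteristics at the default design (13 half-log
concentrations, triplicates, 5% noise): false two-site calls ≈ 1–3% per
curve; detection of the weakest published biphasic curve (first component
5.5% of the window) ≈ 97% when the published replication (7 experiments)
is pooled, as the source study's fits were.

**Shift analyses.** Dose ratios use fitted EC50s only, so they are
invariant to response-axis scaling. Gaddum estimates combine several
antagonist concentrations as the mean of per-concentration log K_Ds; a
shift below DR = 1.2, or within 2 pooled EC50 standard errors of zero, is
reported as the censored "no shift at [B]" rather than an extrapolated
value. Schild regression is ordinary least squares through
(log[B], log(DR−1)) with DR ≤ 1 points excluded (warned); the x-intercept
gives log K_D and the fit is flagged competitive when the slope's 95%
interval covers 1. Stephenson's method reads A1/A2/A3 by inverse
interpolation of the fitted control and combined curves at five evenly
spaced response levels between (plateau + 5 points) and 90% of the control
maximum, averaging the per-level K_Ds in log space with their spread as
the SE. On exact unit-slope competitive curves the per-level values are
identical; the estimate carries a small positive bias of order
log(1 + A1/K_agonist), negligible when the partial agonist's plateau is
low.

## Evidence rubric and classification

Calls are made per cell line and pooled (positive anywhere ⇒ positive;
negative only if tested and negative everywhere; missing data give
indeterminate, never negative). Affinity estimates transfer between cell
lines expressing the same receptor: a K_D is a receptor property, and the
rubric's A call in a low-expression line legitimately uses the binding K_D
measured in the high-expression line.

* **A** — gap = log EC50 − log K_D(CCE) ≥ 1.0 log unit and > 2 pooled SEs.
  The CCE K_D is the most reliable available (functional
  Stephenson/Gaddum/Schild over binding). For two-site curves the first
  component's EC50 is used — a biphasic compound's first component sits at
  the CCE K_D, so A stays negative there and the biphasic evidence is
  carried by C. An EC50 within 0.6 log of the top tested concentration has
  no defined plateau and yields indeterminate.
* **B** — gap = log K_D(reference antagonist vs test response) −
  log K_D(same antagonist vs reference CCE agonist, same line) ≥ 1.0 and
  > 2 pooled SEs.
* **C** — the compound-alone curve selected two-site.
* **D** — the fixed-reference design selected the dip model; absent that
  design D is indeterminate, never negative.

The 1.0-log thresholds sit between the observed positive gaps (≥ 1.9) and
negative gaps (≤ 0.8) with margin on both sides and are configurable
(`Thresholds`). Classification order: `no_interaction` (no affinity better
than 10 µM anywhere — the same ≥ −5 log-molar region that defines a
non-binder — and no agonism) → `neutral_antagonist` (binds, no fitted
agonism; agonism requires a fitted maximum ≥ 10% of the isoprenaline
window, below which a curve is treated as noise) → `biphasic_agonist` (C)
→ `sce_agonist` (A with B, or D, or A with B untestable) → `cce_agonist`.
An agonist whose measured affinities are all censored is flagged as
contradictory rather than classified. The wild-type vs mutant contrast
lists criteria positive in the first background and negative in the
second; `sce_lost` flags loss with retained CCE-type pharmacology.

## Simulator

Ground truth per compound: a log K_D and an intrinsic efficacy e ∈ [0, 1)
per conformation, plus a mode (neutral / cce_agonist / sce_agonist /
biphasic / nonbinder). A single receptor-reserve scalar per cell line
(R, `receptor_expression`) turns these into observable components through
τ = R·e/(1−e), Emax = 100·τ/(1+τ), EC50 = K_D/(1+τ): raising expression
makes responses proportionately greater and left-shifts EC50s while each
component stays an exact unit-slope hyperbola, so noiseless simulation
followed by the corresponding fit recovers the generating parameters to
optimizer tolerance. Components below 2.5% of the window (half the default
noise SD) are below what a triplicate plate resolves and are not emitted —
a low-expression line shows a genuinely monophasic curve even when the
compound has a trace of efficacy at the other conformation. Summed maxima
are capped at the system maximum.

A fixed antagonist right-shifts each component by the Gaddum factor of the
conformation it acts on, and contributes its own constant response if it
has efficacy (which is what makes the cimaterol-plus-fixed-partial-agonist
Stephenson design work). A declared non-binder shifts nothing. Against a
fixed reference agonist the compound produces the composite dip curve with
IC50 equal to its CCE K_D Gaddum-shifted by the reference occupancy.

Noise is additive Gaussian per well with SD a fraction (default 0.05) of
the positive-control window, on controls as well as test wells; signals
are clipped at zero. Randomness derives deterministically from
(config, seed, experiment label), so identical configurations are
bit-identical. Default grids: half-log 10⁻¹¹–10⁻⁵ M for functional
curves (10⁻¹⁰–10⁻⁴ for shift designs and binding, matching the higher
antagonist concentrations those designs need).

**The study fixture** (`make_study_fixture`) instantiates the full
19-compound panel in a low-expression (luciferase-type, R = 1) and a
high-expression (SPAP-type, R = 14.5 ≈ the 1146/79 fmol·mg⁻¹ expression
ratio) line, plus wild-type and TM4-triple-mutant mixed-population lines
(R = 10) for the loss-of-evidence contrast. Affinities come from the
tabulated binding/shift values and efficacies from inverting the reserve
transform at the line that characterizes each component best; where a
single R cannot reproduce every printed EC50/Emax pair across lines
(the published data do not follow a one-parameter reserve model exactly),
component sizes were balanced so that every classification margin is
≥ 0.5 log units or ≥ 3× the detection floor at the default noise — the
fixture is a study *like* the published one, not a digitization of it. In
the mutant background the secondary conformation is absent and former SCE
agonists appear as weak conventional CCE partial agonists with their
published mutant potencies.

What the simulator does **not** emulate: Hill slopes ≠ 1, kinetic
(time-resolved) binding, well-position effects, plate-to-plate drift,
receptor-expression heterogeneity within mixed populations, and operational
transduction beyond the single reserve scalar. Passing tests therefore
demonstrate correctness of the estimators and decision logic under the
stated noise model, not robustness to every artefact of real plate data.

## Problem sizes and numerics

The test suite and acceptance script use: 100 simulated curves per
stochastic operating-characteristic estimate; 8-point instances for
grid-search oracle comparisons (200×200 grids, amplitudes profiled in
closed form for the two-site oracle); single triplicate plates everywhere
except the biphasic-detection study, which pools 7 triplicate experiments
per curve as in the published fits. Optimizer tolerances are 10⁻¹⁴
(xtol/ftol/gtol) so noiseless round-trips close to < 10⁻⁴ log units.
Degenerate inputs (flat curves, zero windows, censored series, DR ≤ 1
points) raise or censor explicitly rather than returning silent numbers.
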