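# Methods

## Scope and model

`fpetki` quantifies task-specific changes in cerebral 6-[¹⁸F]FDOPA trapping —
an index of dopamine synthesis capacity — from a single dynamic PET
acquisition with a bolus + constant-infusion (B+I) administration. The tracer
follows the irreversible two-tissue compartment model

    dC₁/dt = K₁·Cp − (k₂ + k₃(t))·C₁
    dC₂/dt = k₃(t)·C₁

with delivery K₁ (mL·cm⁻³·min⁻¹), washout k₂ (min⁻¹) and trapping k₃ (min⁻¹,
decarboxylation by AADC). The net influx constant is Ki = K₁k₃/(k₂+k₃).
Cognitive task blocks modulate k₃ additively and piecewise-constantly: the
premise is that neuronal firing upregulates the synthesis enzymes, so a task
block raises the trapping rate for its duration and the extra trapped
activity persists afterwards.

The measurement equation used everywhere is

    measured(t) = (1 − vB)·(C₁ + C₂ + C_omfd)(t) + vB·C_wb(t)

with a fixed whole-blood fraction vB = 0.05 and C_omfd the brain signal of
the peripheral metabolite 3-OMFD, modelled as a one-tissue system with
brain-wide uniform kinetics driven by the metabolite plasma curve.

## Pipeline

1. **Input functions.** The plasma/whole-blood ratio is a linear OLS fit to
   the per-sample ratios, evaluated clamped at ≥ 0. The 3-OMFD plasma
   fraction starts from a pure-bolus fraction curve (a configurable input,
   tabulated or from the parametric blood model) and is adapted to B+I by
   superposition: total and metabolite responses are administration-rate
   convolutions of the bolus responses, and the adapted fraction is their
   ratio. Parent input = whole blood × ratio × (1 − fraction); metabolite
   input = whole blood × ratio × fraction, so parent + metabolite equals
   total plasma exactly on the grid.
2. **Reference-region fit.** The occipital (trapping-free) TAC is fitted
   with a one-tissue model by multi-start nonlinear least squares in log
   space. Two modelling choices matter here. First, the fit is driven by
   *total* plasma: under the stated assumption that the distribution
   volumes of 6-FDOPA and 3-OMFD are equal in the reference region, both
   plasma species see the same impulse response, and fitting against the
   parent input alone would absorb the metabolite signal into biased
   parameters. Second, adjustment for task and motion uses the same task
   ramp and motion regressors as the uptake GLM, but they enter the
   one-tissue model linearly with profiled-out coefficients, the reference
   baseline being the one-tissue model itself. Subtracting components
   fitted with the gray-matter baseline regressor instead would distort the
   reference curve badly whenever the gray-matter average has a trapping
   shape the reference cannot share.
3. **Metabolite correction.** The brain 3-OMFD curve is the fitted impulse
   response convolved with the metabolite input, frame-averaged, and
   (1 − vB)-scaled before subtraction from every TAC. Negative residual
   values are permitted and counted in the QC report. The blood component
   is then removed explicitly: tissue = (measured − vB·wb)/(1 − vB).
   Without this step every Ki would inherit a (1 − vB) bias.
4. **GLM.** TACs and the design matrix are low-pass filtered identically
   (zero-phase FFT raised-cosine, half-power at the 2.5 min period,
   transition band 0.82–1.32 f_c, mirror padding; the common linear filter
   leaves noise-free coefficients unchanged). The design holds one
   ramp-and-hold regressor per block — the exact frame average of the
   continuous unit-rate ramp, slope 1 kBq/frame inside the block, held
   afterwards because trapped activity persists — plus the baseline
   regressor (unweighted mean of non-excluded gray-matter series) and the
   first principal component of the six motion parameters. No
   orthogonalization; collinearity is surfaced as the design's condition
   number.
5. **Patlak.** The baseline component is transformed to normalized time
   x = ∫₀ᵗCp/Cp and normalized activity y = C/Cp at frame midpoints
   (trapezoid integral on the input grid) and fitted by OLS from
   t* = 25 min (midpoint ≥ t*, inclusive). Task influx per block uses the
   normative beta conversion Ki_j = β_j/(Δt_frame·C̄p,j); the equivalent
   Patlak-difference construction (baseline + whole-scan ramp, slope
   difference) is computed as a cross-check and agrees with the beta rule
   to well under 2% whenever the parent plasma is near-flat.
6. **Condition averaging.** Per-block Ki are weighted by task performance
   (gain blocks: actual/possible gain; loss blocks: avoided/avoidable
   loss) and averaged per condition; the unweighted variant is reported
   alongside. Percent signal change is Ki_task/Ki_baseline × 100.

## Behavioral analysis

Reaction times from the monetary incentive delay (MID) task are
mean-centered within block (the adaptive staircase makes absolute RTs
non-stationary). The RT-versus-amount relation is modelled by forward
stepwise polynomial regression up to second order: candidate terms
{amount, amount²} enter in order of smallest OLS p-value while below
α = 0.05, with no removal step, and the final model is refitted with all
selected terms. Group-level fits pool trial-level data across subjects;
subject-level fits reuse the group-selected terms. Accumulated gain/loss
and group contrasts use two-sided t-tests with Bonferroni–Holm step-down
correction over the declared test family (every row of a test table).
Brain–behavior associations use Spearman correlation; for n ≤ 9 the
two-sided p-value is exact by complete enumeration of orderings, with
average ranks for ties.

## Synthetic data generator

The generator produces everything the pipeline consumes, with ground truth
recorded for recovery testing.

* **Blood.** The unit-bolus parent response is a sum of exponentials
  (default 40·e^(−0.08t) + 10·e^(−0.6t) kBq/mL per unit activity); the
  metabolite response follows by first-order conversion (k_met = 0.012/min)
  with its own clearance (0.02/min). Responses and their integrals have
  closed forms, so B+I curves are exact superpositions. The dominant
  0.08/min clearance equals (1−f_b)/(T_inf·f_b) for the default 20:80 split
  over 50 min, making the late parent plasma an almost exact plateau — the
  design goal of B+I. The plasma/whole-blood ratio is 1.10 + 0.0015·t.
* **Tissue.** The compartment systems are solved by exact exponential
  stepping of piecewise-constant inputs on a 1 s grid (segment values are
  trapezoid means), which doubles as the convolution oracle; agreement
  with an adaptive ODE solver is ~10⁻⁸ relative. TACs are frame-averaged
  with the conservation identity built in, and optional Gaussian noise is
  seeded per region.
* **Default grid and kinetic regime.** One task-modulated target (ventral
  striatum), six gray-matter regions and one reference region. Gray matter
  shares (k₂, k₃) with the target, with baseline influx scaling with
  delivery K₁ (0.8–1.2×), so the gray-matter average is
  shape-proportional to the target's baseline uptake — exactly the
  assumption the GLM baseline regressor makes. The reference region uses
  K₁ = 0.06, k₂ = 0.05 (also the uniform metabolite kinetics). Target and
  gray matter default to K₁ = 0.6, k₂ = 12/min: a deliberately
  fast-exchange regime (free-compartment time constant ≈ 5 s) in which
  the ramp regressor's premise — an uptake-rate change that is constant
  within a block — holds to better than 2%. With literature-like slow
  FDOPA exchange (k₂ ≈ 0.05/min) the free compartment equilibrates over
  tens of minutes, the block response lags the ramp substantially, and
  block-wise estimates from a 5 min block are biased by tens of percent;
  passing recovery tests in the fast regime therefore validates the
  pipeline's algebra and plumbing, not the short-block identifiability of
  real FDOPA kinetics.
* **Motion.** Stationary frame-to-frame jitter (sd 0.02 mm/deg). Motion
  does not couple into the TACs (image-domain motion effects are out of
  scope); the regressor tests that the GLM tolerates the nuisance column.
  A random-walk trace is deliberately avoided as its first principal
  component is near-collinear with the baseline/ramp trend.
* **Behavior.** The MID staircase shortens the limit by one step (20 ms)
  after each hit and lengthens it after each miss, holding the hit rate
  near 0.5. Separation of conditions applies one-time limit adjustments at
  the beginning and middle of each block (+150 ms in gain blocks, −150 ms
  in loss blocks), which the staircase then gradually erodes — so gain
  blocks end with net wins and loss blocks with net losses. Amount
  magnitudes default to {1, 2, 3} currency units; the currency scale is
  arbitrary. Trial logs are fully replayable from the seed.

What the generator does *not* emulate: image formation (attenuation,
scatter, resolution, reconstruction noise correlations), head-motion image
effects, anatomical heterogeneity, dispersion/delay of the arterial line,
or violations of the metabolite-uniformity assumptions (except where a
test injects one deliberately). Passing recovery tests therefore
demonstrates internal consistency of the estimation chain under the
model's stated assumptions, not robustness to the full physics of real
acquisitions.

## Numerical choices

* Internal grid 1 s; time unit minutes; activity kBq/mL; files store
  seconds and declare units in header comments.
* Reference fit: 10 log-space multi-starts on a fixed log-uniform grid
  over [10⁻⁴, 2]², tolerances 10⁻⁸, lowest converged residual wins;
  delta-method covariance is reported.
* Patlak inclusion is midpoint ≥ t*, inclusive; ≥ 3 points required.
* Blood curves are linearly interpolated, constant-extrapolated past the
  last sample, with a configurable margin (default 5 min) beyond which the
  grid is rejected.
* Degenerate inputs (zero plasma, empty baseline set, rank-deficient
  design, all-zero weights, zero-variance groups) raise structured errors
  or take exact fast paths rather than returning NaN.
* Determinism: the pipeline draws no random numbers; the generator derives
  fixed per-component substreams from the session seed.

## Problem sizes used in validation

Recovery suites run noise-free single-target sessions (50 one-minute
frames, 8 regions, 1 s internal grid — a few seconds each); the group
machinery uses 7 such sessions; behavioral selection rates use 200
replicates of 1080 pooled trials. These sizes make each recovered quantity
sharply identified while keeping the whole suite quick to run.

## Known limitations

* The fast-exchange generator regime is a validation device; absolute
  realism of rate constants is explicitly not claimed (see above).
* The beta-conversion/Patlak-difference equivalence, and the flatness of
  performance of the GLM generally, degrade if the parent plasma deviates
  strongly from a plateau (e.g., bolus-only administration).
* The correction module assumes one brain-wide metabolite kinetic pair;
  regional violations propagate into corrected TACs roughly linearly with
  the violation size (covered by a sensitivity test).
* Subject-level percent-signal-change aggregation order (average of
  subject PSCs vs PSC of averages) changes group numbers; both orders are
  available from the per-subject outputs.
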