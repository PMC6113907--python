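# Methods

## Overview

`islethub` simulates pancreatic islets as networks of electrically coupled
β-cells in order to study *hub cells*: a small, highly metabolic
subpopulation whose silencing can abolish coordinated whole-islet Ca²⁺
oscillations.  A run proceeds in five stages: (1) an islet architecture —
3D β-cell positions — is loaded from text or generated synthetically;
(2) a spatial contact graph connects cells closer than 17.5 µm;
(3) the network is parameterised (hub assignment, per-cell glucose,
heterogeneous conductances, per-edge gap-junction conductances);
(4) the coupled ODE system is integrated through a
baseline → inhibition → recovery protocol in which selected cells are
voltage-clamped at −100 mV, mimicking optogenetic (halorhodopsin)
silencing; (5) Ca²⁺ traces are reduced to binary rasters, activity
metrics, and sigmoid dose-response fits whose midpoint is the IC50 — the
inhibited fraction of the islet at which coordinated activity halves.

## The β-cell backend

The per-cell model follows the Cha–Noma current complement.  Membrane
potential obeys

    Cm dVm/dt = −(I_CaV + I_KDr + I_KCa + I_KATP + I_bNSC + I_TRPM
                  + I_SOC + I_NaK + I_NaCa + I_PMCA + I_coup + I_NpHR)

and cytosolic Ca²⁺ follows the flux balance

    d[Ca²⁺]i/dt = (f/v) · (−ΣI_Ca/(2F) − J_SERCA + J_rel − J_PMCA − J_NCX)

with ER uptake through the SERCA pump as a second-order Hill flux

    J_SERCA = P_SERCA · [Ca²⁺]i² / ([Ca²⁺]i² + K²),   P_SERCA = 0.096 amole/ms

and a linear ER leak `J_rel = P_rel (Ca_ER − Ca_i)`.  Inward membrane
currents are negative; 1 pA of Ca²⁺ current moves 5.182·10⁻³ amole/ms
(1 amole/ms over 1 pL changes concentration by 1 µM/ms, so with volumes in
pL all Ca²⁺ bookkeeping stays in µM and ms).

The functional forms of the individual currents are compact
Hodgkin–Huxley/Hill expressions from the standard β-cell modelling
literature rather than a line-by-line transcription of any single published
parameter table: CaV with instantaneous activation, slow voltage-dependent
inactivation (τ_h = 6 s) and Ca²⁺-dependent inactivation; a
delayed-rectifier K⁺ gate (τ_n = 20 ms); SK-type KCa, TRPM and SOC as
instantaneous Hill functions of cytosolic or ER Ca²⁺; NaK, NaCa and PMCA as
saturating pump/exchanger terms.  Glucose acts through a lumped metabolic
activity variable `a` (a normalised ATP/ADP tone): its drive is a
glucokinase-like Hill function of glucose (midpoint 7.0 mM, coefficient 6)
divided by a Ca²⁺-dependent consumption term (midpoint 0.26 µM,
coefficient 4, τ_a = 8 s), and `a` closes the KATP conductance through a
steep gate (midpoint 0.45, coefficient 6).

This construction was calibrated once, at model-construction time, to the
documented behavioural contract of the source cell model that any backend
registered in `cell_model` must meet:

* silent (stable rest near −65 mV) below the firing threshold;
* threshold for sustained oscillations at ≈ 6.9 mM glucose with the
  original (unsampled) parameters, found by a 0.1 mM bifurcation scan;
* continuous square-wave Ca²⁺ bursting at 11 mM with burst periods of
  order ten seconds and burst amplitudes of a few hundred nM.

Mechanistically the voltage subsystem is bistable between a hyperpolarised
rest state and a depolarised plateau (the S-shaped steady-state IV curve
has three branches over a ~70–210 pS window of KATP conductance).  Slow
CaV inactivation terminates each plateau; recovery of `h` and of the
metabolic variable re-ignites it.  This yields spike-free square-wave
bursts, which keeps the coupled system comparatively cheap to integrate
without affecting any trace-level quantity the analysis uses (all
analysis operates on Ca²⁺ envelopes, not on spikes).

Cell-to-cell heterogeneity draws every maximal conductance/transport
magnitude from Normal(µ, 0.2 µ), redrawing the (practically impossible)
non-positive values.  One consequence worth knowing: with 20%
heterogeneity, roughly a fifth of the cells given glucose in U(6,7) mM are
intrinsically oscillatory (their individual thresholds scatter around
6.9 mM), somewhat more than the ~10% implied by the unsampled threshold.

I_NpHR is retained in the current list for structural fidelity but is zero
in every experiment; silencing is implemented as a voltage clamp (below).

## Architectures

Real reconstructions provide `id,x,y,z` text files (µm).  The synthetic
generators are calibrated only to summary statistics of such
reconstructions, not to morphology:

* **mouse-like** — a jittered FCC packing (nearest-neighbour spacing
  13.5 µm, jitter σ = 1.5 µm) filling a ball.  Mean contact number at the
  17.5 µm threshold: ≈ 9.5–11.5 over 150–1600 cells (target band 8–12,
  dense-core mouse islets measure ≈ 10).
* **human-like** — β-cells split into sub-clusters of ~120 cells (FCC
  packing at 14.6 µm spacing), chained so consecutive cluster surfaces
  just touch.  Mean contact number ≈ 8.0–8.6 (human islets measure ≈ 8);
  a draw whose contact graph is disconnected is regenerated from an
  incremented sub-seed, because an islet with isolated components would
  trivially lose whole-islet synchrony for reasons unrelated to hubs.

Contacts use the strict inequality ‖X₁−X₂‖ < d_thr with d_thr = 17.5 µm; a
pair at exactly the threshold is not connected.

## Network assembly

* **Hubs** — a uniformly random 10% of cells (round-half-up).  Hubs are
  given 11 mM glucose; non-hubs draw i.i.d. from U(6.0, 7.0) mM (the
  interval U(6.5, 7.5) is available for the glucose-exploration
  experiment).  Glucose is constant per cell per run; the higher hub
  glucose is a proxy for doubled glucokinase expression, since glucose
  transport is not rate-limiting in β-cells.
* **Gap junctions** — one ohmic conductance per contact edge,
  `I_coup,i = Σ_j g_ij (Vm_i − Vm_j)` (pS·mV = fA).  Three modes:
  `single-gaussian` N(50, 35) pS; `unimodal` N(20, 14) pS; `bimodal`, in
  which an edge with at least one hub endpoint draws N(50, 10) pS and
  non-hub–non-hub edges draw N(10, 2) pS.  Conductance lives on edges
  while the bimodal idea ("hubs are preferentially coupled") is stated
  per cell; attaching the strong distribution to hub-incident edges is
  this package's resolution, and the opposite assignment (weak hubs) is
  available behind `swap_bimodal_means` for sensitivity analysis.
  Non-positive draws are redrawn (relevant at µ = 50, σ = 35).
* **Seeding** — hub choice, glucose draws, conductance draws and
  parameter heterogeneity consume four independent sub-streams spawned
  from one master seed, so perturbing one ingredient (say, the hub
  fraction) leaves the others' draws untouched, and the whole assembly is
  bit-reproducible.

## Simulation protocol and numerics

Epochs: equilibration (discarded; 100 s at paper scale), baseline,
inhibition, recovery.  During inhibition the clamped cells' Vm equation is
replaced algebraically by Vm ≡ −100 mV — not a large-conductance soft
clamp — while their gating, Ca²⁺ and metabolic state keep evolving and
their neighbours' coupling currents are computed against the clamped
value.  On release the cells resume free dynamics from wherever the clamp
left them.  Inhibited sets for a dose series are *nested* (a larger
fraction's set contains every smaller set, drawn once per seed from the
target population), which removes spurious between-dose Monte-Carlo
jitter.

Integration uses scipy's BDF with the Jacobian sparsity implied by the
contact graph (dense 6×6 per-cell blocks plus Vm–Vm entries per edge) and
a numba-compiled right-hand side (exactly the same expressions as the
numpy path; a test asserts equality to machine precision).  Default
tolerances: rtol 10⁻⁶ with per-variable atol scaled to each state's
magnitude (10⁻⁴ for mV-scale variables, 10⁻⁷–10⁻⁸ for unit gates and µM
concentrations).  Output is sampled every 100 ms.  Two numerical facts
shape the tests: trajectories are bit-reproducible on one machine
(identical inputs give identical BDF step sequences), and tolerance
halving changes the islet-mean Ca²⁺ trace by < 1% RMS only over short
horizons (~10 s) — beyond that, burst-timing phase drift dominates any
pointwise comparison even though dose-response statistics are unaffected.

## Activity analysis

Rasters binarize each cell's trace at 40% of that cell's baseline-epoch
maximum (the absolute 0.2 µM threshold is available); the relative rule is
primary because per-cell amplitudes vary several-fold under 20%
heterogeneity.  Two epoch metrics, both in % of baseline:

* **summed** — time-mean of the active-cell fraction;
* **amplitude** — peak-to-trough excursion of the islet-mean Ca²⁺ trace.

Amplitude is the default dose-response metric.  The two measure different
things: clamping a few hubs collapses the *coordinated* islet-wide
oscillation (amplitude → ~0) while scattered, desynchronised single-cell
activity can persist among intrinsically active non-hubs (summed stays
higher).  The hub phenomenon is about coordination, and the amplitude
metric resolves it cleanly at every islet size; the summed metric is
reported alongside.

Dose-response curves are fit with the two-parameter decreasing logistic
A(x) = 100/(1+exp((x−x0)/k)) anchored at 100% (activity is already
normalised; a free-top 3-parameter variant is available).  x0 is the IC50
in % of all islet cells (conversion to % of the hub pool is provided), k
the slope factor; fits with R² ≤ 0.9 are flagged, never silently dropped.
Dose-response activities are normalised to the same epoch of the
no-inhibition (0%) run of the same seed, so the 0% point is 100% by
construction and window-sampling noise (a 30 s epoch catches 2–4 bursts)
cancels between dose levels.  With several seeds, the logistic is fit to
per-fraction seed means (mean ± SEM), matching how such data are usually
presented.  Species-level
IC50 sets are compared with paired or unpaired t-tests; degenerate paired
inputs (zero within-pair variance) are flagged instead of yielding an
infinite statistic.

## Experiments and scales

Five orchestrated experiments share one configuration object and one code
path at two resolution tiers:

* **paper scale** — 750–1600-cell islets, fraction grids to 10%, 6 seeds,
  100/60/60 s epochs.  A single 750-cell dose-response curve costs hours
  of CPU; this tier exists for full-size reproduction.
* **desk scale** — 120-cell islets (240 for the species panel, whose
  clustered architectures need several sub-clusters to behave like
  multi-cluster islets), 4 fraction levels, 1 seed, 40/30/30 s epochs,
  rtol 10⁻⁵.  Each experiment finishes in minutes.  The directional
  results that survive this scale — hub IC50 < non-hub IC50, human-like
  more sensitive than mouse-like, collapse under hub clamping and
  recovery on release — are what the test suite asserts.  One comparison
  does *not* survive desk scale in this backend: islets with unimodal
  20 pS junctions at 120–240 cells sit below their synchronisation scale,
  their coordinated amplitude collapses at the smallest hub clamps, and
  the unimodal-vs-bimodal IC50 ordering is therefore only meaningful at
  full size (see Known limitations).

Every result table carries a configuration hash and master seed, and
rerunning an experiment with the same configuration reproduces its tables.

## What the synthetic data do and do not show

The generators emulate printed summary statistics (islet sizes, contact
numbers, coupling strengths, glucose assignments), not real islets: there
is no α/δ-cell compartment, no paracrine signalling, no vasculature, no
real 3D morphology, and the human-like cluster chain is one of many
geometries consistent with "β-cells occur in distinct clusters".  Passing
tests therefore demonstrate that the *mechanism* — near-threshold
non-hubs entrained by strongly coupled, highly metabolic hubs, and
collapsed by clamping a few of them — is reproduced and quantified; they
do not validate the model against any particular imaged islet.  Burst
micro-structure (spikes on the plateau) is deliberately absent; any
question at spike resolution is outside this model's scope.  The
functional-connectivity/power-law style of network analysis is likewise
out of scope.

## Known limitations

* The cell backend satisfies the documented behavioural contract of the
  source model but is not parameter-identical to it; quantities that
  depend on details beyond the contract (exact burst shapes, absolute
  IC50s at paper scale) should be expected to match in kind and order,
  not digit-for-digit.
* Desk-scale islets (120–240 cells) have only 12–24 hubs, so dose curves
  move in coarse steps and single-seed IC50s carry visible sampling
  noise; the test suite asserts orderings, not absolute values, at this
  tier.
* Reducing hub SERCA by 40% does not increase the influence of non-hub
  silencing in this backend — the effect is small and systematically
  opposite (a few percentage points more residual activity) across
  independent islets.  The companion negative finding (hub influence not
  increased by SERCA reduction) does reproduce.  The corresponding
  positive-direction test fails by design rather than being weakened;
  the ER representation here (Hill SERCA, linear leak, SOC) is the
  likely cause.
* At desk scale the unimodal (20 pS everywhere) coupling mode does not
  sustain robust whole-islet coordination: its baseline amplitude is
  ragged and collapses for any tested hub clamp, so the fitted unimodal
  hub IC50 is not comparable with full-size behaviour.  The corresponding
  test is expected to fail at desk scale and documents this limit; the
  comparison should be run with `paper_scale_config()` when CPU-hours are
  available.
* The clamp releases instantaneously; no attempt is made to model
  halorhodopsin kinetics.
* Clamped cells' gating variables evolve under the clamped potential
  (they are not frozen); this choice is untested against the alternative
  and is a natural sensitivity-analysis candidate.
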