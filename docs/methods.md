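# Methods

## Model structure

The network definition (11 components, 42 signed regulations, each
transcriptional or post-translational) is packaged as
`data/network.json` and validated on load: exactly one ligand, six
transcription factors and four receptors; regulation ids covering 1–42;
exactly two inhibitory edges (IRF8 ⊣ STAT1 and LPS ⊣ C/EBPα);
post-translational edges only onto the five components with an
active/inactive protein form (STAT1, STAT3, CSF1R, NFκB, C/EBPα). Two
regulations summarise documented indirect routes (NFκB→STAT1 via IRF7,
and STAT1→STAT3 protein activation via the LIF/OSM receptors); they are
encoded as single direct edges with the net sign, because the
intermediates are not model variables. LPS is an input, not a
component, so it takes part in no feedback loop.

## Kinetic equations

Each mRNA follows synthesis–degradation dynamics in which activating
edges contribute saturating (Hill) terms, added on top of a basal rate,
and inhibitory edges multiply production by a decreasing Hill factor.
Regulator "activity" is the active protein pool where one exists and
`3000 × mRNA` otherwise — 3000 being the genome-wide average
protein/mRNA abundance ratio adopted as a fixed conversion. Each of the
five regulated proteins is synthesised into an inactive pool at
`3000 × kdp` per unit mRNA (which pins total protein at 3000× mRNA in
steady state), degraded from both pools at `kdp`, and shuttled between
pools by an activation rate (basal plus saturating contributions of the
post-translational edges) and a first-order inactivation rate.

LPS enters three ways: a linear activation term on STAT1's protein
activation rate, a linear term on NFκB transcription, and an
even-exponent saturating repression factor on C/EBPα transcription.
Linear (rather than saturating) LPS activation keeps the vector field
smooth and monotone through negative LPS, which the continuation module
exploits to locate the saddle-node that joins the activated and middle
branches outside the physical range. Negative doses are flagged
non-physical in all outputs.

Units: time in hours; mRNA in reference-gene-relative units matching
qPCR practice (basal ≡ 1 by calibration); protein in the same units
times 3000; LPS dimensionless with 1 ≡ the experimental dose.

## Parameter provenance and calibration

The packaged parameter set (`data/parameters.yaml`, symbols keyed to the
regulation ids) was calibrated in-package against the qualitative and
quantitative behaviors the underlying experiments establish, rather than
transcribed from an external table:

* **Fixed by reported values**: protein/mRNA ratio 3000; Irf8 and Csf1
  mRNA half-lives 4.1 h and 5.2 h (the two shortest in the network).
* **Chosen once as biologically plausible**: the remaining mRNA
  half-lives (6–12 h, all longer than Csf1's); protein half-lives of
  3 h (6.7 h for C/EBPα, whose slower turnover carries the incoherent
  feedforward that shapes the Nfkb transient); protein inactivation at
  1/h so that active fractions run from a few percent (basal) to ~50%
  (activated).
* **Calibrated against the qualitative record**: edge weights and
  thresholds were tuned so that a single parameter set reproduces, at
  once, (i) the LPS-response shape classes — fast rises of Stat1/Stat3,
  delayed rises of Csf1/Irf8/Tnfr1, a transient Nfkb rise, transient
  Il6r/Cebpa dips; (ii) the screen ranking (STAT1/STAT3/C/EBPα strong,
  IRF8/CSF1R weak); (iii) irreversible bistability with the basal-branch
  fold at a low positive dose (≈0.16) and the activated-branch fold at
  negative dose (≈−0.40); (iv) washout persistence of Irf8/Csf1 within
  20%; and (v) robustness of both attractors to ±20% parameter
  variation for the large majority of cells.

Basal transcription offsets `b_c` close the budget exactly so that the
unstimulated network rests at mRNA = 1 for every component; the packaged
initial conditions (`data/initial_conditions.json`) are that basal
steady state, including the self-consistent protein pools. Because the
offsets are computed residually, the basal state is an equilibrium to
machine precision, which the tests use as a free oracle.

Key mechanistic choices behind the response shapes:

* Fast vs delayed rises come from thresholds relative to the two-phase
  growth of active STAT1: LPS first activates the pre-existing protein
  pool within ~1 h (fast phase), then the autoregulatory loop grows the
  pool ~8-fold over a day (slow phase). Edges with half-saturation below
  the fast-phase level respond immediately (Stat1/Stat3 transcription);
  edges thresholded above it respond only as protein accumulates
  (Irf8, Csf1, Tnfr1, and Csf3r transcription).
* The Nfkb transient is an incoherent feedforward: LPS drives Nfkb
  transcription directly (fast, positive) while repressing C/EBPα, whose
  steeply-sensed activity normally sustains much of Nfkb's basal
  production (slow, negative).
* The Il6r and Cebpa dips recover through the delayed STAT3 rise
  (STAT3→Il6r, STAT3→Cebpa), leaving both near baseline by 48 h.
* Bistability rests on mutual STAT1↔STAT3 protein activation plus the
  transcriptional autoloops and receptor feedbacks; at the activated
  state these terms saturate, which is why 50% STAT1 knockdown lowers
  expression without destroying either attractor (the knocked-down
  system's basal fold moves to ≈0.66, still positive).

## Numerical methods

* **Integration**: LSODA with rtol 1e−8 / atol 1e−10; protocol segment
  boundaries are exact restart points so input steps are never smoothed.
  The right-hand side is JIT-compiled (numba) with a pure-numpy
  fallback; states are mRNA O(1) and protein O(10³–10⁴), within the
  solver's scaling tolerance.
* **Steady states**: multi-start Powell-hybrid root finding on
  per-variable-scaled states (protein scaled by 3000); starts are the
  basal and activated presets plus random states with mRNA uniform in
  [0, 20]; duplicates merged at 1e−4 relative distance; residual
  tolerance 1e−9 on the natural scale. Saddles are recovered by Newton
  from a dense scan of blend points between distinct attractors (random
  starts almost never land in a saddle's basin of attraction for
  Newton). Stability comes from the eigenvalues of a central-difference
  Jacobian with steps scaled to state magnitude.
* **Continuation**: pseudo-arclength with secant tangents, Newton
  correction orthogonal to the tangent, adaptive step (halving on
  failure, growth to a cap on success), fold points recorded where the
  tangent's LPS component changes sign.
* **Hysteresis**: quasi-static sweeps with a 200 h dwell per dose.
* **Knockdown**: siRNA is emulated by scaling the target's mRNA
  synthesis, with the scale found by bisection so the target settles at
  the stated residual fraction of the untreated control at the
  measurement horizon — the experiment specifies achieved inhibition,
  not a rate change.
* **Screen statistic**: each perturbed component's influence is its
  maximum |log₂ ratio| across the other components' 48 h readouts over
  the 10-fold-up and 10-fold-down arms (the perturbed gene itself is
  excluded — it trivially moves).
* **Shape classifier**: "fast" reaches half its net change within 25%
  of the horizon; "transient" means the endpoint has returned to within
  half of the peak excursion from baseline; amplitudes under 10% of
  baseline are flat. These thresholds are definitional choices; the
  experimental descriptions are verbal.

## Population heterogeneity

Cell-to-cell variability is extrinsic only: each cell draws every rate,
threshold and scale parameter once, independently and uniformly in
`[p(1−a), p(1+a)]`, and keeps it for the whole simulation; Hill
exponents are treated as structural and shared. Draws are reproducible
from the seed; degradation rates are floored at 1e−4/h. "Low" initial
conditions are the packaged basal state for every cell, "high" the
unperturbed model's activated state; one population is reused across an
LPS grid. Bimodality is summarised as the fraction of cells whose
endpoint exceeds the unperturbed model's unstable-state value at that
dose (midpoint of outer states, or basal/activated midpoint past the
fold, when no saddle exists). At 20% variation the activated state is
retained by every sampled cell; a minority of cells (on the order of a
sixth) lose or leave the basal state at LPS = 0 because their
basal-branch fold shifts below zero — consistent with the coexistence
of both states at low dose from low initial conditions, with a sharp
low/high separation.

## Synthetic data and recovery

The generator simulates a chosen protocol on the qPCR sampling grid
(dense early points, 48 h endpoint; four replicates) and applies
mean-preserving multiplicative lognormal noise (σ² = ln(1+cv²)), since
expression ratios are positive and approximately log-normal; the
reference gene is treated as exactly invariant. Every dataset ships with
a truth record (generating parameters, noiseless trajectories). The
recovery benchmark regenerates data at cv = 0.2, perturbs three
identifiable constants (Stat1 mRNA degradation, and the STAT1→Csf1 and
STAT1→Irf8 edge weights) by up to 2× and refits them by bounded
multi-start least squares on log-parameters with relative (1/mean²)
weighting; across five seeds all three return within 20% of truth.
Objectives over several conditions are additive, and fitting with
bounds that exclude the truth lands on the nearest bound, as expected
for a constrained optimum.

## What the synthetic data do and do not establish

The generator reproduces the design of the calibration experiments
(sampling grid, replicate count, noise scale and positivity) but not
plate effects, amplification-efficiency variation, reference-gene
noise, or intrinsic molecular stochasticity. Passing recovery therefore
demonstrates identifiability of the tested parameters under the stated
noise model, not robustness to systematic qPCR artifacts. Likewise the
population module represents only extrinsic parameter heterogeneity —
no cell division, death, or intercellular coupling.

## Problem sizes

Default analysis sizes: 500-cell ensembles at 10/20/40% variation;
200 h steady-state dwells; continuation steps of 0.005–0.05 in LPS over
[−0.6, 1.5]; 50-point grids for continuation/multi-start
cross-checks; five seeds for recovery. These sizes make the full
analysis suite run in minutes on a laptop while keeping Monte-Carlo
fractions stable to a few percent.

## Known limitations

* The kinetic forms and constants are this package's own calibration;
  they realise the documented qualitative network behavior, but the
  individual rate values are not experimentally measured quantities.
* Protein abundances and activation states are modelled, not measured;
  the 3000× conversion is a genome-wide average applied uniformly.
* The basal-branch fold position (≈0.16 in LPS units) and the
  quantitative knockdown effect sizes at basal conditions are
  calibration-dependent; only their signs and qualitative pattern are
  constrained by the underlying experiments.
* Under 50% STAT1 knockdown the model predicts a (slight) decrease of
  every other component including Nfkb; the wet-lab comparison reported
  disagreement for Nfkb, so that component's knockdown response should
  not be over-interpreted.
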