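# Methods

`chromodyn` couples a discrete 1D loop-extrusion simulation to Langevin
dynamics of a typed block-copolymer chromosome, drives the coupled system
through a minutes-resolved mitosis-to-G1 (M-to-G1) protocol, and quantifies
the resulting (or any supplied) contact maps with the standard statistics of
the field.  This note records the model, its parameters, the design choices
made where more than one reasonable construction existed, and the limits of
what the synthetic test data can show.

## 1. Loop extrusion on a lattice

Chromatin is a lattice of `L` sites of `sigma = 0.5` kb.  A loop extruder
(condensin I, condensin II or cohesin) occupies two sites; it loads at a
uniformly drawn pair of adjacent free sites, and each leg independently steps
outward with probability `p` per timestep of `tau0 = 0.5` s, giving the loop
growth velocity

    v = 2 p sigma / tau0            (v = 1 kb/s at p = 0.5).

A leg is blocked (the step is lost, not retried) when the destination site is
occupied by any other leg or lies outside the lattice; the lattice is linear,
with no wraparound.  Extruders unload stochastically; the per-step unload
probability is `1 - exp(-tau0/tau_res)`, exact for an exponential residence
time `tau_res`.  Species abundances are maintained at a (possibly
time-varying) target `N = L*sigma/d`, `d` being the mean extruder separation;
when a schedule lowers a target, uniformly random extruders of that species
are unloaded immediately, and fractional targets are resolved by stochastic
rounding.  Within a timestep the order is unload, load, translocate, with
extruders translocated in a fresh random permutation.

CTCF sites carry a motif orientation.  A CTCF-respecting species (cohesin)
stepping onto a site whose orientation opposes its direction of travel stalls
there permanently (until unload) with probability `q = 0.5`; the convention
is convergent capture: a "+" site stalls legs travelling toward lower
indices, "-" stalls the other direction, so a convergent pair is "+"
upstream of "-".  The partner leg of a stalled extruder continues.  A stalled
leg's unload rate is unchanged.

`quench_loops` freezes an equilibrated extruder configuration; the frozen
(left, right) pairs then act as permanent bridges in the 3D simulation and
further extrusion steps are no-ops, which reproduces the static-loop variant
of the model.

The engine's per-step law is verified in the test suite against an exactly
enumerated Markov chain on a 6-site lattice (unload + reload + stepping +
CTCF stalling composed analytically) and against closed-form residence and
velocity statistics.

## 2. Polymer model

Each lattice site is one monomer (`a` = monomer diameter = 25 nm ~ 0.5 kb;
reduced units `a = 1`, `k_B T = 1`, unit mass).  Consecutive monomers are
joined by harmonic springs (stiffness `k = 30 kT/a^2`, rest length `a`;
extruder bridges use the same spring).  Non-bonded monomers interact through
a smooth square-well potential: for `r < a` a soft repulsive core of height
`E_repel = 3 kT` (chains can pass through themselves, emulating
topoisomerase activity), and for `a <= r <= a* = 1.5 a` an attractive well
of depth `eps_i` for homotypic pairs:

    U(r) = E_repel * (1 + ((a0 r / a)^2 - 1) * (a0 r / a)^12 / E0)            r < a
    U(r) = -eps_i * (((r - rc)/w * a0)^2 - 1) * ((r - rc)/w * a0)^12 / E0 - eps_i   a <= r <= a*
    U(r) = 0                                                                  r > a*

with `rc = (a + a*)/2`, `w = (a* - a)/2`, `a0 = sqrt(6/7)`,
`E0 = 46656/823543`.  The polynomial is constructed so that `U(a) = U(a*) =
0` with vanishing slope at both branch points and depth exactly `-eps_i` at
the well midpoint; the outer branch is truncated at its zero crossing `a*`.
Homotypic affinities are `eps_A = 0`, `eps_B = 0.05 kT` (A/B compartments)
and `eps_C = 0.9 kT` (microcompartment anchors); heterotypic affinities are
zero throughout.

Monomer typing: C blocks (CRE-like microcompartment anchors) are 3 monomers
(1.5 kb) wide, planted on average every 20 kb inside the locus — matching
the observed anchor density of roughly 50 anchors per Mb; A and B alternate
in larger blocks beneath them.  The full-scale layout is eight copies of a
3,850-monomer locus separated by 3,850-monomer neutral (A) spacers,
totalling 61,600 monomers; reduced-scale layouts shrink the locus and drop
copies (Section 5).

Confinement is a one-sided harmonic wall (default stiffness `10 kT/a^2`)
around a sphere or a 4:1 (height:diameter) cylinder whose volume follows
from the prescribed volumetric density

    rho_chr = N * (4/3) pi (a/2)^3 / V_container,

giving `R = (a/2)(N/rho)^(1/3)` for the sphere.  In the cylinder phase the
chain ends are tethered to the two cylinder end poles.  Shape changes are
implemented as simultaneous linear ramps of the old wall's stiffness down
and the new wall's up; tethers release on the same ramp.

### Integrator

Dynamics are underdamped Langevin integrated with the BAOAB splitting
(half-kick, half-drift, Ornstein-Uhlenbeck velocity refresh, half-drift,
half-kick; one force evaluation per step), with collision rate
`gamma = 0.1/time` and timestep `dt = 0.02` in reduced units.  The choice is
deliberate: the attraction well is only `0.25 a` wide with curvature of
order `50-100 kT/a^2`, and overdamped first-order schemes at affordable
timesteps measurably erode homotypic binding (we measured a ~2x loss of
anchor-anchor bound fraction at overdamped `dt = 0.008` relative to the
converged value), which directly suppresses microphase separation.  BAOAB at
`dt = 0.02` reproduces the converged bound fraction, samples configurations
with O(dt^2) bias, and is the same family of integrator used by the standard
chromosome-simulation toolchains.  Harmonic-bond statistics are tested
against a quadrature Boltzmann oracle to 2%; forces are tested against
finite differences of the total energy.  Non-bonded forces use a linked-cell
neighbor search (cell edge = interaction cutoff), exact and O(N).

The clock calibration adopted from live-locus imaging is 540 polymer steps
per extrusion step and 0.5 s per extrusion step at full scale; at reduced
scale the steps-per-extrusion coupling is an explicit parameter (Section 5).

## 3. The M-to-G1 protocol

All times in protocol minutes (the full-scale clock); `t = 0` is the start of prometaphase data
collection.

| event | time (min) |
|---|---|
| 1D pre-equilibration | 36,000 extrusion steps (5 condensin II residences) |
| 3D equilibration, cylinder, rho 0.65, tethered | 300 min before t = 0 |
| condensin I (tau 3 min, d 35 kb) + condensin II (1 h, 140 kb) | t < 15 |
| condensin I burst to d = 27 kb | 15-17 (linear in count) |
| condensin I removal | 17-20 (linear to 0) |
| cylinder height halves, density -> 0.45 | 25-30 |
| condensin II removed; CTCF on; eps_B on; cohesin (10 min) starts | 30 |
| cylinder -> sphere crossover at rho 0.25; tethers released | 30-35 |
| cohesin count rises linearly to d = 100 kb | 30-245 |
| collection windows | PM [0,10), AT [20,30), EG1 [55,65), MG1 [115,125), LG1 [235,245) |

The PM/LG1 density ratio is 0.65/0.25 = 2.6.  Ramps are linear unless the
protocol says otherwise; the condensin I burst is linear in extruder count
(up then down); A/B affinity and CTCF activation are instantaneous at t =
30; cohesin starts from zero.  The parameter log emitted by a run reproduces
the schedule exactly and round-trips through its dictionary form.

Steady-state sweeps use a single generic extruder species without CTCF in a
sphere, one equilibrated run per grid point per replicate, with an automatic
plateau check (windowed mean radius of gyration changing < 2% over the last
third of equilibration) replacing by-eye inspection; failing the check warns
and flags the run rather than failing it.  A quenched variant equilibrates
the 1D system, freezes the loops, and runs the 3D stage with static bridges.

## 4. Contact-map statistics

* **Map construction**: two monomers are in contact when their spatial
  distance is at most the contact radius; counts are aggregated over frames
  and binned (full-scale defaults: radius 4 monomers, bin 4 monomers = 2 kb).
* **ICE balancing**: symmetric iterative correction; weights `w` such that
  `diag(w) M diag(w)` has equal row sums; all-zero rows are masked;
  non-convergence warns and returns the best iterate flagged.
* **P(s)**: per-diagonal means pooled into log-spaced separation bins (ratio
  1.12, geometric bin centers), normalized to the first bin; the log-log
  derivative is taken by centered differences on a moving-average-smoothed
  log curve.  Single-separation inputs yield NaN derivatives rather than an
  error.
* **Local background**: for a loop at bins (i, j), the background entry at
  window offset (di, dj) is the mean of all map elements at the same genomic
  separation whose anchors lie within ±100 kb (±200 bins at 500 bp) of the
  corresponding window cell; windows are 21 x 21 at 500 bp.  Loops closer to
  the diagonal than the window half-width are rejected, mirroring the
  exclusion of loops under 10 kb from strength quantification; loops nearer
  than 100 kb to a map edge use the truncated available flank.  This
  construction makes the background-subtracted score exactly invariant under
  addition of any pure distance-decay field, which the tests assert, along
  with cell-by-cell equality with a brute-force enumeration.
* **Loop strength**: `bg_subtracted` = window sum minus background sum;
  `obs_over_exp` = window sum divided by background sum (the ±5 kb square
  window makes observed and expected commensurate); `total` = window sum
  alone.  Balanced values are used when weights exist.
* **Simulation window strength**: mean contacts in a 6 kb x 6 kb (3 x 3 bins
  at 2 kb) window on a site pair; the relative mode divides by the map-wide
  mean at the corresponding separations.
* **APA**: average of per-loop observed/expected windows (expected from the
  map-wide per-diagonal mean), 24-kb windows at 500 bp by default (the
  500 bp vs 250 bp discrepancy between the two printed descriptions is
  resolved in favor of 500 bp, with resolution exposed as a parameter);
  truncated windows are skipped and counted.
* **Anchor classes**: anchors padded ±1 kb are intersected with promoters
  (TSS ±2 kb), enhancers (H3K4me1 AND H3K27ac, non-promoter) and
  CTCF/RAD21 (both peaks, non-promoter, non-enhancer), hierarchically
  promoter > enhancer > CTCF; the exclusive mode drops anchors (and their
  loops) that satisfy both a CRE and the CTCF/RAD21 definition.
* **Compartments**: leading eigenvector of the correlation matrix of the
  observed/expected balanced map (correlation, not covariance — the
  convention of the standard toolchain), sign-oriented by positive
  correlation with an orientation track (G+C content in real data); positive
  bins are A.  Featureless maps are returned flagged unreliable rather than
  raising; all-zero maps raise.  Loops are then intra-A / intra-B / inter by
  their anchors' signs, with masked-bin anchors counted unassigned.

Coordinates are 0-based half-open everywhere; bin membership is by interval
start.

## 5. Reduced ("desk") scale

Full-scale runs (61,600 monomers, 10^6-step equilibrations, 245 simulated
minutes at 540 polymer steps per extrusion step) are available behind
explicit parameters but are not the defaults anywhere in the test suite.
The desk convention, chosen once and used throughout:

* A scale factor `s` multiplies times (residence times, schedule event
  times, collection windows).  Extruder separations `d` stay in literal kb
  by default: the controlling parameter for microcompartment disruption is
  the extrusion activity `2v/d` (extrusion steps per unit time per kb), and
  scaling `d` with `s` would multiply that activity by `1/s` — at `s = 0.1`
  we measured ~10-30x the full-scale activity, which erases all
  microcompartment structure in every window.  (A `scale_separations` flag
  restores fully self-similar scaling for experiments that want it.)
  Transition runs use `s = 0.2` on a 1,000-monomer single-copy locus with
  25 polymer steps per extrusion step; fewer polymer steps per extrusion
  step visibly distorts the window ordering by speeding extrusion relative
  to polymer relaxation.
* Steady-state sweeps likewise keep the full-scale default `d = 100 kb`
  literally; sweep defaults are `d = 100 kb`, `v = 1 kb/s`,
  `tau_res = 150 s` on the same 1,000-monomer single-copy locus
  (~25 anchors).
* Strength metrics on desk maps use a contact radius of `1.5 a` (the
  attraction range, i.e. physically bound contacts) instead of the
  full-scale 4-monomer capture radius, because at desk chain lengths the
  densest containers are only ~4-6 monomer diameters across and a 4 a
  radius saturates the map.  Map construction itself keeps the 4-monomer
  default.

What desk-scale results can and cannot show: orderings and monotone trends
(density up => microcompartments up; extrusion activity up => down; AT peak
of C-C strength; monotone CTCF loop growth in G1) are reproducible.
Quantitative strength ratios are compressed relative to full scale: the
small container raises background contact frequencies, the ~25 anchors per
locus make microphase-separation nucleation slow and noisy, and collection
windows hold fewer frames.  In particular, the sharp (several-fold)
density dependence of microcompartment strength across the microphase
transition requires equilibration well beyond desk-scale run lengths: at
desk lengths the 0.25 -> 0.5 density doubling moves C-C strength in the
right direction but by tens of percent, not multiples.  Equilibration is
correspondingly shorter (the plateau check still applies).

## 6. Spiking classifier

Mean Pol II signal in a 2.5-kb TSS window at the five time points; for genes
with several TSSs the one with the largest signal summed across time points
is kept.  Active genes have signal >= 0.5 (in the units of the input track)
at every time point except PM; each surviving profile is divided by its mean
over EG1/MG1/LG1.  PCA is over genes as observations with column-mean
centering and no variable scaling; PC1's sign is fixed by requiring its AT
loading to exceed its mean G1 loading, which makes "positive PC1 score =
spiking" deterministic across runs.  Degenerate inputs (under 3 active
genes, or all profiles identical) raise.

On the synthetic cohort (planted spiking fraction 0.38, AT amplitude 2x G1,
log-normal noise CV 0.1 — mirroring the observed share of active genes that
spike) the classifier recovers planted labels at >= 95% and the planted
fraction within ±0.05.  Under a pure-noise null (planted fraction 0 or
amplitude 1x) PC1 is a noise direction and its sign splits genes near
50/50; a sub-5% spiking call under the null is not a property PCA sign
labeling can deliver, and the tests assert chance-level behavior instead.

## 7. Synthetic data

Generators are pure functions of seed and parameters and write manifests
from which every planted feature is recoverable: annotations (TSS, enhancer
mark pairs, CTCF/RAD21 peaks with orientations, an adjustable CRE-CTCF
co-location fraction), monomer typings, contact maps (power-law decay times
checkerboard factor plus planted loop excesses, Poisson or noiseless), and
Pol II series.  They emulate marginal statistics — distance decay,
checkerboard compartments, focal excesses, spiking profiles — not the joint
structure of real chromatin (no stripes, no TAD insulation, no coverage
bias, no replicate structure); passing recovery tests on them demonstrates
the estimators' correctness, not field performance on sequencing data.

## 8. Known limitations

* Two-sided extrusion only; no one-sided extruders, bypassing/Z-loops, or
  cohesin-CTCF residence coupling.
* eps_C is constant through the transition; the late-G1 divergence between
  simulated and observed microcompartment strength expected from
  transcription-factor rebinding is out of scope.
* The desk-scale quantitative compressions of Section 5.
* ICE, P(s), eigendecomposition and APA are re-implementations with
  brute-force test oracles, not wrappers of the cooler/cooltools stack; maps
  are exchanged as plain-text dense/triplet matrices rather than cooler
  containers.
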