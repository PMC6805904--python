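# Methods

## 1D lattice loop extrusion

Each chromatid is a row of lattice sites, one per `monomer_bp` = 640 bp.
An extruder occupies two sites (its legs) and is born as a loop of one
bond on a uniformly random unoccupied bond (boundary sites excluded).
One sweep consists of two phases:

1. **Death with instant rebirth.** Every extruder dies with probability
   `p_death = 2·monomer_bp / processivity_bp` and is immediately reborn at
   a random unoccupied bond, so the extruder count is exactly constant at
   `round(total_sites · monomer_bp / separation_bp)`. With each leg
   extruding one site per sweep, the mean unimpeded loop grows to one
   processivity over an extruder lifetime, which is what the processivity
   parameter means.
2. **Leg moves.** All legs attempt one outward step in a freshly
   randomised order (avoiding directional artefacts). A step onto an
   occupied site fails (mutual blocking; legs never pass each other). A
   leg on a barrier site escapes outward with probability `1 − strength`,
   re-drawn independently every sweep; while the draw fails the leg is
   held at the barrier. Centromere and telomere sites are strength-1
   (impermeable), so loops never span the centromere and legs never leave
   the chromatid.

The memoryless pause rule was selected over the alternative — a single
capture draw per encounter that holds the leg until death — by direct
comparison: at the best-fitting parameters the capture rule collapses
coverage to ~43% and mean loops to ~17 kb with almost no barrier-crossing
loops, while the memoryless rule reproduces the dense (~64%), ~26 kb,
frequently-crossing loop arrays that the fitted model is supposed to
produce.

**Steady-state statistics** are computed over sampled configurations
(default: burn-in of ten extruder lifetimes, then 500 samples every 5
sweeps). Pause state is scored positionally — a leg is paused at a
barrier iff it sits on a pausing site — because a sampled configuration
carries positions, not per-sweep random draws. Specifically:

- *coverage*: fraction of sites inside the union of loop intervals;
- *mean loop length*: mean of (right − left) · monomer_bp;
- *barrier occupancy*: fraction of track barrier sites hosting a leg;
- *paused both sides*: fraction of extruders with both legs on pausing
  elements (track barriers or the impermeable centromere/telomere
  boundaries, which act as barriers to extruders);
- *loops crossing a barrier*: fraction of loops with a track barrier site
  strictly between their legs.

Simulated ChIP profiles aggregate both leg positions per site across
samples and chromatid copies, normalised to mean 1 over non-boundary
sites.

Synthetic barrier tracks draw inter-barrier gaps from an exponential
distribution (the memoryless choice when only the ~12 kb mean spacing is
known), snap positions to the 640 bp lattice and deduplicate. Barriers
cover the whole chromosome by default, as cohesin ChIP peaks do; the
20 kb centromere/telomere exclusion applied in contact-map analysis is
available as an option but is not part of the simulation conditions.
Real peak tracks are likely more regular than exponential (peak calling
imposes a minimum separation), which plausibly explains why the fraction
of loops crossing a barrier runs a few points lower here than with a real
track at the same mean spacing.

## 3D polymer model

Monomers are 20 nm spheres (640 bp); chromatids start as confined random
walks inside a nucleus of radius 1 µm at full scale. At desk scale the
confinement radius defaults to `1000 nm · (N/75140)^(1/3)`, conserving
volume density. Forces: harmonic springs (k = 0.35 kT/nm²) on backbone
bonds (rest 20 nm), loop-base bonds (20 nm), sister crosslinks (20 nm)
and homologue crosslinks (100 nm); a truncated harmonic soft-core
repulsion below one monomer diameter (k = 0.05 kT/nm², ~10 kT at full
overlap — finite, so chains can occasionally cross, standing in for
topoisomerase activity); and a harmonic wall outside the confinement
radius. Integration is overdamped Euler (kT = γ = 1) with dt = 0.5 —
validated against the stability bound dt < 2/k_max, with an explicit
error otherwise — plus a 5 nm per-step displacement clamp and a
KD-tree neighbour list rebuilt every 5 steps.

Loop configurations are quasi-static: each sampled lattice configuration
is held fixed while the polymer re-equilibrates (short yeast chromosomes
relax quickly relative to extruder turnover), then contacts are captured
for monomer pairs strictly closer than 60 nm and pooled across all
chromatid copies — intra-chromatid, inter-sister and inter-homologue alike
— onto a single-chromosome map, as an experiment that cannot distinguish
sisters or homologues would.

**Crosslinks.** Sister crosslinks join same-side (left–left or
right–right) *outer* loop bases on the two sisters when they lie within
±30 monomers (~20 kb) and are mutually nearest; nested (inner) loop bases
never anchor links, and the same-side, outer-only, reciprocal-minimum
restrictions are the sole pseudo-knot guard. Homologue crosslinks join
the sister-link positions of the two pairs in a quartet under the same
window and matching rule, at 100 nm rest length. Centromeres and
telomeres are always bonded across paired chromatids.

## Hi-C statistics

All operations act on symmetric binned matrices (default 2 kb bins) with
an explicit bin mask; masked bins are excluded everywhere and undefined
results are NaN, never 0.

- *Translocation masking*: a bin is masked if any trans entry reaches the
  median of its chromosome's third cis diagonal, or its maximum trans
  entry exceeds its maximum cis entry.
- *P(s)*: intra-arm pairs only, both bins ≥20 kb from centromere and
  telomere, aggregated over ~50 log-spaced integer distance bins from 2
  bins (4 kb) to the longest arm, normalised at the distance bin
  containing 4 kb. The stratified variant splits pairs into
  Rec8–Rec8 / Rec8–non / non–non (a bin is "Rec8" if it overlaps ≥1
  site); the three curves share the pooled anchor constant so their
  relative levels survive normalisation (barrier pairs are sparse at
  4 kb).
- *Telomere-distance-stratified P(s)* assigns each pair the summed
  distance of its bins to their arm telomere and drops pairs where a bin
  is closer to the centromere than to the telomere.
- *Insulation*: sliding diamond (±20 kb = ±10 bins at 2 kb) across the
  diagonal, defined only where the window fits inside the arm and
  contains at most one masked bin; scores are log2 of the diamond mean
  over the arm-wide mean diamond score, which makes a uniform matrix
  exactly 0. The normalisation constant is a package choice; only "log2
  insulation" itself is fixed by convention.
- *Observed/expected* divides each intra-arm entry by the pooled
  intra-arm mean at its integer bin distance.
- *Pileups*: average feature maps around single anchors (cis) or anchor
  pairs on different chromosomes (trans), with patches rejected if they
  would extend beyond the chromosome (or arm, for telomere maps);
  site-pair pileups average obs/exp patches at k-th-neighbour site pairs
  and report log2 of the element-wise mean.
- *TSS orientation profiles* count TSSs per strand in 500 bp offset bins
  around anchors, smoothed with a 3-bin sliding mean.

Matrices are assumed depth-normalised only; no iterative balancing is
applied or implemented.

## Goodness-of-fit and grid fitting

The statistic is the geometric standard deviation of the ratio of
simulated to experimental stratified P(s), combined across the three pair
classes over s from 10 to 300 kb (natural logarithm, which the outer
exponential undoes — the only pairing under which a uniform 2-fold ratio
gives exactly 2^√3). Distance bins undefined in either input are dropped
with a warning when they are fewer than 20% of bins; zero or negative
values are an error — no silent pseudocounts.

The grid scan evaluates one simulated stratified P(s) per
(processivity, separation, strength) cell. At desk scale the simulated
map comes from a 1D-lattice contact surrogate: each sampled configuration
collapses loop interiors onto their outer-loop bases (axial coordinate
advances only between loops; a site inside a loop sits at its loop's
axial position with a depth equal to its lattice distance to the nearer
base), an effective contour distance d_eff is formed from axial
separation plus depths (capped by the direct contour distance within a
shared loop), and pairs contribute (1 + d_eff)^(−3/2), the ideal-chain
contact law. This preserves exactly the features the statistic reads —
barrier-anchored proximity and class-resolved distance decay — at a small
fraction of the 3D cost; the full 3D pipeline can be substituted for
final cells. Ties at the grid minimum break toward smaller processivity,
then separation, then strength.

## Problem sizes and defaults

Defaults follow the study conventions: 2 kb bins, 640 bp monomers, 60 nm
contact radius, 1 µm confinement, 20 kb exclusion zones and insulation
half-window, 4 kb P(s) anchor, 10–300 kb fit range, 500 bp TSS bins with
3-bin smoothing, best-fit parameters (76 kb, 32 kb, 0.95), 52 chromatids
(75,140 sites). The steady-state statistics in the test suite and the
acceptance script use the full 52-chromatid lattice with 500 samples;
parameter-recovery scans use one chromatid with 60 surrogate samples per
cell; 3D ensembles in tests use a 480-monomer chromosome, 4 copies and
50 conformations — sizes chosen so the whole loop runs on a single CPU in
minutes while keeping sampling error well inside the stated tolerances.

## What the synthetic data does and does not emulate

Synthetic barrier tracks reproduce the mean spacing and lattice
registration of Rec8 peaks but not their true spacing distribution,
strength heterogeneity or co-orientation with genes; synthetic contact
maps reproduce power-law decay, planted peak grids and Poisson counting
noise but not ligation artefacts, balancing biases or translocations
(translocation masking is exercised on constructed toys). Passing tests
therefore demonstrate correctness of the algorithms and faithfulness of
the model dynamics under the stated conditions, not agreement with any
particular experimental dataset; comparisons against deposited
experimental maps remain an external validation.

## Known limitations

- The lattice simulator has no extruder exchange between chromatids, no
  one-sided extrusion and uniform barrier strength per track entry.
- The polymer model's friction, temperature and step size are effective
  units chosen for stability, not calibrated to real time scales; only
  ensemble properties are meaningful.
- The surrogate contact law ignores excluded volume, confinement and
  inter-chromatid contacts; it is a fitting device, not a conformational
  model.
- Loop configurations and 3D dynamics do not co-evolve (quasi-static
  coupling).
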