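# Methods

`cholmap` implements a systematic protocol for locating specific lipid
(typically cholesterol) interaction sites on a membrane protein from
coarse-grained trajectories, together with a synthetic trajectory generator
that provides ground truth for validating every stage.  This note records the
models, the tunable parameters and their defaults, the numerical conventions,
and what the synthetic validation does and does not demonstrate.

## The protocol

The analysis combines two independent observables and accepts a site only
where they agree.

**Maximum occupancy times.**  A residue contacts a lipid molecule in a frame
when any bead pair between them is within the contact cutoff (6 Å by default,
approximately the first minimum of the bead-bead radial distribution function
at ~4-heavy-atoms-per-bead resolution), evaluated with minimum-image
distances in an orthorhombic box.  The maximum occupancy time t_max of a
residue for a species is the longest run of consecutive contact frames with
one and the same lipid molecule, times the frame interval.  The
single-molecule condition is the point of the definition: a residue in a
busy but anonymous lipid shell accumulates many short runs, while a residue
in a specific site holds one molecule for microseconds.  Runs are strict by
default (`gap_tolerance = 0`); a tolerance for interior gap frames is
exposed for robustness studies but is not part of the protocol.

**Data-set merging.**  Each monomer of each replica is an independent
data-set of per-residue t_max values (contacting residues only).  Data-sets
of one system are pooled only if a Kruskal-Wallis test at alpha = 0.01
(decision against the tabulated chi-square critical value, df = k-1) cannot
distinguish their medians; when the full set fails, the test is repeated
leaving one data-set out at a time, and the passing subset with the smallest
H is merged, recursing to smaller subsets if necessary (pairs are decided by
the same rank test with k = 2).  When several subsets pass, minimal H is a
deliberate, parameter-free tie-break.  Merged ("macro-sample") distributions
are per-residue aggregates — t_max is the maximum over member data-sets and
the population size is the union of contacting residues, which is how the
number of contacting residues of a merged sample stays comparable to a
single data-set's.  Systems whose aggregated distributions again pass the
rank test are pooled into one population.

**Outliers.**  The outlier threshold is the upper box-plot (Tukey) fence
T = Q3 + 1.5 (Q3 - Q1) of the pooled distribution, with quartiles by linear
interpolation between order statistics (the convention is configurable
because published thresholds are reproducible only to printed precision).
Residues with t_max strictly above T are outliers.  No multiple-testing
correction is applied across residues — the fence is a descriptive boundary,
not a hypothesis test.

**Spatial density function.**  Every frame is superposed (Kabsch, SVD with a
reflection guard) onto a common reference over the membrane-facing protein
beads; lipid beads are re-imaged about the protein centroid first, so
molecules wrapped across the periodic boundary land on the correct side.
Species beads are binned into 1 Å³ voxels and normalised as

    g(x,y,z) = N(x,y,z) / (rho dV N_frames),

with rho the bulk bead density (species bead count over box volume), so g
averages to 1 in bulk.  Grids of member data-sets are summed per system.
Hotspots are 26-connected components of voxels at or above a contour level
applied to the raw per-voxel hit counts (hits/Å³, the convention used for
display contours; the normalised lattice can be contoured instead), with a
5-voxel minimum to suppress speckle.  Grid extent is the reference protein
bounding box plus a 15 Å margin; beads outside the grid are tallied, not
silently dropped.

**Site assembly.**  Only hotspots reproducible in every system (centroid
match within the contact cutoff) seed sites.  Nearby reproducible hotspots
(single-linkage, 12 Å — about one lipid length) are clustered into one site:
one physical pocket commonly splits its density into adjacent lobes, one per
bead height or binding mode, just as a site with two preferred orientations
appears as two sub-densities.  A site's residues are all residues with a
bead within the match radius (6 Å, re-using the contact cutoff) of the
hotspot voxels; sites are ranked by matched-outlier count, then peak
density.  Hotspot clusters with no matching outlier are reported as
unranked candidates rather than dropped, since a consistent density without
an outlier can still mark a sequence-defined (linear) site.  Sites are
classified linear when all residues fall on one segment within a 10-residue
window, else non-linear.

**Residence kinetics.**  For each site, every lipid of the site species gets
a reference bound pose: its fitted-frame coordinates at the frame maximising
the summed site density under its beads (ties break to the earliest frame).
The RMSD of the lipid to that pose — computed after the global protein
superposition, with no per-lipid refit — drives a three-state hysteresis
machine: unbound → bound when RMSD < 6 Å; bound persists while RMSD ≤ 10.8 Å;
bound → unbound above 10.8 Å.  The band between the cutoffs absorbs plastic,
partially unbound configurations that would otherwise fragment one long
visit.  Event duration is the number of bound frames times dt; events open
at the trajectory end are flagged censored.  Summaries report the longest
residence, total events, events above 1 µs, and the mean number of distinct
visiting molecules per data-set.

Because event populations mix specific visits with large numbers of brief
diffusive grazes, the mean specific dwell is estimated by the
censored-exponential maximum-likelihood form: the summed excess duration
over a floor (200 ns by default) divided by the number of completed events
above the floor.  Memorylessness makes this unbiased for an exponential
dwell, the floor removes the grazing population, and counting censored
excess time in the numerator avoids the length-biased loss of long events
at the trajectory ends.  Kinetics are computed over the merged data-sets of
every system to maximise event counts at the simulated problem sizes; a
single-system analysis is a configuration choice.

**Selectivity.**  Per species, the mean t_max over site residues (averaged
across data-sets, absent residues counting zero) and the mean normalised
density over site voxels are compared.  A site is non-annular when every
non-reference species shows less than 10% (configurable) of the reference
species' mean site density — a pocket the bulk lipids effectively cannot
enter, as opposed to an annular shell position exchangeable with bulk.

**Motifs.**  CRAC reads N→C apolar (V/L) — aromatic (Y/F) — basic (R/K);
CARC lists the anchors in reverse order, still read N→C.  Spacers count the
residues strictly between anchors and must lie in 1..5; this convention
reproduces the worked motifs (K490→Y495 has spacer 4).  Tryptophan is not
accepted as the aromatic anchor.  All hits are enumerated, overlaps
included; an optional mask restricts hits to membrane-facing anchor
positions (per-spacer masking is a config option, since spacer-level facing
annotations are rarely available).

## The synthetic generator

The generator emulates the structure of the data the protocol consumes, not
membrane physics.  A static ring of vertical helices (default 10 helices of
6 beads, bundle radius 18 Å, two monomers per box) stands in for the
transmembrane protein; each frame adds 0.3 Å Gaussian jitter.  Lipids of 2–3
species (cholesterol 2 beads, phospholipids 3 beads, fixed leaflet-specific
bead heights) perform 2-D lateral Brownian motion with species-specific
diffusion coefficients (order 2–3 Å²/ns, scaled down modestly with
cholesterol enrichment to mimic the observed slow-down in enriched
membranes), wrap periodically, and reflect specularly off the protein
footprint.  Planted sites are two-state continuous-time Markov processes:
one lipid of the site species at a time is captured within a 10 Å radius
with probability 0.3 per frame, pinned near the site residues with 1 Å
jitter for an exponential dwell, then released outside the capture radius.
All randomness flows from one seeded generator, so trajectories are
bit-reproducible.

The default study conditions mirror the simulated design the protocol was
built around: three systems at 15/20/25 mol% cholesterol, two replicas each,
two monomers per box (12 data-sets), 30 µs per replica at a 10 ns frame
interval with the first 500 ns discarded, 360 lipids per box, and three
planted sites per monomer with mean dwells of 2, 1 and 0.5 µs against a
~10–30 ns diffusive contact background.  These sizes keep a full
end-to-end run around a minute on one core while giving each site on the
order of 10² residence events.

What passing recovery tests shows: the full chain — contact detection,
rank-statistics merging, fence outliers, density hotspots, reproducibility
filtering, site assembly and the hysteresis kinetics — identifies exactly
the planted sites and recovers their dwell scales from data with realistic
event statistics.  What it does not show: behaviour under protein
conformational change, lipid flip-flop, correlated lipid motion, anisotropic
or non-exponential binding, force-field realism, or membrane curvature; the
generator has none of these.

## Numerical choices and degenerate inputs

- Lengths in Å, times in ns throughout; GRO files convert from nm on read
  and write.  Orthorhombic boxes only; triclinic input is rejected.
- Superposition selections need at least 3 beads and fail loudly on
  collinear sets; the SVD branch guards against reflections.
- The fast contact path uses a periodic KD-tree; an all-pairs minimum-image
  path is retained and tested as the oracle.
- Quartiles: numpy linear interpolation (configurable); fence comparisons
  are strict (a value exactly at T is not an outlier).
- Rank-sum tests use the normal approximation with tie correction; identical
  samples give p = 1 within that approximation.
- Normality testing warns below n = 20 and refuses constant input.
- Fewer than 4 contacting residues: spread descriptors are undefined and
  raise.  Empty residue masks, empty samples and zero species beads raise
  rather than returning empty results silently.
- Binding-mode counting uses greedy leader clustering at 4 Å RMSD, counting
  clusters holding at least 5% of bound poses; a low-confidence flag is set
  when the counted modes cover less than half of the poses.
- A dimer (or higher oligomer) is split into per-monomer data-sets at
  topology load; sequence positions are shared across monomers so their
  distributions and densities superpose.

## Known limitations

- The hysteresis machine cannot recover a binding state across a trajectory
  split when the junction frame lies inside the tolerance band; the event
  merge helper documents this.
- Reproducibility matching is greedy on centroids; pathological hotspot
  geometries (long ridges) could match ambiguously.
- The dwell estimator assumes an exponential specific dwell and a grazing
  population well below the floor; strongly non-exponential kinetics would
  need survival-curve fitting instead.
- Species grids for selectivity are computed on the most enriched system;
  cross-system density comparisons are not normalised for composition.
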