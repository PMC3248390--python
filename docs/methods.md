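# Methods

This note records the models implemented in `replikinetics`, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Single-cell replication model (`replisim`)

Space is discretized at 1 kb; time is continuous (minutes).  A cell draws a
potential firing time `T_i` for every origin and each position takes the
time of the first arriving fork, `t(x) = min_i(T_i + |x−x_i|/v)`, evaluated
with two linear lower-envelope sweeps (O(L) per cell, exact).  An origin
whose draw loses to an incoming fork is passively replicated and marked
unfired.  Polarity is the direction of the winning fork; exact ties —
origin cells themselves and termination midpoints — are assigned rightward.
Consequences of the 1-kb lattice worth knowing:

* the eikonal bound |dt/dx| ≤ 1/v holds everywhere, with equality except at
  origins and termini;
* the population identity dt/dx = (R−L)/v holds to Monte-Carlo precision
  *away from origin grid cells*.  An origin is a point on the continuum but
  a full 1-kb cell on the lattice, so the slope across an origin-containing
  cell is misstated in every cell of the ensemble; the identity test
  therefore excludes windows containing a configured origin.  This is a
  discretization statement, not a model deficiency.

**Firing models.**  `independent` draws each origin's time iid from a
configurable law (fixed, truncated normal, lognormal parameterized by its
own mean/sd, exponential).  Optional per-origin deterministic offsets
superimpose a reproducible timing landscape (early/late territories);
without them the expected profile is spatially flat and replicate profiles
are uncorrelated by construction.  `domino` additionally lets an approaching
fork trigger an unfired origin: the effective time is
`min(draw_i, min_j T_j + max(0, |x_i−x_j|−d_c)/v + Δ)`, resolved exactly
with a Dijkstra-style relaxation (the added cost is non-negative, so
finalized times are never revisited).  Defaults `d_c = 36 kb`, `Δ = 10 min`
reproduce sequential activation of adjacent origins at ten-minute intervals
— the regime that yields a ~3.6 kb/min TTR.  The defaults elsewhere are the
measured HeLa conditions: `v = 0.68 kb/min`, 20 min IdU + 20 min CldU
pulses, four S-phase compartments.

**Fiber sampling.**  Each synthetic fiber is a random window of a random
cell observed at the end of the second pulse; the pulse start is uniform
over the cell's S phase (asynchronous growth).  Positions replicated during
pulse 1 carry IdU, during pulse 2 CldU; everything else is unlabeled.
Compartments are assigned by the replicated fraction at the end of
labeling, in equal-width windows (quartiles for four compartments — the
experiment sorts on total DNA content, which is monotone in replicated
fraction).  Fiber lengths are lognormal with a 200 kb median and log-sd 0.6;
the length law is not constrained by any measurement here and is fully
configurable.  An origin firing after the second pulse began is rendered as
an isolated CldU-only track.  (The description of such origins as
"doubly-labeled" in the literature is physically inconsistent with firing
after the first label was removed; the CldU-only rendering is the one the
classifier also expects.)

Not modeled: replication stress, checkpoints, re-replication, 3-D nuclear
geometry, chromatin-state-dependent fork speed, and sister-fiber effects.
Passing tests therefore certify the analysis operations, not the biology of
real fibers.

**Repli-seq emulation.**  Each cell's S phase is split into n intervals of
equal replicated-fraction width; a position contributes one tag to the
interval in which it replicates.  Optionally the expected counts are
Poisson-sampled at a target mean depth over a uniform background — the
background produces the low noise mode that the 4m denoising step removes.
Real Repli-seq artifacts (mappability, GC bias, copy-number variation) are
deliberately out of scope.

## Combing statistics (`combing`)

Classification works on the ordered label runs of a fiber: IdU→CldU
boundaries are forks oriented from IdU to CldU; a central IdU run flanked by
CldU on both sides is a type-1 origin (fired before CldU addition); an
isolated CldU-only run is a type-2 origin; a central CldU run flanked by
IdU is a terminus.  Event positions are run midpoints (the underlying
images give patterns, not coordinates).  A tract yields a velocity
(length/pulse) only when delimited on both sides inside the fiber with
exactly one complementary-label neighbour — the unambiguous full-pulse
patterns; central tracts of origins and termini are made by two forks and
are excluded.  Type-2 origins' forks did not exist at CldU addition and are
excluded from fork-to-fork distances.

The fork-clustering test places forks under the null as a uniform Poisson
process at the observed global density on the observed fiber lengths, bins
fibers into {0, 1, ≥2} forks, and uses a chi-square-style discrepancy with
a Monte-Carlo tail probability (expected counts are too small for
asymptotics).  Ties between the observed and simulated statistics are
broken uniformly at random, making the p-value exactly uniform under the
null — the property the calibration test checks.  The adjacent-origin-type
homogeneity test estimates the type-1 proportion from pair slots,
p1 = (2·n11+n12)/(2N), expects (p1², p2², 2p1p2), and uses df = 1 (three
categories, one estimated parameter); expected counts below 1 trigger a
multinomial Monte-Carlo fallback.

Genome duplication time: T_Si = P_Si/(density_i·v_i·10⁻³) minutes per
compartment (the genome size cancels), totalled as ΣT_Si/ΣP_Si — the sum
corrected by the genome fraction the compartments cover.  The printed
mean inter-cluster distance formula, (total − Σ intra-fiber FTFD)/number of
fork-containing fibers, is implemented as stated.

When recovering the configured origin spacing from sampled fibers, the
*median* intra-fiber inter-origin distance is the estimator of record:
origins that fired outside the labeling window are invisible, which doubles
or triples occasional gaps and inflates the mean, while the median of the
(heavily mode-at-spacing) distance distribution is robust to those
drop-outs.

## Timing profiles (`timing`)

Coordinates are 0-based half-open bp; both tiled 100-kb windows and sliding
100-kb/10-kb windows are supported.  Normalization equalizes genome-wide
totals across fractions, then scales each bin's enrichments to sum to one;
all-zero bins are masked.  Denoising zeroes normalized values below four
times the background mode — estimated as the peak of a Freedman–Diaconis
histogram over positive values — and renormalizes; a mode outside
[0.001, 0.2] warns and proceeds.  S50 interpolates the piecewise-linear
cumulative curve through (0,0) and (i/n, Σ_{j≤i} w_j), mapping fraction i
to the S-phase interval ((i−1)/n, i/n]; the first crossing of one half is
taken.  TR50 is either `S_length × S50` (default 8 h, linear content→time
map) or `t(1 + S50)` through a fitted cytometry model.

## Cytometry model (`facs`)

Steady-state exponentially growing population: cells of DNA content x
synthesize at rate φ(x) (six Gaussians), the content→time map is
t(x) = ∫₁ˣ dx′/φ, and the S-phase content density is
ñ(x) ∝ exp(−α·t(x))/φ(x) with α = ln2/22 h by default.  The observable
histogram is G1 (content 1) + S + G2/M (content 2) convolved with
multiplicative Gaussian error of coefficient of variation cv.  Quadrature
is trapezoidal on a 2001-point grid (verified against a fine Riemann
oracle to 10⁻⁶ relative).

Fitting minimizes least squares between predicted and observed counts by
Nelder–Mead.  The primary start is moment-based, estimated directly from the
histogram: the S-region counts approximate ñ(x), residence time is
proportional to density so t(x) follows from the cumulative integral of ñ,
and φ = exp(−αt)/(C·ñ) is projected onto the Gaussian basis by non-negative
least squares.  Random restarts perturb that start; because the informed
start already lies in the right basin, the selected optimum is identical
across restart seeds (the stability property the tests check).  Simplex
termination tolerances are set on the loss scale (10⁻⁶ of the summed
squared counts) so runs terminate by convergence, not by iteration budget.
Two identifiability decisions:

* the six Gaussian means are frozen on an equally spaced grid over [1, 2]
  with one shared fitted width — a well-conditioned non-negative basis for
  φ rather than an unidentifiable free 18-parameter mixture; amplitudes are
  optimized in log space so φ > 0 by construction;
* a single histogram cannot determine the absolute S-phase duration —
  rescaling φ while the growth weighting compensates leaves the predicted
  counts nearly unchanged — so T_S is constrained to an externally supplied
  S-phase length (default 8 h) and the fit recovers the *shape* of the
  content→time map.  Round-trip accuracy is assessed on t(x)/T_S.

Phase fractions (θ1, θ2) are fitted through a softmax so θ1 + θ2 ≤ 1; a
histogram with fewer than 50 informative (non-empty) bins — e.g. a pure-G1
sample — is rejected.

## Speed maps and segmentation (`speedscale`)

The slope at scale s is the correlation of the TR50 profile with a
first-derivative-of-Gaussian kernel of standard deviation s/2 (≈95% of the
kernel mass spans the nominal scale), discretely normalized so an affine
profile returns its exact slope; support truncates at 4 sd.  Edges and
bins within half a kernel of a gap are masked.  Apparent speed is the
signed inverse slope; |slope| < 10⁻⁶ min/kb is reported as ±10³ kb/min
rather than infinity.  Classification and segmentation use |speed|; runs
above the 10 kb/min threshold are CTRs, at or below (ties to TTR, with a
10⁻⁹ relative tolerance so exact-threshold profiles are not split by
floating-point jitter) are TTRs.  With sliding windows each bin stands for
the step-sized interval at its window center, so segments tile the support
without overlap.

Per-TTR statistics: Dx is the segment length; Dt is the TR50 difference
across the segment, linearly extrapolated from the edge-bin centers to the
full extent (profile values live at window centers, so the raw edge
difference spans Dx minus one step and would bias Dx/Dt upward on linear
gradients); orientation follows the smaller-TR50 edge; along-gradient
speeds are read from the speed map at fixed offsets from the early edge
and are missing beyond the TTR's length.  Speeds within half a kernel of a
TTR border mix with the flanking domains — offset speeds are only unbiased
when the offset clears the smoothing support.

The demonstration scenario for sequential activation embeds a 720 kb
gradient (origins every 36 kb firing deterministically 10 min apart,
v = 0.68 kb/min) between synchronous flanking domains built from densely
spaced origins (2 kb apart, so the flanks are flat to < 1.5 min), binned in
tiled 100 kb windows and segmented at the 100 kb scale.  The measured
Dx/Dt ≈ 3.65 kb/min; the construction's trend slope is
36 kb/10 min = 3.6 kb/min, and detection widens the called TTR slightly
into the flanks, which the edge extrapolation compensates to within ~1%.

## Interval analytics (`annotate`)

All BED ingestion is 0-based half-open; features are merged before any
coverage computation, so overlap is never double-counted (verified against
a base-wise oracle).  Enlargement pads, clips to chromosome bounds, then
merges.  Along-TTR gradients traverse each TTR from its early border
(orientation taken from the segmentation, never recomputed) in fixed-width
distance bins, average coverage over the TTRs of each size class
(defaults < 200 kb, 200–360 kb, > 360 kb) and divide by the genome-wide
average coverage; bins beyond a TTR's own length contribute nothing.

## Pipeline and reproducibility (`io`, `cli`)

Profiles and intervals are exchanged as bedGraph/BED, fibers and summary
tables as TSV with one header line, FACS histograms as CSV.  Every output
carries a provenance header (package version, stage, seed, config hash).
Configuration is YAML with unknown keys rejected, and every random stage
requires an explicit seed; identical config + seed reproduces outputs
byte-for-byte.  A heuristic flags 1-based fully-closed interval input by
its systematic 1-bp gaps.

## Problem sizes

The test suite and the acceptance script run on desk-scale synthetic data
chosen to keep every check sharp at interactive run times: populations of
60–1000 cells on 2–10 Mb genomes, 2000 sampled fibers, FACS histograms of
10⁵ cells, and Monte-Carlo tests with 500–20 000 replicates.  The
quantities that depend on these sizes (Monte-Carlo tolerances, correlation
thresholds) are stated next to each test.
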