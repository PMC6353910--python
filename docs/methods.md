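# Methods

`porequeue` quantifies the nuclear export of pre-ribosomal particles from
snapshot data: electron tomograms of high-pressure-frozen yeast freeze the
cell in under 10 ms, far faster than a translocation event, so the fraction
of nuclear pore complexes (NPCs) seen holding a cargo is an unbiased sample
of the equilibrium occupancy. The package covers the four analysis stages —
particle morphometry in 2D sections, per-NPC coordinate mapping, occupancy
and ring statistics, and queueing-based dwell-time inference — plus a
synthetic-data generator that provides ground truth for all of them.

## The queueing model

Export is modeled as a Jackson network of `n` parallel M/M/1 queues. Cargoes
arrive in the cell as a Poisson stream of rate λ (default 4000 subunits/min:
~2000 ribosomes/min synthesized, each contributing a 40S and a 60S
precursor), are routed to one of `n` NPCs uniformly at random (justified by
the absence of compartment bias in the census, see `compartment_bias`), and
are serviced — translocated — in an exponential time of mean `d`, the dwell
time, with unbounded FIFO queueing at each pore. At equilibrium each queue
has occupation rate

    ψ = λ d / n,        P(N = k) = ψ^k (1 − ψ),

so ψ is both the server-busy probability and the quantity the tomographic
census measures (an NPC counts as occupied whether its particle is in
transit or queued; at ψ ≈ 0.05 the distinction is a 0.3% effect, see below).
Fitting is inversion: `d = ψ n / λ`. With the measured ψ = 0.054 (44 of 818
NPCs), n = 110 (the cell-cycle average of the NPC count, which runs from
~80 in G1 to ~140 in mitosis) and λ = 4000/min, the fit gives d = 89 ms.
The same law prices the queue: P(N ≥ 2) = ψ² = 0.0029, i.e. only ~0.3% of
NPCs should ever hold a second, waiting particle — which is why the model
treats pre-ribosomes as essentially non-competing.

Assumptions worth keeping in view: constant flux over the cell cycle,
unidirectional transport, a single cargo class (pre-40S and pre-60S pooled),
and no competition from other cargo. Competition would reduce the number of
NPCs effectively available and hence shorten the inferred dwell time; 89 ms
is in that sense a high estimate.

### Uncertainty

Two uncertainty statements are provided and must not be conflated:

* `DwellTimeResults.dwell_ci_ms` propagates the exact (Clopper–Pearson)
  binomial confidence interval of the occupancy — sampling error of 44/818 —
  linearly through the inversion (65–118 ms at 95%).
* `DwellTimeResults.sensitivity()` scans systematic error in the inputs:
  n ∈ [90, 130] and ψ ∈ [0.039, 0.069] span d ≈ 53–135 ms. Because
  d = ψn/λ is monotone in both arguments the extrema sit at the domain
  corners; the grid exists for level-line plotting, not for optimization.

### The simulator

`simulate_network` is an exact event-driven simulation (binary heap of
departure events plus the next arrival; no time discretization). Service
times are drawn at service start; a single seeded `numpy` generator drives
interarrival, routing and service draws in event order, making every
`SimulationResult` bit-reproducible under its seed. Statistics are time
averages accumulated after a warmup (default five relaxation times,
5·max(d, n/λ)); the standard error of the busy fraction comes from 20-batch
means. An optional `sample_interval` censuses per-server states at regular
epochs — spacing the epochs well beyond the relaxation time yields
near-independent equilibrium samples for goodness-of-fit tests, which a
time-integrated histogram does not provide. The simulator is deliberately
independent of the analytic formulas: it is the stochastic oracle the
closed-form law is tested against (occupancy, mean queue length ψ/(1−ψ),
Little's law, and a χ² fit of the state histogram to the geometric law).

At the fitted operating point (λ = 4000/min, n = 110, d = 89 ms) a 2000 s
simulation (~140,000 arrivals) reproduces the 5.4% occupancy within a few
hundredths of a percentage point.

## Morphometry

Particles are segmented by thresholding. The default rule is
`mean − 1σ` of the gray-level distribution for dark (electron-dense)
particles — the σ-offset convention common for tomogram segmentation —
after a light Gaussian pre-filter (σ = 1 px) that suppresses single-pixel
noise; Otsu and fixed thresholds are alternatives. Foreground components
are 8-connected; border-touching regions are flagged rather than silently
dropped (a clipped particle biases every descriptor), and can be excluded
from density counts.

Descriptors, all in physical units via the pixel size (1.01 or 0.64 nm/px
for the two microscope/camera combinations the defaults emulate):

* **area** — pixel count × pixel_size²;
* **perimeter** — length of the sub-pixel marching-squares isocontour after
  periodic Savitzky–Golay smoothing (window 13 vertices, degree 4). The raw
  isocontour carries pixelation jitter that inflates the length ~5–10% and
  would deflate circularity of a perfect disc to ~0.90–0.93; the smoothed
  estimator measures rasterized discs at 0.98–0.99 and axis-aligned squares
  at ~0.81–0.83, close to the continuous 1 and π/4. Degree-4 smoothing was
  chosen over a plain moving average because it preserves corners, keeping
  square-like shapes inside their analytic band;
* **circularity** — 4πA/P², reported capped at 1.0;
* **Feret diameter** — rotating-calipers maximum over the convex hull of
  the raw contour vertices; verified exactly equal to the brute-force
  pairwise maximum.

Size and circularity filters (defaults 150 nm² and 0.6) remove debris and
non-globular profiles before counting, matching the filtering used for
pre-ribosome morphometry. Note that sizes measured at a shallow σ-offset
threshold are systematically larger than the underlying particle (the
threshold crosses the blurred edge profile outside the half-depth point);
with the generator's defaults the bias is ~+3 nm on a 19 nm particle.
Counting and density are insensitive to this; unbiased size recovery
requires a fixed threshold at half the particle contrast, which is what the
size-recovery test uses.

## NPC frames and ring classification

Each NPC is annotated by the four bend-edge points of the nuclear envelope
(outer/inner membrane × left/right side). The two side midpoints define the
median plane; their midpoint is the pore center; the central axis is the
in-plane perpendicular, signed so +Y points from the inner to the outer
membrane (nucleus → cytoplasm). Pore width (distance between side
midpoints) and envelope width (mean within-side distance) act as quality
controls: values outside 100 ± 5 nm or 31 ± 3 nm flag a section that was
probably not orthogonal to the envelope — flags, not corrections, since the
analysis is strictly 2D in the section plane.

Particle centroids are projected to (X, Y); the ring label is a pure
function of Y. Defaults place the nuclear/inner boundary at −10.2 nm and
the inner/cytoplasmic boundary at +13.2 nm — the midpoints between the
observed ring centers (−21.5, 1.2, 25.1 nm) — with boundaries owned by the
inner ring; the in-NPC window is |Y| ≤ 40 nm, a basket zone extends to
−50 nm (where export-blocked particles accumulate), and anything further is
`outside`. The assignment rule is configurable because no published
assignment rule exists; misassignment between adjacent rings is an
unavoidable consequence of the overlapping Y distributions, and the test
suite checks that the confusion matches the analytic Gaussian overlap
rather than pretending it is zero.

## Statistics

Per-cell densities are compared by Shapiro–Wilk normality checks followed
by one-way ANOVA, with Kruskal–Wallis reported alongside (flagged) when
normality fails. Ring distributions are compared pairwise with two
procedures: the default exact permutation test — null: each particle of the
pair falls in either ring with probability ½, so the count splits
binomially — and a Mann–Whitney U on binary per-particle ring indicators,
kept for comparability with published analyses. The U construction treats
the two complementary indicator vectors as independent samples, which they
are not; its measured size under the null is ~0.18 at nominal α = 0.05, so
it is labeled and never used as the default. The permutation test's exact
size at the study scale (51 particles) is 0.049. Pairwise p-values are
reported raw and Holm-adjusted. Integer ring percentages use
largest-remainder rounding so they always sum to 100.

## Synthetic data

`generate_section` renders dark discs (diameter ~ Normal(19, 1.5) nm) at
Poisson counts matching the requested density, uniformly placed with a
minimum edge-to-edge gap of 8 nm, Gaussian edge blur of σ = 2 nm, and
additive Gaussian noise of σ = contrast/SNR. The gap default encodes the
working assumption that imaged particles are resolved, discrete objects: at
shallow thresholds the blurred tails of two discs closer than ~2 blur
widths merge into one component, which is a property of the scene, not of
the detector. An overlap mode (smaller margin) exists precisely to test
that merge behavior. What the renderer does **not** model: projection
through the 80 nm section thickness, CTF, missing-wedge anisotropy, stain
granularity, or background structure. Passing recovery tests on these
scenes therefore validates the measurement chain (thresholding, labeling,
descriptor math, unit handling), not robustness to real EM artifacts.

`generate_npc_scene` draws per-NPC particle counts from the geometric
equilibrium law at the configured ψ, samples Y from the three-Gaussian ring
mixture (weights 0.18/0.49/0.33), X from Normal(0, 0.65) nm in the
nuclear/inner rings or a random-signed folded Normal(5.4, 3.7) nm shift in
the cytoplasmic ring, jitters the pore geometry (100 ± 5 / 31 ± 3 nm), and
emits every annotation in a random rigid pose so the mapper genuinely has
to reconstruct the frame. Truth tables accompany every output; generators
are bit-deterministic under their seed.

## Numerical choices and edge cases

* All rates are s⁻¹ and times s internally; constructors and the CLI accept
  per-minute fluxes. Dwell times print as ms, percentages to one decimal.
* ψ ≥ 1 is rejected everywhere (`NonErgodicError`): the network has no
  equilibrium and no statistic would converge.
* d = 0 is legal and gives an idle network (zero occupancy), used as a
  trivial oracle.
* Single-pixel regions get a 4·pixel_size perimeter fallback and a flag;
  degenerate (collinear) point sets fall back to brute-force Feret.
* Ties: Y exactly on a ring boundary is `inner`; equal Feret pairs resolve
  to the first found (the value is identical by definition).
* The occupancy used for inference is the table's reported one-decimal
  fraction (5.4% → ψ = 0.054), matching the convention in which such
  censuses are published; the raw-count fit (44/818 → 88.7 ms) rounds to
  the same integer millisecond.

## Problem sizes in the test suite

The suite favors sizes where sampling bands are tight enough to be
informative but runs stay interactive: three to eight 1024²/512² synthetic
sections for recovery checks, 2000-NPC scenes for occupancy recovery,
2000-replicate null calibrations, and simulator horizons of 200–2100 s
(the acceptance-level run uses 2000 s of measurement after a 100 s warmup,
~140,000 arrivals). `scripts/acceptance.py` completes in a few seconds; the
full suite in well under a minute of simulation-dominated tests.
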