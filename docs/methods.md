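# Methods

This note documents the statistical models behind `protistnet`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Normalization

Replicate samples are pooled by summation within (station, date) groups
before any other step; pooling precedes rarefying so that the subsampling
operates on the replicate-combined library. Rarefying draws, for each
sample column, a multivariate hypergeometric sample of the target depth —
subsampling *without* replacement, so a rarefied count can never exceed the
original and column sums hit the depth exactly. Samples whose library is
below the target depth are dropped with a logged warning; the
`second-lowest` depth policy exists precisely because dropping the single
shallowest sample in exchange for a much higher common depth is often the
right trade. A with-replacement (multinomial) mode exists behind a flag for
comparison only.

Singletons (OTUs with a single read in the whole dataset) are removed
before rarefying; the abundance filter for network inference (total < 50
reads excluded, boundary value 50 retained) is applied separately, only to
the network stage's input.

## CLAM habitat classification

Given depth-equalized pooled counts (a, b) for an OTU in habitats A and B,
we condition on the total t = a + b, under which a ∼ Bin(t, π) with
π = p_A/(p_A + p_B). A two-sided Clopper–Pearson interval for π at level
1 − 2α is compared with the supermajority threshold K:

* `specialist_A` if the interval lies strictly above K;
* `specialist_B` if strictly below 1 − K;
* `generalist` if contained in [1 − K, K] (boundary contact allowed);
* `too_rare` otherwise, including t = 0.

Ties at a threshold therefore resolve toward the *less specific* class.
Defaults K = 2/3, α = 0.005. The exact interval was chosen over the
normal approximation because the rare-OTU tail is exactly where the
approximation is worst; a `poisson_normal` mode (normal interval for the
log-ratio with a 0.5 continuity correction) is provided as a cross-check.
The two modes agree to ~0.01 on interior intervals but differ at one-sided
extremes: with all evidence in one habitat the continuity correction makes
the normal mode *more* conservative (minimum specialist evidence 39 reads
vs 14 for the exact rule). No multiplicity correction is applied across
OTUs — the classification is treated as descriptive, and α = 0.005 per
side is already conservative.

`clam_min_abundance` exposes the detectability boundary: the smallest t
with (t, 0) classified specialist, analytically ⌈ln α / ln K⌉ (14 under
defaults), found by scanning the classifier itself.

A deliberate property of the interval-containment formulation: *generalist*
requires affirmative evidence that π lies inside (1 − K, K), not merely
failure to prove specialization. R vegan's `clamtest`, used as an
independent cross-check in the test suite, treats generalist as the
residual class of two one-sided tests; consequently it classifies as
generalist many OTUs this package leaves too-rare. All confident calls
agree between the two implementations on test data; the disagreement is
one-directional and surfaced in the tests.

## MIC and the signed edge set

For vectors x, y of length n the maximal information coefficient is

    MIC(x, y) = max over shapes kx*ky <= B(n), kx, ky >= 2 of
                I*(x, y; kx, ky) / log2 min(kx, ky),

B(n) = max(⌊n^0.6⌋, 4). I\* is approximated with ApproxMaxMI: the y-axis is
equipartitioned into ky rows by a greedy tie-respecting rule (tied values
never split across rows), and the x-axis partition into ≤ kx columns is
then optimized *exactly* by dynamic programming. The DP exploits the
identity I(P;Q) = H(Q) − H(Q|P): with the row partition Q fixed, the total
conditional entropy is additive over columns, and an optimal partition only
needs cuts at *clump* boundaries (maximal runs of x-consecutive points in a
single row; x-ties are unbreakable). When clumps outnumber c·kx
(clumps_factor c = 15) they are coarsened into superclumps of near-equal
mass. Both axis orientations are computed and the larger value kept. All
partitions are rank-based, so MIC is invariant under strictly monotone
transforms of either variable; constant input gives MIC 0 by convention.
The kernel is numba-compiled; at the pipeline's n = 28 samples a single
MIC evaluation costs a few microseconds.

The test suite checks the DP against exhaustive search two ways: per
orientation it must *equal* brute-force search over every free-axis
partition (the quantity it optimizes — equality to 1e-9, exercising the
clump lemma), and the whole statistic is compared with an independently
coded brute-force ApproxMaxMI at the study's sample count. Note that the
equipartition of one axis is a genuine restriction: full joint optimization
of both axes can exceed the heuristic by up to ~0.3 at small n, for any
faithful implementation of this algorithm family. The heuristic, not the
joint optimum, is the statistic computed by the standard tools, so it is
what this package implements and validates.

**Significance.** Published p-value tables for this statistic are tied to
specific n and parameter sets; we replace them with an explicit permutation
null — y is shuffled (default 1000 times) and
p = (1 + #{MIC_perm ≥ MIC_obs}) / (1 + N). The p < 0.01 edge-selection cut
is kept. The permutation p-value is finite-sample valid and slightly
conservative by construction; calibration (rate of p < 0.01 on independent
pairs within 3 binomial SE of 0.01) is asserted in the acceptance tests.
No multiple-testing correction across pairs by default (a Benjamini–
Hochberg flag exists), preserving the raw-threshold convention of the
procedure this package reproduces.

**Sign.** The nonlinearity statistic MIC − r² (r = Pearson correlation)
assigns the sign: strictly above 0.5 → negative association (strongly
non-linear, exclusion-like co-occurrence), otherwise positive. The rule is
isolated in `edge_sign` so an alternative reading can be swapped in.

## Network statistics

The graph is simple and undirected; isolated OTUs are excluded. The
clustering coefficient C is the mean *local* clustering coefficient with
degree-<2 nodes contributing 0, and the characteristic path length L is
the mean shortest-path length over connected ordered pairs (the number of
excluded disconnected pairs is logged; L over the largest component is also
reported). These match the conventions of the interactive network-analysis
tools whose outputs this package mirrors. The random null is uniform
G(n, m) with the observed node and edge counts (default, 100 replicates;
mean Cr ≈ 2m/n(n−1) as expected for Erdős–Rényi graphs) — the pattern of a
much lower Cr and shorter Lr characteristic of G(n, m) matches the
reported behaviour of the tool-generated randomizations this null stands
in for — with degree-preserving edge-swap randomization (≥ 10·|E| swaps)
as an alternative. Hubs are nodes with degree ≥ `min_degree` (default 20,
matching the degree range that delimited hubs in the full-scale survey this
pipeline targets); the threshold is configurable because an absolute degree
cut only makes sense relative to network size — the benchmark suite uses a
top-decile rule on its ~60-node networks.

## Synthetic data generator

Each OTU gets a lognormal(0, σ = 1.8) mean abundance (few dominant taxa,
long rare tail); planted classes take fractions 0.15/0.15/0.20 (specialists
A/B, generalists) with the remainder "rare" (mean abundance scaled by
0.002, landing them near the detection limit). A specialist's expected
abundance is `habitat_effect` (default 8) times higher in its preferred
habitat; each OTU has a preferred date boosting it `season_effect`-fold
(default 4). The design mirrors a paired lagoon/sea survey: 4 + 3 stations
× 4 dates × 2 replicates = 56 samples. Library sizes are lognormal around
`depth_mean` (default 20,000, dispersion 0.3) — unequal on purpose, to
exercise rarefaction — and counts are multinomial given the per-sample
expected composition, so column sums equal library sizes exactly.

Association blocks plant co-occurrence: members share a per-sample
lognormal latent factor (σ = `strength`), inducing positive rank
association detectable by MIC. Optional per-OTU-per-sample lognormal
overdispersion (`otu_noise_sigma`, default 0) models sample-to-sample taxon
fluctuation beyond multinomial noise.

What the generator does *not* emulate: sequence-level artifacts (chimeras,
clustering errors), realistic taxon proportions, compositional coupling
beyond the multinomial constraint, and spatial autocorrelation among
stations. Passing the benchmark therefore shows the statistics recover the
structure they model — not that they are robust to every artifact of real
metabarcoding data.

Two benchmark regimes are used deliberately. CLAM calibration (type-I
error ≤ 2α among abundant OTUs on null data; recall ≥ 0.9 for strong
planted specialists) is checked under the pure multinomial model
(`otu_noise_sigma = 0`), which is the sampling model the conditional
binomial assumes. The end-to-end network benchmark instead switches
overdispersion *on* (σ = 0.8): without it, every specialist pair shares a
near-deterministic habitat step pattern and the network is blanketed with
habitat edges that mask the planted blocks — an artifact of noiseless
simulation, not a property of real communities. Under overdispersion the
conditional binomial is misspecified and CLAM over-calls specialists; this
is a real limitation of the method on overdispersed data (shared with the
standard implementations) and is documented rather than patched.

## Numerical and degenerate-input choices

* Rarefaction curves use the exact hypergeometric expectation via
  log-gamma, not resampling; a Monte-Carlo mode exists in the test oracles.
* Shannon uses natural log (values quoted for thousand-OTU communities in
  this literature are consistent with nats).
* All-zero sample columns are hard errors for Hellinger/Bray-Curtis;
  all-zero OTU rows are legal and flow through as too-rare/absent.
* OTUs absent from both habitat pools are reported `too_rare`, never
  silently dropped.
* Every randomized stage takes an explicit seed; the pipeline derives
  per-stage seeds deterministically from one master seed and records them
  in the run manifest, which suffices to reproduce a run bit-identically.
* Problem sizes in the benchmark (120–500 OTUs, 56 samples, 100–200
  simulation replicates, 1000 permutations) were chosen so the full suite
  and the acceptance script each complete in minutes on one CPU while
  leaving wide statistical margins.

## Known limitations

* The package analyzes exactly two habitats; multi-habitat designs are out
  of scope.
* MIC p-values are per-pair permutation tests; at thousands of pairs the
  raw p < 0.01 threshold implies a nontrivial number of false edges (as in
  the procedure reproduced here). Use the BH flag for error-rate control.
* CLAM assumes multinomial sampling of pooled reads; overdispersion
  inflates specialist calls (see above).
* Ordination (nMDS/CCA/adonis) is intentionally not reimplemented; the
  package exports the Hellinger and Bray–Curtis matrices those methods
  consume.
* The shipped trophic rules encode only group-level conventions;
  species-level assignments are user data.
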