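# Methods

This note documents the models, estimators, numerical choices, and known
limitations behind `avanet`, in the order the analysis runs.

## Synthetic data: what is emulated, and what is not

The package is exercised entirely on synthetic data with known ground
truth; no recorded data ship with it. Three generative families cover the
analysis surface.

**Branching-process rasters** (`simulate_branching_raster`). Cascade
dynamics on an `n_rows × n_cols` electrode grid. Propagation happens in
micro-steps (branching generations): a node active at one micro-step
activates each node of its offspring pool at the next micro-step with
probability σ/deg, so the expected offspring per active node is exactly
the branching ratio σ. Three design choices matter:

- *Mean-field offspring pool.* By default every other node on the array is
  a potential target. Restricting the pool to lattice neighbors
  (`neighborhood_radius`) turns the dynamics into 2-D directed-percolation
  spread, whose avalanche exponents (size exponent ≈ 1.25, collapse
  exponent ≈ 1.5) differ from the mean-field branching values (3/2 and 2)
  that this analysis is anchored to. The mean-field pool is the classic
  critical-branching-network model of an electrode array.
- *Binary saturation.* Node states are binary per micro-step: simultaneous
  activations of one target merge. Without saturation a critical cascade's
  population grows without bound (a single avalanche can absorb millions
  of events); saturation supplies the finite-size cutoff near the array
  size that a physical preparation has.
- *Two generations per bin* (`generations_per_bin = 2`). Event binning is
  coarser than synaptic propagation, so one raster bin aggregates several
  branching generations. A single-seeded branching process observed at one
  generation per bin is pre-asymptotic at the short lifetimes (L = 3–5)
  the collapse uses: a Monte-Carlo oracle of the pure process gives an
  apparent collapse exponent of ≈1.6 there, with ⟨S⟩(L) ~ L^1.4. Two
  generations per bin put L = 3–5 bins at 6–10 generations, inside the
  asymptotic regime (χ ≈ 2.0 measured), and make multiple events per node
  per bin occur naturally inside avalanches.

The default drive (2·10⁻⁴ spontaneous events per node per bin) puts a
10 × 10 grid at criticality in the regime where the pooled ⟨IEI⟩ is 1–2
bins, i.e. where binning at ⟨IEI⟩ balances premature termination against
concatenation of avalanches — the operating point of the avalanche
definition. These defaults were fixed during generator design and define
the package's study conditions.

**Cascades on a known network** (`simulate_cascades_on_network`). Counts
propagate per link with probability weights[i, j] per activation
(binomial thinning), plus Poisson drive. This simulator is deliberately
*not* saturating so that empirical transition frequencies converge to the
generative probabilities (the law-of-large-numbers check in the tests
conditions on frames where one node is active alone). It refuses to
continue when the population runs away, which happens if row sums of the
weight matrix are supercritical — scale the weights instead. Ground-truth
topologies: `make_small_world_network` (Watts-Strogatz with log-normal
directed weights) and `make_integrative_network` (strong links inside
cliques, sparse weak links between them, so link weight is coupled to
neighborhood overlap by construction).

**Continuous signals** (`make_synthetic_signal`). White Gaussian noise
plus one 20 ms negative biphasic kernel (inverted Ricker) per raster
event, trough aligned to the bin center, depth in units of the raw noise
SD. Two consequences the tests respect: the 1–100 Hz band-pass removes
~90% of white-noise power, so planted depths are ≈2.5× deeper relative to
the *filtered* noise; and kernels superpose linearly, so events closer
than the kernel width on one channel stack into deep excursions. Distinct
events are therefore only resolvable when per-channel activity is sparser
than the kernel — the regime matching real recordings, where multiple
nLFPs per electrode per avalanche are rare. Dense critical rasters pushed
through the signal layer produce stacked deflections that the artifact
stage (correctly) treats as out-of-range; end-to-end signal studies use
subcritical dynamics, or raise the artifact threshold when the synthetic
signal is known to contain no artifacts.

**Drifting sessions** (`generate_session_sequence`). Each day a fraction
of links is redrawn from the day-1 weight pool (preserving the marginal
distribution while mixing link identities) and all links get
multiplicative log-normal jitter. This provides the ground truth for the
entropy-of-mixing trend: zero drift ⇒ flat H_M; ≥5%/day resampling ⇒ a
monotone rise.

What the synthetic data do **not** emulate: biophysical LFP generation,
volume conduction, γ-oscillations, electrode impedance drift, non-Poisson
artifacts. Passing tests therefore certify the estimators and their
contracts, not robustness to those phenomena.

## Preprocessing

Sixth-order Butterworth band-pass (1–100 Hz, zero-phase forward-backward,
so event peak times are not lag-shifted) plus a Q = 30 notch at 60 Hz.
Artifacts are samples where any channel exceeds 7 SD, padded by ±0.25 s,
recorded in a per-sample mask that every downstream statistic honors;
thresholds are computed on retained samples so artifacts cannot inflate
the scale. Z-scoring is per channel over retained samples; zero-variance
channels are dropped and logged. nLFP detection takes one event per
contiguous sub-threshold (≤ −2 SD) excursion at the excursion's most
negative sample, quantized to 0.5 ms; no sub-sample interpolation.
Binning is half-open with the origin at recording start, so boundary
events go to the later bin and counts are conserved exactly.

## Avalanche statistics

Sizes are fitted on the fixed window S ∈ [1, 40] (below the cutoff near
the array size) with a *discrete* power-law MLE, normalizing over the
window rather than conditioning on the tail; at s_min = 1 the continuous
approximation is badly biased. The exponential and log-normal
alternatives are normalized over the same window, and model choice uses
the Vuong-style normalized LLR with a two-sided p; positive LLR and
p < 0.05 favor the power law. The exponential rate and log-normal (μ, σ)
are themselves MLEs (1-d bounded and Nelder-Mead respectively). A
configurable floor (default 100 in-window sizes) guards the fit.

## Shape collapse

Profiles use bin centers, t → (t − 0.5)/L, which treats the first and
last bins symmetrically. Each mean profile is rescaled by L^−(χ−1),
mapped onto a 25-point common grid spanning the overlap of the bin
centers, and Δ_F(χ) is the mean squared deviation of the rescaled
profiles from their pointwise average, divided by the squared range of
that average. This normalization makes Δ_F scale-free (χ̂ is exactly
invariant to multiplying all profiles by a constant) and gives the
failure threshold Δ_F > 1 a meaning independent of units. Interpolation
is exact polynomial through the profile points for short profiles (≤7
points; the unique parabola through 3 points is reproduced exactly, so
analytically constructed families are recovered to the 0.001 scan step),
falling back to a cubic spline for longer profiles to avoid Runge
oscillation. The arg-min over the χ grid (0.5–3, step 0.001) takes the
first minimum on ties.

Profile-model comparison fits y = A·[(t/T)(1 − t/T)]^m with amplitude and
shape exponent free (m = 1 is the exact inverted parabola) against an
amplitude-scaled semicircular arc y = A·sqrt(1 − (2t/T − 1)²) over the
normalized lifetime; the semicircle amplitude has a closed-form
least-squares solution. Per-profile RMSEs feed a paired t test and a
one-way ANOVA. Profiles at different Δt are analyzed as separate runs;
absolute durations are never compared across Δt.

## Network reconstruction

NC: for every activation of node j in frame b, the candidate causes are
the nodes active in the preceding window (default one frame), excluding j
itself; each accrues credit 1/|A| per activation (so one activation
distributes exactly one unit of credit), and w_ij is j's accumulated
credit divided by j's total activation count, making weights comparable
across nodes. Frames with no active predecessor are attributed to
external drive and contribute nothing. The estimator is deterministic and
permutation-equivariant. Sub-bin windows clamp to one bin. Reconstruction
spreads faint spurious credit over most pairs, so graph-theoretical
analyses run on a sparsified network (`threshold_graph`, default 40% link
density, matching the correlation network's sparsity); the mixing
analysis keeps the full weighted reconstruction.

The correlation network uses pairwise Pearson R on retained samples and
raises the threshold from below the weakest correlation in 0.01 steps,
stopping at the first step where undirected link density ≤ 40%. If every
pair is identically correlated the procedure cannot terminate meaningfully
and raises with a diagnostic.

## Integrative metrics

C_L of link (i, j) = |N(i) ∩ N(j)| / |N(i) ∪ N(j) \ {i, j}| with
neighborhoods on the binarized graph ignoring direction; links whose end
nodes have no other neighbors get C_L = 0. The null model is
degree-sequence preserved randomization: repeated double-edge swaps
(a→b, c→d) → (a→d, c→b), rejecting self-loops and multi-edges, weights
traveling with their source slot; 10× the link count swaps per replicate,
20 replicates by default, degree preservation asserted on every call.
Links are sorted by weight with a lexical node-pair tie-break and split
into 10 rank blocks (equal counts to within one); ΔC_L is the observed
block mean minus the randomized expectation, and R_CL is the Pearson
correlation of per-link C_L with raw weight. Pruning removes the weakest
(or strongest) fraction of links in 5% steps and tracks mean node
clustering minus its randomized expectation; node clustering is computed
in closed form from the adjacency matrix (triangle counts via A³).

## Entropy of mixing

Category and group assignment is rank-proportional: the r-th weakest of n
links gets category ⌊r·N_c/n⌋ + 1 and, on a later day, group
⌊r'·N_g/n⌋ + 1 by its new rank r'. Because N_g = k·N_c with integer k,
the group partition refines the category partition for *any* n, so the
day-1 self-comparison gives H_M = 0 exactly, not just approximately, and
block sizes are equal to within one. Ties and absent links (zero weight
on a later day, ranked at the bottom and logged) break by node-pair
lexical order. H_g uses natural logarithms; the theoretical maximum
ln N_c is reported alongside. H_M averages the non-edge groups
g = 2…N_g−1 (13 groups at the defaults), with σ_G their standard error.
The trend test regresses H_M on day, then draws N_MC = 10⁶ pure-noise
replicates N(0, σ_G) per point and counts slopes exceeding the observed
one: p = (N_pos + 1)/(N_MC + 1), one-sided. Zero σ_G gets a jitter floor
with a warning. The randomized baseline permutes labels uniformly and
recomputes H_M (per session); it approaches ln N_c only for large link
counts — with few links per group the plug-in entropy is biased low, which
is visible in small examples.

## Pipeline

`run_study` composes the stages per session (with Δt = ⟨IEI⟩ rounded to
the nearest 0.5 ms under the "iei" policy), then cross-session OLS
stability slopes with 95% confidence limits, pruning curves, and the H_M
trajectory. Sessions that fail any stage are quarantined with their error
message while the study continues. All randomized stages derive their
seeds from the study seed via `SeedSequence`, and reported floats are
rounded to 12 significant digits so reruns are byte-identical (vectorized
reductions can wobble the last ulp with memory alignment).

## Problem sizes

Defaults used by the test suite and the acceptance script: 5·10⁵-bin
branching rasters for the scaling targets (≈270k events), 10⁵-bin
cascades for ground-truth network recovery, 30-node planted integrative
graphs, 10-session drift sequences, and 10³–10⁵ Monte-Carlo replicates
in tests (10⁶ available and default in `trend_test` for production use).
These sizes give the estimators comfortable convergence margins at
desk scale.

## Known limitations

- The branching generator's χ depends on the generations-per-bin
  aggregation; at one generation per bin the L = 3–5 collapse is
  pre-asymptotic (χ̂ ≈ 1.6). This is a property of short lifetimes, not of
  the scan.
- Avalanche lifetime (duration) distributions are deliberately not fitted.
- NC normalization is validated by ground-truth rank recovery, the
  criterion its design targets; absolute weight calibration is not
  claimed.
- The entropy-of-mixing baseline is biased below ln N_c for small link
  counts (plug-in entropy bias); comparisons should use the reported
  baseline, not the theoretical maximum.
- The signal synthesizer superposes kernels linearly; it does not model
  amplitude saturation of real extracellular media.
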