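# avanet

Analysis of ongoing cortical population activity through the lens of
neuronal avalanches and the functional networks they generate: from
continuous multichannel (LFP-like) recordings to avalanche scaling
statistics, temporal-profile shape collapse, directed network
reconstruction, integrative-network metrics, and an entropy-of-mixing
statistic for the long-term stability of individual link weights.

The package is aimed at researchers working with chronic multielectrode
recordings (or models thereof) who want tested, reproducible
implementations of this analysis chain, exercised end to end on synthetic
data with known ground truth.

## What it computes

**Avalanches.** Negative LFP deflections crossing −2 SD (nLFPs) are
detected per electrode, pooled, and binned at Δt (typically the mean
inter-event interval ⟨IEI⟩). An avalanche is a maximal run of consecutive
occupied bins bracketed by empty bins; its size *S* is the total event
count. Sizes follow P(S) ∝ S^−α; the package fits α by discrete maximum
likelihood on a fixed window (S = 1…40) and tests the power law against
exponential and log-normal alternatives with a normalized log-likelihood
ratio (LLR). A critical branching process predicts α = 3/2.

**Shape collapse.** Mean temporal profiles ⟨S⟩(t, L) for lifetimes
L = 3–5 bins are rescaled by L^−(χ−1) and overlaid on a common t/L grid;
the scaling exponent χ minimizes the collapse error Δ_F (χ scanned 0.5–3
in steps of 0.001). Critical branching predicts an inverted-parabola motif
with χ = 2; time-shuffled data collapse near χ = 1 with a flat motif.

**Functional networks.** The normalized-count (NC) estimator reconstructs
directed weights w_ij from event rasters by splitting the causal credit of
each activation equally among the nodes active in the preceding frame,
then normalizing per target. A correlation-threshold network (Pearson R,
threshold raised in 0.01 steps until ≈40% link density) is provided for
comparison.

**Integrative organization.** Per-link clustering C_L (shared fraction of
the end nodes' neighborhoods), its excess ΔC_L over degree-sequence
preserved randomization, the weight–clustering correlation R_CL, and
top/bottom pruning curves of excess node clustering ΔC.

**Entropy of mixing.** Links of a reference day are labeled by weight
quintile (N_c = 5); on later days the same links are re-ranked and split
into N_g = 15 groups, and H_M is the mean Shannon entropy of the original
labels within the non-edge groups (natural log; H_M = 0 when ranks are
unchanged, → ln 5 ≈ 1.609 under complete reshuffling). A Monte-Carlo test
(p = (N_pos + 1)/(N_MC + 1)) decides whether H_M rises across sessions.

**Synthetic ground truth.** `avanet.synth` generates everything the
analysis consumes: critical/subcritical branching rasters on an electrode
grid, cascades on known weighted digraphs (small-world, planted
integrative), continuous signals with planted negative deflections,
multi-day sequences with controlled network drift, and time-shuffle
controls.

## Worked example

```python
import avanet as an

# 100 s of critical branching activity on a 10 x 10 array
cfg = an.SimConfig(n_rows=10, n_cols=10, branching_ratio=1.0,
                   n_bins=100_000, seed=7)
raster = an.simulate_branching_raster(cfg)

avalanches = an.segment_avalanches(raster)
fit = an.fit_size_distribution([a.size for a in avalanches])
res = an.collapse_profiles(an.mean_profiles(avalanches, L_set=(3, 4, 5)))
shuffled = an.shuffle_raster_times(raster, seed=8)
res_s = an.collapse_profiles(
    an.mean_profiles(an.segment_avalanches(shuffled)))
```

This prints (via the obvious f-strings):

```
1865 avalanches, alpha = 1.43 (LLR vs exponential = 369, p = 1.2e-35)
collapse: chi = 1.94, Delta_F = 0.007
shuffled control: chi = 1.02
NC reconstruction: Spearman rho vs ground truth = 0.82
```

α ≈ 1.4–1.5 and χ ≈ 2 are the critical-branching signatures; the positive
LLR with tiny p says the power law beats an exponential decisively; the
shuffled control collapsing at χ ≈ 1 confirms that the parabolic motif
comes from spatiotemporal correlations, not from the event rate. The last
line reconstructs a known 20-node small-world network from 10^5 bins of
cascades (`an.make_small_world_network`, `an.simulate_cascades_on_network`,
`an.nc_reconstruct`) and rank-correlates the recovered weights with the
generative ones.

For a full multi-session study (per-session α, χ, R_CL, cross-session
stability slopes with 95% confidence limits, pruning curves, and the H_M
trajectory with its trend test) see `avanet.pipeline.run_study`.

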