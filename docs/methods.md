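# Methods

This note records the models implemented in `qontour`, the numerical
choices made where the published formulations are silent or ambiguous,
and what the synthetic phantoms do and do not establish about behaviour
on real scans.

## Raster conventions

Volumes use 0-based indices in (slice, row, col) order; NIfTI data is
transposed on read so the slice axis comes first, and spacing follows the
same order. Masks are written as unsigned 8-bit 0/1 NIfTI. Z-score
normalization uses the population (divide-by-N) standard deviation.

## Synthetic phantoms

The phantoms emulate the statistical structure of contrast-enhanced
abdominal MR without claiming MR physics: one bright ellipsoidal "liver"
(default mean 180) over darker background (default mean 80), additive
Gaussian noise (`noise_sd`, default 0; the standard noisy cohort uses 8),
a smooth multiplicative bias field built from one half-period cosine per
axis and rescaled to span exactly 1 ± `bias_amplitude`, and three
contrast phases realized as liver-only intensity multipliers (pre-contrast
1.0, arterial 1.3, venous 1.15 — fixture values, not physiology). An
optional dark distractor sphere exercises the largest-connected-component
post-processing. Markers stand in for AI predictions: `oracle` (the truth),
`eroded`/`dilated` (one structuring-element pass by default), and `noisy`,
which flips exactly `round(error_rate × n)` voxels of the two-sided
boundary band (inner boundary plus face-adjacent background), seeded.

What the phantoms do **not** emulate: heterogeneous liver texture,
neighbouring organs of similar intensity, partial-volume boundaries, and
scanner-dependent artifacts. Passing the phantom suites therefore shows
the algorithms are implemented coherently and behave as designed on
clean, high-contrast input; it says nothing about clinical Dice levels,
which on real abdominal MR are known to be far lower for the two
unguided methods.

## Qutrit fuzzy network

Inputs are min-max scaled to [0, 1] (hence invariance to constant
intensity shifts); border pixels are handled by edge replication so every
pixel has 8 neighbours. Per pixel t with neighbours j ∈ {1..8}:

* cardinality B_t = Σ over the 3×3 window of μ, amplitude A_t = 2πB_t;
* frequency ω_t = 2π(2π − d_t) with d_t = Σ_j (μ_j − μ_t);
* aggregated input x_t = Σ_j μ_j cos(ω_t − A_t);
* membership angle α_{t,j} = π/2 − (μ_t − μ_j), so α ∈ [π/2 − 1, π/2 + 1]
  (equality to π/2 exactly on flat neighbourhoods);
* threshold angle γ_t and gray-level index λ_ω, below;
* activation σ(x) = 1/(λ_ω + e^(−ν(x−β))) with β = 0.5 on the scaled
  range (the midpoint; no published value exists) and exponent clipping
  at ±700 to avoid overflow.

**Interpreted readings.** The published formulations of this network carry
index-ambiguous sums; the readings adopted here are isolated in
`neighborhood_features` and `qisnet_iterate` so they can be audited in one
place:

* γ_t is taken as (π/2)·(mean of the 8 neighbour intensities). A literal
  2π × (neighbour *sum*) is degenerate modulo 2π at both intensity
  extremes — an all-0 and an all-1 neighbourhood land on the same angle —
  which collapses foreground and background; a quarter-period span keeps
  the threshold monotone in neighbourhood brightness.
* λ_ω is the interval width F(l) − F(l−1) of the selected transition-table
  row, where l is the quantization bin of the 8-neighbour sum S_N ∈ [0, 8],
  rescaled by the row's maximum width onto (0, 1] and floored at 1e-6 so
  the activation stays finite.
* The two rotation layers are implemented as
  h_t = σ(x_t) Σ_j cos(α_{t,j} − γ_t) e^{+2πi s_j} (counter-clockwise) and
  z_t = σ(x_t) Σ_j cos(α_{t,j} − γ_t) e^{−2πi q_j} (clockwise), where s is
  the current population map and q = clip(|h|², 0, 1); the measured
  population is clip(|z|², 0, 1). Because only the phases carry the state,
  a constant image reaches a fixed point after a single iteration — the
  magnitude of a sum of equal-phase terms does not depend on the common
  phase.

The transition table ships twelve rows: the eleven published candidate
ladders plus the variant reported as consistently best,
[0, 0.04, 0.28, 0.42, 0.56, 0.70, 0.90, 1.0], which differs from row 2
only in its second level (0.04 vs 0.14). Whether that difference is a
typo cannot be resolved from the sources, so both rows are available;
row 12 is the default.

Iteration stops when the mean absolute population change falls below
1e-4 or after 50 iterations (no published stopping rule exists; on the
48×48 phantoms the cap dominates and one sweep of four ν values runs in
under a second). 3D volumes are processed slice-wise — the network is
defined on 2D 8-neighbourhoods — and the slices are restacked before 3D
post-processing. Binarization uses the highest of the 4-level Otsu
thresholds; when the converged map has fewer than four distinct values
the split falls back to the gap below the top value, and an all-constant
map yields an empty mask with a warning flag rather than an exception.

## NAQSS encoding and Grover amplification

Intensities are quantized to M levels (default 256) by uniform binning
of the min-max range; an image entirely at the minimum level has all
colour angles zero and is rejected as unnormalizable. Non-power-of-two
inputs are padded with zero-amplitude, label-0 states. The simulation
operates directly on the real amplitude vector — oracle as a sign flip of
marked entries, diffusion as reflection about the mean — rather than on a
2ⁿ complex statevector with gate decompositions; the original study
likewise ran the algebra classically without noise modelling. The test
suite carries an independent small-N statevector oracle (explicit
2|s⟩⟨s| − I diffusion matrix) and the analytic rotation formula; the
three routes agree to better than 1e-9 across N ≤ 64.

The iteration-count formula needs an interpretable φ: the expression is
implemented as φ = arctan((A₀/L₀)·√(r/(N−r))), the only reading that (a)
reduces, for uniform amplitudes (A₀ = L₀), to the textbook rotation
ω = 2·arcsin√(r/N) with t ≈ (π/4)√(N/r), and (b) is validated by the
statevector oracle (N = 4, r = 1 gives ω = π/3, φ = π/6, t = 1 and
success probability exactly 1). Fractional t is rounded half-up with a
floor of 0; when L₀ = 0 (all amplitude already marked) t = 0. Recovery
thresholds the final squared amplitudes at the uniform level 1/N; at
superpixel granularity a superpixel is marked when more than half its
voxels are marked, and recovered labels are broadcast back to voxels.

## Graph-energy cuts

Superpixels come from compact k-means-style clustering over intensity
and scaled coordinates (SLIC; the only named design constraint is
compactness, and SLIC is the standard realization). The graph is kept
fully connected — no k-NN sparsification — which is cheap for ≤ 1024
nodes. The Gaussian bandwidth σ defaults to the standard deviation of
the pairwise |S_i − S_j| values, floored at 1 on constant images where
any bandwidth is equivalent.

The energy is realized exactly as a Rayleigh quotient: unary part
diag(seed indicator), binary part λ(D − W) with D the diagonal of column
sums (the ordered-pair sum Σ_ij w_ij(z_j² − z_i z_j) equals zᵀ(D − W)z
for symmetric W). λ defaults to 1. E_binary sums over *ordered* pairs;
the exhaustive oracle in the tests uses the same convention. Seeds
default to max(1, 5% of nodes) lowest-mean superpixels (the published
rule, suited to dark targets); `invert_seeds=True` selects highest-mean
seeds for bright organs such as the phantom liver, leaving the printed
default intact.

Mapping the relaxed eigenvector to labels is not specified anywhere, so
this package's rule is: orient z so its sum is positive, threshold z² at
the highest 4-level Otsu split (falling back to the mean of z² when z²
is nearly two-valued), assign +1/−1 about the split and 0 to exact
zeros, and declare **foreground the class containing the majority of
seeds** — the unary term pushes z toward 0 on seeds, so seeds land in the
low-z² class, and any other reading would make the seeds label the
background. The discrete labeling's energy is compared against
exhaustive {−1,0,1}ⁿ minimization for n ≤ 8 in the tests; the relaxation
gap is asserted non-negative and reported, never hidden — on random
graphs it can be substantial, which is a property of the one-eigenvector
relaxation, not a defect of the solver.

## Post-processing and metrics

All methods share the same post-processing: largest connected component
(8-connectivity in 2D, 26 in 3D; size ties broken by lowest linear voxel
index) followed by hole filling with the complementary background
connectivity (4/6). Dice is defined 1.0 when both masks are empty;
Hausdorff distance is computed between inner-boundary voxel sets with
the Euclidean metric, in voxel units by default (mm when a spacing is
passed — published distance figures state no unit, so none is asserted),
and returns infinity as a flag when either mask is empty. Multi-Otsu
uses 256 histogram bins with exhaustive between-class-variance
maximization.

## Evaluation harness

`run_cohort` runs any method subset over a phantom cohort and reports
median ± population sd of Dice and (finite) Hausdorff per method,
mirroring the usual summary-table style. Every artifact carries the
configuration hash and seed; identical configurations produce
byte-identical CSV output. Per-case failures are logged and recorded in
the result, never dropped. The standard noisy cohort (five 48×48 cases,
noise sd 8, 10% bias field, 10% marker boundary error, phases cycling)
reproduces the expected qualitative ordering: marker-guided Grover ≥
marker-only baseline > qutrit network and graph cuts. Default problem
sizes (48×48 cohort cases, 64 superpixels, M = 256 levels) were chosen
so the full comparison runs in seconds while every method still has
hundreds of boundary voxels to get wrong; all of them scale up via
parameters.

## Known limitations

* The qutrit network's formulas are interpreted (see above); other
  readings of the ambiguous indices would change its dynamics. The
  readings are confined to two functions for auditability.
* Grover here is algebra, not hardware: no gate decomposition, no noise,
  no measurement sampling. Resource accounting stops at logical qubit
  counts; physical-qubit embedding on real annealers is out of scope.
* QCuts inherits the known weaknesses of intensity-only graph cuts:
  without correctly oriented seeds it happily returns the background
  (visible in the cohort numbers), and the one-eigenvector relaxation of
  a three-valued labeling can be loose.
* Slice-wise qutrit segmentation degrades near the poles of small 3D
  phantoms, where per-slice cross-sections shrink to a few voxels.
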