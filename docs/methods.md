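# Methods

## Chain matching as min-cost flow

The matcher maximizes the number of disjoint chains (one particle per
channel, adjacent distances ≤ t) and, among maximal matchings, minimizes
the summed adjacent-pair distance. Both objectives are folded into one
linear program by giving every completed chain a reward λ: chain cost
Σ d(xⱼ, xⱼ₊₁) − λ, with marginal constraints that let particles stay
unmatched. Because the cost decomposes over adjacent channel pairs, the
program is solved as a min-cost flow on a layered network:

- per particle a node pair v → v̂ joined by an edge of cost −λ/k′
  (k′ = chain length) and capacity 1 — using the split edge is the only
  way to traverse a particle, which enforces the one-to-one constraint;
- edges v̂⁽ʲ⁾ → v⁽ʲ⁺¹⁾ with cost d and capacity 1 wherever d ≤ t; pairs
  beyond t are simply not added;
- source → first layer and last layer → sink at cost 0, capacity 1, plus
  a free source→sink edge of infinite capacity, so the requested flow
  m = minⱼ nⱼ is always feasible and unmatched mass is costless.

Total unimodularity guarantees an integral optimum; we solve with
`networkx.network_simplex`. Solver details:

- **λ default** = (k′−1)·t_max + 1 distance unit. Any feasible chain then
  has negative net cost, so maximal matchings always win; results are
  identical for every λ above the (k′−1)·t_max bound (property-tested).
  Overridable for users who want a different unmatched penalty.
- **Cost discretization**: the simplex backend needs exact arithmetic, so
  distances are scaled by 10⁶ and rounded to integers; the induced error
  is ≤ 10⁻⁶ per edge and cannot change the matching unless two matchings
  are cost-degenerate at that resolution (in which case either is optimal
  to within the guarantee).
- **Ties**: multiple cost-optimal matchings may exist. The contract is
  the structure counts and total cost, never specific assignments; node
  insertion is channel-major, index-minor, so a given input always
  produces the same solution.
- Distance ties at exactly d = t are inclusive; coincident particles
  (distance 0) match at any t ≥ 0. 2D and 3D coordinates, per-pair
  thresholds t_{j,j+1} (edge admission per pair, λ from the maximum) and
  user-supplied distance matrices are supported throughout.

**Mode I** solves the full k-marginal problem, removes matched particles,
then re-solves shorter-chain problems on the leftovers in priority order
(default: longest first, left to right, e.g. ABC → AB → BC). Each stage
re-optimizes only over its own structure; the stated priority-order
semantics is followed rather than a joint re-optimization over all
leftover pair types, whose result can differ when leftovers are
contested. **Mode II** solves the k−1 adjacent-pair problems
independently and couples pairs through shared particles (union-find;
components are necessarily contiguous chains since a particle carries at
most one left and one right link). The greedy nearest-neighbor baseline
repeatedly accepts the globally closest unmatched admissible pair
(deterministic tie-break by distance, then channel pair, then indices)
and couples like Mode II; it exists to demonstrate how local pairing
breaks chains that the global matching keeps.

Abundance curves re-run the configured mode per grid point, re-deriving λ
from each t. Relative abundances divide by the detected particle count of
a scaling channel — channel B by default, exposed as a parameter since
for k > 3 no canonical anchor exists.

## Labeling-efficiency correction

Each particle of channel i is observed independently with probability
s_i ∈ (0,1]. For a true structure spanning channels a..b the observed
detection pattern is one of 2^k channel subsets (subsets outside the span
have probability 0); its probability is Π s_i over detected members times
Π (1−s_i) over missed ones. A pattern is counted as its **maximal
contiguous runs**: for k = 3, the pattern A·C of a true triplet is one A
and one C singlet; for k = 4, A·CD is one A singlet plus one CD pair.
This run rule is the general-k extension of the three-color bookkeeping
and is what the aggregation matrix Θ encodes (Θ[structure, pattern] =
number of runs of that pattern equal to the structure). Patterns are
ordered size-descending, contiguous-first; structures longest-first,
left-to-right (ABC, AB, BC, A, B, C for k = 3). The test suite verifies
Θ, μ = [p_ABC … p_C] and (Θμ)⁻¹ against the closed-form three-color
matrices symbolically.

Since E[W] = Θμn, n̂ = (Θμ)⁻¹W is unbiased. Negative entries of n̂ are
reported raw — flooring would bias the estimator; they are clipped to
zero only inside the plug-in covariance Σ(n̂) = Σᵢ n̂ᵢ(diag(pᵢ) − pᵢpᵢᵀ) so
that Σ stays positive semidefinite. The statistic
Ξ = (n̂−n₀)ᵀ(Θμ)ᵀ(ΘΣ(n̂)Θᵀ)⁻¹(Θμ)(n̂−n₀) is asymptotically χ² with as many
degrees of freedom as observable structures (6 for k = 3); if ΘΣΘᵀ is
singular (singular values below 10⁻¹⁰ of the largest) its pseudoinverse
is used and the degrees of freedom drop to the rank. The 1−α region is
{n₀ : Ξ ≤ χ²_{r,1−α}} — the *upper*-α critical value; a 90% region at
α = 0.1. Per-structure intervals are ellipsoid **slices** (all other
abundances fixed at n̂): half-width √(χ²_{r,1−α}/Q_jj) with
Q = (Θμ)ᵀ(ΘΣΘᵀ)⁻¹(Θμ). Slices are narrower than shadows (projections);
we document and implement the slice reading, matching the "fixing the
other estimated abundances" semantics. Degenerate limit s ≡ 1: the model
is deterministic, Σ = 0, rank 0, n̂ = W exactly and all intervals collapse
to the point estimate. Curve bands are pointwise in t, with no
multiplicity adjustment across the grid.

Estimation of unknown efficiencies from data is out of scope; s is
assumed known (e.g. from staining controls).

## Synthetic data generator

The simulator emulates three-color STED recordings of nanoruler-like
chains: 400×400 px images at 25 nm/px, chain spacing 70 nm = 2.8 px,
PSF FWHM 40 nm (σ = FWHM/(2√(2 ln 2)) ≈ 0.68 px). Chains are drawn in
pixel units: the anchor (second channel of the span) uniform on the
image; the preceding member at a uniform angle and distance N(2.8, 0.5²)
px; subsequent members chained from their predecessor. The
`near_linear` geometry places the two outer members of a three-chain on
approximately opposite sides of the middle one (second angle =
first + π + N(0, 0.2²)), emulating stretched nanorulers; `curled` uses
independent uniform angles, as in the four-color study. All coordinates
are rounded to the integer pixel grid; a chain with any member off-grid
is redrawn whole. Rounding can make particles coincide — they are kept,
and distance 0 is a valid match.

Per-channel Bernoulli thinning implements incomplete labeling on point
patterns; `simulate_misdetection_counts` draws the multinomial
observation model directly at the abundance level, which validates the
correction machinery without any imaging in the loop.

Rendering superimposes isotropic Gaussian spots with **peak expected
signal 100 counts** over a **flat background of mean 1 count** (10 in the
high-noise mode) and draws per-pixel Poisson counts. The absolute
intensity scale is the package's own choice — detection statistics, not
radiometry, are what the simulation is meant to reproduce — and both
knobs are exposed in `SimScenario`.

What the simulator does *not* model: fluorophore blinking and multiple
localizations per particle, chromatic aberration and drift, anisotropic
or spatially varying PSFs, clustered/misfolded structures, autofluorescent
background structure. Passing the recovery tests therefore demonstrates
correctness of the matching and correction machinery under the stated
point-process model, not robustness to every experimental artifact.

## Spot detection

The analysis pipeline treats detection as pluggable; the built-in
detector is deliberately plain: Gaussian smoothing (σ = 0.8 px), local
maxima above an absolute threshold (20 counts on the smoothed image)
separated by ≥ 2 px, optional subpixel refinement by an
intensity-weighted centroid in a 3×3 window (background-insensitive via
local-minimum subtraction). On low-noise rendered images with
well-separated particles it achieves ≥ 99% recall and precision
(round-trip tested). Same-channel particles closer than the separation
limit merge into one detection — visible in the studies as a ~2% loss of
particles per channel, which the relative-abundance scaling largely
cancels. No blob segmentation, PSF fitting or deconvolution.

## Validation studies and problem sizes

`scripts/acceptance.py` re-runs, per invocation: the three simulation
scenarios (singlets only; singlets + pairs; triplets + pairs + singlets)
at 25 images each through the full simulate→render→detect→match pipeline
at t = 5 px for both modes, reporting the worst median and IQR of signed
relative-abundance errors over chain structures (pairs/triplets; singlet
errors at 125 nm include irreducible chance-proximity matches and are
reported by the study module but are not part of the chain-detection
benchmark); the four-color scenario (100 curled quadruplets per image,
tenfold background) at 25 images with Mode II; and 10,000 multinomial
draws at n = (500, 50, 50, 50, 50, 50), s ≡ 0.95 for estimator mean and
90%-region coverage. Batch sizes were chosen so a full run takes well
under a minute on one core while keeping Monte-Carlo error far below the
tolerances being checked; the image batches use one derived seed per
image so every quantity is reproducible from the single `--seed`
argument.

## Known limitations

- Dense scenes are fundamentally ambiguous: beyond a certain particle
  density no matcher can distinguish biological from chance proximity;
  Mode I degrades most gracefully, greedy pairing worst.
- Mode I's leftover priority can reassign contested particles; different
  priority orders give different (each internally optimal) results.
- The χ² region is asymptotic; at small true abundances (entries ≲ 20)
  coverage can deviate from the nominal level.
- The matcher's output is invariant only up to cost ties; consumers must
  not rely on which cost-equal assignment is returned.
- Tree-shaped (non-chain) structure costs do not admit the flow
  reduction and are not supported.
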