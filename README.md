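# chainmatch

Geometry-informed colocalization analysis for multi-color super-resolution
microscopy: detect **chain-like particle assemblies** — ordered tuples with
exactly one particle per color channel and every adjacent pair within a
colocalization distance *t* — in coordinate data from STED or
localization microscopy, and statistically correct the detected structure
abundances for incomplete labeling efficiencies.

Intended for quantitative bio-image analysts studying complexes with a
known linear geometry and stoichiometry (e.g. multiple labeled loci along
an mRNA or DNA strand, or DNA-origami nanorulers): generic pairwise
colocalization tools overestimate multi-color assemblies because one
particle may be counted in several structures; a one-to-one chain matching
does not.

## Model

Given per-channel point clouds X⁽¹⁾, …, X⁽ᵏ⁾, a *d_t^k-chain* is a tuple
(x⁽¹⁾, …, x⁽ᵏ⁾), x⁽ʲ⁾ ∈ X⁽ʲ⁾, with d(x⁽ʲ⁾, x⁽ʲ⁺¹⁾) ≤ t for all j. The
matcher finds a maximal set of pairwise-disjoint chains, and among all
maximal sets one with minimal summed adjacent-pair distance. This is an
unbalanced multi-marginal optimal-transport problem with chain cost

    c(x₁,…,x_k) = Σⱼ d(xⱼ, xⱼ₊₁) − λ    (admissible only if every d ≤ t)

whose chain structure lets it be solved exactly as an **integer min-cost
network flow** (one split node pair per particle, adjacent-channel edges
only within t, a free source→sink edge for unmatched mass), rather than as
an intractable n₁·n₂⋯n_k-variable linear program. Two matching semantics:

- **Mode I** — maximize full chains first, then re-match the leftovers
  with shorter-chain problems in a priority order (best when one target
  structure is known; robust in dense scenes);
- **Mode II** — match each adjacent channel pair independently and couple
  pairs sharing a particle into longer chains (no prioritization; best
  when several structures are equally plausible).

With per-channel labeling efficiencies s_i ∈ (0,1] a true chain is only
partially observed: each particle is detected independently with
probability s_i and the maximal contiguous runs of the surviving pattern
are counted as shorter structures. Observed abundances **W** then satisfy
E[W] = Θμ **n**, where **n** are the true abundances, μ stacks the
per-structure multinomial pattern probabilities and Θ credits pattern runs
to observable structures. The package computes the unbiased estimator

    n̂ = (Θμ)⁻¹ W

its asymptotic covariance, the chi-squared statistic
Ξ = (n̂−n₀)ᵀ(Θμ)ᵀ(ΘΣ(n̂)Θᵀ)⁻¹(Θμ)(n̂−n₀), joint confidence ellipsoids and
per-structure intervals, for any number of channels.

A synthetic STED simulator (chains with 70 nm spacing on a 400×400 px,
25 nm/px grid, Gaussian PSF of 40 nm FWHM, Poisson noise) and a
local-maxima spot detector close the loop from ground truth to intensity
images and back.

## Worked example

Simulate one three-color image with 100 triplets, 50 AB and BC pairs and
50 singlets per channel, render and detect it, and match at t = 5 px:

```python
import numpy as np
from chainmatch import (SimScenario, simulate_chain_points, render_sted_image,
                        detect_spots_multichannel, MatchConfig, match)

sc = SimScenario(k=3, structure_counts={"ABC": 100, "AB": 50, "BC": 50,
                                        "A": 50, "B": 50, "C": 50}, seed=7)
rng = np.random.default_rng(7)
gt = simulate_chain_points(sc, rng)
clouds = detect_spots_multichannel(render_sted_image(gt, sc, rng))
matching, w = match(clouds, MatchConfig(t=5.0, mode="I"))
print(clouds.counts)   # (197, 244, 199)  — of 200/250/200 simulated
print(w.w)             # {'ABC': 104, 'AB': 45, 'BC': 49, 'A': 48, 'B': 46, 'C': 46}
```

The matcher recovers the simulated mixture: 104 detected triplets vs 100
true ones (a few extra from chance proximity at 125 nm), with every
particle in exactly one structure. Correct an observed abundance vector
for 95% labeling efficiency and attach 90% confidence intervals:

```python
from chainmatch import (EfficiencyModel, estimate_true_abundances,
                        confidence_region, simulate_misdetection_counts)

eff = EfficiencyModel([0.95, 0.95, 0.95])
n_true = np.array([500, 50, 50, 50, 50, 50])
W = simulate_misdetection_counts(n_true, eff, rng)   # [432 64 76 63 56 64]
est = estimate_true_abundances(W, eff)
region = confidence_region(est, alpha=0.1)
print(est.n_hat[0])                  # 503.86
print(region.intervals["ABC"])       # (497.00, 510.73)
```

The raw observation undercounts triplets (432 of 500) because a triplet
missing one member is seen as a pair or two singlets; the corrected
estimate 503.9 [497.0, 510.7] recovers the truth.

The same workflows are available from the shell via the `chainmatch` CLI
(`match`, `curve`, `correct`, `simulate`, `detect`, `evaluate`), which
reads per-channel `x,y[,z]` CSVs or multi-page TIFFs and writes CSV
results plus a manifest with the full configuration and seed.

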