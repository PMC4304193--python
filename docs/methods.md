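# Methods

## The problem

Given K independent studies of the same hypothesis, each reporting only a
p-value `p_i`, we want a single test of the global null that no study has an
effect. Under that null the `p_i` are i.i.d. Uniform(0,1); every combiner in
this package is a deterministic transform of the p-value vector whose null
distribution follows from that fact. The package covers the classical
z-based and chi-square/gamma quantile-sum families, and an adaptive-shape
gamma statistic designed for the regime where a few studies carry most of
the signal (a common situation in GWAS meta-analysis with heterogeneous
effects, and in set-based rare-variant testing).

## The combiners

**Weighted z family.** `Z_W = Σ w_i Φ⁻¹(p_i) / √(Σ w_j²)` is standard normal
under the null for any fixed positive weights. We treat inputs as one-sided
p-values with "small = evidence for the shared alternative", so `Z_W` is
negative under the alternative and the combined p-value is `Φ(Z_W)`; this
convention is pinned down by the K=1 identity (combining a single p-value
must return it). Unit weights give the Stouffer test (`z`); weights `n_i`
the Mosteller–Bush test (`z_n`); `√n_i` and `1/se_i` are the other common
variants (`z_sqrt_n`, `z_se`). Only weight ratios matter, so weights are
used exactly as supplied.

**Quantile-sum family.** Fisher's statistic `−2 Σ ln p_i` is chi-square with
2K df. Lancaster generalizes it to `Σ F⁻¹_{d_i}(1−p_i)` (per-study
chi-square quantiles), chi-square with `Σ d_i` df under the null; the
Chen–Nadarajah (CN) test is the `d_i = 1` case. The gamma combiner
`T = Σ G⁻¹_{α_i,β}(1−p_i)` generalizes further: for fixed shapes the null
of T is gamma(`Σ α_i`, β), and the combined p-value is invariant to the
scale β (it rescales statistic and null identically — checked numerically).
Setting `α_i = v/2, β = 2` recovers Lancaster with df v.

**Adaptive-shape gamma test** (`new`). Shapes are chosen from the data:
`α_i = 1/p_i`, scale 1, so `T = Σ G⁻¹_{1/p_i,1}(1−p_i)`. A gamma variate
with shape α and scale 1 has mean α, so a study with a small p-value
contributes a term with a large expected value — the test adaptively
up-weights strong studies, which is what makes it powerful under sparse,
heterogeneous effects. Because the shapes are random, T is no longer gamma
distributed; its p-value is estimated by resampling: draw K i.i.d.
uniforms, compute T, repeat N times, and take the exceedance proportion of
the observed statistic.

A note on one reading of CN: it can also be presented as a weighted z-test
with weight `|Φ⁻¹(p_i)|`. For mixed-direction p-values that reading is not
algebraically identical to Lancaster with df 1; this package implements the
Lancaster df=1 reading, which is the one the collapse identities pin down.

## Monte-Carlo null

- **Estimator**: `p̂ = (#{t ≥ T_obs} + 1)/(N + 1)`, inclusive ties. The
  add-one correction keeps p̂ strictly positive, so it is a valid p-value at
  any level; it differs from the raw proportion by O(1/N). Reported
  standard error: `√(p̂(1−p̂)/N)`.
- **Default N = 10⁶** for data analysis (relative error ~1% at p ≈ 0.008),
  10⁵ inside simulation loops. N is everywhere a parameter; the stderr
  field makes the attained precision explicit. P-values below 1/(N+1)
  cannot be resolved — there is no tail extrapolation.
- **Determinism**: a null store is keyed by (K, N, seed) and regenerating it
  reproduces identical samples. Stores can be cached on disk as raw
  little-endian float64 arrays (`null_K{K}_N{N}_seed{seed}.f64`).
  Generation is blocked (10⁵ draws per block) to bound memory; the block
  size is internal and only affects draw order, not the distribution.
- **Lookup** is a binary search on the sorted store.

## Numerical choices

- Inputs are validated to [0,1]; exact 0/1 are clipped to
  `[1e-15, 1−1e-15]` with a warning so quantile transforms stay finite.
- The upper gamma quantile is the inverse regularized incomplete gamma
  (`gammainccinv`). Above shape 10⁸ (p-values below 10⁻⁸) it switches to
  the Wilson–Hilferty cube-root normal approximation
  `α(1 − 1/(9α) + z/(3√α))³`; both branches agree to ~10⁻⁷ relative at the
  switchover (tested), so the boundary is not a discontinuity in practice.
- The adaptive statistic is strictly decreasing in each `p_i` (quantile
  monotone in shape and tail probability together); a property test
  enforces this.

## Simulation engine

Each replicate simulates K two-group studies: group 1 ~ N(0, σ²), group 2 ~
N(μ_i, σ²), n observations per group, and the study's p-value is the
one-sided pooled-variance two-sample t-test for mean₂ > mean₁. Effect
allocation helpers produce the two designs studied: a K=2 split of a total
effect in a given ratio, and "i of K studies each carry total/i".

Design choices where the design was genuinely open:

- **One-sided p-values feed all combiners** (a `two_sided` switch exists for
  sensitivity analysis). The z family needs directional p-values to be
  meaningful, and the CN construction is defined in terms of one-sided
  p-values; a two-sided choice would have left the z-tests powerless
  against a common direction.
- **Pooled-variance t-test**, since the two groups share σ by construction.
- **Random designs**: per-group sample sizes may be Poisson(λ) — redrawn
  below a floor of n_min=2 so the t-test is always defined (for Poi(20)
  this triggers with probability ~5·10⁻⁸) — and σ may be gamma(shape,
  scale) distributed, defaults gamma(10, 0.1) (mean 1).
- **Weighted methods use the replicate's realized quantities**: `z_n` the
  realized per-study total sample size, `z_se` the realized estimated
  standard error of the mean difference.
- **One null store per (K, N)** is built before the replicate loop and
  shared by all replicates; its draws are independent of the data stream
  (seeded at an offset), so the rejection rule is a fixed data-independent
  threshold, at the cost of a small common noise in that threshold
  (SD ≈ √(α(1−α)/N) on the attained level).
- The replicate loop is vectorized by sampling each study's t-statistic
  from sufficient statistics — group means are normal, the pooled variance
  is σ²·χ²_{2n−2}/(2n−2) — which is exactly the t-statistic's sampling
  distribution. The scalar `simulate_study_pvalue` keeps the literal
  per-observation draw and is checked against a closed-form noncentral-t
  power oracle.
- Default problem sizes: 10⁴ replicates for type-I error estimation and
  2·10³ for power comparisons, with binomial standard errors reported
  alongside every estimate; both are parameters.

## What the generator emulates — and does not

The synthetic studies are ideal two-group normal experiments with exactly
the stated effect allocation and independent studies throughout. Real
meta-analyses add ingredients the generator deliberately omits: correlated
studies (overlapping cohorts, linkage between variants in set-based tests),
non-normal outcomes, publication bias in which p-values are available, and
effect directions that flip between studies. Passing tests therefore
demonstrate calibration and relative power under clean heterogeneity, not
robustness to correlation — the combiners here all assume independent
p-values, and the adaptive test's resampled null is only valid under that
assumption (a permutation null would be needed for correlated inputs,
which is out of scope).

## Count-table application

For per-study 2×2 case/control tables the per-study test is the pooled
two-proportion z-test, two-sided, no continuity correction, treating counts
as subject counts. On the packaged five-study depression GWAS table this
reproduces the published per-study p-values 0.94/0.97/0.81 for studies 1,
3, 5 at two decimals; studies 2 and 4 come out 0.0014 and 0.80 against
published 0.0015 and 0.79 (the original analysis did not state its test —
allele-count or likelihood-ratio variants, or rounding, would explain the
last digit). The published p-values can therefore be supplied directly to
the pipeline, and they are the canonical fixture. For the weighted z-tests
on count data, `z_n` uses the study's total sample size and `z_se` the
reciprocal pooled two-proportion standard error (the published analysis did
not specify which standard error).

Reproduction caveat: from the five published p-values the package
reproduces the published combined values for the unweighted z (0.83 vs
0.84), Fisher (0.169 vs 0.17) and the adaptive test (~0.008 vs 0.0081).
The published Z_n (0.53), Z_se (0.29) and CN (0.062) do not follow from
any reading of the stated formulas we tried (we get 0.21, 0.76, 0.069);
those three are reported by the package as computed, not as published.

## Known limitations

- Independent p-values only; no correlated/permutation extension.
- No effect-size (fixed/random-effects) meta-analysis — inputs are
  p-values or 2×2 counts by design.
- MC p-values are bounded below by 1/(N+1); choose N for the resolution
  needed.
- The adaptive test trades power under homogeneous effects (where z-tests
  win, by ~10 percentage points in the K=2 equal-split condition we
  measure) for large gains under sparse heterogeneous effects; it is a
  complement to, not a replacement for, Fisher/CN.
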