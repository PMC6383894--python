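# Methods

## Model and sampling assumptions

A diallelic X-chromosomal marker is observed in two independent samples:
n₁ females with genotype counts (X₁, X₂, X₃) ~ multinomial(n₁; π₁, π₂, π₃)
for AA/AB/BB, and n₂ hemizygous males whose A-allele count Y ~
binomial(n₂; p_Y). Allele A is whatever the input encodes first; no
minor-allele re-orientation is performed. This is justified by the
relabeling symmetry of the procedure: swapping the allele labels
(π₁↔π₃, p_Y↔1−p_Y) leaves the female component invariant (log REH is
symmetric in the homozygote frequencies), negates the male component,
and leaves the combined distance and the test decision unchanged (the
test statistic is invariant to 1e-12, property-tested).

HWE on the X chromosome requires both π₂² = 4π₁π₃ (random mating among
females) and p_X = π₁ + π₂/2 = p_Y (equal allele frequencies across
sexes). Distance from the model is the Euclidean norm Δ of the signed
pair (Δf±, Δm±) defined in the README. Asymptotics are taken with
n₁/N → λ ∈ (0,1), N = n₁ + n₂.

## Parameters that matter

| parameter | meaning | default | rationale |
|---|---|---|---|
| α | one-sided level | 0.05 | conventional QC level |
| ε | equivalence margin on Δ (log units) | √2·log 1.4 ≈ 0.47584 | radius of the smallest circle containing the square with half-edge log 1.4, the established per-component margin for log REH; the log-odds-ratio literature's looser 0.41 is deliberately not used — the tighter component margin governs |
| sparse_policy | zero-cell handling | reject-input | the correction alters data; it must be opt-in (CLI: `--sparse-correct`) |
| convention (designs) | boundary scale τ̃ in the non-null formula | `sigma-f` (τ̃ = σ̃f) | see "Design conventions" |

A note on the margin: the circle-through-the-square derivation gives
√2·log 1.4; the occasionally quoted "2 log 1.4 ≈ 0.48" is internally
inconsistent (2·log 1.4 = 0.673) and is not used anywhere.

## Variances

σf² = (1/λ)[¼(1−π₂)/(π₁π₃) + 1/π₂] is the delta-method variance of the
√N-scaled log-REH estimate. The male component's variance is the
delta-method variance of the empirical logit difference,

σm² = 1/((1−λ) p_Y q_Y) + (π₁ + π₂/4 − p_X²)/(λ p_X² q_X²),

whose second term is Var(p̂_X) = (π₁ + π₂/4 − p_X²)/n₁ pushed through the
logit. This form is verified two ways: against a numerically
differentiated delta-method oracle built from the full multinomial /
binomial covariance matrix (to 1e-6 relative), and against four published
σm/σf ratios (1.22475, 1.12250, 1.00000, 0.73485) to 1e-5.

τ² = (Δf²σf² + Δm²σm²)/Δ² is undefined at Δ = 0. Convention: the
symmetric equal-weight mean (σf² + σm²)/2. Outcomes with Δ̂ = 0 occur
with positive probability in finite samples, but at every tabulated
setting any convention between σf² and σm² yields the same decision (the
bound is far below ε there); the symmetric limit is the least arbitrary.

## The test and degenerate counts

Reject H₀: Δ ≥ ε iff Δ̂ + z₁₋α τ̂/√N < ε, with λ replaced by n₁/N in the
plug-in τ̂. No continuity corrections anywhere.

Counts with a zero cell among {x₁, x₂, x₃, y, n₂−y} leave the logs
undefined. Programmatic default: a distinct `DegenerateCountsError`.
Opt-in correction (standard sparse-contingency-table practice): each
zero cell is set to 1 and the total added is compensated from the
largest cell of the same sex stratum, preserving n₁ and n₂; inputs too
small to compensate raise `UnrecoverableSparsityError`.

Inside the exact engine, degenerate outcomes are simply non-rejections:
a conservative test cannot reject where its statistic is undefined. This
convention reproduces the published exact level at the rare-allele
boundary configuration (π₁ = 0.00564, n = 400 per sex → 0.00726), which
discriminates it from the alternative of correcting inside the sum.

## Exact engine

The rejection probability is the triple sum of trinomial × binomial
masses over the critical region. Masses are computed in log space via
log-gamma (n per sex beyond 1600 poses no overflow risk). Enumeration
vectorizes chunks of (x₁, x₂) pairs against the full y range; only
all-positive outcomes are enumerated (degenerate ones cannot reject).
No monotonicity in y is assumed — the bound is not monotone in y through
Δ̂ and τ̂ jointly. Pruning is off by default; an optional threshold skips
low-mass (x₁, x₂) pairs and reports the skipped mass, which bounds the
(one-sided) error. Problem sizes: n = 100 per sex runs in ~0.2 s,
n = 400 in ~1–2 s, n = 800 in ~25 s on one CPU; the test suite and the
reproduction script use exactly these sizes.

The engine is validated by exact agreement (1e-12) with a naive
per-outcome brute force over random configurations at n ≤ 12, and by
reproducing published five-decimal rejection probabilities at n = 100
and 400.

## Extended χ distribution

Under null alternatives √N·Δ̂ ⇒ σf·√(Z₁² + c²Z₂²), c = σm/σf. The CDF

Q_c(q) = 2∫₋q^q Φ(√(q²−z²)/c) φ(z) dz − (2Φ(q) − 1)

is evaluated by composite Gauss–Legendre quadrature, 96 nodes × 10
panels, after the substitution z = q·sin θ. The substitution matters:
the raw integrand has a square-root endpoint singularity that stalls the
composite rule near 1e-8 absolute error, while the transformed integrand
is smooth and the same node budget reaches ~1e-12 (closed form at c = 1
agrees to 1e-9 across q ∈ [0,6]; 10⁷-draw Monte-Carlo agreement within
4 SE for c ∈ {0.6, 0.9, 1.5}). Quantiles by bracketed root-finding with
upper bracket max(1,c)·√(−2 log(1−p)). Only k = 2 degrees of freedom is
implemented — the only case the limit theory needs.

## Design conventions

Conjugate boundary point: for an alternative with AA-frequency π₁*, the
planning formulas evaluate "boundary" variances at the point with
π̃₁ = π₁* and both signed components equal to +ε/√2 (so Δ = ε). The
per-component value ε/√2 — not ε/2 — is what places the point on the
circle of radius ε; it also makes the balanced uniform-allele boundary
configuration the conjugate of the uniform null alternative, consistent
with all downstream reproductions.

Boundary scale τ̃ in the non-null formula
N = (τ̃ z₁₋α + τ z₁₋β)²/(Δ*−ε)²: the literal weighted-mean variance at a
diagonal conjugate point is the average of σ̃f² and σ̃m² (`weighted-mean`
convention), but the published sample-size table is reproduced — all six
size pairs exactly — only with τ̃ = σ̃f (`sigma-f` convention, the
default). Both are implemented and the choice is recorded in
`DesignResult.convention`; with `weighted-mean` the first tabulated design gives
n₁ = 541 instead of 485. This is a genuine ambiguity in the source
method description, resolved empirically in favor of table reproduction.

Null-alternative formula: N = (z₁₋α·max{σ̃f, σ̃m} + σf·Q_c⁻¹(1−β))²/ε²,
using max{σ̃f, σ̃m} rather than τ̃ (the refinement that markedly improves
the approximation) and the extended-χ quantile at c = σm/σf evaluated at
the null alternative.

Rounding: N is rounded up to the next total for which both λN and
(1−λ)N are integers (λ is a design fraction a/b; N' = b·⌈N/b⌉, n₁ = a·⌈N/b⌉).
This reproduces every published size pair, including the λ = 2/3 case
where the naive n₁ = ⌈λN⌉ is off by one; for λ that is not a small
fraction the naive rule is the fallback.

## Synthetic data and the Monte-Carlo harness

The sampler draws counts from the model itself: multinomial female
genotypes and an independent binomial male count, with numpy's
`default_rng` seeded from a single master seed (vectorized draws;
bit-reproducible for a fixed seed and numpy version). It therefore
emulates exactly the sampling assumptions of the test — independent
sexes, no genotyping error, no population structure, no missingness, no
linkage between markers. Passing Monte-Carlo checks consequently
validate the *statistical procedure under its own model*, not
robustness to real-data artifacts such as differential missingness by
sex or batch effects.

The comparator is the combined 2-df lack-of-fit statistic: a 1-df
Pearson HWE χ² among females plus a 1-df 2×2 allele-table χ² comparing
female allele counts (2x₁+x₂, x₂+2x₃) with male counts (y, n₂−y),
without continuity correction. Published comparisons of this family of
tests vary in details (exact vs asymptotic, corrections), so the
comparator's rates are indicative; the harness asserts only its
qualitative pathologies (anti-conservatism at small n, power capped near
1−α and non-increasing in n), which are variant-robust. Degenerate
replicates follow each procedure's own policy: the equivalence test
never rejects them, the χ² statistic uses sparse-corrected counts.

## Known limitations

- Diallelic markers only; no multiallelic extension.
- The test is asymptotic and conservative in finite samples: at the
  hypotheses' boundary the exact level at n = 100 per sex is ~0.01, and
  even at n > 1000 it remains ~1% below nominal. The exact engine is
  provided precisely so users can check attained level/power.
- No multiple-testing adjustment across SNPs; the test is per marker.
- Per-SNP statistics assume the rounded printed inputs when reproducing
  published configurations; five-decimal parameter rounding propagates
  ~1e-4 into distances, which the reproduction tolerances reflect.
- The non-null power approximation is known to degrade when females far
  outnumber males (λ large); the null-alternative formula is accurate to
  within ~3% of target power except at low targets.
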