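# xhwe — establishing (not refuting) Hardy–Weinberg equilibrium for X-chromosomal SNPs

Quality control of genetic association studies routinely filters SNPs by a
Hardy–Weinberg equilibrium (HWE) check. For markers on the X chromosome
this is complicated by hemizygous males: females contribute genotype
triples (AA/AB/BB), males a single allele, and the marker is in HWE only if
the female genotype distribution sits on the HWE curve **and** the allele
frequencies agree between the sexes. The common practice — run a χ²
lack-of-fit test and keep the SNP when p > 0.05 — controls nothing: the
"confirmation" rate can reach 95% for truly disequilibrated markers in
small samples, while in huge samples near-perfect markers get discarded.

`xhwe` implements the opposite, logically sound formulation as an
**equivalence (goodness-of-fit) test**, together with its exact
finite-sample operating characteristics and closed-form study planning.
It is aimed at statistical geneticists running X-chromosome QC and at
methodologists studying equivalence tests for categorical models.

## The statistic

For female genotype frequencies (π₁, π₂, π₃) and male A-allele frequency
p_Y, disequilibrium is measured on the log scale by two signed components

- Δf± = log π₂ − (log π₁ + log π₃)/2 − log 2  (log relative excess
  heterozygosity; 0 on the HWE curve),
- Δm± = logit(p_X) − logit(p_Y), with p_X = π₁ + π₂/2  (log odds ratio
  between the sexes' allele frequencies; 0 when they agree),

combined as Δ = √(Δf² + Δm²). The hypotheses are H₀: Δ ≥ ε versus
H₁: Δ < ε with default margin ε = √2·log 1.4 ≈ 0.4758. With plug-in
estimates from counts (x₁, x₂, x₃; y of n₂) the test **rejects H₀ — i.e.
establishes approximate HWE compatibility — iff**

    Δ̂ + z₁₋α · τ̂ / √(n₁+n₂)  <  ε ,

where τ̂² is the delta-method variance of √N·Δ̂ (a weighted mean of the
component variances σ̂f², σ̂m²). Because under perfect HWE (Δ = 0) the
limit of √N·Δ̂ is non-Gaussian — σf·√(Z₁² + c²Z₂²) with c = σm/σf, an
*extended χ* variable — power and sample size against such "null
alternatives" use this distribution's CDF/quantile, computed here by
high-accuracy quadrature. An exact engine enumerates the full
trinomial × binomial outcome space to give the test's exact level and
power at any configuration.

## Worked example

```sh
xhwe test --input tests/data/geneva.tsv --sparse-correct
```

```
snp_id      n1   x1   x2   x3  n2   y    delta_hat  tau_hat_sq  upper_bound  decision  corrected
rs6646338   651  230  314  107 604  399  0.2835     13.2641     0.4526       +         0
rs12010339  651  651  0    0   605  603  3.9475     1568.4547   5.7856       -         1
rs5935567   651  231  337  83  605  372  0.1964     8.8719      0.3346       +         0
rs5968922   651  275  296  80  604  392  0.0040     12.1492     0.1658       +         0
```

Three SNPs get a "+": their upper 95% confidence bound on Δ falls below
ε = 0.4758, so approximate HWE compatibility is *established* at the 5%
level. rs12010339 is monomorphic among females (two zero cells,
handled by the opt-in sparse-table correction); its distance estimate is
huge and the bound (5.79) vastly exceeds the margin, so compatibility is
not established.

Planning from Python (see `examples/` for more):

```python
>>> from xhwe import FemaleGenotypeFreqs, PopulationConfig, sample_size_null
>>> null_alt = PopulationConfig(FemaleGenotypeFreqs(0.25, 0.5, 0.25), 0.5, 0.5)
>>> d = sample_size_null(null_alt, power_target=0.80)
>>> d.n1, d.n2
(279, 279)
```

279 females and 279 males suffice for 80% power to certify a SNP with
allele frequency 0.5 that is truly in perfect HWE.

Other CLI subcommands: `exact-power` (exact enumeration), `power-approx`,
`samplesize`, `simulate` (comparison with the inverted χ² rule), `qchi`
(extended-χ CDF/quantile). Counts tables are plain TSV/CSV with columns
`snp_id, x1, x2, x3, n2, y`; a recipe for producing them from VCF/PLINK
files is in the `xhwe.io` module docstring.

## Layout

- `src/xhwe/` — measures, variances, the test, extended-χ kernel, exact
  engine, design formulas, comparator/Monte-Carlo harness, I/O, CLI
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, conventions, numerics and limitations
- `tests/` — pytest suite (unit, hypothesis property tests, reproduction)
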