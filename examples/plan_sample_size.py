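"""Plan the sample size needed to establish HWE compatibility.

Two closed-form designs: against a *null alternative* (the truth is in
perfect HWE — the best case) using the extended-chi quantile, and
against a *non-null alternative* halfway to the margin using the normal
approximation.  lam is the fraction of females among all subjects.
"""

from xhwe import (
    FemaleGenotypeFreqs,
    PopulationConfig,
    sample_size_nonnull,
    sample_size_null,
)

# perfect HWE with common allele frequency 0.5, equal numbers of sexes
null_alt = PopulationConfig(FemaleGenotypeFreqs(0.25, 0.5, 0.25), 0.5, 0.5)
for power in (0.60, 0.80, 0.90):
    d = sample_size_null(null_alt, power_target=power)
    print(
        f"null alternative, target power {power:.0%}: "
        f"n1 = {d.n1} females, n2 = {d.n2} males (N formula = {d.N_total:.1f})"
    )

# an alternative at half the equivalence margin (both components equal)
alt = PopulationConfig(FemaleGenotypeFreqs(0.25, 0.54097, 0.20903), 0.47846, 0.5)
d = sample_size_nonnull(alt, power_target=0.80)
print(
    f"\nnon-null alternative at half margin, target power 80%: "
    f"n1 = {d.n1}, n2 = {d.n2} "
    f"(boundary-scale convention: {d.convention})"
)
print(
    "\nRarer alleles need far larger samples: the female variance term\n"
    "grows like 1/(pi1 pi3), so planning should use realistic frequencies."
)
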