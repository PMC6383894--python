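"""Why 'p > 0.05 in a chi-square test' is not evidence of HWE.

Simulates SNP counts under (a) a truth with relevant disequilibrium
(combined distance exactly at the margin) and (b) perfect HWE, then
applies both the equivalence test and the inverted lack-of-fit rule
(declare HWE when the combined chi-square p-value exceeds 5%).
"""

from xhwe import FemaleGenotypeFreqs, PopulationConfig, monte_carlo_compare

REPS = 50_000

boundary = PopulationConfig(
    FemaleGenotypeFreqs(0.09, 0.52274, 0.38726), 0.27899, 0.5
)
null_alt = PopulationConfig(FemaleGenotypeFreqs(0.09, 0.42, 0.49), 0.3, 0.5)

print(f"{REPS} replicates per experiment; rates of 'declare HWE-compatible':\n")
for label, cfg in [("relevant disequilibrium", boundary), ("perfect HWE", null_alt)]:
    for n in (100, 1200):
        r = monte_carlo_compare(cfg, n, n, REPS, seed=2026)
        print(
            f"  truth: {label:24s} n1=n2={n:5d}  "
            f"equivalence test: {r.gof_rate:.4f}  inverted chi2: {r.inverted_rate:.4f}"
        )

print(
    "\nUnder relevant disequilibrium the inverted rule 'confirms' HWE ~60%\n"
    "of the time at n=100 (the equivalence test stays below its 5% level),\n"
    "while under perfect HWE its rate is stuck near 95% regardless of n —\n"
    "the equivalence test's power instead grows to 1 with the sample size."
)
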