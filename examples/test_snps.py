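"""Test four X-chromosomal SNPs for approximate HWE compatibility.

The counts are the published GENEVA venous-thrombosis examples: female
genotype counts (AA/AB/BB) and male A-allele counts.  A "+" decision
means the upper 95% confidence bound on the combined disequilibrium
distance falls below the margin sqrt(2)*log(1.4) ~ 0.476, i.e. the SNP
is established as approximately HWE-compatible; "-" means compatibility
could not be established.
"""

from xhwe import SnpCounts, TestSettings, run_table

records = [
    SnpCounts("rs6646338", 230, 314, 107, 604, 399),
    SnpCounts("rs12010339", 651, 0, 0, 605, 603),   # sparse: two zero cells
    SnpCounts("rs5935567", 231, 337, 83, 605, 372),
    SnpCounts("rs5968922", 275, 296, 80, 604, 392),
]

frame = run_table(records, TestSettings(sparse_policy="auto-correct"))
print(frame.to_string(index=False))
print(
    "\ndelta_hat = combined distance estimate; upper_bound < 0.4758 => '+'.\n"
    "rs12010339 is monomorphic in females up to sparse correction: its\n"
    "distance is huge and compatibility is (correctly) not established."
)
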