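from pathlib import Path

import pytest

from xhwe import FemaleGenotypeFreqs, PopulationConfig, SnpCounts

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture
def geneva_path() -> Path:
    return DATA_DIR / "geneva.tsv"


@pytest.fixture
def geneva_counts() -> list[SnpCounts]:
    """The four GENEVA venous-thrombosis SNPs (printed counts)."""
    return [
        SnpCounts("rs6646338", 230, 314, 107, 604, 399),
        SnpCounts("rs12010339", 651, 0, 0, 605, 603),
        SnpCounts("rs5935567", 231, 337, 83, 605, 372),
        SnpCounts("rs5968922", 275, 296, 80, 604, 392),
    ]


def make_config(pi1, pi2, pY, lam=0.5) -> PopulationConfig:
    return PopulationConfig(FemaleGenotypeFreqs(pi1, pi2, 1.0 - pi1 - pi2), pY, lam)


def hwe_null(p, lam=0.5) -> PopulationConfig:
    """Perfect-HWE configuration with common allele frequency p."""
    return PopulationConfig(
        FemaleGenotypeFreqs(p * p, 2 * p * (1 - p), (1 - p) ** 2), p, lam
    )
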