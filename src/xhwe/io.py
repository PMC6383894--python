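"""Reading per-SNP count tables and writing test results.

The input format is a minimal delimited table mirroring the way such
counts are reported: one row per SNP with columns ``snp_id, x1, x2, x3,
n2, y`` (tab- or comma-separated; ``n1`` is derived as x1+x2+x3).  To
produce it from standard genotype files, tabulate female genotype calls
(AA/AB/BB) and male hemizygous calls (A/B) per marker — e.g. with
``bcftools query`` plus a groupby, or PLINK's ``--freqx`` split by sex —
and write the five counts per line.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import pandas as pd

from .equivtest import TestResult, TestSettings, decide
from .errors import XhweError
from .measures import SnpCounts

__all__ = ["CountsTable", "read_counts", "run_table", "write_results", "RESULT_COLUMNS"]

REQUIRED_COLUMNS = ("snp_id", "x1", "x2", "x3", "n2", "y")
RESULT_COLUMNS = (
    "snp_id",
    "n1",
    "x1",
    "x2",
    "x3",
    "n2",
    "y",
    "delta_hat",
    "tau_hat_sq",
    "upper_bound",
    "decision",
    "corrected",
)


@dataclass
class CountsTable:
    """Validated SNP count records plus per-row error report."""

    records: list[SnpCounts] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def read_counts(path, *, strict: bool = True) -> CountsTable:
    """Read a counts table from a TSV/CSV file.

    Row-level validation failures (negative counts, y > n2, non-integer
    fields) are collected with their line numbers.  With ``strict=True``
    (default) any such failure raises ``ValueError`` carrying the full
    report; with ``strict=False`` the valid rows are returned alongside
    the error list.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    except (pd.errors.EmptyDataError, csv.Error):
        logging.getLogger("xhwe").warning("%s: empty counts file", path)
        return CountsTable()
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")

    table = CountsTable()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            counts = SnpCounts(
                snp_id=str(row["snp_id"]).strip(),
                x1=int(row["x1"]),
                x2=int(row["x2"]),
                x3=int(row["x3"]),
                n2=int(row["n2"]),
                y=int(row["y"]),
            )
        except (ValueError, TypeError, XhweError) as exc:
            table.errors.append(f"{path}:{line}: {exc}")
            continue
        table.records.append(counts)
    if strict and table.errors:
        raise ValueError("invalid rows in counts table:\n" + "\n".join(table.errors))
    return table


def run_table(
    records: list[SnpCounts], settings: TestSettings | None = None
) -> pd.DataFrame:
    """Run the equivalence test on each record; return a result frame
    with one row per SNP (columns :data:`RESULT_COLUMNS`)."""
    settings = settings or TestSettings()
    rows = []
    for counts in records:
        result: TestResult = decide(counts, settings)
        rows.append(
            {
                "snp_id": counts.snp_id,
                "n1": counts.n1,
                "x1": counts.x1,
                "x2": counts.x2,
                "x3": counts.x3,
                "n2": counts.n2,
                "y": counts.y,
                "delta_hat": round(result.delta_hat, 4),
                "tau_hat_sq": round(result.tau_hat_sq, 4),
                "upper_bound": round(result.upper_bound, 4),
                "decision": "+" if result.reject_null else "-",
                "corrected": int(result.corrected),
            }
        )
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(frame: pd.DataFrame, path) -> None:
    """Write a result frame as TSV."""
    frame.to_csv(path, sep="\t", index=False)
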